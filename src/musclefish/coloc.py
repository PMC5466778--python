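"""Dot-to-nucleus assignment and per-nucleus (co-)transcription tabulation.

A nucleus is ON for a gene when at least one detected dot is assigned to it
(two dots from sister loci still count as one transcribing nucleus).  For a
gene pair the nuclei partition into {A only, B only, both, neither}, from
which the active fraction and the co-transcription fraction among active
nuclei are derived.  Also provides lineage-label (RFP-proxy) counting and
the mutual-exclusion check for genes that are never co-transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .dot_quant import DotRecord


@dataclass
class NucleusRecord:
    nucleus_id: int
    fibre_id: str
    centroid: tuple[float, float]  # (x, y)
    radius: float
    states: dict[str, bool] = field(default_factory=dict)
    lineage_label: str = "unknown"  # labelled / unlabelled / unknown
    is_fc: Optional[bool] = None


@dataclass
class CotranscriptionTable:
    fibre_id: str
    gene_a: str
    gene_b: str
    n_a_only: int
    n_b_only: int
    n_both: int
    n_neither: int

    @property
    def n_total(self) -> int:
        return self.n_a_only + self.n_b_only + self.n_both + self.n_neither

    @property
    def active_fraction(self) -> float:
        return (self.n_a_only + self.n_b_only + self.n_both) / self.n_total

    @property
    def co_given_active(self) -> float:
        active = self.n_a_only + self.n_b_only + self.n_both
        return self.n_both / active if active else float("nan")


# ---------------------------------------------------------------------------
# Nucleus segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(projection: np.ndarray, threshold: float = 10.0,
                   min_distance: int = 5) -> np.ndarray:
    """Label mask of nuclei from a nuclear-channel projection.

    Foreground by absolute threshold, touching nuclei split by watershed on
    the distance transform with peak markers at least ``min_distance``
    apart.  Returns a uint16 label image (0 = background); an image with no
    foreground yields an empty labelling.
    """
    fg = np.asarray(projection, float) > threshold
    if not fg.any():
        return np.zeros(fg.shape, np.uint16)
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=fg,
                           exclude_border=False)
    markers = np.zeros(fg.shape, np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        return ndi.label(fg)[0].astype(np.uint16)
    return watershed(-dist, markers, mask=fg).astype(np.uint16)


def nuclei_from_labels(label_mask: np.ndarray, fibre_id: str = "fibre0"
                       ) -> list[NucleusRecord]:
    """Build nucleus records (centroid + equivalent radius) from a label
    mask — either a segmentation result or ground-truth masks."""
    label_mask = np.asarray(label_mask)
    records = []
    for k in np.unique(label_mask):
        if k == 0:
            continue
        ys, xs = np.nonzero(label_mask == k)
        records.append(NucleusRecord(
            nucleus_id=int(k) - 1, fibre_id=fibre_id,
            centroid=(float(xs.mean()), float(ys.mean())),
            radius=float(np.sqrt(ys.size / np.pi))))
    return records


# ---------------------------------------------------------------------------
# Assignment and tabulation
# ---------------------------------------------------------------------------

def assign_dot_to_nucleus(dot: DotRecord, nuclei: Sequence[NucleusRecord],
                          label_mask: Optional[np.ndarray] = None,
                          max_distance: Optional[float] = None) -> Optional[int]:
    """Assign a dot to a nucleus: containment of the centroid pixel in a
    nucleus mask first, else the nearest nucleus centroid within
    ``max_distance`` (default 1.5 x the median nucleus radius); ties broken
    by smaller distance then smaller nucleus id.  Returns the nucleus id or
    None when unassigned."""
    if not nuclei:
        return None
    if label_mask is not None:
        cx, cy = int(round(dot.x)), int(round(dot.y))
        if 0 <= cy < label_mask.shape[0] and 0 <= cx < label_mask.shape[1]:
            k = int(label_mask[cy, cx])
            if k > 0:
                return k - 1
    if max_distance is None:
        max_distance = 1.5 * float(np.median([n.radius for n in nuclei]))
    best: Optional[tuple[float, int]] = None
    for n in sorted(nuclei, key=lambda n: n.nucleus_id):
        d = float(np.hypot(dot.x - n.centroid[0], dot.y - n.centroid[1]))
        if d <= max_distance and (best is None or d < best[0]):
            best = (d, n.nucleus_id)
    return best[1] if best else None


def mark_states(nuclei: Sequence[NucleusRecord], dots: Sequence[DotRecord],
                gene: str, label_mask: Optional[np.ndarray] = None,
                max_distance: Optional[float] = None) -> None:
    """Set each nucleus' ON/OFF state for ``gene`` from the assigned dots
    (ON iff at least one dot assigned)."""
    by_id = {n.nucleus_id: n for n in nuclei}
    for n in nuclei:
        n.states.setdefault(gene, False)
    for dot in dots:
        nid = assign_dot_to_nucleus(dot, nuclei, label_mask, max_distance)
        if nid is not None:
            by_id[nid].states[gene] = True


def tabulate_cotranscription(nuclei: Sequence[NucleusRecord], gene_a: str,
                             gene_b: str, fibre_id: str = "fibre0"
                             ) -> CotranscriptionTable:
    """Exact 4-way partition of nuclei by their (A, B) states."""
    if not nuclei:
        raise ValueError("cannot tabulate co-transcription over zero nuclei")
    a = np.array([n.states.get(gene_a, False) for n in nuclei])
    b = np.array([n.states.get(gene_b, False) for n in nuclei])
    return CotranscriptionTable(
        fibre_id=fibre_id, gene_a=gene_a, gene_b=gene_b,
        n_a_only=int((a & ~b).sum()), n_b_only=int((~a & b).sum()),
        n_both=int((a & b).sum()), n_neither=int((~a & ~b).sum()))


def exclusion_check(nuclei: Sequence[NucleusRecord], gene_a: str,
                    gene_b: str) -> int:
    """Number of nuclei jointly ON for two genes of an exclusion group
    (expected 0 under the mutual-exclusion model)."""
    return sum(1 for n in nuclei
               if n.states.get(gene_a, False) and n.states.get(gene_b, False))


# ---------------------------------------------------------------------------
# Lineage labelling
# ---------------------------------------------------------------------------

def classify_lineage(nuclei: Sequence[NucleusRecord], label_mask: np.ndarray,
                     lineage_projection: np.ndarray,
                     threshold: float = 75.0) -> None:
    """Call each nucleus labelled/unlabelled by its mean lineage-channel
    intensity over its mask vs a threshold (RFP-positive proxy)."""
    label_mask = np.asarray(label_mask)
    proj = np.asarray(lineage_projection, float)
    for n in nuclei:
        m = label_mask == (n.nucleus_id + 1)
        if not m.any():
            n.lineage_label = "unknown"
            continue
        n.lineage_label = "labelled" if proj[m].mean() > threshold else "unlabelled"


def count_labelled_nuclei(nuclei: Sequence[NucleusRecord],
                          muscle_mask: np.ndarray) -> tuple[int, int]:
    """(labelled, total) counts over nuclei whose centroid lies inside the
    muscle mask; nuclei with unknown lineage are excluded from both."""
    muscle = np.asarray(muscle_mask).astype(bool)
    n_lab = n_tot = 0
    for n in nuclei:
        cx, cy = int(round(n.centroid[0])), int(round(n.centroid[1]))
        if not (0 <= cy < muscle.shape[0] and 0 <= cx < muscle.shape[1]):
            continue
        if not muscle[cy, cx] or n.lineage_label == "unknown":
            continue
        n_tot += 1
        if n.lineage_label == "labelled":
            n_lab += 1
    return n_lab, n_tot


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def nuclei_table(nuclei: Sequence[NucleusRecord]) -> pd.DataFrame:
    genes = sorted({g for n in nuclei for g in n.states})
    rows = []
    for n in nuclei:
        row = {"fibre_id": n.fibre_id, "nucleus_id": n.nucleus_id,
               "x": n.centroid[0], "y": n.centroid[1],
               "is_fc": n.is_fc, "lineage_label": n.lineage_label}
        for g in genes:
            row[f"state_{g}"] = n.states.get(g, False)
        rows.append(row)
    return pd.DataFrame(rows)


def coloc_table(tables: Sequence[CotranscriptionTable]) -> pd.DataFrame:
    rows = [{"fibre_id": t.fibre_id, "geneA": t.gene_a, "geneB": t.gene_b,
             "n_Aonly": t.n_a_only, "n_Bonly": t.n_b_only, "n_both": t.n_both,
             "n_neither": t.n_neither} for t in tables]
    return pd.DataFrame(rows, columns=["fibre_id", "geneA", "geneB", "n_Aonly",
                                       "n_Bonly", "n_both", "n_neither"])
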