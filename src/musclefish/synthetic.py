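"""Synthetic fluorescence-microscopy generator for syncytial muscle fibres.

Produces multi-channel Z-stacks with known ground truth: a muscle-outline
channel (filled template polygon), a nuclear channel (filled discs), one
FISH dot channel per gene (2-D Gaussian transcription spots rendered over
the fibre's Z range) and, when lineage mixing is configured, a lineage
(RFP-proxy) channel.  The per-nucleus per-gene ON/OFF states follow the
burst model declared in :class:`~musclefish.config.GeneratorConfig`:
independent Bernoulli bursting, FC restriction, mutually exclusive gene
groups, and correlated gene pairs drawn from a joint table.

All randomness flows through a single :class:`numpy.random.Generator`, so
identical config + seed yields an identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import LineString, Point, Polygon
from skimage.draw import disk as _draw_disk
from skimage.draw import polygon as _draw_polygon

from .config import (
    JOINT_STATES,
    ConfigurationError,
    GeneBurstSpec,
    GeneratorConfig,
)
from .spatial import SUBDOMAINS, classify_mask_pixels

#: margin (px) kept between any spot centre and the image border so the
#: full rendering window always fits inside the frame.
SPOT_WINDOW_RADIUS = 8

#: intensity of filled shapes in the muscle / nuclear channels.
SHAPE_INTENSITY = 100.0
#: lineage-channel disc intensities for labelled vs unlabelled nuclei.
LINEAGE_ON, LINEAGE_OFF = 150.0, 20.0


class PackingError(RuntimeError):
    """Raised when nuclei cannot be packed into the muscle polygon."""


@dataclass
class FibreGeometry:
    """Ground-truth geometry of one simulated fibre."""

    muscle: str
    stage: int
    polygon: Polygon
    centres: np.ndarray  # (n, 2) nucleus centres as (x, y)
    radius: float
    fc_index: int
    z_extent: tuple[int, int]
    image_shape: tuple[int, int, int]

    @property
    def n_nuclei(self) -> int:
        return len(self.centres)


@dataclass
class GroundTruth:
    """Per-nucleus states and per-dot truth for one fibre, tidy format."""

    nuclei: pd.DataFrame  # fibre_id, stage, nucleus_id, x, y, is_fc, gene, state, lineage_label
    dots: pd.DataFrame    # fibre_id, stage, gene, nucleus_id, x, y, intensity, is_decoy


@dataclass
class SimulatedFibre:
    fibre_id: str
    geometry: FibreGeometry
    states: dict[str, np.ndarray]
    lineage: Optional[np.ndarray]
    channels: dict[str, np.ndarray]
    muscle_mask: np.ndarray   # uint16 label mask, 1 = the muscle
    nuclei_mask: np.ndarray   # uint16 label mask, k = nucleus k-1
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def muscle_polygon(config: GeneratorConfig) -> Polygon:
    """Muscle outline: the flat-capped buffer of the template midline."""
    return LineString(config.midline).buffer(
        config.half_thickness, cap_style=2, join_style=2)


def rasterize_polygon(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    xs, ys = poly.exterior.xy
    rr, cc = _draw_polygon(np.asarray(ys), np.asarray(xs), shape=shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def _valid_region(config: GeneratorConfig, poly: Polygon) -> Polygon:
    """Region where a nucleus centre may fall: inside the polygon eroded by
    the nucleus radius, with the spot-rendering margin from the border."""
    nz, h, w = config.image_shape
    margin = SPOT_WINDOW_RADIUS + 1
    frame = Polygon([(margin, margin), (w - 1 - margin, margin),
                     (w - 1 - margin, h - 1 - margin), (margin, h - 1 - margin)])
    eroded = poly.buffer(-config.nucleus_radius)
    region = eroded.intersection(frame)
    if region.is_empty:
        raise PackingError(
            f"muscle {config.muscle}: polygon too small for nucleus radius "
            f"{config.nucleus_radius} within a {h}x{w} frame")
    return region

def _sample_point_in(region: Polygon, rng: np.random.Generator,
                     max_attempts: int) -> tuple[float, float]:
    minx, miny, maxx, maxy = region.bounds
    for _ in range(max_attempts):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if region.contains(Point(x, y)):
            return x, y
    raise PackingError("could not sample a point inside the valid region")


def _fc_position(config: GeneratorConfig, poly: Polygon, region: Polygon,
                 rng: np.random.Generator) -> tuple[float, float]:
    if config.fc_position == "center":
        cx, cy = poly.centroid.x, poly.centroid.y
        for _ in range(config.max_packing_attempts):
            x = cx + rng.uniform(-config.fc_jitter, config.fc_jitter)
            y = cy + rng.uniform(-config.fc_jitter, config.fc_jitter)
            if region.contains(Point(x, y)):
                return x, y
        raise PackingError(
            f"muscle {config.muscle}: FC jitter {config.fc_jitter} px never "
            f"landed inside the valid region")
    # subdomain mode: draw the subdomain from the configured weights, then a
    # uniform valid pixel within it.
    weights = dict(config.fc_subdomain_weights)
    if not weights:
        raise ConfigurationError("fc_position='subdomain' needs fc_subdomain_weights")
    nz, h, w = config.image_shape
    labels = classify_mask_pixels(rasterize_polygon(poly, (h, w)))
    candidates: dict[str, np.ndarray] = {}
    for i, name in enumerate(SUBDOMAINS):
        ys, xs = np.nonzero(labels == i)
        if xs.size:
            inside = np.fromiter(
                (region.contains(Point(float(x), float(y))) for x, y in zip(xs, ys)),
                dtype=bool, count=xs.size)
            xs, ys = xs[inside], ys[inside]
        candidates[name] = np.stack([xs, ys], axis=1)
    names = [n for n in SUBDOMAINS if weights.get(n, 0.0) > 0 and len(candidates[n])]
    if not names:
        raise ConfigurationError("no valid FC positions in any weighted subdomain")
    probs = np.array([weights[n] for n in names], float)
    probs /= probs.sum()
    chosen = names[rng.choice(len(names), p=probs)]
    pick = candidates[chosen][rng.integers(len(candidates[chosen]))]
    return float(pick[0]), float(pick[1])


def build_fibre_geometry(config: GeneratorConfig, stage: int,
                         rng: np.random.Generator) -> FibreGeometry:
    """Place the FC and syncytial nuclei inside the muscle template.

    The FC goes first (canonical centre position with jitter, or drawn from
    the configured subdomain law); the remaining nuclei are rejection-
    sampled uniformly with a minimum centre separation.
    """
    if stage not in config.nuclei_per_stage:
        raise ConfigurationError(
            f"no nuclei count configured for stage {stage} "
            f"(have {sorted(config.nuclei_per_stage)})")
    n = config.nuclei_per_stage[stage]
    if n < 1:
        raise ConfigurationError(f"stage {stage}: nuclei count must be >= 1")
    poly = muscle_polygon(config)
    region = _valid_region(config, poly)
    sep = config.separation * (1.0 - config.max_overlap_fraction)

    centres = [np.asarray(_fc_position(config, poly, region, rng))]
    attempts = 0
    while len(centres) < n:
        if attempts >= config.max_packing_attempts:
            raise PackingError(
                f"muscle {config.muscle}, stage {stage}: failed to pack {n} "
                f"nuclei of radius {config.nucleus_radius} at separation "
                f"{sep:.1f} px after {attempts} attempts")
        attempts += 1
        x, y = _sample_point_in(region, rng, config.max_packing_attempts)
        cand = np.array([x, y])
        if all(np.hypot(*(cand - c)) >= sep for c in centres):
            centres.append(cand)
    return FibreGeometry(
        muscle=config.muscle, stage=stage, polygon=poly,
        centres=np.asarray(centres, float), radius=config.nucleus_radius,
        fc_index=0, z_extent=config.z_extent, image_shape=config.image_shape)


# ---------------------------------------------------------------------------
# Transcriptional states
# ---------------------------------------------------------------------------

def sample_transcription_states(geometry: FibreGeometry,
                                specs: Sequence[GeneBurstSpec],
                                rng: np.random.Generator,
                                joint_tables: Optional[dict] = None,
                                ) -> dict[str, np.ndarray]:
    """Draw per-nucleus per-gene ON/OFF states.

    Drawing order: joint-table pairs first, then exclusion groups (one
    categorical draw per nucleus so group members are never jointly ON),
    then independent genes.  FC-restricted genes can be ON only at
    ``fc_index``.
    """
    joint_tables = joint_tables or {}
    n = geometry.n_nuclei
    stage = geometry.stage
    states: dict[str, np.ndarray] = {}
    by_name = {s.gene: s for s in specs}

    # joint-table pairs
    handled: set[str] = set()
    for table_name in sorted({s.joint_table for s in specs if s.joint_table}):
        table = joint_tables.get(table_name)
        if table is None:
            raise ConfigurationError(f"unknown joint table {table_name!r}")
        a, b = table.genes
        for g in (a, b):
            if g not in by_name or by_name[g].joint_table != table_name:
                raise ConfigurationError(
                    f"joint table {table_name!r} expects genes {table.genes}")
            if by_name[g].exclusion_group is not None:
                raise ConfigurationError(
                    f"{g}: cannot be both in a joint table and an exclusion group")
        probs = np.array([table.probabilities[s] for s in JOINT_STATES])
        draw = rng.choice(4, size=n, p=probs)
        states[a] = (draw == 0) | (draw == 1)
        states[b] = (draw == 0) | (draw == 2)
        handled.update((a, b))

    # exclusion groups: categorical over (members..., none)
    groups: dict[str, list[GeneBurstSpec]] = {}
    for s in specs:
        if s.gene not in handled and s.exclusion_group is not None:
            groups.setdefault(s.exclusion_group, []).append(s)
    for name in sorted(groups):
        members = sorted(groups[name], key=lambda s: s.gene)
        ps = np.array([m.p_on(stage) for m in members])
        if ps.sum() > 1.0 + 1e-12:
            raise ConfigurationError(
                f"exclusion group {name!r}: p_on values sum to {ps.sum():.3f} > 1")
        draw = rng.choice(len(members) + 1, size=n,
                          p=np.append(ps, 1.0 - ps.sum()))
        for i, m in enumerate(members):
            on = draw == i
            states[m.gene] = _apply_fc_rules(m, on, geometry, rng, drawn=True)
            handled.add(m.gene)

    # independent genes
    for s in specs:
        if s.gene in handled:
            continue
        if s.fc_restricted:
            on = np.zeros(n, bool)
            p = s.fc_p_on if s.fc_p_on is not None else s.p_on(stage)
            on[geometry.fc_index] = rng.random() < p
        else:
            on = rng.random(n) < s.p_on(stage)
            if s.fc_p_on is not None:
                on[geometry.fc_index] = rng.random() < s.fc_p_on
        states[s.gene] = on
    return states


def _apply_fc_rules(spec: GeneBurstSpec, on: np.ndarray,
                    geometry: FibreGeometry, rng: np.random.Generator,
                    drawn: bool) -> np.ndarray:
    if spec.fc_restricted:
        fc_on = on[geometry.fc_index]
        on = np.zeros_like(on)
        on[geometry.fc_index] = fc_on
    return on


def sample_lineage_labels(geometry: FibreGeometry, labelled_fraction: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Bernoulli lineage labels (promuscular-cluster RFP proxy)."""
    return rng.random(geometry.n_nuclei) < labelled_fraction


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _draw_intensity(spec: GeneBurstSpec, is_fc: bool,
                    rng: np.random.Generator) -> float:
    """Log-normal dot intensity with the configured mean and CV; the FC
    multiplier scales the mean for the founder nucleus."""
    mean = spec.dot_intensity_mean * (spec.fc_intensity_multiplier if is_fc else 1.0)
    cv = spec.dot_intensity_cv
    if cv <= 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _render_spot(stack: np.ndarray, x: float, y: float,
                 z_range: tuple[int, int], intensity: float,
                 sigma: float) -> None:
    """Add one diffraction-limited spot.  The kernel is renormalised so the
    rendered pixel sum equals ``intensity`` exactly; a window that would
    leave the image is an error, never a silent clip."""
    nz, h, w = stack.shape
    r = SPOT_WINDOW_RADIUS
    cx, cy = int(round(x)), int(round(y))
    if not (r <= cx < w - r and r <= cy < h - r):
        raise ValueError(f"spot at ({x:.1f}, {y:.1f}) too close to the image "
                         f"border for a window of radius {r}")
    z0, z1 = z_range
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"spot z range {z_range} outside stack of {nz} slices")
    gx = np.arange(cx - r, cx + r + 1) - x
    gy = np.arange(cy - r, cy + r + 1) - y
    kern = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2.0 * sigma * sigma))
    kern *= intensity / (kern.sum() * (z1 - z0))
    for z in range(z0, z1):
        stack[z, cy - r:cy + r + 1, cx - r:cx + r + 1] += kern


def _fill_disc(plane: np.ndarray, x: float, y: float, radius: float,
               value: float) -> None:
    rr, cc = _draw_disk((y, x), radius, shape=plane.shape)
    plane[rr, cc] = value


def render_stack(geometry: FibreGeometry, states: dict[str, np.ndarray],
                 specs: Sequence[GeneBurstSpec], rng: np.random.Generator,
                 noise=None, lineage: Optional[np.ndarray] = None,
                 spot_sigma: float = 1.5,
                 decoys: Iterable[tuple[str, float, float, int, float]] = (),
                 fibre_id: str = "fibre0",
                 ) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render all channels for one fibre and return them with ground truth.

    ``decoys`` are extra spots ``(gene, x, y, z_centre, intensity)`` planted
    outside the fibre's Z range to exercise the Z filter.
    """
    nz, h, w = geometry.image_shape
    z0, z1 = geometry.z_extent
    by_name = {s.gene: s for s in specs}

    channels: dict[str, np.ndarray] = {}
    # muscle-outline channel
    muscle = np.zeros((nz, h, w), np.float32)
    poly_mask = rasterize_polygon(geometry.polygon, (h, w))
    muscle[z0:z1, poly_mask] = SHAPE_INTENSITY
    channels["muscle"] = muscle
    # nuclear channel
    nuc = np.zeros((nz, h, w), np.float32)
    plane = np.zeros((h, w), np.float32)
    for (x, y) in geometry.centres:
        _fill_disc(plane, x, y, geometry.radius, SHAPE_INTENSITY)
    nuc[z0:z1] = plane
    channels["nuclei"] = nuc
    # lineage channel
    if lineage is not None:
        lin_plane = np.zeros((h, w), np.float32)
        for i, (x, y) in enumerate(geometry.centres):
            _fill_disc(lin_plane, x, y, geometry.radius,
                       LINEAGE_ON if lineage[i] else LINEAGE_OFF)
        lin = np.zeros((nz, h, w), np.float32)
        lin[z0:z1] = lin_plane
        channels["lineage"] = lin

    dot_rows = []
    for gene in sorted(states):
        spec = by_name[gene]
        chan = np.zeros((nz, h, w), np.float32)
        for i in np.flatnonzero(states[gene]):
            x, y = geometry.centres[i]
            intensity = _draw_intensity(spec, i == geometry.fc_index, rng)
            _render_spot(chan, x, y, geometry.z_extent, intensity, spot_sigma)
            dot_rows.append({"fibre_id": fibre_id, "stage": geometry.stage,
                             "gene": gene, "nucleus_id": int(i), "x": x, "y": y,
                             "intensity": intensity, "is_decoy": False})
        channels[f"fish_{gene}"] = chan
    for gene, x, y, zc, intensity in decoys:
        chan = channels.setdefault(f"fish_{gene}", np.zeros((nz, h, w), np.float32))
        _render_spot(chan, x, y, (zc, zc + 1), intensity, spot_sigma)
        dot_rows.append({"fibre_id": fibre_id, "stage": geometry.stage,
                         "gene": gene, "nucleus_id": -1, "x": x, "y": y,
                         "intensity": intensity, "is_decoy": True})

    if noise is not None and (noise.background or noise.read_sigma or noise.poisson):
        for name, chan in channels.items():
            img = chan + noise.background
            if noise.poisson:
                img = rng.poisson(np.clip(img, 0, None)).astype(np.float32)
            if noise.read_sigma > 0:
                img = img + rng.normal(0.0, noise.read_sigma, img.shape)
            channels[name] = img.astype(np.float32)

    nuc_rows = []
    for gene in sorted(states):
        for i, (x, y) in enumerate(geometry.centres):
            nuc_rows.append({
                "fibre_id": fibre_id, "stage": geometry.stage, "nucleus_id": i,
                "x": x, "y": y, "is_fc": i == geometry.fc_index, "gene": gene,
                "state": bool(states[gene][i]),
                "lineage_label": ("labelled" if lineage is not None and lineage[i]
                                  else "unlabelled" if lineage is not None
                                  else "unknown")})
    truth = GroundTruth(
        nuclei=pd.DataFrame(nuc_rows, columns=["fibre_id", "stage", "nucleus_id",
                                               "x", "y", "is_fc", "gene", "state",
                                               "lineage_label"]),
        dots=pd.DataFrame(dot_rows, columns=["fibre_id", "stage", "gene",
                                             "nucleus_id", "x", "y", "intensity",
                                             "is_decoy"]))
    return channels, truth


def make_label_masks(geometry: FibreGeometry) -> tuple[np.ndarray, np.ndarray]:
    """16-bit label masks: muscle (1 = the muscle) and nuclei (k = nucleus
    k-1), on the projection grid."""
    nz, h, w = geometry.image_shape
    muscle = rasterize_polygon(geometry.polygon, (h, w)).astype(np.uint16)
    nuclei = np.zeros((h, w), np.uint16)
    for i, (x, y) in enumerate(geometry.centres):
        rr, cc = _draw_disk((y, x), geometry.radius, shape=(h, w))
        nuclei[rr, cc] = i + 1
    return muscle, nuclei


# ---------------------------------------------------------------------------
# Cohort convenience + dataset I/O
# ---------------------------------------------------------------------------

def simulate_fibre(config: GeneratorConfig, stage: int,
                   rng: np.random.Generator, fibre_id: str = "fibre0",
                   decoys=()) -> SimulatedFibre:
    geometry = build_fibre_geometry(config, stage, rng)
    states = sample_transcription_states(geometry, config.genes, rng,
                                         config.joint_tables)
    lineage = (sample_lineage_labels(geometry, config.labelled_fraction, rng)
               if config.labelled_fraction is not None else None)
    channels, truth = render_stack(geometry, states, config.genes, rng,
                                   noise=config.noise, lineage=lineage,
                                   spot_sigma=config.spot_sigma,
                                   decoys=decoys, fibre_id=fibre_id)
    muscle_mask, nuclei_mask = make_label_masks(geometry)
    return SimulatedFibre(fibre_id=fibre_id, geometry=geometry, states=states,
                          lineage=lineage, channels=channels,
                          muscle_mask=muscle_mask, nuclei_mask=nuclei_mask,
                          truth=truth)


def simulate_cohort(config: GeneratorConfig, stage: int, n_fibres: int,
                    seed: int) -> list[SimulatedFibre]:
    rng = np.random.default_rng(seed)
    return [simulate_fibre(config, stage, rng, fibre_id=f"fibre{i:04d}")
            for i in range(n_fibres)]


def write_dataset(fibres: Sequence[SimulatedFibre], out_dir,
                  config: Optional[GeneratorConfig] = None) -> Path:
    """Write a dataset: per-fibre per-channel multi-page TIFFs, 16-bit label
    masks, ground truth CSVs and a config echo."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        for f in fibres:
            stem = f"{f.fibre_id}_{f.geometry.stage}"
            for chan, stack in f.channels.items():
                tifffile.imwrite(out / f"{stem}_{chan}.tif", stack)
            tifffile.imwrite(out / f"{stem}_muscle_mask.tif", f.muscle_mask)
            tifffile.imwrite(out / f"{stem}_nuclei_mask.tif", f.nuclei_mask)
        nuclei = pd.concat([f.truth.nuclei for f in fibres], ignore_index=True)
        dots = pd.concat([f.truth.dots for f in fibres], ignore_index=True)
        nuclei.to_csv(out / "ground_truth_nuclei.csv", index=False)
        dots.to_csv(out / "ground_truth_dots.csv", index=False)
        if config is not None:
            config.to_yaml(out / "config.yaml")
    except OSError as exc:
        raise OSError(f"failed to write dataset under {out}: {exc}") from exc
    return out


def read_stack(path) -> np.ndarray:
    try:
        return tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"failed to read TIFF {path}: {exc}") from exc
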