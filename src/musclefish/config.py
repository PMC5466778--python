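"""Configuration objects for the synthetic-fibre generator and the
quantification pipeline.

The generator emulates nascent-transcript FISH in syncytial *Drosophila*
body-wall muscles: a fibre is a 2-D muscle outline occupying a few Z slices,
containing one founder-cell (FC) nucleus plus fusion-derived syncytial
nuclei.  Each gene transcribes stochastically (ON/OFF per nucleus), and an
ON nucleus carries one diffraction-limited transcription dot whose
integrated intensity is drawn from a log-normal law.

Everything a simulation needs is captured in :class:`GeneratorConfig`,
which round-trips to YAML.  ``packaged_config(name)`` returns the presets
that encode the empirical regularities the pipeline is validated against
(burst probabilities, the duf/col joint law, FC restriction and the FC
intensity multiplier, lineage-label mixing, FC positional bias).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

STAGES = (12, 13, 14, 15, 16)

#: Joint-state keys, in categorical-draw order.
JOINT_STATES = ("both", "a_only", "b_only", "neither")


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


@dataclass
class NoiseConfig:
    """Acquisition-noise model: Poisson shot noise on the signal plus
    additive Gaussian read noise on a constant background.  Both default
    off so that fixtures are clean and intensity conservation is exact."""

    background: float = 0.0
    read_sigma: float = 0.0
    poisson: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseConfig":
        return cls(**d)


@dataclass
class JointBurstTable:
    """Categorical law over the four joint ON/OFF states of a gene pair.

    Independence cannot reproduce a high union probability together with a
    moderate co-transcription probability (e.g. P(at least one) = 0.8 with
    P(both | at least one) = 0.5 would need marginals summing to 1.2 while
    multiplying to 0.4), so correlated pairs are drawn from this table
    instead of from independent Bernoulli draws.
    """

    genes: tuple[str, str]
    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)  # type: ignore[assignment]
        missing = set(JOINT_STATES) - set(self.probabilities)
        if missing:
            raise ConfigurationError(f"joint table missing states: {sorted(missing)}")
        probs = [self.probabilities[s] for s in JOINT_STATES]
        if any(p < 0 for p in probs):
            raise ConfigurationError("joint table probabilities must be >= 0")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError(f"joint table probabilities sum to {sum(probs)}, not 1")

    @property
    def p_union(self) -> float:
        """P(at least one gene ON)."""
        return 1.0 - self.probabilities["neither"]

    @property
    def p_both_given_union(self) -> float:
        """P(both ON | at least one ON)."""
        return self.probabilities["both"] / self.p_union

    def to_dict(self) -> dict:
        return {"genes": list(self.genes), "probabilities": dict(self.probabilities)}

    @classmethod
    def from_dict(cls, d: dict) -> "JointBurstTable":
        return cls(genes=tuple(d["genes"]), probabilities=dict(d["probabilities"]))


@dataclass
class GeneBurstSpec:
    """Per-gene transcriptional bursting model.

    ``p_on_by_stage`` is the probability that a syncytial nucleus is caught
    in an ON phase at fixation, per embryonic stage.  ``fc_restricted``
    genes (e.g. *Kr*, or *Con* in DA3) can only be ON in the FC nucleus.
    ``fc_p_on``/``fc_intensity_multiplier`` let the FC nucleus burst with a
    different probability and transcribe at a higher initiation rate than
    syncytial nuclei (*col* is 9-fold brighter in the FC at stage 14).
    """

    gene: str
    p_on_by_stage: dict[int, float] = field(default_factory=dict)
    fc_restricted: bool = False
    fc_p_on: Optional[float] = None
    fc_intensity_multiplier: float = 1.0
    dot_intensity_mean: float = 5000.0
    dot_intensity_cv: float = 0.3
    exclusion_group: Optional[str] = None
    joint_table: Optional[str] = None

    def __post_init__(self) -> None:
        self.p_on_by_stage = {int(k): float(v) for k, v in self.p_on_by_stage.items()}
        for stage, p in self.p_on_by_stage.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{self.gene}: p_on={p} at stage {stage} not in [0,1]")
        if self.fc_p_on is not None and not 0.0 <= self.fc_p_on <= 1.0:
            raise ConfigurationError(f"{self.gene}: fc_p_on={self.fc_p_on} not in [0,1]")
        if self.fc_intensity_multiplier < 1.0:
            raise ConfigurationError(f"{self.gene}: fc_intensity_multiplier must be >= 1")
        if self.fc_restricted and self.joint_table is not None:
            raise ConfigurationError(
                f"{self.gene}: a gene cannot be both fc_restricted and in a joint table"
            )

    def p_on(self, stage: int) -> float:
        return self.p_on_by_stage.get(stage, 0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneBurstSpec":
        return cls(**d)


@dataclass
class GeneratorConfig:
    """Full description of one simulated cohort condition.

    Geometry: the muscle outline is the buffer of a polyline midline
    (``midline``, ``half_thickness``); the DA3 template is an angled
    chevron reflecting the transient tripartite attachment of that muscle,
    straight bands stand in for the other muscles.  Pixel grid is 0-based,
    origin top-left, y increasing downward (dorsal is up).

    ``fc_position`` is either ``"center"`` (FC at the fibre centre with
    ``fc_jitter`` of uniform jitter) or ``"subdomain"`` (FC position drawn
    from ``fc_subdomain_weights`` over the antero-ventral / central /
    postero-dorsal partition of the muscle template — used to exercise the
    spatial classifier without hard-coding its answer).
    """

    muscle: str = "DA3"
    image_shape: tuple[int, int, int] = (8, 128, 192)  # (z, y, x)
    midline: tuple[tuple[float, float], ...] = ((24.0, 104.0), (96.0, 60.0), (168.0, 16.0))
    half_thickness: float = 12.0
    nucleus_radius: float = 5.0
    nuclei_per_stage: dict[int, int] = field(
        default_factory=lambda: {12: 1, 13: 4, 14: 8, 15: 12, 16: 14}
    )
    min_separation: Optional[float] = None  # centre-to-centre; default 2 * radius
    max_overlap_fraction: float = 0.0
    fc_position: str = "center"
    fc_jitter: float = 4.0
    fc_subdomain_weights: dict[str, float] = field(default_factory=dict)
    z_extent: tuple[int, int] = (2, 6)  # half-open slice range occupied by the fibre
    spot_sigma: float = 1.5
    genes: list[GeneBurstSpec] = field(default_factory=list)
    joint_tables: dict[str, JointBurstTable] = field(default_factory=dict)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    labelled_fraction: Optional[float] = None  # lineage (RFP+) mixing; None = no lineage channel
    max_packing_attempts: int = 2000

    def __post_init__(self) -> None:
        self.image_shape = tuple(self.image_shape)  # type: ignore[assignment]
        self.midline = tuple(tuple(p) for p in self.midline)  # type: ignore[assignment]
        self.z_extent = tuple(self.z_extent)  # type: ignore[assignment]
        self.nuclei_per_stage = {int(k): int(v) for k, v in self.nuclei_per_stage.items()}
        if self.fc_position not in ("center", "subdomain"):
            raise ConfigurationError(f"unknown fc_position mode {self.fc_position!r}")
        nz = self.image_shape[0]
        z0, z1 = self.z_extent
        if not (0 <= z0 < z1 <= nz):
            raise ConfigurationError(f"z_extent {self.z_extent} outside stack of {nz} slices")
        if self.labelled_fraction is not None and not 0.0 <= self.labelled_fraction <= 1.0:
            raise ConfigurationError("labelled_fraction must be in [0,1]")
        for spec in self.genes:
            if spec.joint_table is not None and spec.joint_table not in self.joint_tables:
                raise ConfigurationError(
                    f"{spec.gene}: references unknown joint table {spec.joint_table!r}"
                )

    @property
    def separation(self) -> float:
        return self.min_separation if self.min_separation is not None else 2 * self.nucleus_radius

    def gene_spec(self, gene: str) -> GeneBurstSpec:
        for spec in self.genes:
            if spec.gene == gene:
                return spec
        raise KeyError(gene)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genes"] = [g.to_dict() for g in self.genes]
        d["joint_tables"] = {k: t.to_dict() for k, t in self.joint_tables.items()}
        d["noise"] = self.noise.to_dict()
        d["image_shape"] = list(self.image_shape)
        d["midline"] = [list(p) for p in self.midline]
        d["z_extent"] = list(self.z_extent)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["genes"] = [GeneBurstSpec.from_dict(g) for g in d.get("genes", [])]
        d["joint_tables"] = {
            k: JointBurstTable.from_dict(t) for k, t in d.get("joint_tables", {}).items()
        }
        if "noise" in d:
            d["noise"] = NoiseConfig.from_dict(d["noise"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable short hash of the configuration, for report metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Muscle templates
# ---------------------------------------------------------------------------

#: midline polyline + half thickness per muscle, on the 128 x 192 grid.
#: DA3 is the late-stage-14 angled chevron; the others are straight bands.
MUSCLE_TEMPLATES: dict[str, dict] = {
    "DA3": {"midline": ((24.0, 104.0), (96.0, 60.0), (168.0, 16.0)), "half_thickness": 12.0},
    "DT1": {"midline": ((24.0, 64.0), (168.0, 64.0)), "half_thickness": 12.0},
    "LL1": {"midline": ((28.0, 64.0), (164.0, 64.0)), "half_thickness": 12.0},
    "VA2": {"midline": ((32.0, 64.0), (160.0, 64.0)), "half_thickness": 11.0},
    "VT1": {"midline": ((32.0, 64.0), (160.0, 64.0)), "half_thickness": 11.0},
}

#: the ventral muscles are smaller and recruit fewer myoblasts than the
#: dorsolateral DA3/DT1 pair (which have similar nuclei counts).
VENTRAL_NUCLEI_PER_STAGE = {12: 1, 13: 3, 14: 6, 15: 8, 16: 9}


def _base(muscle: str, **overrides) -> GeneratorConfig:
    tpl = MUSCLE_TEMPLATES[muscle]
    if muscle in ("VA2", "VT1") and "nuclei_per_stage" not in overrides:
        overrides["nuclei_per_stage"] = dict(VENTRAL_NUCLEI_PER_STAGE)
    return GeneratorConfig(muscle=muscle, midline=tpl["midline"],
                           half_thickness=tpl["half_thickness"], **overrides)


# ---------------------------------------------------------------------------
# Packaged cohort configurations
# ---------------------------------------------------------------------------

def _packaged_builders() -> dict:
    def da3_col_stage14() -> GeneratorConfig:
        # col in DA3: stochastic syncytial bursting, FC always caught ON and
        # transcribing 9-fold brighter at stage 14.
        return _base("DA3", genes=[GeneBurstSpec(
            gene="col", p_on_by_stage={13: 0.3, 14: 0.35, 15: 0.3, 16: 0.0},
            fc_p_on=1.0, fc_intensity_multiplier=9.0)])

    def s59(muscle: str, p15: float):
        def build() -> GeneratorConfig:
            return _base(muscle, genes=[GeneBurstSpec(
                gene="S59", p_on_by_stage={13: 0.3, 14: 0.35, 15: p15, 16: 0.1})])
        return build

    def dt1_kon_stage15() -> GeneratorConfig:
        # kon in DT1 peaks at stage 15 with 4.35 dots/fibre on average;
        # 12 nuclei at stage 15 gives p_on = 4.35/12.
        return _base("DT1", genes=[GeneBurstSpec(
            gene="kon", p_on_by_stage={13: 0.15, 14: 0.25, 15: 4.35 / 12, 16: 0.1})])

    def pax_stage_course() -> GeneratorConfig:
        # Pax: activated post fusion, similar in DA3 and DT1, maximum of
        # 2.5 dots/fibre at stage 15 (p_on = 2.5/12 with 12 nuclei).
        return _base("DA3", genes=[GeneBurstSpec(
            gene="Pax", p_on_by_stage={12: 0.0, 13: 0.08, 14: 0.14, 15: 2.5 / 12, 16: 0.05})])

    def da3_dufcol_stage14() -> GeneratorConfig:
        # Correlated duf/col bursting: the minimal joint law reproducing an
        # 80% union with 50% co-transcription among active nuclei.
        table = JointBurstTable(genes=("duf", "col"), probabilities={
            "both": 0.4, "a_only": 0.2, "b_only": 0.2, "neither": 0.2})
        return _base("DA3", genes=[
            GeneBurstSpec(gene="duf", joint_table="dufcol"),
            GeneBurstSpec(gene="col", joint_table="dufcol"),
        ], joint_tables={"dufcol": table})

    def da3_con_stage14() -> GeneratorConfig:
        # Con in DA3: FC-restricted, with the FC position drawn from a
        # positional law biased towards the central subdomain.
        return _base("DA3", fc_position="subdomain",
                     fc_subdomain_weights={"central": 0.70,
                                           "antero_ventral": 0.15,
                                           "postero_dorsal": 0.15},
                     genes=[GeneBurstSpec(gene="Con", fc_restricted=True,
                                          p_on_by_stage={13: 1.0, 14: 1.0, 15: 1.0})])

    def ll1_kr() -> GeneratorConfig:
        # Kr: transcribed at a constant level in a single nucleus per fibre
        # (the FC) from stage 12 to 14.
        return _base("LL1", genes=[GeneBurstSpec(
            gene="Kr", fc_restricted=True,
            p_on_by_stage={12: 1.0, 13: 1.0, 14: 1.0}, dot_intensity_cv=0.1)])

    def da3_recruitment_stage15() -> GeneratorConfig:
        # Lineage tracking: about half the recruited myoblast nuclei carry
        # the promuscular-cluster label (H2B-RFP proxy).
        return _base("DA3", labelled_fraction=0.5, genes=[GeneBurstSpec(
            gene="col", p_on_by_stage={15: 0.3})])

    def da3_snscol_stage14() -> GeneratorConfig:
        # Mutually exclusive programmes: sns (FCM) vs col (fibre identity)
        # are never jointly ON in one nucleus.
        return _base("DA3", genes=[
            GeneBurstSpec(gene="sns", p_on_by_stage={13: 0.15, 14: 0.08},
                          exclusion_group="fcm_vs_fibre"),
            GeneBurstSpec(gene="col", p_on_by_stage={13: 0.3, 14: 0.35},
                          exclusion_group="fcm_vs_fibre"),
        ])

    return {
        "da3_col_stage14": da3_col_stage14,
        "dt1_s59_stage15": s59("DT1", 0.45),
        "va2_s59_stage15": s59("VA2", 0.27),
        "vt1_s59_stage15": s59("VT1", 0.23),
        "dt1_kon_stage15": dt1_kon_stage15,
        "pax_stage_course": pax_stage_course,
        "da3_dufcol_stage14": da3_dufcol_stage14,
        "da3_con_stage14": da3_con_stage14,
        "ll1_kr": ll1_kr,
        "da3_recruitment_stage15": da3_recruitment_stage15,
        "da3_snscol_stage14": da3_snscol_stage14,
    }


_PACKAGED = _packaged_builders()


def packaged_config_names() -> list[str]:
    return sorted(_PACKAGED)


def packaged_config(name: str) -> GeneratorConfig:
    """Return a fresh instance of a packaged cohort configuration."""
    try:
        return _PACKAGED[name]()
    except KeyError:
        raise KeyError(f"unknown packaged config {name!r}; "
                       f"available: {packaged_config_names()}") from None
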