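"""Summary statistics, declared tests and end-to-end parameter recovery.

Summaries follow the supplementary-table convention: per muscle/gene/stage,
mean +/- SD (n-1 denominator), SEM, min and max of dot counts, nuclei
counts and integrated densities.  The declared tests are the unpaired
two-sample t-test (equal-variance by default, Welch optional) and Pearson's
chi-squared test on active/inactive nucleus proportions, with the star
convention ns / * / ** / *** at 0.05 / 0.01 / 0.001.

The recovery drivers at the bottom run the whole chain — simulate fibres,
quantify dots, assign them to nuclei, standardize positions — and compare
the recovered statistics against the generator's configured parameters.
They are what the acceptance harness calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import coloc, dot_quant, spatial, synthetic
from .config import GeneratorConfig, packaged_config
from .dot_quant import FibreMeasurement, QuantProfile


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p_value: float

    @property
    def significance(self) -> str:
        return significance_class(self.p_value)


def significance_class(p: float) -> str:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(measurements: Sequence[FibreMeasurement],
              group_keys: Sequence[str] = ("gene", "stage")) -> pd.DataFrame:
    """Group fibre measurements and emit mean/SD/SEM/min/max per variable.

    Per-dot IntDen values are pooled within the group; the other variables
    are per-fibre.  Groups are ordered deterministically by key.
    """
    if not measurements:
        raise ValueError("no measurements to summarize")
    base = pd.DataFrame([{
        "fibre_id": m.fibre_id, "gene": m.gene, "stage": m.stage,
        "n_dots": m.n_dots, "n_nuclei": m.n_nuclei,
        "total_intden": m.total_intden} for m in measurements])
    rows = []
    for key, grp in base.groupby(list(group_keys), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(group_keys, key))
        row["n_fibres"] = len(grp)
        for var in ("n_dots", "n_nuclei", "total_intden"):
            row.update(_stats_block(grp[var].to_numpy(float), var))
        in_group = [m for m in measurements
                    if tuple(getattr(m, k) for k in group_keys) == key]
        intdens = np.array([v for m in in_group for v in m.dot_intdens], float)
        row.update(_stats_block(intdens, "dot_intden"))
        rows.append(row)
    return pd.DataFrame(rows)


def _stats_block(values: np.ndarray, prefix: str) -> dict:
    if values.size == 0:
        return {f"{prefix}_{s}": float("nan")
                for s in ("mean", "sd", "sem", "min", "max")}
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return {f"{prefix}_mean": float(values.mean()), f"{prefix}_sd": sd,
            f"{prefix}_sem": sd / np.sqrt(values.size),
            f"{prefix}_min": float(values.min()),
            f"{prefix}_max": float(values.max())}


# ---------------------------------------------------------------------------
# Declared tests
# ---------------------------------------------------------------------------

def t_test_unpaired(group_a, group_b, equal_var: bool = True) -> TestResult:
    """Two-sided unpaired two-sample t-test."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        df = a.size + b.size - 2 if equal_var else float(a.size + b.size - 2)
        return TestResult("unpaired t", 0.0, float(df), 1.0)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return TestResult("unpaired t" if equal_var else "Welch t",
                      float(res.statistic), float(df), float(res.pvalue))


def chi2_proportions(counts) -> TestResult:
    """Pearson chi-squared over a k x 2 (active, inactive) table,
    df = k - 1, no continuity correction."""
    table = np.asarray(counts, float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("counts must be a k x 2 table of (active, inactive)")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("chi-squared test undefined with a zero-sum row/column")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult("Pearson chi2", float(chi2), float(df), float(p))


def fraction_active(n_active, n_nuclei) -> tuple[float, float]:
    """Mean percentage of transcribing nuclei across fibres, +/- SEM."""
    act = np.asarray(n_active, float)
    tot = np.asarray(n_nuclei, float)
    if (tot <= 0).any():
        raise ValueError("every fibre needs n_nuclei > 0")
    pct = 100.0 * act / tot
    sem = pct.std(ddof=1) / np.sqrt(pct.size) if pct.size > 1 else 0.0
    return float(pct.mean()), float(sem)


# ---------------------------------------------------------------------------
# End-to-end cohort drivers (simulate -> quantify -> coloc -> spatial)
# ---------------------------------------------------------------------------

def _quantified(fibre: synthetic.SimulatedFibre, gene: str,
                profile: QuantProfile):
    meas, dots = dot_quant.quantify_fibre(
        fibre.channels[f"fish_{gene}"], fibre.muscle_mask, fibre.nuclei_mask,
        profile=profile, z_extent=fibre.geometry.z_extent,
        fibre_id=fibre.fibre_id, gene=gene, stage=fibre.geometry.stage)
    return meas, dots


def recover_mean_dots(config: GeneratorConfig, stage: int, n_fibres: int,
                      seed: int, gene: Optional[str] = None,
                      profile: QuantProfile = QuantProfile.standard()
                      ) -> tuple[float, list[FibreMeasurement]]:
    """Mean detected dots per fibre for one gene at one stage."""
    gene = gene or config.genes[0].gene
    measurements = []
    for fibre in synthetic.simulate_cohort(config, stage, n_fibres, seed):
        meas, _ = _quantified(fibre, gene, profile)
        measurements.append(meas)
    return float(np.mean([m.n_dots for m in measurements])), measurements


def recover_active_fraction(config: GeneratorConfig, stage: int,
                            n_fibres: int, seed: int,
                            gene: Optional[str] = None) -> float:
    """Mean per-fibre percentage of dot-bearing nuclei (coloc mode)."""
    gene = gene or config.genes[0].gene
    n_on, n_tot = [], []
    for fibre in synthetic.simulate_cohort(config, stage, n_fibres, seed):
        _, dots = _quantified(fibre, gene, QuantProfile.standard())
        nuclei = coloc.nuclei_from_labels(fibre.nuclei_mask, fibre.fibre_id)
        coloc.mark_states(nuclei, dots, gene, fibre.nuclei_mask)
        n_on.append(sum(n.states[gene] for n in nuclei))
        n_tot.append(len(nuclei))
    return fraction_active(n_on, n_tot)[0]


def recover_fc_intensity_ratio(config: GeneratorConfig, stage: int,
                               n_fibres: int, seed: int,
                               gene: Optional[str] = None) -> float:
    """FC-dot IntDen over mean syncytial-dot IntDen, per fibre, averaged
    over fibres where both are measurable."""
    gene = gene or config.genes[0].gene
    ratios = []
    for fibre in synthetic.simulate_cohort(config, stage, n_fibres, seed):
        _, dots = _quantified(fibre, gene, QuantProfile.standard())
        nuclei = coloc.nuclei_from_labels(fibre.nuclei_mask, fibre.fibre_id)
        fc_id = fibre.geometry.fc_index
        fc_vals, syn_vals = [], []
        for d in dots:
            nid = coloc.assign_dot_to_nucleus(d, nuclei, fibre.nuclei_mask)
            if nid is None:
                continue
            (fc_vals if nid == fc_id else syn_vals).append(d.intden)
        if fc_vals and syn_vals:
            ratios.append(np.mean(fc_vals) / np.mean(syn_vals))
    if not ratios:
        raise ValueError("no fibre had both an FC dot and syncytial dots")
    return float(np.mean(ratios))


def recover_cotranscription(config: GeneratorConfig, stage: int,
                            n_fibres: int, seed: int,
                            genes: Optional[tuple[str, str]] = None
                            ) -> tuple[float, float]:
    """Pooled (active %, co-transcribing % among active) over all nuclei of
    a double-FISH cohort, via the permissive detection profile."""
    if genes is None:
        genes = tuple(s.gene for s in config.genes[:2])  # type: ignore[assignment]
    a, b = genes
    tables = []
    for fibre in synthetic.simulate_cohort(config, stage, n_fibres, seed):
        nuclei = coloc.nuclei_from_labels(fibre.nuclei_mask, fibre.fibre_id)
        for g in genes:
            _, dots = _quantified(fibre, g, QuantProfile.permissive())
            coloc.mark_states(nuclei, dots, g, fibre.nuclei_mask)
        tables.append(coloc.tabulate_cotranscription(nuclei, a, b, fibre.fibre_id))
    n_total = sum(t.n_total for t in tables)
    n_active = sum(t.n_a_only + t.n_b_only + t.n_both for t in tables)
    n_both = sum(t.n_both for t in tables)
    return (100.0 * n_active / n_total,
            100.0 * n_both / n_active if n_active else float("nan"))


def recover_subdomain_repartition(config: GeneratorConfig, stage: int,
                                  n_fibres: int, seed: int,
                                  gene: Optional[str] = None) -> dict[str, float]:
    """Percentage of detected dots per DA3 subdomain, positions standardized
    against each fibre's measured muscle frame."""
    gene = gene or config.genes[0].gene
    labels = []
    for fibre in synthetic.simulate_cohort(config, stage, n_fibres, seed):
        _, dots = _quantified(fibre, gene, QuantProfile.standard())
        frame = spatial.compute_frame(fibre.muscle_mask.astype(bool))
        for d in dots:
            labels.append(spatial.standardize((d.x, d.y), frame).subdomain)
    return spatial.repartition(labels)


def recover_labelled_fraction(config: GeneratorConfig, stage: int,
                              n_fibres: int, seed: int) -> float:
    """Mean percentage of lineage-labelled nuclei per fibre, with labels
    called from the rendered lineage channel."""
    fractions = []
    for fibre in synthetic.simulate_cohort(config, stage, n_fibres, seed):
        nuclei = coloc.nuclei_from_labels(fibre.nuclei_mask, fibre.fibre_id)
        lin_proj = dot_quant.project(fibre.channels["lineage"], "max")
        coloc.classify_lineage(nuclei, fibre.nuclei_mask, lin_proj)
        n_lab, n_tot = coloc.count_labelled_nuclei(nuclei, fibre.muscle_mask)
        fractions.append(100.0 * n_lab / n_tot)
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# Recovery experiment harness
# ---------------------------------------------------------------------------

def run_recovery_experiment(n_fibres: int = 200, seed: int = 0,
                            experiments: Optional[Sequence[str]] = None
                            ) -> pd.DataFrame:
    """Run the packaged recovery experiments end-to-end and compare each
    recovered statistic to its configured generator parameter.

    Returns a table (experiment, parameter, configured, recovered,
    tolerance, passed).  Tolerances: 15% relative on the FC intensity
    ratio, 10% relative on mean dot counts, 3 binomial/empirical SE on
    fractions.
    """
    rows = []
    seq = np.random.SeedSequence(seed)

    def sub_seed() -> int:
        return int(seq.spawn(1)[0].generate_state(1)[0] % (2**31))

    def add(experiment, parameter, configured, recovered, tol):
        rows.append({"experiment": experiment, "parameter": parameter,
                     "configured": configured, "recovered": recovered,
                     "tolerance": tol,
                     "passed": abs(recovered - configured) <= tol})

    todo = set(experiments) if experiments is not None else None

    def wanted(name: str) -> bool:
        return todo is None or name in todo

    def se3(p: float, n: int) -> float:
        return 3.0 * 100.0 * np.sqrt(p * (1 - p) / n)

    if wanted("fc_intensity_ratio"):
        cfg = packaged_config("da3_col_stage14")
        m = cfg.gene_spec("col").fc_intensity_multiplier
        r = recover_fc_intensity_ratio(cfg, 14, n_fibres, sub_seed())
        add("fc_intensity_ratio", "col FC/syncytial IntDen fold", m, r, 0.15 * m)

    for name, muscle in (("dt1_s59_stage15", "DT1"), ("va2_s59_stage15", "VA2"),
                         ("vt1_s59_stage15", "VT1")):
        if not wanted(name):
            continue
        cfg = packaged_config(name)
        p = cfg.gene_spec("S59").p_on(15)
        n_nuc = cfg.nuclei_per_stage[15] * n_fibres
        r = recover_active_fraction(cfg, 15, n_fibres, sub_seed())
        add(name, f"S59 active nuclei % ({muscle})", 100 * p, r, se3(p, n_nuc))

    if wanted("dt1_kon_stage15"):
        cfg = packaged_config("dt1_kon_stage15")
        mean_dots = cfg.nuclei_per_stage[15] * cfg.gene_spec("kon").p_on(15)
        r, _ = recover_mean_dots(cfg, 15, n_fibres, sub_seed())
        add("dt1_kon_stage15", "kon dots/fibre (DT1, stage 15)",
            mean_dots, r, 0.10 * mean_dots)

    if wanted("pax_stage15"):
        cfg = packaged_config("pax_stage_course")
        mean_dots = cfg.nuclei_per_stage[15] * cfg.gene_spec("Pax").p_on(15)
        r, _ = recover_mean_dots(cfg, 15, n_fibres, sub_seed())
        add("pax_stage15", "Pax dots/fibre (stage 15)", mean_dots, r,
            0.10 * mean_dots)

    if wanted("dufcol_joint"):
        cfg = packaged_config("da3_dufcol_stage14")
        table = cfg.joint_tables["dufcol"]
        n_nuc = cfg.nuclei_per_stage[14] * n_fibres
        union, co = recover_cotranscription(cfg, 14, n_fibres, sub_seed())
        add("dufcol_joint", "duf/col union %", 100 * table.p_union, union,
            se3(table.p_union, n_nuc))
        add("dufcol_joint", "duf/col co-transcription % of active",
            100 * table.p_both_given_union, co,
            se3(table.p_both_given_union, int(n_nuc * table.p_union)))

    if wanted("con_subdomain"):
        cfg = packaged_config("da3_con_stage14")
        p = cfg.fc_subdomain_weights["central"]
        rep = recover_subdomain_repartition(cfg, 14, n_fibres, sub_seed())
        add("con_subdomain", "Con dots in central subdomain %", 100 * p,
            rep[spatial.CENTRAL], se3(p, n_fibres))

    if wanted("kr_single_dot"):
        cfg = packaged_config("ll1_kr")
        r, meas = recover_mean_dots(cfg, 13, n_fibres, sub_seed())
        exact = float(np.mean([m.n_dots == 1 for m in meas]))
        add("kr_single_dot", "Kr dots/fibre", 1.0, r, 0.0)
        add("kr_single_dot", "fraction of fibres with exactly 1 Kr dot",
            1.0, exact, 0.0)

    if wanted("recruitment_mixing"):
        cfg = packaged_config("da3_recruitment_stage15")
        p = cfg.labelled_fraction
        n_nuc = cfg.nuclei_per_stage[15] * n_fibres
        r = recover_labelled_fraction(cfg, 15, n_fibres, sub_seed())
        add("recruitment_mixing", "lineage-labelled nuclei %", 100 * p, r,
            se3(p, n_nuc))

    return pd.DataFrame(rows, columns=["experiment", "parameter", "configured",
                                       "recovered", "tolerance", "passed"])


def export_report(summaries: Optional[pd.DataFrame],
                  tests: Sequence[TestResult],
                  repartitions: Optional[pd.DataFrame],
                  out_dir, metadata: Optional[dict] = None) -> Path:
    """Write summary.csv / tests.csv / repartition.csv plus a plain-text
    report with run metadata; identical inputs yield identical files."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        lines = ["musclefish report"]
        for k in sorted(metadata or {}):
            lines.append(f"{k}: {metadata[k]}")
        if summaries is not None:
            summaries.to_csv(out / "summary.csv", index=False)
            lines.append(f"summary groups: {len(summaries)}")
        if tests:
            tdf = pd.DataFrame([{"name": t.name, "statistic": t.statistic,
                                 "df": t.df, "p_value": t.p_value,
                                 "significance": t.significance} for t in tests])
            tdf.to_csv(out / "tests.csv", index=False)
            lines.append(f"tests run: {len(tests)}")
        if repartitions is not None:
            repartitions.to_csv(out / "repartition.csv", index=False)
        lines.append("note: no multiple-testing correction is applied")
        (out / "report.txt").write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"failed to write report under {out}: {exc}") from exc
    return out
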