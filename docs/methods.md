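# Methods

## The measurement problem

In syncytial *Drosophila* muscles, transcription of identity and
realisation genes is episodic: at fixation, only some nuclei of a fibre
carry a nascent-transcript FISH dot, and dot brightness varies with the
transcription initiation rate. The package quantifies this regime with
three read-outs — dot counts per fibre, integrated density (IntDen) per
dot, and per-nucleus ON/OFF tables for one or two genes — plus a spatial
read-out that standardises dot and nucleus positions within the DA3 muscle
frame. Because such measurements are normally validated by eye, the
package pairs the pipeline with a generator that renders images from a
known stochastic model, so every stage can be checked against ground
truth and against brute-force oracles.

## Generative model

**Geometry.** A fibre is a 2-D muscle outline extruded over a few Z slices
of a (8, 128, 192) stack. The outline is the flat-capped buffer of a
template midline: an angled chevron for DA3 (its transient tripartite
attachment gives it a bent shape at late stage 14) and straight bands for
DT1/LL1/VA2/VT1. Nuclei are discs (radius 5 px) packed by rejection
sampling with a minimum centre separation (default 2 radii); the founder
nucleus is placed first, either at the fibre centre with ±4 px jitter or —
for the FC-positional experiment — at a pixel drawn from configured
weights over the antero-ventral/central/postero-dorsal partition of the
template. Packing that cannot satisfy the separation constraint fails
loudly rather than degrading.

**Nuclei counts per stage** default to 1 (stage 12, the founder alone),
4, 8, 12, 14 through the fusion period for the dorsolateral muscles, with
a smaller table (1, 3, 6, 8, 9) for the ventral muscles. These are
calibration defaults expressing the growth narrative — one founder rising
through fusion, DA3 and DT1 similar — not measured values, and all
percentage read-outs normalise them away.

**Transcriptional states.** Each gene is Bernoulli-ON per nucleus with a
stage-dependent probability `p_on`. Three refinements:

- *FC restriction* (`fc_restricted`): genes such as *Kr*, or *Con* in DA3,
  can be ON only in the founder nucleus; with `p_on = 1` this yields
  exactly one dot per fibre.
- *Mutual exclusion* (`exclusion_group`): programmes that are never
  co-active in one nucleus (*sns* vs *col*/*duf*) are drawn as a single
  categorical over (members…, none), which preserves each marginal while
  making joint activation structurally impossible.
- *Correlated pairs* (`joint_table`): a categorical law over
  {both, A-only, B-only, neither}. This exists because a high union with
  moderate co-activation is infeasible under independence: union 0.8 with
  co|active 0.5 would need marginals summing to 1.2 while multiplying to
  0.4. The packaged duf/col table {0.4, 0.2, 0.2, 0.2} is the minimal
  joint law with union 80% and co|active 50%.

**Intensities.** Dot intensity is log-normal with configurable mean
(default 5000 a.u.) and coefficient of variation (default 0.3); the
founder nucleus can transcribe at a multiple of the syncytial mean
(9-fold for *col* at stage 14 in the packaged configuration).

**Rendering.** Each ON nucleus carries one isotropic 2-D Gaussian spot
(σ = 1.5 px, single parameter — no attempt at a realistic PSF) spread
evenly over the fibre's Z range; the discrete kernel is renormalised so
the rendered pixel sum equals the drawn intensity exactly, which makes
intensity conservation testable to rounding. A spot whose 17×17 window
would leave the frame is an error, never a silent clip. Muscle and nuclear
channels are filled shapes at 100 a.u.; the lineage channel renders
labelled nuclei at 150 and unlabelled at 20. Optional noise is Poisson
shot noise plus Gaussian read noise, both off by default so fixtures are
clean; robustness is exercised separately.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optics (no 3-D PSF, no chromatic shift), uneven
illumination and bleed-through, nuclear texture, fibre curvature,
segmentation error in hand-drawn muscle outlines, and the cell biology of
fusion itself (only its statistical consequences appear). Recovery results
certify the measurement chain, not the microscope.

## Measurement pipeline

Order is fixed: sum-slices projection → threshold (strictly `pixel > t`;
ties are background) → 8-connected particle analysis with `min_area` ≥ 2
px → muscle-mask intersection → Z filter → IntDen. Choices worth noting:

- **Profiles.** The *standard* profile (absolute threshold 5 a.u.,
  min_area 2) serves single-gene stage courses. The *permissive* profile
  (threshold = background median + 2 robust SD, min_area 1) serves
  double-FISH nucleus tabulation, where every dot counts however weak. On
  noise-free images the background estimate degenerates to zero, so it is
  floored at 2% of the dynamic range — low enough to catch dots several
  fold dimmer than the brightest, high enough that the far Gaussian tails
  of spots in adjacent nuclei do not fuse into one particle. An Otsu
  fallback exists for unknown data; it refuses constant images.
- **"AND" intersection** is membership of the dot's centroid pixel in the
  muscle mask, so a boundary-straddling dot belongs to exactly one muscle
  and per-muscle counts cannot double-count. Nuclei are counted with the
  same centroid rule.
- **Z filter.** The manual curation step — discarding dots above or below
  the muscle — is automated: a dot's Z peak (argmax of summed footprint
  intensity per slice) must lie within the fibre's slice range ± 1.
- **Dot→nucleus assignment**: containment of the dot centroid in a
  nucleus mask wins; otherwise the nearest nucleus centroid within 1.5 ×
  the median nucleus radius; ties break by distance then by smaller id.
  The distance rule is an artifact decision (the original call was visual)
  and its parameters are exposed. A nucleus with two dots of one gene
  (sister loci) counts once.
- **Nucleus segmentation** (threshold + distance-transform watershed) is
  provided for raw nuclear channels, but pipelines accept label masks
  directly, and the recovery experiments use the generator's masks — the
  quantity under test is the dot measurement chain, not segmentation.

Two deliberate readings of ambiguous conventions, both configurable:
thresholding is strict (`>`), and in the subdomain rule antero-ventral
(standΔY < −1) takes priority over postero-dorsal (standΔX > 1), with
boundary equalities falling to central — the printed inequalities are
strict, and the overlap corner is otherwise unassigned. The ×100/area
standardisation is kept verbatim, which makes standardized units scale
*with* the image (a uniform rescale by s divides them by s); a property
test documents this rather than hiding it. Spatial work uses the
max-intensity projection convention and assumes dorsal-up, anterior-left
framing; `orient_and_crop` rotates a fibre's principal axis onto X for
inputs that need it.

## Statistics

Summaries use the supplementary-table convention (mean ± SD with n−1,
SEM, min/max, per muscle/gene/stage). The unpaired t-test defaults to
equal variances — the likely instrument behind the published comparisons,
which do not state otherwise — with Welch as a flag. Pearson's χ² on k×2
active/inactive tables uses no continuity correction, df = k−1. The star
convention is ns/*/**/*** at 0.05/0.01/0.001. No multiple-testing
correction is applied, matching the source workflow; the report says so.
Zero-variance identical groups return t = 0, p = 1 by convention.

## Recovery experiments and problem sizes

`stats_report.run_recovery_experiment` simulates each packaged cohort,
runs the full pipeline on rendered images, and compares recovered
statistics with configured parameters: FC/syncytial IntDen fold (within
15%), mean dots per fibre (within 10%), all fraction-type read-outs
(within 3 binomial SE), and the FC-restricted single-dot invariant
(exact). Cohorts of 200 fibres keep every experiment under a minute on one
CPU while holding binomial SEs on fractions near one percentage point;
property suites use 10,000 nuclei for frequency convergence and ~100
random instances per brute-force oracle. Known small biases at this scale:
per-fibre ratio-of-means estimation adds a few percent (Jensen) to the FC
fold change, and spots in nuclei at the minimum separation occasionally
fuse, trimming dot counts by ~1–2% — both well inside the stated
tolerances and inherent to projection-based counting rather than to the
implementation.
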