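# musclefish

Quantification of nascent-transcript FISH signals in syncytial *Drosophila*
body-wall muscles, together with a ground-truthed synthetic image generator
that makes every stage of the pipeline testable without microscopy data.

Each larval body-wall muscle is a syncytium formed by fusion of one founder
cell (FC) with fusion-competent myoblasts (FCMs). Intronic FISH probes
detect active transcription as a nuclear dot at the gene locus, so at any
time point the nuclei of one fibre are a mixture of ON and OFF states —
transcription is bursty rather than synchronous. The measurements that
characterise this regime, per fibre, per gene and per embryonic stage
(12–16), are:

- the number of transcription dots (nuclei caught in an ON phase),
- each dot's **integrated density**, IntDen = Σ pixel values over the dot
  region of the sum-projection, a proxy for transcription initiation rate,
- the **Total IntDen per fibre**, Σ of its dots' IntDen,
- per-nucleus (co-)transcription tables for double-FISH: counts of nuclei
  in {A only, B only, both, neither} and the derived fractions
  *active* = (A+B+both)/total and *co|active* = both/active,
- standardized dot/nucleus positions in the DA3 muscle frame:
  ΔX = X − X_DA3, ΔY = −(Y − Y_DA3), standΔX = ΔX·100/Area,
  standΔY = ΔY·100/Area, classified into antero-ventral (standΔY < −1),
  postero-dorsal (standΔX > 1) and central subdomains.

The pipeline mirrors the classical ImageJ workflow: sum-slices projection →
intensity threshold ("mask of dots") → particle analysis (8-connected
components) → AND-intersection with the muscle mask → Z filter → IntDen
measurement. The generator renders multi-channel Z-stacks (dot, nuclear,
muscle-outline, optional lineage channel) with known per-nucleus states,
dot intensities and positions, so recovered statistics can be compared
against configured truth.

## Modules

| module | role |
| --- | --- |
| `musclefish.config` | generator/burst-model configuration, YAML I/O, packaged cohort presets |
| `musclefish.synthetic` | fibre geometry, ON/OFF state sampling, stack rendering, dataset I/O |
| `musclefish.dot_quant` | projection, thresholding, particle analysis, IntDen |
| `musclefish.coloc` | nucleus segmentation, dot→nucleus assignment, co-transcription tables, lineage counting |
| `musclefish.spatial` | muscle frame, coordinate standardisation, subdomain classification |
| `musclefish.stats_report` | summaries (mean ± SD, SEM, min/max), unpaired t-test, Pearson χ², parameter-recovery harness |

## Worked example

```python
import numpy as np
from musclefish import packaged_config, simulate_fibre, quantify_fibre

cfg = packaged_config("dt1_s59_stage15")          # S59 in DT1, p_on = 0.45
fibre = simulate_fibre(cfg, 15, np.random.default_rng(1))
meas, dots = quantify_fibre(fibre.channels["fish_S59"], fibre.muscle_mask,
                            fibre.nuclei_mask, z_extent=fibre.geometry.z_extent,
                            gene="S59", stage=15)
print(f"nuclei={meas.n_nuclei}  dots={meas.n_dots}  total_intden={meas.total_intden:.0f}")
for d in dots:
    print(f"  dot at ({d.x:5.1f}, {d.y:5.1f})  area={d.area}  intden={d.intden:.0f}")
```

prints

```
nuclei=12  dots=6  total_intden=28789
  dot at ( 90.5,  57.9)  area=58  intden=4731
  dot at ( 34.2,  64.4)  area=59  intden=4763
  dot at (130.0,  64.5)  area=60  intden=4464
  dot at ( 80.0,  67.2)  area=57  intden=3811
  dot at (157.9,  67.1)  area=65  intden=6090
  dot at ( 48.3,  70.2)  area=61  intden=4929
```

Six of the twelve DT1 nuclei were caught transcribing *S59*; each detected
dot's IntDen sits within a few percent of the intensity the generator drew
for it (the remainder is the sub-threshold Gaussian tail), and the
per-fibre active fraction (6/12) fluctuates around the configured burst
probability of 0.45.

The same stages are available from the shell:

```sh
musclefish simulate --preset dt1_s59_stage15 --stage 15 --n-fibres 20 --out data --seed 4
musclefish quantify --images data --out quant --z-extent 2 6
musclefish coloc    --images data --genes duf,col --out co
musclefish spatial  --dots quant/dots.csv --masks data --out sp
musclefish recover  --n-fibres 200 --seed 0
```

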