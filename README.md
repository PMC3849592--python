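# fiberox

Per-myofiber quantification of oxidative damage and cross-sectional
area in muscle histology, with a ground-truthed synthetic cohort
generator for validating every step.

## The problem

In peripheral arterial disease (PAD), atherosclerotic blockages starve
leg muscles of blood, and a progressive myopathy develops: myofibers
accumulate oxidative damage and shrink. Quantitative fluorescence
microscopy can resolve this fiber by fiber: muscle cross-sections are
imaged in three channels — a wheat-germ-agglutinin membrane
(sarcolemma) label that outlines each fiber, a hydrazide-based label
for protein **carbonyl groups**, and an antibody label for
**4-hydroxy-2-nonenal (HNE) Michael adducts**. `fiberox` implements
the complete analysis for such data, aimed at muscle-biology groups
doing per-cell morphometry and damage quantification on biopsy
sections:

1. **segment** individual myofibers from the membrane channel;
2. **quantify**, per fiber, the background-corrected mean signal of
   each damage marker in grayscale units (gsu, 12-bit scale) and the
   cross-sectional area (CSA, µm²), then pool fiber-weighted specimen
   means;
3. **stratify** each patient's fibers into quartile classes Q1–Q4 of a
   damage marker (Q1 ≤ lower quartile < Q2 ≤ median < Q3 ≤ upper
   quartile < Q4) and compare class CSA means;
4. **test** cohort-level hypotheses: ANCOVA-style group contrasts
   adjusted for coronary artery disease (CAD) and hypertension (HTN),
   linear damage trends over Fontaine stage, Pearson partial
   correlations of damage with the ankle-brachial index (ABI), and a
   within-patient repeated-measures model of quartile-class CSA with
   least-squares post hoc contrasts.

Because clinical images are rarely shareable, the package ships a
first-class **synthetic data module**: centroidal-Voronoi fiber
tessellations rendered into three 12-bit channels with configurable
point-spread blur and camera noise, on top of a patient-level
statistical model (group means, stage and ABI effects, patient and
fiber random effects, damage–CSA coupling) whose every parameter is
known ground truth.

## Core model

For patient *i* in the diseased group, the programmed specimen mean of
a damage marker is

```
μ_i = μ_group + b_s (S_i − E[S]) + b_a (ABI_i − E[ABI]) + u_i,   u_i ~ N(0, σ_p²)
```

with Fontaine stage `S ∈ {2,3,4}` and stage-dependent ABI. Fiber *j*
of patient *i* draws a shared damage latent `d_ij ~ N(0,1)`:

```
carbonyl_ij = μ_i^c + σ_f^c d_ij + ε,    hne_ij = μ_i^h + σ_f^h d_ij + ε,
CSA_ij = μ_i^csa + γ σ_f^c d_ij + η,     γ ≤ 0 in disease, γ = 0 in controls
```

so the most damaged fibers are also the smallest, for both markers.
The analysis side never sees these parameters; recovering them from
rendered or tabulated cohorts is the package's acceptance standard.

## Worked example

Run a small end-to-end demo — 2 control and 3 PAD patients, three
512×512 px fields each, simulated, segmented, measured, stratified and
tested:

```python
from fiberox.pipeline import RunConfig, run_all

cfg = RunConfig(
    outdir="demo", seed=7,
    cohort=dict(n_control=2, n_pad=3, fields_per_specimen_range=(3, 3)),
    field_cfg=dict(image_height_px=512, image_width_px=512),
)
manifest = run_all(cfg)
```

This writes TIFF images, label maps, fiber/summary/quartile CSV
tables, a results JSON, figures and a hashed run manifest under
`demo/`. The generated `demo/stats/report.txt` reads:

```
fiberox cohort report
=====================

carbonyl: adjusted means control=503.7 pad=615.0  Δ%=+18.1 (vs larger)  F[group]=2.55 p=0.25
hne: adjusted means control=231.7 pad=352.0  Δ%=+34.2 (vs larger)  F[group]=2.70 p=0.24
csa: adjusted means control=4302.7 pad=3217.6  Δ%=-25.2 (vs larger)  F[group]=1.34 p=0.37
stage trend carbonyl: slope=108.2 gsu/stage R²=1.00 p=nan
stage trend hne: slope=97.5 gsu/stage R²=1.00 p=nan
quartile RM carbonyl_pad: F=0.26 p=0.85 (0 post hoc contrasts)
...
```

Read it as: measured PAD fibers carry more carbonyl (+18%) and HNE
(+34%) signal and 25% less cross-sectional area than controls — the
direction programmed into the generator — but with only five patients
nothing reaches significance, and the saturated three-patient stage
regression has no residual degrees of freedom (R² = 1, p undefined).
At realistic cohort sizes (21 control / 34 PAD, 400+ fibers each) the
same estimators recover the programmed effects; see the test suite and
the acceptance script.

The same stages are scriptable from a shell:

```
fiberox simulate --seed 7 --outdir demo
fiberox segment --in demo/images/PAD01_f01.tif --out labels.tif
fiberox run --config run.yaml
fiberox validate --dir demo
```

## Layout

| module | role |
| --- | --- |
| `fiberox.synthdata` | synthetic cohorts: patients, fields, ground truth |
| `fiberox.segment` | membrane-channel fiber segmentation + IoU matching |
| `fiberox.quantify` | background estimation, per-fiber measurement, pooling |
| `fiberox.quartiles` | damage-quartile classes and class CSA means |
| `fiberox.stats` | cohort statistics (ANCOVA, trends, partial r, RM model) |
| `fiberox.pipeline` | orchestration, manifests, input validation |
| `fiberox.cli` | `fiberox` command-line entry points |

See `docs/methods.md` for the underlying models, parameter defaults
and known limitations.
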