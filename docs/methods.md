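# Methods

This note documents the models implemented in `fiberox`, the defaults
and why they were chosen, what the synthetic data do and do not
emulate, and the numerical conventions that affect results.

## Imaging model and units

All intensities are grayscale units (gsu) on a 12-bit scale
(0–4095), the native scale of a monochrome CCD camera. A field is
three co-registered channels: membrane (sarcolemma), carbonyl, HNE.
The camera contributes a constant black level (`camera_black_gsu`,
default 100 gsu) to every pixel; fluorescence adds on top of it. The
default pixel size is 0.65 µm/px, typical for a 10× objective on a
1.3 MP-class scientific CCD; it is configurable because magnification
and chip geometry vary between rigs.

A biological asymmetry between the two damage markers is built in and
exploited throughout: carbonyl signal is genuinely present in the
extracellular matrix (ECM) between fibers (`ecm_carbonyl_gsu`, default
300 gsu above black), whereas HNE adducts are confined to fiber
interiors — extracellular HNE is exactly the camera black when noise
is off. This is why the two markers need different background
conventions (below).

## Synthetic cohorts

### Patient layer

A cohort has `n_control` (default 21) and `n_pad` (default 34)
patients. PAD patients draw a Fontaine stage from proportions
13 : 9 : 12 over stages 2/3/4 and an ABI from a truncated normal
inside [0.01, 0.81] whose mean falls with stage (0.50 / 0.34 / 0.18 at
stages 2/3/4, within-stage SD 0.15); controls draw ABI from a
truncated normal 1.13 ± 0.21 on [0.94, 1.34]. CAD and HTN are
independent Bernoulli draws at group prevalences 23.8%/61.7% and
57.1%/82.3%. These values parameterize the generator at the
conditions of the reference control/PAD gastrocnemius cohorts.

The programmed specimen mean of marker *m* for a PAD patient is

    mu_i = group_mean_m + b_s^m (S_i − E[S]) + b_a^m (ABI_i − E[ABI]) + u_i

Group means/SDs default to carbonyl 486 ± 135 (control) and 695 ± 132
(PAD) gsu, HNE 261 ± 101 and 436 ± 119 gsu, CSA 5,324 ± 1,371 and
3,760 ± 1,546 µm². Centring uses the *exact truncated-normal* moments
of the stage/ABI joint model, so the PAD group mean is recovered
without bias regardless of the effect sizes.

The stage and ABI effects are per-marker pairs: `b_s` = (90, 80)
gsu/stage and `b_a` = (−300, −250) gsu per ABI unit for (carbonyl,
HNE). Because ABI falls with stage, the *marginal* damage increment
per stage is `b_s + b_a·Cov(S, ABI)/Var(S)` ≈ 132 (carbonyl) and 115
(HNE) gsu/stage; with these defaults the marginal stage means land
near 561/699/837 gsu for carbonyl and 320/438/559 for HNE — close to
the reference stage profiles (552/707/827 and 310/454/548). One shared
effect value could not hit both markers' profiles, which is why the
pair parameterization exists. `CohortConfig.marginal_stage_slope()`
returns the implied slope so recovery tests compare against the right
estimand.

The quoted group SDs are *specimen-level* SDs, so the patient random
effect u_i cannot simply use them: for PAD patients the stage/ABI
model already contributes ≈ 120 (carbonyl) and 104 (HNE) gsu of
between-patient spread. The generator subtracts this systematic
variance analytically and assigns the remainder to u_i (with a floor
of 15% of the group SD). Controls have no systematic part, so their
patient SD is the group SD.

### Fiber layer

Within a specimen, each fiber draws a shared standard-normal damage
latent `d`; carbonyl and HNE deviations are `σ_f^c d` and `σ_f^h d`
plus small independent noise (30 gsu). Defaults `σ_f^c` = 150 and
`σ_f^h` = 120 gsu are a modeling choice: no specimen-level report
constrains within-specimen fiber spread, and these values give the
wide fiber-to-fiber variation visible in stained PAD sections without
driving a large fraction of fibers to zero. The shared latent makes
the two markers agree fiber-by-fiber and specimen-by-specimen
(specimen-mean correlation ≈ 0.8 at defaults), as real sections show.

Fiber CSA couples to the same latent: `CSA = μ_csa + γ σ_f^c d +
noise`, with γ = −1.55 µm²/gsu in PAD and 0 in controls, fiber CSA
noise SD 1,300 µm². The mean of the top and bottom quartile of a
standard normal is ±1.27, so the programmed Q4 − Q1 CSA deficit is
γ·σ_f^c·2.54 ≈ −590 µm², matching the magnitude of the reference
quartile tables; the zero control coupling reproduces their flat
control rows. Fiber damage values below 0 gsu are clipped only when
pixels are rendered (a camera cannot go below black); the table-only
ground truth keeps the unclipped draws so cohort statistics stay
exactly unbiased.

Each specimen contributes 5–15 fields (uniform draw) of 80 fibers by
default in table mode, i.e. 400–1,200 fibers per specimen, inside the
400–2,800 range typical of this assay.

### Geometry layer

A rendered field is a centroidal-relaxed random-point tessellation:
seed points are placed uniformly, Lloyd-relaxed twice on the pixel
grid (region centroids become new seeds), and each pixel takes the
label of its nearest seed. Pixels whose two nearest-seed distances
differ by less than `membrane_width_px` (default 3 px ≈ 2 µm) form
the membrane rim; rims widen naturally at three-cell junctions, as
WGA staining does. Fibers at the image border keep their interiors
open to the edge — fields truncate fibers exactly as real
acquisitions do, and the ground truth flags them (`touches_border`).

Ground-truth CSA is defined as interior pixel count × pixel size² —
what an ideal segmenter measuring the same raster would report. The
stored per-fiber polygon (convex hull of interior pixel centres) is
descriptive geometry for plotting, not the area authority.

When the damage sampler supplies per-fiber CSA targets, damage values
are assigned to tessellation cells by CSA rank, so the programmed
damage–size coupling survives rendering even though cell areas are
set by the tessellation, not by the draw. The per-patient fiber count
per field is chosen as 0.88 × field area / target mean CSA (≈ 12% of
a default field is membrane rim), which makes realized mean CSA track
the programmed specimen mean approximately; the exact statistical
ground truth lives in the table-mode output.

Optional realism layers, in order: Gaussian point-spread blur
(`psf_sigma_px`), Poisson shot noise, Gaussian read noise
(`noise_scale` gsu) — the standard CCD model — then clamping to
[0, 4095]. All defaults are off/0 so that the exactness contracts
(extracellular HNE = black, interior = black + programmed level) hold
identically.

What the generator does **not** emulate: fatty infiltration,
endomysial fibrosis beyond the uniform ECM carbonyl level, target
lesions, nuclei (no DAPI channel), staining chemistry, uneven
illumination, or section-folding artifacts. Passing tests therefore
demonstrate correctness of the measurement and inference machinery on
membrane-delineated convex fibers with known signal — not robustness
to every pathology of real histology.

## Segmentation

Gaussian smoothing (σ = 1 px) → Otsu threshold of the membrane
channel → morphological closing (radius 1) → connected components of
the mask complement with 4-connectivity (so fibers cannot leak through
diagonal rim gaps) → border and size filtering → consecutive
relabeling. A marker-based watershed refinement
(`watershed_refine=True`) splits merged fibers on noisy inputs using
the interior distance transform. This is deliberately the simplest
algorithm satisfying the contract for ridge-delineated convex fibers;
the commercial software used in the original assay is undocumented,
so the package treats segmentation as a replaceable component held to
a measurable standard: on noise-free default fields, precision and
recall ≥ 0.95 against ground truth (IoU ≥ 0.5, greedy one-to-one
matching) and median |area error| ≤ 5%. In practice all three are
exact (1.0 / 1.0 / < 1%) at defaults.

Size filters default to 200–20,000 µm², bracketing the plausible
human myofiber CSA range with wide margins. Border-touching fibers
are excluded from all downstream statistics because their CSA is
truncated; their pixels are tracked separately (`excluded_mask`) so
they are never mistaken for extracellular background.

## Quantification

Per fiber: mean channel intensity over the fiber's pixels minus a
per-field background, and CSA = pixel count × pixel size². Negative
corrected means are kept — clamping would bias group means upward.
Specimen summaries are **fiber-weighted**: all fibers pooled across
fields, every fiber counting once (a two-field specimen with fibers
{100, 200} and {300} gsu means 200, not 175).

Background is estimated once per field and channel. For HNE the
extracellular median equals the camera black exactly (no ECM signal).
For carbonyl the extracellular median would *over-correct* — the ECM
carbonyl is real signal — so the default carbonyl background is the
black-level estimate taken from the **HNE channel's** extracellular
median; a fixed configured value is also supported. Whether the
original assay corrected per field or globally is unknowable from its
description; both options are exposed.

## Quartile classes

Per patient and marker, the 25th/50th/75th percentiles of all pooled
fibers define Q1–Q4 with ties falling in the lower class (Q1 ≤ lower
quartile < Q2 ≤ median < Q3 ≤ upper quartile < Q4). Percentiles use
linear interpolation between order statistics (numpy's default,
"type 7"); the convention is a config option because boundary fibers
change class under other conventions. Empty classes report a missing
mean, never 0, so the repeated-measures model drops them.

## Statistics

All models are OLS on explicit design matrices (statsmodels).

* **Group comparison** — `outcome ~ group + CAD + HTN`. The group
  term is tested with a partial F (numerator df 1; equals t² of the
  group coefficient); the result also carries the overall model F
  with (df_model, df_resid) for the conventional F_{3,51}-style
  report at n = 55. Adjusted means are least-squares means at pooled
  covariate prevalences. Constant covariates are dropped with a
  warning rather than making the design singular.
* **Percent difference** — two conventions, both reported:
  `vs_control` = (PAD − control)/control, and `vs_larger` =
  (PAD − control)/max(both). At the reference means the increases
  print as +30.07% (carbonyl) and +40.14% (HNE) under `vs_larger`
  and the CSA reduction as −29.38% under either (control is larger).
  Which denominator the reference damage percentages used is not
  derivable from the reported means — only `vs_larger` reproduces
  all three printed values — so the ambiguity is documented rather
  than resolved, and `vs_larger` is the default.
* **Stage trend** — outcome on numeric stage (2/3/4) + covariates;
  a single slope with the fitted model's R², matching the
  single-R²-per-marker reporting convention.
* **ABI partial correlation** — residual method (outcome and ABI each
  regressed on covariates, residuals correlated); p from t with
  n − k − 2 df, 95% CI by Fisher z with variance 1/(n − k − 3).
  Cross-checked in the tests against an independent normal-equations
  oracle and against `pingouin.partial_corr`.
* **Quartile repeated-measures model** — class-mean CSA on class
  fixed effect + patient blocking effect (the within-subject ANOVA on
  up to four repeated values per patient). The overall class effect
  is a partial F; when significant at α = 0.05, least-squares
  contrasts of Q4 against Q1/Q2/Q3 are reported unadjusted (matching
  the raw-pairwise-p reporting convention); Holm adjustment is a
  flag. A zero-residual (saturated or perfectly flat) fit returns
  p = 1 when the class effect is null rather than a 0/0 F.
* **Demographics** — chi-square without continuity correction for
  binary variables (the CAD table 5/21 vs 21/34 gives χ² = 7.50,
  HTN 12/21 vs 28/34 gives 4.15), one-way F for continuous ones;
  significant variables are flagged as covariate candidates.

Type-I error of the stage-trend and repeated-measures tests is
verified by 1,000-rep null simulations at reduced n (20 patients / 8
patients), with acceptance bounds from the exact binomial 99%
interval at the nominal 5% level.

## Problem sizes and determinism

Everything is reproducible from a single integer seed
(`numpy.random.default_rng`); identical config + seed gives
bit-identical images, tables and file hashes. The validation suites
use: ten noise-free default fields (≈ 35 interior fibers each) for
segmentation fidelity; ten full-size table-mode cohorts (21/34
patients, 400–1,200 fibers each) for parameter recovery — the
statistical layer is exactly the ground truth those criteria probe,
while image-path fidelity is established separately on rendered
fields and in the end-to-end pipeline test; and 1,000-rep null
simulations for calibration. Parameter recovery is judged against
3 standard errors of the across-seed mean.

## Known limitations

* Segmentation is tuned for membrane-ridge-delineated convex fibers;
  heavily fibrotic or fat-infiltrated sections will need the
  watershed flag and possibly different thresholds.
* The ABI–stage joint model is a linear-mean truncated normal; real
  cohorts have heavier tails and measurement error in ABI.
* The repeated-measures model treats patients as fixed blocks; with
  many missing classes a mixed model would use information more
  efficiently.
* Rendered-mode realized CSA tracks programmed CSA only through the
  fiber-count heuristic and rank assignment; per-fiber CSA in images
  is tessellation-determined, not an exact draw from the programmed
  distribution.
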