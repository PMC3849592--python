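"""Synthetic three-channel muscle-section cohorts with known ground truth.

The generator emulates the structure that the downstream analysis
assumes, at two coupled levels:

* **Cohort statistics** — per-patient mean damage (gsu) for the carbonyl
  and HNE markers is group mean + Fontaine-stage effect + ABI effect +
  patient random effect; individual fibers scatter around that mean with
  a shared fiber-level latent, and fiber cross-sectional area (CSA) is
  coupled (negatively, in disease) to that latent.  Defaults reproduce
  the magnitudes observed in peripheral-arterial-disease (PAD) vs
  control gastrocnemius cohorts: control/PAD carbonyl 486/695 gsu, HNE
  261/436 gsu, CSA 5,324/3,760 µm², stage-dependent damage and an
  ABI-damage anticorrelation.

* **Field geometry** — each microscopic field is a centroidal-relaxed
  random-point tessellation: convex polygonal fibers separated by a
  bright membrane (sarcolemma) rim.  Carbonyl signal is present both in
  fibers and in the extracellular matrix (ECM); HNE signal is confined
  to fiber interiors, so extracellular HNE sits exactly at the camera
  black level when noise is off.  All intensities live on a 12-bit
  grayscale (0–4095 gsu).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.stats import truncnorm

from fiberox.io import MAX_GSU, ImageStack, write_image_stack

BIT_DEPTH = 12

STAGES = (2, 3, 4)

#: minimum CSA a generated fiber may be assigned (µm²); avoids non-physical
#: negative areas in the far tail of the normal draw
MIN_FIBER_CSA_UM2 = 50.0


class FieldTooCrowdedError(ValueError):
    """fibers_per_field too large for the image area (minimum feasible fiber size violated)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class FieldConfig:
    """Geometry and camera model of one microscopic field."""

    image_height_px: int = 768
    image_width_px: int = 768
    pixel_size_um: float = 0.65
    fibers_per_field: int = 60
    membrane_width_px: float = 3.0
    membrane_intensity_gsu: float = 3000.0
    camera_black_gsu: float = 100.0
    ecm_carbonyl_gsu: float = 300.0
    psf_sigma_px: float = 0.0
    noise_model: str = "none"  # none | gaussian | poisson_gaussian
    noise_scale: float = 0.0
    lloyd_iterations: int = 2

    def __post_init__(self) -> None:
        if self.fibers_per_field < 1:
            raise ValueError("fibers_per_field must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.membrane_width_px <= 0:
            raise ValueError("membrane_width_px must be > 0")
        if not 0 <= self.membrane_intensity_gsu <= MAX_GSU:
            raise ValueError("membrane_intensity_gsu outside [0, 4095]")
        if self.camera_black_gsu < 0 or self.psf_sigma_px < 0 or self.noise_scale < 0:
            raise ValueError("camera_black_gsu, psf_sigma_px, noise_scale must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class CohortConfig:
    """Cohort composition, effect sizes and variance components.

    Defaults are parameterized from the reference control/PAD cohorts
    (21 controls, 34 PAD patients; Fontaine stages 2/3/4 in proportions
    13:9:12; specimen-level means/SDs as documented in the class
    attributes).  ``stage_effect_gsu_per_stage`` and ``abi_damage_slope``
    are (carbonyl, hne) pairs.

    ``fiber_level_sd_gsu`` / ``fiber_level_sd_hne_gsu`` set the
    within-specimen fiber-to-fiber spread of the shared damage latent;
    no specimen-level report constrains them, so they are a modeling
    choice (see docs/methods.md).
    """

    n_control: int = 21
    n_pad: int = 34
    stage_proportions: dict[int, float] = field(
        default_factory=lambda: {2: 13 / 34, 3: 9 / 34, 4: 12 / 34}
    )
    fields_per_specimen_range: tuple[int, int] = (5, 15)
    fibers_per_field: int = 80

    control_csa_mean_um2: float = 5324.0
    control_csa_sd_um2: float = 1371.0
    pad_csa_mean_um2: float = 3760.0
    pad_csa_sd_um2: float = 1546.0

    control_carbonyl_mean_gsu: float = 486.0
    control_carbonyl_sd_gsu: float = 135.0
    pad_carbonyl_mean_gsu: float = 695.0
    pad_carbonyl_sd_gsu: float = 132.0

    control_hne_mean_gsu: float = 261.0
    control_hne_sd_gsu: float = 101.0
    pad_hne_mean_gsu: float = 436.0
    pad_hne_sd_gsu: float = 119.0

    stage_effect_gsu_per_stage: tuple[float, float] = (90.0, 80.0)
    abi_damage_slope: tuple[float, float] = (-300.0, -250.0)

    csa_damage_coupling_pad: float = -1.55  # µm² per gsu of fiber damage deviation
    csa_damage_coupling_control: float = 0.0

    fiber_level_sd_gsu: float = 150.0
    fiber_level_sd_hne_gsu: float = 120.0
    fiber_marker_noise_gsu: float = 30.0
    fiber_csa_sd_um2: float = 1300.0

    ecm_carbonyl_gsu: float = 300.0

    cad_prevalence: dict[str, float] = field(
        default_factory=lambda: {"control": 0.238, "pad": 0.617}
    )
    htn_prevalence: dict[str, float] = field(
        default_factory=lambda: {"control": 0.571, "pad": 0.823}
    )

    abi_control_range: tuple[float, float] = (0.94, 1.34)
    abi_control_mean: float = 1.13
    abi_control_sd: float = 0.21
    abi_pad_range: tuple[float, float] = (0.01, 0.81)
    abi_stage_means: dict[int, float] = field(
        default_factory=lambda: {2: 0.50, 3: 0.34, 4: 0.18}
    )
    abi_within_stage_sd: float = 0.15

    field: FieldConfig = field(default_factory=FieldConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = list(self.stage_proportions.values())
        if any(not 0 <= p <= 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("stage_proportions must be probabilities summing to 1")
        for name in ("control_csa_sd_um2", "pad_csa_sd_um2", "control_carbonyl_sd_gsu",
                     "pad_carbonyl_sd_gsu", "control_hne_sd_gsu", "pad_hne_sd_gsu",
                     "fiber_level_sd_gsu", "fiber_level_sd_hne_gsu",
                     "fiber_marker_noise_gsu", "fiber_csa_sd_um2",
                     "abi_within_stage_sd", "abi_control_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for rng_ in (self.abi_control_range, self.abi_pad_range):
            if not (0 <= rng_[0] <= rng_[1] <= 2):
                raise ValueError("ABI intervals must lie within [0, 2]")
        for prev in (*self.cad_prevalence.values(), *self.htn_prevalence.values()):
            if not 0 <= prev <= 1:
                raise ValueError("prevalences must be in [0, 1]")
        if self.csa_damage_coupling_pad > 0:
            raise ValueError("csa_damage_coupling_pad must be <= 0")
        lo, hi = self.fields_per_specimen_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid fields_per_specimen_range")

    # -- analytic moments of the PAD stage/ABI model ----------------------

    def _stage_abi_moments(self) -> dict[str, float]:
        """Exact first/second moments of (stage, ABI) for PAD patients.

        ABI within a stage is a truncated normal on ``abi_pad_range``;
        the truncated means/variances are used so that centring of the
        stage and ABI effects is exact and the programmed PAD group mean
        is recovered without bias.
        """
        cached = self.__dict__.get("_moments_cache")
        if cached is not None:
            return cached
        lo, hi = self.abi_pad_range
        s_vals, probs, m, v = [], [], [], []
        for s, p in self.stage_proportions.items():
            mu = self.abi_stage_means[s]
            sd = self.abi_within_stage_sd
            if sd > 0:
                a, b = (lo - mu) / sd, (hi - mu) / sd
                m.append(float(truncnorm.mean(a, b, loc=mu, scale=sd)))
                v.append(float(truncnorm.var(a, b, loc=mu, scale=sd)))
            else:
                m.append(mu)
                v.append(0.0)
            s_vals.append(s)
            probs.append(p)
        s_vals = np.array(s_vals, float)
        probs = np.array(probs, float)
        m = np.array(m)
        v = np.array(v)
        e_s = float(probs @ s_vals)
        var_s = float(probs @ s_vals**2 - e_s**2)
        e_abi = float(probs @ m)
        var_abi = float(probs @ (v + m**2) - e_abi**2)
        cov = float(probs @ (s_vals * m) - e_s * e_abi)
        moments = {"E_stage": e_s, "Var_stage": var_s, "E_abi": e_abi,
                   "Var_abi": var_abi, "Cov_stage_abi": cov}
        self.__dict__["_moments_cache"] = moments
        return moments

    def marginal_stage_slope(self, marker: str) -> float:
        """Expected regression slope of PAD damage on Fontaine stage.

        Combines the direct stage effect with the ABI-mediated part
        (lower ABI at higher stage adds damage): b_s + b_a·Cov(S,ABI)/Var(S).
        """
        i = _marker_index(marker)
        mo = self._stage_abi_moments()
        return (self.stage_effect_gsu_per_stage[i]
                + self.abi_damage_slope[i] * mo["Cov_stage_abi"] / mo["Var_stage"])

    def systematic_damage_sd(self, marker: str) -> float:
        """SD of the stage+ABI systematic component of PAD patient mean damage."""
        i = _marker_index(marker)
        b_s = self.stage_effect_gsu_per_stage[i]
        b_a = self.abi_damage_slope[i]
        mo = self._stage_abi_moments()
        var = (b_s**2 * mo["Var_stage"] + b_a**2 * mo["Var_abi"]
               + 2 * b_s * b_a * mo["Cov_stage_abi"])
        return float(np.sqrt(max(var, 0.0)))

    def patient_effect_sd(self, group: str, marker: str) -> float:
        """Patient random-effect SD chosen so specimen-mean SDs match the group SD.

        For PAD the stage/ABI systematic variance is subtracted from the
        target specimen-level variance; a floor of 15% of the group SD
        keeps the component positive if effects are configured large.
        """
        group_sd = {
            ("control", "carbonyl"): self.control_carbonyl_sd_gsu,
            ("pad", "carbonyl"): self.pad_carbonyl_sd_gsu,
            ("control", "hne"): self.control_hne_sd_gsu,
            ("pad", "hne"): self.pad_hne_sd_gsu,
        }[(group, marker)]
        if group == "control":
            return group_sd
        resid_var = group_sd**2 - self.systematic_damage_sd(marker) ** 2
        return float(np.sqrt(max(resid_var, (0.15 * group_sd) ** 2)))

    def group_mean(self, group: str, marker: str) -> float:
        return {
            ("control", "carbonyl"): self.control_carbonyl_mean_gsu,
            ("pad", "carbonyl"): self.pad_carbonyl_mean_gsu,
            ("control", "hne"): self.control_hne_mean_gsu,
            ("pad", "hne"): self.pad_hne_mean_gsu,
            ("control", "csa"): self.control_csa_mean_um2,
            ("pad", "csa"): self.pad_csa_mean_um2,
        }[(group, marker)]


def _marker_index(marker: str) -> int:
    try:
        return {"carbonyl": 0, "hne": 1}[marker]
    except KeyError:
        raise ValueError(f"unknown marker {marker!r}") from None


# ---------------------------------------------------------------------------
# patients
# ---------------------------------------------------------------------------


@dataclass
class PatientRecord:
    """Clinical attributes of one specimen donor."""

    patient_id: str
    group: str  # control | pad
    fontaine_stage: int | None
    abi: float
    cad: bool
    htn: bool

    def __post_init__(self) -> None:
        if self.group not in ("control", "pad"):
            raise ValueError(f"invalid group {self.group!r}")
        if self.group == "control" and self.fontaine_stage is not None:
            raise ValueError("controls carry no Fontaine stage")
        if self.group == "pad":
            if self.fontaine_stage not in STAGES:
                raise ValueError("PAD patients need a Fontaine stage in {2,3,4}")
            if self.abi >= 0.9:
                raise ValueError("PAD implies ABI < 0.9")


def sample_patient(config: CohortConfig, group: str,
                   rng: np.random.Generator, patient_id: str = "") -> PatientRecord:
    """Draw one patient's clinical attributes.

    Controls get an ABI from a truncated normal inside the normal range;
    PAD patients get a Fontaine stage from ``stage_proportions`` and an
    ABI whose mean decreases with stage, producing the negative
    damage–ABI correlation downstream.  CAD and HTN are independent
    coin flips at the group prevalences.
    """
    if group not in ("control", "pad"):
        raise ValueError(f"invalid group {group!r}")
    if group == "pad" and not config.stage_proportions:
        raise ValueError("stage_proportions is empty")

    if group == "control":
        stage = None
        lo, hi = config.abi_control_range
        mu, sd = config.abi_control_mean, config.abi_control_sd
        abi = float(truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd,
                                  loc=mu, scale=sd, random_state=rng))
    else:
        stages = np.array(sorted(config.stage_proportions))
        probs = np.array([config.stage_proportions[s] for s in stages])
        stage = int(rng.choice(stages, p=probs))
        lo, hi = config.abi_pad_range
        mu, sd = config.abi_stage_means[stage], config.abi_within_stage_sd
        if sd > 0:
            abi = float(truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd,
                                      loc=mu, scale=sd, random_state=rng))
        else:
            abi = float(np.clip(mu, lo, hi))
    cad = bool(rng.random() < config.cad_prevalence[group])
    htn = bool(rng.random() < config.htn_prevalence[group])
    return PatientRecord(patient_id or f"{group}_x", group, stage, abi, cad, htn)


# ---------------------------------------------------------------------------
# field geometry and rendering
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-field ground truth: label image, per-fiber table, outlines."""

    labels: np.ndarray  # interior fiber labels, 0 = extracellular/membrane
    fibers: pd.DataFrame  # fiber_id, n_pixels, true_csa_um2, true gsu, touches_border
    polygons: dict[int, np.ndarray]  # fiber_id -> (k, 2) hull vertices (row, col)
    pixel_size_um: float


def _tessellate(shape: tuple[int, int], n_fibers: int, membrane_width_px: float,
                rng: np.random.Generator, lloyd_iterations: int = 2
                ) -> tuple[np.ndarray, np.ndarray]:
    """Centroidal-relaxed random-point tessellation on the pixel grid.

    Returns ``(cell_labels, interior_labels)``: ``cell_labels`` is the
    full nearest-seed partition (1..n); ``interior_labels`` zeroes a
    membrane rim of total width ~``membrane_width_px`` centred on the
    inter-cell edges.  Cells at the image border keep their interiors
    open to the edge (fields truncate fibers, as in real acquisitions).
    """
    h, w = shape
    min_cell_px = (3.0 * membrane_width_px) ** 2
    if h * w / n_fibers < min_cell_px:
        raise FieldTooCrowdedError(
            f"{n_fibers} fibers cannot fit a {h}x{w} px field at membrane "
            f"width {membrane_width_px} px")

    if n_fibers == 1:
        # a single fiber fills the field; there is no inter-cell membrane
        ones = np.ones((h, w), np.int32)
        return ones, ones.copy()

    yy, xx = np.indices((h, w))
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float) + 0.5
    seeds = rng.uniform([0, 0], [h, w], size=(n_fibers, 2))
    for _ in range(lloyd_iterations):
        lab = cKDTree(seeds).query(pix)[1]
        counts = np.bincount(lab, minlength=n_fibers).astype(float)
        cy = np.bincount(lab, weights=pix[:, 0], minlength=n_fibers)
        cx = np.bincount(lab, weights=pix[:, 1], minlength=n_fibers)
        nonempty = counts > 0
        seeds = seeds.copy()
        seeds[nonempty] = np.column_stack(
            [cy[nonempty] / counts[nonempty], cx[nonempty] / counts[nonempty]])

    dist, lab = cKDTree(seeds).query(pix, k=2)
    cell_labels = (lab[:, 0] + 1).reshape(h, w).astype(np.int32)
    # pixels nearly equidistant from two seeds lie on the membrane rim
    rim = ((dist[:, 1] - dist[:, 0]) < membrane_width_px).reshape(h, w)
    interior = np.where(rim, 0, cell_labels)
    present = np.unique(interior[interior > 0])
    if len(present) < n_fibers:
        raise FieldTooCrowdedError(
            f"{n_fibers} fibers in a {h}x{w} px field left "
            f"{n_fibers - len(present)} fiber(s) without interior pixels")
    return cell_labels, interior


def _apply_psf_noise(channel: np.ndarray, cfg: FieldConfig,
                     rng: np.random.Generator) -> np.ndarray:
    out = channel
    if cfg.psf_sigma_px > 0:
        out = ndi.gaussian_filter(out, cfg.psf_sigma_px)
    if cfg.noise_model == "gaussian" and cfg.noise_scale > 0:
        out = out + rng.normal(0.0, cfg.noise_scale, size=out.shape)
    elif cfg.noise_model == "poisson_gaussian":
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
        if cfg.noise_scale > 0:
            out = out + rng.normal(0.0, cfg.noise_scale, size=out.shape)
    return np.clip(out, 0.0, float(MAX_GSU))


FiberMeanSampler = Callable[[int, np.random.Generator], np.ndarray]


def generate_field(field_config: FieldConfig, fiber_mean_sampler: FiberMeanSampler,
                   rng: np.random.Generator) -> tuple[ImageStack, GroundTruth]:
    """Render one field and its ground truth.

    ``fiber_mean_sampler(n, rng)`` must return an ``(n, 2)`` array of
    per-fiber (carbonyl, hne) gsu, or ``(n, 3)`` with a target CSA (µm²)
    as third column; when targets are given, damage values are assigned
    to tessellation cells by CSA rank so that the programmed damage–size
    coupling is preserved in the rendered geometry.
    """
    cfg = field_config
    h, w = cfg.image_height_px, cfg.image_width_px
    cells, interior = _tessellate((h, w), cfg.fibers_per_field,
                                  cfg.membrane_width_px, rng, cfg.lloyd_iterations)
    n = cfg.fibers_per_field
    values = np.atleast_2d(np.asarray(fiber_mean_sampler(n, rng), dtype=float))
    if values.shape[0] != n or values.shape[1] not in (2, 3):
        raise ValueError("fiber_mean_sampler must return an (n, 2) or (n, 3) array")

    areas_px = np.bincount(interior.ravel(), minlength=n + 1)[1:]
    if values.shape[1] == 3:
        # rank-match: largest target CSA -> largest realized cell
        order_cells = np.argsort(areas_px, kind="stable")
        order_vals = np.argsort(values[:, 2], kind="stable")
        assigned = np.empty((n, 2))
        assigned[order_cells] = values[order_vals, :2]
    else:
        assigned = values[:, :2]

    carb_levels = np.clip(assigned[:, 0], 0.0, None)
    hne_levels = np.clip(assigned[:, 1], 0.0, None)

    black = cfg.camera_black_gsu
    membrane = np.full((h, w), black)
    carbonyl = np.full((h, w), black + cfg.ecm_carbonyl_gsu)
    hne = np.full((h, w), black)
    inside = interior > 0
    membrane[~inside] += cfg.membrane_intensity_gsu
    idx = interior[inside] - 1
    carbonyl[inside] = black + carb_levels[idx]
    hne[inside] = black + hne_levels[idx]

    membrane = _apply_psf_noise(membrane, cfg, rng)
    carbonyl = _apply_psf_noise(carbonyl, cfg, rng)
    hne = _apply_psf_noise(hne, cfg, rng)
    stack = ImageStack(membrane, carbonyl, hne, cfg.pixel_size_um)

    border = np.zeros((h, w), bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touches = np.zeros(n, bool)
    touched_ids = np.unique(interior[border & inside])
    touches[touched_ids - 1] = True

    polygons: dict[int, np.ndarray] = {}
    for fid in range(1, n + 1):
        pts = np.column_stack(np.nonzero(interior == fid)).astype(float)
        try:
            hull = ConvexHull(pts)
            polygons[fid] = pts[hull.vertices]
        except (QhullError, ValueError):  # pragma: no cover - degenerate slivers
            polygons[fid] = pts

    fibers = pd.DataFrame({
        "fiber_id": np.arange(1, n + 1),
        "n_pixels": areas_px,
        "true_csa_um2": areas_px * cfg.pixel_size_um**2,
        "true_carbonyl_gsu": carb_levels,
        "true_hne_gsu": hne_levels,
        "touches_border": touches,
    })
    truth = GroundTruth(interior, fibers, polygons, cfg.pixel_size_um)
    return stack, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    """In-memory product of :func:`generate_cohort`."""

    patients: pd.DataFrame
    fibers: pd.DataFrame
    programmed: pd.DataFrame  # per-patient programmed specimen means
    manifest: dict
    outdir: Path | None = None


def _patient_mean_damage(config: CohortConfig, rec: PatientRecord,
                         rng: np.random.Generator) -> tuple[float, float, float]:
    """Programmed specimen means (carbonyl, hne, csa) for one patient."""
    mus = []
    for marker in ("carbonyl", "hne"):
        i = _marker_index(marker)
        mu = config.group_mean(rec.group, marker)
        if rec.group == "pad":
            mo = config._stage_abi_moments()
            mu += config.stage_effect_gsu_per_stage[i] * (rec.fontaine_stage - mo["E_stage"])
            mu += config.abi_damage_slope[i] * (rec.abi - mo["E_abi"])
        mu += rng.normal(0.0, config.patient_effect_sd(rec.group, marker))
        mus.append(mu)
    csa_sd = (config.pad_csa_sd_um2 if rec.group == "pad"
              else config.control_csa_sd_um2)
    mu_csa = config.group_mean(rec.group, "csa") + rng.normal(0.0, csa_sd)
    mu_csa = max(mu_csa, 10 * MIN_FIBER_CSA_UM2)
    return mus[0], mus[1], mu_csa


def _draw_fibers(config: CohortConfig, group: str, mu_c: float, mu_h: float,
                 mu_csa: float, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Fiber-level draws around programmed specimen means.

    A shared standard-normal latent drives both markers (damaged fibers
    are damaged for carbonyl and HNE alike) and, through the coupling
    coefficient, the CSA deficit of the most damaged fibers.
    """
    d = rng.standard_normal(n)
    eps_c = rng.normal(0.0, config.fiber_marker_noise_gsu, n)
    eps_h = rng.normal(0.0, config.fiber_marker_noise_gsu, n)
    csa_noise = rng.normal(0.0, config.fiber_csa_sd_um2, n)
    coupling = (config.csa_damage_coupling_pad if group == "pad"
                else config.csa_damage_coupling_control)
    carb = mu_c + config.fiber_level_sd_gsu * d + eps_c
    hne = mu_h + config.fiber_level_sd_hne_gsu * d + eps_h
    csa = np.clip(mu_csa + coupling * config.fiber_level_sd_gsu * d + csa_noise,
                  MIN_FIBER_CSA_UM2, None)
    return pd.DataFrame({"true_carbonyl_gsu": carb, "true_hne_gsu": hne,
                         "true_csa_um2": csa})


def generate_cohort(config: CohortConfig, outdir: str | Path | None = None,
                    render_images: bool | None = None) -> CohortResult:
    """Generate a full synthetic cohort, reproducible from ``config.seed``.

    With ``render_images=True`` (requires ``outdir``) every field is
    rendered and written as a 3-page TIFF, and ground-truth fiber CSA is
    the realized tessellation-cell area.  With ``render_images=False``
    only the statistical layer is materialized: the fiber table holds
    the exact programmed draws, which is the fast path for cohort-level
    statistical studies.  Default: render when ``outdir`` is given.
    """
    if render_images is None:
        render_images = outdir is not None
    if render_images and outdir is None:
        raise ValueError("render_images=True requires an output directory")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        if render_images:
            (outdir / "images").mkdir(exist_ok=True)

    rng = np.random.default_rng(config.seed)
    lo, hi = config.fields_per_specimen_range

    patient_rows, programmed_rows, fiber_frames = [], [], []
    field_entries = []
    for group, count, prefix in (("control", config.n_control, "CTRL"),
                                 ("pad", config.n_pad, "PAD")):
        for k in range(count):
            pid = f"{prefix}{k + 1:02d}"
            rec = sample_patient(config, group, rng, patient_id=pid)
            mu_c, mu_h, mu_csa = _patient_mean_damage(config, rec, rng)
            n_fields = int(rng.integers(lo, hi + 1))
            programmed_rows.append({
                "patient_id": pid, "group": group,
                "programmed_carbonyl_gsu": mu_c, "programmed_hne_gsu": mu_h,
                "programmed_csa_um2": mu_csa, "n_fields": n_fields,
            })
            patient_rows.append({
                "patient_id": pid, "group": group,
                "fontaine_stage": rec.fontaine_stage if group == "pad" else pd.NA,
                "abi": rec.abi, "cad": int(rec.cad), "htn": int(rec.htn),
            })
            for f in range(1, n_fields + 1):
                field_id = f"f{f:02d}"
                path = None
                if render_images:
                    fld = dataclasses.replace(
                        config.field,
                        ecm_carbonyl_gsu=config.ecm_carbonyl_gsu,
                        fibers_per_field=_fibers_for_target_csa(config.field, mu_csa),
                    )
                    draws = _draw_fibers(config, group, mu_c, mu_h, mu_csa,
                                         fld.fibers_per_field, rng)
                    sampler = _constant_sampler(draws[["true_carbonyl_gsu",
                                                      "true_hne_gsu",
                                                      "true_csa_um2"]].to_numpy())
                    stack, truth = generate_field(fld, sampler, rng)
                    path = outdir / "images" / f"{pid}_{field_id}.tif"
                    write_image_stack(stack, path)
                    tf = truth.fibers.copy()
                else:
                    draws = _draw_fibers(config, group, mu_c, mu_h, mu_csa,
                                         config.fibers_per_field, rng)
                    tf = draws.copy()
                    tf.insert(0, "fiber_id", np.arange(1, len(tf) + 1))
                    tf["touches_border"] = False
                tf.insert(0, "field_id", field_id)
                tf.insert(0, "patient_id", pid)
                fiber_frames.append(tf)
                field_entries.append({
                    "patient_id": pid, "field_id": field_id,
                    "n_fibers": int(len(tf)),
                    "path": str(path.relative_to(outdir)) if path else None,
                })

    patients = pd.DataFrame(patient_rows)
    programmed = pd.DataFrame(programmed_rows)
    fiber_cols = ["patient_id", "field_id", "fiber_id", "true_csa_um2",
                  "true_carbonyl_gsu", "true_hne_gsu", "touches_border"]
    if not any("fiber_id" in f.columns for f in fiber_frames):  # pragma: no cover
        raise RuntimeError("no fibers generated")
    for f in fiber_frames:
        if "fiber_id" not in f.columns:
            f["fiber_id"] = np.arange(1, len(f) + 1)
        if "n_pixels" in f.columns:
            f.drop(columns=["n_pixels"], inplace=True)
    fibers = pd.concat(fiber_frames, ignore_index=True)[fiber_cols]

    manifest = {
        "seed": config.seed,
        "n_control": config.n_control,
        "n_pad": config.n_pad,
        "render_images": render_images,
        "n_fields_total": len(field_entries),
        "fields": field_entries,
    }
    if outdir is not None:
        patients.to_csv(outdir / "patients.csv", index=False)
        fibers.to_csv(outdir / "fibers_truth.csv", index=False)
        programmed.to_csv(outdir / "programmed_means.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return CohortResult(patients, fibers, programmed, manifest, outdir)


def _fibers_for_target_csa(fld: FieldConfig, target_mean_csa_um2: float) -> int:
    """Fiber count that makes mean realized cell area track the target CSA.

    Roughly 12% of the field is membrane rim at default geometry, hence
    the 0.88 usable-area factor; realized means track the target only
    approximately (the statistical ground-truth table is exact).
    """
    area_um2 = fld.image_height_px * fld.image_width_px * fld.pixel_size_um**2
    n = int(round(0.88 * area_um2 / max(target_mean_csa_um2, MIN_FIBER_CSA_UM2)))
    return max(n, 2)


def _constant_sampler(values: np.ndarray) -> FiberMeanSampler:
    def sampler(n: int, rng: np.random.Generator) -> np.ndarray:
        if n != len(values):
            raise ValueError("sampler called with unexpected fiber count")
        return values
    return sampler
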