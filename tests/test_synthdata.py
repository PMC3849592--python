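"""Generator tests: geometry, compartment rules, patient sampling, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fiberox.io import MAX_GSU
from fiberox.synthdata import (
    CohortConfig,
    FieldConfig,
    FieldTooCrowdedError,
    generate_cohort,
    generate_field,
    sample_patient,
)

from conftest import uniform_sampler


class TestFieldGeometry:
    def test_additive_construction_interior_pixels(self, uniform_field,
                                                   small_field_config):
        """Noise off: interior pixels are camera black + painted fiber level."""
        stack, truth = uniform_field
        black = small_field_config.camera_black_gsu
        inside = truth.labels > 0
        assert np.all(stack.carbonyl[inside] == black + 800.0)
        assert np.all(stack.hne[inside] == black + 400.0)
        assert np.all(stack.membrane[inside] == black)

    def test_compartment_rule(self, uniform_field, small_field_config):
        """Extracellular HNE is exactly camera black; carbonyl is black + ECM."""
        stack, truth = uniform_field
        cfg = small_field_config
        ecm = truth.labels == 0
        assert ecm.any()
        assert np.all(stack.hne[ecm] == cfg.camera_black_gsu)
        assert np.all(stack.carbonyl[ecm] == cfg.camera_black_gsu + cfg.ecm_carbonyl_gsu)
        assert np.all(stack.membrane[ecm]
                      == cfg.camera_black_gsu + cfg.membrane_intensity_gsu)

    def test_label_partition_and_count(self, rng):
        """Exactly fibers_per_field positive labels, disjoint from the rim."""
        cfg = FieldConfig(image_height_px=512, image_width_px=512,
                          fibers_per_field=100)
        _, truth = generate_field(cfg, uniform_sampler(500, 300), rng)
        present = np.unique(truth.labels[truth.labels > 0])
        assert np.array_equal(present, np.arange(1, 101))
        # per-fiber pixel counts sum to the interior pixel count (disjointness)
        assert truth.fibers["n_pixels"].sum() == int((truth.labels > 0).sum())
        assert (truth.fibers["true_csa_um2"]
                == truth.fibers["n_pixels"] * cfg.pixel_size_um**2).all()

    def test_twelve_bit_clamp(self, small_field_config, rng):
        """All emitted pixels stay in [0, 4095] even with extreme noise."""
        cfg = FieldConfig(image_height_px=256, image_width_px=256,
                          fibers_per_field=12, membrane_intensity_gsu=3995,
                          noise_model="gaussian", noise_scale=2000)
        stack, _ = generate_field(cfg, uniform_sampler(4000, 4000), rng)
        for ch in (stack.membrane, stack.carbonyl, stack.hne):
            assert ch.min() >= 0 and ch.max() <= MAX_GSU

    def test_psf_and_noise_models_run(self, rng):
        cfg = FieldConfig(image_height_px=256, image_width_px=256,
                          fibers_per_field=12, psf_sigma_px=1.0,
                          noise_model="poisson_gaussian", noise_scale=10)
        stack, _ = generate_field(cfg, uniform_sampler(700, 300), rng)
        assert np.isfinite(stack.carbonyl).all()

    def test_too_many_fibers_raises(self, rng):
        cfg = FieldConfig(image_height_px=64, image_width_px=64,
                          fibers_per_field=500)
        with pytest.raises(FieldTooCrowdedError):
            generate_field(cfg, uniform_sampler(500, 300), rng)

    def test_csa_rank_assignment(self, rng):
        """With CSA targets, larger targets land on larger tessellation cells."""
        cfg = FieldConfig(image_height_px=384, image_width_px=384,
                          fibers_per_field=20)

        def sampler(n, r):
            csa = np.linspace(1000, 9000, n)
            return np.column_stack([csa / 10.0, csa / 20.0, csa])  # damage ∝ size

        _, truth = generate_field(cfg, sampler, rng)
        r = np.corrcoef(truth.fibers["true_csa_um2"],
                        truth.fibers["true_carbonyl_gsu"])[0, 1]
        assert r > 0.95


class TestPatientSampling:
    def test_control_record(self, rng):
        cfg = CohortConfig()
        for _ in range(50):
            rec = sample_patient(cfg, "control", rng)
            assert rec.fontaine_stage is None
            assert 0.94 <= rec.abi <= 1.34

    def test_pad_record_invariants(self, rng):
        cfg = CohortConfig()
        for _ in range(50):
            rec = sample_patient(cfg, "pad", rng)
            assert rec.fontaine_stage in (2, 3, 4)
            assert rec.abi < 0.9
            assert 0.01 <= rec.abi <= 0.81

    def test_degenerate_stage_distribution(self, rng):
        cfg = CohortConfig(stage_proportions={2: 1.0})
        assert all(sample_patient(cfg, "pad", rng).fontaine_stage == 2
                   for _ in range(20))

    def test_cad_prevalence_within_binomial_bounds(self, rng):
        """Empirical CAD fraction over many draws sits in the exact 99% interval."""
        cfg = CohortConfig()
        n = 10_000
        p = cfg.cad_prevalence["pad"]
        hits = sum(sample_patient(cfg, "pad", rng).cad for _ in range(n))
        lo, hi = sps.binom.interval(0.99, n, p)
        assert lo <= hits <= hi

    def test_invalid_group(self, rng):
        with pytest.raises(ValueError):
            sample_patient(CohortConfig(), "sham", rng)

    def test_empty_stage_proportions(self, rng):
        cfg = CohortConfig()
        cfg.stage_proportions = {}
        with pytest.raises(ValueError):
            sample_patient(cfg, "pad", rng)


class TestCohort:
    def test_determinism(self):
        """Identical config + seed give bit-identical tables."""
        cfg = dict(n_control=2, n_pad=3, fields_per_specimen_range=(2, 4),
                   fibers_per_field=30, seed=5)
        a = generate_cohort(CohortConfig(**cfg), render_images=False)
        b = generate_cohort(CohortConfig(**cfg), render_images=False)
        pd.testing.assert_frame_equal(a.fibers, b.fibers)
        pd.testing.assert_frame_equal(a.patients, b.patients)
        assert a.manifest == b.manifest

    def test_manifest_field_count(self):
        cfg = CohortConfig(n_control=2, n_pad=3, fields_per_specimen_range=(5, 5),
                           fibers_per_field=20, seed=3)
        res = generate_cohort(cfg, render_images=False)
        assert res.manifest["n_fields_total"] == 25
        assert len(res.manifest["fields"]) == 25

    def test_zero_coupling_gives_null_csa_damage_correlation(self):
        """With both couplings 0, fiber CSA and damage are uncorrelated."""
        cfg = CohortConfig(n_control=0, n_pad=1, fields_per_specimen_range=(25, 25),
                           fibers_per_field=80, csa_damage_coupling_pad=0.0,
                           csa_damage_coupling_control=0.0, seed=11)
        res = generate_cohort(cfg, render_images=False)
        n = len(res.fibers)
        r = np.corrcoef(res.fibers["true_csa_um2"],
                        res.fibers["true_carbonyl_gsu"])[0, 1]
        assert abs(r) < 4.0 / np.sqrt(n)

    def test_patient_mean_converges_to_programmed_mean(self):
        """Law of large numbers: fiber means approach the programmed specimen mean."""
        cfg = CohortConfig(n_control=1, n_pad=1, fields_per_specimen_range=(40, 40),
                           fibers_per_field=100, seed=21)
        res = generate_cohort(cfg, render_images=False)
        merged = res.fibers.groupby("patient_id")[
            ["true_carbonyl_gsu", "true_hne_gsu"]].mean().join(
            res.programmed.set_index("patient_id"))
        n = 4000
        sd_c = np.hypot(cfg.fiber_level_sd_gsu, cfg.fiber_marker_noise_gsu)
        sd_h = np.hypot(cfg.fiber_level_sd_hne_gsu, cfg.fiber_marker_noise_gsu)
        err_c = (merged["true_carbonyl_gsu"] - merged["programmed_carbonyl_gsu"]).abs()
        err_h = (merged["true_hne_gsu"] - merged["programmed_hne_gsu"]).abs()
        assert (err_c < 4 * sd_c / np.sqrt(n)).all()
        assert (err_h < 4 * sd_h / np.sqrt(n)).all()

    def test_defaults_program_reference_group_means(self):
        """Default cohort means encode the reference control/PAD values."""
        cfg = CohortConfig()
        assert cfg.group_mean("control", "csa") == 5324.0
        assert cfg.group_mean("pad", "csa") == 3760.0
        assert cfg.group_mean("control", "carbonyl") == 486.0
        assert cfg.group_mean("pad", "carbonyl") == 695.0
        assert (cfg.n_control, cfg.n_pad) == (21, 34)

    def test_rendered_cohort_writes_files(self, tmp_path):
        cfg = CohortConfig(n_control=1, n_pad=1, fields_per_specimen_range=(2, 2),
                           seed=9,
                           field=FieldConfig(image_height_px=256,
                                             image_width_px=256))
        res = generate_cohort(cfg, outdir=tmp_path, render_images=True)
        assert (tmp_path / "patients.csv").exists()
        assert (tmp_path / "manifest.json").exists()
        tifs = sorted((tmp_path / "images").glob("*.tif"))
        assert len(tifs) == 4
        listed = {e["path"] for e in res.manifest["fields"]}
        assert listed == {f"images/{t.name}" for t in tifs}

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            CohortConfig(stage_proportions={2: 0.5, 3: 0.2})
        with pytest.raises(ValueError):
            CohortConfig(csa_damage_coupling_pad=1.0)
        with pytest.raises(ValueError):
            CohortConfig(abi_pad_range=(-0.1, 0.8))
        with pytest.raises(ValueError):
            FieldConfig(noise_model="salt")
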