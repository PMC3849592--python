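"""Shared fixtures: small synthetic fields and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from fiberox.synthdata import CohortConfig, FieldConfig, generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_field_config():
    """A 384-px noise-free field small enough for fast unit tests."""
    return FieldConfig(image_height_px=384, image_width_px=384, fibers_per_field=40)


def uniform_sampler(carbonyl: float, hne: float):
    """Sampler painting every fiber with the same damage levels."""

    def sampler(n, rng):
        return np.column_stack([np.full(n, carbonyl), np.full(n, hne)])

    return sampler


@pytest.fixture
def uniform_field(small_field_config, rng):
    """Noise-free field with every fiber at carbonyl 800 / HNE 400 gsu."""
    return generate_field(small_field_config, uniform_sampler(800.0, 400.0), rng)


@pytest.fixture
def small_cohort():
    """Table-only cohort, 4 control / 6 PAD, for fast statistical checks."""
    from fiberox.synthdata import generate_cohort

    cfg = CohortConfig(n_control=4, n_pad=6, fields_per_specimen_range=(3, 5),
                       fibers_per_field=60, seed=77)
    return generate_cohort(cfg, render_images=False)


def truth_labels_nonborder(truth):
    """Ground-truth label image with border-touching fibers zeroed."""
    border_ids = truth.fibers.loc[truth.fibers["touches_border"], "fiber_id"].to_numpy()
    labels = truth.labels.copy()
    labels[np.isin(labels, border_ids)] = 0
    return labels
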