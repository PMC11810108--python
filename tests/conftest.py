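"""Shared fixtures: small synthetic fields kept cheap enough for unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from ibscreen.counts import CategoricalCounts
from ibscreen.simulate import FieldSpec, generate_field


def small_spec(**overrides) -> FieldSpec:
    """A 360x360 field with ~20 cells: fast but fully representative."""
    base = dict(width_px=360, height_px=360, n_cells=20,
                count_law=CategoricalCounts({1: 0.3, 2: 0.3, 3: 0.4}),
                prevalence=0.9, seed=42)
    base.update(overrides)
    return FieldSpec(**base)


@pytest.fixture(scope="session")
def small_field():
    """(field, ground truth) for the default small spec."""
    return generate_field(small_spec())


@pytest.fixture(scope="session")
def small_field_shells():
    """Two-channel small field with shells around 70% of inclusions."""
    return generate_field(small_spec(shell_probability=0.7, n_cells=12,
                                     cell_radius_px=(15.0, 1.0),
                                     count_law=CategoricalCounts({1: 0.6, 2: 0.4}),
                                     ib_min_separation_px=12.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
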