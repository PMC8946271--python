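"""Shared fixtures.

Two phantom scales are used: a small, coarse phantom (32^3 at 3 mm) for
fast unit-level checks of the planning chain, and the default-size
phantom (64^3 at 2 mm, 18 dual-electrode applicators) whose precomputed
bases back the end-to-end validation tests.  Both are generated at test
time; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from thermobrachy import brachy_dose, workbench_io
from thermobrachy.tissue_model import PhantomConfig, generate_phantom

SMALL_CONFIG = PhantomConfig(domain_mm=96.0, spacing_mm=3.0, n_applicators=8)


@pytest.fixture(scope="session")
def small_model():
    return generate_phantom(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def small_bases(small_model):
    delta_t, elec, _ = workbench_io.compute_bases(small_model)
    return delta_t, elec


@pytest.fixture(scope="session")
def model18():
    """Default-scale phantom: 18 applicators, 36 electrodes, 64^3 grid."""
    return generate_phantom(PhantomConfig(n_applicators=18), seed=1)


@pytest.fixture(scope="session")
def bases18(model18):
    """Per-electrode elevation + E-field bases for the default phantom."""
    delta_t, elec, efields = workbench_io.compute_bases(model18, keep_efields=True)
    return delta_t, elec, efields


@pytest.fixture(scope="session")
def bt_plan18(model18):
    """Surrogate BT-only plan (dwells, metric report, dose grid)."""
    dwells, report = brachy_dose.heuristic_dwell_weights(model18)
    dose = brachy_dose.tg43_dose(brachy_dose.SourceModel(), dwells, model18.grid)
    return dwells, report, dose


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
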