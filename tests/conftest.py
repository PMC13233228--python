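"""Shared fixtures: fast coarse-grid phantoms for unit tests.

The fast spec keeps the phantom's world-mm geometry but samples it on a
2 mm template grid and a 2.3 mm in-plane DSC grid, which is enough spatial
detail for contract and property tests at a fraction of the cost. Study-
condition (default-grid) phantoms are built only where a test is about the
default conditions themselves.
"""

import numpy as np
import pytest

from artroi.phantom import PhantomSpec, make_subject, make_template_assets

FAST_GRIDS = dict(
    shape_template=(48, 56, 48),
    spacing_template=(2.0, 2.0, 2.0),
    shape_dsc=(44, 44, 14),
    spacing_dsc=(2.308, 2.308, 6.0),
)


def fast_spec(**overrides) -> PhantomSpec:
    params = dict(seed=7, **FAST_GRIDS)
    params.update(overrides)
    return PhantomSpec(**params)


CLEAN = dict(
    deformation_amplitude_mm=0.0,
    rater_jitter_inplane_mm=0.0,
    rater_jitter_z_mm=0.0,
    coreg_shift_mm=0.0,
    noise_sd=0.0,
)


@pytest.fixture(scope="session")
def spec_fast():
    return fast_spec()


@pytest.fixture(scope="session")
def template_fast(spec_fast):
    return make_template_assets(spec_fast)


@pytest.fixture(scope="session")
def subject_fast(spec_fast, template_fast):
    return make_subject(spec_fast, template_fast, index=0)


@pytest.fixture(scope="session")
def spec_clean():
    return fast_spec(**CLEAN)


@pytest.fixture(scope="session")
def template_clean(spec_clean):
    return make_template_assets(spec_clean)


@pytest.fixture(scope="session")
def subject_clean(spec_clean, template_clean):
    return make_subject(spec_clean, template_clean, index=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
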