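"""Shared fixtures: the default LV phantom (with oracle truth) and its
analysis are expensive, so they are built once per session."""

import numpy as np
import pytest

from flowcomp4d.io import AnalysisConfig
from flowcomp4d.phantom import PhantomSpec, make_lv_phantom
from flowcomp4d.pipeline import analyze_flow


def small_spec(**overrides) -> PhantomSpec:
    """A down-scaled phantom for cheap unit tests: same program, ~600 seeds."""
    kwargs = dict(chamber_width_mm=24.0, edv_target_ml=15.0)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def default_phantom():
    """The default-resolution LV phantom with oracle ground truth."""
    return make_lv_phantom(PhantomSpec(), truth="oracle")


@pytest.fixture(scope="session")
def default_analysis(default_phantom):
    """Full automatic analysis of the default phantom."""
    ph = default_phantom
    config = AnalysisConfig(t_ivc_ms=ph.spec.t_ivc_ms, t_ivr_ms=ph.spec.t_ivr_ms)
    return analyze_flow(ph.field, ph.mask_ivc, ph.mask_ivr, config)


@pytest.fixture(scope="session")
def small_phantom():
    """Down-scaled phantom with programmed truth, for cheap integration tests."""
    return make_lv_phantom(small_spec(), truth="programmed")
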