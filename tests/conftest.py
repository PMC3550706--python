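"""Shared fixtures: phantoms and detection runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from octstrut.evaluate import match_detections, summarize
from octstrut.pipeline import detect_pullback
from octstrut.pullback_io import DetectionParameters
from octstrut.synthetic import generate_pullback, standard_phantom_suite

SUITE_SEED = 1


@pytest.fixture(scope="session")
def suite():
    return standard_phantom_suite(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def hq_phantom(suite):
    """(pullback, truth, guide-wire truth) of the standard high-quality spec."""
    return generate_pullback(suite["high_quality_apposed"].spec)


@pytest.fixture(scope="session")
def hq_params(hq_phantom):
    pullback, _, _ = hq_phantom
    return DetectionParameters().scaled_for(pullback.n_alines, pullback.n_depth)


@pytest.fixture(scope="session")
def hq_result(hq_phantom):
    pullback, _, _ = hq_phantom
    return detect_pullback(pullback)


@pytest.fixture(scope="session")
def hq_report(hq_phantom, hq_result, hq_params):
    pullback, truth, _ = hq_phantom
    active = hq_result.struts
    match = match_detections(active, truth, hq_params.acceptance_distance, pullback.n_alines)
    return summarize(match, truth, active), match


@pytest.fixture(scope="session")
def gwfree_phantom(suite):
    return generate_pullback(suite["guide_wire_free"].spec)


@pytest.fixture(scope="session")
def gwfree_result(gwfree_phantom):
    pullback, _, _ = gwfree_phantom
    return detect_pullback(pullback)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
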