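"""Shared fixtures: synthetic suites and their detection reports.

The suites are generated once per session; end-to-end detection over them
is the expensive part, so reports are cached at session scope and reused
by the module tests and the acceptance tests alike.
"""

import numpy as np
import pytest

from maculoc import FundusImage, PipelineConfig, detect
from maculoc.synthetic import SyntheticSpec, generate_fundus, generate_suite

SUITE_SEED = 11


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def nominal_fundus():
    """One nominal-difficulty left-lateral image with its ground truth."""
    spec = SyntheticSpec(seed=7, gradient=12.0, noise_sigma=5.0)
    image, truth = generate_fundus(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def clean_suite():
    return generate_suite(20, "clean", seed=SUITE_SEED)


@pytest.fixture(scope="session")
def nominal_suite():
    return generate_suite(40, "nominal", seed=SUITE_SEED)


@pytest.fixture(scope="session")
def hard_suite():
    return generate_suite(10, "hard", seed=SUITE_SEED)


def _run(suite, tag):
    reports = []
    for i, (spec, image, truth) in enumerate(suite):
        reports.append(detect(FundusImage(image, f"{tag}_{i:03d}")))
    return reports


@pytest.fixture(scope="session")
def clean_reports(clean_suite):
    return _run(clean_suite, "clean")


@pytest.fixture(scope="session")
def nominal_reports(nominal_suite):
    return _run(nominal_suite, "nominal")


@pytest.fixture(scope="session")
def hard_reports(hard_suite):
    return _run(hard_suite, "hard")


def detection_errors(suite, reports):
    """Per-image distance to ground truth at original scale (NaN if failed)."""
    out = []
    for (spec, image, truth), rep in zip(suite, reports):
        if not rep.ok:
            out.append(float("nan"))
            continue
        out.append(float(np.hypot(rep.macula["x_original"] - truth.macula[0],
                                  rep.macula["y_original"] - truth.macula[1])))
    return out
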