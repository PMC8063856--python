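"""Shared fixtures: the deterministic toy network and cached solutions."""

from pathlib import Path

import pytest

from fluxscan import (
    STANDARD_CONDITIONS,
    build_toy_model,
    condition_table,
)
from fluxscan.scan import detect_regions, scan_demand
from fluxscan.toy import default_scan_caps

REPO_ROOT = Path(__file__).resolve().parents[1]

#: location of the deposited genome-scale model (see scripts/fetch_model.py)
DEPOSITED_MODEL = REPO_ROOT / "models" / "MODEL2102080001.xml"


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_model()


@pytest.fixture(scope="session")
def toy_results(toy_model):
    """Solutions of the four standard conditions on the toy model."""
    return condition_table(toy_model, STANDARD_CONDITIONS)


@pytest.fixture(scope="session")
def toy_scan(toy_model):
    """Demand scan under the toy's default caps, plus its region labels."""
    result = scan_demand(toy_model, default_scan_caps(), step=0.025)
    regions = detect_regions(result)
    return result, regions
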