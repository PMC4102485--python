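import warnings

import numpy as np
import pytest

from areavenn import Ellipse, Quantities7, VennDiagram3
from areavenn.geometry import region_areas

# printed worked-example data sets used across the suite
MEDICAL_SURVEY = {
    "a": 0.25, "b": 0.01, "c": 0.11, "ab": 0.10, "ac": 0.29, "bc": 0.03, "abc": 0.15,
}
DRAWABLE_EXAMPLE = {
    "a": 2273, "b": 24458, "c": 44454, "ab": 7116, "ac": 740, "bc": 18807, "abc": 12092,
}
TINY_REGION_EXAMPLE = {
    "a": 10018, "b": 27132, "c": 39737, "ab": 9567, "ac": 11454, "bc": 3, "abc": 668,
}


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def classic_venn() -> VennDiagram3:
    """Three equal circles in the familiar symmetric 3-Venn layout."""
    return VennDiagram3(
        {
            "a": Ellipse(0.0, 0.0, 1.2, 1.2),
            "b": Ellipse(1.0, 0.0, 1.2, 1.2),
            "c": Ellipse(0.5, 0.9, 1.2, 1.2),
        }
    )


def sample_valid_diagrams(n: int, seed: int, min_region_frac: float = 0.0):
    """Rejection-sample random diagrams with valid 3-Venn topology."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        arr = np.column_stack(
            [
                rng.uniform(0, 100, 3),
                rng.uniform(0, 100, 3),
                rng.uniform(10, 50, 3),
                rng.uniform(10, 50, 3),
                rng.uniform(0, np.pi, 3),
            ]
        )
        d = VennDiagram3.from_array(arr)
        ra = region_areas(d)
        if not ra.valid:
            continue
        if min_region_frac and min(ra.areas.values()) < min_region_frac * ra.total:
            continue
        out.append(d)
    return out


@pytest.fixture(scope="session")
def random_valid_diagrams():
    return sample_valid_diagrams(20, seed=42)


@pytest.fixture(scope="session")
def medical_survey() -> Quantities7:
    return Quantities7(MEDICAL_SURVEY)
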