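import numpy as np
import pytest

from bnec.bn_core import DagStructure, GaussianBnParameters, GaussianNodeParams
from bnec.roi_io import RoiTimeSeriesMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chain3():
    """X1 -> X2 -> X3 with weights 0.8, unit noise on the root."""
    structure = DagStructure.from_edges(
        ("X1", "X2", "X3"), [("X1", "X2"), ("X2", "X3")]
    )
    params = GaussianBnParameters(
        {
            "X1": GaussianNodeParams(0.0, {}, 1.0),
            "X2": GaussianNodeParams(0.0, {"X1": 0.8}, 0.36),
            "X3": GaussianNodeParams(0.0, {"X2": 0.8}, 0.36),
        }
    )
    return structure, params


def make_ts(values, labels=None, tr=2.0, segments=None):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = [f"X{i + 1}" for i in range(values.shape[1])]
    return RoiTimeSeriesMatrix(
        values=values,
        node_labels=list(labels),
        segment_bounds=segments or [],
        sampling_interval=tr,
    )
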