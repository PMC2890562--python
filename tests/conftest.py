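import numpy as np
import pandas as pd
import pytest

from mirconcord.types import ArrayDesign, IntensityDataset


@pytest.fixture
def one_color_arrays():
    return [
        ArrayDesign("A1", {"Cy3": "Ref1"}, replicate_index=1),
        ArrayDesign("A2", {"Cy3": "Ref1"}, replicate_index=2),
        ArrayDesign("A3", {"Cy3": "Ref2"}, replicate_index=1),
        ArrayDesign("A4", {"Cy3": "Ref2"}, replicate_index=2),
    ]


@pytest.fixture
def two_color_arrays():
    return [
        ArrayDesign("A1", {"Cy3": "Ref1", "Cy5": "Ref2"}, 1, False),
        ArrayDesign("A2", {"Cy3": "Ref2", "Cy5": "Ref1"}, 1, True),
        ArrayDesign("A3", {"Cy3": "Ref1", "Cy5": "Ref2"}, 2, False),
        ArrayDesign("A4", {"Cy3": "Ref2", "Cy5": "Ref1"}, 2, True),
    ]


@pytest.fixture
def small_one_color(one_color_arrays):
    """12 signal probes + 6 negative controls, 4 one-color arrays."""
    rng = np.random.default_rng(42)
    probes = [f"p{i}" for i in range(12)] + [f"neg{i}" for i in range(6)]
    values = pd.DataFrame(
        rng.lognormal(mean=5, sigma=1, size=(18, 4)),
        index=pd.Index(probes, name="probe_id"),
        columns=[a.columns()[0] for a in one_color_arrays],
    )
    return IntensityDataset(
        platform_id="toy",
        color_mode="one",
        arrays=one_color_arrays,
        values=values,
        negative_control_ids=frozenset(p for p in probes if p.startswith("neg")),
    )
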