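import numpy as np
import pytest

from lightmeta.datamodel import CountStudy, SampleRecord


def make_sample(sid, cond="E1_LEAF_25_800_30_min", exp="E1", tissue="leaf",
                intensity=800.0, duration=30.0, age=25.0, control=False):
    return SampleRecord(
        sample_id=sid, experiment_id=exp, condition_id=cond, tissue=tissue,
        intensity_ppfd=intensity, duration_min=duration, age_days=age,
        is_control=control,
    )


@pytest.fixture
def tiny_study():
    """2 genes x 2 samples: one control, one stress library."""
    samples = [
        make_sample("s1", cond="E1_LEAF_25_CTRL", intensity=0.0, duration=0.0,
                    control=True),
        make_sample("s2"),
    ]
    counts = np.array([[10, 20], [5, 0]], dtype=np.int64)
    return CountStudy(genes=["AT1G01010", "AT1G01020"], samples=samples, counts=counts)


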