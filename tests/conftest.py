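import pandas as pd
import pytest

from refstab import CtTable


@pytest.fixture
def abc_rq() -> pd.DataFrame:
    """Three-gene worked example: A and B perfectly proportional, C flat.

    log2(A/C) over samples is (0, 1, 2) with sample SD 1, so
    M_A = M_B = 0.5 and M_C = 1.0; V_2/3 = 1/3 exactly.
    """
    return pd.DataFrame(
        [[1.0, 2.0, 4.0], [1.0, 2.0, 4.0], [1.0, 1.0, 1.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture
def small_ct() -> CtTable:
    meta = pd.DataFrame(
        {"time_point": [0.0, 1.0, 7.0], "model": ["control", "crush", "crush"],
         "replicate": [1, 1, 1]},
        index=pd.Index(["d0_r1", "d1_r1", "d7_r1"], name="sample_id"),
    )
    ct = pd.DataFrame(
        [[30.0, 28.0, 27.0], [25.0, 25.0, 25.0]],
        index=["g1", "g2"], columns=meta.index,
    )
    return CtTable(ct, meta)
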