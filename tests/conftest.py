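import numpy as np
import pandas as pd
import pytest

from gbmcna import CnProfile, load_table1_fixture, load_table2_fixture


def make_profile(values, chrom="chr1", spacing=100, sample_id="S01", start=100):
    """CnProfile with evenly spaced probes on one chromosome."""
    values = np.asarray(values, dtype=float)
    pos = start + spacing * np.arange(len(values))
    df = pd.DataFrame(
        {
            "probe_id": [f"{chrom}_{p}" for p in pos],
            "chrom": chrom,
            "pos": pos,
            "cn": values,
        }
    )
    return CnProfile(sample_id, df)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()
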