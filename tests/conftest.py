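import numpy as np
import pandas as pd
import pytest

from hepazone.config import SimulatorConfig


@pytest.fixture
def clean_sim() -> SimulatorConfig:
    """Noise-free simulator settings for exact round-trip checks."""
    return SimulatorConfig(
        n_cells=8, n_proteins=12,
        noise_sd=0.0, missingness=False, ratio_noise_sd=0.0,
        q_fail_lib=0.0, q_fail_q=0.0, q_fail_channel=0.0,
    )


@pytest.fixture
def toy_report() -> pd.DataFrame:
    """Two-run, three-channel toy report with clean q-values."""
    rows = []
    for run in ("R1", "R2"):
        for channel, scale in ((0, 1.0), (4, 0.5), (8, 2.0)):
            rows.append({
                "Run": run,
                "Protein.Group": "PG1",
                "Precursor.Id": "PG1_pre1",
                "Channel": channel,
                "Ms1.Area": 1000.0 * scale,
                "Fragment.Quant.Raw": ";".join(
                    f"{v * scale:g}" for v in (100.0, 200.0, 300.0)
                ),
                "Lib.PG.Q.Value": 0.001,
                "Q.Value": 0.001,
                "Channel.Q.Value": 0.01,
            })
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231002)
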