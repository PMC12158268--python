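import numpy as np
import pandas as pd
import pytest

from halochrom import synthetic


@pytest.fixture(scope="session")
def paper_design() -> synthetic.DesignSpec:
    return synthetic.DesignSpec()


@pytest.fixture(scope="session")
def linear_dataset() -> pd.DataFrame:
    """180 in-bounds records following the exactly linear law y = 3 x1 - 2 x2."""
    rng = np.random.default_rng(1234)
    x1 = rng.uniform(6.0, 10.0, 180)
    x2 = rng.uniform(0.01, 0.05, 180)
    return pd.DataFrame(
        {"peg_pct": x1, "btb_pct": x2, "response_time_s": 3.0 * x1 - 2.0 * x2}
    )


@pytest.fixture(scope="session")
def noiseless_kinetics():
    def make(ph: int = 8, midpoint: float = 300.0, rate: float = 0.05):
        cfg = synthetic.default_kinetics_config(
            ph, noise_sd=0.0, transition_midpoint_s=midpoint, transition_rate=rate
        )
        return cfg, synthetic.generate_color_kinetics(cfg, seed=0)

    return make
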