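import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from jsdmkit import landscape as lsc  # noqa: E402


@pytest.fixture(scope="session")
def small_grid():
    """40x40-cell landscape with two smooth layers and one urban layer."""
    cfg = lsc.LandscapeConfig(
        extent=(34.0, 31.0, 34.16, 31.16), cell_size=0.004, seed=11,
        predictors=[
            lsc.PredictorSpecification("temp", corr_length=10.0),
            lsc.PredictorSpecification("precip", corr_length=8.0),
            lsc.PredictorSpecification("urban", corr_length=5.0, urban=True),
        ])
    return lsc.generate_predictor_grid(cfg)


def block_correlation():
    """4x4 residual correlation with a +0.6 and a -0.6 block."""
    R = np.eye(4)
    R[0, 1] = R[1, 0] = 0.6
    R[2, 3] = R[3, 2] = -0.6
    return R


@pytest.fixture(scope="session")
def community_truth():
    """Four species, three predictors, block-structured residual correlation."""
    rng = np.random.default_rng(5)
    beta = rng.uniform(-1.2, 1.2, size=(4, 3))
    return lsc.CommunityTruth(
        species=["focal", "sp1", "sp2", "sp3"],
        predictors=["temp", "precip", "urban"],
        alpha=np.array([0.0, -0.3, 0.2, 0.1]),
        beta=beta,
        residual_corr=block_correlation(),
        foraging_km={s: 1.0 for s in ["focal", "sp1", "sp2", "sp3"]},
        home_range_km={s: 2.0 for s in ["focal", "sp1", "sp2", "sp3"]},
        detection_rate=0.9,
    )


@pytest.fixture(scope="session")
def simulated_sites(small_grid, community_truth):
    return lsc.simulate_community(small_grid, community_truth, n_sites=800,
                                  seed=21)
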