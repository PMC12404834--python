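import pandas as pd
import pytest

import robustmr as mr


def make_dataset(p=60, beta=0.3, seed=0, **cfg_kwargs) -> mr.HarmonizedDataset:
    """Seeded harmonized two-sample dataset from the synthetic generator."""
    cfg = mr.SimConfig(p=p, beta=beta, seed=seed, **cfg_kwargs)
    exposure, outcome, _ = mr.simulate_two_sample(cfg)
    return mr.as_harmonized(exposure, outcome)


@pytest.fixture
def strong_ds():
    """Strong-instrument, no-pleiotropy fixture (p=60, beta=0.3)."""
    return make_dataset(p=60, beta=0.3, seed=11)


@pytest.fixture
def toy_exposure():
    return mr.SummaryStats(
        pd.DataFrame(
            {
                "SNP": ["rs1", "rs2", "rs3"],
                "EA": ["A", "C", "G"],
                "OA": ["G", "T", "A"],
                "EAF": [0.2, 0.3, 0.7],
                "BETA": [0.5, -0.4, 0.3],
                "SE": [0.05, 0.04, 0.06],
                "P": [1e-10, 1e-8, 1e-6],
                "N": [30000, 30000, 30000],
            }
        ),
        trait_label="exposure",
    )


@pytest.fixture
def toy_outcome():
    return mr.SummaryStats(
        pd.DataFrame(
            {
                "SNP": ["rs1", "rs2", "rs3"],
                "EA": ["A", "C", "G"],
                "OA": ["G", "T", "A"],
                "EAF": [0.2, 0.3, 0.7],
                "BETA": [0.10, -0.08, 0.05],
                "SE": [0.02, 0.02, 0.02],
                "P": [1e-4, 1e-3, 1e-2],
                "N": [15000, 15000, 15000],
            }
        ),
        trait_label="outcome",
    )
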