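import numpy as np
import pandas as pd
import pytest

from tissuevote import ExpressionDataset, StudyConfig, generate_study


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 probe sets x 4 samples, one sample per tissue."""
    matrix = pd.DataFrame(
        {
            "s1": [10.0, 2.0, 5.0],
            "s2": [2.0, 9.0, 5.0],
            "s3": [2.0, 2.0, 5.0],
            "s4": [2.0, 2.0, 5.0],
        },
        index=["p1", "p2", "p3"],
    )
    return ExpressionDataset(
        "tiny", matrix, {"s1": "liver", "s2": "kidney", "s3": "heart", "s4": "lung"}
    )


@pytest.fixture(scope="session")
def clean_study():
    """Small near-noise-free study: strong effects, no discordant probes."""
    config = StudyConfig(
        n_genes=40,
        effect_size=6.0,
        noise_sd=0.3,
        discordant_rate=0.0,
        panel_size=12,
        core_size=8,
        seed=5,
    )
    return generate_study(config)
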