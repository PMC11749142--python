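import numpy as np
import pandas as pd
import pytest

import hepatoregulon as hr


def truth_regulons(truth: hr.GroundTruth) -> list[hr.Regulon]:
    """Planted regulons as scoring-ready objects."""
    return [
        hr.Regulon(tf=tf, link_scores={t: 1.0 for t in targets})
        for tf, targets in sorted(truth.regulons.items())
    ]


@pytest.fixture(scope="session")
def zero_noise_dataset() -> hr.SimulatedDataset:
    return hr.simulate_dataset(hr.SimConfig(seed=0, noise_sd=0.0))


@pytest.fixture(scope="session")
def default_dataset() -> hr.SimulatedDataset:
    return hr.simulate_dataset(hr.SimConfig(seed=0))


@pytest.fixture()
def toy_expression() -> hr.ExpressionMatrix:
    """6 genes x 9 samples (3 stages x 3 reps) with hand-designed patterns."""
    samples = [f"{st}_r{i}" for st in ("S1", "S2", "S3") for i in (1, 2, 3)]
    tf = np.array([1.0, 2, 3, 10, 11, 12, 2, 3, 1])
    values = pd.DataFrame(
        {
            "TFA": tf,
            "COPY2X": 2 * tf,
            "NEG": -tf + 20,
            "FLAT": np.ones(9),
            "NOISY": np.array([5.0, 1, 4, 2, 8, 3, 9, 7, 6]),
            "HIGH2": np.array([0.1, 0.2, 0.1, 9, 8, 9, 0.2, 0.1, 0.2]),
        },
        index=samples,
    ).T
    stage_of = pd.Series({s: s.split("_")[0] for s in samples})
    return hr.ExpressionMatrix(values=values, stage_of=stage_of, stage_order=["S1", "S2", "S3"])
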