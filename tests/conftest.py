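import numpy as np
import pandas as pd
import pytest

from targetexpress import (FEATURE_NAMES, DiffExprRecord, ExpressionProfile,
                           FeatureMatrix, PredictionRecord, SimConfig,
                           simulate_experiment)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated perturbation experiment (deterministic)."""
    return simulate_experiment(SimConfig(n_transcripts=600, seed=42))


@pytest.fixture
def toy_predictions():
    return [
        PredictionRecord("A", "miR-x", context_plus=-0.5, pct=0.9),
        PredictionRecord("B", "miR-x", mitg=0.7),
        PredictionRecord("C", "miR-x", mirza=2.0, mirza_f=1.0, mirza_n=0.5),
        PredictionRecord("D", "miR-x", context_plus=-0.1),
    ]


@pytest.fixture
def toy_expression():
    return ExpressionProfile({"A": 10.0, "B": 5.0, "C": 1.0, "D": 100.0},
                             label="toy")


def make_matrix(n_pos, n_neg, rng, informative=True):
    """A labeled FeatureMatrix whose expression column separates the
    classes when `informative`, with small jitter elsewhere."""
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [-1] * n_neg)
    data = pd.DataFrame(
        rng.uniform(-0.2, 0.2, size=(n, len(FEATURE_NAMES))),
        columns=list(FEATURE_NAMES),
        index=pd.Index([f"t{i}" for i in range(n)], name="transcript_id"),
    )
    if informative:
        data["expression"] = np.where(y == 1, 0.85, -0.85) + rng.uniform(
            -0.1, 0.1, size=n
        )
    imputed = pd.DataFrame(False, index=data.index, columns=data.columns)
    labels = pd.Series(y, index=data.index)
    return FeatureMatrix(data, imputed, labels, "toy")
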