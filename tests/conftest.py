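import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from peershift import (
    Dataset,
    ExperimentDesign,
    MCMCConfig,
    REDUCED_MCMC,
    TrueParameters,
    fit,
    recovery_study,
    simulate_experiment,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Study-scale design: 6 groups of 7 raters = 42 participants x 30 trials.
STUDY_DESIGN = ExperimentDesign(n_groups=6, group_size_range=(7, 7))


def make_tiny_dataset(n_participants: int = 4, n_images: int = 6, seed: int = 0) -> Dataset:
    """Small hand-rollable dataset (one group, every member rates every image)."""
    rng = np.random.default_rng(seed)
    conds = ["face", "hand", "art"] * ((n_images + 2) // 3)
    rows = []
    ratings = rng.integers(5, 96, size=(n_participants, n_images)).astype(float)
    for i in range(n_participants):
        for j in range(n_images):
            peers = np.delete(ratings[:, j], i)
            rows.append(
                {
                    "participant_id": f"P{i + 1}",
                    "group_id": "G1",
                    "block_index": 1 + j // 3,
                    "condition": conds[j],
                    "image_id": f"img{j + 1}",
                    "social_rule": "all",
                    "initial_raw": ratings[i, j],
                    "social_raw": float(np.mean(peers)),
                    "final_raw": float(rng.integers(5, 96)),
                }
            )
    participants = [
        {"participant_id": f"P{i + 1}", "group_id": "G1", "orientation_score": 0}
        for i in range(n_participants)
    ]
    return Dataset(pd.DataFrame(rows), pd.DataFrame(participants))


@pytest.fixture(scope="session")
def tiny_dataset() -> Dataset:
    return make_tiny_dataset()


@pytest.fixture(scope="session")
def study_scale_run():
    """One simulated dataset at the study's scale, fitted at the reduced budget."""
    dataset = simulate_experiment(
        ExperimentDesign(n_groups=6, group_size_range=(7, 7), seed=11),
        TrueParameters(),
    )
    samples = fit(dataset, mcmc=REDUCED_MCMC)
    return dataset, samples


@pytest.fixture(scope="session")
def recovery_result():
    """20-replicate parameter-recovery study at the study's operating point."""
    return recovery_study(
        STUDY_DESIGN, TrueParameters(), n_replicates=20, mcmc=REDUCED_MCMC, seed=42
    )
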