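import pandas as pd
import pytest

from etchnet.repository import build_repository
from etchnet.simulate import SimulationConfig, generate_runs


def make_runs(rows):
    """Build a long-format run table from (run_id, bait_id, is_control,
    tag_class, bio, tech, prey_id, psm) tuples."""
    return pd.DataFrame(rows, columns=[
        "run_id", "bait_id", "is_control", "tag_class",
        "biological_rep", "technical_rep", "prey_id", "psm_count"])


@pytest.fixture(scope="session")
def small_screen():
    """A small synthetic screen shared by several test modules."""
    config = SimulationConfig(seed=11, n_baits=5, n_preys=400,
                              true_interactors_per_bait=25)
    runs, truth = generate_runs(config)
    return config, runs, truth


@pytest.fixture(scope="session")
def small_repo(small_screen):
    _, runs, _ = small_screen
    return build_repository(runs[runs["is_control"]], qc_min_proteins=1)
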