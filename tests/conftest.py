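import numpy as np
import pandas as pd
import pytest

from chemevol.library import default_library
from chemevol.simulate import (
    MSParams,
    SimConfig,
    make_compound_panel,
    simulate_feature_table,
    simulate_profiles,
    simulate_tree,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def tree48():
    return simulate_tree(48, seed=1)


@pytest.fixture(scope="session")
def tree12():
    return simulate_tree(12, seed=3)


@pytest.fixture(scope="session")
def noise_free_dataset(library):
    """Noise-free synthetic LC-MS dataset with full ground truth."""
    ms = MSParams(noise_peaks=0)
    panel = make_compound_panel(library, ms, seed=7)
    tree = simulate_tree(6, seed=1)
    config = SimConfig(
        n_tips=6,
        n_compounds=len(panel),
        n_experiments=1,
        experiment_effects=(0.0,),
        noise_sd_cell=0.0,
        noise_sd_rep=0.0,
        n_replicates=1,
    )
    matrices, _ = simulate_profiles(tree, config, seed=2)
    abundance = np.maximum(np.exp(matrices[0]) - 0.1, 0.0)
    abundance.columns = [c.compound_id for c in panel]
    features, gt = simulate_feature_table(library, abundance, panel, ms, seed=3)
    return {
        "panel": panel,
        "abundance": abundance,
        "features": features,
        "ground_truth": gt,
    }


def positive_features(rows):
    """Build a minimal positive-mode feature table from (id, mz, rt, intensity)."""
    return pd.DataFrame(
        [(fid, mz, rt, inten, "s1", "positive") for fid, mz, rt, inten in rows],
        columns=["feature_id", "mz", "rt", "intensity", "sample_id", "mode"],
    )
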