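import numpy as np
import pandas as pd
import pytest

import canalex as cx


@pytest.fixture(scope="session")
def small_experiment():
    """A modest synthetic experiment shared by several unit tests."""
    cfg = cx.SimulationConfig(n_genes=300, seed=11)
    counts, meta, truth = cx.simulate_experiment(cfg)
    return cfg, counts, meta, truth


@pytest.fixture(scope="session")
def small_lcv(small_experiment):
    _, counts, meta, _ = small_experiment
    stats, scores = cx.lcv_pipeline(counts, meta, window_size=50)
    return stats, scores


def make_two_group_meta(n_per_group: int, time_point: int = 150) -> cx.SampleTable:
    """Metadata with only the two pure crosses (for two-sample DE tests)."""
    rows = []
    for i in range(n_per_group):
        rows.append(dict(sample_id=f"pl{i}", maternal_morph="PL", paternal_morph="PL",
                         time_point=time_point, family_id="f1"))
    for i in range(n_per_group):
        rows.append(dict(sample_id=f"sb{i}", maternal_morph="SB", paternal_morph="SB",
                         time_point=time_point, family_id="f2"))
    return cx.SampleTable(pd.DataFrame(rows))


def nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray,
              n_samples: int) -> np.ndarray:
    """Draw NB counts with variance mu + phi*mu^2, genes x samples."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    out = np.zeros((mu.size, n_samples), dtype=np.int64)
    r = 1.0 / phi
    p = r / (r + mu)
    for j in range(n_samples):
        out[:, j] = rng.negative_binomial(r, p)
    return out
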