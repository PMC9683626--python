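import numpy as np
import pandas as pd
import pytest

from lensgex import ReversalCascade, SignalMatrix, SimulationDesign, simulate_microarray


@pytest.fixture(scope="session")
def sim400():
    """Small planted study shared across tests: 400 genes, 10 probes, seed 7."""
    design = SimulationDesign(
        n_genes=400,
        seed=7,
        class_sizes={
            "galactose_up_reversed": 30,
            "monotherapy_confounded": 15,
            "early_plateau": 15,
            "monotonic_rise": 15,
            "early_peak": 15,
            "late_rise": 15,
            "galactose_down_restored": 15,
        },
    )
    probes, matrix, truth = simulate_microarray(design)
    return design, probes, matrix, truth


@pytest.fixture(scope="session")
def cascade400(sim400):
    _, probes, matrix, truth = sim400
    results = ReversalCascade(matrix, probes).fit()
    return results, truth


@pytest.fixture()
def tiny_matrix():
    """Hand-built 4-gene x 3-sample matrix with full annotations."""
    values = pd.DataFrame(
        {
            "ctrl": [10.0, 3.0, 50.0, 2.0],
            "gal1": [20.0, 4.0, 50.0, 1.0],
            "gal2": [30.0, 2.0, 50.0, 3.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "condition": ["control", "galactose", "galactose"],
            "day": [pd.NA, 4, 4],
            "treatment": [pd.NA, pd.NA, pd.NA],
            "replicate": [1, 1, 2],
        },
        index=pd.Index(["ctrl", "gal1", "gal2"], name="sample_id"),
    )
    return SignalMatrix(values, meta)


def exhaustive_permutation_p(a, b):
    """Two-sided exhaustive-permutation p for the difference of means.

    Enumerates every split of the pooled values into groups of the original
    sizes and ranks |mean(b) - mean(a)| among them.  Independent of any
    t machinery.
    """
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = abs(np.mean(b) - np.mean(a))
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        stat = abs(pooled[~mask].mean() - pooled[mask].mean())
        count += stat >= observed - 1e-12
        total += 1
    return count / total


def student_t_p(a, b):
    """Closed-form two-tailed pooled-variance Student's t p-value."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * tdist.sf(abs(t), na + nb - 2)
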