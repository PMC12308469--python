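import numpy as np
import pytest

from toxqsar import (
    DescriptorMatrix,
    NumericSynthConfig,
    SmilesSynthConfig,
    generate_numeric,
    generate_smiles,
)


@pytest.fixture
def tiny_csv(tmp_path):
    path = tmp_path / "compounds.csv"
    path.write_text("id,smiles,label\nm1,CCO,1\nm2,c1ccccc1,0\nm3,CC(=O)O,1\n")
    return path


@pytest.fixture(scope="session")
def numeric_data():
    """Small default-style numeric fixture: 200x10 with 3 informative columns."""
    cfg = NumericSynthConfig(n=200, p=10, n_informative=3, effect=2.0, seed=7)
    return generate_numeric(cfg)


@pytest.fixture(scope="session")
def smiles_set():
    return generate_smiles(SmilesSynthConfig(n=60, seed=11))


@pytest.fixture
def simple_matrix():
    values = np.array([[2.0, 1.0, 0.0], [4.0, 1.0, 5.0], [6.0, 1.0, 10.0]])
    return DescriptorMatrix(values, ["a", "b", "c"], ["r1", "r2", "r3"], "test")


# ---------------------------------------------------------------------------
# independent oracles (used by unit and acceptance tests)
# ---------------------------------------------------------------------------

def pairwise_auc_oracle(y, scores):
    """Exhaustive Mann-Whitney pair counting: ties credited 0.5."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def information_gain_oracle(x, y, bins):
    """Brute-force contingency-table computation of H(Y) - sum p(b) H(Y|b)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0

    def entropy(labels):
        h = 0.0
        for val in set(labels.tolist()):
            p = np.mean(labels == val)
            h -= p * np.log2(p)
        return h

    assignments = np.minimum((bins * (x - lo) / (hi - lo)).astype(int), bins - 1)
    ig = entropy(y)
    for b in range(bins):
        cell = y[assignments == b]
        if len(cell):
            ig -= (len(cell) / len(y)) * entropy(cell)
    return ig


def brute_force_shapley(score_fn, x, background):
    """Direct Shapley formula: per-feature sum over coalitions of the rest."""
    import itertools
    import math

    p = len(x)
    phi = np.zeros(p)
    for j in range(p):
        others = [k for k in range(p) if k != j]
        for size in range(p):
            for coalition in itertools.combinations(others, size):
                weight = math.factorial(size) * math.factorial(p - size - 1) / math.factorial(p)

                def value(members):
                    z = background.copy()
                    for k in members:
                        z[:, k] = x[k]
                    return score_fn(z).mean()

                phi[j] += weight * (value(coalition + (j,)) - value(coalition))
    return phi
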