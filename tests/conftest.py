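import numpy as np
import pandas as pd
import pytest

from transdiv import CountMatrix, DistanceMatrix

# Published pairwise Euclidean distances between the six lima-bean leaf
# transcriptomes in the (Hj, deltaj) plane (verbatim, incl. the one
# five-decimal entry); used as a direct input fixture for the proximity
# summary.
CONDITIONS = ["C", "E", "JA", "W", "F", "S"]
PUBLISHED_DISTANCES = {
    ("E", "C"): 0.0235,
    ("JA", "C"): 0.0342,
    ("JA", "E"): 0.0197,
    ("W", "C"): 0.0524,
    ("W", "E"): 0.0404,
    ("W", "JA"): 0.0284,
    ("F", "C"): 0.0224,
    ("F", "E"): 0.0151,
    ("F", "JA"): 0.0223,
    ("F", "W"): 0.0452,
    ("S", "C"): 0.0954,
    ("S", "E"): 0.0958,
    ("S", "JA"): 0.1047,
    ("S", "W"): 0.1113,
    ("S", "F"): 0.10127,
}

# Published two-block overlap table: sign-pattern multiplicities over the
# treatments (E, JA, W).
PUBLISHED_UP_PATTERNS = {
    "+++": 43, "++0": 33, "+0+": 29, "0++": 14, "00+": 63, "+00": 7, "0+0": 26,
}
PUBLISHED_DOWN_PATTERNS = {
    "---": 71, "--0": 3, "-0-": 19, "0--": 13, "00-": 33, "-00": 5, "0-0": 5,
}


@pytest.fixture
def published_distance_matrix() -> DistanceMatrix:
    d = pd.DataFrame(0.0, index=CONDITIONS, columns=CONDITIONS)
    for (a, b), v in PUBLISHED_DISTANCES.items():
        d.loc[a, b] = v
        d.loc[b, a] = v
    return DistanceMatrix(condition_ids=CONDITIONS, d=d)


@pytest.fixture
def small_counts() -> CountMatrix:
    """5 genes x 2 conditions, equal depth 100 (hand-checkable ratios)."""
    df = pd.DataFrame(
        {"C": [10, 10, 10, 10, 60], "E": [25, 10, 4, 10, 51]},
        index=[f"g{i}" for i in range(1, 6)],
        dtype=np.int64,
    )
    return CountMatrix(counts=df, control_id="C")


def random_count_matrix(
    rng: np.random.Generator,
    n_genes: int,
    n_conditions: int,
    max_count: int = 50,
) -> CountMatrix:
    """Random non-degenerate count matrix (every column total positive)."""
    counts = rng.integers(0, max_count + 1, size=(n_genes, n_conditions))
    for j in range(n_conditions):  # guarantee non-empty libraries
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_genes), j] = 1
    cols = [f"cond{j}" for j in range(n_conditions)]
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
        dtype=np.int64,
    )
    return CountMatrix(counts=df, control_id=cols[0])


def random_frequency_matrix(
    rng: np.random.Generator, n_genes: int, n_conditions: int
) -> pd.DataFrame:
    """Random column-stochastic matrix, possibly with structural zeros."""
    x = rng.gamma(0.5, size=(n_genes, n_conditions))
    x[rng.random(x.shape) < 0.2] = 0.0
    for j in range(n_conditions):
        if x[:, j].sum() == 0:
            x[rng.integers(n_genes), j] = 1.0
    x = x / x.sum(axis=0)
    return pd.DataFrame(
        x,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"cond{j}" for j in range(n_conditions)],
    )
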