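"""Independent oracles used by the tests.

These deliberately avoid the package's own EM / kappa code paths:
the grid search enumerates the likelihood directly over a frequency
simplex, and the kappa oracle tabulates the 3x3 contingency table by
brute force.
"""

from __future__ import annotations

import itertools

import numpy as np


def simplex_grid(k: int, step: float = 0.01) -> np.ndarray:
    """All probability vectors of length ``k`` on a lattice of ``step``."""
    m = round(1.0 / step)
    if k == 1:
        return np.array([[1.0]])
    idx = np.array(list(itertools.product(range(m + 1), repeat=k - 1)), dtype=np.int64)
    idx = idx[idx.sum(axis=1) <= m]
    last = m - idx.sum(axis=1)
    return np.column_stack([idx, last]).astype(float) * step


def grid_search_loglik(
    pair_lists: list[list[tuple[int, int]]],
    k: int,
    step: float = 0.01,
) -> float:
    """Maximum log-likelihood over the simplex grid.

    ``pair_lists[i]`` holds the ordered haplotype index pairs compatible
    with sample i; the likelihood of a frequency vector f is
    prod_i sum_pairs f[a] * f[b].
    """
    grid = simplex_grid(k, step)
    ll = np.zeros(len(grid))
    for pairs in pair_lists:
        s = np.zeros(len(grid))
        for a, b in pairs:
            s += grid[:, a] * grid[:, b]
        ll += np.log(np.maximum(s, 1e-300))
    return float(ll.max())


def kappa_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's kappa from an explicitly tabulated 3x3 contingency table."""
    table = np.zeros((3, 3))
    for xi, yi in zip(x, y):
        table[int(xi), int(yi)] += 1
    n = table.sum()
    pr_a = np.trace(table) / n
    pr_e = float((table.sum(axis=1) / n * table.sum(axis=0) / n).sum())
    if pr_a == 1.0:
        return 1.0
    if pr_e == 1.0:
        return 0.0
    return (pr_a - pr_e) / (1.0 - pr_e)
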