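"""Friedman ranking of paired insert shapes across reconstruction settings.

For each feature and each pair of insert shapes, the feature values at
the n = 21 reconstruction settings form an n × 2 table (rows = settings,
columns = regions).  Each row is ranked, column rank sums R_j are
formed, and

    Q = 12 / (n·k·(k+1)) · Σ_j R_j²  −  3·n·(k+1)

is referred to a chi-square distribution with k−1 degrees of freedom
(or, for k = 2 and modest n, to the exact permutation distribution).  A
feature distinguishes the uptake patterns when it is significant for
every one of the C(4,2) = 6 shape pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FriedmanRecord",
    "friedman_q",
    "friedman_p",
    "friedman_test",
    "shape_pairs",
    "select_distinguishable",
]


@dataclass(frozen=True)
class FriedmanRecord:
    feature_name: str
    pair: tuple[int, int]
    rank_sums: tuple[float, ...]
    q: float
    p: float
    significant: bool


def friedman_q(matrix) -> tuple[np.ndarray, float]:
    """Rank sums and Friedman statistic of an n×k table.

    Rows are ranked ascending with midranks on ties; ``Q`` reduces to
    zero when every column collects the same rank mass.
    """
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("Friedman input must be a 2D table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if not np.all(np.isfinite(x)):
        raise ValueError("Friedman input has missing entries")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    r = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * float((r**2).sum()) - 3.0 * n * (k + 1)
    return r, float(q)


def _exact_p_two_columns(matrix) -> float:
    """Exact permutation p-value for k = 2 (two regions).

    Under the null each untied row assigns ranks (1, 2) to the two
    columns with equal probability; tied rows contribute fixed midranks.
    The distribution of Q follows from the Binomial(m, 1/2) count of
    rows won by the first column, enumerated exactly.
    """
    x = np.asarray(matrix, dtype=np.float64)
    n = x.shape[0]
    tied = x[:, 0] == x[:, 1]
    t = int(tied.sum())
    m = n - t
    _, q_obs = friedman_q(x)
    if m == 0:
        return 1.0
    w = np.arange(m + 1)
    r1 = 1.5 * t + m + w          # rank sum of column 1 when it loses w rows
    r2 = 3.0 * n - r1
    q = 12.0 / (n * 2 * 3) * (r1**2 + r2**2) - 9.0 * n
    pmf = stats.binom.pmf(w, m, 0.5)
    return float(pmf[q >= q_obs - 1e-12].sum())


def friedman_p(q: float, n: int, k: int, method: str = "chisq",
               matrix=None) -> float:
    """Upper-tail probability of the Friedman statistic.

    ``method="chisq"`` uses the chi-square approximation with k−1
    degrees of freedom.  ``method="exact"`` (k = 2 only, n ≤ 25)
    enumerates the permutation null and requires the original
    ``matrix`` to account for ties; the approximation is conservative
    for two columns, which is why the exact mode exists.
    """
    if q < 0:
        raise ValueError("Q must be non-negative")
    if k < 2:
        raise ValueError("need at least two columns")
    if method == "chisq":
        return float(stats.chi2.sf(q, df=k - 1))
    if method == "exact":
        if k != 2:
            raise ValueError("exact mode implemented for k = 2 only")
        if matrix is None:
            raise ValueError("exact mode needs the original table")
        if np.asarray(matrix).shape[0] > 25:
            raise ValueError("exact mode limited to n <= 25")
        return _exact_p_two_columns(matrix)
    raise ValueError(f"unknown method {method!r}")


def friedman_test(matrix, method: str = "chisq") -> tuple[np.ndarray, float, float]:
    """Convenience wrapper: (rank_sums, Q, p) for one table."""
    r, q = friedman_q(matrix)
    n, k = np.asarray(matrix).shape
    p = friedman_p(q, n, k, method=method, matrix=matrix)
    return r, q, p


def shape_pairs(shape_ids=(1, 2, 3, 4)) -> list[tuple[int, int]]:
    """All unordered shape pairs (6 for the four study inserts)."""
    return list(combinations(sorted(shape_ids), 2))


def select_distinguishable(stable_features, table: pd.DataFrame,
                           alpha: float = 0.05,
                           method: str = "chisq") -> pd.DataFrame:
    """Friedman-test every stable feature on every shape pair.

    ``table`` is the long-form feature table (feature, shape_id,
    setting_id, family, value).  Returns one row per (feature, pair)
    with Q, p and significance, plus a ``distinguishable`` flag that is
    true only when all pairs are significant at ``alpha``.  An empty
    stable set yields an empty frame.
    """
    shapes = sorted(table["shape_id"].unique())
    pairs = shape_pairs(shapes)
    rows = []
    for feature in stable_features:
        sub = table[table["feature"] == feature]
        if sub.empty:
            raise ValueError(f"feature {feature!r} absent from table")
        wide = sub.pivot(index="setting_id", columns="shape_id",
                         values="value").sort_index()
        if wide.isna().any().any():
            raise ValueError(f"incomplete table for feature {feature!r}")
        results = {}
        for a, b in pairs:
            mat = wide[[a, b]].to_numpy()
            r, q, p = friedman_test(mat, method=method)
            results[(a, b)] = (r, q, p, bool(p < alpha))
        all_sig = all(v[3] for v in results.values())
        for (a, b), (r, q, p, sig) in results.items():
            rows.append({
                "feature": feature, "shape_a": a, "shape_b": b,
                "rank_sum_a": float(r[0]), "rank_sum_b": float(r[1]),
                "q": q, "p": p, "significant": sig,
                "distinguishable": all_sig,
            })
    columns = ["feature", "shape_a", "shape_b", "rank_sum_a", "rank_sum_b",
               "q", "p", "significant", "distinguishable"]
    return pd.DataFrame(rows, columns=columns)
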