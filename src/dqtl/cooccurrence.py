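"""Pairwise somatic-driver co-occurrence / mutual exclusivity statistics.

Hypergeometric tails (inclusive, hence conservative): with N patients, K
carrying driver a, n carrying driver b and k carrying both,
co-occurrence p = P(X >= k) and exclusivity p = P(X <= k) for
X ~ Hypergeometric(N, K, n). BH runs separately per direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pairwise_tests",
    "extreme_case_p",
    "min_cohort_for_exclusivity",
]

PAIR_COLUMNS = [
    "driver_a", "driver_b", "N", "K", "n", "k", "direction",
    "p", "q", "min_possible_p", "powered", "significant",
]


def _tail_p(N, K, n, k, direction):
    if direction == "cooccur":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    return float(stats.hypergeom.cdf(k, N, K, n))


def extreme_case_p(N: int, K: int, n: int, direction: str) -> float:
    """Minimum achievable p for the given margins (the power proxy).

    Exclusivity: zero patients with both (P(X <= max(0, K+n-N))); co-occurrence:
    everyone with the rarer event also has the commoner one (P(X >= min(K, n))).
    """
    if K > N or n > N:
        raise ValueError("K and n must not exceed N")
    if direction == "cooccur":
        return _tail_p(N, K, n, min(K, n), "cooccur")
    if direction == "exclusive":
        return _tail_p(N, K, n, max(0, K + n - N), "exclusive")
    raise ValueError(f"unknown direction {direction!r}")


def pairwise_tests(
    driver_matrix: pd.DataFrame,
    min_patients: int = 15,
    q_threshold: float = 0.05,
    joint_adjustment: bool = False,
) -> pd.DataFrame:
    """All driver pairs with both events in >= ``min_patients`` patients.

    Direction is the sign of the deviation of k from its hypergeometric
    expectation K*n/N; the reported p is the inclusive tail in that direction.
    BH per direction by default (``joint_adjustment`` pools both directions).
    """
    dm = driver_matrix.astype(int)
    N = len(dm)
    counts = dm.sum(axis=0)
    eligible = [c for c in dm.columns if counts[c] >= min_patients]
    rows = []
    for i, a in enumerate(eligible):
        for b in eligible[i + 1:]:
            K, n = int(counts[a]), int(counts[b])
            k = int((dm[a] & dm[b]).sum())
            expected = K * n / N
            if k > expected:
                direction = "cooccur"
            elif k < expected:
                direction = "exclusive"
            else:
                direction = ("cooccur"
                             if _tail_p(N, K, n, k, "cooccur") <= _tail_p(N, K, n, k, "exclusive")
                             else "exclusive")
            p = _tail_p(N, K, n, k, direction)
            mp = extreme_case_p(N, K, n, direction)
            rows.append({"driver_a": a, "driver_b": b, "N": N, "K": K, "n": n, "k": k,
                         "direction": direction, "p": p, "q": np.nan,
                         "min_possible_p": mp, "powered": mp < q_threshold})
    df = pd.DataFrame(rows, columns=[c for c in PAIR_COLUMNS if c != "significant"])
    if not len(df):
        df["significant"] = []
        return df
    if joint_adjustment:
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        for direction in ("cooccur", "exclusive"):
            sel = df["direction"] == direction
            if sel.any():
                df.loc[sel, "q"] = multipletests(df.loc[sel, "p"], method="fdr_bh")[1]
    df["significant"] = df["q"] < q_threshold
    return df


def _log_p_none_shared(N: int, K: int, n: int) -> float:
    """log P(X = 0) = log[ C(N-K, n) / C(N, n) ], valid for n <= N - K."""
    if K + n > N:
        return -np.inf
    return float(
        gammaln(N - K + 1) - gammaln(n + 1) - gammaln(N - K - n + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def min_cohort_for_exclusivity(
    freq_a: float, freq_b: float, alpha: float = 0.05, n_cap: int = 2_000_000
) -> int:
    """Smallest N at which perfect mutual exclusivity would reach p < alpha.

    K = round(freq_a * N), n = round(freq_b * N); the extreme case is zero
    patients carrying both.
    """
    if not (0 < freq_a < 1 and 0 < freq_b < 1):
        raise ValueError("frequencies must be in (0, 1)")
    for N in range(2, n_cap + 1):
        K = round(freq_a * N)
        n = round(freq_b * N)
        if K < 1 or n < 1:
            continue
        if np.exp(_log_p_none_shared(N, K, n)) < alpha:
            return N
    raise ValueError(f"no cohort size <= {n_cap} reaches alpha = {alpha}")
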