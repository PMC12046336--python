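"""Analytic power for dQTL detection via the chi-square non-centrality parameter.

The power model is the allelic (2n alleles) case-control test: case and control
allele frequencies are derived in closed form from the population MAF and the
per-allele OR, the NCP follows from the two-proportion statistic, and power is
the upper tail of the noncentral chi-square(1) at the alpha critical value.
The fitted scan is a genotype-based logistic model, so this is an approximation;
the Monte Carlo oracle in the test-suite quantifies the gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerQuery",
    "case_control_freqs",
    "analytic_power",
    "power_grid",
    "extrapolate_undiscovered",
    "monte_carlo_power",
]


@dataclass
class PowerQuery:
    maf: float
    or_: float
    n_total: int
    driver_frequency: float
    alpha: float

    def __post_init__(self):
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.or_ <= 0:
            raise ValueError("or_ must be > 0")
        if not 0 < self.driver_frequency < 1:
            raise ValueError("driver_frequency must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def case_control_freqs(maf: float, or_: float, case_fraction: float):
    """Exact (p_case, p_control) from population MAF and per-allele OR.

    Solves phi*p1 + (1-phi)*p0 = maf with odds(p1) = OR * odds(p0) via the
    quadratic in p1.
    """
    phi, p, A = case_fraction, maf, or_
    if A == 1.0:
        return p, p
    a = phi * (1 - A)
    b = phi * A + (1 - phi) - p * (1 - A)
    c = -p * A
    disc = b * b - 4 * a * c
    roots = [(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)]
    p1 = next(r for r in roots if 0 < r < 1)
    p0 = p1 / (p1 + A * (1 - p1))
    return float(p1), float(p0)


def analytic_power(query: PowerQuery) -> float:
    """Power of the allelic chi-square(1) test at the query's alpha."""
    n_case = query.n_total * query.driver_frequency
    n_control = query.n_total - n_case
    p1, p0 = case_control_freqs(query.maf, query.or_, query.driver_frequency)
    pbar = query.driver_frequency * p1 + (1 - query.driver_frequency) * p0
    var = pbar * (1 - pbar) * (1 / (2 * n_case) + 1 / (2 * n_control))
    ncp = (p1 - p0) ** 2 / var
    crit = stats.chi2.ppf(1 - query.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def monte_carlo_power(query: PowerQuery, n_sim: int = 50_000, seed: int = 0) -> float:
    """Monte Carlo oracle: simulate allele counts, run the allelic chi-square test."""
    rng = np.random.default_rng(seed)
    n_case = int(round(query.n_total * query.driver_frequency))
    n_control = query.n_total - n_case
    p1, p0 = case_control_freqs(query.maf, query.or_, query.driver_frequency)
    a = rng.binomial(2 * n_case, p1, size=n_sim).astype(float)
    b = rng.binomial(2 * n_control, p0, size=n_sim).astype(float)
    tot = a + b
    n1, n2 = 2.0 * n_case, 2.0 * n_control
    pbar = tot / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = pbar * (1 - pbar) * (1 / n1 + 1 / n2)
        z2 = (a / n1 - b / n2) ** 2 / var
    z2 = np.where(np.isfinite(z2), z2, 0.0)
    crit = stats.chi2.ppf(1 - query.alpha, df=1)
    return float(np.mean(z2 > crit))


def power_grid(maf_grid, or_grid, freq_grid, n_total: int, alpha: float) -> pd.DataFrame:
    """Long-format power surface over MAF x OR x driver-frequency grids.

    Includes per-(or_, freq) maxima over MAF in the companion 'max' frame
    accessible via groupby; callers needing the raw tensor can pivot.
    """
    rows = []
    for f in freq_grid:
        for o in or_grid:
            for m in maf_grid:
                q = PowerQuery(maf=m, or_=o, n_total=n_total, driver_frequency=f, alpha=alpha)
                rows.append((m, o, f, analytic_power(q)))
    return pd.DataFrame(rows, columns=["maf", "or_", "driver_frequency", "power"])


def per_frequency_maxima(grid: pd.DataFrame) -> pd.DataFrame:
    return grid.groupby(["driver_frequency", "or_"], as_index=False)["power"].max()


def extrapolate_undiscovered(
    discovered,
    n_total: int,
    alpha: float,
    maf_bins=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    or_bins=(1.0, 2.0, 3.0, 5.0, np.inf),
    freq_bins=(0.0, 0.1, 0.3, 1.0),
    power_floor: float = 0.01,
):
    """Expected number of undiscovered dQTLs by inverse-power extrapolation.

    ``discovered``: iterable of (maf, or_, driver_frequency). Each bin's
    expected total = observed / mean power; undiscovered = sum of
    (expected - observed), floored at 0 per bin. Bins whose mean power falls
    below ``power_floor`` are excluded with a warning (they would explode).

    Returns (undiscovered_total, per_bin DataFrame).
    """
    import warnings

    recs = [(float(m), float(o), float(f)) for m, o, f in discovered]
    if not recs:
        return 0.0, pd.DataFrame(columns=["bin", "observed", "mean_power", "expected"])
    df = pd.DataFrame(recs, columns=["maf", "or_", "freq"])
    df["power"] = [
        analytic_power(PowerQuery(maf=m, or_=max(o, 1e-9), n_total=n_total,
                                  driver_frequency=f, alpha=alpha))
        for m, o, f in recs
    ]
    df["maf_bin"] = pd.cut(df["maf"], maf_bins)
    df["or_bin"] = pd.cut(df["or_"], or_bins)
    df["freq_bin"] = pd.cut(df["freq"], freq_bins)
    per_bin = []
    undiscovered = 0.0
    for key, grp in df.groupby(["maf_bin", "or_bin", "freq_bin"], observed=True):
        mean_power = float(grp["power"].mean())
        observed = len(grp)
        if mean_power < power_floor:
            warnings.warn(f"bin {key} excluded: mean power {mean_power:.3g} < floor")
            continue
        expected = observed / mean_power
        undiscovered += max(0.0, expected - observed)
        per_bin.append({"bin": key, "observed": observed,
                        "mean_power": mean_power, "expected": expected})
    return float(undiscovered), pd.DataFrame(per_bin)
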