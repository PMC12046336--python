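"""Two-locus LD from unphased genotypes and Gabriel-style haplotype blocks.

Haplotype frequencies are estimated by EM from the 3x3 diploid genotype table
(only the double heterozygote is phase-ambiguous). |D'| gets a 90% confidence
interval from the normalized likelihood profile over D' in [0,1] with allele
frequencies held at their MLEs. Blocks follow the Gabriel et al. rules:

* strong LD pair:            ci_low >= 0.70 and ci_high >= 0.98
* strong recombination pair: ci_high < 0.90
* a candidate block is accepted when >= 95% of its informative pairs are in
  strong LD; blocks are resolved greedily longest-first (ties leftmost) and
  leftover SNPs become singleton blocks.

Thresholds are parameters; the defaults are the cited publication's values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LDEstimate", "HaplotypeBlockSet", "two_locus_ld", "gabriel_blocks", "count_tests"]

_DP_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass
class LDEstimate:
    d_prime: float
    ci_low: float
    ci_high: float
    r2: float
    n_informative: int
    defined: bool = True


@dataclass
class HaplotypeBlockSet:
    """Ordered partition of SNP ids into contiguous blocks (singletons allowed)."""

    blocks: list  # list of lists of snp ids, in genomic order
    strong_fraction: list = field(default_factory=list)  # per-block strong-LD fraction

    def __post_init__(self):
        if not self.strong_fraction:
            self.strong_fraction = [float("nan")] * len(self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self) -> dict:
        return {snp: i for i, blk in enumerate(self.blocks) for snp in blk}


def _genotype_table(g1, g2):
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    keep = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[keep].astype(int), g2[keep].astype(int)
    n = np.zeros((3, 3), dtype=float)
    np.add.at(n, (g1, g2), 1.0)
    return n, int(keep.sum())


def _em_haplotypes(n: np.ndarray, tol: float = 1e-10, max_iter: int = 2000):
    """EM for the four haplotype frequencies (pAB, pAb, paB, pab).

    Alleles: uppercase = ALT at each locus; genotype g counts ALT copies.
    Returns (freqs 2x2 array indexed [allele1][allele2], loglik).
    """
    total = n.sum()
    pA = (n[1, :].sum() + 2 * n[2, :].sum()) / (2 * total)
    pB = (n[:, 1].sum() + 2 * n[:, 2].sum()) / (2 * total)
    # haplotype counts that are unambiguous from the genotype table
    base = np.zeros((2, 2))
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = n[i, j]
            if c == 0:
                continue
            # each individual contributes two haplotypes
            a_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[i]
            b_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[j]
            if i != 1 and j != 1:
                base[a_alleles[0], b_alleles[0]] += c
                base[a_alleles[1], b_alleles[1]] += c
            elif i == 1:  # j fixed allele
                b = b_alleles[0]
                base[0, b] += c
                base[1, b] += c
            else:  # j == 1
                a = a_alleles[0]
                base[a, 0] += c
                base[a, 1] += c
    ndh = n[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    f = np.array([[(1 - pA) * (1 - pB), (1 - pA) * pB], [pA * (1 - pB), pA * pB]])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    prev_ll = -np.inf
    for _ in range(max_iter):
        cis = f[1, 1] * f[0, 0]
        trans = f[1, 0] * f[0, 1]
        denom = cis + trans
        w = 0.5 if denom == 0 else cis / denom
        counts = base.copy()
        counts[1, 1] += ndh * w
        counts[0, 0] += ndh * w
        counts[1, 0] += ndh * (1 - w)
        counts[0, 1] += ndh * (1 - w)
        f = counts / counts.sum()
        ll = _table_loglik(n, f)
        if ll - prev_ll < tol and ll >= prev_ll:
            prev_ll = ll
            break
        prev_ll = ll
    return f, prev_ll


def _genotype_probs(f: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair probabilities under HWE from 2x2 haplotype freqs."""
    p = np.zeros((3, 3))
    for a1 in range(2):
        for b1 in range(2):
            for a2 in range(2):
                for b2 in range(2):
                    p[a1 + a2, b1 + b2] += f[a1, b1] * f[a2, b2]
    return p


def _table_loglik(n: np.ndarray, f: np.ndarray) -> float:
    p = np.clip(_genotype_probs(f), 1e-300, None)
    return float((n * np.log(p)).sum())


def _freqs_at_dprime(pA, pB, dprime):
    """Haplotype freqs with given |D'| in the positive-D orientation."""
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    d = dprime * dmax
    f = np.array([
        [(1 - pA) * (1 - pB) + d, (1 - pA) * pB - d],
        [pA * (1 - pB) - d, pA * pB + d],
    ])
    return np.clip(f, 0.0, 1.0)


def _profile_logliks(table, pA, pB, grid):
    """Log-likelihood of the genotype table at each |D'| grid point (vectorized)."""
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    d = grid * dmax
    f = np.empty((len(grid), 2, 2))
    f[:, 0, 0] = (1 - pA) * (1 - pB) + d
    f[:, 0, 1] = (1 - pA) * pB - d
    f[:, 1, 0] = pA * (1 - pB) - d
    f[:, 1, 1] = pA * pB + d
    np.clip(f, 0.0, 1.0, out=f)
    probs = np.zeros((len(grid), 3, 3))
    for a1 in range(2):
        for b1 in range(2):
            for a2 in range(2):
                for b2 in range(2):
                    probs[:, a1 + a2, b1 + b2] += f[:, a1, b1] * f[:, a2, b2]
    np.clip(probs, 1e-300, None, out=probs)
    return (table[None, :, :] * np.log(probs)).sum(axis=(1, 2))


def two_locus_ld(dosage_i, dosage_j, ci_level: float = 0.90) -> LDEstimate:
    """EM-based D', r2 and a likelihood-profile CI for |D'| from unphased dosages."""
    n, n_inf = _genotype_table(dosage_i, dosage_j)
    if n_inf == 0:
        return LDEstimate(np.nan, np.nan, np.nan, np.nan, 0, defined=False)
    pA = (n[1, :].sum() + 2 * n[2, :].sum()) / (2 * n_inf)
    pB = (n[:, 1].sum() + 2 * n[:, 2].sum()) / (2 * n_inf)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LDEstimate(np.nan, np.nan, np.nan, np.nan, n_inf, defined=False)
    f, _ = _em_haplotypes(n)
    pA_hat = f[1, :].sum()
    pB_hat = f[:, 1].sum()
    D = f[1, 1] - pA_hat * pB_hat
    if D >= 0:
        dmax = min(pA_hat * (1 - pB_hat), (1 - pA_hat) * pB_hat)
    else:
        dmax = min(pA_hat * pB_hat, (1 - pA_hat) * (1 - pB_hat))
    d_prime = min(1.0, abs(D) / dmax) if dmax > 0 else np.nan
    denom = pA_hat * (1 - pA_hat) * pB_hat * (1 - pB_hat)
    r2 = float(D * D / denom) if denom > 0 else np.nan

    # orient so the MLE D is positive (flip locus-2 alleles), then profile over D'
    table = n if D >= 0 else n[:, ::-1]
    qB = pB_hat if D >= 0 else 1 - pB_hat
    lls = _profile_logliks(table, pA_hat, qB, _DP_GRID)
    like = np.exp(lls - lls.max())
    cum = np.cumsum(like)
    cum /= cum[-1]
    lo_q = (1.0 - ci_level) / 2.0
    ci_low = float(_DP_GRID[np.searchsorted(cum, lo_q)])
    ci_high = float(_DP_GRID[min(len(cum) - 1, np.searchsorted(cum, 1.0 - lo_q))])
    return LDEstimate(float(d_prime), ci_low, ci_high, r2, n_inf)


# pair classes
_STRONG, _RECOMB, _UNINF = 1, -1, 0


def classify_pair(est: LDEstimate, strong_low=0.70, strong_high=0.98,
                  recomb_high=0.90, min_informative=20) -> int:
    if not est.defined or est.n_informative < min_informative:
        return _UNINF
    if est.ci_low >= strong_low and est.ci_high >= strong_high:
        return _STRONG
    if est.ci_high < recomb_high:
        return _RECOMB
    return _UNINF


def gabriel_blocks(
    dosage: np.ndarray,
    snp_ids,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    strong_fraction: float = 0.95,
    min_informative: int = 20,
    max_block_span: int | None = None,
) -> HaplotypeBlockSet:
    """Partition contiguous SNPs into haplotype blocks (Gabriel criteria).

    ``dosage``: patients x SNPs matrix restricted to the SNPs of one region, in
    genomic order; ``snp_ids`` labels its columns.
    """
    snp_ids = list(snp_ids)
    k = len(snp_ids)
    if k == 0:
        return HaplotypeBlockSet(blocks=[])
    if k == 1:
        return HaplotypeBlockSet(blocks=[[snp_ids[0]]], strong_fraction=[float("nan")])
    span = k if max_block_span is None else min(k, max_block_span)
    cls = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, min(k, i + span)):
            est = two_locus_ld(dosage[:, i], dosage[:, j])
            cls[i, j] = classify_pair(est, strong_low, strong_high, recomb_high, min_informative)

    candidates = []  # (length, start, end, frac)
    for i in range(k):
        for j in range(i + 1, min(k, i + span)):
            sub = cls[i:j + 1, i:j + 1]
            n_strong = int((sub == _STRONG).sum())
            n_recomb = int((sub == _RECOMB).sum())
            informative = n_strong + n_recomb
            if informative == 0:
                continue
            frac = n_strong / informative
            if frac >= strong_fraction and n_strong >= 1:
                candidates.append((j - i + 1, i, j, frac))
    # greedy longest-first, ties leftmost
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(k, dtype=bool)
    chosen = []
    for _, i, j, frac in candidates:
        if taken[i:j + 1].any():
            continue
        taken[i:j + 1] = True
        chosen.append((i, j, frac))
    for i in range(k):
        if not taken[i]:
            chosen.append((i, i, float("nan")))
    chosen.sort()
    return HaplotypeBlockSet(
        blocks=[[snp_ids[x] for x in range(i, j + 1)] for i, j, _ in chosen],
        strong_fraction=[frac for _, _, frac in chosen],
    )


def count_tests(block_set: HaplotypeBlockSet) -> int:
    """The per-driver, per-strategy multiple-testing denominator."""
    return block_set.n_blocks
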