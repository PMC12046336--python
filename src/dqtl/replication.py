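"""Replication testing of discovered dQTLs, distal candidate screening and
random-effects (REML) meta-analysis across cohorts.

Replication rule: a discovered dQTL replicates when its replication-cohort BH
q-value is < 0.1 AND the discovery and replication log-OR share a sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import burden_covariate, fit_driver_model

__all__ = ["MetaResult", "test_replication", "distal_screen", "meta_analyze"]


@dataclass
class MetaResult:
    beta: float
    se: float
    tau2: float
    ci_low: float
    ci_high: float
    p: float
    k_studies: int
    q: float = np.nan


def test_replication(
    discovered: pd.DataFrame,
    replication_cohort,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Refit each discovered (snp, driver) pair in the replication cohort.

    BH runs over the discovered set. Records for SNPs or drivers missing from
    the replication cohort are flagged untestable. Output is order-invariant:
    rows are sorted by (snp_id, driver_id).
    """
    rows = []
    snp_ids = set(replication_cohort.snp_table["id"])
    for rec in discovered.sort_values(["snp_id", "driver_id"]).itertuples(index=False):
        row = {
            "snp_id": rec.snp_id, "driver_id": rec.driver_id,
            "beta_discovery": rec.beta, "se_discovery": rec.se, "p_discovery": rec.p,
            "beta_replication": np.nan, "se_replication": np.nan, "p_replication": np.nan,
            "testable": True,
        }
        if (rec.snp_id not in snp_ids
                or rec.driver_id not in replication_cohort.drivers.columns):
            row["testable"] = False
            rows.append(row)
            continue
        dtype = (replication_cohort.driver_meta.loc[rec.driver_id, "type"]
                 if rec.driver_id in replication_cohort.driver_meta.index else "cna_loss")
        cov = replication_cohort.model_covariates(burden_covariate(dtype))
        res = fit_driver_model(
            replication_cohort.dosage_of(rec.snp_id),
            replication_cohort.drivers[rec.driver_id].to_numpy(),
            cov, snp_id=rec.snp_id, driver_id=rec.driver_id, strategy="replication",
        )
        row.update(beta_replication=res.beta, se_replication=res.se, p_replication=res.p)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not len(df):
        df["q_replication"] = []
        df["concordant"] = []
        df["replicated"] = []
        return df
    df["q_replication"] = np.nan
    ok = df["p_replication"].notna()
    if ok.any():
        df.loc[ok, "q_replication"] = multipletests(df.loc[ok, "p_replication"],
                                                    method="fdr_bh")[1]
    df["concordant"] = (np.sign(df["beta_discovery"]) == np.sign(df["beta_replication"])) \
        & df["beta_replication"].notna()
    df["replicated"] = df["concordant"] & (df["q_replication"] < q_threshold)
    return df.reset_index(drop=True)


def distal_screen(
    tag_snps,
    cohort,
    origin_pairs=None,
    drivers=None,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Candidate screen of each tag SNP against all drivers.

    ``origin_pairs`` (set of (snp_id, driver_id)) names the discovery pairs,
    which are excluded from candidacy. BH runs within the screened grid.
    """
    origin_pairs = set(origin_pairs or ())
    driver_ids = list(drivers) if drivers is not None else list(cohort.drivers.columns)
    rows = []
    for snp_id in tag_snps:
        g = cohort.dosage_of(snp_id)
        for driver_id in driver_ids:
            if (snp_id, driver_id) in origin_pairs:
                continue
            dtype = (cohort.driver_meta.loc[driver_id, "type"]
                     if driver_id in cohort.driver_meta.index else "cna_loss")
            cov = cohort.model_covariates(burden_covariate(dtype))
            res = fit_driver_model(g, cohort.drivers[driver_id].to_numpy(), cov,
                                   snp_id=snp_id, driver_id=driver_id, strategy="distal")
            rows.append(res.as_row())
    df = pd.DataFrame(rows)
    if not len(df):
        return df
    ok = df["p"].notna()
    df.loc[ok, "q"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["threshold"] = q_threshold
    df["significant"] = df["q"] < q_threshold
    return df


def _reml_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    return -0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                   + np.sum(w * (y - mu) ** 2))


def meta_analyze(estimates, method: str = "REML", ci_level: float = 0.95,
                 tol: float = 1e-8, max_iter: int = 100) -> MetaResult:
    """Random-effects meta-analysis of (beta, se) pairs.

    tau2 by REML Fisher scoring with nonnegativity projection; the pooled mean
    is the inverse-variance weighted average at tau2-hat. ``method='FE'`` fixes
    tau2 = 0 (closed-form inverse-variance estimate).
    """
    est = list(estimates)
    if len(est) == 0:
        raise ValueError("meta_analyze requires k >= 1 estimates")
    y = np.array([e[0] for e in est], dtype=float)
    v = np.array([e[1] for e in est], dtype=float) ** 2
    if (v <= 0).any():
        raise ValueError("all standard errors must be > 0")
    k = len(y)
    tau2 = 0.0
    if method.upper() == "REML" and k >= 2:
        # DerSimonian-Laird start, then Fisher scoring on the REML score
        w = 1.0 / v
        mu = np.sum(w * y) / np.sum(w)
        q_stat = np.sum(w * (y - mu) ** 2)
        c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        tau2 = max(0.0, (q_stat - (k - 1)) / c) if c > 0 else 0.0
        for _ in range(max_iter):
            w = 1.0 / (v + tau2)
            sw = np.sum(w)
            mu = np.sum(w * y) / sw
            r = y - mu
            # P v = W v - W 1 (1'W1)^-1 1'W v  with X = 1
            Pr = w * r  # since 1'W r = 0 at mu-hat
            trP = sw - np.sum(w ** 2) / sw
            # tr(P^2) = sum_ij P_ij^2 for X=1: P_ij = w_i delta_ij - w_i w_j / sw
            trP2 = np.sum(w ** 2) - 2.0 * np.sum(w ** 3) / sw + (np.sum(w ** 2) / sw) ** 2
            P2r = w * (Pr - np.sum(w * Pr) / sw)
            score = -0.5 * trP + 0.5 * float(r @ P2r)
            info = 0.5 * trP2
            if info <= 0:
                break
            step = score / info
            new = tau2 + step
            if new < 0:
                new = tau2 / 2.0 if tau2 > 0 else 0.0
            if abs(new - tau2) < tol:
                tau2 = max(0.0, new)
                break
            tau2 = new
        tau2 = max(0.0, tau2)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    p = float(2 * stats.norm.sf(abs(mu / se)))
    return MetaResult(beta=mu, se=se, tau2=float(tau2),
                      ci_low=mu - z * se, ci_high=mu + z * se, p=p, k_studies=k)


def meta_analyze_set(records: dict, q_threshold: float = 0.1) -> pd.DataFrame:
    """Meta-analyze a set of dQTLs ({id: [(beta, se), ...]}) with BH across the set."""
    rows = []
    for key, est in records.items():
        m = meta_analyze(est)
        rows.append({"dqtl": key, "beta": m.beta, "se": m.se, "tau2": m.tau2,
                     "ci_low": m.ci_low, "ci_high": m.ci_high, "p": m.p,
                     "k_studies": m.k_studies})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["replicated"] = df["q"] < q_threshold
    return df
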