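"""Per-SNP logistic dQTL models, strategy-specific multiple testing, tag SNPs.

Every scan fits ``driver ~ dosage + PC1-5 + age + burden`` where the burden
covariate is PGA for copy-number/fusion drivers and SNV density for SNV
drivers. Genotypes are coded additively (per-allele). Complete separation
triggers a Firth-type penalized refit, flagged in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "maf_filter",
    "fit_driver_model",
    "scan_risk",
    "scan_local",
    "select_tag_snps",
    "index_event_adjustment",
    "burden_covariate",
    "firth_logistic",
]

RESULT_COLUMNS = [
    "snp_id", "driver_id", "strategy", "beta", "se", "or_", "p",
    "threshold", "significant", "q", "n_used", "converged", "separation_flag",
]


@dataclass
class AssociationResult:
    snp_id: str
    driver_id: str
    strategy: str
    beta: float
    se: float
    p: float
    n_used: int
    converged: bool = True
    separation_flag: bool = False
    threshold: float = np.nan
    significant: bool = False
    q: float = np.nan

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    def as_row(self) -> dict:
        return {
            "snp_id": self.snp_id, "driver_id": self.driver_id, "strategy": self.strategy,
            "beta": self.beta, "se": self.se, "or_": self.or_, "p": self.p,
            "threshold": self.threshold, "significant": self.significant, "q": self.q,
            "n_used": self.n_used, "converged": self.converged,
            "separation_flag": self.separation_flag,
        }


def maf_filter(snp_table: pd.DataFrame, min_maf: float = 0.05) -> pd.DataFrame:
    """SNPs with MAF strictly greater than ``min_maf``."""
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    return snp_table[snp_table["maf"] > min_maf].reset_index(drop=True)


def burden_covariate(driver_type: str) -> str:
    """PGA for structural drivers, SNV density for point-mutation drivers."""
    return "snv_density" if driver_type == "snv" else "pga"


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth penalized-likelihood logistic regression (Jeffreys prior).

    Returns (beta, se, converged).
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return beta, np.full(p, np.nan), False
        h = np.einsum("ij,jk,ik->i", X, info_inv, XtW.T)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # step-halving for stability
        for _ in range(20):
            if np.max(np.abs(step)) < 5:
                break
            step *= 0.5
        beta_new = beta + step
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        info = (X.T * w) @ X
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        return beta, se, False
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    info = (X.T * w) @ X
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se, True


def _design(dosage, covariates: pd.DataFrame | None, extra: pd.DataFrame | None = None):
    cols = [np.asarray(dosage, dtype=float)]
    names = ["dosage"]
    for df in (covariates, extra):
        if df is not None and len(df.columns):
            for c in df.columns:
                cols.append(df[c].to_numpy(dtype=float))
                names.append(c)
    X = np.column_stack(cols)
    return X, names


def fit_driver_model(
    dosage,
    driver,
    covariates: pd.DataFrame | None = None,
    extra_covariates: pd.DataFrame | None = None,
    snp_id: str = "",
    driver_id: str = "",
    strategy: str = "",
) -> AssociationResult:
    """Logistic fit of a binary driver on SNP dosage plus covariates.

    Complete-case over all inputs. Wald two-sided p on the dosage coefficient.
    Degenerate dosage or separation is flagged; separation falls back to a
    Firth penalized fit.
    """
    import statsmodels.api as sm

    y = np.asarray(driver, dtype=float)
    X, _ = _design(dosage, covariates, extra_covariates)
    keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X = y[keep], X[keep]
    n_used = int(keep.sum())
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"driver {driver_id!r} has a single class; cannot fit")
    if np.nanstd(X[:, 0]) == 0:
        return AssociationResult(snp_id, driver_id, strategy, np.nan, np.nan, np.nan,
                                 n_used, converged=False, separation_flag=True)
    Xc = np.column_stack([np.ones(n_used), X])
    separation = False
    beta = se = p = np.nan
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", False))
            beta, se = res.params[1], res.bse[1]
            if not converged or not np.isfinite(se) or se > 50 or abs(beta) > 15:
                separation = True
        except Exception:
            separation = True
    if separation:
        fb, fse, fconv = firth_logistic(Xc, y)
        beta, se, converged = fb[1], fse[1], fconv
    if np.isfinite(se) and se > 0:
        z = beta / se
        p = 2 * stats.norm.sf(abs(z))
    elif not converged:
        p = np.nan
    return AssociationResult(snp_id, driver_id, strategy, float(beta), float(se), float(p),
                             n_used, converged=converged, separation_flag=separation)


def _results_frame(results: list) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.DataFrame([r.as_row() for r in results], columns=RESULT_COLUMNS)


def scan_risk(
    cohort,
    risk_snps,
    drivers=None,
    q_threshold: float = 0.1,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Risk-SNP strategy: all risk SNPs x all drivers, BH over the full grid."""
    present = [s for s in risk_snps if s in set(cohort.snp_table["id"])]
    missing = [s for s in risk_snps if s not in set(cohort.snp_table["id"])]
    if missing:
        warnings.warn(f"{len(missing)} risk SNPs absent from genotypes: {missing[:5]}...")
    snp_sub = cohort.snp_table[cohort.snp_table["id"].isin(present)]
    snp_sub = maf_filter(snp_sub, min_maf)
    driver_ids = list(drivers) if drivers is not None else list(cohort.drivers.columns)
    results = []
    for driver_id in driver_ids:
        dtype = cohort.driver_meta.loc[driver_id, "type"] if driver_id in cohort.driver_meta.index else "cna_loss"
        cov = cohort.model_covariates(burden_covariate(dtype))
        y = cohort.drivers[driver_id].to_numpy()
        for snp_id in snp_sub["id"]:
            g = cohort.dosage_of(snp_id)
            results.append(fit_driver_model(g, y, cov, snp_id=snp_id,
                                            driver_id=driver_id, strategy="risk"))
    df = _results_frame(results)
    if not len(df):
        warnings.warn("empty risk scan: no testable SNP/driver combinations")
        return df
    ok = df["p"].notna()
    df.loc[ok, "q"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["threshold"] = q_threshold
    df["significant"] = df["q"] < q_threshold
    return df


def scan_local(
    cohort,
    driver_id: str,
    strategy: str,
    region_set,
    block_set,
    alpha: float = 0.1,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Linear/spatial/enhancer scan with block-Bonferroni at ``alpha``."""
    from .ld import count_tests
    from .regions import snps_in_regions

    if strategy not in {"linear", "spatial", "enhancer"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    n_blocks = count_tests(block_set)
    if n_blocks == 0:
        return _results_frame([])
    threshold = alpha / n_blocks
    snp_ids = snps_in_regions(cohort.snp_table, region_set)
    snp_sub = cohort.snp_table[cohort.snp_table["id"].isin(snp_ids)]
    snp_sub = maf_filter(snp_sub, min_maf)
    snp_sub = snp_sub.sort_values(["chrom", "pos"], kind="mergesort")
    dtype = cohort.driver_meta.loc[driver_id, "type"] if driver_id in cohort.driver_meta.index else "cna_loss"
    cov = cohort.model_covariates(burden_covariate(dtype))
    y = cohort.drivers[driver_id].to_numpy()
    results = []
    for snp_id in snp_sub["id"]:
        g = cohort.dosage_of(snp_id)
        r = fit_driver_model(g, y, cov, snp_id=snp_id, driver_id=driver_id, strategy=strategy)
        r.threshold = threshold
        r.significant = bool(np.isfinite(r.p) and r.p < threshold)
        results.append(r)
    return _results_frame(results)


def select_tag_snps(results: pd.DataFrame, block_set, snp_table: pd.DataFrame) -> pd.DataFrame:
    """One tag SNP per block holding at least one significant result.

    The block's minimum-p SNP is tagged; p ties break to the smaller position.
    """
    if not len(results):
        return results.iloc[0:0]
    block_of = block_set.block_of()
    df = results.merge(snp_table[["id", "pos"]], left_on="snp_id", right_on="id", how="left")
    df["block"] = df["snp_id"].map(block_of)
    tagged = []
    for block, grp in df[df["block"].notna()].groupby("block"):
        if not grp["significant"].any():
            continue
        grp = grp.sort_values(["p", "pos"], kind="mergesort")
        tagged.append(grp.iloc[0])
    if not tagged:
        return results.iloc[0:0]
    out = pd.DataFrame(tagged).drop(columns=["id", "pos"])
    return out.sort_values("block").reset_index(drop=True)


def index_event_adjustment(
    cohort,
    snp_id: str,
    driver_id: str,
    strategy: str = "",
) -> AssociationResult:
    """Refit adding ISUP GG (ordinal-coded), T category (>=T3 binary), log PSA."""
    cov = cohort.covariates
    clinical = {}
    n_before = len(cov)
    if "ISUP_GG" in cov:
        clinical["ISUP_GG"] = cov["ISUP_GG"].astype(float)
    if "T_category" in cov:
        t = cov["T_category"]
        if t.dtype == object:
            t = t.str.lstrip("T").str[0].astype(float)
        tbin = (t >= 3).astype(float)
        if tbin.nunique() > 1:
            clinical["T_ge3"] = tbin
        else:
            warnings.warn("T category has a single level; covariate dropped")
    if "PSA" in cov:
        clinical["log_psa"] = np.log(cov["PSA"].astype(float))
    extra = pd.DataFrame(clinical)
    n_complete = int((~extra.isna().any(axis=1)).sum()) if len(extra.columns) else n_before
    if n_complete < n_before:
        warnings.warn(f"index-event adjustment uses {n_complete}/{n_before} complete cases")
    dtype = cohort.driver_meta.loc[driver_id, "type"] if driver_id in cohort.driver_meta.index else "cna_loss"
    base = cohort.model_covariates(burden_covariate(dtype))
    return fit_driver_model(
        cohort.dosage_of(snp_id), cohort.drivers[driver_id].to_numpy(), base, extra,
        snp_id=snp_id, driver_id=driver_id, strategy=strategy or "adjusted",
    )
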