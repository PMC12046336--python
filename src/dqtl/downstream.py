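"""dQTL characterization: molecular QTL models, tumor specificity, permutation
enrichment, ancestry VAF bias with explained fractions, p-value-skew and pi0
diagnostics, and clinical genetic-model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MolecularQTLResult",
    "AncestryVAFRecord",
    "ExplainedFraction",
    "rank_inverse_normal",
    "latent_factors",
    "molecular_qtl",
    "tumor_specificity",
    "qtl_enrichment_permutation",
    "vaf_ancestry_test",
    "explained_fraction",
    "pvalue_skew_test",
    "pi0_estimate",
    "clinical_association",
]


@dataclass
class MolecularQTLResult:
    snp: str
    trait_id: str
    beta: float
    se: float
    p: float
    q: float
    cohort: str
    tumor_specific: object = None


@dataclass
class AncestryVAFRecord:
    snp: str
    vaf_pop1: float
    vaf_pop2: float
    n_pop1: int
    n_pop2: int

    def allele_table(self) -> np.ndarray:
        """2x2 alt/ref counts reconstructed as round(vaf * 2n)."""
        a1 = int(round(self.vaf_pop1 * 2 * self.n_pop1))
        a2 = int(round(self.vaf_pop2 * 2 * self.n_pop2))
        return np.array([[a1, 2 * self.n_pop1 - a1], [a2, 2 * self.n_pop2 - a2]])


@dataclass
class ExplainedFraction:
    or_ancestry: float
    or_dqtl: float
    delta_vaf: float
    formula_variant: str
    fraction: float


def rank_inverse_normal(x: np.ndarray, c: float = 0.375) -> np.ndarray:
    """Blom-offset rank inverse normal transform (NaN-preserving)."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    r = stats.rankdata(x[ok])
    out[ok] = stats.norm.ppf((r - c) / (ok.sum() - 2 * c + 1))
    return out


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(C)), C])
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


def latent_factors(trait_matrix: pd.DataFrame, covariates: pd.DataFrame,
                   n_factors: int = 10) -> pd.DataFrame:
    """Top principal components of the covariate-residualized trait matrix.

    Stands in for PEER-style latent noise factors in the molecular QTL models.
    """
    M = trait_matrix.to_numpy(dtype=float)
    R = _residualize(M, covariates.to_numpy(dtype=float))
    R = R - R.mean(axis=0)
    n_factors = min(n_factors, min(R.shape) - 1)
    if n_factors < 1:
        return pd.DataFrame(index=trait_matrix.index)
    u, s, _ = np.linalg.svd(R, full_matrices=False)
    pcs = u[:, :n_factors] * s[:n_factors]
    return pd.DataFrame(pcs, index=trait_matrix.index,
                        columns=[f"LF{i+1}" for i in range(n_factors)])


def _ols_test(y: np.ndarray, g: np.ndarray, C: np.ndarray | None):
    """OLS of y ~ g + C; returns (beta_g, se, p) with complete-case handling."""
    cols = [g] if C is None else [g] + [C[:, j] for j in range(C.shape[1])]
    X = np.column_stack([np.ones(len(y))] + cols)
    keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X = y[keep], X[keep]
    n, p = X.shape
    if n <= p:
        return np.nan, np.nan, np.nan
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    if se == 0:
        return float(coef[1]), 0.0, np.nan
    t = coef[1] / se
    return float(coef[1]), se, float(2 * stats.t.sf(abs(t), dof))


def molecular_qtl(
    snp_id: str,
    dosage: np.ndarray,
    snp_pos: int,
    snp_chrom,
    trait_matrix: pd.DataFrame,
    trait_table: pd.DataFrame,
    covariates: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    window: int = 500_000,
    transform: str | None = None,
    q_threshold: float = 0.1,
    cohort: str = "discovery",
) -> pd.DataFrame:
    """Linear QTL scan of one SNP against traits within +/- window.

    ``transform='rint'`` applies the rank inverse normal transform per trait
    (expression); methylation beta values stay untransformed.
    """
    sel = trait_table[(trait_table["chrom"] == snp_chrom)
                      & (trait_table["pos"] >= snp_pos - window)
                      & (trait_table["pos"] <= snp_pos + window)]
    C_parts = [covariates.to_numpy(dtype=float)]
    if factors is not None and len(factors.columns):
        C_parts.append(factors.to_numpy(dtype=float))
    C = np.column_stack(C_parts)
    rows = []
    for trait_id in sel["trait_id"]:
        y = trait_matrix[trait_id].to_numpy(dtype=float)
        if transform == "rint":
            y = rank_inverse_normal(y)
        beta, se, p = _ols_test(y, np.asarray(dosage, float), C)
        rows.append({"snp": snp_id, "trait_id": trait_id, "beta": beta, "se": se,
                     "p": p, "q": np.nan, "cohort": cohort})
    df = pd.DataFrame(rows, columns=["snp", "trait_id", "beta", "se", "p", "q", "cohort"])
    if len(df):
        ok = df["p"].notna()
        if ok.any():
            df.loc[ok, "q"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < q_threshold
    else:
        df["significant"] = []
    return df


def tumor_specificity(tumor_results: pd.DataFrame, reference_results: pd.DataFrame,
                      q_threshold: float = 0.10) -> pd.DataFrame:
    """Tumor-specific <=> Q_tumor < 0.1 and (Q_reference > 0.1 or opposite signs)."""
    merged = tumor_results.merge(
        reference_results, on=["snp", "trait_id"], how="left", suffixes=("_t", "_r")
    )
    spec = []
    for row in merged.itertuples(index=False):
        if pd.isna(row.q_r) or pd.isna(row.q_t):
            spec.append(None)
            continue
        opposite = np.sign(row.beta_t) != np.sign(row.beta_r)
        spec.append(bool(row.q_t < q_threshold and (row.q_r > q_threshold or opposite)))
    merged["tumor_specific"] = spec
    return merged


def qtl_enrichment_permutation(
    tag_snps,
    snp_pool,
    qtl_pipeline,
    n_iter: int = 1000,
    seed: int = 0,
    add_one: bool = False,
):
    """Permutation enrichment of molecular-QTL yield at the tag SNPs.

    ``qtl_pipeline(snp_ids)`` must return (n_snps_with_replicated_qtl,
    n_replicated_qtls) for any SNP subset. Each iteration draws len(tag_snps)
    SNPs from the pool and reruns the pipeline. p = fraction of iterations with
    a null count >= observed (the strict-fraction estimator; ``add_one`` for
    (1+x)/(1+n)).
    Returns (p_snps_involved, p_total_qtls, null DataFrame).
    """
    pool = list(snp_pool)
    tags = list(tag_snps)
    if len(pool) < len(tags):
        raise ValueError("SNP pool smaller than the tag set")
    rng = np.random.default_rng(seed)
    obs_snps, obs_qtls = qtl_pipeline(tags)
    null = np.empty((n_iter, 2))
    for i in range(n_iter):
        draw = list(rng.choice(pool, size=len(tags), replace=False))
        null[i] = qtl_pipeline(draw)
    if add_one:
        p_snps = (1 + int((null[:, 0] >= obs_snps).sum())) / (1 + n_iter)
        p_qtls = (1 + int((null[:, 1] >= obs_qtls).sum())) / (1 + n_iter)
    else:
        p_snps = float((null[:, 0] >= obs_snps).mean())
        p_qtls = float((null[:, 1] >= obs_qtls).mean())
    null_df = pd.DataFrame(null, columns=["n_snps_involved", "n_qtls"])
    return p_snps, p_qtls, null_df


def vaf_ancestry_test(records, q_threshold: float = 0.01) -> pd.DataFrame:
    """Two-sided Fisher exact tests on reconstructed 2x2 allele tables, BH over SNPs."""
    rows = []
    for rec in records:
        table = rec.allele_table()
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            rows.append({"snp": rec.snp, "vaf_pop1": rec.vaf_pop1, "vaf_pop2": rec.vaf_pop2,
                         "allele_or": np.nan, "fisher_p": 1.0, "or_defined": False})
            continue
        res = stats.fisher_exact(table, alternative="two-sided")
        try:  # conditional-MLE odds ratio
            cmle = stats.contingency.odds_ratio(table, kind="conditional").statistic
        except Exception:
            cmle = res[0]
        rows.append({"snp": rec.snp, "vaf_pop1": rec.vaf_pop1, "vaf_pop2": rec.vaf_pop2,
                     "allele_or": float(cmle), "fisher_p": float(res[1]), "or_defined": True})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["fisher_p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < q_threshold
    return df


_EF_VARIANTS = ("delta2", "delta", "odds")


def explained_fraction(or_ancestry: float, or_dqtl: float, vaf_pop1: float,
                       vaf_pop2: float, variant: str = "delta2") -> ExplainedFraction:
    """Fraction of an ancestry-somatic OR explained by one dQTL.

    Variants (always recorded in the output):
      delta2 (default): 2*(v1 - v2)*log(OR_dqtl) / log(OR_ancestry)
      delta:              (v1 - v2)*log(OR_dqtl) / log(OR_ancestry)
      odds:   [log odds(v1) - log odds(v2)]*log(OR_dqtl) / log(OR_ancestry)
    """
    if or_ancestry <= 0 or or_dqtl <= 0:
        raise ValueError("odds ratios must be > 0")
    if or_ancestry == 1.0:
        raise ValueError("or_ancestry = 1 leaves the fraction undefined")
    if variant not in _EF_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {_EF_VARIANTS}")
    delta = vaf_pop1 - vaf_pop2
    if variant == "delta2":
        num = 2.0 * delta * np.log(or_dqtl)
    elif variant == "delta":
        num = delta * np.log(or_dqtl)
    else:
        lo = np.log(vaf_pop1 / (1 - vaf_pop1)) - np.log(vaf_pop2 / (1 - vaf_pop2))
        num = lo * np.log(or_dqtl)
    frac = float(num / np.log(or_ancestry))
    return ExplainedFraction(or_ancestry, or_dqtl, float(delta), variant, frac)


def pvalue_skew_test(
    scan_callable,
    driver_labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    add_one: bool = False,
):
    """Permutation test for small-p skew of a dQTL scan.

    ``scan_callable(labels)`` returns the scan's p-values for arbitrary driver
    labels. Labels are permuted (exact frequency preserved); the statistic is
    the sample skewness of -log10 p. p = #{perm skew > observed}/n_perm
    (the strict estimator; ``add_one`` available).
    Returns (p, observed_skew, null_skews).
    """
    labels = np.asarray(driver_labels)
    rng = np.random.default_rng(seed)
    obs_p = np.asarray(scan_callable(labels), dtype=float)
    obs_p = obs_p[np.isfinite(obs_p)]
    if len(obs_p) < 3:
        raise ValueError("scan produced < 3 p-values; skew undefined")
    obs_skew = float(stats.skew(-np.log10(np.clip(obs_p, 1e-300, 1.0))))
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        pv = np.asarray(scan_callable(perm), dtype=float)
        pv = pv[np.isfinite(pv)]
        null[i] = stats.skew(-np.log10(np.clip(pv, 1e-300, 1.0)))
    if add_one:
        p = (1 + int((null > obs_skew).sum())) / (1 + n_perm)
    else:
        p = float((null > obs_skew).mean())
    return p, obs_skew, null


def pi0_estimate(p_values, lambda_grid=None) -> float:
    """Storey pi0 with cubic-smoother extrapolation to lambda -> 1."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return 1.0
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    if m < 20:
        warnings.warn("fewer than 20 p-values; falling back to fixed lambda = 0.5")
        return float(np.clip((p > 0.5).sum() / (m * 0.5), 0.0, 1.0))
    pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
    coefs = np.polyfit(lam, pi0_lam, deg=3)
    pi0 = float(np.polyval(coefs, lam.max()))
    return float(np.clip(pi0, 0.0, 1.0))


def _genetic_codings(dosage: np.ndarray) -> dict:
    return {
        "codominant": dosage.astype(float),
        "dominant": (dosage > 0).astype(float),
        "recessive": (dosage == 2).astype(float),
    }


def clinical_association(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    kind: str,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Fit dominant / recessive / codominant codings; report the lowest-AIC model.

    ``kind``: 'linear' (PSA, age), 'logistic' (binary T category), 'ordinal'
    (ISUP GG). Recessive is skipped when no homozygous-alt carriers exist.
    Returns {"best": name, "models": {name: {beta, se, p, aic}}, "skipped": [...]}.
    """
    import statsmodels.api as sm
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    if kind not in {"linear", "logistic", "ordinal"}:
        raise ValueError(f"unknown kind {kind!r}")
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    C = covariates.to_numpy(dtype=float) if covariates is not None else None
    models = {}
    skipped = []
    for name, g in _genetic_codings(dosage).items():
        if name == "recessive" and np.nansum(dosage == 2) == 0:
            skipped.append(name)
            continue
        if np.nanstd(g) == 0:
            skipped.append(name)
            continue
        cols = [g] if C is None else [g] + [C[:, j] for j in range(C.shape[1])]
        X = np.column_stack(cols)
        keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
        Xk, yk = X[keep], y[keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                if kind == "linear":
                    res = sm.OLS(yk, sm.add_constant(Xk)).fit()
                    beta, se, p = res.params[1], res.bse[1], res.pvalues[1]
                elif kind == "logistic":
                    res = sm.Logit(yk, sm.add_constant(Xk)).fit(disp=0)
                    beta, se, p = res.params[1], res.bse[1], res.pvalues[1]
                else:
                    res = OrderedModel(yk, Xk, distr="logit").fit(method="bfgs", disp=0)
                    beta, se, p = res.params[0], res.bse[0], res.pvalues[0]
                models[name] = {"beta": float(beta), "se": float(se), "p": float(p),
                                "aic": float(res.aic)}
            except Exception as exc:  # degenerate fits happen at tiny n
                skipped.append(name)
                warnings.warn(f"{name} coding failed: {exc}")
    if not models:
        raise ValueError("no genetic model could be fit")
    best = min(models, key=lambda k: models[k]["aic"])
    return {"best": best, "models": models, "skipped": skipped}
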