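"""Synthetic multi-cohort, multi-ancestry data with the statistical structure the
dQTL analysis assumes: block-structured LD, configurable MAF spectrum, binary
somatic drivers at target frequencies with planted per-allele log-odds effects,
confounding covariates, chromatin-loop anchors and molecular trait matrices.

Everything is driven by an explicit integer seed; a fixed seed fixes every
emitted byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LoopAnchorSet, RegionSet, compute_maf, write_bed, write_bedpe, write_tsv_matrix, write_vcf

__all__ = [
    "PlantedEffect",
    "PlantedQTL",
    "SimulationConfig",
    "Cohort",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_drivers",
    "simulate_cohort",
    "simulate_loop_anchors",
    "simulate_molecular_traits",
    "ancestry_frequencies",
    "export_cohort",
]

PC_COLUMNS = ["PC1", "PC2", "PC3", "PC4", "PC5"]
DRIVER_TYPES = ("cna_loss", "cna_gain", "snv", "fusion")


@dataclass
class PlantedEffect:
    """Ground-truth SNP -> driver effect for parameter-recovery tests."""

    snp_id: str
    driver_id: str
    per_allele_log_odds: float
    confounded_by: str | None = None


@dataclass
class PlantedQTL:
    """Ground-truth SNP -> molecular trait effect."""

    snp_id: str
    trait_id: str
    beta: float
    tumor_specific: bool = False


@dataclass
class SimulationConfig:
    n_patients: int = 427
    n_snps: int = 200
    block_lengths: list | None = None       # explicit SNPs-per-block; else geometric
    mean_block_size: float = 7.0            # mean of the geometric block-length law
    maf_range: tuple = (0.05, 0.5)
    ld_decay: float = 0.1                   # per-site haplotype-copying mutation rate
    n_ancestral_haplotypes: int = 4
    n_drivers: int = 4
    driver_freqs: list | None = None        # defaults spread over 5%-57%
    planted_effects: list = field(default_factory=list)
    covariate_model: dict = field(default_factory=dict)  # covariate -> coef on driver logit
    ancestry_panels: dict = field(default_factory=dict)  # population -> Fst
    missing_rate: float = 0.0
    snp_spacing: int = 2_000
    block_gap: int = 200_000
    chromosome: str = "1"
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if not 0 <= self.ld_decay <= 1:
            raise ValueError("ld_decay must be in [0, 1]")
        if self.driver_freqs is None:
            spread = np.linspace(0.051, 0.573, max(self.n_drivers, 1))
            self.driver_freqs = [float(f) for f in spread]
        if len(self.driver_freqs) != self.n_drivers:
            raise ValueError("driver_freqs length must equal n_drivers")
        for f in self.driver_freqs:
            if not 0 < f < 1:
                raise ValueError("driver frequencies must be in (0, 1)")
        if self.block_lengths is not None and any(b < 1 for b in self.block_lengths):
            raise ValueError("block lengths must be >= 1")


@dataclass
class Cohort:
    """Genotypes, SNP metadata, covariates and somatic driver calls for one cohort."""

    dosage: np.ndarray                 # patients x SNPs, {0,1,2} + NaN
    snp_table: pd.DataFrame            # id, chrom, pos, ref, alt, maf, block
    samples: list
    covariates: pd.DataFrame = None
    drivers: pd.DataFrame = None       # patients x drivers, binary
    driver_meta: pd.DataFrame = None   # index driver_id: type, timing, chrom, start, end, freq

    def __post_init__(self):
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated patient identifiers")
        self._col = {s: j for j, s in enumerate(self.snp_table["id"])}

    @property
    def n_patients(self) -> int:
        return self.dosage.shape[0]

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self._col[snp_id]]

    def model_covariates(self, burden: str = "pga") -> pd.DataFrame:
        """PC1-5 + age + the requested burden column, the standard dQTL model."""
        cols = PC_COLUMNS + ["age", burden]
        return self.covariates[cols]

    def driver_region(self, driver_id: str) -> RegionSet:
        row = self.driver_meta.loc[driver_id]
        return RegionSet(
            pd.DataFrame([(row["chrom"], int(row["start"]), int(row["end"]))],
                         columns=["chrom", "start", "end"]),
            provenance="driver", driver_id=driver_id,
        )


def _draw_block_lengths(config: SimulationConfig, rng) -> list:
    if config.block_lengths is not None:
        lengths = list(config.block_lengths)
        if sum(lengths) != config.n_snps:
            raise ValueError("block_lengths must sum to n_snps")
        return lengths
    lengths = []
    total = 0
    p = 1.0 / max(config.mean_block_size, 1.0)
    while total < config.n_snps:
        k = int(rng.geometric(p))
        k = min(k, config.n_snps - total)
        lengths.append(k)
        total += k
    return lengths


def simulate_genotypes(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Block-wise haplotype-copying genotype simulation.

    Per block an ancestral haplotype pool is drawn from per-site allele
    frequencies; each individual haplotype copies a random pool member and
    resamples each site independently with probability ``ld_decay``. Diploids
    pair two haplotypes. SNPs drifting outside ``maf_range`` are dropped
    (planted-effect SNPs excepted downstream by id lookup failing loudly).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.maf_range
    lengths = _draw_block_lengths(config, rng)
    n = config.n_patients
    dosage_cols, meta_rows = [], []
    pos = 10_000
    snp_idx = 0
    for b, k in enumerate(lengths):
        freqs = rng.uniform(lo, hi, size=k)
        pool = (rng.random((config.n_ancestral_haplotypes, k)) < freqs).astype(np.int8)
        hap_choice = rng.integers(0, config.n_ancestral_haplotypes, size=(2 * n,))
        haps = pool[hap_choice]
        if config.ld_decay > 0:
            mutate = rng.random((2 * n, k)) < config.ld_decay
            fresh = (rng.random((2 * n, k)) < freqs).astype(np.int8)
            haps = np.where(mutate, fresh, haps)
        dos = haps[0::2] + haps[1::2]
        dosage_cols.append(dos.astype(float))
        for j in range(k):
            meta_rows.append((f"snp{snp_idx:05d}", config.chromosome, pos, "A", "G", b))
            pos += config.snp_spacing
            snp_idx += 1
        pos += config.block_gap
    dosage = np.hstack(dosage_cols)
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan
    snp_table = pd.DataFrame(meta_rows, columns=["id", "chrom", "pos", "ref", "alt", "block"])
    maf = compute_maf(dosage)
    keep = (maf >= lo) & (maf <= hi)
    # planted-effect SNPs must survive drift filtering (they stay polymorphic)
    planted = {e.snp_id for e in config.planted_effects}
    if planted:
        keep |= snp_table["id"].isin(planted).to_numpy() & (maf > 0)
    dosage = dosage[:, keep]
    snp_table = snp_table[keep].reset_index(drop=True)
    snp_table["maf"] = compute_maf(dosage)
    snp_table = snp_table[["id", "chrom", "pos", "ref", "alt", "maf", "block"]]
    samples = [f"patient{i:05d}" for i in range(n)]
    return Cohort(dosage=dosage, snp_table=snp_table, samples=samples)


def simulate_covariates(n: int, rng) -> pd.DataFrame:
    cov = {c: rng.normal(0, 1, n) for c in PC_COLUMNS}
    cov["age"] = rng.normal(65, 7, n)
    cov["pga"] = rng.beta(1.5, 18, n)
    cov["snv_density"] = rng.lognormal(-0.9, 0.6, n)
    cov["ISUP_GG"] = rng.integers(1, 6, n).astype(float)
    cov["T_category"] = rng.choice([2.0, 3.0], size=n, p=[0.6, 0.4])
    cov["PSA"] = rng.lognormal(2.0, 0.6, n)
    return pd.DataFrame(cov)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _solve_intercept(eta: np.ndarray, target: float, tol: float = 1e-6) -> float:
    """Bisection on beta0 so that mean(logistic(beta0 + eta)) = target."""
    lo, hi = -30.0, 30.0
    f = lambda b0: float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta))))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target frequency unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * 1e-3:
            break
    return 0.5 * (lo + hi)


def simulate_drivers(
    cohort: Cohort,
    planted_effects: list,
    config: SimulationConfig,
    seed: int | None = None,
    timing_available: bool = True,
) -> Cohort:
    """Draw binary driver calls from a logistic generative model.

    P(driver=1) = logistic(beta0 + sum planted beta * dosage + covariate terms);
    beta0 is solved by bisection so the marginal frequency hits the target
    within +/- 0.5%.
    """
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    n = cohort.n_patients
    if cohort.covariates is None:
        cohort.covariates = simulate_covariates(n, rng)
    driver_ids = [f"driver{d:02d}" for d in range(config.n_drivers)]
    effects_by_driver: dict = {d: [] for d in driver_ids}
    for eff in planted_effects:
        if eff.driver_id not in effects_by_driver:
            raise ValueError(f"planted effect references unknown driver {eff.driver_id!r}")
        if eff.snp_id not in set(cohort.snp_table["id"]):
            raise ValueError(f"planted effect references unknown SNP {eff.snp_id!r}")
        effects_by_driver[eff.driver_id].append(eff)

    cols = {}
    meta = []
    blocks = sorted(cohort.snp_table["block"].unique())
    for d, (driver_id, freq) in enumerate(zip(driver_ids, config.driver_freqs)):
        eta = np.zeros(n)
        for eff in effects_by_driver[driver_id]:
            g = cohort.dosage_of(eff.snp_id)
            g = np.where(np.isnan(g), np.nanmean(g), g)
            eta = eta + eff.per_allele_log_odds * g
        for cov_name, coef in config.covariate_model.items():
            eta = eta + coef * _standardize(cohort.covariates[cov_name].to_numpy(float))
        try:
            b0 = _solve_intercept(eta, freq)
        except ValueError:
            raise ValueError(f"target frequency {freq} unreachable for {driver_id}") from None
        prob = 1.0 / (1.0 + np.exp(-(b0 + eta)))
        cols[driver_id] = (rng.random(n) < prob).astype(int)
        dtype = DRIVER_TYPES[d % len(DRIVER_TYPES)]
        timing = ("NA" if dtype in ("snv", "fusion") or not timing_available
                  else ("trunk" if d % 2 == 0 else "branch"))
        # driver region anchored on one simulated block
        blk = blocks[d % len(blocks)]
        sub = cohort.snp_table[cohort.snp_table["block"] == blk]
        meta.append((driver_id, dtype, timing, config.chromosome,
                     int(sub["pos"].min()), int(sub["pos"].max()), freq))
    cohort.drivers = pd.DataFrame(cols, index=cohort.samples)
    cohort.driver_meta = pd.DataFrame(
        meta, columns=["driver_id", "type", "timing", "chrom", "start", "end", "target_freq"]
    ).set_index("driver_id")
    return cohort


def simulate_cohort(config: SimulationConfig, seed: int | None = None,
                    timing_available: bool = True) -> Cohort:
    """Genotypes + covariates + drivers in one call (the default fixture)."""
    base = config.seed if seed is None else seed
    cohort = simulate_genotypes(config, seed=base)
    rng = np.random.default_rng(base + 10_007)
    cohort.covariates = simulate_covariates(config.n_patients, rng)
    return simulate_drivers(cohort, config.planted_effects, config,
                            seed=base + 20_011, timing_available=timing_available)


def simulate_loop_anchors(
    snp_table: pd.DataFrame,
    driver_regions: dict,
    planted_snp_ids: dict | None = None,
    cell_lines=("LNCaP", "DU145"),
    target: str = "RNAPII",
    fraction: float = 1.0,
    n_background: int = 10,
    anchor_size: int = 5_000,
    distal_offset: int = 2_000_000,
    seed: int = 0,
) -> LoopAnchorSet:
    """BEDPE-style loop anchors pairing driver regions with distal windows.

    ``driver_regions``: driver_id -> RegionSet. ``planted_snp_ids``:
    driver_id -> snp id whose position the distal partner window must contain;
    with probability ``fraction`` a planted loop is emitted in every listed
    cell line. Background loops fall far from all SNPs.
    """
    rng = np.random.default_rng(seed)
    pos_of = dict(zip(snp_table["id"], zip(snp_table["chrom"], snp_table["pos"])))
    rows = []
    planted_snp_ids = planted_snp_ids or {}
    for driver_id, region in driver_regions.items():
        row = region.intervals.iloc[0]
        a = (row["chrom"], int(row["start"]), int(row["end"]))
        snp = planted_snp_ids.get(driver_id)
        if snp is not None and rng.random() < fraction:
            chrom, p = pos_of[snp]
            b = (chrom, max(1, p - anchor_size // 2), p + anchor_size // 2)
            for cl in cell_lines:
                rows.append((*a, *b, cl, target))
    max_pos = int(snp_table["pos"].max()) if len(snp_table) else 1_000_000
    for _ in range(n_background):
        chrom = snp_table["chrom"].iloc[0] if len(snp_table) else "1"
        s1 = int(rng.integers(max_pos + distal_offset, max_pos + 2 * distal_offset))
        s2 = int(rng.integers(max_pos + 2 * distal_offset, max_pos + 3 * distal_offset))
        rows.append((chrom, s1, s1 + anchor_size, chrom, s2, s2 + anchor_size,
                     cell_lines[int(rng.integers(0, len(cell_lines)))], target))
    return LoopAnchorSet(pd.DataFrame(rows, columns=LoopAnchorSet.COLS))


def simulate_molecular_traits(
    cohort: Cohort,
    planted_qtls: list,
    n_traits: int = 20,
    noise_sd: float = 1.0,
    covariate_coefs: dict | None = None,
    window_positions: bool = True,
    seed: int = 0,
):
    """Trait matrices (tumor and paired reference) with planted linear QTLs.

    trait = alpha + beta * dosage + covariate effects + N(0, noise_sd).
    Tumor-specific planted betas are applied to the tumor matrix only.
    Returns (tumor_df, reference_df, trait_table) with traits as columns.
    """
    rng = np.random.default_rng(seed)
    n = cohort.n_patients
    covariate_coefs = covariate_coefs or {}
    trait_ids = [f"trait{t:03d}" for t in range(n_traits)]
    planted = {q.trait_id: q for q in planted_qtls}
    base = {}
    tumor = {}
    ref = {}
    positions = []
    snp_pos = dict(zip(cohort.snp_table["id"], cohort.snp_table["pos"]))
    for t, trait_id in enumerate(trait_ids):
        alpha = rng.normal(0, 1)
        shared = alpha + rng.normal(0, noise_sd, n)
        for cov_name, coef in covariate_coefs.items():
            shared = shared + coef * _standardize(cohort.covariates[cov_name].to_numpy(float))
        tum = shared + rng.normal(0, noise_sd * 0.2, n)
        rf = shared + rng.normal(0, noise_sd * 0.2, n)
        q = planted.get(trait_id)
        chrom = cohort.snp_table["chrom"].iloc[0]
        pos = int(rng.integers(10_000, int(cohort.snp_table["pos"].max()) + 10_000))
        if q is not None:
            g = cohort.dosage_of(q.snp_id)
            g = np.where(np.isnan(g), np.nanmean(g), g)
            tum = tum + q.beta * g
            if not q.tumor_specific:
                rf = rf + q.beta * g
            if window_positions:
                pos = int(snp_pos[q.snp_id])
        tumor[trait_id] = tum
        ref[trait_id] = rf
        positions.append((trait_id, chrom, pos))
    idx = cohort.samples
    trait_table = pd.DataFrame(positions, columns=["trait_id", "chrom", "pos"])
    return (pd.DataFrame(tumor, index=idx), pd.DataFrame(ref, index=idx), trait_table)


def ancestry_frequencies(snp_table: pd.DataFrame, panels: dict,
                         panel_sizes: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Balding-Nichols per-population allele frequencies for each SNP.

    ``panels``: population -> Fst. Returns long table
    (snp, population, vaf, n_individuals).
    """
    rng = np.random.default_rng(seed)
    panel_sizes = panel_sizes or {}
    rows = []
    for pop, fst in panels.items():
        npop = int(panel_sizes.get(pop, 1000))
        for snp_id, p in zip(snp_table["id"], snp_table["maf"]):
            if fst <= 0:
                vaf = float(p)
            else:
                a = p * (1 - fst) / fst
                b = (1 - p) * (1 - fst) / fst
                vaf = float(rng.beta(a, b))
            rows.append((snp_id, pop, vaf, npop))
    return pd.DataFrame(rows, columns=["snp", "population", "vaf", "n_individuals"])


def export_cohort(cohort: Cohort, out_dir, anchors: LoopAnchorSet | None = None,
                  traits: dict | None = None) -> dict:
    """Write VCF / TSV / BED / BEDPE artifacts; returns the path map."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["vcf"] = out / "genotypes.vcf"
    write_vcf(paths["vcf"], cohort.dosage, cohort.snp_table, cohort.samples)
    paths["drivers"] = out / "drivers.tsv"
    write_tsv_matrix(paths["drivers"], cohort.drivers, index_label="patient")
    paths["driver_meta"] = out / "driver_meta.tsv"
    write_tsv_matrix(paths["driver_meta"], cohort.driver_meta, index_label="driver_id")
    paths["covariates"] = out / "covariates.tsv"
    cov = cohort.covariates.copy()
    cov.index = cohort.samples
    write_tsv_matrix(paths["covariates"], cov, index_label="patient")
    paths["driver_regions"] = out / "driver_regions.bed"
    bed_rows = [(r["chrom"], int(r["start"]), int(r["end"]))
                for _, r in cohort.driver_meta.iterrows()]
    write_bed(paths["driver_regions"],
              RegionSet(pd.DataFrame(bed_rows, columns=["chrom", "start", "end"])),
              names=list(cohort.driver_meta.index))
    if anchors is not None:
        paths["anchors"] = out / "loop_anchors.bedpe"
        write_bedpe(paths["anchors"], anchors)
    if traits:
        for name, df in traits.items():
            paths[name] = out / f"{name}.tsv"
            write_tsv_matrix(paths[name], df, index_label="patient")
    return paths
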