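import numpy as np
import pandas as pd
import pytest

from dqtl.io import LoopAnchorSet, RegionSet
from dqtl.simulate import Cohort, SimulationConfig, simulate_cohort, simulate_covariates


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_patients=300, n_snps=60, seed=7, ld_decay=0.1,
        n_drivers=4, driver_freqs=[0.1, 0.2, 0.3, 0.5],
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


def make_cohort(dosage, maf=None, drivers=None, driver_types=None, seed=0,
                chrom="1", spacing=1000):
    """Assemble a Cohort directly from a dosage matrix (test helper)."""
    rng = np.random.default_rng(seed)
    n, m = dosage.shape
    snp_table = pd.DataFrame({
        "id": [f"s{j:04d}" for j in range(m)],
        "chrom": chrom, "pos": np.arange(1, m + 1) * spacing,
        "ref": "A", "alt": "G",
        "maf": (np.nanmean(dosage, axis=0) / 2 if maf is None else maf),
        "block": np.arange(m),
    })
    snp_table["maf"] = np.minimum(snp_table["maf"], 1 - snp_table["maf"])
    samples = [f"p{i:05d}" for i in range(n)]
    cov = simulate_covariates(n, rng)
    drv = pd.DataFrame(drivers if drivers is not None else {}, index=samples)
    types = driver_types or {c: "cna_loss" for c in drv.columns}
    meta = pd.DataFrame(
        [(c, types[c], "trunk", chrom, 1, spacing * m, float(drv[c].mean()) if len(drv.columns) else 0.0)
         for c in drv.columns],
        columns=["driver_id", "type", "timing", "chrom", "start", "end", "target_freq"],
    ).set_index("driver_id")
    return Cohort(dosage=dosage.astype(float), snp_table=snp_table, samples=samples,
                  covariates=cov, drivers=drv, driver_meta=meta)


def region(chrom, start, end, provenance="", driver_id=""):
    return RegionSet(pd.DataFrame([(chrom, start, end)], columns=["chrom", "start", "end"]),
                     provenance, driver_id)


def anchor_set(rows):
    """rows: (chrom_a, sa, ea, chrom_b, sb, eb, cell_line, target), 1-based inclusive."""
    return LoopAnchorSet(pd.DataFrame(rows, columns=LoopAnchorSet.COLS))
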