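"""Readers and writers for VCF / BED / BEDPE / TSV with strict coordinate conventions.

Internal coordinates are 1-based inclusive everywhere (matching VCF POS).
BED and BEDPE files are 0-based half-open on disk; conversion happens only here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionSet",
    "LoopAnchorSet",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "MalformedFileError",
]


class MalformedFileError(ValueError):
    """Raised for unparseable lines; carries the 1-based line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent-overlapping 1-based inclusive intervals."""
    if len(df) == 0:
        return df.reset_index(drop=True)
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    out = []
    cur = None
    for row in df.itertuples(index=False):
        if cur is None or row.chrom != cur[0] or row.start > cur[2] + 1:
            if cur is not None:
                out.append(cur)
            cur = [row.chrom, int(row.start), int(row.end)]
        else:
            cur[2] = max(cur[2], int(row.end))
    out.append(cur)
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


@dataclass
class RegionSet:
    """A set of genomic intervals, 1-based inclusive, merged and sorted.

    ``provenance`` records the discovery strategy ('risk', 'linear', 'spatial',
    'enhancer' or free text); ``driver_id`` ties the set to a somatic driver.
    """

    intervals: pd.DataFrame  # columns: chrom, start, end
    provenance: str = ""
    driver_id: str = ""

    def __post_init__(self):
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end"])
        if len(df):
            bad = df[df["start"] > df["end"]]
            if len(bad):
                raise ValueError(f"start > end in intervals: {bad.values.tolist()}")
            if (df["start"] < 1).any():
                raise ValueError("1-based coordinates must be >= 1")
        self.intervals = _merge_intervals(df)

    def __len__(self):
        return len(self.intervals)

    @property
    def total_span(self) -> int:
        if not len(self.intervals):
            return 0
        return int((self.intervals["end"] - self.intervals["start"] + 1).sum())

    def subtract(self, other: "RegionSet") -> "RegionSet":
        """Set difference (self minus other), preserving provenance labels."""
        if not len(other):
            return RegionSet(self.intervals.copy(), self.provenance, self.driver_id)
        pieces = []
        for row in self.intervals.itertuples(index=False):
            segs = [(int(row.start), int(row.end))]
            cuts = other.intervals[other.intervals["chrom"] == row.chrom]
            for cut in cuts.itertuples(index=False):
                nxt = []
                for s, e in segs:
                    if cut.end < s or cut.start > e:
                        nxt.append((s, e))
                        continue
                    if cut.start > s:
                        nxt.append((s, min(e, cut.start - 1)))
                    if cut.end < e:
                        nxt.append((max(s, cut.end + 1), e))
                segs = nxt
            pieces.extend((row.chrom, s, e) for s, e in segs)
        return RegionSet(
            pd.DataFrame(pieces, columns=["chrom", "start", "end"]),
            self.provenance,
            self.driver_id,
        )

    def contains(self, chrom, pos) -> bool:
        sub = self.intervals[self.intervals["chrom"] == chrom]
        return bool(((sub["start"] <= pos) & (pos <= sub["end"])).any())


@dataclass
class LoopAnchorSet:
    """Paired chromatin-loop anchors (ChIA-PET / HiChIP style), 1-based inclusive.

    ``pairs`` columns: chrom_a, start_a, end_a, chrom_b, start_b, end_b,
    cell_line, target.
    """

    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "cell_line", "target"]

    def __post_init__(self):
        if len(self.pairs) == 0:
            self.pairs = pd.DataFrame(columns=self.COLS)
        self.pairs = pd.DataFrame(self.pairs)[self.COLS].reset_index(drop=True)
        for side in ("a", "b"):
            if len(self.pairs) and (
                self.pairs[f"start_{side}"] > self.pairs[f"end_{side}"]
            ).any():
                raise ValueError("anchor with start > end")

    def __len__(self):
        return len(self.pairs)

    @classmethod
    def concat(cls, sets) -> "LoopAnchorSet":
        frames = [s.pairs for s in sets if len(s)]
        if not frames:
            return cls()
        return cls(pd.concat(frames, ignore_index=True))

    def anchors(self) -> pd.DataFrame:
        """Flatten to single anchors (two rows per pair), keeping labels."""
        a = self.pairs[["chrom_a", "start_a", "end_a", "cell_line", "target"]].rename(
            columns={"chrom_a": "chrom", "start_a": "start", "end_a": "end"}
        )
        b = self.pairs[["chrom_b", "start_b", "end_b", "cell_line", "target"]].rename(
            columns={"chrom_b": "chrom", "start_b": "start", "end_b": "end"}
        )
        return pd.concat([a, b], ignore_index=True)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, allow_multiallelic: bool = False):
    """Read a VCF into (dosage, snp_table, samples).

    dosage is a float (n_patients x n_snps) array with values {0,1,2} and NaN
    for missing genotypes. snp_table columns: id, chrom, pos, ref, alt, maf.
    Multiallelic records are rejected unless ``allow_multiallelic`` (then skipped).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosages = []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            if allow_multiallelic:
                continue
            raise MalformedFileError(path, i + 1, f"multiallelic record at {var.CHROM}:{var.POS}")
        # gts012=True: gt_types is the alt dosage {0,1,2}, 3 = missing
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 3, np.nan, gt)
        dosages.append(dos)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if rows:
        dosage = np.vstack(dosages).T
    else:
        dosage = np.empty((len(samples), 0))
    snp_table = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    snp_table["maf"] = compute_maf(dosage)
    return dosage, snp_table, samples


def compute_maf(dosage: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per SNP column, ignoring missing entries."""
    with np.errstate(invalid="ignore"):
        af = np.nanmean(dosage, axis=0) / 2.0
    return np.minimum(af, 1.0 - af)


def write_vcf(path, dosage, snp_table, samples):
    """Write biallelic GT-only VCFv4.2. Missing dosages become './.'."""
    dosage = np.asarray(dosage, dtype=float)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(snp_table["chrom"])
        for c in chroms:
            sub = snp_table[snp_table["chrom"] == c]
            fh.write(f"##contig=<ID={c},length={int(sub['pos'].max()) + 1_000_000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, row in enumerate(snp_table.itertuples(index=False)):
            col = dosage[:, j]
            gts = ["./." if math.isnan(d) else ("0/0" if d == 0 else ("0/1" if d == 1 else "1/1")) for d in col]
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED / BEDPE


def read_bed(path, provenance: str = "", driver_id: str = "") -> RegionSet:
    """Read BED (0-based half-open) into an internal 1-based inclusive RegionSet."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedFileError(path, lineno, "BED line with < 3 columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError:
                raise MalformedFileError(path, lineno, "non-integer BED coordinates") from None
            if end0 < start0:
                raise MalformedFileError(path, lineno, "BED end < start")
            if end0 == start0:
                raise MalformedFileError(path, lineno, "zero-length BED interval")
            rows.append((parts[0], start0 + 1, end0))
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), provenance, driver_id)


def write_bed(path, region_set: RegionSet, names=None):
    with open(path, "w") as fh:
        for i, row in enumerate(region_set.intervals.itertuples(index=False)):
            name = names[i] if names is not None else f"{region_set.driver_id or 'region'}_{i}"
            fh.write(f"{row.chrom}\t{int(row.start) - 1}\t{int(row.end)}\t{name}\t0\t+\n")


def read_bedpe(path) -> LoopAnchorSet:
    """Read BEDPE with two trailing label columns (cell_line, target)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise MalformedFileError(path, lineno, "BEDPE line with < 8 columns")
            try:
                sa, ea, sb, eb = int(parts[1]), int(parts[2]), int(parts[4]), int(parts[5])
            except ValueError:
                raise MalformedFileError(path, lineno, "non-integer BEDPE coordinates") from None
            if ea <= sa or eb <= sb:
                raise MalformedFileError(path, lineno, "empty or inverted BEDPE anchor")
            rows.append((parts[0], sa + 1, ea, parts[3], sb + 1, eb, parts[6], parts[7]))
    return LoopAnchorSet(pd.DataFrame(rows, columns=LoopAnchorSet.COLS))


def write_bedpe(path, anchor_set: LoopAnchorSet):
    with open(path, "w") as fh:
        for row in anchor_set.pairs.itertuples(index=False):
            fh.write(
                f"{row.chrom_a}\t{int(row.start_a) - 1}\t{int(row.end_a)}\t"
                f"{row.chrom_b}\t{int(row.start_b) - 1}\t{int(row.end_b)}\t"
                f"{row.cell_line}\t{row.target}\n"
            )


# ---------------------------------------------------------------------------
# TSV


def read_tsv_matrix(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv_matrix(path, df: pd.DataFrame, index_label=None):
    df.to_csv(path, sep="\t", index_label=index_label)
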