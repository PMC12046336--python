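"""SNP search-space construction for each somatic driver and loop-anchor enrichment.

Four discovery strategies define a driver's search space:

* ``risk``     - an externally supplied risk-SNP list (no region logic here)
* ``linear``   - a +/- flank window around the driver region
* ``spatial``  - distal partner anchors of ChIA-PET loops touching the driver
                 region, supported by >= 2 cell lines, outside the linear window
* ``enhancer`` - partner anchors of HiChIP loops with exactly one anchor in the
                 driver region

Overlap means >= 1 shared base. All coordinates 1-based inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import LoopAnchorSet, RegionSet, _merge_intervals

__all__ = [
    "linear_window",
    "spatial_regions",
    "enhancer_regions",
    "snps_in_regions",
    "anchor_enrichment",
]


def _as_anchor_frame(anchor_sets) -> pd.DataFrame:
    if isinstance(anchor_sets, LoopAnchorSet):
        return anchor_sets.pairs
    return LoopAnchorSet.concat(list(anchor_sets)).pairs


def _overlaps(chrom, start, end, region: RegionSet) -> np.ndarray:
    """Vectorized >= 1 bp overlap of (chrom,start,end) arrays against a RegionSet."""
    hit = np.zeros(len(chrom), dtype=bool)
    for row in region.intervals.itertuples(index=False):
        hit |= (chrom == row.chrom) & (start <= row.end) & (end >= row.start)
    return hit


def linear_window(driver_region: RegionSet, flank: int = 500_000, chrom_sizes=None) -> RegionSet:
    """The +/- ``flank`` bp window around each driver interval, clipped to bounds."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    rows = []
    for row in driver_region.intervals.itertuples(index=False):
        if chrom_sizes is not None and row.chrom not in chrom_sizes:
            raise KeyError(f"unknown chromosome {row.chrom!r}")
        start = max(1, int(row.start) - flank)
        end = int(row.end) + flank
        if chrom_sizes is not None:
            end = min(end, int(chrom_sizes[row.chrom]))
        rows.append((row.chrom, start, end))
    return RegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end"]),
        provenance="linear",
        driver_id=driver_region.driver_id,
    )


def _partner_records(pairs: pd.DataFrame, driver_region: RegionSet) -> pd.DataFrame:
    """Partner anchors of pairs where the *other* anchor overlaps the driver region."""
    ca = pairs["chrom_a"].to_numpy()
    cb = pairs["chrom_b"].to_numpy()
    hit_a = _overlaps(ca, pairs["start_a"].to_numpy(), pairs["end_a"].to_numpy(), driver_region)
    hit_b = _overlaps(cb, pairs["start_b"].to_numpy(), pairs["end_b"].to_numpy(), driver_region)
    recs = []
    for side_hit, other in ((hit_a, "b"), (hit_b, "a")):
        sub = pairs[side_hit]
        if len(sub):
            recs.append(
                sub[[f"chrom_{other}", f"start_{other}", f"end_{other}", "cell_line", "target"]]
                .set_axis(["chrom", "start", "end", "cell_line", "target"], axis=1)
            )
    if not recs:
        return pd.DataFrame(columns=["chrom", "start", "end", "cell_line", "target"])
    return pd.concat(recs, ignore_index=True)


def _cluster_support(partners: pd.DataFrame, min_cell_lines: int) -> pd.DataFrame:
    """Merge overlapping partner anchors; keep merged clusters with enough distinct
    cell-line support."""
    kept = []
    for chrom, sub in partners.groupby("chrom"):
        sub = sub.sort_values(["start", "end"]).reset_index(drop=True)
        cur_start = cur_end = None
        cur_lines: set = set()
        for row in sub.itertuples(index=False):
            if cur_start is None or row.start > cur_end:
                if cur_start is not None and len(cur_lines) >= min_cell_lines:
                    kept.append((chrom, cur_start, cur_end))
                cur_start, cur_end, cur_lines = int(row.start), int(row.end), {row.cell_line}
            else:
                cur_end = max(cur_end, int(row.end))
                cur_lines.add(row.cell_line)
        if cur_start is not None and len(cur_lines) >= min_cell_lines:
            kept.append((chrom, cur_start, cur_end))
    return pd.DataFrame(kept, columns=["chrom", "start", "end"])


def spatial_regions(
    driver_region: RegionSet,
    anchor_sets,
    min_cell_lines: int = 2,
    exclude: RegionSet | None = None,
) -> RegionSet:
    """Distal loop partners of the driver region with multi-cell-line support.

    For every anchor pair with one anchor overlapping the driver region the
    partner anchor is collected; overlapping partners are merged and a merged
    cluster is retained only if supported by >= ``min_cell_lines`` distinct cell
    lines.  ``exclude`` (normally the linear window) is then subtracted.
    """
    if min_cell_lines < 1:
        raise ValueError("min_cell_lines must be >= 1")
    pairs = _as_anchor_frame(anchor_sets)
    if len(pairs) == 0:
        return RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]),
                         "spatial", driver_region.driver_id)
    partners = _partner_records(pairs, driver_region)
    kept = _cluster_support(partners, min_cell_lines)
    out = RegionSet(kept, "spatial", driver_region.driver_id)
    if exclude is not None:
        out = out.subtract(exclude)
    return out


def enhancer_regions(driver_region: RegionSet, hichip_anchors) -> RegionSet:
    """Partner anchors of pairs with exactly one anchor inside the driver region."""
    pairs = _as_anchor_frame(hichip_anchors)
    if len(pairs) == 0:
        return RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]),
                         "enhancer", driver_region.driver_id)
    hit_a = _overlaps(pairs["chrom_a"].to_numpy(), pairs["start_a"].to_numpy(),
                      pairs["end_a"].to_numpy(), driver_region)
    hit_b = _overlaps(pairs["chrom_b"].to_numpy(), pairs["start_b"].to_numpy(),
                      pairs["end_b"].to_numpy(), driver_region)
    rows = []
    one = hit_a & ~hit_b
    rows.append(pairs.loc[one, ["chrom_b", "start_b", "end_b"]]
                .set_axis(["chrom", "start", "end"], axis=1))
    other = hit_b & ~hit_a
    rows.append(pairs.loc[other, ["chrom_a", "start_a", "end_a"]]
                .set_axis(["chrom", "start", "end"], axis=1))
    out = pd.concat(rows, ignore_index=True)
    return RegionSet(out, "enhancer", driver_region.driver_id)


def snps_in_regions(snp_table: pd.DataFrame, region_set: RegionSet,
                    snp_build: str | None = None, region_build: str | None = None) -> list:
    """SNP ids whose position falls in any interval, ordered by (chrom, pos)."""
    if snp_build is not None and region_build is not None and snp_build != region_build:
        raise ValueError(f"coordinate build mismatch: {snp_build} vs {region_build}")
    chrom = snp_table["chrom"].to_numpy()
    pos = snp_table["pos"].to_numpy()
    hit = _overlaps(chrom, pos, pos, region_set)
    sub = snp_table[hit].sort_values(["chrom", "pos"], kind="mergesort")
    return sub["id"].tolist()


def anchor_enrichment(
    snp_chrom,
    snp_position: int,
    anchor_sets,
    chrom_sizes: dict | None = None,
    window: int = 1_000_000,
    n_permutations: int = 100_000,
    seed: int = 0,
    gap_mask: RegionSet | None = None,
):
    """Permutation enrichment of loop anchors around one SNP.

    For each (cell_line, target) anchor group: observed = number of anchors
    overlapping [pos - window, pos + window]; the null places equally sized
    regions uniformly over the chromosome lengths (excluding ``gap_mask``) and
    counts anchors the same way.  p = (1 + #{null >= observed}) / (1 + n_perm).

    Returns a DataFrame with columns cell_line, target, observed, expected, p.
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be > 0")
    anchors = (anchor_sets.anchors() if isinstance(anchor_sets, LoopAnchorSet)
               else LoopAnchorSet.concat(list(anchor_sets)).anchors())
    if chrom_sizes is None:
        chrom_sizes = {
            c: int(sub["end"].max()) + window
            for c, sub in anchors.groupby("chrom")
        }
        chrom_sizes.setdefault(snp_chrom, snp_position + window)
        chrom_sizes[snp_chrom] = max(chrom_sizes.get(snp_chrom, 0), snp_position + window)
    rng = np.random.default_rng(seed)
    win_lo = max(1, snp_position - window)
    win_hi = min(int(chrom_sizes[snp_chrom]), snp_position + window)
    length = win_hi - win_lo  # region size matched in the null

    chroms = sorted(chrom_sizes)
    usable = np.array([max(0, int(chrom_sizes[c]) - length) for c in chroms], dtype=float)
    if usable.sum() <= 0:
        raise ValueError("window larger than every chromosome")
    probs = usable / usable.sum()
    pick = rng.choice(len(chroms), size=n_permutations, p=probs)
    starts = (rng.random(n_permutations) * usable[pick]).astype(np.int64) + 1
    if gap_mask is not None and len(gap_mask):
        # resample draws that land in the mask (rejection, bounded retries)
        for _ in range(50):
            bad = np.zeros(n_permutations, dtype=bool)
            for i, c in enumerate(chroms):
                sel = pick == i
                if not sel.any():
                    continue
                s = starts[sel]
                hitm = _overlaps(np.repeat(c, sel.sum()), s, s + length, gap_mask)
                idx = np.where(sel)[0][hitm]
                bad[idx] = True
            if not bad.any():
                break
            pick[bad] = rng.choice(len(chroms), size=bad.sum(), p=probs)
            starts[bad] = (rng.random(bad.sum()) * usable[pick[bad]]).astype(np.int64) + 1

    results = []
    for (cell_line, target), grp in anchors.groupby(["cell_line", "target"]):
        observed = 0
        null_counts = np.zeros(n_permutations, dtype=np.int64)
        for i, c in enumerate(chroms):
            sub = grp[grp["chrom"] == c]
            if not len(sub):
                continue
            s_sorted = np.sort(sub["start"].to_numpy())
            e_sorted = np.sort(sub["end"].to_numpy())
            if c == snp_chrom:
                observed += int(np.searchsorted(s_sorted, win_hi, "right")
                                - np.searchsorted(e_sorted, win_lo, "left"))
            sel = pick == i
            if sel.any():
                qs = starts[sel]
                cnt = (np.searchsorted(s_sorted, qs + length, "right")
                       - np.searchsorted(e_sorted, qs, "left"))
                null_counts[sel] = cnt
        p = (1 + int((null_counts >= observed).sum())) / (1 + n_permutations)
        results.append((cell_line, target, observed, float(null_counts.mean()), p))
    return pd.DataFrame(results, columns=["cell_line", "target", "observed", "expected", "p"])
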