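"""Candidate-region calling, intersection and QTL-overlap arithmetic.

All coordinates are 1-based inclusive; the length of [start, end] is
end - start + 1.  Above-threshold SNPs are grouped into maximal runs, runs
closer than a gap tolerance are merged, and sparse runs are discarded.
Intersecting the delta(SNP-index) regions with the ED^4 regions yields the
common candidate set; overlap with an externally mapped QTL interval then
narrows the QTL support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from cottonbsa.stats import Threshold

DEFAULT_MIN_SNPS = 3
DEFAULT_MAX_GAP = 200_000


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive span [start, end] on a named chromosome."""

    chrom: str
    start: int
    end: int
    n_snps: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def interval_length(interval: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval (end - start + 1)."""
    return interval.length


def _sorted_disjoint(regions: list[GenomicInterval]) -> list[GenomicInterval]:
    out = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    for a, b in zip(out, out[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError(f"overlapping intervals {a} and {b}")
    return out


def call_regions(
    track: pd.DataFrame,
    threshold: Threshold,
    statistic: str | None = None,
    min_snps: int = DEFAULT_MIN_SNPS,
    max_gap: int = DEFAULT_MAX_GAP,
    source: str = "",
) -> list[GenomicInterval]:
    """Candidate regions from the SNPs strictly exceeding a threshold.

    ``track`` has chrom, pos and one or more statistic columns (position
    sorted within chromosome).  Above-threshold SNPs separated by more than
    ``max_gap`` bp start a new region; regions supported by fewer than
    ``min_snps`` SNPs are discarded.  Region bounds are the first and last
    contributing SNP positions.
    """
    col = statistic or threshold.statistic
    if col == "abs_delta_snp_index" and col not in track.columns:
        values = np.abs(track["delta_snp_index"].to_numpy(dtype=float))
    else:
        values = track[col].to_numpy(dtype=float)
    cutoff = threshold.cutoff
    regions: list[GenomicInterval] = []
    mask = np.isfinite(values) & (values > cutoff)
    for chrom in track["chrom"].unique():
        sel = (track["chrom"] == chrom).to_numpy() & mask
        pos = track.loc[sel, "pos"].to_numpy(dtype=np.int64)
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [pos.size - 1]])
        for s, e in zip(starts, ends):
            n = e - s + 1
            if n >= min_snps:
                regions.append(
                    GenomicInterval(chrom, int(pos[s]), int(pos[e]), n, source or col)
                )
    return _sorted_disjoint(regions)


def intersect_region_sets(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Pairwise intersection of two sorted, disjoint region sets.

    Returns the maximal intervals covered by some interval of ``a`` and some
    interval of ``b`` on the same chromosome.
    """
    a = _sorted_disjoint(list(a))
    b = _sorted_disjoint(list(b))
    out: list[GenomicInterval] = []
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for r in b:
        by_chrom_b.setdefault(r.chrom, []).append(r)
    for ra in a:
        for rb in by_chrom_b.get(ra.chrom, ()):
            start = max(ra.start, rb.start)
            end = min(ra.end, rb.end)
            if start <= end:
                out.append(GenomicInterval(ra.chrom, start, end, 0, "common"))
    return _sorted_disjoint(out)


def overlap_with_qtl(
    regions: list[GenomicInterval], qtl: GenomicInterval
) -> pd.DataFrame:
    """Per-region overlap with one QTL interval, plus total region length.

    Returns one row per input region with the intersected span and its
    length (0 and missing bounds when there is no overlap).  The summary
    total over all reported regions is exposed via the ``region_length``
    column sum.
    """
    rows = []
    if regions and all(r.chrom != qtl.chrom for r in regions):
        warnings.warn(
            f"no region shares chromosome {qtl.chrom!r} with the QTL", stacklevel=2
        )
    for r in regions:
        if r.chrom == qtl.chrom and r.start <= qtl.end and qtl.start <= r.end:
            o_start = max(r.start, qtl.start)
            o_end = min(r.end, qtl.end)
            o_len = o_end - o_start + 1
        else:
            o_start = o_end = pd.NA
            o_len = 0
        rows.append(
            {
                "chrom": r.chrom,
                "region_start": r.start,
                "region_end": r.end,
                "region_length": r.length,
                "overlap_start": o_start,
                "overlap_end": o_end,
                "overlap_length": o_len,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "region_start",
            "region_end",
            "region_length",
            "overlap_start",
            "overlap_end",
            "overlap_length",
        ],
    )


def regions_to_frame(regions: list[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "length": r.length,
                "n_snps": r.n_snps,
                "source": r.source,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "length", "n_snps", "source"],
    )


def regions_to_bed(regions: list[GenomicInterval]) -> pd.DataFrame:
    """0-based half-open BED view of a 1-based inclusive region set."""
    return pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start - 1, "end": r.end} for r in regions],
        columns=["chrom", "start", "end"],
    )


def bed_to_regions(bed: pd.DataFrame, source: str = "") -> list[GenomicInterval]:
    return [
        GenomicInterval(str(row.chrom), int(row.start) + 1, int(row.end), 0, source)
        for row in bed.itertuples(index=False)
    ]


def count_snps_in_regions(
    track: pd.DataFrame, regions: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Annotate regions with the number of track SNPs they contain."""
    out = []
    for r in regions:
        sel = (
            (track["chrom"] == r.chrom)
            & (track["pos"] >= r.start)
            & (track["pos"] <= r.end)
        )
        out.append(replace(r, n_snps=int(sel.sum())))
    return out
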