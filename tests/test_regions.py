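"""Region calling, interval intersection, QTL overlap, and BED conversion."""

import numpy as np
import pandas as pd
import pytest

from cottonbsa.regions import (
    GenomicInterval,
    bed_to_regions,
    call_regions,
    count_snps_in_regions,
    intersect_region_sets,
    interval_length,
    overlap_with_qtl,
    regions_to_bed,
    regions_to_frame,
)
from cottonbsa.stats import Threshold


def make_track(positions, values, chrom="c1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions, "stat": values})


THRESH = Threshold("stat", 0.5, 0.0)  # cutoff 0.5; SNPs above need value > 0.5


def test_all_above_gives_single_spanning_region():
    track = make_track([100, 200, 300, 400], [1, 1, 1, 1])
    regions = call_regions(track, THRESH, min_snps=1, max_gap=1000)
    assert regions == [GenomicInterval("c1", 100, 400, 4, "stat")]


def test_none_above_gives_empty_set():
    track = make_track([100, 200], [0.1, 0.2])
    assert call_regions(track, THRESH) == []
    assert call_regions(track.iloc[0:0], THRESH) == []


def test_gap_splits_regions():
    positions = list(range(100_000, 201_000, 10_000)) + list(
        range(800_000, 901_000, 10_000)
    )
    track = make_track(positions, [1.0] * len(positions))
    regions = call_regions(track, THRESH, min_snps=1, max_gap=100_000)
    assert [(r.start, r.end) for r in regions] == [
        (100_000, 200_000),
        (800_000, 900_000),
    ]


def test_min_snps_discards_sparse_runs():
    track = make_track([100, 200, 50_000], [1.0, 1.0, 1.0])
    regions = call_regions(track, THRESH, min_snps=3, max_gap=1000)
    assert regions == []


def test_threshold_exceedance_is_strict():
    track = make_track([1, 2, 3], [0.5, 0.5, 0.5])
    assert call_regions(track, THRESH, min_snps=1) == []


def naive_call_oracle(positions, values, cutoff, min_snps, max_gap):
    """Per-SNP scan: group above-threshold SNPs whenever the gap to the
    previous above-threshold SNP is <= max_gap."""
    above = [(p, v) for p, v in zip(positions, values) if v > cutoff]
    groups = []
    for p, _ in above:
        if groups and p - groups[-1][-1] <= max_gap:
            groups[-1].append(p)
        else:
            groups.append([p])
    return [(g[0], g[-1], len(g)) for g in groups if len(g) >= min_snps]


def test_call_regions_matches_naive_oracle_on_random_instances(rng):
    for _ in range(100):
        n = rng.integers(1, 120)
        positions = np.sort(rng.choice(np.arange(1, 100_000), size=n, replace=False))
        values = rng.random(n)
        min_snps = int(rng.integers(1, 4))
        max_gap = int(rng.integers(100, 20_000))
        got = call_regions(
            make_track(positions, values),
            Threshold("stat", 0.6, 0.0),
            min_snps=min_snps,
            max_gap=max_gap,
        )
        expected = naive_call_oracle(positions, values, 0.6, min_snps, max_gap)
        assert [(r.start, r.end, r.n_snps) for r in got] == expected


def test_call_regions_never_bridges_more_than_max_gap(rng):
    positions = np.sort(rng.choice(np.arange(1, 50_000), size=80, replace=False))
    values = rng.random(80)
    regions = call_regions(
        make_track(positions, values), Threshold("stat", 0.5, 0.0), min_snps=1,
        max_gap=2000,
    )
    above = positions[values > 0.5]
    for r in regions:
        inside = above[(above >= r.start) & (above <= r.end)]
        assert np.all(np.diff(inside) <= 2000)


def intervals_to_base_set(intervals):
    out = set()
    for iv in intervals:
        out |= set(range(iv.start, iv.end + 1))
    return out


def test_intersection_identity_disjoint_and_partial():
    a = [GenomicInterval("c1", 100, 500)]
    b = [GenomicInterval("c1", 300, 900)]
    out = intersect_region_sets(a, b)
    assert [(r.start, r.end) for r in out] == [(300, 500)]
    assert interval_length(out[0]) == 201
    assert intersect_region_sets(a, a) == [
        GenomicInterval("c1", 100, 500, 0, "common")
    ]
    assert intersect_region_sets(a, [GenomicInterval("c1", 600, 700)]) == []
    assert intersect_region_sets(a, [GenomicInterval("c2", 100, 500)]) == []


def test_intersection_matches_per_base_oracle_on_random_instances(rng):
    for _ in range(100):
        def random_set():
            k = rng.integers(1, 6)
            cuts = np.sort(rng.choice(np.arange(1, 2000), size=2 * k, replace=False))
            return [
                GenomicInterval("c1", int(cuts[2 * i]), int(cuts[2 * i + 1]))
                for i in range(k)
            ]

        a, b = random_set(), random_set()
        got = intersect_region_sets(a, b)
        expected = intervals_to_base_set(a) & intervals_to_base_set(b)
        assert intervals_to_base_set(got) == expected
        # commutativity and idempotence
        assert intersect_region_sets(b, a) == got
        assert intersect_region_sets(got, got) == got
        total = sum(r.length for r in got)
        assert total <= min(sum(r.length for r in a), sum(r.length for r in b))


def test_interval_length_convention():
    assert interval_length(GenomicInterval("D3", 17_130_008, 41_839_226)) == 24_709_219
    assert interval_length(GenomicInterval("c1", 5, 5)) == 1
    assert interval_length(GenomicInterval("D3", 41_836_768, 41_872_287)) == 35_520
    with pytest.raises(ValueError):
        GenomicInterval("c1", 10, 5)


def test_overlap_with_qtl_full_partial_and_mismatch():
    qtl = GenomicInterval("D3", 17_130_008, 41_839_226, source="QTL")
    regions = [
        GenomicInterval("D3", 41_779_195, 41_836_120),
        GenomicInterval("D3", 41_836_768, 41_872_287),
    ]
    report = overlap_with_qtl(regions, qtl)
    assert report["overlap_length"].tolist() == [56_926, 2_459]
    assert report["region_length"].sum() == 92_446

    with pytest.warns(UserWarning):
        empty = overlap_with_qtl([GenomicInterval("A1", 1, 10)], qtl)
    assert empty["overlap_length"].tolist() == [0]


def test_bed_round_trip():
    regions = [GenomicInterval("c1", 100, 500), GenomicInterval("c2", 1, 1)]
    bed = regions_to_bed(regions)
    assert bed["start"].tolist() == [99, 0]
    assert bed["end"].tolist() == [500, 1]
    back = bed_to_regions(bed)
    assert [(r.chrom, r.start, r.end) for r in back] == [
        (r.chrom, r.start, r.end) for r in regions
    ]
    for orig, conv in zip(regions, back):
        assert conv.length == orig.length


def test_count_snps_and_frame_export():
    track = make_track([100, 200, 300, 900], [1, 1, 1, 1])
    regions = [GenomicInterval("c1", 150, 350)]
    annotated = count_snps_in_regions(track, regions)
    assert annotated[0].n_snps == 2
    frame = regions_to_frame(annotated)
    assert frame.loc[0, "length"] == 201
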