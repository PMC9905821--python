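"""Arithmetic cross-checks against the published genetic-map summary.

The study's published per-chromosome map summary (marker counts, map
lengths, average intervals, collinearity coefficients) and the printed D3
coordinates of the stable NFFB QTL and the two common BSA regions are
bundled as package data.  This module recomputes the derived quantities —
subgenome subtotals, average marker intervals, interval lengths, QTL
overlaps — from the printed per-row values and compares them with the
printed totals.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from cottonbsa.regions import GenomicInterval, interval_length, overlap_with_qtl


def load_map_summary() -> pd.DataFrame:
    with resources.files("cottonbsa.data").joinpath("map_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_qtl_coordinates() -> dict:
    with resources.files("cottonbsa.data").joinpath("qtl_coordinates.json").open() as fh:
        return json.load(fh)


def d3_intervals() -> tuple[GenomicInterval, list[GenomicInterval]]:
    """The published QTL interval and the two common BSA regions on D3."""
    coords = load_qtl_coordinates()
    q = coords["qtl"]
    qtl = GenomicInterval(q["chrom"], q["start"], q["end"], source="QTL")
    regions = [
        GenomicInterval(r["chrom"], r["start"], r["end"], source="common")
        for r in coords["bsa_regions"]
    ]
    return qtl, regions


def published_arithmetic_report() -> pd.DataFrame:
    """Recompute the derived map/interval arithmetic and compare to print.

    Each row gives the check name, the recomputed value, the published
    value, and whether they agree to the published precision.
    """
    summary = load_map_summary()
    coords = load_qtl_coordinates()
    printed = coords["printed"]
    qtl, regions = d3_intervals()

    at = summary[summary["chrom"].str.startswith("A")]
    dt = summary[summary["chrom"].str.startswith("D")]
    d3 = summary[summary["chrom"] == "D3"].iloc[0]

    overlap = overlap_with_qtl(regions, qtl)
    # a sum of n values printed to 2 decimals can differ from the printed
    # total by up to n * 0.005
    checks = [
        ("at_n_markers", int(at["n_markers"].sum()), printed["at_n_markers"], 0),
        (
            "at_length_cM",
            float(at["length_cM"].sum()),
            printed["at_length_cM"],
            0.005 * len(at),
        ),
        ("dt_n_markers", int(dt["n_markers"].sum()), printed["dt_n_markers"], 0),
        (
            "dt_length_cM",
            float(dt["length_cM"].sum()),
            printed["dt_length_cM"],
            0.005 * len(dt),
        ),
        (
            "total_n_markers",
            int(summary["n_markers"].sum()),
            printed["total_n_markers"],
            0,
        ),
        (
            "total_length_cM",
            float(summary["length_cM"].sum()),
            printed["total_length_cM"],
            0.005 * len(summary),
        ),
        (
            "d3_avg_interval_cM",
            float(d3["length_cM"] / (d3["n_markers"] - 1)),
            printed["d3_avg_interval_cM"],
            0.005,
        ),
        (
            "qtl_length_Mb",
            interval_length(qtl) / 1e6,
            printed["qtl_length_Mb"],
            0.05,
        ),
        (
            "common_regions_total_Kb",
            sum(interval_length(r) for r in regions) / 1e3,
            printed["common_regions_total_Kb"],
            0.05,
        ),
        (
            "regions_inside_qtl_overlap_bp",
            int(overlap["overlap_length"].sum()),
            # first region fully inside; second truncated at the QTL end
            (41_836_120 - 41_779_195 + 1) + (41_839_226 - 41_836_768 + 1),
            0,
        ),
    ]
    rows = [
        {
            "check": name,
            "computed": computed,
            "published": expected,
            "pass": abs(computed - expected) <= tol,
        }
        for name, computed, expected, tol in checks
    ]
    return pd.DataFrame(rows, columns=["check", "computed", "published", "pass"])
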