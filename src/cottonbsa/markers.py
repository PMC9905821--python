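"""Marker segregation-pattern classification, filtering, and map collinearity.

Polymorphic markers scored on two parents are classified into the eight
two-way pseudo-testcross segregation patterns of the CP convention
(aa x bb, ab x cc, ab x cd, cc x ab, ef x eg, hk x hk, lm x ll, nn x np);
only aa x bb markers (both parents homozygous for different alleles) are
informative for an F2 map.  Those markers are then filtered on segregation
distortion (chi-square against 1:2:1, p < 0.001), call integrity (< 40% of
plants genotyped), co-location on one sequencing fragment, and calls whose
alleles occur in neither parent ("abnormal bases").  Map quality is
summarised by the Spearman rank correlation between genetic map order and
physical position (collinearity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

PATTERNS = (
    "aaxbb",
    "abxcc",
    "abxcd",
    "ccxab",
    "efxeg",
    "hkxhk",
    "lmxll",
    "nnxnp",
    "uninformative",
)

DISTORTION_ALPHA = 0.001
INTEGRITY_MIN_FRACTION = 0.40
FRAGMENT_LENGTH = 150
ABNORMAL_MAX_FRACTION = 0.05

Call = tuple[str, str] | None  # unordered allele pair, None = missing


def parse_call(text: str) -> Call:
    """Parse "A/T"-style genotype text; "./." or "" is missing."""
    if not text or text in (".", "./.", ".|."):
        return None
    sep = "/" if "/" in text else "|"
    a, b = text.split(sep)
    if a == "." or b == ".":
        return None
    return (a, b)


def classify_pattern(p1: Call, p2: Call) -> str:
    """CP segregation pattern for one marker from the two parental calls.

    Exactly one of the eight informative patterns (or "uninformative") is
    returned for any pair of calls; a missing parental call is
    uninformative.
    """
    if p1 is None or p2 is None:
        return "uninformative"
    s1, s2 = set(p1), set(p2)
    het1, het2 = len(s1) == 2, len(s2) == 2
    if not het1 and not het2:
        return "aaxbb" if s1 != s2 else "uninformative"
    if het1 and not het2:
        return "lmxll" if s2 <= s1 else "abxcc"
    if not het1 and het2:
        return "nnxnp" if s1 <= s2 else "ccxab"
    shared = len(s1 & s2)
    if shared == 2:
        return "hkxhk"
    if shared == 1:
        return "efxeg"
    return "abxcd"


def test_segregation_distortion(
    counts: tuple[int, int, int], population_type: str = "F2"
) -> float:
    """Chi-square goodness-of-fit p-value for (AA, Aa, BB) progeny counts.

    The expectation is Mendelian 1:2:1 (F2, or a BC1F2 selfed from
    heterozygous BC1 plants); missing calls are excluded upstream.  Returns
    NaN for zero informative progeny (such markers fall to the integrity
    filter instead).
    """
    if population_type not in ("F2", "BC1F2"):
        raise ValueError(f"unknown population_type {population_type!r}")
    obs = np.asarray(counts, dtype=float)
    n = obs.sum()
    if n == 0:
        return float("nan")
    expected = n * np.array([0.25, 0.5, 0.25])
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return float(sps.chi2.sf(chi2, df=2))


def filter_integrity(n_called: int, n_plants: int) -> bool:
    """True (keep) iff at least 40% of plants have a genotype call."""
    return n_called / n_plants >= INTEGRITY_MIN_FRACTION


def flag_abnormal_calls(
    calls: list[Call], parental_alleles: set[str]
) -> tuple[list[Call], int]:
    """Set calls carrying an allele absent from both parents to missing.

    Returns the cleaned calls and the number of abnormal calls found.
    """
    cleaned: list[Call] = []
    n_abnormal = 0
    for c in calls:
        if c is not None and not set(c) <= parental_alleles:
            cleaned.append(None)
            n_abnormal += 1
        else:
            cleaned.append(c)
    return cleaned, n_abnormal


def dedupe_same_fragment(
    positions: np.ndarray, fragment_length: int = FRAGMENT_LENGTH
) -> np.ndarray:
    """Indices of surviving markers after same-fragment deduplication.

    Markers are chained when adjacent distances are <= fragment_length
    (SNPs on one sequencing read are not independent); the first marker of
    each chain is kept.  Positions must be sorted ascending.
    """
    positions = np.asarray(positions)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    if positions.size == 0:
        return np.array([], dtype=int)
    new_chain = np.concatenate([[True], np.diff(positions) > fragment_length])
    return np.flatnonzero(new_chain)


def collinearity(genetic_ranks, physical_positions) -> float:
    """Spearman rank correlation between map order and physical position.

    Returns NaN for fewer than 2 markers.
    """
    g = np.asarray(genetic_ranks, dtype=float)
    p = np.asarray(physical_positions, dtype=float)
    if g.size < 2:
        return float("nan")
    return float(sps.spearmanr(g, p).statistic)


@dataclass
class MarkerFilterReport:
    """Removal counts of each marker filter and the surviving marker ids."""

    n_input: int = 0
    removed_distortion: int = 0
    removed_integrity: int = 0
    removed_abnormal: int = 0
    removed_same_fragment: int = 0
    surviving: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"filter": "input", "count": self.n_input},
                {"filter": "segregation_distortion", "count": self.removed_distortion},
                {"filter": "integrity", "count": self.removed_integrity},
                {"filter": "abnormal_bases", "count": self.removed_abnormal},
                {"filter": "same_fragment", "count": self.removed_same_fragment},
                {"filter": "surviving", "count": len(self.surviving)},
            ]
        )


def filter_aaxbb_markers(
    markers: pd.DataFrame,
    progeny_calls: list[list[Call]],
    p1_calls: list[Call],
    p2_calls: list[Call],
    n_plants: int,
    population_type: str = "F2",
    alpha: float = DISTORTION_ALPHA,
    fragment_length: int = FRAGMENT_LENGTH,
    abnormal_max_fraction: float = ABNORMAL_MAX_FRACTION,
) -> MarkerFilterReport:
    """Apply the mapping-marker filters to position-sorted aa x bb markers.

    ``markers`` has columns (id, chrom, pos); ``progeny_calls[j]`` are the
    calls of all plants at marker j.  Per-marker predicates (distortion,
    integrity, abnormal-call excess) run first; same-fragment deduplication
    runs last on the survivors since it is order-sensitive.
    """
    report = MarkerFilterReport(n_input=len(markers))
    keep_mask = np.ones(len(markers), dtype=bool)
    for j in range(len(markers)):
        p1, p2 = p1_calls[j], p2_calls[j]
        parental = set(p1) | set(p2)
        calls, n_abn = flag_abnormal_calls(progeny_calls[j], parental)
        n_called = sum(c is not None for c in calls)
        if n_abn / n_plants > abnormal_max_fraction:
            report.removed_abnormal += 1
            keep_mask[j] = False
            continue
        if not filter_integrity(n_called, n_plants):
            report.removed_integrity += 1
            keep_mask[j] = False
            continue
        a1 = p1[0]
        n_aa = sum(c is not None and c == (a1, a1) for c in calls)
        n_het = sum(c is not None and len(set(c)) == 2 for c in calls)
        n_bb = n_called - n_aa - n_het
        p = test_segregation_distortion((n_aa, n_het, n_bb), population_type)
        if np.isfinite(p) and p < alpha:
            report.removed_distortion += 1
            keep_mask[j] = False
    survivors = markers[keep_mask].reset_index(drop=True)
    kept_ids: list = []
    for chrom, sub in survivors.groupby("chrom", sort=False):
        idx = dedupe_same_fragment(sub["pos"].to_numpy(), fragment_length)
        kept_ids.extend(sub["id"].to_numpy()[idx].tolist())
        report.removed_same_fragment += len(sub) - idx.size
    report.surviving = kept_ids
    return report
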