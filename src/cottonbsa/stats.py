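"""Per-SNP bulk-segregant statistics and the median+3SD scan threshold.

For a SNP with maternal-allele depth M and paternal-allele depth P in a
pool, SNP-index = M / (M + P).  The between-pool contrast is
delta = SNP-index(low) - SNP-index(high).  The Euclidean distance between
the two pools' four-base frequency vectors,

    ED = sqrt((Ah-Al)^2 + (Ch-Cl)^2 + (Gh-Gl)^2 + (Th-Tl)^2),

is raised to the fourth power (ED^4) to suppress background noise.  The
genome-wide threshold for a statistic track is median + 3 * sample SD; for
the delta track the thresholded statistic is |delta| so that enrichment in
either bulk is detected.

When both pools are purely biallelic for the same two alleles,
ED = sqrt(2) * |delta| exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: minimum combined parental-allele depth for a pool's SNP-index to be defined
DEFAULT_MIN_DEPTH = 4

BASE_ORDER = ("A", "C", "G", "T")


def snp_index(M, P, min_depth: int = DEFAULT_MIN_DEPTH):
    """SNP-index M/(M+P); NaN where M+P < min_depth.

    Accepts scalars or arrays.  Negative depths raise.
    """
    M = np.asarray(M, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(M < 0) or np.any(P < 0):
        raise ValueError("allele depths must be non-negative")
    total = M + P
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(total >= min_depth, M / np.where(total == 0, np.nan, total), np.nan)
    return idx if idx.ndim else float(idx)


def delta_snp_index(idx_low, idx_high):
    """delta(SNP-index) = SNP-index(low) - SNP-index(high); NaN propagates."""
    out = np.asarray(idx_low, dtype=float) - np.asarray(idx_high, dtype=float)
    return out if out.ndim else float(out)


def euclidean_distance(high_freqs, low_freqs):
    """4-base Euclidean distance between pool frequency vectors.

    Inputs are length-4 vectors (or (n, 4) arrays) of A,C,G,T frequencies,
    each summing to 1.  ED lies in [0, sqrt(2)].
    """
    h = np.asarray(high_freqs, dtype=float)
    l = np.asarray(low_freqs, dtype=float)
    d = np.sqrt(np.sum((h - l) ** 2, axis=-1))
    return d if d.ndim else float(d)


def ed_power(ed, power: int = 4):
    """ED raised to the given power (default: ED^4)."""
    out = np.asarray(ed, dtype=float) ** power
    return out if out.ndim else float(out)


def base_frequencies(counts: pd.DataFrame, pool: str) -> np.ndarray:
    """(n, 4) A,C,G,T frequencies for one pool; NaN rows at zero depth."""
    depths = counts[[f"{pool}_{b}" for b in BASE_ORDER]].to_numpy(dtype=float)
    total = depths.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return depths / np.where(total == 0, np.nan, total)


def compute_tracks(
    counts: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH
) -> pd.DataFrame:
    """All per-SNP statistics for a pool-allele-counts table.

    Returns chrom, pos plus snp_index_high, snp_index_low, delta_snp_index,
    ED and ED4 columns; SNPs failing the per-pool depth requirement carry
    NaN for the affected statistics.
    """
    high = snp_index(counts["high_M"], counts["high_P"], min_depth)
    low = snp_index(counts["low_M"], counts["low_P"], min_depth)
    delta = delta_snp_index(low, high)

    fh = base_frequencies(counts, "high")
    fl = base_frequencies(counts, "low")
    depth_ok = (
        counts[[f"high_{b}" for b in BASE_ORDER]].sum(axis=1).to_numpy() >= min_depth
    ) & (counts[[f"low_{b}" for b in BASE_ORDER]].sum(axis=1).to_numpy() >= min_depth)
    ed = np.where(depth_ok, euclidean_distance(fh, fl), np.nan)

    return pd.DataFrame(
        {
            "chrom": counts["chrom"],
            "pos": counts["pos"],
            "snp_index_high": high,
            "snp_index_low": low,
            "delta_snp_index": delta,
            "ED": ed,
            "ED4": ed_power(ed),
        }
    )


@dataclass(frozen=True)
class Threshold:
    """A genome-scan cutoff: median + 3 * SD of a statistic track."""

    statistic: str
    median: float
    sd: float

    @property
    def cutoff(self) -> float:
        return self.median + 3.0 * self.sd


def median_3sd_threshold(
    values, statistic: str = "stat", ddof: int = 1
) -> Threshold:
    """median + 3*SD over the non-missing values of a track.

    SD is the sample standard deviation (ddof=1) by default; set ddof=0 for
    the population form.  Raises on a track with fewer than 2 finite values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("threshold needs at least 2 non-missing values")
    return Threshold(statistic, float(np.median(v)), float(np.std(v, ddof=ddof)))


def track_thresholds(tracks: pd.DataFrame) -> dict[str, Threshold]:
    """Genome-wide thresholds for the |delta| and ED^4 tracks."""
    return {
        "abs_delta_snp_index": median_3sd_threshold(
            np.abs(tracks["delta_snp_index"]), "abs_delta_snp_index"
        ),
        "ED4": median_3sd_threshold(tracks["ED4"], "ED4"),
    }


def smooth_track(values: np.ndarray, window_snps: int) -> np.ndarray:
    """Optional centered moving-average smoother (window in SNPs, NaN-aware)."""
    s = pd.Series(values)
    return (
        s.rolling(window_snps, center=True, min_periods=1).mean().to_numpy()
    )
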