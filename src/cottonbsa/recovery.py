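"""End-to-end parameter-recovery experiments on simulated crosses.

One replicate runs the whole analysis in memory: simulate a BC1F2
population at the reference settings, select the phenotypic-tail bulks,
draw pooled read counts, compute the |delta(SNP-index)| and ED^4 tracks and
their median+3SD thresholds, call regions for each scan and intersect them.
The replicate "recovers" the locus when the common candidate region set
contains the causal marker position.  Null replicates (no causal locus)
measure how often drift alone produces a common region covering a large
genome fraction.
"""

from __future__ import annotations


import numpy as np

from cottonbsa import regions as rg
from cottonbsa import stats
from cottonbsa.config import SimulationConfig
from cottonbsa.simulate import select_bulks, simulate_pool_counts, simulate_population


def run_replicate(
    seed: int,
    config: SimulationConfig | None = None,
    min_snps: int = rg.DEFAULT_MIN_SNPS,
    max_gap: int = rg.DEFAULT_MAX_GAP,
) -> dict:
    """One full simulate-to-common-regions run.

    Returns the recovery indicator, the common region list, and the largest
    common region's fraction of the simulated genome.
    """
    base = config if config is not None else SimulationConfig()
    cfg_dict = base.to_dict()
    cfg_dict["seed"] = seed
    cfg = SimulationConfig(**cfg_dict)

    pop = simulate_population(cfg)
    bulks = select_bulks(pop, cfg.bulk_size)
    counts = simulate_pool_counts(pop, bulks, cfg)
    tracks = stats.compute_tracks(counts)
    thresholds = stats.track_thresholds(tracks)
    delta_regions = rg.call_regions(
        tracks, thresholds["abs_delta_snp_index"], min_snps=min_snps, max_gap=max_gap
    )
    ed_regions = rg.call_regions(
        tracks, thresholds["ED4"], min_snps=min_snps, max_gap=max_gap
    )
    common = rg.intersect_region_sets(delta_regions, ed_regions)

    # recovery targets the strongest (major) locus
    if pop.causal_markers:
        major = max(
            range(len(cfg.causal_loci)), key=lambda i: abs(cfg.causal_loci[i].additive)
        )
        chrom, pos = pop.causal_markers[major]
        contains = any(
            r.chrom == chrom and r.start <= pos <= r.end for r in common
        )
    else:
        contains = False

    genome_bp = cfg.n_chromosomes * cfg.chrom_length_bp
    max_frac = max((r.length / genome_bp for r in common), default=0.0)
    return {
        "seed": seed,
        "contains_causal": bool(contains),
        "n_common_regions": len(common),
        "max_common_fraction": float(max_frac),
        "common": common,
    }


def recovery_experiment(
    n_replicates: int = 50,
    base_seed: int = 0,
    config: SimulationConfig | None = None,
) -> dict:
    """Recovery rate over seeded replicates with the causal locus present."""
    results = [
        run_replicate(_child_seed(base_seed, i), config) for i in range(n_replicates)
    ]
    rate = float(np.mean([r["contains_causal"] for r in results]))
    return {"recovery_rate": rate, "n_replicates": n_replicates, "replicates": results}


def null_experiment(
    n_replicates: int = 50,
    base_seed: int = 0,
    config: SimulationConfig | None = None,
    genome_fraction_limit: float = 0.10,
) -> dict:
    """False-positive behaviour without any causal locus.

    Reports the fraction of replicates in which some common region covers
    more than ``genome_fraction_limit`` of the genome.
    """
    base = config if config is not None else SimulationConfig()
    null_cfg = SimulationConfig(**{**base.to_dict(), "causal_loci": ()})
    results = [
        run_replicate(_child_seed(base_seed, i), null_cfg)
        for i in range(n_replicates)
    ]
    frac_large = float(
        np.mean([r["max_common_fraction"] > genome_fraction_limit for r in results])
    )
    return {
        "large_region_rate": frac_large,
        "n_replicates": n_replicates,
        "replicates": results,
    }


def _child_seed(base_seed: int, i: int) -> int:
    # distinct, reproducible, and < 2**31
    return (base_seed * 100_003 + i * 7919 + 1) % (2**31)
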