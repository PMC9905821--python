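"""Seeded simulator of bi-parental cross populations and pooled read counts.

The simulator emulates the design the downstream bulk-segregant statistics
assume: two inbred parents (the maternal allele is labelled M throughout,
mirroring the JF914-type allele; the paternal allele P mirrors JF173),
an F2 or BC1F2 mapping population, a quantitative trait built from a small
number of causal loci plus Gaussian noise, tail bulks chosen on phenotype,
and per-SNP pooled sequencing depths with a Poisson depth model and an
optional per-read base-error rate.

Meiosis uses the Haldane map function (no crossover interference):
the recombination fraction between adjacent markers d centimorgans apart is
r = (1 - exp(-2d/100)) / 2.  BC1 founders are modelled as heterozygous at
every marker that differs between the parents (optionally fixed within
configured regions), so a BC1F2 plant — like an F2 plant — is the selfed
offspring of a genome-wide heterozygote and segregates 1:2:1 in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cottonbsa.config import SimulationConfig
from cottonbsa import vcfio

BASES = np.array(["A", "C", "G", "T"])

GENOTYPE_CODES = np.array(["aa", "Aa", "AA"])  # indexed by maternal-allele dosage


@dataclass
class SimulatedPopulation:
    """A simulated mapping population.

    ``dosage`` holds, per plant and marker, the count (0/1/2) of the
    maternal (M-type) allele; ``markers`` carries chromosome, physical
    position, genetic position and the two parental allele bases.
    """

    config: SimulationConfig
    markers: pd.DataFrame  # columns: chrom, pos, cM, ref, alt
    dosage: np.ndarray  # (n_plants, n_markers) uint8
    phenotypes: np.ndarray  # (n_plants,) float
    pedigree_label: str
    #: (chrom, marker position) where each causal effect was applied —
    #: causal loci are snapped to the nearest simulated marker
    causal_markers: tuple = ()

    @property
    def n_plants(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def genotype_codes(self) -> np.ndarray:
        """Genotype matrix coded as strings aa / Aa / AA (A = maternal)."""
        return GENOTYPE_CODES[self.dosage]

    def truth_table(self) -> pd.DataFrame:
        """Causal loci with both the configured and the genotyped (nearest
        marker) positions."""
        rows = []
        for i, c in enumerate(self.config.causal_loci):
            marker_pos = self.causal_markers[i][1] if self.causal_markers else c.pos
            rows.append(
                {
                    "chrom": c.chrom,
                    "pos": c.pos,
                    "marker_pos": marker_pos,
                    "additive": c.additive,
                    "dominance": c.dominance,
                }
            )
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "marker_pos", "additive", "dominance"]
        )


@dataclass(frozen=True)
class BulkAssignment:
    """Plant indices of the two phenotypic-tail bulks (disjoint by construction)."""

    high_ids: np.ndarray
    low_ids: np.ndarray

    def __post_init__(self) -> None:
        if set(self.high_ids.tolist()) & set(self.low_ids.tolist()):
            raise ValueError("bulks overlap")


def _marker_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for chrom in config.chrom_names():
        pos = np.unique(
            np.round(np.linspace(1, config.chrom_length_bp, config.n_markers_per_chrom))
        ).astype(np.int64)
        cm = (pos - 1) / max(config.chrom_length_bp - 1, 1) * config.chrom_length_cM
        ref_idx = rng.integers(0, 4, size=pos.size)
        alt_idx = (ref_idx + rng.integers(1, 4, size=pos.size)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "cM": cm,
                    "ref": BASES[ref_idx],
                    "alt": BASES[alt_idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _gamete_states(cm: np.ndarray, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """Haplotype indicators (0/1) for gametes of one fully heterozygous parent.

    One chromosome; the gamete starts on either parental haplotype with equal
    probability and switches between adjacent markers with the Haldane
    recombination fraction for their map distance.
    """
    m = cm.size
    start = rng.integers(0, 2, size=(n_gametes, 1), dtype=np.int8)
    if m == 1:
        return start.astype(np.uint8)
    d = np.diff(cm)
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    switches = (rng.random((n_gametes, m - 1)) < r).astype(np.int8)
    steps = np.concatenate([start, switches], axis=1)
    return (np.cumsum(steps, axis=1) % 2).astype(np.uint8)


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Simulate genotypes and phenotypes for a bi-parental mapping population.

    Deterministic given ``config.seed``.  Phenotype model:
    trait = baseline + sum_l [ a_l * (dosage_l - 1) + d_l * 1{het} ] + N(0, sd^2).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    markers = _marker_table(config, rng)
    n = config.n_plants

    dosage_cols = []
    for chrom in config.chrom_names():
        cm = markers.loc[markers["chrom"] == chrom, "cM"].to_numpy()
        # both gametes of a selfed heterozygote (F2 and BC1F2 alike)
        g1 = _gamete_states(cm, n, rng)
        g2 = _gamete_states(cm, n, rng)
        dosage_cols.append((g1 + g2).astype(np.uint8))
    dosage = np.concatenate(dosage_cols, axis=1)

    pheno = np.full(n, config.trait_baseline, dtype=float)
    causal_markers = []
    for locus in config.causal_loci:
        idx = _nearest_marker(markers, locus.chrom, locus.pos)
        causal_markers.append((locus.chrom, int(markers.loc[idx, "pos"])))
        dl = dosage[:, idx].astype(float)
        pheno += locus.additive * (dl - 1.0) + locus.dominance * (dl == 1.0)
    if config.residual_sd > 0:
        pheno += rng.normal(0.0, config.residual_sd, size=n)

    return SimulatedPopulation(
        config=config,
        markers=markers,
        dosage=dosage,
        phenotypes=pheno,
        pedigree_label=config.population_type,
        causal_markers=tuple(causal_markers),
    )


def _nearest_marker(markers: pd.DataFrame, chrom: str, pos: int) -> int:
    sub = markers.index[markers["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"no markers on chromosome {chrom!r}")
    p = markers.loc[sub, "pos"].to_numpy()
    return int(sub[np.argmin(np.abs(p - pos))])


def select_bulks(pop: SimulatedPopulation, bulk_size: int) -> BulkAssignment:
    """Pick the phenotypic tails: ``bulk_size`` largest and smallest plants.

    Ties are broken deterministically by (phenotype, plant id) stable order.
    """
    if 2 * bulk_size > pop.n_plants:
        raise ValueError("2 * bulk_size exceeds population size")
    order = np.lexsort((np.arange(pop.n_plants), pop.phenotypes))
    low = np.sort(order[:bulk_size])
    high = np.sort(order[-bulk_size:])
    return BulkAssignment(high_ids=high, low_ids=low)


def _pool_base_counts(
    freq_m: np.ndarray,
    ref_idx: np.ndarray,
    alt_idx: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_snps, 4) base depths for one pool.

    Total depth per SNP is Poisson(mean_depth); reads support the true bulk
    allele binomially; with probability ``base_error_rate`` a read is
    replaced by a uniformly random different base.
    """
    n_snps = freq_m.size
    depth = rng.poisson(config.mean_depth, size=n_snps)
    m_reads = rng.binomial(depth, freq_m)
    p_reads = depth - m_reads
    counts = np.zeros((n_snps, 4), dtype=np.int64)
    rows = np.arange(n_snps)
    counts[rows, ref_idx] = m_reads
    counts[rows, alt_idx] += p_reads
    e = config.base_error_rate
    if e > 0:
        for true_idx, reads in ((ref_idx, m_reads), (alt_idx, p_reads)):
            n_err = rng.binomial(reads, e)
            counts[rows, true_idx] -= n_err
            split = rng.multinomial(n_err, [1 / 3] * 3)
            # scatter over the three bases other than the true one
            others = np.argsort(
                np.eye(4, dtype=np.int8)[true_idx], axis=1, kind="stable"
            )[:, :3]
            np.add.at(counts, (rows[:, None], others), split)
    return counts


def simulate_pool_counts(
    pop: SimulatedPopulation, bulks: BulkAssignment, config: SimulationConfig
) -> pd.DataFrame:
    """Per-SNP pooled base depths for the high and low bulks.

    Returns a pool-allele-counts table: chrom, pos, ref, alt, per-pool A/C/G/T
    depths, and the depths of the maternal (M) and paternal (P) alleles.
    Zero-depth SNPs are retained and simply carry all-zero counts (treated
    as missing downstream).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    ref_idx = np.searchsorted(BASES, pop.markers["ref"].to_numpy())
    alt_idx = np.searchsorted(BASES, pop.markers["alt"].to_numpy())

    out = pop.markers[["chrom", "pos", "ref", "alt"]].copy()
    rows = np.arange(len(out))
    for name, ids in (("high", bulks.high_ids), ("low", bulks.low_ids)):
        freq = pop.dosage[ids].mean(axis=0) / 2.0
        counts = _pool_base_counts(freq, ref_idx, alt_idx, config, rng)
        for b, base in enumerate(BASES):
            out[f"{name}_{base}"] = counts[:, b]
        out[f"{name}_M"] = counts[rows, ref_idx]
        out[f"{name}_P"] = counts[rows, alt_idx]
    return out


def write_fixtures(
    pop: SimulatedPopulation,
    counts: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the standard files a downstream run consumes.

    Emits a VCF with parental genotypes and pooled allele depths, a
    phenotype TSV, a causal-locus truth TSV and an echo of the simulation
    config; all round-trip through this package's readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "pools.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.yaml",
        "counts": outdir / "pool_counts.tsv",
    }
    vcfio.write_pool_vcf(counts, paths["vcf"])
    vcfio.write_pool_counts_tsv(counts, paths["counts"])
    pheno = pd.DataFrame(
        {
            "plant_id": [f"plant_{i:04d}" for i in range(pop.n_plants)],
            "NFFB": pop.phenotypes,
        }
    )
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)
    pop.truth_table().to_csv(paths["truth"], sep="\t", index=False)
    pop.config.to_yaml(paths["config"])
    return paths
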