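"""Simulator behaviour: Mendelian segregation, bulk selection, pool depths."""

import numpy as np
import pandas as pd
import pytest

from cottonbsa.config import CausalLocus, SimulationConfig
from cottonbsa.simulate import (
    select_bulks,
    simulate_pool_counts,
    simulate_population,
    write_fixtures,
)
from cottonbsa import vcfio


def test_noise_free_no_loci_gives_constant_phenotype():
    cfg = SimulationConfig(
        n_chromosomes=1,
        n_markers_per_chrom=50,
        n_plants=60,
        bulk_size=5,
        causal_loci=(),
        residual_sd=0.0,
        seed=3,
    )
    pop = simulate_population(cfg)
    assert np.all(pop.phenotypes == cfg.trait_baseline)


@pytest.mark.parametrize("population_type", ["F2", "BC1F2"])
def test_unselected_marker_segregates_1_2_1(population_type):
    """Genotype frequencies at any marker match the Mendelian 1:2:1
    expectation for the selfed offspring of a heterozygote, within 3 SE of
    the exact multinomial proportions."""
    n = 10_000
    cfg = SimulationConfig(
        n_chromosomes=1,
        n_markers_per_chrom=11,
        n_plants=n,
        bulk_size=10,
        causal_loci=(),
        population_type=population_type,
        seed=5,
    )
    pop = simulate_population(cfg)
    mid = 5
    counts = np.bincount(pop.dosage[:, mid], minlength=3)
    expected = np.array([0.25, 0.5, 0.25])
    se = np.sqrt(expected * (1 - expected) / n)
    np.testing.assert_array_less(np.abs(counts / n - expected), 3 * se)


def test_linked_markers_are_correlated_and_chromosomes_independent():
    cfg = SimulationConfig(
        n_chromosomes=2,
        n_markers_per_chrom=50,
        chrom_length_cM=100.0,
        n_plants=4000,
        bulk_size=10,
        causal_loci=(),
        seed=9,
    )
    pop = simulate_population(cfg)
    d = pop.dosage.astype(float)
    r_adjacent = np.corrcoef(d[:, 0], d[:, 1])[0, 1]
    r_across = np.corrcoef(d[:, 0], d[:, 60])[0, 1]
    assert r_adjacent > 0.8
    assert abs(r_across) < 0.06


def test_determinism_given_seed(small_config):
    pop1 = simulate_population(small_config)
    pop2 = simulate_population(small_config)
    assert np.array_equal(pop1.dosage, pop2.dosage)
    assert np.array_equal(pop1.phenotypes, pop2.phenotypes)
    b1 = select_bulks(pop1, 10)
    c1 = simulate_pool_counts(pop1, b1, small_config)
    c2 = simulate_pool_counts(pop2, select_bulks(pop2, 10), small_config)
    pd.testing.assert_frame_equal(c1, c2)


def test_select_bulks_takes_extreme_tails():
    cfg = SimulationConfig(
        n_chromosomes=1,
        n_markers_per_chrom=10,
        n_plants=10,
        bulk_size=3,
        causal_loci=(),
        seed=1,
    )
    pop = simulate_population(cfg)
    pop.phenotypes = np.arange(1.0, 11.0)  # plants 0..9 get phenotypes 1..10
    bulks = select_bulks(pop, 3)
    assert set(bulks.low_ids) == {0, 1, 2}
    assert set(bulks.high_ids) == {7, 8, 9}


def test_select_bulks_ties_are_deterministic_and_disjoint():
    cfg = SimulationConfig(
        n_chromosomes=1,
        n_markers_per_chrom=10,
        n_plants=10,
        bulk_size=4,
        causal_loci=(),
        residual_sd=0.0,
        seed=1,
    )
    pop = simulate_population(cfg)  # all phenotypes identical
    bulks = select_bulks(pop, 4)
    assert set(bulks.low_ids) == {0, 1, 2, 3}
    assert set(bulks.high_ids) == {6, 7, 8, 9}
    assert not set(bulks.low_ids) & set(bulks.high_ids)


def test_select_bulks_rejects_oversized_bulks(small_config):
    pop = simulate_population(small_config)
    with pytest.raises(ValueError):
        select_bulks(pop, small_config.n_plants // 2 + 1)


def test_bulks_differ_in_causal_allele_dosage(small_config):
    """The high-phenotype bulk carries more of the trait-raising maternal
    allele at the causal marker — recomputed directly from stored genotypes."""
    pop = simulate_population(small_config)
    bulks = select_bulks(pop, small_config.bulk_size)
    chrom, pos = pop.causal_markers[0]
    j = int(
        np.flatnonzero(
            (pop.markers["chrom"] == chrom) & (pop.markers["pos"] == pos)
        )[0]
    )
    assert pop.dosage[bulks.high_ids, j].mean() > pop.dosage[bulks.low_ids, j].mean()


def test_pool_counts_fixed_bulk_gives_snp_index_one():
    cfg = SimulationConfig(
        n_chromosomes=1,
        n_markers_per_chrom=20,
        n_plants=20,
        bulk_size=10,
        causal_loci=(),
        base_error_rate=0.0,
        seed=2,
    )
    pop = simulate_population(cfg)
    pop.dosage[:] = 2  # whole population fixed AA
    bulks = select_bulks(pop, 10)
    counts = simulate_pool_counts(pop, bulks, cfg)
    nonzero = counts["high_M"] + counts["high_P"] > 0
    assert (counts.loc[nonzero, "high_P"] == 0).all()
    assert (
        counts.loc[nonzero, "high_M"]
        / (counts.loc[nonzero, "high_M"] + counts.loc[nonzero, "high_P"])
        == 1.0
    ).all()


def test_pool_counts_frequency_converges_at_high_depth():
    """Observed pooled allele frequency near a 0.5 bulk frequency, within 3
    binomial SE at ~10^6 aggregate depth."""
    cfg = SimulationConfig(
        n_chromosomes=1,
        n_markers_per_chrom=1000,
        n_plants=20,
        bulk_size=10,
        causal_loci=(),
        mean_depth=1000.0,
        base_error_rate=0.0,
        seed=4,
    )
    pop = simulate_population(cfg)
    pop.dosage[:] = 1  # every plant heterozygous: true frequency 0.5
    bulks = select_bulks(pop, 10)
    counts = simulate_pool_counts(pop, bulks, cfg)
    m = counts["high_M"].sum()
    total = (counts["high_M"] + counts["high_P"]).sum()
    se = np.sqrt(0.25 / total)
    assert abs(m / total - 0.5) < 3 * se


def test_pool_depth_mean_matches_declared_poisson_mean():
    cfg = SimulationConfig(
        n_chromosomes=1,
        n_markers_per_chrom=100_000,
        chrom_length_bp=100_000_000,
        n_plants=20,
        bulk_size=10,
        causal_loci=(),
        mean_depth=31.99,
        base_error_rate=0.0,
        seed=6,
    )
    pop = simulate_population(cfg)
    bulks = select_bulks(pop, 10)
    counts = simulate_pool_counts(pop, bulks, cfg)
    depth = (counts[["high_A", "high_C", "high_G", "high_T"]].sum(axis=1)).mean()
    assert abs(depth - 31.99) / 31.99 < 0.02


def test_fixture_round_trip(tmp_path, small_config):
    pop = simulate_population(small_config)
    bulks = select_bulks(pop, small_config.bulk_size)
    counts = simulate_pool_counts(pop, bulks, small_config)
    paths = write_fixtures(pop, counts, tmp_path)
    via_vcf = vcfio.read_pool_vcf(paths["vcf"])
    via_tsv = vcfio.read_pool_counts_tsv(paths["counts"])
    ref = counts.reset_index(drop=True)
    pd.testing.assert_frame_equal(via_vcf, ref[via_vcf.columns], check_dtype=False)
    pd.testing.assert_frame_equal(via_tsv, ref[via_tsv.columns], check_dtype=False)
    assert len(via_vcf) == small_config.n_chromosomes * small_config.n_markers_per_chrom
    pheno = vcfio.read_phenotypes_tsv(paths["phenotypes"])
    assert len(pheno) == small_config.n_plants


def test_empty_population_writes_valid_header_only_files(tmp_path):
    cfg = SimulationConfig(
        n_chromosomes=1,
        n_markers_per_chrom=5,
        n_plants=4,
        bulk_size=2,
        causal_loci=(),
        seed=1,
    )
    pop = simulate_population(cfg)
    counts = simulate_pool_counts(pop, select_bulks(pop, 2), cfg)
    paths = write_fixtures(pop, counts.iloc[0:0], tmp_path)
    assert vcfio.read_pool_vcf(paths["vcf"]).empty
    assert vcfio.read_pool_counts_tsv(paths["counts"]).empty


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(population_type="RIL")
    with pytest.raises(ValueError):
        SimulationConfig(n_plants=10, bulk_size=6)
    with pytest.raises(ValueError):
        SimulationConfig(causal_loci=(CausalLocus("chr9", 1000, 0.5),))
    with pytest.raises(ValueError):
        SimulationConfig(
            causal_loci=(CausalLocus("chr1", 60_000_000, 0.5),)
        )
    with pytest.raises(ValueError):
        SimulationConfig(mean_depth=0)
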