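# Methods

This note documents the statistical model, the filtering rules, the tunable
parameters (with units, defaults, and the reasoning behind each default),
and the known limitations of the `cottonbsa` package.

## 1. Simulation model

### Cross and genome

Two fully inbred parents are assumed: every simulated marker is fixed for
the maternal allele (labelled **M**) in one parent and the paternal allele
(**P**) in the other. Markers are placed at evenly spaced physical
positions per chromosome; genetic position is a linear function of physical
position (constant recombination rate per chromosome).

Meiosis uses the **Haldane map function** (no crossover interference): two
adjacent markers `d` centimorgans apart recombine with fraction
`r = (1 − exp(−2d/100)) / 2`. A gamete is simulated as a Markov chain along
the chromosome — a fair-coin starting haplotype followed by independent
Bernoulli(r) switches — vectorised across all plants at once
(cumulative sum of switch indicators mod 2).

Both **F2** and **BC1F2** population types model each plant as the selfed
offspring of a genome-wide heterozygote, so genotypes segregate 1:2:1 in
expectation. This is exact for an F2; for a BC1F2 it assumes the BC1
founder was heterozygous at every scored marker, which holds for all
markers inside the still-segregating portion of a backcross genome (the
only portion where BSA markers are informative). Markers fixed by the
backcross would be monomorphic and carry no signal either way.

### Phenotype

```
trait = baseline + Σ_loci [ a · (dosage − 1) + d · 1{heterozygote} ] + N(0, σ²)
```

where `dosage` ∈ {0, 1, 2} counts maternal alleles at the marker nearest
the configured causal position (causal loci are snapped to the nearest
simulated marker, and the snapped position is recorded in the truth table
so recovery checks are exact).

### Bulks and pooled sequencing

The high and low bulks are the `bulk_size` plants with the largest and
smallest phenotypes; ties are broken deterministically by plant id
(stable lexicographic sort), so a given seed always yields the same bulks.
Per SNP and pool, total depth is **Poisson(mean_depth)**; reads support
the true bulk maternal-allele frequency **binomially**; each read is
independently mis-called with probability `base_error_rate`, scattering
uniformly over the three other bases (multinomial). Zero-depth SNPs are
retained with all-zero counts and treated as missing downstream.

### Seeding

`numpy.random.SeedSequence(seed).spawn(2)` gives independent streams for
(0) the population and (1) the pool counts, so regenerating pool counts
never perturbs the population. Replicate experiments derive child seeds
arithmetically from the base seed.

## 2. Read quality control (`readqc`)

Two rule sets mirror the two sequencing arms of the design:

| rule | GBS | resequencing |
| --- | --- | --- |
| N fraction | ≥ 10% removed (inclusive) | > 10% removed (strict) |
| low-quality bases | > 50% with Phred < 5 | > 40% with Phred ≤ 20 |
| adapter | any 10-nt read window within 1 mismatch of any 10-nt adapter window | same |
| restriction sites | reads containing HaeIII (`GGCC`) or EcoRI (`GAATTC`) sites removed | — |

Decisions taken where the verbal rules were ambiguous:

- **Adapter matching is anywhere-vs-anywhere**: every 10-nt window of the
  read is compared against every 10-nt window of the adapter, and one
  mismatch (10% of the match length) is tolerated. This is the most
  conservative reading (removes the most contamination) and is what
  window-based contaminant screens do.
- **"Q ≤ 20"** is implemented as `low_qual_below = 21` so the boundary base
  Q = 20 counts as low-quality; the GBS arm's "quality < 5" keeps the
  strict inequality.
- **Paired-end filtering drops the pair if either mate fails**, keeping
  files in sync — the standard behaviour of paired trimmers.

`failed_rules` returns all rules a read violates (not just the first), so
filter reports attribute removals consistently regardless of rule order.

## 3. Marker engine (`markers`)

Markers from a cross-pollinated (CP) coding are classified into the eight
informative patterns (`aaxbb`, `abxcc`, `abxcd`, `ccxab`, `efxeg`, `hkxhk`,
`lmxll`, `nnxnp`) by set logic on the parental calls; everything else is
uninformative. The classification is tested by exhaustive enumeration
against an independent oracle over all genotype pairs.

Filters applied to `aaxbb` markers, in order:

1. **Abnormal bases** — markers where > 5% of progeny calls contain an
   allele absent from both parents are removed (genotyping artefacts).
2. **Integrity** — markers called in < 40% of plants are removed.
3. **Segregation distortion** — χ² goodness-of-fit against 1:2:1
   (2 degrees of freedom); markers with p < 0.001 are removed. The
   acceptance script measures the realised type-I rate of this filter on
   truly 1:2:1 multinomial data (n = 200 plants) and it sits near the
   nominal 0.001 (the χ² approximation is adequate at this sample size).
4. **Same-fragment de-duplication** — within a chromosome, markers whose
   adjacent gaps are ≤ 150 bp are chained into one presumed sequencing
   fragment and only the first is kept.

Collinearity between genetic and physical order is summarised by the
Spearman rank correlation.

## 4. BSA statistics (`stats`)

For a pool with maternal depth M and paternal depth P:

- `SNP-index = M / (M + P)`, undefined (NaN) when `M + P < min_depth`
  (default **4** — below that the index is dominated by sampling noise and
  a single read error can move it by ≥ 0.25).
- `Δ(SNP-index) = SNP-index(low) − SNP-index(high)` — low minus high, in
  that order, so a maternal-allele-raises-trait locus gives negative Δ in
  the high bulk sense and the scan is thresholded on |Δ|.
- `ED = sqrt(Σ_{b∈ACGT} (f_high,b − f_low,b)²)` over the four base
  frequencies, range [0, √2]; `ED⁴` is the thresholded statistic (raising
  to the 4th power suppresses the noise floor while preserving peaks).
- For exactly biallelic data, `ED = √2 · |Δ(SNP-index)|`; the test suite
  verifies this identity to 1e-12 and the acceptance script reports the
  max deviation on simulated data.

**Threshold rule:** each statistic is cut at
`median + 3 × sample SD (ddof = 1)` of its own genome-wide finite values,
and exceedance uses strict `>`. The Δ scan thresholds **|Δ|** (sign only
encodes which parent contributes the allele). Sample SD (ddof = 1) is used
because the genome-wide SNP set is treated as a sample from the noise
distribution. Under a pure Gaussian null this rule passes ≈ 0.135% of SNPs
(P(Z > 3)); both the test suite and the acceptance script confirm the
calibration by Monte Carlo. Thresholds are genome-wide rather than
per-chromosome: per-chromosome thresholds would be inflated on the
chromosome that actually carries the signal, which is exactly where
sensitivity matters.

## 5. Region calling (`regions`)

Above-threshold SNPs are grouped into maximal runs per chromosome; runs
separated by ≤ `max_gap` bp are merged; merged runs with fewer than
`min_snps` SNPs are discarded. Intervals are **1-based inclusive**
(`length = end − start + 1`); BED export converts to 0-based half-open.
Defaults:

- `min_snps = 3` — a single above-threshold SNP is expected by chance
  ~0.135% of the time per SNP; requiring 3 clustered exceedances makes a
  chance region vanishingly rare at realistic marker densities.
- `max_gap = 200,000` bp — about an order of magnitude larger than the
  simulated inter-marker spacing, so a region is not split by one or two
  below-threshold SNPs, yet far smaller than a chromosome.

Two region sets are intersected pairwise (both sets are sorted and
disjoint); the intersection is validated in tests against a per-base set
oracle. Overlap with an externally supplied QTL interval is reported per
region with the overlapping span and its length.

## 6. Phenotype statistics (`pheno`)

Summaries report max, min, mean, skewness and kurtosis using the
**bias-corrected (SPSS/Excel) convention** (`scipy` with `bias=False`),
the convention used in breeding-trial summaries; skew/kurtosis are NaN for
n < 4 or constant samples. Parent comparison uses **Welch's t-test**
(unequal variances), with significance stars at p < 0.05 (\*) and
p < 0.01 (\*\*).

## 7. Bundled published data (`verify`)

`data/map_summary.tsv` holds a published genetic-map summary: 26
chromosomes with marker counts, map lengths (cM), average intervals,
largest gaps and collinearity. `data/qtl_coordinates.json` holds the
published QTL interval (D3: 17,130,008–41,839,226) and the two common BSA
regions (D3: 41,779,195–41,836,120 and 41,836,768–41,872,287), plus the
printed totals. `published_arithmetic_report()` recomputes every total from
the per-row values:

- Subgenome/total marker counts must match exactly.
- Summed map lengths are compared with tolerance `0.005 × n_rows`, the
  worst-case accumulation of per-row values printed to 2 decimals.
- The QTL length (24,709,219 bp ≈ 24.7 Mb), the common-region total
  (92,446 bp ≈ 92.4 Kb), the D3 average interval (166.45 cM / 82 markers
  ≈ 2.03 cM), and the 59,385 bp overlap of the common regions with the
  QTL are recomputed from coordinates.

## 8. Reference study configuration

`config.study_config()` reproduces the design scale: 561 BC1F2 plants,
3 chromosomes × 2,000 markers (50 Mb / 150 cM each), 30-plant bulks,
32× mean pool depth, base-error rate 0.001, and three causal loci — one
major (additive 0.75, dominance 0.1) and two minor (additive 0.30 each).

The major-locus effect and baseline are derived from the published
parental phenotypes, not tuned: parents at ≈ 8.0 and ≈ 5.3 nodes differ by
≈ 2.7 nodes, i.e. a summed additive effect of ≈ 1.35 across loci
(0.75 + 0.30 + 0.30), with baseline 6.65 the parental midpoint. The
default single-locus `SimulationConfig` keeps the major locus alone
(additive 0.75, baseline 6.65).

Residual SD 0.6 gives a broad-sense heritability of the major locus of
roughly 0.44 in the default single-locus configuration, consistent with a
"major QTL" for a moderately heritable earliness trait.

## 9. What the simulator does and does not emulate

Modelled: Haldane meiosis, 1:2:1 segregation, tail-bulk selection on
phenotype, Poisson sequencing depth, binomial allele sampling within a
pool, uniform base-calling error, missing data as zero depth.

Not modelled: crossover interference, segregation distortion with a
biological cause, read alignment/mapping bias, PCR duplicates, indels and
structural variants, variable marker density, polyploid homoeologue
cross-mapping, genotype-calling error in the population (the marker engine
is exercised on separately constructed inputs), and read-level GBS library
simulation (the QC module consumes real or externally generated FASTQ).

## 10. Numerical and implementation choices

- Interval arithmetic is hand-written (a few dozen lines) and cross-checked
  in tests against a per-base set oracle, rather than pulling in an
  interval library for one intersect operation.
- VCF reading uses `pysam`; writing uses a small text writer (the output
  is a narrow, fixed-schema VCF and the writer keeps the pool base counts
  in a custom `BC` FORMAT field).
- FASTQ parsing uses Biopython's `FastqGeneralIterator` (fast path, no
  per-record object construction); gzip is handled transparently.
- All randomness flows through `numpy.random.Generator`; no global seeding.
- Pipeline manifests record a SHA-256 of the sorted-JSON parameter set and
  of every output file, so identical config + seed ⇒ identical checksums.

## 11. Limitations

- The 1:2:1 BC1F2 model ignores markers fixed by the backcross; real BC1F2
  maps contain such monomorphic regions.
- The median+3SD threshold is a heuristic, not a formal error-rate control;
  its null exceedance (~0.135%) is calibrated only under the Gaussian/
  high-depth approximation.
- ED⁴ and |Δ| thresholds are computed on the same data they are applied
  to, so a very strong signal slightly inflates the genome-wide SD and
  makes the rule conservative.
- The χ² distortion test is asymptotic; for very small populations
  (n ≲ 30) an exact multinomial test would be preferable.
- Recovery/null rates are reported for the reference configuration;
  sensitivity at much lower depth, smaller bulks, or weaker effects is not
  characterised.
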