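# Methods

## Comparison model

All metrics operate on a `PanelPair`: truth and imputed panels restricted
to identical samples and markers, genotypes coded as unphased ALT-allele
dosage (0/1/2) with a missing sentinel. Comparison is pairwise-complete —
a call missing in either panel is excluded from every denominator. This
is a deliberate choice: evaluation data rarely document how missing calls
were handled, and pairwise-complete deletion is the only convention that
never scores a guess against an absent answer. Counts of excluded calls
are carried in every per-sample/per-SNP table so the effective sample
size is always visible.

Per-SNP Pearson correlations are undefined when either dosage vector has
zero variance within the compared calls (monomorphic markers being the
common case). Undefined values are NaN, excluded from means, and counted
separately — at sequence density the monomorphic fraction is large enough
that silently zero-filling or dropping them would change summary
correlations materially.

Confusion tables are row-normalized within the true-genotype class, so
each row answers "given the true genotype, where did imputation send
it?". The heterozygote error rate (100 minus the het-row diagonal
percentage) is exposed directly because heterozygotes dominate the error
budget in every imputation scenario.

Frequency binning uses the truth ALT frequency on [0, 1] in 100 bins of
width 0.01 (`[k·w, (k+1)·w)`, final bin closed), with a folded-MAF view
(50 bins on [0, 0.5]) available; which axis a published figure used is
often ambiguous, so both are first-class. Empty bins are flagged with a
zero marker count and NaN mean rather than zero-filled.

## Hard filters and harmonization

Site hard filters implement the GATK-style exclusion thresholds for
short-variant calls (QUAL < 50, QD < 2.0, MQ < 40.0, FS > 100.0,
MQRankSum < −8.0, ReadPosRankSum < −20.0, ExcessHet > 54.69,
missingness > 0.2). All violated rule codes are returned, not just the
first. An absent annotation passes its rule by default — the common
convention, since rank-sum annotations are undefined for
homozygous-reference-free sites — with a strict mode that fails them
instead.

Missingness filters (samples > 10%, markers > 20% or non-autosomal) use
strict inequality: values exactly at the threshold are kept. The
pipeline order is fixed (samples first, then markers) because the two
filters do not commute at nonzero thresholds.

Harmonization matches markers by chromosome + position, which must be a
bijection: duplicate positions are an error, not a silent first-wins.
Exact REF/ALT matches pass through; swapped alleles flip dosage
d → 2 − d (an involution, tested as such); complementary pairs (A/T,
C/G) are dropped unconditionally because strand orientation cannot be
resolved from the alleles alone; everything else is an allele mismatch.
The disposition counts always sum to the input marker count.

## Info score

The info measure is the IMPUTE-style ratio of observed to expected
statistical information about the allele frequency. With per-sample
posterior triples, expected dosage `e = p1 + 2·p2`, second moment
`f = p1 + 4·p2` and `θ = Σe / 2N`:

    info = 1 − Σ(f − e²) / (2N·θ·(1−θ))

defined as 1 when θ ∈ {0, 1} and clamped to [0, 1]. Published evaluation
work names the concept without committing to a formula; this is the
field-standard formulation, and the simulator emits exact posteriors
(the effective transition row used for each call) so the score has
well-defined inputs without depending on any external imputation tool.

## GRM comparison

VanRaden method 1: `G = ZZ' / (2Σp(1−p))` with `Z` the dosage matrix
centered at `2p`, monomorphic markers excluded, and missing calls
mean-imputed to `2p` for this computation only. When comparing truth- and
imputed-panel GRMs, both use the truth panel's frequencies so that the
sum-of-squares deviation reflects genotype error rather than centering
differences; the frequency source is recorded on the GRM object. The
deviation is summed over all n² elements including the diagonal. PCA
coordinates are eigenvectors scaled by the square root of their
(non-negative-truncated) eigenvalues.

## Region scan

Per-SNP concordance is smoothed with a centered running median per
chromosome (default window 1001 SNPs). At chromosome edges the window
shrinks to the markers available; discarding edge markers instead would
blind the scan exactly where accuracy is empirically worst. The flagging
cutoff is the genome-wide nearest-rank quantile (default percentile 0.1,
i.e. the ⌈0.001·n⌉-th smallest smoothed value) — nearest-rank rather
than interpolated so the cutoff is an actual data value and reproducible
across numeric environments. Flagging is `value ≤ cutoff`; on a
constant track this floods (documented degenerate behavior of the
primitive), so the evaluation pipeline short-circuits zero-variance
tracks to an empty region table — truth compared against itself yields
CR 1 and no regions.

Flagged SNPs within 1 Mb join one region; a gap strictly greater than
1 Mb starts a new one; regions need at least 2 flagged SNPs. Intervals
are 1-based closed with length = end − start — the convention validated
row-by-row against the published Hanwoo region table shipped as a
fixture (31 regions; per-chromosome flagged-SNP sums 15,339 / 9,177 /
5,326 for chromosomes 4 / 17 / 10; fifth-longest region 510,536 bp).
BED export converts explicitly to 0-based half-open.

## Synthetic data generator

The generator emulates the structure of a paired array/sequence cattle
dataset, not any particular population's parameters:

- **Founders.** Per-marker ALT frequencies from Beta(0.3, 0.3) — U-shaped
  so the edge frequency bins (rare variants) are populated as in sequence
  data — with 10% of markers forced exactly monomorphic (half fixed-REF,
  half fixed-ALT) by default. 40 founder haplotypes, positions uniform on
  100 Mb chromosomes.
- **Descendants.** Each haplotype is a founder mosaic with per-marker
  switch probability 0.01 (geometric segment lengths), creating LD and
  half-sib-like relatedness without a coalescent model. Genotype = sum of
  the two haplotypes.
- **Density masking** keeps a deterministic `round(m·keep)` uniformly
  chosen marker subset, composable to emulate nested 50K ⊂ 700K ⊂
  sequence panels.
- **Error injection.** Each call is resampled from the row of a 3×3
  genotype transition matrix (default off-diagonal mass ~1.5–5% per
  class). Off-diagonal mass is locally multiplied by `1 + 2·slope·MAF`,
  by planted bad-region multipliers, and by
  `1 + boost·(1 − d/range)` near chromosome ends, then renormalized
  (diagonal floors at 0 if error mass saturates). The effective row is
  emitted as the call's posterior, so confusion rows recover the matrix
  within binomial error and info scores are exactly self-consistent.
- **Spurious segregation.** A fraction of truth-monomorphic markers
  receives at least one wrong minor allele; the wrong-allele count is
  Binomial(2N, f) with f ~ Exponential(mean = scale, default 0.01),
  matching the empirical pattern that spurious variants at fixed sites
  appear at very low frequency. Note that the base transition errors
  also create spurious segregation at fixed sites, so at pipeline level
  the observed spurious fraction exceeds this module's rate — the rate is
  recovered exactly only on clean panels, which is how the tests measure
  it.
- **Naive imputer.** Within windows of consecutive reference markers
  (default 100), the two reference haplotypes best matching a sample's
  observed genotypes are chosen greedily (first by hom-mismatch count,
  then by residual dosage distance) and unobserved markers are copied
  from them. It is a transparent stand-in for haplotype-copying
  imputation software — sufficient to reproduce the qualitative
  reference-composition findings (within-population reference beats a
  diverged one; adding few within-population haplotypes to a diverged
  panel recovers most of the gap) but not calibrated to any production
  tool's accuracy.

What the simulator does **not** emulate: genotyping-platform batch
effects, variant-calling error correlated with depth, realistic
recombination maps or mutation-age/frequency coupling, and phasing
error as a distinct process. Passing tests therefore demonstrate that
the metrics and scan recover known planted structure, not that any
particular real dataset would show the same numbers.

All randomness flows from a single integer seed through one
`numpy` generator per run; identical configurations are byte-identical
across runs.

## Problem sizes

Defaults in tests and the acceptance script are chosen for statistical
resolution at interactive scale: ≥ 10,000 calls per genotype class for
3-SE confusion-row recovery, 3 seeds for every Monte-Carlo ordering
claim, 3,000-marker chromosomes with 101-SNP windows for planted-region
recovery (boundary error bounded by half a window), and ~100-sample
panels for GRM and composition experiments. Larger panels change runtime,
not the contracts.

## Known limitations

- Harmonization requires exact chromosome + position matches; there is no
  liftover, multiallelic decomposition, or probe realignment.
- The naive imputer's greedy diplotype search is not a Li–Stephens HMM;
  absolute accuracies from it should never be quoted, only contrasts
  between reference compositions run under identical settings.
- Info scores require posteriors; panels imputed by tools that emit only
  hard calls get no info-score report.
- The published region table is used solely as an internal-consistency
  fixture; the scan's percentile cutoff on new data is a genome-wide
  quantile of smoothed values and will not match any particular published
  cutoff value.
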