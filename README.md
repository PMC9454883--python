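# imputeval

Evaluation framework for whole-genome-sequence genotype imputation in
livestock panels. Given a *truth* panel (array or sequence genotypes held
out as the reference standard) and an *imputed* panel for the same
animals, the package quantifies imputation quality at every level the
field reports and locates the genomic regions where imputation fails.

It is aimed at quantitative geneticists running imputation pipelines
(50K array → high-density array → sequence) who need more than a single
accuracy number: per-animal and per-SNP diagnostics, genotype-class error
structure, the effect of imputation error on genomic relationship
matrices, and defensible filtering decisions.

## What it computes

With `X` and `Y` the truth and imputed ALT-dosage matrices (samples ×
markers, entries 0/1/2, compared over pairwise non-missing calls):

- **Concordance rate** `CR = #{x_ij = y_ij} / #compared` — overall, per
  sample, per SNP, and in allele-frequency bins of width 0.01.
- **Pearson correlation** `r(x, y)` of dosages per sample and per SNP
  (zero-variance vectors are reported as undefined, not zero).
- **Genotype confusion tables**: 3×3 counts of true × imputed genotype
  class with row percentages; the heterozygote error rate
  `100 − P(het | het)` is the headline statistic, since heterozygotes are
  the hardest class to impute.
- **Allele-frequency agreement**: `r` between truth and imputed ALT
  frequencies, and a fixed-SNP report — how many markers monomorphic in
  the population spuriously segregate after imputation, and at what mean
  MAF.
- **GRM comparison**: VanRaden method-1 relationship matrices
  `G = ZZ' / 2Σp(1−p)` from truth and imputed panels (shared truth
  frequencies), their element-wise sum-of-squares deviation, and PCA.
- **Info scores**: the IMPUTE-style ratio of observed to expected
  statistical information, `1 − Σ(f−e²) / (2Nθ(1−θ))`, and an evaluation
  of how well a hard info-score cutoff separates well- from
  poorly-imputed markers.
- **Region scan**: a per-chromosome running median of per-SNP CR
  (1001-SNP windows by default), genome-wide nearest-rank percentile
  flagging (default 0.1th percentile), and merging of flagged SNPs less
  than 1 Mb apart into poorly imputed regions with ≥ 2 SNPs — plus an
  accuracy-versus-distance-to-chromosome-end profile.

Upstream of the metrics, `qc` implements GATK-style site hard filters
(QUAL ≥ 50, QD ≥ 2, MQ ≥ 40, FS ≤ 100, MQRankSum ≥ −8,
ReadPosRankSum ≥ −20, ExcessHet ≤ 54.69, missingness ≤ 0.2), sample
(>10% missing) and marker (>20% missing, non-autosomal) filters, REF/ALT
harmonization between panels (dosage flip for swapped alleles,
strand-ambiguous A/T and C/G markers dropped), and panel intersection.

Because real cattle evaluation panels are access-restricted, the
`simulate` module generates diploid biallelic panels with the error
structure the evaluation assumes: founder haplotypes from a U-shaped
frequency spectrum, mosaic descendants, density masking, genotype-class
transition errors with MAF, planted-region and chromosome-end modifiers,
spurious segregation at fixed markers, and a naive haplotype-copying
imputer for reference-panel composition experiments.

## Worked example

```python
from imputeval import evaluate_panels, EvaluationOptions, ScanParameters
from imputeval.simulate import SimulationConfig, ErrorModel, simulate_dataset

cfg = SimulationConfig(
    n_chromosomes=2, markers_per_chrom=2000, n_samples=100,
    error_model=ErrorModel(end_boost=8.0,
                           bad_regions=[("1", 40_000_000, 50_000_000, 12.0)]),
    seed=11,
)
ds = simulate_dataset(cfg)
res = evaluate_panels(
    ds.truth, ds.imputed, posteriors=ds.posteriors,
    options=EvaluationOptions(scan=ScanParameters(window=101, percentile=2.0)),
)
```

prints, via `res.summary()` and `res.regions`:

```
overall CR        0.9595
het error rate    9.73%
mean per-sample r 0.9701
allele-freq r     0.9986
GRM ss deviation  4.5026
info~CR corr      0.1350
scan cutoff       0.7900
chrom    start      end  length  n_snps
    1 42747477 48629891 5882414      99
```

Reading this: ~96% of calls are imputed correctly but almost 10% of
heterozygotes are wrong; allele frequencies survive imputation almost
perfectly even where genotypes do not; the info score is a poor proxy
for realized per-SNP concordance (r ≈ 0.14); and the scan recovers the
planted low-accuracy region on chromosome 1 (40–50 Mb) from the
concordance track alone. The same pipeline is available from the shell:

```sh
imputeval simulate --config config.json --out sim/
imputeval evaluate --truth sim/truth.vcf --imputed sim/imputed.vcf --out report/
imputeval region-scan --track per_snp.tsv --out regions.tsv
```

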