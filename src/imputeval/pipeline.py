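"""End-to-end evaluation orchestration and report bundles.

``evaluate_panels`` runs harmonize -> intersect -> every accuracy metric
-> optional GRM comparison -> region scan on a truth/imputed VCF pair (or
in-memory panels) and assembles a machine-readable bundle: one JSON
summary plus tab-separated tables for the per-sample, per-marker,
confusion, frequency-bin, fixed-marker and region outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import grm as grm_mod
from . import metrics, qc
from .containers import GenotypeMatrix, PanelPair
from .regions import ScanParameters, scan_regions


@dataclass
class EvaluationOptions:
    bin_width: float = 0.01
    info_cutoff: float = 0.6
    compute_grm: bool = True
    scan: ScanParameters = field(default_factory=ScanParameters)


@dataclass
class EvaluationResult:
    """All evaluation outputs for one truth/imputed pair."""

    pair: PanelPair
    concordance: metrics.ConcordanceResult
    correlation: metrics.CorrelationResult
    confusion: metrics.ConfusionTable
    bins: pd.DataFrame
    af_correlation: float
    fixed: metrics.FixedSnpReport
    harmonization: qc.HarmonizationReport | None
    cutoff: float
    regions: pd.DataFrame
    grm_ss: float | None = None
    grm_pca_truth: pd.DataFrame | None = None
    grm_pca_imputed: pd.DataFrame | None = None
    info_report: metrics.InfoScoreReport | None = None
    info_scores: np.ndarray | None = None

    def summary(self) -> dict:
        s = self.concordance.summary()
        per_r = self.correlation.per_sample["r"]
        s.update(
            {
                "mean_sample_r": float(per_r.mean()),
                "min_sample_r": float(per_r.min()),
                "max_sample_r": float(per_r.max()),
                "mean_snp_r": self.correlation.mean_snp_r,
                "n_undefined_snp_r": self.correlation.n_undefined_snps,
                "het_error_rate_pct": self.confusion.het_error_rate,
                "allele_frequency_r": self.af_correlation,
                "monomorphic_pct": self.fixed.monomorphic_pct,
                "spurious_segregation_fraction": self.fixed.spurious_fraction,
                "cr_on_monomorphic": self.fixed.concordance_on_monomorphic,
                "region_cutoff": self.cutoff,
                "n_regions": int(len(self.regions)),
            }
        )
        if self.grm_ss is not None:
            s["grm_ss_deviation"] = self.grm_ss
        if self.info_report is not None:
            s["info_report"] = asdict(self.info_report)
        return s


def evaluate_panels(
    truth: GenotypeMatrix,
    imputed: GenotypeMatrix,
    options: EvaluationOptions = EvaluationOptions(),
    posteriors: np.ndarray | None = None,
    harmonize: bool = True,
) -> EvaluationResult:
    """Run the full evaluation pipeline on two genotype panels.

    ``posteriors`` (aligned to the *imputed* panel's samples x markers)
    enables the info-score report. With ``harmonize`` the imputed panel is
    first allele-aligned to the truth marker map.
    """
    report = None
    if harmonize and truth.markers == imputed.markers:
        harmonize = False  # identical maps need no allele alignment
    if harmonize:
        imputed, report = qc.harmonize_markers(imputed, truth.markers)
        if posteriors is not None and report.total != report.kept_unchanged:
            # posterior columns follow the surviving markers; a flip swaps
            # the hom-REF/hom-ALT posterior entries
            raise ValueError(
                "posteriors cannot be carried through harmonization that "
                "drops or flips markers; harmonize beforehand"
            )
    pair = qc.intersect_panels(truth, imputed)

    conc = metrics.concordance(pair)
    corr = metrics.correlation(pair)
    conf = metrics.genotype_confusion(pair)
    bins = metrics.af_binned_concordance(
        pair, bin_width=options.bin_width, per_snp=conc.per_snp
    )
    af_r = metrics.allele_frequency_correlation(pair)
    fixed = metrics.fixed_snp_report(pair)

    track = conc.per_snp.rename(columns={"cr": "value"})[["chrom", "pos", "value"]]
    track = track[~track["value"].isna()].reset_index(drop=True)
    if track["value"].nunique() <= 1:
        # constant track (e.g. perfect imputation): no low tail to flag
        cutoff = float(track["value"].iloc[0]) if len(track) else float("nan")
        region_table = pd.DataFrame(columns=["chrom", "start", "end", "length", "n_snps"])
    else:
        cutoff, _flagged, region_table = scan_regions(track, options.scan)

    result = EvaluationResult(
        pair=pair,
        concordance=conc,
        correlation=corr,
        confusion=conf,
        bins=bins,
        af_correlation=af_r,
        fixed=fixed,
        harmonization=report,
        cutoff=cutoff,
        regions=region_table,
    )

    if options.compute_grm:
        freqs = pair.truth.alt_frequency()
        g_t = grm_mod.compute_grm(pair.truth, frequencies=freqs)
        g_i = grm_mod.compute_grm(pair.imputed, frequencies=freqs)
        result.grm_ss = grm_mod.grm_ss_deviation(g_t, g_i)
        k = min(2, pair.n_samples)
        result.grm_pca_truth, _ = grm_mod.grm_pca(g_t, k)
        result.grm_pca_imputed, _ = grm_mod.grm_pca(g_i, k)

    if posteriors is not None:
        # align posterior tensor to the intersected pair
        s_idx = np.asarray([imputed.samples.index(s) for s in pair.truth.samples])
        lookup = {k: j for j, k in enumerate(imputed.markers.key())}
        m_idx = np.asarray([lookup[k] for k in pair.truth.markers.key()])
        posteriors = posteriors[np.ix_(s_idx, m_idx)]
        info = metrics.impute_info_score(posteriors)
        result.info_scores = info
        result.info_report = metrics.info_filter_evaluation(
            info, conc.per_snp, options.info_cutoff
        )
    return result


def write_bundle(
    result: EvaluationResult,
    outdir: str,
    config: dict | None = None,
) -> None:
    """Write the evaluation bundle (JSON summary + TSV tables) to a directory."""
    os.makedirs(outdir, exist_ok=True)
    summary = result.summary()
    if config is not None:
        summary["config"] = config
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    result.concordance.per_sample.merge(
        result.correlation.per_sample[["sample", "r"]], on="sample"
    ).to_csv(os.path.join(outdir, "per_sample.tsv"), sep="\t", index=False)
    per_snp = result.concordance.per_snp.merge(
        result.correlation.per_snp[["chrom", "pos", "r"]], on=["chrom", "pos"]
    )
    if result.info_scores is not None:
        per_snp["info"] = result.info_scores
    per_snp.to_csv(os.path.join(outdir, "per_snp.tsv"), sep="\t", index=False)
    result.confusion.to_frame().to_csv(
        os.path.join(outdir, "confusion.tsv"), sep="\t"
    )
    result.bins.to_csv(os.path.join(outdir, "bins.tsv"), sep="\t", index=False)
    result.regions.to_csv(os.path.join(outdir, "regions.tsv"), sep="\t", index=False)
    if result.harmonization is not None:
        result.harmonization.to_tsv(os.path.join(outdir, "harmonization.tsv"))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
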