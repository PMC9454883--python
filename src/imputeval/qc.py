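"""Quality control and allele harmonization for genotype panels.

Implements the standard hard-filter rules applied to sequence-derived
variant calls (QUAL/QD/MQ/FS/rank-sum/ExcessHet thresholds), sample- and
marker-level missingness filters, REF/ALT harmonization between panels,
and sample/marker intersection to build a comparable truth/imputed pair.

Missingness filters use strict inequality: a sample at exactly the
threshold is kept ("more than 10% missing" excludes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np

from .containers import CATTLE_AUTOSOMES, GenotypeMatrix, MarkerMap, PanelPair

# strand-ambiguous allele pairs: complementary, so orientation is unresolvable
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass
class SiteAnnotationRecord:
    """Per-site variant-calling annotations used by the hard filters.

    Any annotation may be ``None`` (absent); by default an absent
    annotation does not trigger its rule.
    """

    qual: float | None = None
    qd: float | None = None
    mq: float | None = None
    fs: float | None = None
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None
    excess_het: float | None = None
    missingness: float | None = None
    allele_count: int | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if not isinstance(v, (int, float)) or (
                isinstance(v, float) and math.isnan(v)
            ):
                raise ValueError(f"non-numeric annotation value for {f.name}: {v!r}")
        if self.missingness is not None and not 0 <= self.missingness <= 1:
            raise ValueError(f"missingness {self.missingness} outside [0, 1]")


@dataclass(frozen=True)
class HardFilterThresholds:
    """Exclusion thresholds for sequence variant calls.

    Defaults follow GATK-style short-variant filtering for cattle
    whole-genome calls: fail a site when QUAL < 50, QD < 2.0, MQ < 40.0,
    FS > 100.0, MQRankSum < -8.0, ReadPosRankSum < -20.0,
    ExcessHet > 54.69, or missingness > 0.2.
    """

    min_qual: float = 50.0
    min_qd: float = 2.0
    min_mq: float = 40.0
    max_fs: float = 100.0
    min_mq_rank_sum: float = -8.0
    min_read_pos_rank_sum: float = -20.0
    max_excess_het: float = 54.69
    max_missingness: float = 0.2


def apply_site_hard_filters(
    record: SiteAnnotationRecord,
    thresholds: HardFilterThresholds = HardFilterThresholds(),
    strict_missing_annotations: bool = False,
) -> tuple[bool, list[str]]:
    """Evaluate every hard-filter rule on one site.

    Returns ``(passed, reasons)`` where ``reasons`` lists the code of every
    violated rule. With ``strict_missing_annotations`` an absent annotation
    fails its rule (code suffixed ``_MISSING``).
    """
    rules = [
        ("QUAL", record.qual, lambda v: v < thresholds.min_qual),
        ("QD", record.qd, lambda v: v < thresholds.min_qd),
        ("MQ", record.mq, lambda v: v < thresholds.min_mq),
        ("FS", record.fs, lambda v: v > thresholds.max_fs),
        ("MQRankSum", record.mq_rank_sum, lambda v: v < thresholds.min_mq_rank_sum),
        (
            "ReadPosRankSum",
            record.read_pos_rank_sum,
            lambda v: v < thresholds.min_read_pos_rank_sum,
        ),
        ("ExcessHet", record.excess_het, lambda v: v > thresholds.max_excess_het),
        ("MISSINGNESS", record.missingness, lambda v: v > thresholds.max_missingness),
    ]
    reasons = []
    for code, value, violated in rules:
        if value is None:
            if strict_missing_annotations:
                reasons.append(f"{code}_MISSING")
            continue
        if violated(value):
            reasons.append(code)
    return (not reasons, reasons)


def filter_samples(
    matrix: GenotypeMatrix, max_missing: float = 0.10
) -> GenotypeMatrix:
    """Drop samples whose missing-call fraction strictly exceeds ``max_missing``."""
    if not 0 <= max_missing <= 1:
        raise ValueError(f"max_missing {max_missing} outside [0, 1]")
    keep = np.flatnonzero(matrix.sample_missing_rate() <= max_missing)
    if keep.size == 0:
        warnings.warn("sample missingness filter removed every sample")
    return matrix.subset(sample_idx=keep)


def filter_markers(
    matrix: GenotypeMatrix,
    max_missing: float = 0.20,
    autosomes: frozenset[str] = CATTLE_AUTOSOMES,
) -> GenotypeMatrix:
    """Drop markers with missingness strictly above ``max_missing`` or on
    chromosomes outside ``autosomes``."""
    if not 0 <= max_missing <= 1:
        raise ValueError(f"max_missing {max_missing} outside [0, 1]")
    on_autosome = np.isin(matrix.markers.chrom, list(autosomes))
    keep = np.flatnonzero((matrix.marker_missing_rate() <= max_missing) & on_autosome)
    if keep.size == 0:
        warnings.warn("marker filter removed every marker")
    return matrix.subset(marker_idx=keep)


@dataclass
class HarmonizationReport:
    """Disposition counts for every marker of the harmonized target panel."""

    kept_unchanged: int = 0
    kept_flipped: int = 0
    dropped_ambiguous: int = 0
    dropped_allele_mismatch: int = 0
    dropped_unmatched: int = 0

    @property
    def total(self) -> int:
        return (
            self.kept_unchanged
            + self.kept_flipped
            + self.dropped_ambiguous
            + self.dropped_allele_mismatch
            + self.dropped_unmatched
        )

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("disposition\tcount\n")
            for f in fields(self):
                fh.write(f"{f.name}\t{getattr(self, f.name)}\n")


def harmonize_markers(
    target: GenotypeMatrix, reference_map: MarkerMap
) -> tuple[GenotypeMatrix, HarmonizationReport]:
    """Align the target panel's alleles to a reference marker map.

    Markers are matched by chromosome+position (duplicates are an error).
    An exact REF/ALT match is kept as-is; a swapped pair (target REF equal
    to reference ALT and vice versa) is kept with dosages flipped d -> 2-d;
    complementary pairs (A/T, C/G) are strand-unresolvable and dropped;
    any other configuration is dropped as an allele mismatch.
    """
    ref_key = reference_map.key()
    tgt_key = target.markers.key()
    ref_alleles = dict(
        zip(ref_key, zip(reference_map.ref, reference_map.alt))
    )

    keep_idx: list[int] = []
    flip: list[bool] = []
    report = HarmonizationReport()
    for j, key in enumerate(tgt_key):
        pair = ref_alleles.get(key)
        if pair is None:
            report.dropped_unmatched += 1
            continue
        t_ref, t_alt = target.markers.ref[j], target.markers.alt[j]
        if {t_ref, t_alt} in _AMBIGUOUS_PAIRS:
            report.dropped_ambiguous += 1
            continue
        r_ref, r_alt = pair
        if (t_ref, t_alt) == (r_ref, r_alt):
            report.kept_unchanged += 1
            keep_idx.append(j)
            flip.append(False)
        elif (t_ref, t_alt) == (r_alt, r_ref):
            report.kept_flipped += 1
            keep_idx.append(j)
            flip.append(True)
        else:
            report.dropped_allele_mismatch += 1

    out = target.subset(marker_idx=np.asarray(keep_idx, dtype=np.int64))
    flip_arr = np.asarray(flip, dtype=bool)
    if flip_arr.any():
        calls = out.calls
        cols = np.flatnonzero(flip_arr)
        block = calls[:, cols]
        nonmiss = block >= 0
        block[nonmiss] = 2 - block[nonmiss]
        calls[:, cols] = block
        # adopt the reference allele labels for the flipped markers
        t = out.markers.table
        r = t.loc[cols, "ref"].copy()
        t.loc[cols, "ref"] = t.loc[cols, "alt"].to_numpy()
        t.loc[cols, "alt"] = r.to_numpy()
    return out, report


def intersect_panels(
    truth: GenotypeMatrix, imputed: GenotypeMatrix
) -> PanelPair:
    """Restrict both panels to shared samples and markers, in truth order."""
    shared_samples = [s for s in truth.samples if s in set(imputed.samples)]
    if not shared_samples:
        raise ValueError("panels share no samples")
    truth_key = truth.markers.key()
    imputed_key = imputed.markers.key()
    shared = truth_key.isin(imputed_key)
    if not shared.any():
        raise ValueError("panels share no markers")

    t_sample_idx = np.asarray([truth.samples.index(s) for s in shared_samples])
    i_sample_idx = np.asarray([imputed.samples.index(s) for s in shared_samples])
    t_marker_idx = np.flatnonzero(shared)
    imp_lookup = {k: j for j, k in enumerate(imputed_key)}
    i_marker_idx = np.asarray([imp_lookup[truth_key[j]] for j in t_marker_idx])

    t = truth.subset(sample_idx=t_sample_idx, marker_idx=t_marker_idx)
    i = imputed.subset(sample_idx=i_sample_idx, marker_idx=i_marker_idx)
    # allele labels may legitimately differ pre-harmonization; require equality
    if not (t.markers == i.markers):
        raise ValueError(
            "shared markers disagree on alleles; run harmonize_markers first"
        )
    return PanelPair(truth=t, imputed=i)
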