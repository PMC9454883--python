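"""Imputation accuracy metrics.

All comparisons are pairwise-complete: a call missing in either panel is
excluded from the denominator. Concordance rate (CR) is the fraction of
imputed calls identical to the truth; correlation is Pearson's r on ALT
dosages. Both are computed overall, per sample and per marker, plus
genotype-level confusion tables, allele-frequency-binned concordance,
fixed-marker (monomorphic) diagnostics, observed-panel discordance, and
IMPUTE-style info scores with filter evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, PanelPair

GENOTYPE_LABELS = ("AA", "AB", "BB")  # hom-REF, het, hom-ALT


def _masked_pearson(x: np.ndarray, y: np.ndarray, mask: np.ndarray, axis: int):
    """Pairwise-complete Pearson r along ``axis``; NaN where undefined."""
    m = mask.astype(float)
    n = m.sum(axis=axis)
    xm = np.where(mask, x, 0.0)
    ym = np.where(mask, y, 0.0)
    sx = xm.sum(axis=axis)
    sy = ym.sum(axis=axis)
    sxx = (xm * xm).sum(axis=axis)
    syy = (ym * ym).sum(axis=axis)
    sxy = (xm * ym).sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / np.where(n > 0, n, np.nan)
        vx = sxx - sx * sx / np.where(n > 0, n, np.nan)
        vy = syy - sy * sy / np.where(n > 0, n, np.nan)
        r = cov / np.sqrt(vx * vy)
    r = np.where((n >= 2) & (vx > 1e-12) & (vy > 1e-12), r, np.nan)
    return r, n


def _marker_frame(pair: PanelPair) -> pd.DataFrame:
    t = pair.truth.markers.table
    return pd.DataFrame(
        {"chrom": t["chrom"], "pos": t["pos"], "id": t["id"]}
    )


@dataclass
class ConcordanceResult:
    """Overall, per-sample and per-marker concordance rates."""

    overall_cr: float
    per_sample: pd.DataFrame  # sample, cr, n_compared
    per_snp: pd.DataFrame  # chrom, pos, id, cr, freqs, maf, n_compared

    def summary(self, thresholds: tuple[float, ...] = (0.9,)) -> dict:
        cr = self.per_snp["cr"].dropna()
        s = {
            "overall_cr": self.overall_cr,
            "per_sample_min": float(self.per_sample["cr"].min()),
            "per_sample_mean": float(self.per_sample["cr"].mean()),
            "per_sample_max": float(self.per_sample["cr"].max()),
            "per_snp_min": float(cr.min()) if len(cr) else float("nan"),
            "per_snp_mean": float(cr.mean()) if len(cr) else float("nan"),
            "per_snp_max": float(cr.max()) if len(cr) else float("nan"),
        }
        for thr in thresholds:
            s[f"frac_snps_cr_below_{thr}"] = (
                float((cr < thr).mean()) if len(cr) else float("nan")
            )
        return s


def concordance(pair: PanelPair) -> ConcordanceResult:
    """Concordance rate over pairwise non-missing calls."""
    if pair.n_samples == 0 or pair.n_markers == 0:
        raise ValueError("empty panel pair")
    cmp = pair.compared_mask()
    match = (pair.truth.calls == pair.imputed.calls) & cmp
    total = cmp.sum()
    if total == 0:
        raise ValueError("no pairwise non-missing calls to compare")
    overall = match.sum() / total

    n_s = cmp.sum(axis=1)
    with np.errstate(invalid="ignore"):
        cr_s = np.where(n_s > 0, match.sum(axis=1) / n_s, np.nan)
    per_sample = pd.DataFrame(
        {"sample": pair.truth.samples, "cr": cr_s, "n_compared": n_s}
    )

    n_m = cmp.sum(axis=0)
    with np.errstate(invalid="ignore"):
        cr_m = np.where(n_m > 0, match.sum(axis=0) / n_m, np.nan)
    per_snp = _marker_frame(pair)
    per_snp["cr"] = cr_m
    per_snp["truth_alt_freq"] = pair.truth.alt_frequency()
    per_snp["imputed_alt_freq"] = pair.imputed.alt_frequency()
    per_snp["truth_maf"] = pair.truth.maf()
    per_snp["n_compared"] = n_m
    return ConcordanceResult(float(overall), per_sample, per_snp)


@dataclass
class CorrelationResult:
    """Pearson dosage correlations per sample and per marker.

    Zero-variance (e.g. monomorphic) vectors are undefined: NaN in the
    tables, excluded from means, counted in ``n_undefined_snps``.
    """

    per_sample: pd.DataFrame
    per_snp: pd.DataFrame
    n_undefined_snps: int
    n_undefined_samples: int

    @property
    def mean_sample_r(self) -> float:
        return float(self.per_sample["r"].mean())

    @property
    def mean_snp_r(self) -> float:
        return float(self.per_snp["r"].mean())


def correlation(pair: PanelPair) -> CorrelationResult:
    """Pearson correlation of truth vs imputed dosage, per sample and marker."""
    if pair.n_samples == 0 or pair.n_markers == 0:
        raise ValueError("empty panel pair")
    cmp = pair.compared_mask()
    t = pair.truth.calls.astype(float)
    i = pair.imputed.calls.astype(float)
    r_s, n_s = _masked_pearson(t, i, cmp, axis=1)
    r_m, n_m = _masked_pearson(t, i, cmp, axis=0)
    per_sample = pd.DataFrame(
        {"sample": pair.truth.samples, "r": r_s, "n_compared": n_s.astype(int)}
    )
    per_snp = _marker_frame(pair)
    per_snp["r"] = r_m
    per_snp["n_compared"] = n_m.astype(int)
    return CorrelationResult(
        per_sample,
        per_snp,
        n_undefined_snps=int(np.isnan(r_m).sum()),
        n_undefined_samples=int(np.isnan(r_s).sum()),
    )


@dataclass
class ConfusionTable:
    """3x3 genotype confusion counts (rows: true, columns: imputed)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion table must be 3x3")

    def row_percent(self) -> np.ndarray:
        """Row-normalized percentages (rows sum to 100); NaN for empty rows."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.counts / totals, np.nan)

    @property
    def overall_cr(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    @property
    def het_error_rate(self) -> float:
        """100 minus the heterozygote row's diagonal percentage."""
        pct = self.row_percent()
        return float(100.0 - pct[1, 1])

    def to_frame(self) -> pd.DataFrame:
        pct = self.row_percent()
        return pd.DataFrame(
            pct,
            index=[f"{g}_ref" for g in GENOTYPE_LABELS],
            columns=[f"{g}_imp" for g in GENOTYPE_LABELS],
        )


def genotype_confusion(pair: PanelPair) -> ConfusionTable:
    """Count true-vs-imputed genotype classes over compared calls."""
    cmp = pair.compared_mask()
    t = pair.truth.calls[cmp].astype(np.int64)
    i = pair.imputed.calls[cmp].astype(np.int64)
    counts = np.bincount(t * 3 + i, minlength=9).reshape(3, 3)
    return ConfusionTable(counts)


def af_binned_concordance(
    pair: PanelPair,
    bin_width: float = 0.01,
    use_maf: bool = False,
    per_snp: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean per-marker CR in allele-frequency bins.

    Bins are ``[k*w, (k+1)*w)`` on the truth ALT frequency (or folded MAF
    with ``use_maf``), the final bin closed above. Empty bins appear with
    ``n_markers == 0`` and NaN mean rather than being zero-filled.
    """
    if per_snp is None:
        per_snp = concordance(pair).per_snp
    freq = per_snp["truth_maf" if use_maf else "truth_alt_freq"].to_numpy()
    cr = per_snp["cr"].to_numpy()
    top = 0.5 if use_maf else 1.0
    n_bins = int(round(top / bin_width))
    idx = np.floor(freq / bin_width).astype(float)
    idx = np.where(np.isnan(freq), np.nan, np.clip(idx, 0, n_bins - 1))
    rows = []
    for k in range(n_bins):
        sel = (idx == k) & ~np.isnan(cr)
        rows.append(
            {
                "bin_low": k * bin_width,
                "bin_high": (k + 1) * bin_width,
                "mean_cr": float(cr[sel].mean()) if sel.any() else float("nan"),
                "n_markers": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def allele_frequency_correlation(pair: PanelPair) -> float:
    """Pearson r between truth and imputed ALT-frequency vectors.

    Monomorphic markers contribute as ordinary points (frequencies 0/1).
    """
    t = pair.truth.alt_frequency()
    i = pair.imputed.alt_frequency()
    ok = ~(np.isnan(t) | np.isnan(i))
    if ok.sum() < 2:
        raise ValueError("fewer than 2 markers with defined frequencies")
    r, _ = _masked_pearson(t[ok], i[ok], np.ones(ok.sum(), dtype=bool), axis=0)
    return float(r)


@dataclass
class FixedSnpReport:
    """Diagnostics on markers monomorphic (MAF = 0) in the truth panel."""

    n_markers: int
    n_monomorphic: int
    n_spurious: int  # monomorphic in truth, imputed MAF > 0
    mean_spurious_maf: float
    concordance_on_monomorphic: float

    @property
    def monomorphic_pct(self) -> float:
        return 100.0 * self.n_monomorphic / self.n_markers if self.n_markers else 0.0

    @property
    def spurious_fraction(self) -> float:
        return self.n_spurious / self.n_monomorphic if self.n_monomorphic else 0.0


def fixed_snp_report(pair: PanelPair) -> FixedSnpReport:
    """Quantify spurious segregation at truth-monomorphic markers."""
    maf_t = pair.truth.maf()
    mono = np.nan_to_num(maf_t, nan=1.0) == 0.0
    n_mono = int(mono.sum())
    if n_mono == 0:
        return FixedSnpReport(pair.n_markers, 0, 0, float("nan"), float("nan"))
    maf_i = pair.imputed.maf()[mono]
    spurious = maf_i > 0
    cmp = pair.compared_mask()[:, mono]
    match = (pair.truth.calls == pair.imputed.calls)[:, mono] & cmp
    total = cmp.sum()
    cr = float(match.sum() / total) if total else float("nan")
    return FixedSnpReport(
        n_markers=pair.n_markers,
        n_monomorphic=n_mono,
        n_spurious=int(spurious.sum()),
        mean_spurious_maf=float(maf_i[spurious].mean()) if spurious.any() else 0.0,
        concordance_on_monomorphic=cr,
    )


@dataclass
class DiscordanceReport:
    """Discordance decomposition between two observed/filled panels."""

    overall_discordance: float
    n_compared: int
    discordance_on_prefill_missing: float | None
    n_prefill_missing_compared: int
    discordance_on_subset: float | None
    discordance_off_subset: float | None


def panel_discordance(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    original_a: GenotypeMatrix | None = None,
    marker_subset: np.ndarray | None = None,
) -> DiscordanceReport:
    """Discordance (1 - CR) between harmonized, intersected panels.

    ``original_a`` is panel ``a`` before gap-filling: the report then also
    isolates the discordance on calls that were missing there (i.e. filled
    in by phasing/imputation). ``marker_subset`` (boolean, len = markers)
    splits the rate into on-/off-subset strata, e.g. excluding the
    original low-density panel's markers.
    """
    pair = PanelPair(truth=a, imputed=b)
    cmp = pair.compared_mask()
    mismatch = (a.calls != b.calls) & cmp
    n = int(cmp.sum())
    if n == 0:
        raise ValueError("no pairwise non-missing calls")
    overall = float(mismatch.sum() / n)

    d_fill, n_fill = None, 0
    if original_a is not None:
        if original_a.calls.shape != a.calls.shape:
            raise ValueError("original_a shape differs from a")
        filled = (original_a.calls == MISSING) & cmp
        n_fill = int(filled.sum())
        if n_fill:
            d_fill = float((mismatch & filled).sum() / n_fill)

    d_on = d_off = None
    if marker_subset is not None:
        marker_subset = np.asarray(marker_subset, dtype=bool)
        on = cmp & marker_subset[None, :]
        off = cmp & ~marker_subset[None, :]
        if on.sum():
            d_on = float((mismatch & on).sum() / on.sum())
        if off.sum():
            d_off = float((mismatch & off).sum() / off.sum())
    return DiscordanceReport(overall, n, d_fill, n_fill, d_on, d_off)


def impute_info_score(posteriors: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """IMPUTE-style info measure from genotype posterior probabilities.

    For marker posteriors ``p_i = (p0, p1, p2)`` over N samples, with
    expected dosage ``e_i = p1 + 2 p2`` and second moment
    ``f_i = p1 + 4 p2``, the estimated ALT frequency is
    ``theta = sum(e) / 2N`` and

        info = 1 - sum(f - e^2) / (2N theta (1 - theta))

    i.e. one minus the ratio of mean posterior dosage variance to the
    binomial variance at the estimated frequency. Defined as 1 when theta
    is 0 or 1; clamped to [0, 1].

    Accepts one marker (N x 3) or a panel (N x markers x 3); returns a
    scalar array per marker.
    """
    p = np.asarray(posteriors, dtype=float)
    single = p.ndim == 2
    if single:
        p = p[:, None, :]
    if p.ndim != 3 or p.shape[2] != 3:
        raise ValueError("posteriors must have shape (samples, markers, 3)")
    sums = p.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=atol):
        bad = np.argwhere(~np.isclose(sums, 1.0, atol=atol))[0]
        raise ValueError(
            f"posterior triple does not sum to 1 at sample {bad[0]}, marker {bad[1]}"
        )
    n = p.shape[0]
    e = p[:, :, 1] + 2.0 * p[:, :, 2]
    f = p[:, :, 1] + 4.0 * p[:, :, 2]
    theta = e.sum(axis=0) / (2.0 * n)
    denom = 2.0 * n * theta * (1.0 - theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        info = 1.0 - (f - e * e).sum(axis=0) / denom
    info = np.where((theta <= 0.0) | (theta >= 1.0), 1.0, info)
    info = np.clip(info, 0.0, 1.0)
    return float(info[0]) if single else info


@dataclass
class InfoScoreReport:
    """How well info scores predict per-marker concordance."""

    r_info_cr: float
    r_info_freq: float
    cutoff: float
    mean_cr_retained: float
    mean_cr_removed: float
    frac_calls_retained: float
    frac_low_cr_before: float  # fraction of markers with CR < 0.9
    frac_low_cr_after: float


def info_filter_evaluation(
    info: np.ndarray,
    per_snp: pd.DataFrame,
    cutoff: float,
    strict: bool = False,
    low_cr_threshold: float = 0.9,
) -> InfoScoreReport:
    """Evaluate an info-score hard filter against realized concordance.

    Retention is ``info >= cutoff`` (``>`` with ``strict``). Correlations
    and means are over markers with defined CR; the retained-call fraction
    weights markers by their compared-call counts.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    info = np.asarray(info, dtype=float)
    if len(info) != len(per_snp):
        raise ValueError("info scores and per-marker table are not aligned")
    cr = per_snp["cr"].to_numpy()
    freq = per_snp["truth_alt_freq"].to_numpy()
    n_calls = per_snp["n_compared"].to_numpy().astype(float)
    ok = ~np.isnan(cr)

    r_cr, _ = _masked_pearson(info[ok], cr[ok], np.ones(ok.sum(), bool), axis=0)
    okf = ok & ~np.isnan(freq)
    r_fq, _ = _masked_pearson(info[okf], freq[okf], np.ones(okf.sum(), bool), axis=0)

    retained = info > cutoff if strict else info >= cutoff
    ret, rem = retained & ok, ~retained & ok
    return InfoScoreReport(
        r_info_cr=float(r_cr),
        r_info_freq=float(r_fq),
        cutoff=cutoff,
        mean_cr_retained=float(cr[ret].mean()) if ret.any() else float("nan"),
        mean_cr_removed=float(cr[rem].mean()) if rem.any() else float("nan"),
        frac_calls_retained=float(n_calls[retained].sum() / n_calls.sum()),
        frac_low_cr_before=float((cr[ok] < low_cr_threshold).mean()),
        frac_low_cr_after=(
            float((cr[ret] < low_cr_threshold).mean()) if ret.any() else float("nan")
        ),
    )
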