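"""Genome scan for poorly imputed regions.

Per-marker concordance values are smoothed with a per-chromosome centered
running median (window in SNPs, shrinking at chromosome edges), markers in
the lowest tail of the genome-wide smoothed distribution are flagged by a
nearest-rank percentile cutoff, and flagged markers closer than a maximum
gap are merged into regions; regions with fewer than a minimum number of
flagged SNPs are discarded. A companion profile of accuracy versus
distance to the nearest chromosome end exposes telomere-proximal error
inflation.

Accuracy tracks are DataFrames with columns ``chrom``, ``pos``, ``value``
sorted by chromosome then position; region tables have columns ``chrom``,
``start``, ``end``, ``length`` (= end - start, closed 1-based interval
endpoints) and ``n_snps``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

TRACK_COLUMNS = ("chrom", "pos", "value")
REGION_COLUMNS = ("chrom", "start", "end", "length", "n_snps")


@dataclass(frozen=True)
class ScanParameters:
    """Tuning of the poorly-imputed-region scan.

    Defaults: 1001-SNP running-median window, the genome-wide 0.1th
    percentile as the flagging cutoff, regions split where flagged SNPs
    are more than 1 Mb apart, and at least 2 flagged SNPs per region.
    """

    window: int = 1001
    percentile: float = 0.1
    max_gap_bp: int = 1_000_000
    min_snps: int = 2

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be positive")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


def _check_track(track: pd.DataFrame) -> pd.DataFrame:
    for col in TRACK_COLUMNS:
        if col not in track.columns:
            raise ValueError(f"accuracy track missing column {col!r}")
    for _, grp in track.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) < 0):
            raise ValueError("accuracy track is not sorted by position")
    return track


def running_median(track: pd.DataFrame, window: int) -> pd.DataFrame:
    """Centered per-chromosome running median of the track values.

    The window shrinks at chromosome edges (a marker near the edge is
    smoothed over whatever neighbours exist); even-count edge windows take
    the midpoint of the two central values.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    _check_track(track)
    out = track.copy()
    out["value"] = (
        track.groupby("chrom", sort=False)["value"]
        .transform(
            lambda s: s.rolling(window, center=True, min_periods=1).median()
        )
        .to_numpy()
    )
    return out


def flag_low_snps(
    smoothed: pd.DataFrame, percentile: float
) -> tuple[float, pd.DataFrame]:
    """Flag markers at or below the genome-wide percentile cutoff.

    The cutoff is the nearest-rank empirical quantile of the smoothed
    values: the ceil(q * n)-th smallest value with q = percentile / 100.
    Flagging uses ``value <= cutoff``; with ties or a constant track this
    may flag more than q * n markers (documented degenerate behavior).
    """
    if len(smoothed) == 0:
        raise ValueError("empty accuracy track")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    values = np.sort(smoothed["value"].to_numpy())
    rank = max(1, math.ceil(percentile / 100.0 * len(values)))
    cutoff = float(values[rank - 1])
    flagged = smoothed[smoothed["value"] <= cutoff].reset_index(drop=True)
    return cutoff, flagged


def merge_regions(
    flagged: pd.DataFrame, params: ScanParameters = ScanParameters()
) -> pd.DataFrame:
    """Group flagged markers into regions by the maximum-gap rule.

    Within a chromosome, consecutive flagged markers join one region while
    their gap is at most ``max_gap_bp``; a strictly larger gap starts a
    new region. Regions with fewer than ``min_snps`` flagged markers are
    discarded. Start/end are the first/last flagged positions and
    ``length = end - start``.
    """
    rows = []
    for chrom, grp in flagged.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > params.max_gap_bp) + 1
        for seg in np.split(pos, breaks):
            if seg.size >= params.min_snps:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(seg[0]),
                        "end": int(seg[-1]),
                        "length": int(seg[-1] - seg[0]),
                        "n_snps": int(seg.size),
                    }
                )
    return pd.DataFrame(rows, columns=list(REGION_COLUMNS))


def per_chromosome_flag_counts(regions: pd.DataFrame) -> pd.Series:
    """Flagged-SNP totals per chromosome, ranked descending."""
    if len(regions) == 0:
        return pd.Series(dtype=np.int64, name="n_snps")
    return (
        regions.groupby("chrom")["n_snps"].sum().sort_values(ascending=False)
    )


def scan_regions(
    track: pd.DataFrame, params: ScanParameters = ScanParameters()
) -> tuple[float, pd.DataFrame, pd.DataFrame]:
    """Full scan: smooth, flag, merge. Returns (cutoff, flagged, regions)."""
    smoothed = running_median(track, params.window)
    cutoff, flagged = flag_low_snps(smoothed, params.percentile)
    return cutoff, flagged, merge_regions(flagged, params)


def end_distance_profile(
    track: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_width_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Mean track value binned by distance to the nearest chromosome end."""
    _check_track(track)
    chrom = track["chrom"].astype(str).to_numpy()
    pos = track["pos"].to_numpy()
    lengths = np.asarray([chrom_lengths[c] for c in chrom], dtype=np.int64)
    if (pos > lengths).any():
        j = int(np.argmax(pos > lengths))
        raise ValueError(
            f"position {pos[j]} exceeds stated length of chromosome {chrom[j]}"
        )
    dist = np.minimum(pos, lengths - pos)
    idx = dist // bin_width_bp
    frame = pd.DataFrame({"bin": idx, "value": track["value"].to_numpy()})
    agg = frame.groupby("bin")["value"].agg(["mean", "size"]).reset_index()
    agg["dist_low_bp"] = agg["bin"] * bin_width_bp
    agg["dist_high_bp"] = (agg["bin"] + 1) * bin_width_bp
    return agg.rename(columns={"mean": "mean_value", "size": "n_markers"})[
        ["dist_low_bp", "dist_high_bp", "mean_value", "n_markers"]
    ]


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """Convert a 1-based closed region table to 0-based half-open BED."""
    bed = regions[["chrom", "start", "end"]].copy()
    bed["start"] = bed["start"] - 1
    return bed


def load_reference_region_table() -> pd.DataFrame:
    """Published table of poorly imputed genomic regions in Hanwoo cattle.

    31 regions across 20 autosomes, produced by a 1001-SNP running-median
    scan at the 0.1th percentile with a 1 Mb merge rule on a real
    sequence-imputation evaluation. Shipped as a validation fixture: its
    internal consistency (length rule, merge-gap rule, per-chromosome
    flagged-SNP totals) is checked against this package's region
    machinery.
    """
    with resources.files("imputeval.data").joinpath(
        "hanwoo_poor_regions.tsv"
    ).open() as fh:
        t = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return t
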