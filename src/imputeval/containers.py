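"""Core in-memory containers for genotype panels.

Genotypes are stored as ALT-allele dosage (0, 1, 2) in a dense
samples x markers ``int8`` matrix; missing calls use the sentinel
:data:`MISSING`. Phase is never stored — every downstream metric is
genotype-level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing (or half-missing) genotype call.
MISSING: int = -1

#: The 29 cattle autosomes, the default chromosome universe.
CATTLE_AUTOSOMES: frozenset[str] = frozenset(str(c) for c in range(1, 30))

_VALID_ALLELES = {"A", "C", "G", "T"}


class MarkerMap:
    """Ordered table of biallelic SNP markers.

    Wraps a DataFrame with columns ``chrom`` (label), ``pos`` (1-based bp),
    ``id``, ``ref`` and ``alt`` (single bases, REF != ALT). Positions must be
    strictly increasing within each chromosome.
    """

    COLUMNS = ("chrom", "pos", "id", "ref", "alt")

    def __init__(self, table: pd.DataFrame, validate: bool = True) -> None:
        missing_cols = set(self.COLUMNS) - set(table.columns)
        if missing_cols:
            raise ValueError(f"marker map missing columns: {sorted(missing_cols)}")
        table = table.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        table["chrom"] = table["chrom"].astype(str)
        table["pos"] = table["pos"].astype(np.int64)
        self.table = table
        if validate:
            self._validate()

    def _validate(self) -> None:
        t = self.table
        bad = ~(t["ref"].isin(_VALID_ALLELES) & t["alt"].isin(_VALID_ALLELES))
        if bad.any():
            raise ValueError(
                f"non-ACGT allele at marker(s) {t.index[bad].tolist()[:5]}"
            )
        if (t["ref"] == t["alt"]).any():
            raise ValueError("marker with REF == ALT")
        for chrom, grp in t.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerMap):
            return NotImplemented
        return self.table.equals(other.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def ref(self) -> np.ndarray:
        return self.table["ref"].to_numpy()

    @property
    def alt(self) -> np.ndarray:
        return self.table["alt"].to_numpy()

    def key(self) -> pd.Index:
        """Chromosome+position key; errors on duplicates.

        Harmonization matches markers by this key, so it must be a
        bijection within a map.
        """
        idx = pd.MultiIndex.from_arrays([self.chrom, self.pos])
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate chrom+position {dup} in marker map")
        return idx

    def subset(self, marker_idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(marker_idx)], validate=False)


class GenotypeMatrix:
    """Samples x markers ALT-dosage call matrix with its marker map."""

    def __init__(
        self,
        samples: list[str],
        markers: MarkerMap,
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(markers)):
            raise ValueError(
                f"call matrix shape {calls.shape} != "
                f"({len(samples)} samples, {len(markers)} markers)"
            )
        valid = (calls == MISSING) | ((calls >= 0) & (calls <= 2))
        if not valid.all():
            raise ValueError("genotype calls must be 0, 1, 2 or the missing sentinel")
        self.samples = list(samples)
        self.markers = markers
        self.calls = calls

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def sample_missing_rate(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_samples)
        return self.missing_mask().mean(axis=1)

    def marker_missing_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_markers)
        return self.missing_mask().mean(axis=0)

    def alt_frequency(self) -> np.ndarray:
        """Per-marker ALT allele frequency over non-missing calls (NaN if none)."""
        obs = ~self.missing_mask()
        n = obs.sum(axis=0)
        dose = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dose / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def subset(
        self,
        sample_idx: np.ndarray | None = None,
        marker_idx: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        samples = self.samples
        markers = self.markers
        calls = self.calls
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            samples = [self.samples[i] for i in sample_idx]
            calls = calls[sample_idx, :]
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            markers = markers.subset(marker_idx)
            calls = calls[:, marker_idx]
        return GenotypeMatrix(samples, markers, calls.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PanelPair:
    """Truth and imputed panels harmonized to identical samples and markers."""

    truth: GenotypeMatrix
    imputed: GenotypeMatrix

    def __post_init__(self) -> None:
        if self.truth.samples != self.imputed.samples:
            raise ValueError("truth and imputed sample lists differ")
        if self.truth.markers != self.imputed.markers:
            raise ValueError("truth and imputed marker maps differ")

    @property
    def n_samples(self) -> int:
        return self.truth.n_samples

    @property
    def n_markers(self) -> int:
        return self.truth.n_markers

    def compared_mask(self) -> np.ndarray:
        """Cells non-missing in both panels (the comparison denominator)."""
        return ~(self.truth.missing_mask() | self.imputed.missing_mask())


@dataclass
class HaplotypeSet:
    """Binary haplotype matrix (haplotypes x markers) with its marker map."""

    haplotypes: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.markers):
            raise ValueError("haplotype matrix shape does not match marker map")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0 or 1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]
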