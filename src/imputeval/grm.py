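"""Genomic relationship matrices and their comparison.

GRMs use the VanRaden method-1 form: with dosage matrix M (samples x
markers) and ALT frequencies p, Z = M - 2p and G = Z Z' / (2 sum p(1-p))
over polymorphic markers. Missing calls are mean-imputed (to 2p) for this
computation only. Panels are compared by the elementwise sum of squared
deviations between their GRMs and by principal components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .containers import GenotypeMatrix


@dataclass
class GRM:
    """Symmetric sample x sample genomic relationship matrix."""

    values: np.ndarray
    samples: list[str]
    n_markers: int
    freq_source: str  # "panel" or "supplied"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("GRM dimension does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM is not symmetric")

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.values, columns=self.samples).to_csv(
            path, sep="\t", index=False
        )


def compute_grm(
    matrix: GenotypeMatrix, frequencies: np.ndarray | None = None
) -> GRM:
    """VanRaden method-1 GRM from a genotype panel.

    ``frequencies`` supplies external ALT frequencies (e.g. from the truth
    panel so that truth- and imputed-panel GRMs share a centering); by
    default the panel's own frequencies are used. Monomorphic markers are
    excluded from numerator and denominator.
    """
    if frequencies is None:
        p = matrix.alt_frequency()
        source = "panel"
    else:
        p = np.asarray(frequencies, dtype=float)
        if p.shape != (matrix.n_markers,):
            raise ValueError("supplied frequency vector length mismatch")
        source = "supplied"
    poly = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic markers for GRM computation")
    p = p[poly]
    calls = matrix.calls[:, poly].astype(float)
    miss = matrix.missing_mask()[:, poly]
    calls[miss] = np.broadcast_to(2.0 * p, calls.shape)[miss]
    z = calls - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    g = z @ z.T / denom
    return GRM(g, list(matrix.samples), int(poly.sum()), source)


def grm_ss_deviation(g1: GRM, g2: GRM) -> float:
    """Sum over all n^2 elements (diagonal included) of (g1 - g2)^2."""
    if g1.samples != g2.samples:
        raise ValueError("GRMs have different sample lists")
    d = g1.values - g2.values
    return float(np.sum(d * d))


def grm_pca(g: GRM, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k principal components of a GRM.

    Returns sample coordinates (eigenvectors scaled by sqrt(eigenvalue),
    negative eigenvalues truncated at 0) and the eigenvalues in
    non-increasing order.
    """
    n = len(g.samples)
    if k <= 0:
        raise ValueError("component count must be positive")
    if k > n:
        raise ValueError(f"k = {k} exceeds sample count {n}")
    vals, vecs = eigh(g.values)
    order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    frame = pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(k)]
    )
    frame.insert(0, "sample", g.samples)
    return frame, vals
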