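"""Synthetic genotype panels with controlled imputation-error structure.

The generator builds diploid biallelic autosomal panels in three stages:

1. founder haplotypes with per-marker ALT frequencies drawn from a
   U-shaped Beta spectrum (so every 0.01-wide frequency bin, including the
   rare-variant edges, is populated) and a configurable fraction of
   markers forced monomorphic;
2. descendant samples as haplotype mosaics of the founders with
   geometric segment lengths (per-marker switch rate), which creates LD
   and half-sib-like relatedness without a coalescent simulation;
3. an "imputed" panel derived from the truth by sampling each call from a
   3x3 genotype transition matrix whose off-diagonal mass can be modulated
   by minor-allele frequency, by planted low-accuracy regions, and by a
   gradient of extra error toward chromosome ends. The effective
   transition row used for each call is emitted as its genotype posterior,
   so info scores have exact, self-consistent inputs.

A deliberately naive reference-based imputer (nearest-haplotype copying
within marker windows) stands in for production imputation software in
end-to-end tests of reference-panel composition effects; its accuracy is
not calibrated to any real tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, HaplotypeSet, MarkerMap


@dataclass
class ErrorModel:
    """Genotype transition model driving error injection.

    ``transition[g, h]`` is the probability that a call with true genotype
    ``g`` is emitted as ``h``; rows sum to 1. Off-diagonal (error) mass is
    locally multiplied by ``1 + 2 * maf_slope * MAF`` (more error at
    intermediate frequencies when ``maf_slope > 0``), by the multiplier of
    any planted bad region containing the marker, and by
    ``1 + end_boost * (1 - d / end_range_bp)`` within ``end_range_bp`` of a
    chromosome end, then renormalized against the diagonal.
    """

    transition: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.985, 0.013, 0.002], [0.025, 0.95, 0.025], [0.002, 0.013, 0.985]]
        )
    )
    maf_slope: float = 0.0
    #: (chrom, start_bp, end_bp, off-diagonal multiplier), closed interval
    bad_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    end_boost: float = 0.0
    end_range_bp: float = 5_000_000.0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3")
        if (self.transition < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")

    @classmethod
    def identity(cls) -> "ErrorModel":
        return cls(transition=np.eye(3))

    def to_dict(self) -> dict:
        return {
            "transition": self.transition.tolist(),
            "maf_slope": self.maf_slope,
            "bad_regions": [list(r) for r in self.bad_regions],
            "end_boost": self.end_boost,
            "end_range_bp": self.end_range_bp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorModel":
        d = dict(d)
        if "bad_regions" in d:
            d["bad_regions"] = [
                (str(c), int(s), int(e), float(m)) for c, s, e, m in d["bad_regions"]
            ]
        return cls(**d)


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic truth/imputed panel pair."""

    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    markers_per_chrom: int = 2_000
    n_founder_haplotypes: int = 40
    n_samples: int = 100
    #: Beta(a, b) ALT-frequency spectrum; the U-shaped default keeps the
    #: edge frequency bins populated, as in real sequence data.
    af_beta: tuple[float, float] = (0.3, 0.3)
    switch_rate: float = 0.01
    mask_keep_fraction: float = 0.2
    error_model: ErrorModel = field(default_factory=ErrorModel)
    monomorphic_fraction: float = 0.10
    spurious_rate: float = 0.0
    spurious_freq_scale: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "chrom_length_bp",
            "markers_per_chrom",
            "n_founder_haplotypes",
            "n_samples",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "switch_rate",
            "mask_keep_fraction",
            "monomorphic_fraction",
            "spurious_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} {v} outside [0, 1]")
        a, b = self.af_beta
        if a <= 0 or b <= 0:
            raise ValueError("allele-frequency spectrum parameters must be positive")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["af_beta"] = list(self.af_beta)
        d["error_model"] = self.error_model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "af_beta" in d:
            d["af_beta"] = tuple(d["af_beta"])
        if "error_model" in d and isinstance(d["error_model"], dict):
            d["error_model"] = ErrorModel.from_dict(d["error_model"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)

    @property
    def chromosomes(self) -> list[str]:
        return [str(c) for c in range(1, self.n_chromosomes + 1)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chromosomes}


def _random_marker_map(config: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    rows = []
    bases = np.array(list("ACGT"))
    for chrom in config.chromosomes:
        pos = np.sort(
            rng.choice(
                np.arange(1, config.chrom_length_bp + 1),
                size=config.markers_per_chrom,
                replace=False,
            )
        )
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((chrom, int(p), f"snp_{chrom}_{p}", bases[ref], bases[alt]))
    return MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS)))


def simulate_founder_haplotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    markers: MarkerMap | None = None,
) -> HaplotypeSet:
    """Draw founder haplotypes from the configured frequency spectrum.

    Passing an existing ``markers`` map redraws frequencies on the same
    positions — an independently evolved (diverged) population for
    reference-panel composition experiments.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if markers is None:
        markers = _random_marker_map(config, rng)
    m = len(markers)
    a, b = config.af_beta
    freqs = rng.beta(a, b, size=m)
    mono = rng.random(m) < config.monomorphic_fraction
    freqs[mono] = rng.integers(0, 2, size=int(mono.sum())).astype(float)
    haps = (rng.random((config.n_founder_haplotypes, m)) < freqs).astype(np.int8)
    haps[:, mono] = freqs[mono].astype(np.int8)  # exact fixation, not sampling
    return HaplotypeSet(haplotypes=haps, markers=markers)


def _mosaic_origins(
    rng: np.random.Generator, n_haps: int, n_founders: int, m: int, switch_rate: float
) -> np.ndarray:
    """Founder index mosaics: switch to a different founder w.p. switch_rate."""
    origins = np.empty((n_haps, m), dtype=np.int64)
    origins[:, 0] = rng.integers(n_founders, size=n_haps)
    if m == 1:
        return origins
    switch = rng.random((n_haps, m - 1)) < switch_rate
    # draw "next founder" as an offset 1..K-1 from the current one (mod K)
    # so every switch changes the founder index
    offsets = rng.integers(1, max(n_founders, 2), size=(n_haps, m - 1))
    for j in range(1, m):
        prev = origins[:, j - 1]
        origins[:, j] = np.where(
            switch[:, j - 1], (prev + offsets[:, j - 1]) % n_founders, prev
        )
    return origins


def simulate_descendants(
    founders: HaplotypeSet,
    n_samples: int,
    switch_rate: float,
    seed: int | np.random.Generator,
    return_origins: bool = False,
):
    """Build descendant samples as founder-haplotype mosaics.

    Each of the ``2 * n_samples`` descendant haplotypes copies founder
    alleles along a mosaic with geometric segment lengths; the genotype is
    the sum of a sample's two haplotypes. With ``return_origins`` the
    founder-index mosaic is returned as a third element.
    """
    if founders.n_haplotypes == 0:
        raise ValueError("founder set is empty")
    if not 0 <= switch_rate <= 1:
        raise ValueError(f"switch_rate {switch_rate} outside [0, 1]")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    m = len(founders.markers)
    origins = _mosaic_origins(
        rng, 2 * n_samples, founders.n_haplotypes, m, switch_rate
    )
    haps = founders.haplotypes[origins, np.arange(m)[None, :]]
    hapset = HaplotypeSet(haplotypes=haps, markers=founders.markers)
    calls = (haps[0::2] + haps[1::2]).astype(np.int8)
    gm = GenotypeMatrix(
        [f"s{i}" for i in range(n_samples)], founders.markers, calls
    )
    if return_origins:
        return gm, hapset, origins
    return gm, hapset


def mask_to_density(
    truth: GenotypeMatrix, keep_fraction: float, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Retain a uniform random, order-preserving marker subset.

    The retained count is deterministic, ``round(m * keep_fraction)``;
    which markers survive is random. Masks compose, emulating nested
    low-density / high-density / sequence marker panels.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError(f"keep_fraction {keep_fraction} outside (0, 1]")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n_keep = int(round(truth.n_markers * keep_fraction))
    if n_keep == 0:
        raise ValueError("keep_fraction retains zero markers")
    idx = np.sort(rng.choice(truth.n_markers, size=n_keep, replace=False))
    return truth.subset(marker_idx=idx)


def _off_diagonal_factors(
    markers: MarkerMap,
    maf: np.ndarray,
    model: ErrorModel,
    chrom_lengths: dict[str, int],
) -> np.ndarray:
    """Per-marker multiplier on the transition matrix's off-diagonal mass."""
    m = len(markers)
    factor = np.ones(m)
    if model.maf_slope != 0.0:
        factor *= 1.0 + 2.0 * model.maf_slope * np.nan_to_num(maf)
    chrom = markers.chrom
    pos = markers.pos
    for reg_chrom, start, end, mult in model.bad_regions:
        reg_chrom = str(reg_chrom)
        if reg_chrom not in chrom_lengths:
            raise ValueError(f"planted region on unknown chromosome {reg_chrom}")
        if not 1 <= start <= end <= chrom_lengths[reg_chrom]:
            raise ValueError(
                f"planted region {reg_chrom}:{start}-{end} outside chromosome"
            )
        inside = (chrom == reg_chrom) & (pos >= start) & (pos <= end)
        factor[inside] *= mult
    if model.end_boost != 0.0:
        lengths = np.asarray([chrom_lengths[c] for c in chrom], dtype=float)
        dist = np.minimum(pos, lengths - pos)
        ramp = np.clip(1.0 - dist / model.end_range_bp, 0.0, None)
        factor *= 1.0 + model.end_boost * ramp
    return factor


def effective_transition_rows(
    markers: MarkerMap,
    maf: np.ndarray,
    model: ErrorModel,
    chrom_lengths: dict[str, int],
) -> np.ndarray:
    """Locally modified transition matrix per marker, shape (m, 3, 3).

    Off-diagonal entries are scaled by the combined MAF/region/end factor
    and the diagonal takes the remaining mass; if the scaled error mass
    exceeds 1 it is renormalized to 1 and the diagonal floors at 0.
    """
    factor = _off_diagonal_factors(markers, maf, model, chrom_lengths)
    base = model.transition
    off = base * (1.0 - np.eye(3))
    rows = off[None, :, :] * factor[:, None, None]
    row_err = rows.sum(axis=2)  # (m, 3)
    over = row_err > 1.0
    if over.any():
        scale = np.where(over, 1.0 / np.where(row_err > 0, row_err, 1.0), 1.0)
        rows *= scale[:, :, None]
        row_err = np.minimum(row_err, 1.0)
    diag = 1.0 - row_err
    rows[:, np.arange(3), np.arange(3)] = diag
    return rows


def inject_errors(
    truth: GenotypeMatrix,
    model: ErrorModel,
    seed: int | np.random.Generator,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Sample an error-injected panel from the transition model.

    Returns the emitted panel and a samples x markers x 3 posterior tensor
    holding, for every call, the effective transition row it was sampled
    from (missing calls stay missing and carry a uniform posterior row).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(p.max())
            for c, p in truth.markers.table.groupby("chrom", sort=False)["pos"]
        }
    rows = effective_transition_rows(
        truth.markers, truth.maf(), model, chrom_lengths
    )
    calls = truth.calls
    miss = calls == MISSING
    g = np.where(miss, 0, calls)
    cell_rows = rows[np.arange(truth.n_markers)[None, :], g]  # (n, m, 3)
    cum = np.cumsum(cell_rows, axis=2)
    u = rng.random(calls.shape)
    emitted = (u[:, :, None] > cum).sum(axis=2).astype(np.int8)
    emitted[miss] = MISSING
    posteriors = cell_rows.copy()
    posteriors[miss] = 1.0 / 3.0
    out = GenotypeMatrix(truth.samples, truth.markers, emitted)
    return out, posteriors


def inject_spurious_segregation(
    imputed: GenotypeMatrix,
    truth: GenotypeMatrix,
    rate: float,
    freq_scale: float,
    seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Make a fraction of truth-monomorphic markers spuriously segregate.

    Each affected marker (chosen w.p. ``rate`` among markers with truth
    MAF exactly 0) receives at least one wrong minor allele; the number of
    wrong alleles is Binomial(2N, f) with f drawn from an exponential of
    mean ``freq_scale``, so the mean imputed MAF of affected markers is
    close to ``freq_scale``.
    """
    if not 0 <= rate <= 1:
        raise ValueError(f"rate {rate} outside [0, 1]")
    if freq_scale <= 0:
        raise ValueError("freq_scale must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    maf = truth.maf()
    mono = np.flatnonzero(maf == 0.0)
    out = imputed.calls.copy()
    n = imputed.n_samples
    fixed_allele = truth.alt_frequency()  # 0.0 or 1.0 on the monomorphic set
    for j in mono:
        if rng.random() >= rate:
            continue
        f = min(rng.exponential(freq_scale), 0.5)
        k = max(1, rng.binomial(2 * n, f))
        k = min(k, 2 * n)
        slots = rng.choice(2 * n, size=k, replace=False)
        counts = np.bincount(slots // 2, minlength=n).astype(np.int8)
        if fixed_allele[j] == 0.0:
            out[:, j] = np.minimum(out[:, j] + counts, 2)
        else:
            out[:, j] = np.maximum(out[:, j] - counts, 0)
    return GenotypeMatrix(imputed.samples, imputed.markers, out)


def _haplotype_genotype_penalty(haps: np.ndarray, geno: np.ndarray) -> np.ndarray:
    """Mismatch count of each haplotype against one genotype vector.

    A haplotype allele is incompatible only with the opposite homozygote;
    heterozygotes accept either allele.
    """
    hom_ref = geno == 0
    hom_alt = geno == 2
    return (haps[:, hom_ref] == 1).sum(axis=1) + (haps[:, hom_alt] == 0).sum(axis=1)


def naive_reference_imputer(
    target: GenotypeMatrix,
    reference: HaplotypeSet,
    window: int = 100,
) -> GenotypeMatrix:
    """Impute a low-density panel up to the reference marker density.

    Within each window of ``window`` consecutive reference markers the two
    reference haplotypes best matching a sample's observed genotypes are
    chosen greedily (first haplotype by compatibility with the genotype
    calls, second by residual dosage distance) and unobserved markers are
    copied from that diplotype. A transparent stand-in for production
    haplotype-copying imputation software.
    """
    if window < 2:
        raise ValueError("window must cover at least 2 markers")
    ref_key = reference.markers.key()
    tgt_key = target.markers.key()
    if not tgt_key.isin(ref_key).all():
        raise ValueError("target markers are not a subset of the reference markers")
    lookup = {k: j for j, k in enumerate(ref_key)}
    obs_ref_idx = np.asarray([lookup[k] for k in tgt_key])

    m_ref = len(reference.markers)
    n = target.n_samples
    out = np.empty((n, m_ref), dtype=np.int8)
    obs_in_window_of = np.full(m_ref, -1, dtype=np.int64)

    # windows never span chromosomes
    chrom = reference.markers.chrom
    boundaries = [0]
    for j in range(1, m_ref):
        if chrom[j] != chrom[j - 1]:
            boundaries.append(j)
    boundaries.append(m_ref)

    haps = reference.haplotypes
    for c0, c1 in zip(boundaries[:-1], boundaries[1:]):
        for w0 in range(c0, c1, window):
            w1 = min(w0 + window, c1)
            in_win = (obs_ref_idx >= w0) & (obs_ref_idx < w1)
            obs_t = np.flatnonzero(in_win)  # target-marker indices
            obs_r = obs_ref_idx[obs_t]
            for i in range(n):
                geno = target.calls[i, obs_t]
                seen = geno != MISSING
                if seen.any():
                    sub = haps[:, obs_r[seen]]
                    g = geno[seen]
                    h1 = int(np.argmin(_haplotype_genotype_penalty(sub, g)))
                    resid = np.abs(g - haps[h1, obs_r[seen]] - sub).sum(axis=1)
                    h2 = int(np.argmin(resid))
                else:
                    # no observed markers in this window: copy the first
                    # diplotype (documented degenerate behavior)
                    h1, h2 = 0, min(1, haps.shape[0] - 1)
                out[i, w0:w1] = haps[h1, w0:w1] + haps[h2, w0:w1]
    # observed target calls are preserved verbatim where non-missing
    tgt_calls = target.calls
    seen = tgt_calls != MISSING
    for t_idx, r_idx in enumerate(obs_ref_idx):
        col = tgt_calls[:, t_idx]
        keep = col != MISSING
        out[keep, r_idx] = col[keep]
    return GenotypeMatrix(target.samples, reference.markers, out)


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    founders: HaplotypeSet
    truth: GenotypeMatrix
    sample_haplotypes: HaplotypeSet
    masked: GenotypeMatrix
    imputed: GenotypeMatrix
    posteriors: np.ndarray


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: founders -> samples -> mask -> errors.

    All randomness flows from ``config.seed`` through a single generator,
    so a fixed config is byte-identical across runs.
    """
    rng = np.random.default_rng(config.seed)
    founders = simulate_founder_haplotypes(config, rng=rng)
    truth, sample_haps = simulate_descendants(
        founders, config.n_samples, config.switch_rate, rng
    )
    masked = mask_to_density(truth, config.mask_keep_fraction, rng)
    imputed, posteriors = inject_errors(
        truth, config.error_model, rng, chrom_lengths=config.chrom_lengths
    )
    if config.spurious_rate > 0:
        imputed = inject_spurious_segregation(
            imputed, truth, config.spurious_rate, config.spurious_freq_scale, rng
        )
    return SimulatedDataset(
        config=config,
        founders=founders,
        truth=truth,
        sample_haplotypes=sample_haps,
        masked=masked,
        imputed=imputed,
        posteriors=posteriors,
    )
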