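import numpy as np
import pandas as pd
import pytest

from imputeval.containers import GenotypeMatrix, MarkerMap, PanelPair


def make_marker_map(n, chrom="1", start=1000, step=1000, ref="A", alt="G"):
    """Evenly spaced single-chromosome marker map."""
    rows = [
        (chrom, start + i * step, f"m{i}", ref, alt) for i in range(n)
    ]
    return MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS)))


def make_matrix(calls, markers=None, samples=None, **map_kwargs):
    """GenotypeMatrix from a nested list / array of dosages."""
    calls = np.asarray(calls, dtype=np.int8)
    if markers is None:
        markers = make_marker_map(calls.shape[1], **map_kwargs)
    if samples is None:
        samples = [f"s{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(samples, markers, calls)


def make_pair(truth_calls, imputed_calls, **kwargs):
    truth = make_matrix(truth_calls, **kwargs)
    imputed = GenotypeMatrix(truth.samples, truth.markers, np.asarray(imputed_calls))
    return PanelPair(truth=truth, imputed=imputed)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated dataset reused by read-only tests."""
    from imputeval.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        n_chromosomes=2,
        markers_per_chrom=1500,
        n_samples=60,
        n_founder_haplotypes=30,
        seed=7,
    )
    return simulate_dataset(cfg)
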