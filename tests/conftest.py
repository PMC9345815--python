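import numpy as np
import pandas as pd
import pytest

from fiebin.binning import IntensityMatrix, bin_name, coarse_key, fine_key
from fiebin.io import ScanEvent, assign_cycle_ordinals
from fiebin.simulate import SimSpec, simulate_scans


def make_run(tics, polarity="positive", scan_range=(50.0, 1000.0), sample="s1", mz=100.0):
    """Build a single-filter run whose per-scan TICs are ``tics``.

    Each scan holds one peak at ``mz`` carrying the whole TIC (or no
    peaks for a zero TIC).
    """
    scans = []
    for i, tic in enumerate(tics, start=1):
        peaks = ([mz], [float(tic)]) if tic > 0 else ([], [])
        scans.append(
            ScanEvent(sample, i, polarity, scan_range, np.array(peaks[0]), np.array(peaks[1]))
        )
    return assign_cycle_ordinals(scans)


def make_matrix(values: pd.DataFrame, width=0.01) -> IntensityMatrix:
    """Wrap a samples x bins DataFrame in an IntensityMatrix with stub metadata."""
    bin_table = pd.DataFrame(
        {
            "polarity": ["positive"] * values.shape[1],
            "center": np.arange(values.shape[1], dtype=float) + 100.0,
            "accurate_mz": np.arange(values.shape[1], dtype=float) + 100.0,
            "purity": 1.0,
            "centrality": 1.0,
            "occupancy": (values.gt(0).mean(axis=0)).to_numpy(),
        },
        index=values.columns,
    )
    values = values.copy()
    values.index.name = "sample"
    return IntensityMatrix(values, bin_table, width)


@pytest.fixture(scope="session")
def small_spec():
    """A quick two-sample simulation used by several suites."""
    return SimSpec(n_samples=2, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_spec):
    return simulate_scans(small_spec)
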