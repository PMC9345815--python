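"""Synthetic flow-infusion runs with known ground truth.

The generator emulates what the binning method actually consumes: a
multi-scan infusion per sample whose TIC follows a unimodal trapezoid
envelope (linear rise, plateau, linear fall — the instrument's true
gradient shape does not matter, only its supra-threshold support), a
set of compounds that appear in every scan of their ionisation mode
with small per-scan multiplicative m/z jitter (ppm-scaled, the way
Orbitrap calibration drifts), per-scan abundance noise, and random
single-scan noise peaks at uniform m/z.  Noise abundances are drawn
log-uniformly over the two decades below the smallest compound
abundance so noise never perturbs plug-flow detection.

Everything is deterministic given the spec's seed; a run can be kept in
memory for tests or written out as standard mzML plus a ground-truth
CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adducts import adduct_mz, monoisotopic_mass, rule as adduct_rule
from .io import Polarity, ScanEvent, ScanFilter, assign_cycle_ordinals, write_mzml

__all__ = [
    "SimCompound",
    "SimSpec",
    "STANDARD_MIX",
    "example_compounds",
    "envelope",
    "expected_window",
    "simulate_scans",
    "simulate_run",
]


@dataclass(frozen=True)
class SimCompound:
    """A ground-truth ion: observed m/z, ionisation mode, peak abundance."""

    name: str
    mz: float
    polarity: Polarity
    abundance: float
    formula: str = ""


# A small mix of common metabolites used as the default simulation input.
# Amines/zwitterions are simulated as [M+H]1+ ions, organic acids and
# sugars as [M-H]1- ions.  Abundances span two orders of magnitude.
STANDARD_MIX: tuple[tuple[str, str, Polarity, float], ...] = (
    ("glycine", "C2H5NO2", "positive", 8.0e5),
    ("alanine", "C3H7NO2", "positive", 2.5e6),
    ("serine", "C3H7NO3", "positive", 1.2e6),
    ("proline", "C5H9NO2", "positive", 4.0e6),
    ("valine", "C5H11NO2", "positive", 3.0e6),
    ("threonine", "C4H9NO3", "positive", 9.0e5),
    ("leucine", "C6H13NO2", "positive", 5.0e6),
    ("asparagine", "C4H8N2O3", "positive", 6.0e5),
    ("glutamine", "C5H10N2O3", "positive", 1.8e6),
    ("lysine", "C6H14N2O2", "positive", 1.4e6),
    ("methionine", "C5H11NO2S", "positive", 7.0e5),
    ("histidine", "C6H9N3O2", "positive", 1.1e6),
    ("phenylalanine", "C9H11NO2", "positive", 2.2e6),
    ("arginine", "C6H14N4O2", "positive", 1.6e6),
    ("tyrosine", "C9H11NO3", "positive", 9.5e5),
    ("tryptophan", "C11H12N2O2", "positive", 8.5e5),
    ("creatinine", "C4H7N3O", "positive", 3.5e6),
    ("carnitine", "C7H15NO3", "positive", 2.8e6),
    ("lactic acid", "C3H6O3", "negative", 4.5e6),
    ("pyruvic acid", "C3H4O3", "negative", 6.5e5),
    ("fumaric acid", "C4H4O4", "negative", 1.3e6),
    ("succinic acid", "C4H6O4", "negative", 2.0e6),
    ("malic acid", "C4H6O5", "negative", 2.4e6),
    ("citric acid", "C6H8O7", "negative", 3.2e6),
    ("glucose", "C6H12O6", "negative", 5.5e6),
)


def example_compounds(n: int = 20) -> list[SimCompound]:
    """The first ``n`` standard-mix compounds with exact theoretical m/z.

    The true m/z of each compound is the theoretical [M+H]1+ or [M-H]1-
    m/z computed from its molecular formula, so a simulated run can be
    matched back against predicted ionisation products.
    """
    if not 1 <= n <= len(STANDARD_MIX):
        raise ValueError(f"n must be in 1..{len(STANDARD_MIX)}")
    out = []
    for name, formula, polarity, abundance in STANDARD_MIX[:n]:
        r = adduct_rule("[M+H]1+" if polarity == "positive" else "[M-H]1-")
        mz = adduct_mz(monoisotopic_mass(formula), r)
        out.append(SimCompound(name, mz, polarity, abundance, formula))
    return out


_DEFAULT_FILTERS = (
    ScanFilter("negative", (55.0, 280.0)),
    ScanFilter("negative", (270.0, 1200.0)),
    ScanFilter("positive", (55.0, 280.0)),
    ScanFilter("positive", (270.0, 1200.0)),
)


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a simulated sample set.

    Defaults emulate a standards-mix acquisition: 10 replicate
    injections, two polarities x two overlapping acquisition ranges
    (55-280 and 270-1200 m/z), a trapezoid infusion envelope (7-scan
    rise, 10-scan plateau, 11-scan fall within 32 scans per filter),
    2 ppm per-scan m/z jitter, 10% between-scan abundance variation and
    on average two random single-scan noise peaks per scan.  The rise
    and fall lengths are odd so no scan sits exactly at half maximum.
    """

    compounds: tuple[SimCompound, ...] = field(
        default_factory=lambda: tuple(example_compounds(20))
    )
    n_samples: int = 10
    filters: tuple[ScanFilter, ...] = _DEFAULT_FILTERS
    scans_per_filter: int = 32
    rise: int = 7
    plateau: int = 10
    fall: int = 11
    mz_jitter_ppm: float = 2.0
    mz_jitter_da: float = 0.0
    noise_events_per_scan: float = 2.0
    abundance_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.scans_per_filter < 1 or not self.compounds:
            raise ValueError("counts must be >= 1 and compounds non-empty")
        if min(self.rise, self.plateau, self.fall) < 1:
            raise ValueError("envelope phases must each span at least one scan")
        if self.mz_jitter_ppm < 0 or self.mz_jitter_da < 0:
            raise ValueError("jitter must be non-negative")
        for c in self.compounds:
            if not any(
                f.polarity == c.polarity and f.scan_range[0] <= c.mz <= f.scan_range[1]
                for f in self.filters
            ):
                raise ValueError(
                    f"compound {c.name!r} at m/z {c.mz} falls outside every "
                    f"{c.polarity} acquisition range"
                )


def envelope(spec: SimSpec, cycle: int) -> float:
    """Infusion envelope value (0..1) at a 1-based cycle ordinal."""
    r, p, f = spec.rise, spec.plateau, spec.fall
    if cycle <= r:
        return cycle / r
    if cycle <= r + p:
        return 1.0
    j = cycle - r - p
    if j < f:
        return (f - j) / f
    return 0.0


def expected_window(spec: SimSpec, fraction: float = 0.5) -> tuple[int, int]:
    """Analytic supra-threshold scan window of the trapezoid envelope."""
    cycles = [
        i
        for i in range(1, spec.scans_per_filter + 1)
        if envelope(spec, i) > fraction
    ]
    return (min(cycles), max(cycles))


def _sample_ids(spec: SimSpec) -> list[str]:
    return [f"sample_{i + 1:02d}" for i in range(spec.n_samples)]


def simulate_scans(
    spec: SimSpec,
) -> tuple[dict[str, list[ScanEvent]], pd.DataFrame]:
    """Generate a sample set in memory.

    Returns
    -------
    runs : dict of sample id -> scans (cycle ordinals assigned)
    ground_truth : DataFrame
        One row per injected compound (``kind == "compound"``, applying
        to every sample) and one per random noise event
        (``kind == "noise"`` with its sample, cycle and filter range).
    """
    rng = np.random.default_rng(spec.seed)
    min_abundance = min(c.abundance for c in spec.compounds)
    truth_rows: list[dict] = [
        {
            "kind": "compound",
            "name": c.name,
            "formula": c.formula,
            "sample": "",
            "polarity": c.polarity,
            "cycle": -1,
            "range_low": np.nan,
            "range_high": np.nan,
            "mz": c.mz,
            "abundance": c.abundance,
        }
        for c in spec.compounds
    ]
    runs: dict[str, list[ScanEvent]] = {}
    for sample in _sample_ids(spec):
        scans: list[ScanEvent] = []
        index = 0
        for cycle in range(1, spec.scans_per_filter + 1):
            level = envelope(spec, cycle)
            for filt in spec.filters:
                low, high = filt.scan_range
                mzs: list[float] = []
                intensities: list[float] = []
                for c in spec.compounds:
                    if c.polarity != filt.polarity or not low <= c.mz <= high:
                        continue
                    if level <= 0:
                        continue
                    mz = c.mz * (1 + rng.normal(0, spec.mz_jitter_ppm * 1e-6))
                    if spec.mz_jitter_da:
                        mz += rng.normal(0, spec.mz_jitter_da)
                    ab = c.abundance * level * (1 + rng.normal(0, spec.abundance_cv))
                    mzs.append(min(max(mz, low), high))
                    intensities.append(max(ab, 1.0))
                n_noise = rng.poisson(spec.noise_events_per_scan)
                for _ in range(n_noise):
                    mz = rng.uniform(low, high)
                    ab = 10 ** rng.uniform(
                        np.log10(min_abundance) - 2, np.log10(min_abundance)
                    )
                    mzs.append(mz)
                    intensities.append(ab)
                    truth_rows.append(
                        {
                            "kind": "noise",
                            "name": "",
                            "formula": "",
                            "sample": sample,
                            "polarity": filt.polarity,
                            "cycle": cycle,
                            "range_low": low,
                            "range_high": high,
                            "mz": mz,
                            "abundance": ab,
                        }
                    )
                index += 1
                scans.append(
                    ScanEvent(
                        sample_id=sample,
                        scan_index=index,
                        polarity=filt.polarity,
                        scan_range=filt.scan_range,
                        mz=np.array(mzs),
                        intensity=np.array(intensities),
                    )
                )
        runs[sample] = assign_cycle_ordinals(scans)
    return runs, pd.DataFrame(truth_rows)


def simulate_run(
    spec: SimSpec, out_dir: str | os.PathLike
) -> tuple[list[str], pd.DataFrame]:
    """Write a simulated sample set to disk as mzML files.

    Creates ``<out_dir>/<sample>.mzML`` per sample plus
    ``ground_truth.csv`` and a ``sample_info.csv`` (all samples in one
    class, no QC flags).  Returns the mzML paths and the ground truth.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    runs, truth = simulate_scans(spec)
    paths = []
    for sample, scans in runs.items():
        path = os.path.join(out_dir, f"{sample}.mzML")
        write_mzml(path, scans)
        paths.append(path)
    truth.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
    pd.DataFrame(
        {
            "file": [os.path.basename(p) for p in paths],
            "class": "S",
            "qc": 0,
        }
    ).to_csv(os.path.join(out_dir, "sample_info.csv"), index=False)
    return paths, truth
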