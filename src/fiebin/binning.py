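"""The core spectral-binning pipeline.

Processing of a flow-infusion sample set runs, per ionisation mode:

1. every scan's peaks are binned to 0.00001 amu ("fine" bins) by
   rounding m/z to five decimal places and sum-aggregating abundances;
2. where a polarity was acquired with several overlapping scan ranges,
   the per-cycle fine spectra of those ranges are merged, averaging the
   abundance of any m/z present in more than one range;
3. fine bins are grouped onto a coarser grid (default 0.01 amu) by the
   same rounding rule;
4. coarse bins containing only a single fine m/z that appeared in one
   single scan of one sample across the whole set are removed (random
   single-scan noise);
5. abundances are averaged across the plug-flow scans (a scan where the
   bin is absent contributes zero);
6. each surviving coarse bin is assigned an *accurate m/z*: the modal
   fine m/z among its pooled occurrences;
7. the per-sample averages are assembled into a samples x bins intensity
   matrix with per-bin purity, centrality and occupancy metadata.

Grid assignment uses round-half-away-from-zero at both precisions,
implemented in decimal-scaled integer arithmetic: a fine bin is an
integer key in units of 1e-5 Da, and coarse keys are derived from fine
keys by exact integer rounding.  This keeps the half-way cases (e.g.
133.01500 at width 0.01 -> 133.02) independent of binary-float
representation and makes bin identity hashable and stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .infusion import InfusionWindow, TicProfile, averaged_tic_profile, detect_plug_flow
from .io import Polarity, ScanEvent, ScanFilter
from .metrics import compute_bin_stats

__all__ = [
    "SUPPORTED_WIDTHS",
    "FINE_DECIMALS",
    "FineBin",
    "CoarseBin",
    "IntensityMatrix",
    "fine_key",
    "fine_keys",
    "coarse_key",
    "coarse_center",
    "bin_name",
    "width_decimals",
    "fine_bin_scan",
    "merge_scan_ranges",
    "coarse_bin",
    "remove_single_scan_events",
    "average_over_window",
    "assign_accurate_mz",
    "build_intensity_matrix",
    "bin_sample_set",
]

FINE_DECIMALS = 5
FINE_SCALE = 10**FINE_DECIMALS

#: Supported coarse bin widths (amu) -> decimal places of the grid.
SUPPORTED_WIDTHS: dict[float, int] = {1.0: 0, 0.1: 1, 0.01: 2, 0.001: 3, 0.0001: 4}


def width_decimals(width: float) -> int:
    """Decimal places of the grid for a supported bin width."""
    for w, d in SUPPORTED_WIDTHS.items():
        if abs(width - w) <= 1e-9 * w:
            return d
    raise ValueError(
        f"unsupported bin width {width!r}; choose one of {sorted(SUPPORTED_WIDTHS)}"
    )


def fine_key(mz: float) -> int:
    """Round an m/z to the 0.00001 amu grid, returning the scaled integer key.

    Half-way cases round away from zero, evaluated on the shortest
    decimal representation of the float to dodge binary half-case
    artifacts (133.015 scales to 13301500, not 13301499...).
    """
    return int(
        Decimal(repr(float(mz))).scaleb(FINE_DECIMALS).quantize(Decimal(1), ROUND_HALF_UP)
    )


def fine_keys(mz: Iterable[float]) -> np.ndarray:
    """Vectorised :func:`fine_key`."""
    return np.array([fine_key(m) for m in np.asarray(mz, dtype=float)], dtype=np.int64)


def coarse_key(fine: int, width: float) -> int:
    """Map a fine key onto the coarse grid index for ``width``.

    Exact integer round-half-away-from-zero (fine keys are positive).
    """
    div = 10 ** (FINE_DECIMALS - width_decimals(width))
    return (fine + div // 2) // div


def coarse_center(key: int, width: float) -> float:
    """Bin-window centre (Da) of a coarse grid index."""
    return key / 10 ** width_decimals(width)


def bin_name(polarity: Polarity, key: int, width: float) -> str:
    """Polarity-prefixed bin label, e.g. ``n133.01`` for negative mode.

    Formatted from the integer grid index so the label is exact at the
    grid precision.
    """
    d = width_decimals(width)
    prefix = "p" if polarity == "positive" else "n"
    if d == 0:
        return f"{prefix}{key}"
    return f"{prefix}{key // 10**d}.{key % 10**d:0{d}d}"


@dataclass(frozen=True)
class FineBin:
    """One 0.00001 amu bin of one scan: integer grid key and summed abundance."""

    key: int
    intensity: float

    @property
    def mz(self) -> float:
        return self.key / FINE_SCALE


@dataclass(frozen=True)
class CoarseBin:
    """A coarse bin of one scan with its constituent fine bins."""

    key: int
    width: float
    members: tuple[FineBin, ...]

    @property
    def center(self) -> float:
        return coarse_center(self.key, self.width)

    @property
    def intensity(self) -> float:
        return sum(m.intensity for m in self.members)


def fine_bin_scan(scan: ScanEvent) -> list[FineBin]:
    """Bin one scan to the 0.00001 amu grid.

    m/z are rounded to five decimal places and abundances sum-aggregated
    within each resulting bin.  Returns fine bins sorted ascending;
    empty scans give an empty list.  Zero-intensity peaks are dropped.
    """
    if scan.mz.size == 0:
        return []
    keys = fine_keys(scan.mz)
    agg: dict[int, float] = {}
    for k, a in zip(keys.tolist(), scan.intensity.tolist()):
        agg[k] = agg.get(k, 0.0) + a
    return [FineBin(k, agg[k]) for k in sorted(agg) if agg[k] > 0]


def merge_scan_ranges(
    per_filter: Mapping[ScanFilter, Sequence[FineBin]],
) -> list[FineBin]:
    """Combine the fine spectra of one instrument cycle across scan ranges.

    For acquisitions with several (overlapping) m/z ranges per polarity,
    an m/z present in *k* ranges gets the mean of its *k* abundances; an
    m/z present in a single range keeps its abundance.  All inputs must
    share a polarity.
    """
    polarities = {f.polarity for f in per_filter}
    if len(polarities) > 1:
        raise ValueError("cannot merge scan ranges across ionisation modes")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for bins in per_filter.values():
        for b in bins:
            sums[b.key] = sums.get(b.key, 0.0) + b.intensity
            counts[b.key] = counts.get(b.key, 0) + 1
    return [FineBin(k, sums[k] / counts[k]) for k in sorted(sums)]


def coarse_bin(fine: Sequence[FineBin], width: float) -> list[CoarseBin]:
    """Group a fine spectrum onto the coarse grid for ``width``.

    Fine bins are assigned by rounding their m/z to the grid precision;
    member fine bins are retained for the purity/centrality metrics and
    the accurate-m/z assignment.  Returns coarse bins sorted by key.
    """
    width_decimals(width)  # validate early
    groups: dict[int, list[FineBin]] = {}
    for b in fine:
        groups.setdefault(coarse_key(b.key, width), []).append(b)
    return [CoarseBin(k, width, tuple(groups[k])) for k in sorted(groups)]


# ---------------------------------------------------------------------------
# Sample-set level processing over an occurrence table.
#
# The backbone is a pandas DataFrame with one row per fine-bin occurrence
# (one fine bin in one merged scan of one sample):
#   sample (str), polarity (str), cycle (int), fine_key (int64),
#   intensity (float), coarse_key (int64)

OCCURRENCE_COLUMNS = ["sample", "polarity", "cycle", "fine_key", "intensity", "coarse_key"]


def _occurrence_table(
    runs: Mapping[str, Sequence[ScanEvent]],
    windows: Mapping[str, InfusionWindow],
    width: float,
) -> pd.DataFrame:
    rows: list[tuple] = []
    for sample, scans in runs.items():
        window = windows[sample]
        cycles: dict[tuple[Polarity, int], dict[ScanFilter, list[FineBin]]] = {}
        for scan in scans:
            if scan.cycle not in window:
                continue
            cycles.setdefault((scan.polarity, scan.cycle), {})[scan.filter] = (
                fine_bin_scan(scan)
            )
        for (polarity, cycle), per_filter in cycles.items():
            for b in merge_scan_ranges(per_filter):
                rows.append(
                    (sample, polarity, cycle, b.key, b.intensity, coarse_key(b.key, width))
                )
    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)


def remove_single_scan_events(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Drop coarse bins that are a lone fine m/z in one scan of one sample.

    This is a sample-set-level filter: a coarse bin (per polarity and
    grid index) is deleted everywhere iff, pooled over all samples and
    all processed scans, it contains exactly one fine-bin occurrence.
    A bin whose single fine m/z recurs in a second scan — or that holds
    two distinct fine m/z — is kept.
    """
    if occurrences.empty:
        return occurrences
    sizes = occurrences.groupby(["polarity", "coarse_key"])["fine_key"].transform("size")
    return occurrences[sizes > 1].reset_index(drop=True)


def average_over_window(
    occurrences: pd.DataFrame, window: InfusionWindow
) -> pd.DataFrame:
    """Average coarse-bin abundances across the plug-flow scans.

    Per sample and coarse bin, the averaged intensity is the sum of its
    per-scan intensities divided by the number of window scans — scans
    where the bin is absent contribute zero, which keeps total intensity
    conserved.  Returns a DataFrame with columns
    ``sample, polarity, coarse_key, intensity``.
    """
    if window.n_scans < 1:
        raise ValueError("empty infusion window")
    return _average(occurrences, lambda sample: window.n_scans)


def _average(occurrences: pd.DataFrame, n_scans_of) -> pd.DataFrame:
    if occurrences.empty:
        return pd.DataFrame(columns=["sample", "polarity", "coarse_key", "intensity"])
    out = (
        occurrences.groupby(["sample", "polarity", "coarse_key"], as_index=False)[
            "intensity"
        ].sum()
    )
    out["intensity"] /= out["sample"].map(n_scans_of)
    return out


def assign_accurate_mz(occurrences: Sequence[FineBin]) -> float:
    """Modal fine m/z of a coarse bin's pooled occurrences.

    The accurate m/z is the fine grid value with the greatest number of
    scan-level appearances pooled over the whole sample set; ties are
    broken by larger total abundance, then by smaller m/z.
    """
    if len(occurrences) == 0:
        raise ValueError("no occurrences to assign an accurate m/z from")
    count: dict[int, int] = {}
    total: dict[int, float] = {}
    for occ in occurrences:
        count[occ.key] = count.get(occ.key, 0) + 1
        total[occ.key] = total.get(occ.key, 0.0) + occ.intensity
    best = min(count, key=lambda k: (-count[k], -total[k], k))
    return best / FINE_SCALE


@dataclass
class IntensityMatrix:
    """Terminal product of the pipeline: samples x bins plus bin metadata.

    Attributes
    ----------
    intensities : DataFrame
        Rows = samples (input order), columns = bin names, cells = mean
        abundance over the plug-flow window (0 = not detected).
    bin_table : DataFrame, indexed by bin name
        Columns: polarity, center, accurate_mz, purity, centrality,
        occupancy (proportion of samples with a nonzero cell), plus one
        ``occupancy_<class>`` column per sample class when classes were
        supplied.
    width : float
        Coarse bin width (amu) shared by every column.
    window : InfusionWindow or None
        The plug-flow window the abundances were averaged over.
    """

    intensities: pd.DataFrame
    bin_table: pd.DataFrame
    width: float
    window: InfusionWindow | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def bins(self) -> list[str]:
        return list(self.intensities.columns)

    def select_bins(self, names: Sequence[str]) -> "IntensityMatrix":
        names = [n for n in self.bins if n in set(names)]
        return IntensityMatrix(
            self.intensities[names], self.bin_table.loc[names], self.width, self.window
        )

    def to_csv(self, matrix_path, bins_path=None) -> None:
        self.intensities.to_csv(matrix_path, index_label="sample")
        if bins_path is not None:
            self.bin_table.to_csv(bins_path, index_label="bin")


def build_intensity_matrix(
    averaged: pd.DataFrame,
    bin_table: pd.DataFrame,
    samples: Sequence[str],
    width: float,
    window: InfusionWindow | None = None,
) -> IntensityMatrix:
    """Assemble the samples x bins matrix from averaged abundances.

    Rows follow ``samples`` (input order); columns are bins sorted by
    polarity then grid index; a sample/bin pair with no surviving signal
    gets 0.  Raises on duplicate sample ids.
    """
    samples = list(samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    if averaged.empty:
        mat = pd.DataFrame(index=pd.Index(samples, name="sample"))
        return IntensityMatrix(mat, bin_table, width, window)
    averaged = averaged.copy()
    averaged["bin"] = [
        bin_name(p, k, width)
        for p, k in zip(averaged["polarity"], averaged["coarse_key"])
    ]
    mat = (
        averaged.pivot_table(index="sample", columns="bin", values="intensity", fill_value=0.0)
        .reindex(index=samples, fill_value=0.0)
        .reindex(columns=bin_table.index, fill_value=0.0)
    )
    mat.index.name = "sample"
    mat.columns.name = None
    return IntensityMatrix(mat, bin_table, width, window)


def bin_sample_set(
    runs: Mapping[str, Sequence[ScanEvent]],
    width: float = 0.01,
    fraction: float = 0.5,
    window: InfusionWindow | Mapping[str, InfusionWindow] | None = None,
    classes: Mapping[str, str] | None = None,
    per_sample_window: bool = False,
) -> IntensityMatrix:
    """Run the full spectral-binning pipeline on a set of replicate runs.

    Parameters
    ----------
    runs : mapping of sample id -> scans
        One entry per injection; scans need cycle ordinals (readers
        assign them).  Polarities are processed independently end to end.
    width : float
        Coarse bin width in amu (one of 1, 0.1, 0.01, 0.001, 0.0001).
    fraction : float
        Plug-flow TIC cutoff as a fraction of the profile maximum.
    window : InfusionWindow or mapping of sample id -> window, optional
        Use pre-computed window(s) instead of detecting from the pooled
        TIC profile.
    classes : mapping of sample id -> class label, optional
        Enables per-class occupancy columns in the bin table.
    per_sample_window : bool
        Detect a window per sample from its own profile instead of the
        default pooled detection over all replicate injections.

    Returns
    -------
    IntensityMatrix
    """
    width_decimals(width)
    if len(runs) == 0:
        raise ValueError("no runs supplied")
    if window is None:
        if per_sample_window:
            windows = {
                s: detect_plug_flow(averaged_tic_profile({s: scans}), fraction)
                for s, scans in runs.items()
            }
        else:
            pooled = detect_plug_flow(averaged_tic_profile(runs), fraction)
            windows = {s: pooled for s in runs}
    elif isinstance(window, Mapping):
        windows = dict(window)
    else:
        windows = {s: window for s in runs}
    window = next(iter(windows.values()))  # representative, for metadata

    occ = _occurrence_table(runs, windows, width)
    occ = remove_single_scan_events(occ)
    averaged = _average(occ, lambda sample: windows[sample].n_scans)

    bin_rows = []
    for (polarity, key), group in occ.groupby(["polarity", "coarse_key"]):
        members = [FineBin(k, a) for k, a in zip(group["fine_key"], group["intensity"])]
        center = coarse_center(int(key), width)
        accurate = assign_accurate_mz(members)
        # purity/centrality: per sample first, then unweighted mean over
        # the samples in which the bin was detected
        stats = [
            compute_bin_stats(
                [(fk / FINE_SCALE, a) for fk, a in zip(g["fine_key"], g["intensity"])],
                width,
                center,
            )
            for _, g in group.groupby("sample")
        ]
        row = {
            "bin": bin_name(polarity, int(key), width),
            "polarity": polarity,
            "center": center,
            "accurate_mz": accurate,
            "purity": float(np.mean([s.purity for s in stats])),
            "centrality": float(np.mean([s.centrality for s in stats])),
        }
        bin_rows.append(row)
    bin_table = pd.DataFrame(
        bin_rows,
        columns=["bin", "polarity", "center", "accurate_mz", "purity", "centrality"],
    ).set_index("bin")
    bin_table = bin_table.sort_values(["polarity", "center"], kind="stable")

    matrix = build_intensity_matrix(averaged, bin_table, list(runs), width, window)

    detected = matrix.intensities.gt(0)
    matrix.bin_table["occupancy"] = detected.mean(axis=0).reindex(bin_table.index)
    if classes is not None:
        missing = set(matrix.samples) - set(classes)
        if missing:
            raise ValueError(f"samples without a class label: {sorted(missing)}")
        labels = pd.Series({s: classes[s] for s in matrix.samples})
        for cls, members in detected.groupby(labels):
            matrix.bin_table[f"occupancy_{cls}"] = members.mean(axis=0)
    return matrix
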