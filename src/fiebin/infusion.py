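"""Plug-flow window detection from averaged infusion (TIC) profiles.

In flow-infusion electrospray MS there is no chromatography: each run is
a short infusion whose total ion count (TIC) rises as the sample plug
reaches the source, plateaus, and falls away.  Only scans inside the
"plug flow" region — where sample concentration at the source is
maximal — are processed.  The window is found on the TIC profile
averaged over all scan filters and all replicate injections, as the
maximal contiguous block of scans, containing the TIC maximum, whose
every scan exceeds a fraction (default 50%) of the maximum TIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import ScanEvent, ScanFilter

__all__ = ["TicProfile", "InfusionWindow", "averaged_tic_profile", "detect_plug_flow"]


@dataclass(frozen=True)
class TicProfile:
    """Total ion counts indexed by cycle ordinal (element 0 = cycle 1)."""

    tic: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "tic", np.asarray(self.tic, dtype=float))
        if self.tic.ndim != 1 or self.tic.size == 0:
            raise ValueError("TIC profile must be a non-empty 1-D sequence")
        if np.any(self.tic < 0):
            raise ValueError("TIC values must be non-negative")

    def __len__(self) -> int:
        return self.tic.size


@dataclass(frozen=True)
class InfusionWindow:
    """Inclusive range of cycle ordinals [start, end], 1-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid window ({self.start}, {self.end})")

    def __contains__(self, cycle: int) -> bool:
        return self.start <= cycle <= self.end

    @property
    def n_scans(self) -> int:
        return self.end - self.start + 1


def averaged_tic_profile(runs: Mapping[str, Sequence[ScanEvent]]) -> TicProfile:
    """Average per-filter TIC traces over all samples and filters.

    Each (sample, filter) pair contributes one TIC trace indexed by cycle
    ordinal.  Element ``i`` of the result is the mean over all traces
    that have a scan at cycle ``i+1``; shorter traces simply contribute
    nothing beyond their length.

    Parameters
    ----------
    runs : mapping of sample id -> scans
        Scans must carry cycle ordinals (see
        :func:`fiebin.io.assign_cycle_ordinals`).
    """
    traces: dict[tuple[str, ScanFilter], dict[int, float]] = {}
    for sample, scans in runs.items():
        for scan in scans:
            if scan.cycle < 1:
                raise ValueError("scans must have cycle ordinals assigned")
            traces.setdefault((sample, scan.filter), {})[scan.cycle] = scan.tic
    if not traces:
        raise ValueError("no scans supplied")
    length = max(max(t) for t in traces.values())
    total = np.zeros(length)
    count = np.zeros(length)
    for trace in traces.values():
        for cycle, tic in trace.items():
            total[cycle - 1] += tic
            count[cycle - 1] += 1
    # cycles are contiguous per trace, so every position up to `length`
    # is covered by at least one trace
    return TicProfile(total / np.maximum(count, 1))


def detect_plug_flow(profile: TicProfile, fraction: float = 0.5) -> InfusionWindow:
    """Find the plug-flow scan window of an infusion profile.

    Returns the maximal contiguous window containing the (earliest)
    global TIC maximum whose every scan has TIC strictly greater than
    ``fraction * max(TIC)``.  The strict inequality means scans tied
    exactly at the cutoff are excluded.  Disjoint supra-threshold
    regions away from the maximum are ignored: the plug flow is a single
    injection bolus.

    Raises ``ValueError`` on an all-zero profile or fraction outside (0, 1).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    tic = profile.tic
    peak = tic.max()
    if peak <= 0:
        raise ValueError("all-zero TIC profile: no infusion detected")
    cutoff = fraction * peak
    argmax = int(np.argmax(tic))  # earliest maximal scan
    start = argmax
    while start > 0 and tic[start - 1] > cutoff:
        start -= 1
    end = argmax
    while end < tic.size - 1 and tic[end + 1] > cutoff:
        end += 1
    return InfusionWindow(start + 1, end + 1)
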