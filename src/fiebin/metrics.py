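"""Bin purity and centrality metrics.

A spectral bin of width *w* centred at *k* collects *n* mass-spectral
signals with m/z values :math:`m_1..m_n` and abundances
:math:`a_1..a_n`.  Two scores summarise how the signal is distributed
inside the bin window:

* **purity** ``p = 1 - e_bar / (0.5 w)`` where ``e_bar`` is the
  abundance-weighted mean absolute deviation of the member m/z from the
  abundance-weighted mean m/z.  ``p = 1`` means all the signal sits at a
  single m/z; low purity warns that the bin may merge more than one real
  mass signal.
* **centrality** ``c = 1 - |m_bar - k| / (0.5 w)`` where ``m_bar`` is
  the abundance-weighted mean m/z.  ``c = 1`` means the signal is
  centred in the bin; low centrality warns that the signal sits near a
  bin edge (and may be split with a neighbour).

Both scores lie in [0, 1] whenever all members lie inside the bin
window, and are invariant under rescaling of the abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["BinStats", "compute_bin_stats"]


@dataclass(frozen=True)
class BinStats:
    """Weighted-moment summary of one spectral bin.

    Attributes
    ----------
    m, a : ndarray
        Member m/z values (Da) and abundances (counts).
    n : int
        Member count.
    t : float
        Bin total ion count, ``sum(a)``.
    mean_mz : float
        Abundance-weighted mean m/z.
    mean_abs_error : float
        Abundance-weighted mean absolute deviation of m/z from ``mean_mz``.
    width, center : float
        Bin width (amu) and bin-window centre (Da).
    purity, centrality : float
        The two scores, clamped to [0, 1].
    """

    m: np.ndarray
    a: np.ndarray
    n: int
    t: float
    mean_mz: float
    mean_abs_error: float
    width: float
    center: float
    purity: float
    centrality: float


def compute_bin_stats(
    members: Sequence[tuple[float, float]],
    width: float,
    center: float,
) -> BinStats:
    """Compute purity, centrality and weighted moments for one bin.

    Parameters
    ----------
    members : sequence of (m/z, abundance)
        Every signal occurrence assigned to the bin; abundances must be
        positive.
    width : float
        Bin width in amu.
    center : float
        Centre of the bin window in Da.

    Raises
    ------
    ValueError
        On an empty member list or a non-positive abundance.
    """
    if len(members) == 0:
        raise ValueError("bin has no members")
    m = np.asarray([mz for mz, _ in members], dtype=float)
    a = np.asarray([ab for _, ab in members], dtype=float)
    if np.any(a <= 0):
        raise ValueError("bin member abundances must be positive")
    t = float(a.sum())
    if np.all(m == m[0]):
        # exact path: a single distinct m/z is perfectly pure
        mean_mz = float(m[0])
        mean_abs_error = 0.0
    else:
        mean_mz = float((m * a).sum() / t)
        mean_abs_error = float((a * np.abs(m - mean_mz)).sum() / t)
    half = 0.5 * width
    purity = 1.0 - mean_abs_error / half
    centrality = 1.0 - abs(mean_mz - center) / half
    if np.any(np.abs(m - center) > half * (1 + 1e-12)):
        # cannot happen for grid-assigned bins; defensive for direct calls
        warnings.warn(
            f"bin members fall outside the window [{center - half}, {center + half}]; "
            "purity/centrality clamped to [0, 1]",
            stacklevel=2,
        )
    purity = min(1.0, max(0.0, purity))
    centrality = min(1.0, max(0.0, centrality))
    return BinStats(
        m=m,
        a=a,
        n=m.size,
        t=t,
        mean_mz=mean_mz,
        mean_abs_error=mean_abs_error,
        width=width,
        center=center,
        purity=purity,
        centrality=centrality,
    )
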