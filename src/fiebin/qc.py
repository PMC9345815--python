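"""Post-binning feature-quality filters.

Flow-infusion fingerprinting matrices carry noisy, sparsely detected
bins.  Two standard pre-treatment filters are provided:

* **class occupancy** — keep a bin only if it is detected in more than
  a threshold proportion (default 2/3, the conventional "66%") of the
  samples of at least one sample class;
* **QC relative standard deviation** — keep a bin only if its RSD
  (100 x sample sd / mean) across quality-control injections is
  strictly below a threshold (default 50%, suited to the more complex
  ionisation environment of infusion compared to the 20-30% used for
  LC-MS/GC-MS).

Both comparisons are strict; the two filters commute, so the order in
which they are applied does not matter.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .binning import IntensityMatrix

__all__ = ["SampleInfo", "read_sample_info", "occupancy_filter", "rsd_filter"]

OCCUPANCY_DEFAULT = 2 / 3
RSD_DEFAULT = 50.0


@dataclass(frozen=True)
class SampleInfo:
    """Sample annotation: id, class label, and whether it is a QC injection."""

    sample_id: str
    class_label: str
    is_qc: bool = False
    path: str | None = None


def read_sample_info(path: str | os.PathLike) -> list[SampleInfo]:
    """Read a sample-information CSV.

    Expected columns: ``file`` (or ``sample``), ``class``, and optional
    ``qc`` (truthy values: 1/true/yes).  The sample id is the file stem
    when a ``file`` column is given.
    """
    infos: list[SampleInfo] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            row = {(k or "").strip().lower(): (v or "").strip() for k, v in row.items()}
            file_ = row.get("file")
            sample = row.get("sample") or (
                os.path.splitext(os.path.basename(file_))[0] if file_ else None
            )
            if not sample:
                raise ValueError(f"sample-info row without sample/file: {row!r}")
            qc = row.get("qc", "").lower() in ("1", "true", "yes", "y")
            infos.append(SampleInfo(sample, row.get("class", ""), qc, file_ or None))
    if not infos:
        raise ValueError(f"no samples in sample-info file {os.fspath(path)!r}")
    ids = [i.sample_id for i in infos]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in sample-info file")
    return infos


def _check_samples(matrix: IntensityMatrix, infos: Sequence[SampleInfo]) -> dict[str, SampleInfo]:
    by_id = {i.sample_id: i for i in infos}
    unknown = set(matrix.samples) - set(by_id)
    if unknown:
        raise ValueError(f"samples in matrix without annotation: {sorted(unknown)}")
    return by_id


def occupancy_filter(
    matrix: IntensityMatrix,
    infos: Sequence[SampleInfo],
    threshold: float = OCCUPANCY_DEFAULT,
) -> IntensityMatrix:
    """Keep bins detected above ``threshold`` occupancy in some class.

    A bin is retained iff, in at least one sample class, the proportion
    of that class's samples with a nonzero cell is strictly greater
    than ``threshold``.  Zero cells count as unoccupied.
    """
    by_id = _check_samples(matrix, infos)
    labels = np.array([by_id[s].class_label for s in matrix.samples])
    detected = matrix.intensities.gt(0)
    keep = np.zeros(len(matrix.bins), dtype=bool)
    for cls in np.unique(labels):
        frac = detected[labels == cls].mean(axis=0).to_numpy()
        keep |= frac > threshold
    return matrix.select_bins([b for b, k in zip(matrix.bins, keep) if k])


def rsd_filter(
    matrix: IntensityMatrix,
    infos: Sequence[SampleInfo],
    threshold_pct: float = RSD_DEFAULT,
) -> IntensityMatrix:
    """Keep bins measured robustly across the QC injections.

    Per bin, RSD = 100 x (sample standard deviation / mean) over the QC
    samples' intensities; bins are retained when the RSD is strictly
    below ``threshold_pct``.  A bin undetected in a QC contributes a
    zero intensity (inflating its RSD); bins with zero mean across QCs
    are removed.  Requires at least two QC samples.
    """
    by_id = _check_samples(matrix, infos)
    qc_ids = [s for s in matrix.samples if by_id[s].is_qc]
    if len(qc_ids) < 2:
        raise ValueError("RSD filtering requires at least two QC samples")
    qc = matrix.intensities.loc[qc_ids]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    keep = (mean > 0) & (rsd < threshold_pct)
    return matrix.select_bins([b for b in matrix.bins if keep[b]])
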