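"""End-to-end processing: files in, intensity matrix and reports out.

`run_pipeline` ties the stages together — read, plug-flow detection,
binning, optional QC filtering, optional adduct matching — and writes
the artifact bundle (matrix CSV, bin metadata CSV, match CSV, filter
report, parameter log).  Each stage failure aborts with a stage-labelled
message and removes any partial outputs.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import binning, qc
from .adducts import match_products, predict_products
from .binning import IntensityMatrix, bin_sample_set
from .io import read_centroided_run
from .qc import SampleInfo, read_sample_info

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "read_compound_table"]

log = logging.getLogger("fiebin")


@dataclass
class RunConfig:
    """Parameters of one processing run.

    Defaults follow the method's recommendations: 0.01 amu bins, a 50%
    plug-flow TIC cutoff, 2/3 class-occupancy and 50% QC-RSD filter
    thresholds, 10 ppm adduct matching against fully occupied bins.
    """

    files: list[str] = field(default_factory=list)
    sample_info: str | None = None
    width: float = 0.01
    plug_fraction: float = 0.5
    per_sample_window: bool = False
    occupancy_threshold: float | None = None
    rsd_threshold: float | None = None
    qc_class: str | None = None
    compounds: str | None = None
    ppm: float = 10.0
    occupancy_min: float = 1.0
    out_dir: str = "."

    def validate(self) -> None:
        binning.width_decimals(self.width)
        if not 0 < self.plug_fraction < 1:
            raise ValueError("plug-flow fraction must lie in (0, 1)")
        if not self.files and not self.sample_info:
            raise ValueError("no input files: give files or a sample-info table")


@dataclass
class PipelineResult:
    matrix: IntensityMatrix
    unfiltered: IntensityMatrix
    matches: pd.DataFrame | None
    removed: pd.DataFrame | None
    outputs: list[str]


def read_compound_table(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a compound CSV with columns ``name`` and ``formula``."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            row = {(k or "").strip().lower(): (v or "").strip() for k, v in row.items()}
            if not row.get("name") or not row.get("formula"):
                raise ValueError(f"compound row needs name and formula: {row!r}")
            out.append((row["name"], row["formula"]))
    if not out:
        raise ValueError(f"no compounds in {os.fspath(path)!r}")
    return out


def _stage(name: str):
    class _Stage:
        def __enter__(self):
            log.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Stage()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow described by ``config``.

    Returns the in-memory results and writes ``matrix.csv``,
    ``bins.csv`` and, when applicable, ``matches.csv`` and
    ``removed_bins.csv`` to ``config.out_dir`` along with
    ``fiebin.log`` recording every parameter.  On any stage error the
    partial outputs are removed and the error re-raised with the stage
    name.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "fiebin.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs = [log_path]
    try:
        for key, value in vars(config).items():
            log.info("parameter %s = %r", key, value)

        infos: list[SampleInfo] | None = None
        files = list(config.files)
        with _stage("read"):
            if config.sample_info:
                infos = read_sample_info(config.sample_info)
                if not files:
                    base = os.path.dirname(os.fspath(config.sample_info))
                    files = [
                        i.path if os.path.isabs(i.path or "") else os.path.join(base, i.path)
                        for i in infos
                        if i.path
                    ]
            runs = {}
            for path in files:
                scans = read_centroided_run(path)
                if not scans:
                    raise ValueError(f"{path!r} contains no spectra")
                runs[scans[0].sample_id] = scans
                log.info("read %s: %d scans", path, len(scans))
            if config.qc_class and infos:
                infos = [
                    SampleInfo(i.sample_id, i.class_label,
                               i.is_qc or i.class_label == config.qc_class, i.path)
                    for i in infos
                ]

        with _stage("binning"):
            classes = (
                {i.sample_id: i.class_label for i in infos} if infos else None
            )
            matrix = bin_sample_set(
                runs,
                width=config.width,
                fraction=config.plug_fraction,
                classes=classes,
                per_sample_window=config.per_sample_window,
            )
            log.info(
                "binned %d samples into %d bins (window %s-%s)",
                len(matrix.samples),
                len(matrix.bins),
                matrix.window.start,
                matrix.window.end,
            )

        unfiltered = matrix
        removed = None
        with _stage("qc-filters"):
            reasons: dict[str, str] = {}
            if config.occupancy_threshold is not None:
                if infos is None:
                    raise ValueError("occupancy filtering needs a sample-info table")
                before = set(matrix.bins)
                matrix = qc.occupancy_filter(matrix, infos, config.occupancy_threshold)
                for b in before - set(matrix.bins):
                    reasons[b] = "occupancy"
            if config.rsd_threshold is not None:
                if infos is None:
                    raise ValueError("RSD filtering needs a sample-info table")
                before = set(matrix.bins)
                matrix = qc.rsd_filter(matrix, infos, config.rsd_threshold)
                for b in before - set(matrix.bins):
                    reasons[b] = "rsd"
            if reasons:
                removed = pd.DataFrame(
                    sorted(reasons.items()), columns=["bin", "reason"]
                )
                log.info("filtered out %d bins", len(removed))

        matches = None
        with _stage("adduct-matching"):
            if config.compounds:
                compounds = read_compound_table(config.compounds)
                products = predict_products(compounds)
                matches = match_products(
                    products,
                    matrix.bin_table,
                    tol_ppm=config.ppm,
                    occupancy_min=config.occupancy_min,
                )
                log.info(
                    "matched %d of %d predicted products",
                    matches["compound"].nunique() if len(matches) else 0,
                    len(products),
                )

        with _stage("write"):
            matrix_path = os.path.join(config.out_dir, "matrix.csv")
            bins_path = os.path.join(config.out_dir, "bins.csv")
            matrix.to_csv(matrix_path, bins_path)
            outputs += [matrix_path, bins_path]
            if removed is not None:
                p = os.path.join(config.out_dir, "removed_bins.csv")
                removed.to_csv(p, index=False)
                outputs.append(p)
            if matches is not None:
                p = os.path.join(config.out_dir, "matches.csv")
                matches.to_csv(p, index=False)
                outputs.append(p)
    except Exception:
        for path in outputs:
            if path != log_path and os.path.exists(path):
                os.remove(path)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return PipelineResult(matrix, unfiltered, matches, removed, outputs)
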