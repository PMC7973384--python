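"""Text I/O for hypnodensity series and hypnograms.

Hypnodensity CSV: columns ``time_s,Wake,N1,N2,N3,REM``, UTF-8, '.' decimal,
``#`` comment lines.  Hypnogram TSV: columns ``epoch_index,stage,artifact``
with stage in {W, N1, N2, N3, REM} and artifact in {0, 1}.  Writing uses
17 significant digits so a write/read round-trip is lossless.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import (
    STAGE_LABELS,
    STAGE_SHORT,
    Hypnogram,
    HypnodensitySeries,
    validate_series,
)
from .errors import HypnodensityParseError

_HD_COLUMNS = ("time_s",) + STAGE_LABELS


def write_hypnodensity_csv(series: HypnodensitySeries, path: str | os.PathLike) -> None:
    """Write a series to CSV at full precision, with provenance comments."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# channel: {series.channel}\n")
        fh.write(f"# step_seconds: {series.step_seconds!r}\n")
        fh.write(f"# window_seconds: {series.window_seconds!r}\n")
        fh.write(",".join(_HD_COLUMNS) + "\n")
        for t, row in zip(series.times, series.probs):
            fields = [f"{t:.17g}"] + [f"{v:.17g}" for v in row]
            fh.write(",".join(fields) + "\n")


def read_hypnodensity_csv(path: str | os.PathLike) -> HypnodensitySeries:
    """Read and validate a hypnodensity CSV.

    Malformed rows, a wrong column count, simplex violations or a
    non-monotone time column raise :class:`HypnodensityParseError` naming
    the first offending data row (1-based, comments and header excluded).
    """
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise HypnodensityParseError(f"cannot parse {path}: {exc}") from exc
    if tuple(df.columns) != _HD_COLUMNS:
        raise HypnodensityParseError(
            f"expected columns {','.join(_HD_COLUMNS)}, found {','.join(map(str, df.columns))}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad_rows = df.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
        raise HypnodensityParseError(
            "non-numeric value", line=int(np.argwhere(bad_rows.to_numpy())[0][0]) + 1
        )
    step = float(meta.get("step_seconds", "nan"))
    if not np.isfinite(step):
        diffs = np.diff(values[:, 0])
        step = float(diffs[0]) if diffs.size else 5.0
    series = HypnodensitySeries(
        times=values[:, 0],
        probs=values[:, 1:],
        channel=meta.get("channel", ""),
        step_seconds=step,
        window_seconds=float(meta.get("window_seconds", 30.0)),
    )
    report = validate_series(series)
    if not report.ok:
        raise HypnodensityParseError(f"invalid hypnodensity data: {report.message}")
    return series


def write_hypnogram_tsv(h: Hypnogram, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# epoch_seconds: {h.epoch_seconds!r}\n")
        fh.write("epoch_index\tstage\tartifact\n")
        for i, (s, a) in enumerate(zip(h.stages, h.artifact_mask)):
            fh.write(f"{i}\t{STAGE_SHORT[s]}\t{int(a)}\n")


def read_hypnogram_tsv(path: str | os.PathLike) -> Hypnogram:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise HypnodensityParseError(f"cannot parse {path}: {exc}") from exc
    if tuple(df.columns) != ("epoch_index", "stage", "artifact"):
        raise HypnodensityParseError(
            "expected columns epoch_index,stage,artifact, found "
            + ",".join(map(str, df.columns))
        )
    lookup = {label: i for i, label in enumerate(STAGE_SHORT)}
    stages = np.empty(len(df), dtype=np.intp)
    for row_no, label in enumerate(df["stage"]):
        if label not in lookup:
            raise HypnodensityParseError(f"unknown stage label {label!r}", line=row_no + 1)
        stages[row_no] = lookup[label]
    return Hypnogram(
        stages=stages,
        epoch_seconds=float(meta.get("epoch_seconds", 30.0)),
        artifact_mask=df["artifact"].to_numpy().astype(bool),
    )
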