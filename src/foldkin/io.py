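"""CSV dialects for chevrons and traces, plus JSON result documents.

Chevron CSV: columns ``variant, urea_M, kobs_s1`` and optional ``sigma``.
Trace CSV: either one file per trace with ``# variant=`` / ``# urea_M=``
metadata header lines and columns ``time_s, fluorescence``, or a long
format with a ``trace_id`` column.  Values round-trip at 12 significant
digits; unknown columns are preserved on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import DataError
from .kinetics import ChevronDataset
from .traces import TraceRecord

__all__ = [
    "read_chevron_csv",
    "write_chevron_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_traces_long_csv",
    "write_json",
]

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {', '.join(missing)}")


def _numeric(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    for c in cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header occupies line 1
            raise DataError(f"{path}: non-numeric value in column {c!r} at line {line}")
        df[c] = converted
    return df


def read_chevron_csv(path: PathLike) -> list[ChevronDataset]:
    """Read chevron datasets grouped by variant, preserving input order."""
    df = pd.read_csv(path)
    _require_columns(df, ["variant", "urea_M", "kobs_s1"], path)
    cols = ["urea_M", "kobs_s1"] + (["sigma"] if "sigma" in df.columns else [])
    df = _numeric(df, cols, path)
    out = []
    for vid, grp in df.groupby("variant", sort=False):
        sigma = None
        if "sigma" in grp.columns and grp["sigma"].notna().all():
            sigma = grp["sigma"].to_numpy()
        out.append(
            ChevronDataset(
                variant_id=str(vid),
                urea=grp["urea_M"].to_numpy(),
                kobs=grp["kobs_s1"].to_numpy(),
                sigma=sigma,
            )
        )
    if not out:
        raise DataError(f"{path}: no chevron data rows")
    return out


def write_chevron_csv(datasets: Sequence[ChevronDataset], path: PathLike) -> None:
    frames = []
    for d in datasets:
        frame = pd.DataFrame({"variant": d.variant_id, "urea_M": d.urea, "kobs_s1": d.kobs})
        if d.sigma is not None:
            frame["sigma"] = d.sigma
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_trace_csv(path: PathLike) -> TraceRecord:
    """Read a single trace with ``# variant=`` / ``# urea_M=`` header lines."""
    meta = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            key, _, value = line.lstrip("#").strip().partition("=")
            meta[key.strip()] = value.strip()
        fh.seek(pos)
        df = pd.read_csv(fh)
    _require_columns(df, ["time_s", "fluorescence"], path)
    df = _numeric(df, ["time_s", "fluorescence"], path)
    if "variant" not in meta or "urea_M" not in meta:
        raise DataError(f"{path}: missing '# variant=' or '# urea_M=' metadata line")
    return TraceRecord(
        variant_id=meta["variant"],
        urea=float(meta["urea_M"]),
        times=df["time_s"].to_numpy(),
        fluorescence=df["fluorescence"].to_numpy(),
    )


def write_trace_csv(trace: TraceRecord, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# variant={trace.variant_id}\n# urea_M={trace.urea:.12g}\n")
        pd.DataFrame({"time_s": trace.times, "fluorescence": trace.fluorescence}).to_csv(
            fh, index=False, float_format="%.12g"
        )


def read_traces_long_csv(path: PathLike) -> list[TraceRecord]:
    """Read many traces from one long-format file with a ``trace_id`` column."""
    df = pd.read_csv(path)
    _require_columns(df, ["trace_id", "variant", "urea_M", "time_s", "fluorescence"], path)
    df = _numeric(df, ["urea_M", "time_s", "fluorescence"], path)
    out = []
    for _, grp in df.groupby("trace_id", sort=False):
        out.append(
            TraceRecord(
                variant_id=str(grp["variant"].iloc[0]),
                urea=float(grp["urea_M"].iloc[0]),
                times=grp["time_s"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
            )
        )
    if not out:
        raise DataError(f"{path}: no trace rows")
    return out


def write_json(obj, path: PathLike) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
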