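"""Readers/writers for marker trajectories, labels, angles and reports.

Supported trajectory formats:

* **TRC** — the standard tab-delimited motion-capture text format (5 header
  lines, per-marker X/Y/Z columns), units ``mm`` or ``m`` declared in the
  header. Marker names are ``R_<LABEL>`` / ``L_<LABEL>``.
* **wide CSV** — ``frame`` column followed by ``<side>_<label>_{x,y,z}``
  columns in metres.

All CSV output uses comma separators, UTF-8, dot decimals, a header row and
a fixed ``%.9f`` float format, so write -> read -> write round-trips are
byte-identical. Frames are 0-based; times are frame / fps seconds.
"""

from __future__ import annotations

import difflib
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .anatomy import SIDES, AnatomicalLabel, TrajectorySet

FLOAT_FMT = "%.9f"


class FormatError(ValueError):
    """A trajectory file violates the expected layout."""


class MarkerNameError(FormatError):
    """A marker column name cannot be mapped to an anatomical label."""


def _marker_name(side: str, label: AnatomicalLabel) -> str:
    return f"{side[0].upper()}_{label.value}"


def _parse_marker_name(name: str) -> tuple:
    prefix, _, rest = name.partition("_")
    side = {"R": "right", "L": "left"}.get(prefix.upper())
    try:
        label = AnatomicalLabel(rest)
    except ValueError:
        label = None
    if side is None or label is None:
        options = [_marker_name(s, lab) for s in SIDES for lab in AnatomicalLabel]
        hints = difflib.get_close_matches(name, options, n=3)
        raise MarkerNameError(
            f"unknown marker name {name!r}; closest valid names: {hints}")
    return side, label


def _iter_present(traj: TrajectorySet):
    for side in SIDES:
        for label in AnatomicalLabel:
            if side in traj.data and label in traj.data[side]:
                yield side, label


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def write_trc(traj: TrajectorySet, path, units: str = "m") -> None:
    """Write a TRC file; missing samples become blank fields."""
    if units not in ("m", "mm"):
        raise ValueError("units must be 'm' or 'mm'")
    scale = 1000.0 if units == "mm" else 1.0
    markers = list(_iter_present(traj))
    names = [_marker_name(s, lab) for s, lab in markers]
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{traj.fps:g}\t{traj.fps:g}\t{traj.n_frames}\t{len(names)}\t"
                 f"{units}\t{traj.fps:g}\t1\t{traj.n_frames}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\n")
        axes = "\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}"
                         for i in range(len(names)))
        fh.write(f"\t\t{axes}\n")
        for f in range(traj.n_frames):
            cells: List[str] = [str(f + 1), FLOAT_FMT % (f / traj.fps)]
            for side, label in markers:
                xyz = traj.data[side][label][f] * scale
                if np.all(np.isfinite(xyz)):
                    cells.extend(FLOAT_FMT % v for v in xyz)
                else:
                    cells.extend(["", "", ""])
            fh.write("\t".join(cells) + "\n")


def read_trc(path) -> TrajectorySet:
    """Read a TRC file, converting to metres; blank samples become NaN."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise FormatError(f"{path}: not a TRC file")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    try:
        fps = float(meta["DataRate"])
        n_frames = int(meta["NumFrames"])
        units = meta["Units"]
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed TRC header ({exc})") from exc
    if units not in ("m", "mm"):
        raise FormatError(f"{path}: unsupported units {units!r}")
    scale = 1e-3 if units == "mm" else 1.0
    names = [n for n in lines[3].split("\t")[2:] if n]
    parsed = [_parse_marker_name(n) for n in names]

    data: Dict[str, Dict[AnatomicalLabel, np.ndarray]] = {s: {} for s in SIDES}
    for side, label in parsed:
        data[side][label] = np.full((n_frames, 3), np.nan)
    for row in lines[5:]:
        if not row.strip():
            continue
        cells = row.split("\t")
        f = int(cells[0]) - 1
        for i, (side, label) in enumerate(parsed):
            triplet = cells[2 + 3 * i: 5 + 3 * i]
            if len(triplet) == 3 and all(c.strip() for c in triplet):
                data[side][label][f] = [float(c) * scale for c in triplet]
    data = {s: m for s, m in data.items() if m}
    return TrajectorySet(fps=fps, n_frames=n_frames, data=data)


# ---------------------------------------------------------------------------
# Wide CSV
# ---------------------------------------------------------------------------

def write_wide_csv(traj: TrajectorySet, path) -> None:
    """Wide CSV: frame, then <side>_<label>_{x,y,z} columns in metres."""
    columns: Dict[str, np.ndarray] = {"frame": np.arange(traj.n_frames)}
    for side, label in _iter_present(traj):
        arr = traj.data[side][label]
        for k, axis in enumerate("xyz"):
            columns[f"{_marker_name(side, label)}_{axis}"] = arr[:, k]
    pd.DataFrame(columns).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_wide_csv(path, fps: float = 30.0) -> TrajectorySet:
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise FormatError(f"{path}: wide CSV must have a 'frame' column")
    n_frames = len(df)
    data: Dict[str, Dict[AnatomicalLabel, np.ndarray]] = {s: {} for s in SIDES}
    for col in df.columns:
        if col == "frame":
            continue
        name, _, axis = col.rpartition("_")
        if axis not in "xyz":
            raise FormatError(f"{path}: unexpected column {col!r}")
        side, label = _parse_marker_name(name)
        arr = data[side].setdefault(label, np.full((n_frames, 3), np.nan))
        arr[:, "xyz".index(axis)] = df[col].to_numpy(dtype=float)
    data = {s: m for s, m in data.items() if m}
    return TrajectorySet(fps=fps, n_frames=n_frames, data=data)


# ---------------------------------------------------------------------------
# Labels, events, angles, reports
# ---------------------------------------------------------------------------

def write_labels_csv(path, labels_by_side: Dict[str, np.ndarray]) -> None:
    """Per-frame labels as (frame, side, label) rows."""
    rows = []
    n = max(len(v) for v in labels_by_side.values())
    for f in range(n):
        for side in SIDES:
            if side in labels_by_side:
                rows.append({"frame": f, "side": side,
                             "label": labels_by_side[side][f]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels_csv(path, side: Optional[str] = None) -> np.ndarray:
    """Read a per-frame label stream; single-column files are accepted too."""
    df = pd.read_csv(path, keep_default_na=False)
    if "label" not in df.columns:
        raise FormatError(f"{path}: no 'label' column")
    if side is not None and "side" in df.columns:
        df = df[df["side"] == side]
    return df["label"].to_numpy(dtype=str)


def write_events_csv(path, events_by_side: Dict[str, list]) -> None:
    rows = []
    for side in SIDES:
        for k, ev in enumerate(events_by_side.get(side, [])):
            row = {"side": side, "cycle": k}
            row.update(dict(zip(("IC", "LR", "MSt", "TSt", "PSw", "HE", "ISw"), ev)))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_anchored_csv(path, rows: Iterable[dict]) -> None:
    """Tidy anchored-angle table (cycle, side, name, value_deg)."""
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_json_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default) + "\n",
                          encoding="utf-8")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, AnatomicalLabel):
        return obj.value
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
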