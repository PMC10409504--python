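"""Readers and writers for the tabular formats used across the pipeline.

All tables are RFC-4180 CSV.  Trace columns follow the convention
``<name>_<segment>[_<side>]`` (case-insensitive; ``-`` is accepted in place
of ``_``), mirroring ROI labels such as ``nSyb_a4`` or ``A26f-a5``.
Round-trips (write then read) are lossless to 1e-9.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CalciumTrace,
    FormatError,
    HierarchicalDataset,
    LandmarkTrack,
    MuscleTrace,
    Stride,
    StrideTable,
)

_FLOAT_FMT = "%.17g"

_SEGMENT_RE = re.compile(r"^a\d$")


def _parse_trace_label(label: str) -> tuple[str, str, str | None]:
    """Split ``LT2_A5_L`` / ``nSyb-a4`` into (name, segment, side)."""
    parts = re.split(r"[_\-]", label.strip())
    if len(parts) == 2:
        name, seg = parts
        side = None
    elif len(parts) == 3:
        name, seg, side = parts
        if side.upper() not in ("L", "R"):
            raise FormatError(f"unparseable trace column label: {label!r}")
        side = side.upper()
    else:
        raise FormatError(f"unparseable trace column label: {label!r}")
    if not _SEGMENT_RE.match(seg.lower()):
        raise FormatError(f"unparseable trace column label: {label!r} "
                          f"(segment field {seg!r})")
    return name, seg.upper(), side


# ---------------------------------------------------------------------------
# landmark tables


def read_landmark_table(path, dialect: str = "simple", *,
                        frame_rate_hz: float = 30.0,
                        animal_id: str = "animal0",
                        episode_id: str = "episode0") -> list[LandmarkTrack]:
    """Read landmark tracks from CSV.

    ``simple`` dialect: columns ``animal_id, episode_id, frame,
    <landmark>_x, <landmark>_y ...`` (one row per frame, possibly several
    animal x episode blocks).  ``pose-3header`` dialect: the three-header
    pose-estimation layout (scorer / bodyparts / coords) holding one episode;
    ``animal_id``/``episode_id`` are then taken from the keyword arguments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "simple":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise FormatError(f"empty landmark table: {path}") from None
        required = {"animal_id", "episode_id", "frame"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"missing required columns {sorted(missing)}")
        names = _landmark_names(df.columns.drop(list(required)))
        tracks = []
        for (aid, eid), g in df.groupby(["animal_id", "episode_id"], sort=True):
            frames = g["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise FormatError(f"non-monotone frame index for {aid}/{eid}")
            positions = {nm: np.column_stack([g[f"{nm}_x"], g[f"{nm}_y"]])
                         for nm in names}
            tracks.append(LandmarkTrack(str(aid), str(eid), frame_rate_hz,
                                        positions))
        return tracks
    if dialect == "pose-3header":
        try:
            df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        except (pd.errors.EmptyDataError, pd.errors.ParserError):
            raise FormatError(f"empty or malformed pose table: {path}") from None
        if df.empty:
            raise FormatError(f"empty pose table: {path}")
        bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
        positions = {}
        for bp in bodyparts:
            sub = df.xs(bp, axis=1, level=1)
            coords = sub.columns.get_level_values(-1)
            if "x" not in coords or "y" not in coords:
                raise FormatError(f"pose table lacks x/y columns for "
                                  f"body part {bp!r}")
            positions[bp] = np.column_stack(
                [sub.xs("x", axis=1, level=-1).iloc[:, 0],
                 sub.xs("y", axis=1, level=-1).iloc[:, 0]])
        idx = np.asarray(df.index, float)
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise FormatError(f"non-monotone frame index in {path}")
        return [LandmarkTrack(animal_id, episode_id, frame_rate_hz, positions)]
    raise ValueError(f"unknown dialect {dialect!r}")


def _landmark_names(columns) -> list[str]:
    names = []
    for c in columns:
        if c.endswith("_x"):
            nm = c[:-2]
            if f"{nm}_y" not in set(columns):
                raise FormatError(f"missing column {nm}_y for landmark {nm!r}")
            names.append(nm)
        elif not c.endswith("_y"):
            raise FormatError(f"unexpected landmark column {c!r}")
    if not names:
        raise FormatError("no landmark columns found")
    return names


def write_landmark_table(tracks: list[LandmarkTrack], path) -> None:
    frames = []
    for tr in tracks:
        data = {"animal_id": tr.animal_id, "episode_id": tr.episode_id,
                "frame": np.arange(tr.n_frames)}
        for nm, xy in tr.positions.items():
            data[f"{nm}_x"] = xy[:, 0]
            data[f"{nm}_y"] = xy[:, 1]
        frames.append(pd.DataFrame(data))
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False,
                                                float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# trace tables (muscle length / calcium dF/F)


def read_trace_table(path, kind: str, *, frame_rate_hz: float = 30.0,
                     animal_id: str = "", episode_id: str = "",
                     recording_id: str = ""):
    """Read a wide trace table: a ``time`` column plus one column per
    muscle x segment (kind='muscle') or ROI (kind='calcium')."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty trace table: {path}") from None
    cols = [c for c in df.columns if c.lower() != "time"]
    if not cols:
        raise FormatError("trace table has no trace columns")
    out = []
    for c in cols:
        name, seg, side = _parse_trace_label(c)
        series = df[c].to_numpy(float)
        if kind == "muscle":
            out.append(MuscleTrace(name, seg, side, series, frame_rate_hz,
                                   animal_id=animal_id, episode_id=episode_id))
        elif kind == "calcium":
            out.append(CalciumTrace(name, seg, series, frame_rate_hz,
                                    recording_id=recording_id))
        else:
            raise ValueError(f"unknown trace kind {kind!r}")
    return out


def write_trace_table(traces, path) -> None:
    if not traces:
        raise ValueError("no traces to write")
    fps = traces[0].frame_rate_hz
    series = {tr.label: (tr.length if isinstance(tr, MuscleTrace) else tr.dff)
              for tr in traces}
    n = len(next(iter(series.values())))
    df = pd.DataFrame({"time": np.arange(n) / fps, **series})
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stride tables


def write_stride_tables(tables: list[StrideTable], path) -> None:
    df = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def read_stride_tables(path) -> list[StrideTable]:
    df = pd.read_csv(Path(path))
    tables = []
    for (aid, eid), g in df.groupby(["animal_id", "episode_id"], sort=True):
        strides = [Stride(int(r["index"]), r["t_unhook_start"],
                          r["t_wave_onset"], r["t_unhook_end"],
                          r["stride_length"], degenerate=bool(r["degenerate"]))
                   for _, r in g.iterrows()]
        tables.append(StrideTable(str(aid), str(eid), strides))
    return tables


# ---------------------------------------------------------------------------
# hierarchical (group / animal / trial / value) tables


def read_hierarchical_table(path) -> dict[str, HierarchicalDataset]:
    df = pd.read_csv(Path(path))
    required = {"group", "animal", "trial", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required columns {sorted(missing)}")
    out = {}
    for grp, g in df.groupby("group", sort=True):
        animals, ids = [], []
        for aid, ga in g.groupby("animal", sort=True):
            animals.append(ga.sort_values("trial")["value"].to_numpy(float))
            ids.append(str(aid))
        out[str(grp)] = HierarchicalDataset(str(grp), animals, ids)
    return out


def write_hierarchical_table(datasets, path) -> None:
    df = pd.concat([ds.to_frame() for ds in datasets], ignore_index=True)
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# JSON results


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
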