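"""Tracker text files, compiled long-format tables, and TPS interop.

The tracker dialect is the frozen text layout this package reads and writes
for per-video, per-rater, per-trial landmark tracks:

.. code-block:: text

    # casm-tracker v1
    # video_id: v001
    # rater_id: R1
    # trial_id: T1
    # frame_rate: 30.0
    # bolus_label: 5 ml thin
    # y_axis: up
    # phase: oral_transport 0 10
    # phase: pharyngeal 10 31
    frame<TAB>x1<TAB>y1<TAB>...<TAB>x12<TAB>y12
    0<TAB>...

One data row per frame, tab-delimited, 1 + 2*12 columns, frame column
strictly increasing. ``y_axis: down`` declares image-space coordinates; they
are flipped (y -> -y) into the package's canonical anatomical frame
(y increasing superiorly) at read time. Floats are serialized with the
shortest round-trip representation so read(write(series)) is exact.

Many tracker files compile into one long-format table (one landmark per
row), the input to reliability analysis and — via per-frame shapes — to the
morphometric pipeline. Shapes also round-trip through the TPS landmark
format (``LM=``/``ID=`` records) for interop with standard geometric
morphometrics tooling.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .exceptions import (
    CompileCollisionError,
    FrameOrderError,
    TPSFormatError,
    TrackerFormatError,
    TrackerParseError,
)
from .landmark_model import (
    N_LANDMARKS,
    FrameCoordinates,
    LandmarkRegistry,
    PhaseInterval,
    SwallowSeries,
    phase_of_frame,
)

DIALECT_VERSION = "casm-tracker v1"

#: columns of a compiled long-format table, in order
COMPILED_COLUMNS = (
    "video_id",
    "rater_id",
    "trial_id",
    "frame_index",
    "landmark_id",
    "x",
    "y",
    "phase",
)

_KEY_COLUMNS = ["video_id", "rater_id", "trial_id", "frame_index", "landmark_id"]


def _fmt(value: float) -> str:
    # shortest repr that round-trips exactly through float()
    return repr(float(value))


def _header_columns() -> list[str]:
    cols = ["frame"]
    for i in range(1, N_LANDMARKS + 1):
        cols += [f"x{i}", f"y{i}"]
    return cols


def write_tracker_file(series: SwallowSeries, sink: TextIO) -> None:
    """Serialize a series to the tracker dialect (canonical y-up axes)."""
    sink.write(f"# {DIALECT_VERSION}\n")
    sink.write(f"# video_id: {series.video_id}\n")
    sink.write(f"# rater_id: {series.rater_id}\n")
    sink.write(f"# trial_id: {series.trial_id}\n")
    sink.write(f"# frame_rate: {_fmt(series.frame_rate)}\n")
    sink.write(f"# bolus_label: {series.bolus_label}\n")
    sink.write("# y_axis: up\n")
    for iv in series.phases:
        sink.write(f"# phase: {iv.phase} {iv.onset_frame} {iv.offset_frame}\n")
    sink.write("\t".join(_header_columns()) + "\n")
    for frame in series.frames:
        cells = [str(frame.frame_index)]
        for x, y in frame.points:
            cells += [_fmt(x), _fmt(y)]
        sink.write("\t".join(cells) + "\n")


def read_tracker_file(
    source: TextIO, registry: LandmarkRegistry
) -> SwallowSeries:
    """Parse a tracker-dialect file into a :class:`SwallowSeries`.

    Raises :class:`TrackerFormatError` on a wrong column count (naming the
    offending line), :class:`FrameOrderError` if the frame column is not
    strictly increasing, and :class:`TrackerParseError` on non-numeric cells.
    """
    meta = {
        "video_id": "",
        "rater_id": "",
        "trial_id": "",
        "frame_rate": 30.0,
        "bolus_label": "",
        "y_axis": "up",
    }
    phases: list[PhaseInterval] = []
    frames: list[FrameCoordinates] = []
    expected_cols = 1 + 2 * len(registry)
    saw_header = False
    last_index: int | None = None

    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" not in body:
                continue  # version banner or free comment
            key, _, value = body.partition(":")
            key, value = key.strip(), value.strip()
            if key == "phase":
                try:
                    phase, onset, offset = value.split()
                    phases.append(PhaseInterval(phase, int(onset), int(offset)))
                except ValueError as exc:
                    raise TrackerParseError(
                        f"line {lineno}: bad phase comment {value!r}"
                    ) from exc
            elif key == "frame_rate":
                try:
                    meta["frame_rate"] = float(value)
                except ValueError as exc:
                    raise TrackerParseError(
                        f"line {lineno}: bad frame_rate {value!r}"
                    ) from exc
            elif key in meta:
                meta[key] = value
            continue
        if not saw_header:
            cols = line.split("\t")
            if len(cols) != expected_cols:
                raise TrackerFormatError(
                    f"line {lineno}: header has {len(cols)} columns, "
                    f"expected {expected_cols}"
                )
            saw_header = True
            continue
        cells = line.split("\t")
        if len(cells) != expected_cols:
            raise TrackerFormatError(
                f"line {lineno}: row has {len(cells)} columns, "
                f"expected {expected_cols}"
            )
        try:
            frame_index = int(cells[0])
            values = [float(c) for c in cells[1:]]
        except ValueError as exc:
            raise TrackerParseError(
                f"line {lineno}: non-numeric cell in {line!r}"
            ) from exc
        if last_index is not None and frame_index <= last_index:
            raise FrameOrderError(
                f"line {lineno}: frame {frame_index} not greater than "
                f"{last_index}"
            )
        last_index = frame_index
        points = np.array(values, dtype=float).reshape(len(registry), 2)
        if meta["y_axis"] == "down":
            points[:, 1] = -points[:, 1]
        frames.append(
            FrameCoordinates(
                video_id=str(meta["video_id"]),
                frame_index=frame_index,
                points=points,
            )
        )

    if not saw_header:
        raise TrackerFormatError("no header line found")
    return SwallowSeries(
        video_id=str(meta["video_id"]),
        frames=tuple(frames),
        phases=tuple(phases),
        frame_rate=float(meta["frame_rate"]),
        bolus_label=str(meta["bolus_label"]),
        rater_id=str(meta["rater_id"]),
        trial_id=str(meta["trial_id"]),
    )


def compile_tables(series_list: Iterable[SwallowSeries]) -> pd.DataFrame:
    """Compile many series into one long-format table (one landmark per row).

    Record count is ``sum over series of n_frames * 12``; the key
    (video_id, rater_id, trial_id, frame_index, landmark_id) is unique,
    otherwise :class:`CompileCollisionError` is raised. Output is sorted
    canonically by that key, so compilation is order-insensitive.
    """
    chunks = []
    for series in series_list:
        n = series.n_frames
        if n == 0:
            continue
        coords = series.as_array().reshape(n * N_LANDMARKS, 2)
        idx = np.repeat(series.frame_indices, N_LANDMARKS)
        phase = [phase_of_frame(series, i) or "" for i in series.frame_indices]
        chunks.append(
            pd.DataFrame(
                {
                    "video_id": series.video_id,
                    "rater_id": series.rater_id,
                    "trial_id": series.trial_id,
                    "frame_index": idx,
                    "landmark_id": np.tile(
                        np.arange(1, N_LANDMARKS + 1), n
                    ),
                    "x": coords[:, 0],
                    "y": coords[:, 1],
                    "phase": np.repeat(phase, N_LANDMARKS),
                }
            )
        )
    if not chunks:
        return pd.DataFrame(columns=list(COMPILED_COLUMNS))
    table = pd.concat(chunks, ignore_index=True)
    dup = table.duplicated(subset=_KEY_COLUMNS)
    if dup.any():
        first = table.loc[dup.idxmax(), _KEY_COLUMNS].tolist()
        raise CompileCollisionError(
            f"duplicate record key {tuple(first)} while compiling"
        )
    return table.sort_values(_KEY_COLUMNS, kind="mergesort").reset_index(
        drop=True
    )


def write_compiled_table(table: pd.DataFrame, sink: TextIO | str) -> None:
    """Write a compiled table as CSV with header."""
    table.to_csv(sink, index=False)


def read_compiled_table(source: TextIO | str) -> pd.DataFrame:
    """Read a compiled-table CSV written by :func:`write_compiled_table`."""
    table = pd.read_csv(source, keep_default_na=False, dtype={"phase": str})
    missing = set(COMPILED_COLUMNS) - set(table.columns)
    if missing:
        raise TrackerFormatError(
            f"compiled table missing columns {sorted(missing)}"
        )
    return table


def table_to_shapes(
    table: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pivot a compiled table into per-frame shapes.

    Returns ``(shapes, info)`` where ``shapes`` is ``(n_obs, 12, 2)`` (one
    observation per video/rater/trial/frame) and ``info`` one metadata row
    per observation (video_id, rater_id, trial_id, frame_index, phase).
    """
    obs_key = ["video_id", "rater_id", "trial_id", "frame_index"]
    table = table.sort_values(obs_key + ["landmark_id"], kind="mergesort")
    groups = table.groupby(obs_key, sort=True)
    shapes, rows = [], []
    for key, grp in groups:
        if list(grp["landmark_id"]) != list(range(1, N_LANDMARKS + 1)):
            raise TrackerFormatError(
                f"observation {key} lacks a full set of 12 landmarks"
            )
        shapes.append(grp[["x", "y"]].to_numpy(dtype=float))
        rows.append(dict(zip(obs_key, key), phase=grp["phase"].iloc[0]))
    return np.stack(shapes), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TPS landmark format
# ---------------------------------------------------------------------------

def export_tps(
    shapes: Sequence[np.ndarray],
    ids: Sequence[str],
    sink: TextIO,
) -> None:
    """Write shapes as standard TPS records (LM= line, coords, ID= line)."""
    if len(shapes) != len(ids):
        raise ValueError("shapes and ids must have equal length")
    for shape, specimen_id in zip(shapes, ids):
        arr = np.asarray(shape, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise TPSFormatError(f"shape must be (k, 2), got {arr.shape}")
        sink.write(f"LM={arr.shape[0]}\n")
        for x, y in arr:
            sink.write(f"{_fmt(x)} {_fmt(y)}\n")
        sink.write(f"ID={specimen_id}\n")


def read_tps(
    source: TextIO, n_landmarks: int = N_LANDMARKS
) -> tuple[list[np.ndarray], list[str]]:
    """Read TPS records; every record must declare ``LM=n_landmarks``."""
    shapes: list[np.ndarray] = []
    ids: list[str] = []
    pending: list[list[float]] = []
    expected = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            if pending:
                raise TPSFormatError(
                    f"line {lineno}: new LM record before ID of previous"
                )
            expected = int(line[3:])
            if expected != n_landmarks:
                raise TPSFormatError(
                    f"line {lineno}: LM={expected}, expected {n_landmarks}"
                )
            pending = []
        elif upper.startswith("ID="):
            if len(pending) != expected:
                raise TPSFormatError(
                    f"line {lineno}: {len(pending)} coordinate lines for "
                    f"LM={expected}"
                )
            shapes.append(np.array(pending, dtype=float))
            ids.append(line[3:])
            pending, expected = [], 0
        else:
            parts = line.split()
            if len(parts) != 2:
                raise TPSFormatError(
                    f"line {lineno}: expected 'x y', got {line!r}"
                )
            try:
                pending.append([float(parts[0]), float(parts[1])])
            except ValueError as exc:
                raise TPSFormatError(
                    f"line {lineno}: non-numeric coordinate {line!r}"
                ) from exc
    if pending:
        raise TPSFormatError("unterminated TPS record (missing ID= line)")
    return shapes, ids
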