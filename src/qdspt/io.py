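"""Readers and writers for trajectory tables.

Two dialects are supported:

* the MOSAIC Particle Tracker plain-text block format, where each track is
  introduced by a ``%% Trajectory <id>`` header followed by whitespace
  separated ``frame x y`` rows (coordinates in pixels);
* a plain CSV dialect with columns ``trajectory_id, frame, x, y, channel``,
  which round-trips a :class:`~qdspt.core.TrackSet` losslessly.

Acquisition metadata (frame interval, pixel size, localization precision)
travels in a small YAML mapping.
"""

from __future__ import annotations

import io as _io
import warnings
from typing import IO, Iterable, Union

import pandas as pd
import yaml

from .core import PIXELS, AcquisitionMeta, Trajectory, TrackSet

CSV_COLUMNS = ["trajectory_id", "frame", "x", "y", "channel"]

#: Fallback metadata for streams that carry no acquisition information:
#: 25 Hz acquisition, 107 nm pixels.
DEFAULT_META = AcquisitionMeta(frame_interval=0.040, pixel_size=0.107,
                               localization_precision=0.0)


class ParseError(ValueError):
    """Malformed trajectory file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _as_text_stream(source: Union[str, IO[str]], mode: str = "r"):
    if isinstance(source, (str,)):
        return open(source, mode, newline=""), True
    return source, False


def read_particle_tracker(
    source: Union[str, IO[str]],
    meta: AcquisitionMeta = DEFAULT_META,
    channel: str = "",
) -> TrackSet:
    """Parse MOSAIC Particle Tracker text output into a TrackSet.

    Coordinates are taken as pixels and frames as given.  Blank lines and
    ``#`` comment lines are ignored.  A malformed row or a non-monotone
    frame sequence raises :class:`ParseError` naming the line; an input with
    no trajectory blocks yields an empty TrackSet with a warning.
    """
    stream, owned = _as_text_stream(source)
    try:
        trajectories: list[Trajectory] = []
        cur_id: str | None = None
        cur_frames: list[int] = []
        cur_xy: list[tuple[float, float]] = []
        header_line = 0

        def flush(lineno: int) -> None:
            nonlocal cur_id
            if cur_id is None:
                return
            if not cur_frames:
                raise ParseError(f"trajectory {cur_id!r} has no data rows",
                                 header_line)
            try:
                trajectories.append(
                    Trajectory(cur_id, cur_frames, cur_xy, channel=channel,
                               unit=PIXELS)
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
            cur_id = None
            cur_frames.clear()
            cur_xy.clear()

        lineno = 0
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("%%"):
                flush(lineno)
                parts = line.lstrip("%").split()
                if len(parts) < 2 or parts[0].lower() != "trajectory":
                    raise ParseError(f"bad trajectory header {line!r}", lineno)
                cur_id = parts[1]
                header_line = lineno
                continue
            if cur_id is None:
                raise ParseError("data row before any '%% Trajectory' header",
                                 lineno)
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"expected 'frame x y', got {line!r}", lineno)
            try:
                frame = int(float(fields[0]))
                x, y = float(fields[1]), float(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-numeric row {line!r}", lineno) from exc
            if cur_frames and frame <= cur_frames[-1]:
                raise ParseError(
                    f"trajectory {cur_id!r}: frame {frame} not after "
                    f"{cur_frames[-1]}", lineno)
            cur_frames.append(frame)
            cur_xy.append((x, y))
        flush(lineno + 1)

        if not trajectories:
            warnings.warn("no trajectories found in Particle Tracker stream",
                          stacklevel=2)
        return TrackSet(trajectories, meta)
    finally:
        if owned:
            stream.close()


def write_particle_tracker(tracks: TrackSet, dest: Union[str, IO[str]]) -> None:
    """Write a TrackSet in the Particle Tracker block dialect."""
    stream, owned = _as_text_stream(dest, "w")
    try:
        for t in tracks:
            stream.write(f"%% Trajectory {t.id}\n")
            for f, (x, y) in zip(t.frames, t.xy):
                stream.write(f"{int(f)} {float(x)!r} {float(y)!r}\n")
    finally:
        if owned:
            stream.close()


def read_csv_tracks(
    source: Union[str, IO[str]],
    meta: AcquisitionMeta = DEFAULT_META,
    unit: str = PIXELS,
    condition: str = "",
) -> TrackSet:
    """Read the CSV trajectory dialect (trajectory_id, frame, x, y, channel)."""
    df = pd.read_csv(source, dtype={"trajectory_id": str, "channel": str},
                     float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV trajectory table missing columns: {missing}")
    df["channel"] = df["channel"].fillna("")
    trajectories = []
    for tid, sub in df.groupby("trajectory_id", sort=False):
        sub = sub.sort_values("frame")
        channels = sub["channel"].unique()
        if len(channels) > 1:
            raise ValueError(f"trajectory {tid!r}: mixed channels {channels}")
        trajectories.append(
            Trajectory(
                id=str(tid),
                frames=sub["frame"].to_numpy(),
                xy=sub[["x", "y"]].to_numpy(),
                channel=str(channels[0]),
                unit=unit,
            )
        )
    return TrackSet(trajectories, meta, condition)


def write_csv_tracks(tracks: TrackSet, dest: Union[str, IO[str]]) -> None:
    """Write the CSV trajectory dialect; full float precision, lossless."""
    rows: list[dict] = []
    for t in tracks:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append({"trajectory_id": t.id, "frame": int(f),
                         "x": x, "y": y, "channel": t.channel})
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    # repr round-trips float64 exactly
    df.to_csv(dest, index=False, float_format=lambda v: repr(float(v)))


def read_meta_yaml(source: Union[str, IO[str]]) -> AcquisitionMeta:
    """Load AcquisitionMeta from a YAML mapping.

    Keys: ``frame_interval`` (s), ``pixel_size`` (µm/px) and optional
    ``localization_precision`` (µm).
    """
    stream, owned = _as_text_stream(source)
    try:
        data = yaml.safe_load(stream) or {}
    finally:
        if owned:
            stream.close()
    return AcquisitionMeta(
        frame_interval=float(data["frame_interval"]),
        pixel_size=float(data["pixel_size"]),
        localization_precision=float(data.get("localization_precision", 0.0)),
    )


def tracks_to_frame(tracks: TrackSet) -> pd.DataFrame:
    """Long-format DataFrame view (trajectory_id, frame, x, y, channel)."""
    buf = _io.StringIO()
    write_csv_tracks(tracks, buf)
    buf.seek(0)
    return pd.read_csv(buf, dtype={"trajectory_id": str, "channel": str})
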