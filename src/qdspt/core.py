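"""Core domain types for single-particle-tracking data.

A :class:`Trajectory` is one particle's time-ordered localizations with
absolute frame indices; a :class:`TrackSet` bundles trajectories from one
detection channel / condition with the acquisition metadata needed to put
them on physical axes (frame interval, pixel size, localization precision).

Conventions: coordinates are 0-based pixel centers or micrometers (the unit
is tracked explicitly on every trajectory); frame indices are 0-based
integers and strictly increasing within a trajectory.  A trajectory of
``N + 1`` localizations has ``N`` displacements ("steps").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PIXELS = "px"
MICROMETERS = "um"
_UNITS = (PIXELS, MICROMETERS)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition geometry and timing.

    Parameters
    ----------
    frame_interval : float
        Time between consecutive frames in seconds (40 ms at 25 Hz).
    pixel_size : float
        Projected pixel size in micrometers per pixel (0.107 for the
        reference setup).
    localization_precision : float
        Radial localization precision δr in micrometers (δr < 0.030 for a
        good QD setup); contributes an offset ``c ≈ 4·(δr/√2)²`` to the MSD.
    """

    frame_interval: float
    pixel_size: float
    localization_precision: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.localization_precision < 0:
            raise ValueError("localization_precision must be >= 0")


@dataclass(frozen=True)
class Localization:
    """A single detected particle position in one frame."""

    frame: int
    x: float
    y: float
    channel: str = ""

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame index must be >= 0")


@dataclass
class Trajectory:
    """One particle's time-ordered localizations.

    ``frames`` and ``xy`` are parallel arrays: ``frames[i]`` is the absolute
    frame index of position ``xy[i] = (x_i, y_i)``.  Frames are strictly
    increasing but need not be contiguous (blink gaps, bridged links).
    """

    id: str
    frames: np.ndarray
    xy: np.ndarray
    channel: str = ""
    unit: str = PIXELS
    merged_from: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if self.frames.shape[0] != self.xy.shape[0]:
            raise ValueError("frames and xy must have equal length")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("frame indices must be >= 0")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(
                f"trajectory {self.id!r}: frames must be strictly increasing"
            )
        if self.unit not in _UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_displacements(self) -> int:
        """Number of steps: one fewer than the number of localizations."""
        return max(len(self) - 1, 0)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    def localizations(self) -> list[Localization]:
        return [
            Localization(int(f), float(x), float(y), self.channel)
            for f, (x, y) in zip(self.frames, self.xy)
        ]

    @classmethod
    def from_localizations(
        cls,
        id: str,
        locs: list[Localization],
        unit: str = PIXELS,
    ) -> "Trajectory":
        channels = {loc.channel for loc in locs}
        if len(channels) > 1:
            raise ValueError(f"trajectory {id!r}: mixed channels {channels}")
        return cls(
            id=id,
            frames=np.array([loc.frame for loc in locs], dtype=np.int64),
            xy=np.array([[loc.x, loc.y] for loc in locs], dtype=np.float64),
            channel=locs[0].channel if locs else "",
            unit=unit,
        )


@dataclass
class TrackSet:
    """Trajectories from one channel or condition plus acquisition metadata."""

    trajectories: list[Trajectory]
    meta: AcquisitionMeta
    condition: str = ""

    def __post_init__(self) -> None:
        ids = [t.id for t in self.trajectories]
        if len(ids) != len(set(ids)):
            raise ValueError("trajectory ids must be unique within a TrackSet")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def unit(self) -> str:
        units = {t.unit for t in self.trajectories}
        if len(units) > 1:
            raise ValueError(f"mixed units in TrackSet: {units}")
        return units.pop() if units else PIXELS

    def channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trajectories:
            seen.setdefault(t.channel)
        return list(seen)

    def split_by_channel(self) -> dict[str, "TrackSet"]:
        """Partition into per-channel subsets (insertion-ordered)."""
        out: dict[str, TrackSet] = {}
        for ch in self.channels():
            out[ch] = TrackSet(
                [t for t in self.trajectories if t.channel == ch],
                self.meta,
                self.condition,
            )
        return out


def convert_units(tracks: TrackSet, to: str) -> TrackSet:
    """Convert all coordinates between pixels and micrometers.

    The conversion multiplies by ``meta.pixel_size`` (px → µm) or its inverse
    and is involutive to floating precision.  Trajectories already in the
    target unit are passed through unchanged.
    """
    if to not in _UNITS:
        raise ValueError(f"unknown unit {to!r}; expected one of {_UNITS}")
    px = tracks.meta.pixel_size
    converted = []
    for t in tracks.trajectories:
        if t.unit == to:
            converted.append(t)
            continue
        scale = px if to == MICROMETERS else 1.0 / px
        converted.append(replace(t, xy=t.xy * scale, unit=to))
    return TrackSet(converted, tracks.meta, tracks.condition)
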