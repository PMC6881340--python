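"""Core data containers for single-molecule trajectory analysis.

Positions are in nanometres, times in microseconds unless a field name says
otherwise.  The containers are deliberately thin: a :class:`Trajectory` is a
uniformly sampled 1D position record (optionally with a lateral coordinate
and ground-truth state labels), a :class:`SegmentList` is its run-length
encoding, and an :class:`ImageStack` is a stack of camera frames with the
pixel size and frame interval needed to interpret them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """Uniformly sampled position record.

    Parameters
    ----------
    times : array of float
        Frame times in microseconds, strictly increasing with constant
        spacing equal to ``frame_interval``.
    positions : array of float
        1D positions in nm (along the actin axis after projection).
    frame_interval : float
        Frame spacing in microseconds.
    labels : array of int, optional
        Per-frame ground-truth state identifiers (0 = detached,
        ``k + 1`` = binding site ``k``); only present for synthetic data.
    lateral : array of float, optional
        Paired lateral coordinate in nm (2D mode).
    meta : dict
        Free-form provenance (e.g. continuous ground-truth dwells for
        simulated records, the sign convention chosen when projecting).
    """

    times: np.ndarray
    positions: np.ndarray
    frame_interval: float
    labels: Optional[np.ndarray] = None
    lateral: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
        if self.lateral is not None:
            self.lateral = np.asarray(self.lateral, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.times.shape != self.positions.shape or self.times.ndim != 1:
            raise ValueError("times and positions must be 1D arrays of equal length")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, self.frame_interval, rtol=1e-6, atol=1e-6):
                raise ValueError("times must be uniformly spaced at frame_interval")
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        for name in ("labels", "lateral"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != len(self.positions):
                raise ValueError(f"{name} must have the same length as positions")

    def __len__(self) -> int:
        return len(self.positions)

    def to_csv(self, path: str | Path) -> None:
        """Write ``t_us, x_nm[, y_nm][, label]`` with a header line."""
        cols = {"t_us": self.times, "x_nm": self.positions}
        if self.lateral is not None:
            cols["y_nm"] = self.lateral
        if self.labels is not None:
            cols["label"] = self.labels
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        if "t_us" not in df or "x_nm" not in df:
            raise ValueError("trajectory CSV requires columns t_us and x_nm")
        t = df["t_us"].to_numpy(float)
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        return cls(
            times=t,
            positions=df["x_nm"].to_numpy(float),
            frame_interval=dt,
            labels=df["label"].to_numpy(int) if "label" in df else None,
            lateral=df["y_nm"].to_numpy(float) if "y_nm" in df else None,
        )


@dataclass
class SegmentList:
    """Run-length encoding of a state path.

    ``segments`` is an ``(n, 3)`` integer array of
    ``(state id, start frame, n frames)`` rows that tile the record
    without gaps; consecutive rows have different state ids.
    """

    segments: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=int).reshape(-1, 3)

    @classmethod
    def from_labels(cls, labels: Sequence[int], frame_interval: float) -> "SegmentList":
        labels = np.asarray(labels, dtype=int)
        if len(labels) == 0:
            return cls(np.empty((0, 3), dtype=int), frame_interval)
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(labels)]))
        seg = np.column_stack((labels[starts], starts, ends - starts))
        return cls(seg, frame_interval)

    def to_labels(self) -> np.ndarray:
        n = int(self.segments[:, 2].sum()) if len(self.segments) else 0
        out = np.empty(n, dtype=int)
        for state, start, length in self.segments:
            out[start : start + length] = state
        return out

    def dwells(self, state: int, drop_censored: bool = False) -> np.ndarray:
        """Dwell times (us) of maximal runs of ``state``.

        With ``drop_censored`` the first and last segments of the record are
        excluded (their dwells are cut by the observation window).
        """
        seg = self.segments
        mask = seg[:, 0] == state
        if drop_censored and len(seg):
            edge = np.zeros(len(seg), dtype=bool)
            edge[0] = edge[-1] = True
            mask = mask & ~edge
        return seg[mask, 2].astype(float) * self.frame_interval

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class ImageStack:
    """Stack of single-channel camera frames.

    ``frames`` has shape ``(n_frames, ny, nx)`` with non-negative counts.
    Pixel centres sit at integer pixel coordinates; a position in nm is
    ``px * pixel_size``.
    """

    frames: np.ndarray
    pixel_size: float  # nm / px
    frame_interval: float  # us
    true_centers: Optional[np.ndarray] = None  # (n_frames, 2) in px, synthetic only

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_frames, ny, nx)")
        if np.any(self.frames < 0):
            raise ValueError("counts must be non-negative")

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        arr = np.clip(np.rint(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, arr)
        sidecar = {
            "pixel_size_nm": self.pixel_size,
            "frame_interval_us": self.frame_interval,
        }
        if self.true_centers is not None:
            sidecar["true_centers_px"] = np.asarray(self.true_centers).tolist()
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ImageStack":
        import tifffile

        path = Path(path)
        frames = tifffile.imread(path).astype(float)
        if frames.ndim == 2:
            frames = frames[None]
        meta = json.loads(path.with_suffix(".json").read_text())
        centers = meta.get("true_centers_px")
        return cls(
            frames=frames,
            pixel_size=float(meta["pixel_size_nm"]),
            frame_interval=float(meta["frame_interval_us"]),
            true_centers=np.asarray(centers, float) if centers is not None else None,
        )


@dataclass
class Track2D:
    """2D localisation track in the lab frame (nm) with fit diagnostics."""

    times: np.ndarray
    xy: np.ndarray  # (n, 2) nm
    quality: Optional[np.ndarray] = None  # per-frame diagnostic (e.g. SNR)
    flagged: Optional[np.ndarray] = None  # per-frame bool, True = unreliable
    frame_interval: float = 40.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.times) != len(self.xy):
            raise ValueError("times and xy must have equal length")
        if self.flagged is None:
            self.flagged = np.zeros(len(self.xy), dtype=bool)

    def __len__(self) -> int:
        return len(self.xy)

    def valid(self) -> "Track2D":
        """Track restricted to unflagged frames (times kept, spacing may break)."""
        m = ~self.flagged
        return Track2D(
            self.times[m],
            self.xy[m],
            None if self.quality is None else self.quality[m],
            np.zeros(int(m.sum()), dtype=bool),
            self.frame_interval,
            dict(self.meta),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"t_us": self.times, "x_nm": self.xy[:, 0], "y_nm": self.xy[:, 1]})
        if self.quality is not None:
            df["quality"] = self.quality
        df["flagged"] = self.flagged.astype(int)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Track2D":
        df = pd.read_csv(path)
        t = df["t_us"].to_numpy(float)
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 40.0
        return cls(
            times=t,
            xy=np.column_stack((df["x_nm"], df["y_nm"])),
            quality=df["quality"].to_numpy(float) if "quality" in df else None,
            flagged=df["flagged"].to_numpy(bool) if "flagged" in df else None,
            frame_interval=dt,
        )


@dataclass
class FluorescenceTrace:
    """ROI-averaged, background-corrected fluorescence time course."""

    times: np.ndarray  # s
    intensity: np.ndarray  # counts
    frame_rate: float = 1000.0  # fps
    roi: Optional[int] = None
    true_events: Optional[np.ndarray] = None  # (n, 2) start/duration in s, synthetic
    overlap_warning: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must have equal length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.times, "intensity": self.intensity}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_rate: Optional[float] = None) -> "FluorescenceTrace":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy(float)
        if frame_rate is None:
            frame_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1000.0
        return cls(times=t, intensity=df["intensity"].to_numpy(float), frame_rate=frame_rate)
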