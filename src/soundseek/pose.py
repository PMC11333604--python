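"""Pose-track container: per-frame body-part coordinates at a fixed frame rate.

The container mirrors pose-estimation output (e.g. SLEAP exports): a
rectangular ``frames x parts x (x, y)`` array, with NaN marking part-frames
the tracker missed.  Coordinates may be in arena cm (synthetic data) or in
video pixels (real data; converted with the arena calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_FPS = 30.0
DEFAULT_PARTS = ("snout", "head", "left_fore", "right_fore",
                 "left_hind", "right_hind", "trunk", "tail")


@dataclass
class PoseTrack:
    fps: float
    body_parts: tuple
    coords: np.ndarray          # (frames, parts, 2), NaN = missing
    units: str = "cm"           # 'cm' | 'px'
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must be (frames, parts, 2)")
        if self.coords.shape[1] != len(self.body_parts):
            raise ValueError("coords second axis must match body_parts")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def part(self, name: str) -> np.ndarray:
        """(frames, 2) coordinates of one body part."""
        return self.coords[:, self.body_parts.index(name), :]


def pose_to_frame(track: PoseTrack) -> pd.DataFrame:
    """Tidy long-format table: frame, part, x, y."""
    n, p, _ = track.coords.shape
    return pd.DataFrame({
        "frame": np.repeat(np.arange(n), p),
        "part": np.tile(track.body_parts, n),
        "x": track.coords[:, :, 0].ravel(),
        "y": track.coords[:, :, 1].ravel(),
    })


def pose_to_csv(track: PoseTrack, path) -> None:
    df = pose_to_frame(track)
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# fps={track.fps} units={track.units}\n")
        df.to_csv(fh, index=False)


def pose_from_csv(path) -> PoseTrack:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, float_precision="round_trip")
    fields = dict(item.split("=") for item in header.lstrip("# ").split())
    parts = tuple(pd.unique(df["part"]))
    n = df["frame"].max() + 1
    coords = np.full((n, len(parts), 2), np.nan)
    pidx = {p: i for i, p in enumerate(parts)}
    coords[df["frame"].to_numpy(), df["part"].map(pidx).to_numpy(), 0] = df["x"].to_numpy()
    coords[df["frame"].to_numpy(), df["part"].map(pidx).to_numpy(), 1] = df["y"].to_numpy()
    return PoseTrack(fps=float(fields["fps"]), body_parts=parts, coords=coords,
                     units=fields.get("units", "cm"))
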