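"""Core containers and file input/output.

Conventions
-----------
* axial = row axis (depth, increasing downward), lateral = column axis.
* Physical positions are in micrometres (μm), measured from the *center* of
  pixel (0, 0). All indices are 0-based.
* Movies are multi-page 32-bit float TIFF stacks with a JSON metadata
  sidecar (same stem, ``.json`` suffix) carrying pixel sizes, frame rate,
  frame count and the generating seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidParameterError


@dataclass
class FrameSequence:
    """A time-ordered stack of 2D intensity images with physical metadata.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Image intensities. Raw input is nonnegative; filtered residuals may
        be signed.
    frame_rate_hz : float
        Compounded frame rate.
    pixel_size_axial_um, pixel_size_lateral_um : float
        Physical pixel pitch along rows / columns.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_axial_um: float
    pixel_size_lateral_um: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise InvalidParameterError(
                f"frames must be 3D (n_frames, rows, cols), got {self.frames.ndim}D"
            )
        if self.frames.shape[0] < 2:
            raise InvalidParameterError("a frame sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise InvalidParameterError("frames contain non-finite values")
        for name in ("frame_rate_hz", "pixel_size_axial_um", "pixel_size_lateral_um"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of one frame."""
        return self.frames.shape[1:]

    @property
    def pixel_sizes(self) -> tuple[float, float]:
        """(axial, lateral) pixel pitch in μm."""
        return (self.pixel_size_axial_um, self.pixel_size_lateral_um)


def write_movie(seq: FrameSequence, path: str | Path, seed: int | None = None) -> Path:
    """Write a movie as multi-page float32 TIFF plus JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, seq.frames.astype(np.float32))
    sidecar = {
        "pixel_size_axial_um": seq.pixel_size_axial_um,
        "pixel_size_lateral_um": seq.pixel_size_lateral_um,
        "frame_rate_hz": seq.frame_rate_hz,
        "n_frames": int(seq.n_frames),
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_movie(path: str | Path) -> FrameSequence:
    """Read a movie written by :func:`write_movie`."""
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return FrameSequence(
        frames=np.asarray(frames, dtype=np.float64),
        frame_rate_hz=meta["frame_rate_hz"],
        pixel_size_axial_um=meta["pixel_size_axial_um"],
        pixel_size_lateral_um=meta["pixel_size_lateral_um"],
    )


def write_roi(vertices_um, path: str | Path, hilum_um=None, name: str = "LN") -> Path:
    path = Path(path)
    payload = {
        "name": name,
        "vertices_um": [[float(a), float(l)] for a, l in vertices_um],
        "hilum_um": None if hilum_um is None else [float(hilum_um[0]), float(hilum_um[1])],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_roi(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def localizations_to_csv(locs, path: str | Path) -> Path:
    rows = [
        {
            "frame": l.frame,
            "axial_um": l.axial_um,
            "lateral_um": l.lateral_um,
            "intensity": l.intensity,
            "area_px": l.area_px,
            "shape_corr": l.shape_corr,
        }
        for l in locs
    ]
    df = pd.DataFrame(rows, columns=["frame", "axial_um", "lateral_um", "intensity", "area_px", "shape_corr"])
    df.to_csv(path, index=False)
    return Path(path)


def tracks_to_csv(tracks, points_path: str | Path, summary_path: str | Path | None = None):
    """Write per-point and per-track summary CSVs."""
    point_rows = []
    summary_rows = []
    for t in tracks:
        for f, (a, l) in zip(t.frames, t.positions_um):
            point_rows.append({"track_id": t.track_id, "frame": int(f), "axial_um": a, "lateral_um": l})
        summary_rows.append(
            {
                "track_id": t.track_id,
                "length": t.length,
                "mean_speed_mm_s": t.mean_speed_mm_s,
                "vel_axial_mm_s": t.mean_velocity_mm_s[0],
                "vel_lateral_mm_s": t.mean_velocity_mm_s[1],
            }
        )
    pd.DataFrame(point_rows, columns=["track_id", "frame", "axial_um", "lateral_um"]).to_csv(
        points_path, index=False
    )
    if summary_path is not None:
        pd.DataFrame(
            summary_rows,
            columns=["track_id", "length", "mean_speed_mm_s", "vel_axial_mm_s", "vel_lateral_mm_s"],
        ).to_csv(summary_path, index=False)


def truth_tracks_to_csv(tracks, path: str | Path) -> Path:
    rows = []
    for t in tracks:
        speeds = t.step_speeds_mm_s
        for i, (f, (a, l)) in enumerate(zip(t.frames, t.positions_um)):
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": int(f),
                    "axial_um": a,
                    "lateral_um": l,
                    "segment_id": t.segment_id,
                    "true_type": t.true_type,
                    "step_speed_mm_s": speeds[i - 1] if i > 0 else np.nan,
                }
            )
    pd.DataFrame(
        rows,
        columns=["track_id", "frame", "axial_um", "lateral_um", "segment_id", "true_type", "step_speed_mm_s"],
    ).to_csv(path, index=False)
    return Path(path)
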