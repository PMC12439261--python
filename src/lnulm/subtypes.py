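"""Hemodynamic vessel subtyping and lymph-node vascular parameters.

Trajectories are split into three hemodynamic classes.  A node-wise
velocity threshold is taken as the mean flow speed over super-resolution
pixels whose accumulation count exceeds 2 (the persistently perfused,
large-volume regions).  Tracks faster than the threshold are Type 1
(large-diameter, high-flow vessels); the remaining slow tracks are Type 2
(arterial branches) when directed outward from the hilum toward the node
surface and Type 3 (venous branches) when directed inward toward the hilum.
Classification is refused without a hilum point — a node with poorly
defined hilar anatomy cannot be subtyped.

The five scalar vascular parameters quantify a node (or one subtype's
restriction of it): number of tracks, vessel area (binarized SR vascular
pixels), vessel density (% of the LN region), mean flow speed
(track-averaged), and sum of microbubble flow counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import HilumRequiredError, InvalidRoiError, NoSignalError
from .mapping import SRGrid, accumulate_map
from .tracking import Track

TYPE1, TYPE2, TYPE3, UNCLASSIFIED = 1, 2, 3, 0


@dataclass
class SubtypeResult:
    """Per-track subtype labels with the velocity threshold that produced them."""

    threshold_mm_s: float
    threshold_provenance: str  # "qualified-pixels" | "fallback"
    labels: dict  # track_id -> label in {1, 2, 3, 0 (unclassified)}
    radial_scores: dict  # track_id -> signed outward score
    type_counts: dict  # label -> number of tracks
    type_grids: dict | None = None  # label -> SRGrid restricted to that type

    def tracks_of_type(self, tracks: list[Track], label: int) -> list[Track]:
        return [t for t in tracks if self.labels[t.track_id] == label]


@dataclass
class VascularParams:
    """The five lymph-node vascular parameters."""

    n_tracks: int
    vessel_area_px: int
    vessel_density_pct: float
    mean_flow_speed_mm_s: float
    sum_mb_flow_count: int

    def to_dict(self) -> dict:
        return {
            "n_tracks": int(self.n_tracks),
            "vessel_area_px": int(self.vessel_area_px),
            "vessel_density_pct": float(self.vessel_density_pct),
            "mean_flow_speed_mm_s": float(self.mean_flow_speed_mm_s),
            "sum_mb_flow_count": int(self.sum_mb_flow_count),
        }


def compute_velocity_threshold(grid: SRGrid) -> tuple[float, str]:
    """Mean flow speed over ROI pixels with accumulation count > 2.

    "Exceeded 2" is read strictly: a pixel qualifies with count >= 3.  When
    no pixel qualifies the threshold falls back to the mean velocity over
    all vascular (count >= 1) ROI pixels, flagged ``fallback``.
    """
    roi = grid.roi_or_full()
    vascular = (grid.counts >= 1) & roi
    if not vascular.any():
        raise NoSignalError("no vascular pixels inside the ROI")
    qualifying = (grid.counts > 2) & roi
    if qualifying.any():
        return float(grid.velocity[qualifying].mean()), "qualified-pixels"
    warnings.warn(
        "no SR pixel has accumulation count > 2; falling back to the mean "
        "velocity over all vascular pixels",
        stacklevel=2,
    )
    return float(grid.velocity[vascular].mean()), "fallback"


def radial_score(track: Track, hilum_um) -> float:
    """Signed outward component of the net displacement.

    Positive when the track's net displacement points away from the hilum
    (along the unit vector from the hilum to the track centroid), negative
    when it points back toward the hilum.
    """
    hilum = np.asarray(hilum_um, dtype=np.float64)
    radial = track.centroid_um - hilum
    norm = np.linalg.norm(radial)
    if norm == 0:
        return 0.0
    return float(np.dot(np.asarray(track.net_displacement_um), radial / norm))


def classify_tracks(
    tracks: list[Track],
    threshold_mm_s: float,
    hilum_um,
    threshold_provenance: str = "qualified-pixels",
    map_spec: dict | None = None,
) -> SubtypeResult:
    """Assign Type 1/2/3 labels to tracks.

    Type 1: mean speed strictly above the velocity threshold.  Otherwise
    the sign of the radial score decides: outward → Type 2 (arterial),
    inward → Type 3 (venous), exactly zero → unclassified (reported, never
    silently assigned).

    ``map_spec`` — dict with keys ``factor``, ``fov_shape``,
    ``pixel_sizes`` — additionally builds per-type SR grids by re-running
    the accumulation on each class.
    """
    if hilum_um is None:
        raise HilumRequiredError(
            "subtype classification requires a hilum point; node excluded"
        )
    labels: dict[int, int] = {}
    scores: dict[int, float] = {}
    for t in tracks:
        score = radial_score(t, hilum_um)
        scores[t.track_id] = score
        if t.mean_speed_mm_s > threshold_mm_s:
            labels[t.track_id] = TYPE1
        elif score > 0:
            labels[t.track_id] = TYPE2
        elif score < 0:
            labels[t.track_id] = TYPE3
        else:
            labels[t.track_id] = UNCLASSIFIED
    counts = {
        lab: sum(1 for v in labels.values() if v == lab)
        for lab in (TYPE1, TYPE2, TYPE3, UNCLASSIFIED)
    }
    grids = None
    if map_spec is not None:
        grids = {}
        for lab in (TYPE1, TYPE2, TYPE3):
            sel = [t for t in tracks if labels[t.track_id] == lab]
            grids[lab] = accumulate_map(
                sel, map_spec["factor"], map_spec["fov_shape"], map_spec["pixel_sizes"]
            )
    return SubtypeResult(
        threshold_mm_s=threshold_mm_s,
        threshold_provenance=threshold_provenance,
        labels=labels,
        radial_scores=scores,
        type_counts=counts,
        type_grids=grids,
    )


def compute_params(tracks: list[Track], grid: SRGrid) -> VascularParams:
    """The five vascular parameters for a set of tracks and its SR grid.

    A vascular pixel is an ROI pixel with count >= 1; vessel density is the
    percentage of vascular pixels among ROI pixels; mean flow speed is the
    unweighted mean of per-track mean speeds; the flow-count sum adds the
    accumulation map over vascular pixels.
    """
    roi = grid.roi_or_full()
    roi_px = int(roi.sum())
    if roi_px == 0:
        raise InvalidRoiError("empty ROI")
    vascular = (grid.counts >= 1) & roi
    area = int(vascular.sum())
    mean_speed = float(np.mean([t.mean_speed_mm_s for t in tracks])) if tracks else 0.0
    return VascularParams(
        n_tracks=len(tracks),
        vessel_area_px=area,
        vessel_density_pct=100.0 * area / roi_px,
        mean_flow_speed_mm_s=mean_speed,
        sum_mb_flow_count=int(grid.counts[vascular].sum()),
    )
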