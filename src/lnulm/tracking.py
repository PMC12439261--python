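"""Frame-to-frame microbubble linking by minimum-cost assignment.

Localizations in consecutive frames are matched by the Hungarian algorithm
on Euclidean distance.  Gating is implemented by augmenting the cost matrix
with per-item "skip" alternatives priced at ``max_link_distance``, so track
termination and track birth compete fairly with linking; a pair farther
apart than the gate is forbidden outright.  There is no gap closing: a
missed detection ends the track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import InvalidParameterError, InvalidTrackError
from .localize import Localization

_FORBIDDEN = 1e12


@dataclass
class Track:
    """An ordered chain of localizations with per-track kinematics.

    Positions are (axial, lateral) in μm; frames are strictly increasing
    with unit step.  Speeds are in mm/s.
    """

    track_id: int
    frames: np.ndarray
    positions_um: np.ndarray
    frame_rate_hz: float
    mean_speed_mm_s: float = field(init=False)
    mean_velocity_mm_s: tuple[float, float] = field(init=False)
    net_displacement_um: tuple[float, float] = field(init=False)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=np.float64)
        k = compute_kinematics(self.positions_um, self.frame_rate_hz)
        self.mean_speed_mm_s = k["mean_speed_mm_s"]
        self.mean_velocity_mm_s = k["mean_velocity_mm_s"]
        self.net_displacement_um = k["net_displacement_um"]

    @property
    def length(self) -> int:
        return len(self.frames)

    @property
    def centroid_um(self) -> np.ndarray:
        return self.positions_um.mean(axis=0)


def compute_kinematics(positions_um: np.ndarray, frame_rate_hz: float) -> dict:
    """Step-averaged kinematics of an ordered position chain.

    Step velocity = position difference × frame rate; mean speed is the
    mean of step magnitudes (not the endpoint displacement rate), so a
    closed loop has positive mean speed but zero net displacement.
    """
    positions_um = np.asarray(positions_um, dtype=np.float64)
    if positions_um.ndim != 2 or len(positions_um) < 2:
        raise InvalidTrackError("a track needs at least 2 positions")
    steps = np.diff(positions_um, axis=0)  # μm per frame
    step_v = steps * frame_rate_hz / 1000.0  # mm/s
    speeds = np.linalg.norm(step_v, axis=1)
    disp = positions_um[-1] - positions_um[0]
    return {
        "mean_speed_mm_s": float(speeds.mean()),
        "mean_velocity_mm_s": (float(step_v[:, 0].mean()), float(step_v[:, 1].mean())),
        "net_displacement_um": (float(disp[0]), float(disp[1])),
        "step_speeds_mm_s": speeds,
    }


def assignment_matches(
    prev_xy: np.ndarray, next_xy: np.ndarray, max_link_distance: float
) -> list[tuple[int, int]]:
    """Gated minimum-cost matching between two point sets.

    Returns index pairs (i, j) linking ``prev_xy[i]`` to ``next_xy[j]``.
    The objective minimized is

        sum of matched distances + max_link_distance × (number unmatched),

    with pairs beyond the gate forbidden.  Solved as a square assignment on
    an augmented matrix with diagonal skip blocks.
    """
    n1, n2 = len(prev_xy), len(next_xy)
    if n1 == 0 or n2 == 0:
        return []
    d = np.linalg.norm(prev_xy[:, None, :] - next_xy[None, :, :], axis=2)
    cost = np.full((n1 + n2, n1 + n2), 0.0)
    block = np.where(d <= max_link_distance, d, _FORBIDDEN)
    cost[:n1, :n2] = block
    cost[:n1, n2:] = _FORBIDDEN
    cost[:n1, n2:][np.arange(n1), np.arange(n1)] = max_link_distance  # terminate
    cost[n1:, :n2] = _FORBIDDEN
    cost[n1:, :n2][np.arange(n2), np.arange(n2)] = max_link_distance  # birth
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n1 and c < n2 and d[r, c] <= max_link_distance
    ]


def _canonical_order(locs: list[Localization]) -> list[Localization]:
    # content-based ordering makes linking invariant to input permutation
    return sorted(locs, key=lambda l: (l.axial_um, l.lateral_um, l.intensity))


def link_tracks(
    localizations: list[Localization],
    max_link_distance_um: float,
    min_track_length: int,
    frame_rate_hz: float,
) -> tuple[list[Track], dict]:
    """Link per-frame localizations into trajectories.

    Parameters
    ----------
    localizations : flat list of Localization (any order)
    max_link_distance_um : gate distance; defaults elsewhere to
        v_max / frame_rate with v_max = 50 mm/s.
    min_track_length : minimum number of localizations for a track to be
        emitted; shorter chains are discarded and counted in the log.

    Returns
    -------
    (tracks, log) where the log records chains formed, short chains
    discarded, and the localization bookkeeping (every input localization
    ends up in exactly one emitted or discarded chain).
    """
    if max_link_distance_um <= 0:
        raise InvalidParameterError("max_link_distance_um must be positive")
    if min_track_length < 2:
        raise InvalidParameterError("min_track_length must be >= 2")

    by_frame: dict[int, list[Localization]] = {}
    for loc in localizations:
        by_frame.setdefault(loc.frame, []).append(loc)
    frames_sorted = sorted(by_frame)

    active: list[list[Localization]] = []  # chains whose last frame == previous frame
    finished: list[list[Localization]] = []
    prev_frame = None
    for f in frames_sorted:
        locs = _canonical_order(by_frame[f])
        if prev_frame is not None and f == prev_frame + 1 and active:
            prev_xy = np.array(
                [[c[-1].axial_um, c[-1].lateral_um] for c in active]
            )
            next_xy = np.array([[l.axial_um, l.lateral_um] for l in locs])
            matches = assignment_matches(prev_xy, next_xy, max_link_distance_um)
            matched_prev = {i for i, _ in matches}
            matched_next = {j for _, j in matches}
            new_active = []
            for i, j in sorted(matches):
                active[i].append(locs[j])
                new_active.append(active[i])
            finished.extend(c for i, c in enumerate(active) if i not in matched_prev)
            new_active.extend([locs[j]] for j in range(len(locs)) if j not in matched_next)
            active = new_active
        else:
            # frame gap (or no active chains): everything active terminates
            finished.extend(active)
            active = [[l] for l in locs]
        prev_frame = f
    finished.extend(active)

    tracks: list[Track] = []
    discarded = 0
    discarded_locs = 0
    next_id = 0
    for chain in finished:
        if len(chain) < min_track_length:
            discarded += 1
            discarded_locs += len(chain)
            continue
        tracks.append(
            Track(
                track_id=next_id,
                frames=[l.frame for l in chain],
                positions_um=[[l.axial_um, l.lateral_um] for l in chain],
                frame_rate_hz=frame_rate_hz,
            )
        )
        next_id += 1
    log = {
        "n_localizations": len(localizations),
        "chains_formed": len(finished),
        "tracks_emitted": len(tracks),
        "short_chains_discarded": discarded,
        "localizations_in_tracks": int(sum(t.length for t in tracks)),
        "localizations_discarded": discarded_locs,
    }
    return tracks, log
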