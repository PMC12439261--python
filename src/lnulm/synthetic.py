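"""Synthetic lymph-node contrast movies and paired histology with ground truth.

The generator states a small, explicit world so every downstream stage is
testable without animal data:

* a rooted vessel tree entering at the hilum — a trunk that bifurcates
  recursively into an arterial subtree (flow outward, toward the node
  surface) and a venous subtree (flow inward, toward the hilum), with
  radius shrinking by a uniform [0.6, 0.8] ratio per branch and flow speed
  scaling with radius squared (laminar heuristic);
* microbubbles advected along segment centerlines at the segment speed,
  rendered per frame as anisotropic Gaussian echoes on top of a
  near-rank-1 tissue clutter field, with optional rigid sinusoidal
  breathing motion and additive Gaussian noise floored at zero;
* a histology cohort in which a single latent immune-activation variable
  drives both the lymphatic-vessel density painted into the LYVE-1 channel
  and the vascular load (CD31 ring count, ground-truth vessel area and
  track count), so cross-modality correlations have a known truth.

Acquisition defaults follow the study geometry: 500 Hz compounded frame
rate and 1500 frames per plane.  In-vivo flow-speed magnitudes per vessel
class are not published; the defaults (trunk ~15 mm/s, branches ~1–7 mm/s)
are stated placeholders, not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, OutOfBoundsError
from .histology import FluorescenceImage
from .io import FrameSequence
from .localize import FWHM_TO_SIGMA
from .tracking import Track, compute_kinematics


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class VesselSegment:
    segment_id: int
    start_um: np.ndarray  # (axial, lateral)
    end_um: np.ndarray
    radius_um: float
    speed_mm_s: float
    vessel_class: str  # trunk | arterial | venous
    generation: int
    parent_id: int | None = None

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(self.end_um - self.start_um))


@dataclass
class VesselTree:
    """Connected vessel tree rooted at the hilum."""

    segments: list
    hilum_um: np.ndarray
    extent_um: tuple  # ((ax_min, ax_max), (lat_min, lat_max))

    def __post_init__(self):
        self.hilum_um = np.asarray(self.hilum_um, dtype=np.float64)

    def children_of(self, segment_id: int | None) -> list:
        return [s for s in self.segments if s.parent_id == segment_id]

    def root_to_leaf_paths(self) -> list:
        """Every root-to-leaf chain of segments (exhaustive walk)."""
        by_parent: dict = {}
        for s in self.segments:
            by_parent.setdefault(s.parent_id, []).append(s)
        paths = []

        def walk(seg, prefix):
            prefix = prefix + [seg]
            kids = by_parent.get(seg.segment_id, [])
            if not kids:
                paths.append(prefix)
            for k in kids:
                walk(k, prefix)

        for root in by_parent.get(None, []):
            walk(root, [])
        return paths


@dataclass
class AcquisitionConfig:
    """Acquisition geometry and forward-model knobs of one imaging plane."""

    pixel_size_axial_um: float = 50.0
    pixel_size_lateral_um: float = 50.0
    frame_rate_hz: float = 500.0
    n_frames: int = 1500
    rows: int = 128
    cols: int = 128
    psf_fwhm_axial_um: float = 143.0
    psf_fwhm_lateral_um: float = 173.0
    bubble_amplitude: float = 1.0
    tissue_amplitude: float = 5.0
    tissue_modulation: float = 0.02  # ε of the (1 + ε·sin) temporal modulation
    noise_sd: float = 0.0
    motion_amplitude_px: float = 0.0
    motion_period_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        positives = (
            "pixel_size_axial_um",
            "pixel_size_lateral_um",
            "frame_rate_hz",
            "psf_fwhm_axial_um",
            "psf_fwhm_lateral_um",
            "motion_period_s",
        )
        for name in positives:
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.n_frames < 2:
            raise InvalidParameterError("n_frames must be >= 2")
        for name in ("tissue_amplitude", "noise_sd", "motion_amplitude_px"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def pixel_sizes(self) -> tuple[float, float]:
        return (self.pixel_size_axial_um, self.pixel_size_lateral_um)

    @property
    def fov_um(self) -> tuple:
        """((ax_min, ax_max), (lat_min, lat_max)) covered by pixel areas."""
        pa, pl = self.pixel_sizes
        return (
            (-pa / 2.0, (self.rows - 0.5) * pa),
            (-pl / 2.0, (self.cols - 0.5) * pl),
        )


@dataclass
class TruthTrack:
    """Ground-truth bubble trajectory with its host segment and subtype."""

    track_id: int
    frames: np.ndarray
    positions_um: np.ndarray
    segment_id: int
    true_type: int  # 1 trunk, 2 arterial, 3 venous
    frame_rate_hz: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=np.float64)

    @property
    def length(self) -> int:
        return len(self.frames)

    @property
    def step_speeds_mm_s(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.positions_um, axis=0), axis=1)
        return steps * self.frame_rate_hz / 1000.0

    @property
    def mean_speed_mm_s(self) -> float:
        return float(self.step_speeds_mm_s.mean())

    def to_track(self) -> Track:
        return Track(
            track_id=self.track_id,
            frames=self.frames,
            positions_um=self.positions_um,
            frame_rate_hz=self.frame_rate_hz,
        )


@dataclass
class SyntheticCohort:
    """A cohort of synthetic lymph nodes driven by latent immune activation.

    With ``rho`` unset, per-node activations (default: evenly spaced on
    [0, 1]) map affinely to the true lymphatic-vessel density and vascular
    measures, plus optional Gaussian noise (``noise_sd`` is a fraction of
    each variable's span).  With ``rho`` set, (LVD, vessel measures) are
    drawn jointly Gaussian at that latent correlation instead.
    """

    n: int = 8
    activations: np.ndarray | None = None
    rho: float | None = None
    noise_sd: float = 0.0
    lvd_floor_pct: float = 1.0
    lvd_span_pct: float = 8.0
    vessel_area_floor_px: float = 1500.0
    vessel_area_span_px: float = 6000.0
    n_tracks_floor: float = 200.0
    n_tracks_span: float = 800.0
    shape: tuple = (256, 256)
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise InvalidParameterError("a cohort needs at least 2 nodes")
        if self.activations is not None:
            self.activations = np.asarray(self.activations, dtype=np.float64)
            if len(self.activations) != self.n:
                raise InvalidParameterError("len(activations) must equal n")


# --------------------------------------------------------------------------
# vessel tree
# --------------------------------------------------------------------------

TRUNK_RADIUS_UM = 40.0
TRUNK_SPEED_MM_S = 15.0
RADIUS_RATIO = (0.6, 0.8)
BRANCH_ANGLE_DEG = (20.0, 50.0)
MAX_OUTWARD_ANGLE_DEG = 65.0  # branches run from the hilum toward the surface


def generate_vessel_tree(extent_um, max_generation: int, seed: int) -> VesselTree:
    """Grow a bifurcating vessel tree inside a bounding box.

    The trunk (generation 0) enters at the hilum on the lateral edge; from
    its distal end an arterial and a venous subtree (generation >= 1) grow
    by recursive bifurcation.  Radius shrinks by a uniform
    [0.6, 0.8] ratio per generation (so every root-to-leaf radius sequence
    is strictly decreasing) and speed scales with radius squared.
    """
    (ax_min, ax_max), (lat_min, lat_max) = extent_um
    if not (ax_max > ax_min and lat_max > lat_min):
        raise InvalidParameterError("degenerate extent")
    if max_generation < 0:
        raise InvalidParameterError("max_generation must be >= 0")
    rng = np.random.default_rng(seed)
    width = lat_max - lat_min
    height = ax_max - ax_min
    hilum = np.array([0.5 * (ax_min + ax_max), lat_min + 0.05 * width])

    def clip(p):
        return np.array([np.clip(p[0], ax_min, ax_max), np.clip(p[1], lat_min, lat_max)])

    max_out = math.radians(MAX_OUTWARD_ANGLE_DEG)

    def clamp_outward(d, at_point):
        """Keep a growth direction within MAX_OUTWARD_ANGLE of the radial
        (hilum → branch point) direction, so every segment runs outward."""
        rad = np.asarray(at_point, dtype=np.float64) - hilum
        n = np.linalg.norm(rad)
        if n == 0:
            return d
        rad = rad / n
        if float(np.dot(d, rad)) >= math.cos(max_out):
            return d
        sgn = 1.0 if rad[0] * d[1] - rad[1] * d[0] >= 0 else -1.0
        ca, sa = math.cos(max_out), math.sin(max_out) * sgn
        return np.array([rad[0] * ca - rad[1] * sa, rad[0] * sa + rad[1] * ca])

    segments: list[VesselSegment] = []

    def add(start, direction, length, radius, speed, cls, gen, parent):
        end = clip(start + direction * length)
        seg = VesselSegment(
            segment_id=len(segments),
            start_um=np.asarray(start, dtype=np.float64),
            end_um=end,
            radius_um=float(radius),
            speed_mm_s=float(speed),
            vessel_class=cls,
            generation=gen,
            parent_id=parent,
        )
        segments.append(seg)
        return seg

    def grow(seg, direction, cls, gen):
        if gen > max_generation:
            return
        ratio = rng.uniform(*RADIUS_RATIO)
        angle = math.radians(rng.uniform(*BRANCH_ANGLE_DEG))
        length = 0.18 * width * (0.72 ** max(gen - 1, 0))
        for sign in (+1, -1):
            ca, sa = math.cos(sign * angle), math.sin(sign * angle)
            d = np.array(
                [direction[0] * ca + direction[1] * sa, -direction[0] * sa + direction[1] * ca]
            )
            d = clamp_outward(d, seg.end_um)
            r = rng.uniform(*RADIUS_RATIO) * seg.radius_um
            child = add(
                seg.end_um,
                d,
                length,
                r,
                seg.speed_mm_s * (r / seg.radius_um) ** 2,
                cls,
                gen,
                seg.segment_id,
            )
            grow(child, d, cls, gen + 1)

    trunk_dir = np.array([0.0, 1.0])
    trunk = add(hilum, trunk_dir, 0.22 * width, TRUNK_RADIUS_UM, TRUNK_SPEED_MM_S, "trunk", 0, None)
    if max_generation >= 1:
        for cls, tilt in (("arterial", +30.0), ("venous", -30.0)):
            a = math.radians(tilt)
            d = np.array(
                [trunk_dir[0] * math.cos(a) + trunk_dir[1] * math.sin(a),
                 -trunk_dir[0] * math.sin(a) + trunk_dir[1] * math.cos(a)]
            )
            r = rng.uniform(*RADIUS_RATIO) * trunk.radius_um
            child = add(
                trunk.end_um,
                d,
                0.18 * width,
                r,
                trunk.speed_mm_s * (r / trunk.radius_um) ** 2,
                cls,
                1,
                trunk.segment_id,
            )
            grow(child, d, cls, 2)
    return VesselTree(segments=segments, hilum_um=hilum, extent_um=extent_um)


# --------------------------------------------------------------------------
# microbubble transport
# --------------------------------------------------------------------------

_CLASS_TYPE = {"trunk": 1, "arterial": 2, "venous": 3}


def simulate_mb_flow(
    tree: VesselTree,
    n_bubbles: int,
    config: AcquisitionConfig,
    jitter_um: float = 0.0,
    min_separation_um: float = 250.0,
    max_lifetime_frames: int | None = None,
) -> list[TruthTrack]:
    """Advect bubbles along segment centerlines and emit ground-truth tracks.

    Each bubble rides one segment — chosen with probability proportional to
    radius² × length (flow-volume heuristic) — entering at a random arc
    position and frame, advancing by speed/frame_rate per frame along the
    flow direction (arterial and trunk: proximal→distal; venous:
    distal→proximal), carrying a fixed perpendicular offset plus optional
    per-step lateral jitter, both bounded by the segment radius.  Bubbles
    exit at segment ends; tracks shorter than two frames are dropped.

    ``min_separation_um`` enforces the dilute-contrast regime localization
    microscopy needs: candidate bubbles whose trajectory would come closer
    than this to an already placed bubble in any shared frame are resampled
    (set to 0 to disable).  Every emitted track respects the separation, so
    isolated-echo detection and unambiguous linking are properties of the
    stated world, not luck.

    ``max_lifetime_frames`` bounds a bubble's in-plane residence: 2D
    imaging sections 3D flow, so a bubble crosses the elevational slice in
    a bounded time even when its in-plane speed is low.  Defaults to 15% of
    the acquisition length; a quasi-static bubble that persisted for a
    large fraction of the ensemble would bleed into the clutter subspace of
    any spatiotemporal filter.
    """
    if not tree.segments:
        raise InvalidParameterError("empty vessel tree")
    if n_bubbles < 0:
        raise InvalidParameterError("n_bubbles must be >= 0")
    rng = np.random.default_rng([config.seed % (2**31), 101])
    if n_bubbles == 0:
        return []
    if max_lifetime_frames is None:
        max_lifetime_frames = max(int(round(0.15 * config.n_frames)), 2)
    weights = np.array([s.radius_um**2 * s.length_um for s in tree.segments])
    weights = weights / weights.sum()
    (ax_min, ax_max), (lat_min, lat_max) = tree.extent_um
    tracks: list[TruthTrack] = []
    occupancy: dict[int, list[np.ndarray]] = {}  # frame -> positions of placed bubbles
    tid = 0
    attempts = 0
    max_attempts = 200 * max(n_bubbles, 1)
    while tid < n_bubbles and attempts < max_attempts:
        attempts += 1
        seg = tree.segments[rng.choice(len(tree.segments), p=weights)]
        if seg.vessel_class == "venous":
            origin, target = seg.end_um, seg.start_um
        else:
            origin, target = seg.start_um, seg.end_um
        length = np.linalg.norm(target - origin)
        if length == 0:
            continue
        u = (target - origin) / length
        perp = np.array([-u[1], u[0]])
        offset = rng.uniform(-seg.radius_um, seg.radius_um)
        s = rng.uniform(0.0, 0.8 * length)
        f = int(rng.integers(0, max(config.n_frames - 1, 1)))
        ds = seg.speed_mm_s * 1000.0 / config.frame_rate_hz  # μm per frame
        lifetime = int(rng.integers(max(max_lifetime_frames // 2, 2), max_lifetime_frames + 1))
        frames, positions = [], []
        while s <= length and f < config.n_frames and len(frames) < lifetime:
            lateral_off = offset
            if jitter_um > 0:
                lateral_off = np.clip(
                    offset + rng.uniform(-jitter_um, jitter_um),
                    -seg.radius_um,
                    seg.radius_um,
                )
            p = origin + u * s + perp * lateral_off
            p = np.array([np.clip(p[0], ax_min, ax_max), np.clip(p[1], lat_min, lat_max)])
            frames.append(f)
            positions.append(p)
            s += ds
            f += 1
        if len(frames) < 2:
            continue
        if min_separation_um > 0:
            clash = False
            for fr, p in zip(frames, positions):
                for q in occupancy.get(fr, ()):
                    if np.hypot(p[0] - q[0], p[1] - q[1]) < min_separation_um:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                continue
            for fr, p in zip(frames, positions):
                occupancy.setdefault(fr, []).append(p)
        tracks.append(
            TruthTrack(
                track_id=tid,
                frames=np.array(frames),
                positions_um=np.array(positions),
                segment_id=seg.segment_id,
                true_type=_CLASS_TYPE[seg.vessel_class],
                frame_rate_hz=config.frame_rate_hz,
            )
        )
        tid += 1
    return tracks


# --------------------------------------------------------------------------
# frame rendering
# --------------------------------------------------------------------------

def tissue_field(config: AcquisitionConfig) -> np.ndarray:
    """The fixed smooth clutter pattern (min–max scaled to [0, 1])."""
    rng = np.random.default_rng([config.seed % (2**31), 202])
    f = ndimage.gaussian_filter(rng.standard_normal(config.shape), sigma=6.0)
    f -= f.min()
    peak = f.max()
    return f / peak if peak > 0 else f


def motion_shifts_px(config: AcquisitionConfig) -> np.ndarray:
    """Per-frame rigid axial shift of the sinusoidal breathing model."""
    t = np.arange(config.n_frames) / config.frame_rate_hz
    return config.motion_amplitude_px * np.sin(2.0 * math.pi * t / config.motion_period_s)


def render_frames(tracks: list[TruthTrack], config: AcquisitionConfig) -> FrameSequence:
    """Forward model: PSF-blurred bubbles + modulated tissue + motion + noise.

    Each bubble echo is an anisotropic Gaussian with the configured
    axial/lateral FWHM centered at its true position; the tissue pattern is
    one fixed smooth field times a slow (1 + ε·sin) temporal modulation, so
    its Casorati matrix is rank 1; rigid breathing translates whole frames
    axially by a sampled sinusoid; Gaussian noise is added last and the
    result floored at zero.
    """
    pa, pl = config.pixel_sizes
    (ax_lo, ax_hi), (lat_lo, lat_hi) = config.fov_um
    bad = [
        t.track_id
        for t in tracks
        if (t.positions_um[:, 0] < ax_lo).any()
        or (t.positions_um[:, 0] > ax_hi).any()
        or (t.positions_um[:, 1] < lat_lo).any()
        or (t.positions_um[:, 1] > lat_hi).any()
    ]
    if bad:
        raise OutOfBoundsError(f"tracks outside the field of view: {bad}", track_ids=bad)

    sigma_a = config.psf_fwhm_axial_um / FWHM_TO_SIGMA / pa
    sigma_l = config.psf_fwhm_lateral_um / FWHM_TO_SIGMA / pl
    wa = int(math.ceil(6.0 * sigma_a))
    wl = int(math.ceil(6.0 * sigma_l))
    rows, cols = config.shape
    out = np.zeros((config.n_frames, rows, cols), dtype=np.float64)

    for t in tracks:
        for f, (a_um, l_um) in zip(t.frames, t.positions_um):
            rc = a_um / pa
            cc = l_um / pl
            r0, r1 = max(int(math.floor(rc)) - wa, 0), min(int(math.floor(rc)) + wa + 2, rows)
            c0, c1 = max(int(math.floor(cc)) - wl, 0), min(int(math.floor(cc)) + wl + 2, cols)
            rr, ccg = np.mgrid[r0:r1, c0:c1]
            out[f, r0:r1, c0:c1] += config.bubble_amplitude * np.exp(
                -((rr - rc) ** 2) / (2 * sigma_a**2) - ((ccg - cc) ** 2) / (2 * sigma_l**2)
            )

    if config.tissue_amplitude > 0:
        pattern = tissue_field(config) * config.tissue_amplitude
        mod = 1.0 + config.tissue_modulation * np.sin(
            2.0 * math.pi * np.arange(config.n_frames) / config.n_frames
        )
        out += mod[:, None, None] * pattern[None, :, :]

    if config.motion_amplitude_px > 0:
        for f, shift in enumerate(motion_shifts_px(config)):
            if shift != 0:
                out[f] = np.fft.ifft2(
                    ndimage.fourier_shift(np.fft.fft2(out[f]), (shift, 0.0))
                ).real

    if config.noise_sd > 0:
        rng = np.random.default_rng([config.seed % (2**31), 303])
        out += config.noise_sd * rng.standard_normal(out.shape)

    np.maximum(out, 0.0, out=out)
    return FrameSequence(
        frames=out,
        frame_rate_hz=config.frame_rate_hz,
        pixel_size_axial_um=pa,
        pixel_size_lateral_um=pl,
    )


# --------------------------------------------------------------------------
# histology cohort
# --------------------------------------------------------------------------

def draw_cohort_truth(cohort: SyntheticCohort) -> list[dict]:
    """Per-node ground-truth values (no images).

    Affine-in-activation mode (``rho`` unset): every measure is a monotone
    affine map of activation plus optional noise, so the noiseless
    LVD–vessel-area correlation is exactly 1.  Latent-correlation mode
    (``rho`` set): LVD and the vascular measures are jointly Gaussian with
    correlation ``rho``; the recorded activation is the LVD normal score.
    """
    rng = np.random.default_rng([cohort.seed % (2**31), 404])
    if cohort.rho is None:
        a = (
            cohort.activations
            if cohort.activations is not None
            else np.linspace(0.0, 1.0, cohort.n)
        )
        lvd = cohort.lvd_floor_pct + cohort.lvd_span_pct * a
        area = cohort.vessel_area_floor_px + cohort.vessel_area_span_px * a
        n_tracks = cohort.n_tracks_floor + cohort.n_tracks_span * a
        if cohort.noise_sd > 0:
            lvd = lvd + cohort.noise_sd * cohort.lvd_span_pct * rng.standard_normal(cohort.n)
            area = area + cohort.noise_sd * cohort.vessel_area_span_px * rng.standard_normal(cohort.n)
            n_tracks = n_tracks + cohort.noise_sd * cohort.n_tracks_span * rng.standard_normal(cohort.n)
        act = np.asarray(a, dtype=np.float64)
    else:
        cov = [[1.0, cohort.rho], [cohort.rho, 1.0]]
        z = rng.multivariate_normal([0.0, 0.0], cov, size=cohort.n)
        mid_l = cohort.lvd_floor_pct + 0.5 * cohort.lvd_span_pct
        mid_a = cohort.vessel_area_floor_px + 0.5 * cohort.vessel_area_span_px
        lvd = mid_l + 0.25 * cohort.lvd_span_pct * z[:, 0]
        area = mid_a + 0.25 * cohort.vessel_area_span_px * z[:, 1]
        n_tracks = cohort.n_tracks_floor + 0.5 * cohort.n_tracks_span + 0.25 * cohort.n_tracks_span * z[:, 1]
        from scipy.stats import norm

        act = norm.cdf(z[:, 0])
    lvd = np.clip(lvd, 0.05, 99.0)
    return [
        {
            "node": i,
            "activation": float(act[i]),
            "true_lvd_pct": float(lvd[i]),
            "true_vessel_area_px": float(area[i]),
            "true_n_tracks": float(n_tracks[i]),
        }
        for i in range(cohort.n)
    ]


def _paint_disks(mask: np.ndarray, target_fraction: float, radius_range, rng) -> float:
    """Paint random disks until the positive fraction reaches the target;
    returns the achieved fraction (overshoot bounded by one disk)."""
    rows, cols = mask.shape
    total = rows * cols
    target = target_fraction * total
    guard = 0
    while mask.sum() < target and guard < 100000:
        guard += 1
        r = int(rng.integers(*radius_range))
        cr = int(rng.integers(r, rows - r))
        cc = int(rng.integers(r, cols - r))
        rr, ccg = np.ogrid[-r : r + 1, -r : r + 1]
        disk = rr**2 + ccg**2 <= r**2
        mask[cr - r : cr + r + 1, cc - r : cc + r + 1] |= disk
    return mask.sum() / total


def _paint_rings(mask: np.ndarray, n_rings: int, rng) -> None:
    rows, cols = mask.shape
    for _ in range(n_rings):
        r_out = int(rng.integers(6, 12))
        r_in = max(r_out - 3, 2)
        cr = int(rng.integers(r_out, rows - r_out))
        cc = int(rng.integers(r_out, cols - r_out))
        rr, ccg = np.ogrid[-r_out : r_out + 1, -r_out : r_out + 1]
        d2 = rr**2 + ccg**2
        ring = (d2 <= r_out**2) & (d2 >= r_in**2)
        mask[cr - r_out : cr + r_out + 1, cc - r_out : cc + r_out + 1] |= ring


def simulate_histology_cohort(cohort: SyntheticCohort) -> list[tuple]:
    """Render per-node fluorescence channels paired with ground truth.

    Per node: a CD31 channel of vessel annuli (ring count scaling with
    activation), a LYVE1 channel of blobs whose painted area fraction
    matches the node's true lymphatic-vessel density up to rasterization
    error, and DAPI / COL1 filler channels.  Returns
    ``[(FluorescenceImage, truth dict), ...]``; the truth dict carries the
    node's latent activation and true LVD / vessel area / track count.
    """
    truth = draw_cohort_truth(cohort)
    out = []
    for row in truth:
        rng = np.random.default_rng([cohort.seed % (2**31), 505, row["node"]])
        shape = tuple(cohort.shape)
        lyve1 = np.zeros(shape, dtype=bool)
        achieved = _paint_disks(lyve1, row["true_lvd_pct"] / 100.0, (3, 6), rng)
        cd31 = np.zeros(shape, dtype=bool)
        n_rings = int(round(4 + 16 * np.clip(row["activation"], 0, 1)))
        _paint_rings(cd31, n_rings, rng)
        dapi = ndimage.gaussian_filter(rng.random(shape), sigma=1.0)
        col1 = ndimage.gaussian_filter(rng.random(shape), sigma=8.0)
        img = FluorescenceImage(
            channels={
                "CD31": cd31.astype(np.float64),
                "LYVE1": lyve1.astype(np.float64),
                "DAPI": dapi,
                "COL1": col1 / max(col1.max(), 1e-12),
            }
        )
        row = dict(row)
        row["achieved_lvd_pct"] = 100.0 * achieved
        out.append((img, row))
    return out


# --------------------------------------------------------------------------
# default end-to-end fixture
# --------------------------------------------------------------------------

def default_fixture(
    seed: int = 42,
    n_frames: int = 200,
    shape: tuple = (128, 128),
    n_bubbles: int = 40,
    max_generation: int = 3,
    tissue_amplitude: float = 5.0,
    noise_sd: float = 0.0,
) -> dict:
    """The standard desk-scale simulation used by tests and the CLI.

    Returns a dict with the vessel tree, ground-truth tracks, rendered
    movie, acquisition config, LN ROI polygon (an octagon covering most of
    the field of view) and the hilum point.
    """
    config = AcquisitionConfig(
        n_frames=n_frames,
        rows=shape[0],
        cols=shape[1],
        tissue_amplitude=tissue_amplitude,
        noise_sd=noise_sd,
        seed=seed,
    )
    pa, pl = config.pixel_sizes
    extent = ((8 * pa, (shape[0] - 9) * pa), (8 * pl, (shape[1] - 9) * pl))
    tree = generate_vessel_tree(extent, max_generation=max_generation, seed=seed)
    tracks = simulate_mb_flow(tree, n_bubbles=n_bubbles, config=config)
    movie = render_frames(tracks, config)
    (ax0, ax1), (l0, l1) = extent
    da, dl = 0.25 * (ax1 - ax0), 0.25 * (l1 - l0)
    roi_vertices = [
        (ax0 - 2 * pa, l0 + dl),
        (ax0 - 2 * pa, l1 - dl),
        (ax0 + da, l1 + 2 * pl),
        (ax1 - da, l1 + 2 * pl),
        (ax1 + 2 * pa, l1 - dl),
        (ax1 + 2 * pa, l0 + dl),
        (ax1 - da, l0 - 2 * pl),
        (ax0 + da, l0 - 2 * pl),
    ]
    return {
        "config": config,
        "tree": tree,
        "truth_tracks": tracks,
        "movie": movie,
        "roi_vertices_um": roi_vertices,
        "hilum_um": tuple(tree.hilum_um),
    }
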