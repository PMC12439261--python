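"""Spatiotemporal clutter filtering and tissue-motion handling.

The microbubble signal is separated from quasi-stationary tissue clutter by
a singular value decomposition of the Casorati matrix (pixels × frames):
tissue concentrates in the largest singular components, electronic noise in
the smallest, and moving bubbles in between.  The filter is exposed as an
explicit 1-based rank band ``[low_rank, high_rank]`` — reconstruction keeps
exactly those components — because an explicit, logged band is reproducible
where an "appropriate threshold" is not.

Out-of-plane motion is handled by rejecting frames that decorrelate from
the most recently kept frame; residual in-plane breathing motion is removed
by rigid (translation-only) compensation from phase correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import InvalidParameterError
from .io import FrameSequence


@dataclass
class FilterReport:
    """Provenance record of a preprocessing step.

    Attributes
    ----------
    singular_values : ndarray
        Full singular spectrum of the Casorati matrix, descending.
    band : (int, int) or None
        Retained 1-based rank band [low, high], inclusive.
    kept_frames : list of int
        Indices of frames surviving motion rejection (strictly increasing).
    shifts_px : ndarray, shape (n_frames, 2) or None
        Estimated per-frame rigid shift (Δrow, Δcol) relative to reference.
    correlations : list of float
        Per-frame correlation with the most recently kept frame (motion
        rejection) — index 0 entry is 1.0 by convention.
    """

    singular_values: np.ndarray | None = None
    band: tuple[int, int] | None = None
    kept_frames: list = field(default_factory=list)
    shifts_px: np.ndarray | None = None
    correlations: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "singular_values": None
            if self.singular_values is None
            else [float(s) for s in self.singular_values],
            "band": None if self.band is None else [int(self.band[0]), int(self.band[1])],
            "kept_frames": [int(i) for i in self.kept_frames],
            "shifts_px": None if self.shifts_px is None else np.asarray(self.shifts_px).tolist(),
            "correlations": [float(c) for c in self.correlations],
        }


def default_low_rank(n_frames: int) -> int:
    """Default lower cut of the clutter band: ceil(5% of the frame count)."""
    return int(math.ceil(0.05 * n_frames))


def svd_filter(
    seq: FrameSequence, low_rank: int, high_rank: int | None = None
) -> tuple[FrameSequence, FilterReport]:
    """Band-pass the singular spectrum of the Casorati matrix.

    Parameters
    ----------
    seq : FrameSequence
    low_rank : int
        1-based index of the first retained singular component.  Components
        1..low_rank-1 (tissue clutter) are removed.
    high_rank : int or None
        Last retained component; ``None`` keeps everything above
        ``low_rank`` (no noise cut).

    Returns
    -------
    (FrameSequence, FilterReport)
        The filtered residual stack (may be signed — downstream detection
        uses magnitude) and the report with the full singular spectrum.
    """
    n, rows, cols = seq.frames.shape
    rank_max = min(n, rows * cols)
    if not (1 <= low_rank <= rank_max):
        raise InvalidParameterError(
            f"low_rank must be in [1, {rank_max}], got {low_rank}"
        )
    if high_rank is None:
        high_rank = rank_max
    if high_rank < low_rank:
        raise InvalidParameterError("high_rank must be >= low_rank")
    high_rank = min(high_rank, rank_max)

    # Casorati matrix: space down the rows, time across the columns.
    casorati = seq.frames.reshape(n, rows * cols).T
    u, s, vt = np.linalg.svd(casorati, full_matrices=False)
    sl = slice(low_rank - 1, high_rank)
    recon = (u[:, sl] * s[sl]) @ vt[sl]
    out = FrameSequence(
        frames=recon.T.reshape(n, rows, cols),
        frame_rate_hz=seq.frame_rate_hz,
        pixel_size_axial_um=seq.pixel_size_axial_um,
        pixel_size_lateral_um=seq.pixel_size_lateral_um,
    )
    report = FilterReport(singular_values=s.copy(), band=(low_rank, high_rank))
    return out, report


def _zero_normalized_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two images; NaN when either is constant."""
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return float("nan")
    return float(np.dot(a, b) / denom)


def reject_motion_frames(seq: FrameSequence, min_correlation: float = 0.9) -> FilterReport:
    """Flag frames decorrelated from the running reference as motion frames.

    Frame 0 is always kept.  Frame *t* is kept iff its zero-normalized
    correlation with the most recently *kept* frame is at least
    ``min_correlation``; strong decorrelation indicates out-of-plane
    motion.  A constant (zero-variance) frame has undefined correlation and
    is rejected with a warning.
    """
    if not (0 < min_correlation <= 1):
        raise InvalidParameterError("min_correlation must be in (0, 1]")
    kept = [0]
    correlations = [1.0]
    for t in range(1, seq.n_frames):
        c = _zero_normalized_correlation(seq.frames[kept[-1]], seq.frames[t])
        correlations.append(c)
        if np.isnan(c):
            warnings.warn(
                f"frame {t}: zero-variance frame, correlation undefined; rejected",
                stacklevel=2,
            )
            continue
        if c >= min_correlation:
            kept.append(t)
    return FilterReport(kept_frames=kept, correlations=correlations)


def select_frames(seq: FrameSequence, kept_frames) -> FrameSequence:
    """Restrict a sequence to the kept frame indices."""
    return FrameSequence(
        frames=seq.frames[np.asarray(kept_frames, dtype=int)],
        frame_rate_hz=seq.frame_rate_hz,
        pixel_size_axial_um=seq.pixel_size_axial_um,
        pixel_size_lateral_um=seq.pixel_size_lateral_um,
    )


def rigid_compensate(
    seq: FrameSequence, reference_index: int = 0, upsample: int = 10
) -> tuple[FrameSequence, FilterReport]:
    """Estimate and undo per-frame rigid translation.

    Shifts are estimated by phase correlation against the reference frame
    with subpixel refinement to 1/``upsample`` px, then each frame is
    translated by the negated shift (Fourier shift, periodic boundary).
    An all-zero frame gets shift (0, 0) with a warning.
    """
    if not (0 <= reference_index < seq.n_frames):
        raise InvalidParameterError(f"reference_index {reference_index} out of range")
    if upsample < 1:
        raise InvalidParameterError("upsample must be >= 1")
    ref = seq.frames[reference_index]
    n = seq.n_frames
    shifts = np.zeros((n, 2), dtype=np.float64)
    out = np.empty_like(seq.frames)
    for t in range(n):
        frame = seq.frames[t]
        if not np.any(frame):
            warnings.warn(f"frame {t}: all-zero frame, shift set to (0, 0)", stacklevel=2)
            out[t] = frame
            continue
        if t == reference_index:
            out[t] = frame
            continue
        correction, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample, normalization=None
        )
        # estimated displacement of this frame relative to the reference;
        # the applied correction is its negation
        shifts[t] = -correction
        if np.allclose(correction, 0):
            out[t] = frame
        else:
            out[t] = np.fft.ifft2(
                ndimage.fourier_shift(np.fft.fft2(frame), correction)
            ).real
    return (
        FrameSequence(
            frames=out,
            frame_rate_hz=seq.frame_rate_hz,
            pixel_size_axial_um=seq.pixel_size_axial_um,
            pixel_size_lateral_um=seq.pixel_size_lateral_um,
        ),
        FilterReport(shifts_px=shifts),
    )
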