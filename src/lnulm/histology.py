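"""Vessel-density quantification from multi-channel immunofluorescence.

CD31 marks blood-vessel endothelium, LYVE-1 marks lymphatic endothelium.
Each channel is binarized by Otsu's threshold (256-bin histogram of the
min–max-scaled intensities) followed by morphological opening; luminal
structures — background regions fully enclosed by foreground — are filled
to reconstruct complete vessel cross-sections.  LYVE-1-positive area is
then subtracted from the CD31-positive area to discriminate blood from
lymphatic vessels, and each density is the percentage of positive pixels
within the LN region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening

from .errors import InvalidParameterError, InvalidRoiError, ShapeMismatchError

REQUIRED_CHANNELS = ("CD31", "LYVE1")
N_BINS = 256


@dataclass
class FluorescenceImage:
    """Named fluorescence channels of one lymph-node section.

    Standard stains: CD31 (vasculature), LYVE1 (lymphatics), DAPI (nuclei),
    COL1 (collagen/stroma).  CD31 and LYVE1 are required for density
    computation; all channels share one shape.
    """

    channels: dict
    pixel_size_um: float = 1.0
    roi_mask: np.ndarray | None = None

    def __post_init__(self):
        if not self.channels:
            raise InvalidParameterError("no channels supplied")
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ShapeMismatchError("channels must share one shape")
        self.channels = {k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()}
        if self.roi_mask is not None and self.roi_mask.shape not in shapes:
            raise ShapeMismatchError("ROI mask must match channel shape")

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    def require(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise InvalidParameterError(f"required channel {name!r} missing")
        return self.channels[name]


@dataclass
class DensityResult:
    """Blood / lymphatic vessel densities and the masks that produced them."""

    bvd_pct: float
    lvd_pct: float
    blood_mask: np.ndarray
    lymph_mask: np.ndarray
    log: dict = field(default_factory=dict)


def otsu_threshold_scaled(channel: np.ndarray) -> float | None:
    """Otsu cut on a 256-bin histogram of the min–max-scaled channel.

    Returns the threshold on the [0, 1] scale (upper edge of the background
    bin maximizing between-class variance), or None for a constant channel.
    """
    channel = np.asarray(channel, dtype=np.float64)
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        return None
    scaled = (channel - lo) / (hi - lo)
    hist, edges = np.histogram(scaled, bins=N_BINS, range=(0.0, 1.0))
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]  # background weight for cut after bin k
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    mu_total = m[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (mu_total - m[:-1]) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.nan_to_num(between, nan=-1.0)
    k = int(np.argmax(between))  # lowest cut on ties
    return float(edges[k + 1])


def binarize_channel(channel: np.ndarray, opening_radius: int = 1) -> tuple[np.ndarray, dict]:
    """Otsu binarization followed by morphological opening.

    A constant channel has a degenerate histogram; an empty mask is
    returned with a warning.  The log records the threshold (on the scaled
    and original intensity scales) and the opening radius.
    """
    channel = np.asarray(channel, dtype=np.float64)
    thr = otsu_threshold_scaled(channel)
    if thr is None:
        warnings.warn("constant channel: degenerate histogram, empty mask", stacklevel=2)
        return np.zeros(channel.shape, dtype=bool), {"threshold_scaled": None, "opening_radius": opening_radius}
    lo, hi = channel.min(), channel.max()
    scaled = (channel - lo) / (hi - lo)
    mask = scaled > thr
    if opening_radius > 0:
        mask = opening(mask, disk(opening_radius))
    return mask, {
        "threshold_scaled": thr,
        "threshold_intensity": lo + thr * (hi - lo),
        "opening_radius": opening_radius,
    }


def fill_lumina(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Fill background regions enclosed by foreground (vessel lumina).

    Background connectivity is 4-connected (the dual of the 8-connected
    foreground convention); a background component is filled iff it cannot
    reach the image border.  Returns the filled mask and the number of
    holes filled.
    """
    mask = np.asarray(mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    holes = filled & ~mask
    _, n_holes = ndimage.label(holes)
    return filled, int(n_holes)


def blood_lymph_split(cd31_mask: np.ndarray, lyve1_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract LYVE-1-positive area from CD31 to isolate blood vessels."""
    if cd31_mask.shape != lyve1_mask.shape:
        raise ShapeMismatchError("CD31 and LYVE1 masks must share shape")
    blood = cd31_mask & ~lyve1_mask
    return blood, lyve1_mask.copy()


def compute_density(mask: np.ndarray, roi_mask: np.ndarray | None = None) -> float:
    """Percentage of positive pixels within the LN region."""
    mask = np.asarray(mask, dtype=bool)
    if roi_mask is None:
        roi_mask = np.ones(mask.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n_roi = roi_mask.sum()
    if n_roi == 0:
        raise InvalidRoiError("empty ROI")
    return float(100.0 * (mask & roi_mask).sum() / n_roi)


def quantify_node(
    image: FluorescenceImage,
    opening_radius: int = 1,
    subtract_first: bool = False,
) -> DensityResult:
    """Full density quantification of one node's CD31/LYVE1 channels.

    Default order fills CD31 lumina first and subtracts LYVE-1 second;
    ``subtract_first`` flips that order.
    """
    cd31, log_c = binarize_channel(image.require("CD31"), opening_radius)
    lyve1, log_l = binarize_channel(image.require("LYVE1"), opening_radius)
    lyve1, holes_l = fill_lumina(lyve1)
    if subtract_first:
        blood, lymph = blood_lymph_split(cd31, lyve1)
        blood, holes_c = fill_lumina(blood)
        # refilling may re-capture lymphatic pixels; subtract again to keep
        # the masks disjoint
        blood &= ~lymph
    else:
        cd31, holes_c = fill_lumina(cd31)
        blood, lymph = blood_lymph_split(cd31, lyve1)
    return DensityResult(
        bvd_pct=compute_density(blood, image.roi_mask),
        lvd_pct=compute_density(lymph, image.roi_mask),
        blood_mask=blood,
        lymph_mask=lymph,
        log={
            "cd31": log_c,
            "lyve1": log_l,
            "filled_holes_cd31": holes_c,
            "filled_holes_lyve1": holes_l,
            "subtract_first": subtract_first,
        },
    )
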