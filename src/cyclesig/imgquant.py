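"""Nuclear-to-cytosolic (N/C) ratio quantification from two-channel images.

Given a background-corrected GFP image, an RFP nuclear-marker image and a
binary cell mask, the readout is

    N/C = mean GFP inside a small disk (radius 0.48 um) centered at the
          nucleus centroid
          / mean GFP over the cell mask minus a large disk (radius 1.44 um),

the dual-radius scheme that keeps the numerator well inside the nucleus and
excludes perinuclear signal from the cytosolic reference.  The nucleus is
segmented by a parameter-free between-class-variance (Otsu-style) threshold
over the in-mask RFP intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

__all__ = [
    "MaskSet",
    "NoNucleusError",
    "background_subtract",
    "otsu_threshold",
    "segment_nucleus",
    "build_masks",
    "nc_ratio",
    "quantify_frame",
]

SMALL_RADIUS_UM = 0.48
LARGE_RADIUS_UM = 1.44
DEFAULT_PIXEL_SIZE_UM = 0.16


class NoNucleusError(ValueError):
    """Raised when the RFP channel shows no detectable nucleus in the mask."""


@dataclass
class MaskSet:
    """All masks involved in one frame's N/C measurement (binary 2-D grids).

    The small/large disks contain the pixels whose centers fall within the
    physical radius (converted to pixels without rounding), centered at the
    unweighted nucleus centroid.
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    nucleus_centroid: tuple
    small_mask: np.ndarray
    large_mask: np.ndarray
    pixel_size: float
    nucleus_touches_boundary: bool = False


def background_subtract(image, ball_radius_px: float) -> np.ndarray:
    """Rolling-ball-style background subtraction via grayscale opening.

    The smooth background is estimated by a morphological opening with a
    disk structuring element of the given radius and subtracted; the result
    is clipped at zero.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single 2-D image")
    r = int(ball_radius_px)
    if r <= 0 or 2 * r + 1 > min(image.shape):
        raise ValueError("ball radius must be positive and smaller than the image")
    bg = morphology.opening(image, footprint=morphology.disk(r))
    return np.clip(image - bg, 0.0, None)


def otsu_threshold(values) -> float:
    """Threshold maximizing the between-class variance w0*w1*(mu0-mu1)^2.

    Exhaustive sweep over the unique sample values (classes are v <= thr and
    v > thr), so the result is exact for the given sample rather than
    depending on a histogram binning.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    uniq = np.unique(v)
    if len(uniq) < 2:
        raise ValueError("cannot threshold a constant sample")
    n = len(v)
    csum = np.cumsum(v)
    total = csum[-1]
    # index of the last element <= each candidate unique value
    counts = np.searchsorted(v, uniq[:-1], side="right")
    w0 = counts / n
    w1 = 1.0 - w0
    mu0 = csum[counts - 1] / counts
    mu1 = (total - csum[counts - 1]) / (n - counts)
    score = w0 * w1 * (mu0 - mu1) ** 2
    return float(uniq[:-1][int(np.argmax(score))])


def segment_nucleus(rfp_image, cell_mask):
    """Threshold the RFP channel within the cell mask to find the nucleus.

    Returns (nucleus_mask, centroid): the largest connected component above
    the between-class-variance threshold and its unweighted centroid.
    Raises NoNucleusError when the in-mask contrast (max/median) is below
    1.2 — no nucleus detectable.
    """
    rfp = np.asarray(rfp_image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.sum() < 50:
        raise ValueError("cell mask too small (< 50 pixels)")
    in_mask = rfp[cell_mask]
    med = float(np.median(in_mask))
    if med <= 0 or float(in_mask.max()) / med < 1.2:
        raise NoNucleusError("in-mask RFP contrast below floor; no nucleus detectable")
    thr = otsu_threshold(in_mask)
    nucleus = (rfp > thr) & cell_mask
    labels = measure.label(nucleus)
    if labels.max() == 0:
        raise NoNucleusError("no pixels above the nuclear threshold")
    if labels.max() > 1:
        sizes = np.bincount(labels.ravel())[1:]
        nucleus = labels == (1 + int(np.argmax(sizes)))
    centroid = tuple(np.argwhere(nucleus).mean(axis=0))
    return nucleus, centroid


def _disk(shape, center, radius_px: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def build_masks(
    cell_mask,
    nucleus_mask,
    centroid,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    r_small_um: float = SMALL_RADIUS_UM,
    r_large_um: float = LARGE_RADIUS_UM,
) -> MaskSet:
    """Rasterize the small/large quantification disks around the centroid.

    Frames where the nucleus touches the cell boundary are kept but flagged
    (mitosis frames matter to the analysis).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    shape = cell_mask.shape
    small = _disk(shape, centroid, r_small_um / pixel_size)
    large = _disk(shape, centroid, r_large_um / pixel_size)
    eroded = morphology.erosion(cell_mask)
    touches = bool((nucleus_mask & ~eroded).any())
    return MaskSet(
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        nucleus_centroid=tuple(centroid),
        small_mask=small,
        large_mask=large,
        pixel_size=pixel_size,
        nucleus_touches_boundary=touches,
    )


def nc_ratio(gfp_image, masks: MaskSet) -> float:
    """Mean GFP in the small nuclear disk over mean GFP in the cytosol
    (cell mask minus the large disk).

    Returns NaN (with a warning) when the cytosolic region has fewer than
    20 pixels — a missing value for the frame, not an abort.
    """
    gfp = np.asarray(gfp_image, dtype=float)
    small = masks.small_mask & masks.cell_mask
    if small.sum() < 4:
        raise ValueError("small nuclear mask has fewer than 4 pixels")
    cyto = masks.cell_mask & ~masks.large_mask
    if cyto.sum() < 20:
        warnings.warn(
            "cytosolic region under 20 pixels (nucleus too large or cell too "
            "small); N/C flagged missing",
            stacklevel=2,
        )
        return float("nan")
    return float(gfp[small].mean() / gfp[cyto].mean())


def quantify_frame(
    gfp_image,
    rfp_image,
    cell_mask,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    r_small_um: float = SMALL_RADIUS_UM,
    r_large_um: float = LARGE_RADIUS_UM,
):
    """Segment the nucleus and compute the N/C ratio for one frame.

    Returns (ratio, MaskSet).
    """
    nucleus, centroid = segment_nucleus(rfp_image, cell_mask)
    masks = build_masks(
        cell_mask, nucleus, centroid, pixel_size, r_small_um, r_large_um
    )
    return nc_ratio(gfp_image, masks), masks
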