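"""Spectral smoothing and kernel segmentation.

Savitzky-Golay smoothing denoises reflectance spectra while preserving the
narrow absorption features that carry varietal information.  The image side
implements the classic marker-based watershed pipeline for splitting a
board of touching/near-touching kernels into single-kernel crops:
grayscale -> Gaussian denoise -> Otsu threshold -> morphological opening ->
sure background (dilation) -> sure foreground (thresholded distance
transform) -> watershed -> per-region crops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import savgol_filter

from .errors import ValidationError


def sg_smooth(values: np.ndarray, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay filter along the last axis.

    A degree-``polyorder`` polynomial is least-squares fitted in a sliding
    window of odd length ``window``; edges use a polynomial fit on the
    truncated window.  Polynomials of degree <= polyorder pass through
    unchanged.
    """
    values = np.asarray(values, float)
    if window % 2 == 0:
        raise ValidationError("window must be odd")
    if window <= polyorder:
        raise ValidationError("window must exceed polyorder")
    if window > values.shape[-1]:
        raise ValidationError("window exceeds spectrum length")
    return savgol_filter(values, window, polyorder, axis=-1, mode="interp")


def center_spectra(values: np.ndarray, mean: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the (training-set) mean spectrum.

    Removing the shared reflectance curve before the 1-D CNN is the usual
    chemometric mean-centering step: it leaves the inter-sample signal on a
    comparable scale across wavelengths.  Returns (centred, mean); pass the
    stored ``mean`` to centre held-out spectra consistently.
    """
    values = np.asarray(values)
    if mean is None:
        mean = values.mean(axis=0)
    return values - mean, mean


@dataclass
class SegmentationParams:
    gaussian_sigma: float = 1.0
    opening_kernel_px: int = 3
    opening_iters: int = 2
    dilation_iters: int = 3
    dist_threshold_frac: float = 0.5
    crop_pad_px: int = 5
    min_region_area_px: int = 50

    def __post_init__(self):
        if not (0 < self.dist_threshold_frac < 1):
            raise ValidationError("dist_threshold_frac must be in (0, 1)")
        for f in ("gaussian_sigma", "opening_kernel_px", "opening_iters",
                  "dilation_iters", "crop_pad_px", "min_region_area_px"):
            if getattr(self, f) <= 0:
                raise ValidationError(f"{f} must be positive")


def segment_kernels(image: np.ndarray,
                    params: SegmentationParams | None = None
                    ) -> tuple[list[np.ndarray], np.ndarray]:
    """Segment a multi-kernel scene into single-kernel crops.

    Returns (crops, boxes) with 0-based half-open boxes
    (x_min, y_min, x_max, y_max) padded by ``crop_pad_px`` and clipped to
    the image bounds.
    """
    from skimage.color import rgb2gray
    from skimage.filters import threshold_otsu
    from skimage.measure import regionprops
    from skimage.morphology import disk
    from skimage.segmentation import watershed

    params = params or SegmentationParams()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("segment_kernels expects an H x W x 3 image")

    gray = (rgb2gray(image) * 255).astype(np.uint8)  # standard luma weights
    blurred = ndi.gaussian_filter(gray.astype(float), params.gaussian_sigma)
    if blurred.max() == blurred.min():  # featureless frame
        return [], np.empty((0, 4), int)
    thresh = threshold_otsu(blurred.astype(np.uint8))
    binary = blurred > thresh

    selem = disk(max(params.opening_kernel_px // 2, 1))
    opened = ndi.binary_opening(binary, structure=selem,
                                iterations=params.opening_iters)
    sure_bg = ndi.binary_dilation(opened, structure=selem,
                                  iterations=params.dilation_iters)

    dist = ndi.distance_transform_edt(opened)
    sure_fg = dist > params.dist_threshold_frac * dist.max()
    markers, _ = ndi.label(sure_fg)
    # pixels in sure_bg but not sure_fg form the "unknown" band the
    # watershed floods; restricting to the opened mask keeps the background
    labels = watershed(-dist, markers, mask=opened)

    H, W = labels.shape
    crops, boxes = [], []
    for region in regionprops(labels):
        if region.area < params.min_region_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        r0 = max(r0 - params.crop_pad_px, 0)
        c0 = max(c0 - params.crop_pad_px, 0)
        r1 = min(r1 + params.crop_pad_px, H)
        c1 = min(c1 + params.crop_pad_px, W)
        crops.append(image[r0:r1, c0:c1].copy())
        boxes.append((c0, r0, c1, r1))
    return crops, np.asarray(boxes, int).reshape(-1, 4)
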