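"""Pixel-level preprocessing: illumination correction, background estimation,
thresholding, labeling, and the cytoskeleton-elaboration filters.

All operations use replicate ("nearest") border padding so that convolution
and morphology do not introduce dark rims that would bias background
estimates near image edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import disk

__all__ = [
    "ShadingEstimate",
    "BackgroundImage",
    "ThresholdResult",
    "estimate_shading",
    "flatfield_correct",
    "opening_background",
    "subtract_background",
    "threshold_mask",
    "label_regions",
    "NORTH_SHADOW_KERNEL",
    "north_shadow",
    "convolve2d",
    "convolve_colorize",
    "merge_elaborated",
    "read_image",
    "write_image",
    "load_kernel",
]


@dataclass
class ShadingEstimate:
    """Smooth multiplicative illumination estimate (strictly positive)."""

    field: np.ndarray
    smoothing_scale_px: float


@dataclass
class BackgroundImage:
    """Background estimated by grayscale opening; pointwise <= input."""

    image: np.ndarray
    disk_diameter_px: int


@dataclass
class ThresholdResult:
    mask: np.ndarray
    threshold: float
    method: str


def estimate_shading(
    image: np.ndarray,
    smoothing_scale_px: float = 100.0,
    foreground_contrast: float = 1.5,
) -> ShadingEstimate:
    """Estimate the illumination field by large-scale Gaussian smoothing.

    ``smoothing_scale_px`` (the Gaussian sigma) must be much larger than the
    typical object size.  Bright objects (cells) would locally inflate a
    plain smoothed estimate, so when an Otsu split of the image finds a
    foreground at least ``foreground_contrast`` times brighter than the
    background, foreground pixels are excluded and the estimate is the
    masked (normalized) Gaussian smoothing of the background alone.  Smooth
    illumination variation by itself stays below that contrast and is
    estimated from all pixels.
    """
    if smoothing_scale_px <= 0:
        raise ValueError("smoothing_scale_px must be > 0")
    img = np.asarray(image, dtype=float)
    weight = np.ones_like(img)
    if np.ptp(img) > 0 and foreground_contrast is not None:
        t = threshold_otsu(img)
        fg = img > t
        if fg.any() and not fg.all():
            bg_mean = img[~fg].mean()
            if bg_mean > 0 and img[fg].mean() / bg_mean >= foreground_contrast:
                weight = (~fg).astype(float)
    num = _smooth_large_scale(img * weight, smoothing_scale_px)
    den = _smooth_large_scale(weight, smoothing_scale_px)
    field = num / np.clip(den, 1e-12, None)
    return ShadingEstimate(field, smoothing_scale_px)


def _smooth_large_scale(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing at large sigma, computed on a downsampled grid.

    A field that only carries structure above ``sigma`` is fully represented
    on a grid ~sigma/20 coarser; smoothing there and bilinearly resampling
    back is equivalent at a fraction of the cost.
    """
    factor = max(1, int(round(sigma / 20.0)))
    if factor == 1:
        return ndi.gaussian_filter(image, sigma=sigma, mode="nearest")
    from skimage.transform import resize

    small_shape = tuple(max(4, s // factor) for s in image.shape)
    small = resize(image, small_shape, order=1, mode="edge", anti_aliasing=False)
    small = ndi.gaussian_filter(small, sigma=sigma / factor, mode="nearest")
    return resize(small, image.shape, order=1, mode="edge", anti_aliasing=False)


def flatfield_correct(
    image: np.ndarray, smoothing_scale_px: float = 100.0, n_iterations: int = 6
) -> np.ndarray:
    """Flat-field (shading) correction by division by the smoothed image.

    A Gaussian estimate at a finite smoothing scale slightly attenuates the
    shading bump it measures, leaving a small residual; repeating the
    divide-by-smoothed step (default six times) suppresses the residual
    multiplicatively while leaving already-flat images untouched.  The
    corrected image is rescaled so its global mean equals that of the input.
    An all-zero image is returned unchanged with a warning (the correction
    is undefined but empty fields must not crash a pipeline); a shading
    estimate that is zero or negative anywhere else is an error.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if not img.any():
        warnings.warn("flatfield_correct: all-zero image returned unchanged")
        return np.zeros_like(img)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    mean = img.mean()
    corrected = img
    for _ in range(n_iterations):
        est = estimate_shading(corrected, smoothing_scale_px)
        if np.any(est.field <= 0):
            raise ValueError(
                "degenerate shading estimate (non-positive values); the image "
                "must be non-negative with positive mean intensity"
            )
        corrected = corrected / est.field
        corrected = corrected * (mean / corrected.mean())
    return corrected


def opening_background(image: np.ndarray, disk_diameter_px: int = 20) -> BackgroundImage:
    """Background image by grayscale morphological opening with a disk.

    A disk of diameter ``d`` is rasterized with radius ``d // 2``.  The
    opening (erosion then dilation) removes bright structures smaller than
    the disk, leaving an estimate of the background beneath them.  For the
    estimate to be a true background, the disk must be larger than the
    largest bright object.
    """
    if disk_diameter_px < 3:
        raise ValueError("disk_diameter_px must be >= 3")
    img = np.asarray(image, dtype=float)
    footprint = disk(disk_diameter_px // 2)
    opened = ndi.grey_opening(img, footprint=footprint, mode="nearest")
    return BackgroundImage(opened, disk_diameter_px)


def subtract_background(
    image: np.ndarray, background: BackgroundImage | np.ndarray
) -> np.ndarray:
    """Clamped subtraction ``max(image - background, 0)``."""
    bg = background.image if isinstance(background, BackgroundImage) else background
    img = np.asarray(image, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if img.shape != bg.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {bg.shape}")
    return np.clip(img - bg, 0.0, None)


def threshold_mask(image: np.ndarray, method: str | float = "otsu") -> ThresholdResult:
    """Foreground mask by thresholding; pixels strictly above are foreground.

    ``method`` is ``"otsu"`` or an explicit numeric threshold.
    """
    img = np.asarray(image, dtype=float)
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown threshold method {method!r}")
        if np.ptp(img) == 0:
            raise ValueError(
                "automatic thresholding is undefined for a constant image"
            )
        t = float(threshold_otsu(img))
        name = "otsu"
    else:
        t = float(method)
        name = "manual"
    return ThresholdResult(img > t, t, name)


def label_regions(mask: np.ndarray, min_area_px: int = 0) -> np.ndarray:
    """8-connected components with components < min_area_px removed, labels 1..K."""
    mask = np.asarray(mask, dtype=bool)
    lab = sk_label(mask, connectivity=2)
    if min_area_px > 1 and lab.max() > 0:
        sizes = np.bincount(lab.ravel())
        keep = np.flatnonzero(sizes >= min_area_px)
        keep = keep[keep > 0]
        remap = np.zeros(len(sizes), dtype=lab.dtype)
        remap[keep] = np.arange(1, len(keep) + 1)
        lab = remap[lab]
    return lab


# north-emboss kernel, sum 1: constant regions pass through unchanged
NORTH_SHADOW_KERNEL = np.array(
    [[1.0, 2.0, 1.0], [0.0, 1.0, 0.0], [-1.0, -2.0, -1.0]]
)


def convolve2d(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True 2-D convolution (kernel flipped) with replicate border padding."""
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 2 or any(s % 2 == 0 for s in kernel.shape):
        raise ValueError("kernel must be 2-D with odd dimensions")
    img = np.asarray(image, dtype=float)
    return ndi.convolve(img, kernel, mode="nearest")


def north_shadow(image: np.ndarray) -> np.ndarray:
    """North-emboss ("north shadow") filter highlighting horizontal relief.

    The output is signed; constant images are unchanged because the kernel
    sums to one.
    """
    return convolve2d(image, NORTH_SHADOW_KERNEL)


_COLOR_INDEX = {"red": 0, "green": 1, "blue": 2}


def convolve_colorize(
    image: np.ndarray, kernel: np.ndarray, color: str
) -> np.ndarray:
    """Convolve a grayscale image and map the result into one RGB channel.

    Negative responses are clipped at zero; the other two channels are zero.
    """
    if color not in _COLOR_INDEX:
        raise ValueError(f"color must be one of {sorted(_COLOR_INDEX)}")
    out = np.clip(convolve2d(image, kernel), 0.0, None)
    rgb = np.zeros(out.shape + (3,), dtype=float)
    rgb[..., _COLOR_INDEX[color]] = out
    return rgb


def merge_elaborated(
    shadow_image: np.ndarray, colorized_image: np.ndarray, vmax: float | None = None
) -> np.ndarray:
    """Blend the emboss result with a colorized convolution by screen blending.

    The grayscale shadow image is replicated to RGB, both inputs are scaled
    to [0, 1] by a common maximum ``vmax`` (inferred from the data when not
    given), screen-blended (``1 - (1-a)(1-b)``), and rescaled.  Screen
    blending is commutative and leaves either input unchanged where the other
    is black.
    """
    shadow = np.clip(np.asarray(shadow_image, dtype=float), 0.0, None)
    colorized = np.asarray(colorized_image, dtype=float)
    if shadow.ndim == 2:
        shadow = np.repeat(shadow[..., None], 3, axis=-1)
    if colorized.ndim == 2:
        colorized = np.repeat(colorized[..., None], 3, axis=-1)
    if shadow.shape != colorized.shape:
        raise ValueError(
            f"shape mismatch: {shadow.shape} vs {colorized.shape}"
        )
    if vmax is None:
        vmax = max(float(shadow.max()), float(colorized.max()))
    if vmax <= 0:
        return np.zeros_like(shadow)
    a = np.clip(shadow / vmax, 0.0, 1.0)
    b = np.clip(colorized / vmax, 0.0, 1.0)
    return vmax * (1.0 - (1.0 - a) * (1.0 - b))


# ---------------------------------------------------------------------------
# image and kernel I/O


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG (8/16-bit) as a 2-D array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[-1] in (3, 4):  # RGB(A) -> luminance
        img = img[..., :3].mean(axis=-1)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image")
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, image)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image)


def load_kernel(path: str | Path) -> np.ndarray:
    """Load a convolution kernel from a plain-text whitespace matrix file."""
    kernel = np.loadtxt(path, dtype=float, ndmin=2)
    if any(s % 2 == 0 for s in kernel.shape):
        raise ValueError(f"{path}: kernel dimensions must be odd")
    return kernel
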