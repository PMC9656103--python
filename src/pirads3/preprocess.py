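"""Image preprocessing: intensity normalization, grid resampling, fixed-bin-number
discretization and one-level stationary wavelet filtering.

Three protocol presets are provided:

``proposed``
    Reference-ROI normalization (divide by the mean intensity of a healthy
    peripheral-zone ROI), b-spline resampling to 0.4x0.4x3.0 mm (T2) /
    0.8x0.8x3.0 mm (ADC), 32-bin quantization on original images and 8 (T2) /
    16 (ADC) bins on the coif1 stationary-wavelet sub-bands LLL, LLH, HHL, HHH.
``hectors``
    mu +/- 3 sigma range normalization inside the lesion VOI to [0, 1],
    0.5 mm isotropic grid, 64 bins, original image only.
``jin``
    Whole-volume z-score standardization, 1 mm isotropic grid, 25 bins,
    wavelet bands HHL (T2) and LLL (DWI stand-in).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pywt
import SimpleITK as sitk

from .volume import ImageVolume, MaskVolume

__all__ = [
    "NormalizationError",
    "QuantizedROI",
    "PreprocessPreset",
    "get_preset",
    "normalize_by_reference_roi",
    "normalize_range_mu3sigma",
    "normalize_zscore",
    "resample",
    "resample_mask",
    "quantize_fbn",
    "wavelet_decompose",
    "wavelet_reconstruct",
    "WAVELET_BANDS",
]

#: All sub-band labels of a one-level 3D decomposition. The first letter refers
#: to the slowest array axis (z), the last to the fastest (x); L = low-pass,
#: H = high-pass.
WAVELET_BANDS = tuple("".join(b) for b in itertools.product("LH", repeat=3))


class NormalizationError(ValueError):
    """Raised when an intensity normalization is undefined for the input."""


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_by_reference_roi(image: ImageVolume, norm_roi: MaskVolume) -> ImageVolume:
    """Divide all intensities by the mean intensity inside ``norm_roi``.

    After normalization the reference ROI has mean exactly 1; the operation is
    invariant to a global intensity rescaling of the input.
    """
    if not image.same_grid(norm_roi):
        raise ValueError("normalization ROI must share the image grid")
    if norm_roi.n_voxels == 0:
        raise NormalizationError("normalization ROI is empty")
    mean = float(image.voxels[norm_roi.voxels].mean())
    if mean == 0.0:
        raise NormalizationError("normalization ROI mean is zero")
    return image.copy_with(image.voxels / mean)


def normalize_range_mu3sigma(
    image: ImageVolume, voi: MaskVolume, out_range: tuple[float, float] = (0.0, 1.0)
) -> ImageVolume:
    """Affinely map the VOI interval [mu - 3 sigma, mu + 3 sigma] onto ``out_range``.

    Values outside the interval are clipped to the range bounds; the VOI mean
    maps to the range midpoint.
    """
    if not image.same_grid(voi):
        raise ValueError("VOI must share the image grid")
    vals = image.voxels[voi.voxels]
    if vals.size < 2:
        raise NormalizationError("VOI must contain at least 2 voxels")
    mu, sigma = float(vals.mean()), float(vals.std())
    if sigma == 0.0:
        raise NormalizationError("VOI intensity standard deviation is zero")
    lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    scaled = (image.voxels - lo) / (hi - lo)
    scaled = out_range[0] + scaled * (out_range[1] - out_range[0])
    return image.copy_with(np.clip(scaled, min(out_range), max(out_range)))


def normalize_zscore(image: ImageVolume) -> ImageVolume:
    """Standardize the whole volume to zero mean and unit standard deviation."""
    mu, sigma = float(image.voxels.mean()), float(image.voxels.std())
    if sigma == 0.0:
        raise NormalizationError("image is constant; z-score undefined")
    return image.copy_with((image.voxels - mu) / sigma)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _to_sitk(volume: ImageVolume | MaskVolume, dtype=None) -> sitk.Image:
    data = volume.voxels
    if dtype is not None:
        data = data.astype(dtype)
    img = sitk.GetImageFromArray(data)  # array (z,y,x) -> sitk (x,y,z)
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    return img


def _resample_sitk(
    img: sitk.Image, target_spacing: tuple[float, float, float], interpolator
) -> sitk.Image:
    in_size = np.array(img.GetSize(), dtype=float)
    in_spacing = np.array(img.GetSpacing(), dtype=float)
    target = np.asarray(target_spacing, dtype=float)
    if np.any(target <= 0):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    out_size = np.maximum(1, np.round(in_size * in_spacing / target).astype(int))
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(target))
    res.SetSize([int(s) for s in out_size])
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(interpolator)
    res.SetDefaultPixelValue(0)
    # grid points past the last voxel centre clamp to the edge value, so
    # constants are reproduced exactly over the whole output grid
    res.SetUseNearestNeighborExtrapolator(True)
    return res.Execute(img)


def resample(
    image: ImageVolume,
    target_spacing: tuple[float, float, float],
    mode: str = "bspline",
) -> ImageVolume:
    """Resample an intensity image to ``target_spacing`` (mm, x/y/z order).

    ``mode='bspline'`` uses cubic b-spline interpolation; ``mode='nearest'``
    nearest-neighbour. The output grid covers the input physical extent and
    shares its origin, so resampling onto the native spacing is the identity.
    """
    interp = {"bspline": sitk.sitkBSpline, "nearest": sitk.sitkNearestNeighbor}
    if mode not in interp:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    if tuple(np.round(target_spacing, 9)) == tuple(np.round(image.spacing, 9)):
        return image.copy_with(image.voxels.copy())
    out = _resample_sitk(_to_sitk(image), tuple(target_spacing), interp[mode])
    return ImageVolume(sitk.GetArrayFromImage(out), out.GetSpacing(), out.GetOrigin())


def resample_mask(mask: MaskVolume, target_spacing: tuple[float, float, float]) -> MaskVolume:
    """Resample a binary mask with nearest-neighbour interpolation and re-binarize."""
    if tuple(np.round(target_spacing, 9)) == tuple(np.round(mask.spacing, 9)):
        return MaskVolume(mask.voxels.copy(), mask.spacing, mask.origin)
    out = _resample_sitk(_to_sitk(mask, dtype=np.uint8), tuple(target_spacing), sitk.sitkNearestNeighbor)
    return MaskVolume(sitk.GetArrayFromImage(out) > 0.5, out.GetSpacing(), out.GetOrigin())


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class QuantizedROI:
    """Fixed-bin-number grey-level labels on lesion voxels.

    ``labels`` holds integers 1..n_bins inside the mask and 0 outside; texture
    matrix builders consume this object.
    """

    labels: np.ndarray  # int array, 0 outside mask
    mask: np.ndarray  # bool array
    n_bins: int
    bin_edges: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def cropped(self, margin: int = 0) -> "QuantizedROI":
        """Restrict arrays to the mask bounding box (texture is mask-local)."""
        idx = np.nonzero(self.mask)
        sl = tuple(
            slice(max(0, i.min() - margin), i.max() + 1 + margin) for i in idx
        )
        return QuantizedROI(self.labels[sl], self.mask[sl], self.n_bins, self.bin_edges, self.spacing)


def quantize_fbn(image: ImageVolume, mask: MaskVolume, n_bins: int) -> QuantizedROI:
    """Fixed-bin-number discretization of masked intensities.

    label(v) = floor(n_bins * (v - min) / (max - min)) + 1, with the ROI
    maximum assigned label ``n_bins``; a constant ROI maps every voxel to 1.
    Quantization is monotone and invariant to affine intensity shifts.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not image.same_grid(mask):
        raise ValueError("mask must share the image grid")
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    m = mask.voxels
    vals = image.voxels[m]
    vmin, vmax = float(vals.min()), float(vals.max())
    labels = np.zeros(image.shape, dtype=np.int32)
    if vmax == vmin:
        labels[m] = 1
        edges = np.array([vmin, vmax])
    else:
        lab = np.floor(n_bins * (vals - vmin) / (vmax - vmin)).astype(np.int32) + 1
        lab[lab > n_bins] = n_bins
        labels[m] = lab
        edges = np.linspace(vmin, vmax, n_bins + 1)
    return QuantizedROI(labels, m.copy(), int(n_bins), edges, image.spacing)


# ---------------------------------------------------------------------------
# stationary wavelet decomposition
# ---------------------------------------------------------------------------

def _pad_even(data: np.ndarray) -> tuple[np.ndarray, tuple[slice, ...]]:
    pads = [(0, s % 2) for s in data.shape]
    crop = tuple(slice(0, s) for s in data.shape)
    if any(p[1] for p in pads):
        data = np.pad(data, pads, mode="symmetric")
    return data, crop


def wavelet_decompose(
    image: ImageVolume,
    bands: tuple[str, ...] = ("LLL", "LLH", "HHL", "HHH"),
    wavelet: str = "coif1",
) -> dict[str, ImageVolume]:
    """One-level undecimated (stationary) 3D separable wavelet decomposition.

    Returns the requested sub-bands at the original grid size. Band labels use
    L (low-pass) / H (high-pass) with the first letter acting along the slowest
    array axis (z). Odd dimensions are symmetrically padded to even lengths and
    the result cropped back.
    """
    for b in bands:
        if b not in WAVELET_BANDS:
            raise ValueError(f"unknown wavelet band {b!r}; valid: {WAVELET_BANDS}")
    data, crop = _pad_even(image.voxels)
    coeffs = pywt.swtn(data, wavelet=wavelet, level=1, start_level=0)[0]
    out: dict[str, ImageVolume] = {}
    for b in bands:
        key = b.replace("L", "a").replace("H", "d")
        out[b] = image.copy_with(coeffs[key][crop])
    return out


def wavelet_reconstruct(
    bands: dict[str, ImageVolume], wavelet: str = "coif1"
) -> ImageVolume:
    """Inverse stationary transform from a complete set of 8 sub-bands."""
    if set(bands) != set(WAVELET_BANDS):
        raise ValueError("reconstruction requires all 8 sub-bands")
    ref = bands["LLL"]
    coeffs = {}
    for b, vol in bands.items():
        data, _ = _pad_even(vol.voxels)
        coeffs[b.replace("L", "a").replace("H", "d")] = data
    rec = pywt.iswtn([coeffs], wavelet=wavelet)
    crop = tuple(slice(0, s) for s in ref.voxels.shape)
    return ref.copy_with(rec[crop])


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessPreset:
    """Protocol preset bundling normalization, grids, bin counts and bands.

    ``target_spacing``, ``n_bins_original`` and ``n_bins_wavelet`` are keyed by
    modality name ('t2', 'adc'); ``wavelet_bands`` likewise (empty tuple =
    no wavelet images for that modality).
    """

    name: str
    normalization: str  # reference_roi | mu3sigma | zscore
    target_spacing: dict[str, tuple[float, float, float]]
    n_bins_original: dict[str, int]
    n_bins_wavelet: dict[str, int]
    wavelet_bands: dict[str, tuple[str, ...]]
    modalities: tuple[str, ...] = ("t2", "adc")


_PRESETS = {
    "proposed": PreprocessPreset(
        name="proposed",
        normalization="reference_roi",
        target_spacing={"t2": (0.4, 0.4, 3.0), "adc": (0.8, 0.8, 3.0)},
        n_bins_original={"t2": 32, "adc": 32},
        n_bins_wavelet={"t2": 8, "adc": 16},
        wavelet_bands={
            "t2": ("LLL", "LLH", "HHL", "HHH"),
            "adc": ("LLL", "LLH", "HHL", "HHH"),
        },
    ),
    "hectors": PreprocessPreset(
        name="hectors",
        normalization="mu3sigma",
        target_spacing={"t2": (0.5, 0.5, 0.5)},
        n_bins_original={"t2": 64},
        n_bins_wavelet={"t2": 64},
        wavelet_bands={"t2": ()},
        modalities=("t2",),
    ),
    "jin": PreprocessPreset(
        name="jin",
        normalization="zscore",
        target_spacing={"t2": (1.0, 1.0, 1.0), "adc": (1.0, 1.0, 1.0)},
        # discretization unspecified upstream; fixed bin number 25, config-exposed
        n_bins_original={"t2": 25, "adc": 25},
        n_bins_wavelet={"t2": 25, "adc": 25},
        wavelet_bands={"t2": ("HHL",), "adc": ("LLL",)},
    ),
}


def get_preset(name: str, **overrides) -> PreprocessPreset:
    """Look up a named preset, optionally overriding individual fields."""
    try:
        preset = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; valid: {sorted(_PRESETS)}") from None
    if overrides:
        from dataclasses import replace

        preset = replace(preset, **overrides)
    return preset
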