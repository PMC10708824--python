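"""Reading, writing and color-space handling for registered VIS/NIR pairs.

All pipeline code works in floating point on the closed interval [0, 1];
integer images are divided by their dtype maximum on load and quantised
back (round half up) on save.  Keeping a single internal scale makes the
image complement simply ``1 - I`` regardless of the source bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor

#: division guard used across the package
EPS = 1e-6

#: Rec.601 luminance weights (R, G, B)
REC601_WEIGHTS = np.array([0.299, 0.587, 0.114])


class RegistrationError(ValueError):
    """The VIS and NIR images do not form a valid registered pair."""


class FormatError(ValueError):
    """The input file has an unsupported layout or sample type."""


@dataclass
class RegisteredPair:
    """An aligned visible-spectrum image and near-infrared plane.

    Attributes
    ----------
    vis:
        H x W x 3 float array of reflectance-like intensities in [0, 1].
    nir:
        H x W float array in [0, 1].
    bit_depth_src:
        Bit depth of the source files (8 or 16); synthetic pairs use 8.
    source_paths:
        ``(vis_path, nir_path)`` when loaded from disk, else ``None``.
    """

    vis: np.ndarray
    nir: np.ndarray
    bit_depth_src: int = 8
    source_paths: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.vis = np.asarray(self.vis, dtype=np.float64)
        self.nir = np.asarray(self.nir, dtype=np.float64)
        if self.vis.ndim != 3 or self.vis.shape[2] != 3:
            raise FormatError(f"vis must be HxWx3, got shape {self.vis.shape}")
        if self.nir.ndim != 2:
            raise FormatError(f"nir must be HxW, got shape {self.nir.shape}")
        if self.vis.shape[:2] != self.nir.shape:
            raise RegistrationError(
                f"vis {self.vis.shape[:2]} and nir {self.nir.shape} "
                "have different pixel dimensions"
            )
        for name, arr in (("vis", self.vis), ("nir", self.nir)):
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"{name} contains non-finite values")
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise FormatError(f"{name} values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.vis.shape[0]

    @property
    def width(self) -> int:
        return self.vis.shape[1]


@dataclass
class ColorPlanes:
    """Derived single-channel planes of a VIS image.

    ``gray`` and ``hsi_S`` are in [0, 1]; the CIELAB planes use the
    conventional scales (L in [0, 100], a/b roughly [-128, 128]).
    """

    gray: np.ndarray
    lab_L: np.ndarray
    lab_a: np.ndarray
    lab_b: np.ndarray
    hsi_S: np.ndarray


def _normalize(arr: np.ndarray, path: str) -> tuple[np.ndarray, int]:
    """Map an integer image to float64 [0, 1]; return (image, source bits)."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0, 16
    raise FormatError(f"{path}: unsupported dtype {arr.dtype} (need uint8/uint16)")


def _collapse_nir(arr: np.ndarray, path: str) -> np.ndarray:
    """Accept single-channel NIR, or multi-channel with identical channels."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            return arr[:, :, 0]
        first = arr[:, :, 0]
        if all(np.array_equal(first, arr[:, :, c]) for c in range(1, arr.shape[2])):
            return first
        raise FormatError(f"{path}: NIR image has differing channels")
    raise FormatError(f"{path}: cannot interpret shape {arr.shape} as NIR")


def load_pair(vis_path: str, nir_path: str) -> RegisteredPair:
    """Load a registered VIS/NIR pair from PNG or TIFF files.

    Raises
    ------
    RegistrationError
        If pixel dimensions differ.
    FormatError
        If a file has an unsupported dtype or channel layout.
    """
    vis_raw = np.asarray(iio.imread(vis_path))
    nir_raw = np.asarray(iio.imread(nir_path))

    if vis_raw.ndim != 3 or vis_raw.shape[2] < 3:
        raise FormatError(f"{vis_path}: VIS image must have 3 channels")
    vis_raw = vis_raw[:, :, :3]  # drop alpha if present
    nir_raw = _collapse_nir(nir_raw, str(nir_path))

    vis, bits = _normalize(vis_raw, str(vis_path))
    nir, nbits = _normalize(nir_raw, str(nir_path))
    if vis.shape[:2] != nir.shape:
        raise RegistrationError(
            f"dimension mismatch: {vis_path} is {vis.shape[:2]}, "
            f"{nir_path} is {nir.shape}"
        )
    return RegisteredPair(
        vis=vis,
        nir=nir,
        bit_depth_src=max(bits, nbits),
        source_paths=(str(vis_path), str(nir_path)),
    )


def save_image(path: str, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write a [0, 1] float image as 8-bit PNG or 16-bit PNG/TIFF.

    Quantisation rounds half up: ``floor(v * (2**b - 1) + 0.5)``.
    """
    if bit_depth == 8:
        scale, dtype = 255.0, np.uint8
    elif bit_depth == 16:
        scale, dtype = 65535.0, np.uint16
    else:
        raise FormatError(f"unsupported output bit depth {bit_depth}")
    q = np.floor(np.clip(image, 0.0, 1.0) * scale + 0.5).astype(dtype)
    iio.imwrite(path, q)


def to_gray(vis: np.ndarray) -> np.ndarray:
    """Rec.601 luminance plane of a [0, 1] RGB image."""
    vis = np.asarray(vis, dtype=np.float64)
    return vis @ REC601_WEIGHTS


def to_lab(vis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CIELAB planes (L, a, b) via the sRGB/D65 transform."""
    lab = _skcolor.rgb2lab(np.asarray(vis, dtype=np.float64))
    return lab[:, :, 0], lab[:, :, 1], lab[:, :, 2]


def hsi_saturation(vis: np.ndarray) -> np.ndarray:
    """HSI saturation plane, ``S = 1 - 3 min(r,g,b) / (r+g+b+eps)``.

    Black pixels get S = 0 via the epsilon guard.
    """
    vis = np.asarray(vis, dtype=np.float64)
    s = vis.sum(axis=2)
    out = 1.0 - 3.0 * vis.min(axis=2) / (s + EPS)
    out = np.where(s < EPS, 0.0, out)  # black is achromatic by convention
    return np.clip(out, 0.0, 1.0)


def color_planes(vis: np.ndarray) -> ColorPlanes:
    """All derived planes of a VIS image in one pass."""
    lab_L, lab_a, lab_b = to_lab(vis)
    return ColorPlanes(
        gray=to_gray(vis),
        lab_L=lab_L,
        lab_a=lab_a,
        lab_b=lab_b,
        hsi_S=hsi_saturation(vis),
    )
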