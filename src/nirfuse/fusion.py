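"""NDVI-weighted low-light enhancement and three-source VIS/NIR fusion.

The pipeline takes a registered VIS/NIR pair and produces a fused RGB
image built from three sources: the original VIS image, an enhanced
(brightened) version of it, and a color-ratio-preserving NIR term.

Stages, in the order they run:

1. **Vegetation index.**  NDVI, ``VI = (N - R) / (N + R)``, computed from
   the NIR plane and the red channel; values above ~0.2 indicate
   vegetation, values near 0 sky/soil, negative values water or cloud.
   Its complement ``VI' = 1 - clip(VI, 0, 1)`` is the non-vegetation
   weight used in the final blend.
2. **Image complement.**  ``I' = 1 - I``.  Underexposed regions become
   bright haze-like regions, which lets a dark-channel-prior dehazing
   step act as a low-light enhancer.
3. **Atmospheric light.**  Per-channel maximum of the VIS image over the
   lowest-VI fraction of pixels (default 0.1%), i.e. the brightest
   values among the least-vegetated (sky/tarpaulin) pixels.  Using the
   VI map rather than raw brightness avoids picking bright leaves.
4. **Dark channel and transmission.**  The dark channel is the
   channel-wise minimum of the complement image normalised by L; the
   transmission ``t = (1 - omega) * D`` (clamped to ``[t_floor, 1]``)
   sets both the enhancement strength and the blend weights.
5. **Enhancement.**  ``R_enh = L + (I' - L) / t`` followed by clipping
   and re-inversion back to normal polarity.
6. **NIR term.**  ``FN_c = delta * N * D * I_c / (I_r + I_g + I_b)``:
   NIR energy distributed across channels in proportion to the VIS
   color ratios, so added information keeps the original hue.
7. **Blend.**  With weight ``w = t * VI'``, the output is
   ``F = clip(FN + I * (1 - w) + R_enh' * w, 0, 1)``: non-vegetated
   bright regions take the enhanced source, vegetation keeps the
   original VIS plus the NIR term.

Defaults ``delta = 0.5`` and ``omega = 0.6`` balance added NIR detail
against over-brightening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import EPS, RegisteredPair, RegistrationError


@dataclass
class FusionParams:
    """Tunable parameters of the fusion pipeline.

    Attributes
    ----------
    delta:
        NIR affectation in [0, 1]; scales how much NIR information the
        FN term adds.  0 disables the NIR source.
    omega:
        Enhancement strength in [0, 1); larger values shrink the
        transmission map and amplify the enhancement.
    t_floor:
        Lower clamp on the transmission map, in (0, 1]; prevents
        unbounded amplification in the enhancement division.
    light_percentile:
        Fraction of lowest-VI pixels considered for the atmospheric
        light (default 0.1%).
    eps:
        Division guard.
    dark_from_complement:
        If True (default) the dark channel is computed on the
        complement image normalised by L, matching the inverted
        low-light scheme; if False, on the original VIS image.
    transmission_form:
        ``"literal"`` (default) uses ``t = (1 - omega) * D``;
        ``"canonical"`` uses the classical dehazing form
        ``t = 1 - omega * D``.
    """

    delta: float = 0.5
    omega: float = 0.6
    t_floor: float = 0.1
    light_percentile: float = 0.001
    eps: float = EPS
    dark_from_complement: bool = True
    transmission_form: str = "literal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if not 0.0 <= self.omega < 1.0:
            raise ValueError(f"omega must be in [0, 1), got {self.omega}")
        if not 0.0 < self.t_floor <= 1.0:
            raise ValueError(f"t_floor must be in (0, 1], got {self.t_floor}")
        if not 0.0 < self.light_percentile <= 1.0:
            raise ValueError(
                f"light_percentile must be in (0, 1], got {self.light_percentile}")
        if self.transmission_form not in ("literal", "canonical"):
            raise ValueError(
                f"transmission_form must be 'literal' or 'canonical', "
                f"got {self.transmission_form!r}")


@dataclass
class VegetationMap:
    """Per-pixel NDVI and its complement weight.

    ``vi`` lies in [-1, 1]; ``vi_comp = 1 - clip(vi, 0, 1)`` in [0, 1].
    Negative NDVI (water/snow/cloud) maps to full non-vegetation weight.
    """

    vi: np.ndarray
    vi_comp: np.ndarray


@dataclass
class TransmissionMap:
    """Transmission scalar field with its ingredients."""

    t: np.ndarray       # in [t_floor, 1]
    dark: np.ndarray    # dark channel, >= 0 (may exceed 1 after normalisation)
    light: np.ndarray   # per-channel atmospheric light, 3-vector in (0, 1]


@dataclass
class FusionResult:
    """Output bundle of :func:`fuse`."""

    fused: np.ndarray      # H x W x 3 in [0, 1]
    enhanced: np.ndarray   # re-inverted enhanced image, [0, 1]
    nir_term: np.ndarray   # FN, >= 0
    weights: np.ndarray    # t * VI', in [0, 1]
    vmap: VegetationMap
    tmap: TransmissionMap


def vegetation_index(pair: RegisteredPair,
                     eps: float = EPS) -> VegetationMap:
    """NDVI from the NIR plane and the red VIS channel.

    Pixels where ``N + R`` is below ``eps`` (no signal) get VI = 0.
    """
    red = pair.vis[:, :, 0]
    nir = pair.nir
    denom = nir + red
    vi = np.where(denom < eps, 0.0, (nir - red) / np.where(denom < eps, 1.0, denom))
    vi = np.clip(vi, -1.0, 1.0)
    return VegetationMap(vi=vi, vi_comp=1.0 - np.clip(vi, 0.0, 1.0))


def complement(image: np.ndarray) -> np.ndarray:
    """Intensity inversion ``1 - I`` (the normalised form of 2^n-1 - I)."""
    return 1.0 - np.asarray(image, dtype=np.float64)


def atmospheric_light(pair: RegisteredPair, vmap: VegetationMap,
                      params: FusionParams | None = None) -> np.ndarray:
    """Per-channel scene illumination from the least-vegetated pixels.

    Takes the K = ceil(light_percentile * H * W) pixels with the lowest
    NDVI (ties broken by row-major scan order) and returns the
    channel-wise maximum of the VIS image over them, floored at eps.
    """
    params = params or FusionParams()
    h, w = vmap.vi.shape
    k = max(1, int(np.ceil(params.light_percentile * h * w)))
    flat_vi = vmap.vi.ravel()
    # stable sort keeps row-major order among ties
    sel = np.argsort(flat_vi, kind="stable")[:k]
    flat_vis = pair.vis.reshape(-1, 3)
    light = flat_vis[sel].max(axis=0)
    return np.maximum(light, params.eps)


def transmission(image: np.ndarray, light: np.ndarray,
                 params: FusionParams | None = None) -> TransmissionMap:
    """Dark channel of ``image / L`` and the transmission map.

    ``image`` is normally the complement of the VIS image (see
    ``FusionParams.dark_from_complement``).  The transmission is the
    per-pixel scalar ``(1 - omega) * D`` (or ``1 - omega * D`` in
    canonical form) clamped to ``[t_floor, 1]`` and broadcast across
    channels downstream.
    """
    params = params or FusionParams()
    dark = (np.asarray(image, dtype=np.float64) / light).min(axis=2)
    if params.transmission_form == "literal":
        t = (1.0 - params.omega) * dark
    else:
        t = 1.0 - params.omega * dark
    t = np.clip(t, params.t_floor, 1.0)
    return TransmissionMap(t=t, dark=dark, light=np.asarray(light, dtype=np.float64))


def enhance(complement_image: np.ndarray, light: np.ndarray,
            tmap: TransmissionMap) -> np.ndarray:
    """Dehazing-style enhancement of the complement, re-inverted.

    ``R = L + (I' - L) / t`` pushes the haze-like (originally dark)
    regions away from the atmospheric light; clipping to [0, 1] and
    inverting returns an enhanced image in normal polarity.
    """
    t = tmap.t[:, :, None]
    enhanced_inv = light + (np.asarray(complement_image, dtype=np.float64) - light) / t
    return 1.0 - np.clip(enhanced_inv, 0.0, 1.0)


def nir_term(pair: RegisteredPair, dark: np.ndarray,
             params: FusionParams | None = None) -> np.ndarray:
    """Color-ratio-preserving NIR contribution FN.

    ``FN_c = delta * N * D * I_c / (I_r + I_g + I_b + eps)``; since each
    channel is scaled in proportion to the VIS color ratio, adding FN
    leaves hue and HSI saturation unchanged.
    """
    params = params or FusionParams()
    ratio = pair.vis / (pair.vis.sum(axis=2, keepdims=True) + params.eps)
    return params.delta * (pair.nir * dark)[:, :, None] * ratio


def fuse(pair: RegisteredPair,
         params: FusionParams | None = None) -> FusionResult:
    """Run the full NDVI-weighted fusion pipeline on a registered pair."""
    params = params or FusionParams()
    vmap = vegetation_index(pair, eps=params.eps)
    comp = complement(pair.vis)
    light = atmospheric_light(pair, vmap, params)
    dark_src = comp if params.dark_from_complement else pair.vis
    tmap = transmission(dark_src, light, params)
    enhanced = enhance(comp, light, tmap)
    fn = nir_term(pair, tmap.dark, params)

    weights = tmap.t * vmap.vi_comp
    w = weights[:, :, None]
    fused = np.clip(fn + pair.vis * (1.0 - w) + enhanced * w, 0.0, 1.0)
    return FusionResult(fused=fused, enhanced=enhanced, nir_term=fn,
                        weights=weights, vmap=vmap, tmap=tmap)


def identity_method(pair: RegisteredPair) -> np.ndarray:
    """Pass-through baseline: returns the VIS image unchanged."""
    return pair.vis.copy()


def fusion_method(params: FusionParams | None = None):
    """A ``pair -> fused image`` callable for the comparison harness."""
    def _run(pair: RegisteredPair) -> np.ndarray:
        return fuse(pair, params).fused
    return _run
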