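"""Fusion-quality metrics: contrast, entropy, colorfulness, saturation.

These four statistics are the standard desk-side yardsticks for judging a
VIS-NIR fusion: contrast should rise (regions separate better), entropy
tracks information content, colorfulness tracks chrominance, and mean HSI
saturation should stay close to the original (no over-saturation).

Contrast is reported on the 0-255 intensity scale.  The variance-style
formula found in parts of the fusion literature prints mean-of-squares
minus squared-mean; reported magnitudes in that literature are only
consistent with its square root, so the default here is RMS contrast
(the standard deviation), with ``mode="variance"`` giving the literal
variance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .image_io import hsi_saturation, to_gray, to_lab

#: histogram resolution used for entropy; 8-bit convention
N_GRAY_LEVELS = 256


@dataclass
class MetricReport:
    """The four quality metrics for one image."""

    contrast: float
    entropy: float
    colorfulness: float
    saturation: float
    image_id: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def contrast(gray: np.ndarray, mode: str = "rms") -> float:
    """Global contrast of a single-channel image on the 0-255 scale.

    Parameters
    ----------
    gray:
        Single-channel image in [0, 1].
    mode:
        ``"rms"`` (default) returns the population standard deviation;
        ``"variance"`` returns the raw variance (mean of squares minus
        squared mean).
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.size == 0:
        raise ValueError("contrast of an empty image is undefined")
    x = gray * 255.0
    # two-pass variance: algebraically mean(x^2) - mean(x)^2, but without
    # the catastrophic cancellation of the one-pass form
    var = float(np.var(x))
    if mode == "rms":
        return float(np.sqrt(var))
    if mode == "variance":
        return var
    raise ValueError(f"unknown contrast mode {mode!r}")


def _channel_entropy(channel: np.ndarray) -> float:
    counts, _ = np.histogram(channel, bins=N_GRAY_LEVELS, range=(0.0, 1.0))
    p = counts[counts > 0] / channel.size
    return float(-np.sum(p * np.log2(p)))


def entropy(image: np.ndarray) -> float:
    """Shannon entropy in bits over a 256-bin gray-level histogram.

    For a 3-channel image the per-channel entropies are averaged; values
    lie in [0, 8].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return _channel_entropy(image)
    if image.ndim == 3:
        return float(np.mean([_channel_entropy(image[:, :, c])
                              for c in range(image.shape[2])]))
    raise ValueError(f"expected 2D or 3D image, got ndim={image.ndim}")


def colorfulness(vis: np.ndarray) -> float:
    """CIELAB colorfulness: sigma_a + sigma_b + 0.94 * mean chroma."""
    _, a, b = to_lab(vis)
    chroma = np.sqrt(a * a + b * b)
    return float(a.std() + b.std() + 0.94 * chroma.mean())


def saturation_metric(vis: np.ndarray) -> float:
    """Mean of the HSI saturation plane, in [0, 1]."""
    return float(hsi_saturation(vis).mean())


def report(vis: np.ndarray, image_id: str = "",
           contrast_mode: str = "rms") -> MetricReport:
    """All four metrics for one RGB image.

    Contrast and entropy conventions: contrast is computed on the Rec.601
    grayscale plane; entropy is the per-channel average.
    """
    return MetricReport(
        contrast=contrast(to_gray(vis), mode=contrast_mode),
        entropy=entropy(vis),
        colorfulness=colorfulness(vis),
        saturation=saturation_metric(vis),
        image_id=image_id,
    )


def reports_to_frame(reports: list[MetricReport]) -> pd.DataFrame:
    """Tabulate reports, one row per image, keyed by ``image_id``."""
    return pd.DataFrame([r.to_dict() for r in reports])


def write_reports(reports: list[MetricReport], path: str) -> None:
    """Emit reports as CSV or JSON depending on the file extension."""
    frame = reports_to_frame(reports)
    if str(path).endswith(".json"):
        with open(path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=2)
    else:
        frame.to_csv(path, index=False)
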