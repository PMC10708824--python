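"""Experimental bookkeeping: exposure split, patches, augmentation,
and paired method comparison.

This module reproduces the evaluation protocol around the fusion
method: images are split into underexposed vs. normally exposed by mean
CIELAB lightness (threshold 40), fruit bounding boxes are cropped and
resized to 224x224 classifier patches with the standard augmentation
set (random reflection, rotation, translation, shear), and competing
fusion methods are compared metric-by-metric with a Tukey HSD
multiple-comparison test at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, resize as _sk_resize, warp

from . import metrics as _metrics
from .image_io import RegisteredPair, to_lab

#: mean-CIELAB-L threshold separating underexposed from normal images
LUMINANCE_THRESHOLD = 40.0

#: classifier patch side in pixels
PATCH_SIZE = 224

RIPENESS_CLASSES = ("no_fruit", "unripe", "nearly_ripe", "ripe")


@dataclass
class ExposureLabel:
    image_id: str
    mean_L: float
    label: str  # "low" | "normal"


@dataclass
class PatchRecord:
    image_id: str
    box: dict               # center-based {"x","y","w","h"}
    ripeness: str
    patch: np.ndarray       # PATCH_SIZE x PATCH_SIZE x 3


def exposure_split(vis: np.ndarray, threshold: float = LUMINANCE_THRESHOLD,
                   image_id: str = "") -> ExposureLabel:
    """Label an image low/normal by its mean CIELAB lightness.

    ``label == "low"`` iff ``mean(L) < threshold`` (strict).
    """
    lab_L, _, _ = to_lab(vis)
    mean_L = float(lab_L.mean())
    return ExposureLabel(image_id=image_id, mean_L=mean_L,
                         label="low" if mean_L < threshold else "normal")


def _crop_box(image: np.ndarray, box: dict) -> np.ndarray | None:
    """Center-based box -> half-open pixel window, clipped to bounds."""
    h, w = image.shape[:2]
    bw, bh = float(box["w"]), float(box["h"])
    x0 = int(round(box["x"] - bw / 2.0))
    y0 = int(round(box["y"] - bh / 2.0))
    x1, y1 = x0 + int(round(bw)), y0 + int(round(bh))
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(w, x1), min(h, y1)
    if x1 - x0 < 2 or y1 - y0 < 2:
        return None
    return image[y0:y1, x0:x1]


def extract_patches(image: np.ndarray, truth_boxes: list[dict],
                    image_id: str = "", n_background: int = 0,
                    rng: np.random.Generator | None = None,
                    patch_size: int = PATCH_SIZE) -> list[PatchRecord]:
    """Crop each annotated box and resize to a classifier patch.

    Degenerate boxes (cropped extent under 2 px) are skipped with a
    warning.  If ``n_background > 0``, that many ``no_fruit`` patches
    are sampled (seeded ``rng`` required) from windows that do not
    intersect any annotated box.
    """
    records: list[PatchRecord] = []
    h, w = image.shape[:2]
    for box in truth_boxes:
        crop = _crop_box(image, box)
        if crop is None:
            warnings.warn(f"skipping degenerate box {box} in {image_id!r}")
            continue
        patch = _sk_resize(crop, (patch_size, patch_size), order=1,
                           mode="reflect", anti_aliasing=False)
        records.append(PatchRecord(image_id=image_id, box=dict(box),
                                   ripeness=box.get("ripeness", "no_fruit"),
                                   patch=patch))
    if n_background > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        side = int(np.median([b["w"] for b in truth_boxes])) if truth_boxes else 32
        side = max(8, min(side, h, w))
        placed, attempts = 0, 0
        while placed < n_background and attempts < 200 * n_background:
            attempts += 1
            y0 = int(rng.integers(0, h - side + 1))
            x0 = int(rng.integers(0, w - side + 1))
            if any(_windows_overlap(x0, y0, side, b) for b in truth_boxes):
                continue
            crop = image[y0:y0 + side, x0:x0 + side]
            patch = _sk_resize(crop, (patch_size, patch_size), order=1,
                               mode="reflect", anti_aliasing=False)
            box = {"x": x0 + (side - 1) / 2.0, "y": y0 + (side - 1) / 2.0,
                   "w": side, "h": side}
            records.append(PatchRecord(image_id=image_id, box=box,
                                       ripeness="no_fruit", patch=patch))
            placed += 1
    return records


def _windows_overlap(x0: int, y0: int, side: int, box: dict) -> bool:
    bx0 = box["x"] - box["w"] / 2.0
    by0 = box["y"] - box["h"] / 2.0
    return not (x0 + side <= bx0 or bx0 + box["w"] <= x0
                or y0 + side <= by0 or by0 + box["h"] <= y0)


@dataclass
class AugmentParams:
    """One draw of the augmentation transforms.

    ``shear_px`` is the horizontal displacement, in pixels, of the top
    and bottom patch rows relative to the center row.
    """

    flip: bool
    angle_deg: float        # in [-180, 180]
    tx: float               # in [-15, 15] px
    ty: float               # in [-15, 15] px
    shear_px: float         # in [-10, 10] px

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(flip=False, angle_deg=0.0, tx=0.0, ty=0.0, shear_px=0.0)


def draw_augment_params(rng: np.random.Generator) -> AugmentParams:
    """Draw one augmentation: 50% reflection, rotation U(-180, 180) deg,
    translation U(-15, 15) px per axis, shear U(-10, 10) px."""
    return AugmentParams(
        flip=bool(rng.random() < 0.5),
        angle_deg=float(rng.uniform(-180.0, 180.0)),
        tx=float(rng.uniform(-15.0, 15.0)),
        ty=float(rng.uniform(-15.0, 15.0)),
        shear_px=float(rng.uniform(-10.0, 10.0)),
    )


def apply_augmentation(patch: np.ndarray, params: AugmentParams) -> np.ndarray:
    """Apply reflection -> rotation -> translation -> shear, in order.

    Rotation and shear act about the patch center; interpolation is
    bilinear with reflected border padding.  Shape and value range are
    preserved.
    """
    h, w = patch.shape[:2]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    to_origin = AffineTransform(translation=(-cx, -cy))
    back = AffineTransform(translation=(cx, cy))

    tform = AffineTransform()
    if params.flip:
        flip = AffineTransform(np.array([[-1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]))
        tform = to_origin + flip + back
    rot = to_origin + AffineTransform(rotation=np.deg2rad(params.angle_deg)) + back
    trans = AffineTransform(translation=(params.tx, params.ty))
    shear_mat = np.array([[1.0, 2.0 * params.shear_px / h, 0.0],
                          [0.0, 1.0, 0.0],
                          [0.0, 0.0, 1.0]])
    shear = to_origin + AffineTransform(shear_mat) + back
    tform = tform + rot + trans + shear

    out = warp(patch, tform.inverse, order=1, mode="reflect",
               preserve_range=True)
    return np.clip(out, patch.min(), patch.max())


def augment(patch: np.ndarray, seed: int) -> np.ndarray:
    """Seeded random augmentation of a classifier patch."""
    params = draw_augment_params(np.random.default_rng(seed))
    return apply_augmentation(patch, params)


def compare_methods(pairs: list[tuple[str, RegisteredPair]],
                    methods: dict, alpha: float = 0.05,
                    contrast_mode: str = "rms"
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per image x method metric table plus Tukey HSD comparisons.

    Parameters
    ----------
    pairs:
        ``(image_id, RegisteredPair)`` entries (see
        ``synthetic.load_manifest_pairs``).
    methods:
        Mapping from method name to a ``pair -> fused RGB image``
        callable.  A failing method is recorded as missing for that
        image and the run continues.

    Returns
    -------
    (metric table, comparison table): the first has one row per
    image x method with the four metrics; the second has, per metric,
    all-pairs mean differences with Tukey-adjusted p-values at
    ``alpha``.
    """
    rows = []
    for image_id, pair in pairs:
        for name, method in methods.items():
            try:
                fused = method(pair)
            except Exception as exc:  # noqa: BLE001 - record and continue
                warnings.warn(f"method {name!r} failed on {image_id!r}: {exc}")
                rows.append({"image_id": image_id, "method": name,
                             "contrast": np.nan, "entropy": np.nan,
                             "colorfulness": np.nan, "saturation": np.nan})
                continue
            rep = _metrics.report(fused, image_id=image_id,
                                  contrast_mode=contrast_mode)
            rows.append({"image_id": image_id, "method": name,
                         **{k: v for k, v in rep.to_dict().items()
                            if k != "image_id"}})
    table = pd.DataFrame(rows)

    comparisons = _tukey_table(table, alpha=alpha)
    return table, comparisons


def _tukey_table(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    out_rows = []
    methods = sorted(table["method"].unique())
    if len(methods) < 2 or table.empty:
        return pd.DataFrame(columns=["metric", "group1", "group2",
                                     "meandiff", "p_adj", "reject"])
    for metric in ("contrast", "entropy", "colorfulness", "saturation"):
        sub = table.dropna(subset=[metric])
        if sub["method"].nunique() < 2:
            continue
        values = sub[metric].to_numpy()
        groups = sub["method"].to_numpy()
        if np.allclose(values, values[0]):
            # degenerate zero-variance case: all means equal, nothing to flag
            for i, g1 in enumerate(methods):
                for g2 in methods[i + 1:]:
                    out_rows.append({"metric": metric, "group1": g1,
                                     "group2": g2, "meandiff": 0.0,
                                     "p_adj": 1.0, "reject": False})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = pairwise_tukeyhsd(values, groups, alpha=alpha)
        frame = pd.DataFrame(res.summary().data[1:],
                             columns=res.summary().data[0])
        for _, r in frame.iterrows():
            meandiff = float(r["meandiff"])
            p_adj = float(r["p-adj"])
            reject = bool(r["reject"])
            if not np.isfinite(p_adj) and meandiff == 0.0:
                p_adj, reject = 1.0, False
            out_rows.append({"metric": metric, "group1": r["group1"],
                             "group2": r["group2"], "meandiff": meandiff,
                             "p_adj": p_adj, "reject": reject})
    return pd.DataFrame(out_rows)
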