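"""Synthetic registered VIS/NIR greenhouse scenes with ground truth.

The generator emulates the ordinal structure a greenhouse berry scene
presents to the fusion pipeline, not its photometric detail:

* a bright, low-vegetation **sky/tarpaulin** band at the top whose NIR
  reflectance tracks its red channel (NDVI ~ 0);
* **foliage** filling the rest: dark green in VIS with high NIR
  reflectance (NDVI well above the 0.2 vegetation threshold);
* thin **stems** crossing the foliage;
* **fruit** rendered as clusters of overlapping drupelet disks placed on
  the foliage with a minimum-separation (Poisson-disk style) rule, in
  three ripeness stages: unripe (green/orange), nearly ripe (dark with
  orange patches) and ripe (uniformly near-black, darker than the
  surrounding leaves — the confusability the fusion method targets).

Global illumination is a single ``exposure`` scale applied to both the
VIS and NIR planes (ambient light reaches both sensors); additive
Gaussian sensor noise is applied to the VIS image only, then clipped.
Scenes are deterministic given their seed.
"""

from __future__ import annotations

import json

import imageio.v3 as iio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .image_io import RegisteredPair, load_pair, save_image

CLASS_IDS = {"sky": 0, "leaf": 1, "stem": 2, "fruit": 3}
RIPENESS_STAGES = ("unripe", "nearly_ripe", "ripe")

# reflectance table: (VIS rgb, NIR); chosen so NDVI semantics hold:
# vegetation and fruit NDVI > 0.2, sky NDVI ~ 0 (and thus the scene
# minimum, so atmospheric-light selection lands on the sky/tarpaulin),
# ripe fruit darker than leaves.
PALETTE = {
    "sky": ((0.86, 0.86, 0.88), None),  # NIR copies the textured red channel
    "leaf": ((0.10, 0.46, 0.09), 0.62),
    "stem": ((0.20, 0.30, 0.12), 0.55),
    "unripe": ((0.30, 0.48, 0.10), 0.60),
    "nearly_ripe": ((0.08, 0.05, 0.07), 0.36),
    "nearly_ripe_patch": ((0.38, 0.20, 0.06), 0.60),
    "ripe": ((0.05, 0.04, 0.06), 0.35),
}

#: fraction of the canvas height taken by the sky/tarpaulin band; greenhouse
#: shots are mostly canopy with a narrow bright band at the top
SKY_FRACTION = 0.20

#: amplitude of the smooth multiplicative texture field (fine structure)
TEXTURE_AMPLITUDE = 0.12

#: depth of the canopy self-shading field: canopy pixels are attenuated by
#: a smooth factor in [1 - SHADE_AMPLITUDE, 1]; the sky band is unshaded
SHADE_AMPLITUDE = 0.45


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene."""

    height: int = 160
    width: int = 160
    exposure: float = 1.0       # <= 0.3 is strongly underexposed
    fruit_count: int = 8
    ripeness_mix: dict = field(
        default_factory=lambda: {"unripe": 0.4, "nearly_ripe": 0.2, "ripe": 0.4})
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("scene dimensions must be at least 64 px")
        if not 0.0 < self.exposure <= 1.0:
            raise ValueError(f"exposure must be in (0, 1], got {self.exposure}")
        total = sum(self.ripeness_mix.get(s, 0.0) for s in RIPENESS_STAGES)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("ripeness_mix proportions must sum to 1")
        if self.fruit_count < 0:
            raise ValueError("fruit_count must be non-negative")


@dataclass
class SceneTruth:
    """Ground truth for one scene: label mask and ripeness boxes."""

    masks: np.ndarray           # H x W uint8 over CLASS_IDS
    boxes: list[dict]           # {"x","y","w","h","ripeness"}, x/y = box center


def _smooth_field(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Zero-mean smooth texture field in roughly [-1, 1]."""
    coarse = rng.normal(size=(max(2, h // 8), max(2, w // 8)))
    fine = _sk_resize(coarse, (h, w), order=1, mode="edge", anti_aliasing=False)
    return np.clip(fine, -2.0, 2.0) / 2.0


def _ripeness_counts(mix: dict, n: int) -> list[str]:
    """Deterministic largest-remainder allocation of n fruits to stages."""
    raw = {s: mix.get(s, 0.0) * n for s in RIPENESS_STAGES}
    counts = {s: int(np.floor(v)) for s, v in raw.items()}
    short = n - sum(counts.values())
    for s in sorted(RIPENESS_STAGES, key=lambda s: raw[s] - counts[s], reverse=True):
        if short <= 0:
            break
        counts[s] += 1
        short -= 1
    out: list[str] = []
    for s in RIPENESS_STAGES:
        out.extend([s] * counts[s])
    return out


def _place_fruits(rng: np.random.Generator, spec: SceneSpec,
                  sky_bottom: np.ndarray, radius: int) -> list[tuple[int, int]]:
    """Poisson-disk style rejection placement of fruit cluster centers."""
    h, w = spec.height, spec.width
    margin = 2 * radius
    y_lo = int(sky_bottom.max()) + margin
    y_hi = h - margin
    x_lo, x_hi = margin, w - margin
    min_dist = 3.2 * radius
    if y_hi <= y_lo or x_hi <= x_lo:
        raise ValueError("canvas too small for any fruit placement")
    capacity = (y_hi - y_lo) * (x_hi - x_lo) / (min_dist * min_dist)
    if spec.fruit_count > 0.6 * capacity:
        raise ValueError(
            f"fruit_count={spec.fruit_count} infeasible for a "
            f"{h}x{w} canvas (capacity ~{int(0.6 * capacity)})")
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < spec.fruit_count:
        if attempts > 400 * max(1, spec.fruit_count):
            raise ValueError("could not place all fruits; reduce fruit_count")
        attempts += 1
        cy = int(rng.integers(y_lo, y_hi))
        cx = int(rng.integers(x_lo, x_hi))
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_dist ** 2 for y, x in centers):
            centers.append((cy, cx))
    return centers


def generate_scene(spec: SceneSpec) -> tuple[RegisteredPair, SceneTruth]:
    """Render one scene; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]

    # sky/tarpaulin band with a wavy lower boundary
    base = SKY_FRACTION * h
    amp = 0.05 * h
    freq = rng.integers(1, 3)
    phase = rng.uniform(0, 2 * np.pi)
    sky_bottom = (base + amp * np.sin(2 * np.pi * freq * np.arange(w) / w + phase))
    labels = np.full((h, w), CLASS_IDS["leaf"], dtype=np.uint8)
    labels[yy < sky_bottom[None, :]] = CLASS_IDS["sky"]

    # thin wavy stems through the foliage
    n_stems = max(1, w // 56)
    stem_mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_stems):
        x0 = rng.uniform(0.1 * w, 0.9 * w)
        sway = rng.uniform(1.5, 3.0)
        sph = rng.uniform(0, 2 * np.pi)
        xc = x0 + sway * np.sin(2 * np.pi * yy[:, 0] / h * 2 + sph)
        for dy in range(h):
            lo = int(round(xc[dy] - 1))
            stem_mask[dy, max(0, lo):min(w, lo + 2)] = True
    stem_mask &= labels == CLASS_IDS["leaf"]
    labels[stem_mask] = CLASS_IDS["stem"]

    # fruit clusters (overlapping drupelet disks)
    radius = max(3, round(min(h, w) / 22))
    centers = _place_fruits(rng, spec, sky_bottom, radius) if spec.fruit_count else []
    stages = _ripeness_counts(spec.ripeness_mix, len(centers))
    rng.shuffle(stages)

    vis = np.empty((h, w, 3))
    nir = np.empty((h, w))
    for name in ("sky", "leaf", "stem"):
        sel = labels == CLASS_IDS[name]
        rgb, n_refl = PALETTE[name]
        vis[sel] = rgb
        nir[sel] = rgb[0] if n_refl is None else n_refl

    boxes: list[dict] = []
    for (cy, cx), stage in zip(centers, stages):
        rgb, n_refl = PALETTE[stage]
        cluster = np.zeros((h, w), dtype=bool)
        n_drupelets = int(rng.integers(4, 8))
        for _ in range(n_drupelets):
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0, 0.8 * radius)
            dy, dx = cy + dist * np.sin(ang), cx + dist * np.cos(ang)
            rr = 0.55 * radius
            cluster |= (yy - dy) ** 2 + (xx - dx) ** 2 <= rr * rr
        labels[cluster] = CLASS_IDS["fruit"]
        vis[cluster] = rgb
        nir[cluster] = n_refl
        if stage == "nearly_ripe":
            # orange patch on part of the cluster
            p_rgb, p_n = PALETTE["nearly_ripe_patch"]
            ang = rng.uniform(0, 2 * np.pi)
            py, px = cy + 0.5 * radius * np.sin(ang), cx + 0.5 * radius * np.cos(ang)
            patch = cluster & ((yy - py) ** 2 + (xx - px) ** 2 <= (0.5 * radius) ** 2)
            vis[patch] = p_rgb
            nir[patch] = p_n
        ys, xs = np.nonzero(cluster)
        bw, bh = int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1)
        boxes.append({
            "x": float(xs.min() + (bw - 1) / 2.0),
            "y": float(ys.min() + (bh - 1) / 2.0),
            "w": bw, "h": bh, "ripeness": stage,
        })

    # shared multiplicative texture keeps NDVI and hue invariant
    tex = 1.0 + TEXTURE_AMPLITUDE * _smooth_field(rng, h, w)
    # smooth canopy self-shading (leaf angles, gaps); scales VIS and NIR
    # together, so NDVI and local fruit-vs-leaf ordering are preserved
    shade_u = np.clip((_smooth_field(rng, h, w) + 1.0) / 2.0, 0.0, 1.0)
    shade = 1.0 - SHADE_AMPLITUDE * shade_u
    canopy = labels != CLASS_IDS["sky"]
    tex = tex * np.where(canopy, shade, 1.0)
    vis *= tex[:, :, None]
    nir *= tex

    vis = np.clip(vis * spec.exposure, 0.0, 1.0)
    nir = np.clip(nir * spec.exposure, 0.0, 1.0)
    if spec.noise_sigma > 0:
        vis = np.clip(vis + rng.normal(0.0, spec.noise_sigma, vis.shape), 0.0, 1.0)

    pair = RegisteredPair(vis=vis, nir=nir)
    return pair, SceneTruth(masks=labels, boxes=boxes)


def scene_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-scene seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def generate_dataset(n_scenes: int, spec_template: SceneSpec,
                     seed: int, out_dir: str) -> pd.DataFrame:
    """Write ``n_scenes`` scene pairs plus truth files and a manifest.

    Files per scene: 8-bit VIS and NIR PNGs, an indexed-PNG label mask
    and a JSON-lines box file; ``manifest.csv`` indexes them all.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(scene_seeds(seed, n_scenes)):
        spec = SceneSpec(
            height=spec_template.height, width=spec_template.width,
            exposure=spec_template.exposure,
            fruit_count=spec_template.fruit_count,
            ripeness_mix=dict(spec_template.ripeness_mix),
            noise_sigma=spec_template.noise_sigma, seed=s)
        pair, truth = generate_scene(spec)
        sid = f"scene_{i:03d}"
        paths = {
            "vis_path": str(out / f"{sid}_vis.png"),
            "nir_path": str(out / f"{sid}_nir.png"),
            "mask_path": str(out / f"{sid}_mask.png"),
            "boxes_path": str(out / f"{sid}_boxes.jsonl"),
        }
        save_image(paths["vis_path"], pair.vis)
        save_image(paths["nir_path"], pair.nir)
        iio.imwrite(paths["mask_path"], truth.masks)
        with open(paths["boxes_path"], "w") as fh:
            for box in truth.boxes:
                fh.write(json.dumps(box) + "\n")
        rows.append({"scene_id": sid, **paths, "seed": s,
                     "exposure": spec.exposure})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_manifest_pairs(manifest_path: str) -> list[tuple[str, RegisteredPair]]:
    """Load all (scene_id, RegisteredPair) entries listed in a manifest."""
    manifest = pd.read_csv(manifest_path)
    return [(row.scene_id, load_pair(row.vis_path, row.nir_path))
            for row in manifest.itertuples()]


def load_truth(mask_path: str, boxes_path: str) -> SceneTruth:
    """Read back a scene's label mask and box records."""
    masks = np.asarray(iio.imread(mask_path)).astype(np.uint8)
    boxes = []
    with open(boxes_path) as fh:
        for line in fh:
            if line.strip():
                boxes.append(json.loads(line))
    return SceneTruth(masks=masks, boxes=boxes)
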