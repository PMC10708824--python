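"""Independent per-pixel scalar reference implementations.

These are deliberately naive Python loops over pixels, written directly
from the scalar definitions, and share no array code with the package.
They serve as brute-force oracles for the vectorized pipeline and the
metric implementations on tiny images.
"""

from __future__ import annotations

import math

import numpy as np
from skimage import color as _skcolor

EPS = 1e-6


# ---------------------------------------------------------------- metrics

def oracle_contrast_rms(gray):
    vals = [float(v) * 255.0 for row in gray for v in row]
    n = len(vals)
    mean = sum(vals) / n
    mean_sq = sum(v * v for v in vals) / n
    return math.sqrt(max(mean_sq - mean * mean, 0.0))


def oracle_entropy(image):
    image = np.asarray(image)
    channels = [image] if image.ndim == 2 else [image[:, :, c]
                                                for c in range(image.shape[2])]
    ents = []
    for ch in channels:
        counts = [0] * 256
        n = 0
        for row in ch:
            for v in row:
                b = int(float(v) * 256.0)
                if b > 255:
                    b = 255
                counts[b] += 1
                n += 1
        ent = 0.0
        for c in counts:
            if c > 0:
                p = c / n
                ent -= p * math.log2(p)
        ents.append(ent)
    return sum(ents) / len(ents)


def oracle_colorfulness(vis):
    lab = _skcolor.rgb2lab(np.asarray(vis, dtype=np.float64))
    a_vals, b_vals, chroma = [], [], []
    h, w = lab.shape[:2]
    for i in range(h):
        for j in range(w):
            a, b = float(lab[i, j, 1]), float(lab[i, j, 2])
            a_vals.append(a)
            b_vals.append(b)
            chroma.append(math.sqrt(a * a + b * b))
    n = len(a_vals)

    def _std(xs):
        m = sum(xs) / n
        return math.sqrt(sum((x - m) ** 2 for x in xs) / n)

    return _std(a_vals) + _std(b_vals) + 0.94 * sum(chroma) / n


def oracle_saturation(vis):
    vis = np.asarray(vis, dtype=np.float64)
    h, w = vis.shape[:2]
    total = 0.0
    for i in range(h):
        for j in range(w):
            r, g, b = (float(vis[i, j, c]) for c in range(3))
            if r + g + b < EPS:
                s = 0.0  # black is achromatic by convention
            else:
                s = 1.0 - 3.0 * min(r, g, b) / (r + g + b + EPS)
            total += min(max(s, 0.0), 1.0)
    return total / (h * w)


# ----------------------------------------------------------------- fusion

def oracle_fuse(vis, nir, delta=0.5, omega=0.6, t_floor=0.1,
                light_percentile=0.001, eps=EPS):
    """Scalar reference of the whole fusion pipeline.

    Returns a dict with every intermediate stage so tests can compare
    stage by stage as well as end to end.
    """
    vis = np.asarray(vis, dtype=np.float64)
    nir = np.asarray(nir, dtype=np.float64)
    h, w = nir.shape

    # NDVI and complement weight
    vi = [[0.0] * w for _ in range(h)]
    vi_comp = [[0.0] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            n, r = float(nir[i, j]), float(vis[i, j, 0])
            v = 0.0 if n + r < eps else (n - r) / (n + r)
            vi[i][j] = v
            vi_comp[i][j] = 1.0 - min(max(v, 0.0), 1.0)

    # complement image
    comp = [[[1.0 - float(vis[i, j, c]) for c in range(3)]
             for j in range(w)] for i in range(h)]

    # atmospheric light: K lowest-VI pixels, row-major tie-break
    k = max(1, math.ceil(light_percentile * h * w))
    order = sorted(range(h * w), key=lambda idx: (vi[idx // w][idx % w], idx))
    light = [eps, eps, eps]
    for idx in order[:k]:
        i, j = idx // w, idx % w
        for c in range(3):
            light[c] = max(light[c], float(vis[i, j, c]))

    # dark channel of the complement normalised by L; literal transmission
    dark = [[min(comp[i][j][c] / light[c] for c in range(3))
             for j in range(w)] for i in range(h)]
    t = [[min(max((1.0 - omega) * dark[i][j], t_floor), 1.0)
          for j in range(w)] for i in range(h)]

    # enhancement of the complement, re-inverted
    enhanced = [[[0.0] * 3 for _ in range(w)] for _ in range(h)]
    for i in range(h):
        for j in range(w):
            for c in range(3):
                r_val = light[c] + (comp[i][j][c] - light[c]) / t[i][j]
                enhanced[i][j][c] = 1.0 - min(max(r_val, 0.0), 1.0)

    # NIR term
    fn = [[[0.0] * 3 for _ in range(w)] for _ in range(h)]
    for i in range(h):
        for j in range(w):
            s = sum(float(vis[i, j, c]) for c in range(3)) + eps
            for c in range(3):
                fn[i][j][c] = (delta * float(nir[i, j]) * dark[i][j]
                               * float(vis[i, j, c]) / s)

    # blend
    fused = np.zeros((h, w, 3))
    weights = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            wgt = t[i][j] * vi_comp[i][j]
            weights[i, j] = wgt
            for c in range(3):
                val = (fn[i][j][c] + float(vis[i, j, c]) * (1.0 - wgt)
                       + enhanced[i][j][c] * wgt)
                fused[i, j, c] = min(max(val, 0.0), 1.0)

    return {
        "vi": np.array(vi), "vi_comp": np.array(vi_comp),
        "light": np.array(light), "dark": np.array(dark), "t": np.array(t),
        "enhanced": np.array(enhanced), "fn": np.array(fn),
        "weights": weights, "fused": fused,
    }
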