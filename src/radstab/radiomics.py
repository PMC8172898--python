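"""First-order and grey-level co-occurrence (GLCM) feature extraction.

The feature set is 13 first-order statistics of the ROI grey-level
distribution plus 19 GLCM texture features, the latter computed both
slice-wise in 2D (four directions: 0°, 45°, 90°, 135°, features averaged
over slices) and in 3D (the 13 unique directions of the 26-neighbourhood
modulo sign), at five odd displacement distances δ ∈ {1, 3, 5, 7, 9}.

Pre-processing per ROI and image variant: grey levels outside the ROI's own
[2.5, 97.5] percentile band are discarded (tail trimming), and the surviving
range is quantized into 32 equal-width bins.  Co-occurrence counts are
summed over directions (pair-count weighting), symmetrized by adding the
transpose, and normalized to a joint probability matrix.

Formulations follow the classical Haralick / Soh–Tsatsoulis / Clausi
definitions; every feature is unit-tested against a brute-force oracle.
Logarithms are base 2 with the 0·log 0 = 0 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .core import CTVolume, ROIMask

__all__ = [
    "GLCMConfig",
    "QuantizedROI",
    "CooccurrenceMatrix",
    "DIRECTIONS_2D",
    "directions_3d",
    "trim_and_quantize",
    "first_order_features",
    "glcm_accumulate",
    "glcm_features",
    "glcm2d_case_features",
    "glcm3d_case_features",
    "extract_all",
    "FO_IDS",
    "GLCM_IDS",
    "canonical_feature_ids",
    "feature_class",
]

#: 2D co-occurrence directions (dy, dx) for θ = 0°, 45°, 90°, 135°
DIRECTIONS_2D = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

FO_IDS = (
    "m", "M", "s", "max", "m90th", "M90th", "std",
    "MAD", "iqr", "lCV", "u", "e", "k",
)

GLCM_IDS = (
    "autoc", "corr", "cprom", "homom", "maxpr", "contr", "cshade",
    "sosvh", "dissi", "energ", "entro", "dvarh", "denth", "inf1h",
    "indnc", "idmnc", "savgh", "svarh", "senth",
)


def directions_3d() -> tuple:
    """The 13 unique displacement vectors of the 26-neighbourhood modulo sign.

    All (dz, dy, dx) in {-1, 0, 1}^3 minus the origin form 26 vectors in 13
    antipodal pairs; one representative per pair (the lexicographically
    positive one) is kept, since symmetrized co-occurrence makes v and -v
    equivalent.
    """
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                v = (dz, dy, dx)
                if v == (0, 0, 0):
                    continue
                if v > tuple(-c for c in v):
                    dirs.append(v)
    return tuple(dirs)


@dataclass
class GLCMConfig:
    """Quantization and co-occurrence configuration."""

    n_levels: int = 32
    distances: tuple = (1, 3, 5, 7, 9)
    trim_fraction: float = 0.025
    symmetrize: bool = True
    direction_weighting: str = "pair-count"  # or "mean-of-features"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if any(d < 1 or d % 2 == 0 for d in self.distances):
            raise ValueError("distances must be positive odd integers")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")


@dataclass
class QuantizedROI:
    """Trimmed, quantized ROI.

    ``levels`` is a full-volume int array with values 1..n_levels at kept ROI
    voxels and 0 elsewhere; ``kept_mask`` marks the kept voxels; ``raw`` holds
    the post-trim HU values at kept voxels (flattened, volume order).
    """

    levels: np.ndarray
    kept_mask: np.ndarray
    level_edges: np.ndarray
    n_levels: int
    raw_volume: np.ndarray  # original HU, full volume (for lCV neighbourhoods)

    @property
    def raw(self) -> np.ndarray:
        return self.raw_volume[self.kept_mask]


@dataclass
class CooccurrenceMatrix:
    """Direction-summed, symmetrized, normalized co-occurrence matrix."""

    P: np.ndarray
    delta: int
    mode: str  # "2D-slice" or "3D"
    n_pairs: int

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


def trim_and_quantize(vol: CTVolume, mask: ROIMask, cfg: GLCMConfig) -> QuantizedROI:
    """Tail-trim the ROI histogram and quantize to equal-width bins.

    Voxels whose HU lies outside the ROI's own [trim, 1−trim] percentile band
    are excluded; the remaining min–max range is split into ``n_levels``
    equal-width bins and each kept voxel is assigned its 1-based bin index.
    A constant post-trim ROI collapses to a single level (level 1).
    """
    if not mask.voxels.any():
        raise ValueError("empty ROI mask")
    vals = vol.voxels[mask.voxels].astype(float)
    if cfg.trim_fraction > 0:
        lo, hi = np.quantile(vals, [cfg.trim_fraction, 1.0 - cfg.trim_fraction])
    else:
        lo, hi = vals.min(), vals.max()
    kept = np.zeros_like(mask.voxels)
    kept[mask.voxels] = (vals >= lo) & (vals <= hi)
    kept_vals = vol.voxels[kept].astype(float)
    vmin, vmax = kept_vals.min(), kept_vals.max()
    levels = np.zeros(vol.voxels.shape, dtype=np.int32)
    if vmax == vmin:
        levels[kept] = 1
        edges = np.array([vmin, vmax])
    else:
        width = (vmax - vmin) / cfg.n_levels
        edges = vmin + width * np.arange(cfg.n_levels + 1)
        idx = np.floor((vol.voxels[kept] - vmin) / width).astype(np.int32) + 1
        levels[kept] = np.clip(idx, 1, cfg.n_levels)
    return QuantizedROI(
        levels=levels, kept_mask=kept, level_edges=edges,
        n_levels=cfg.n_levels, raw_volume=np.asarray(vol.voxels, dtype=float),
    )


# --- first-order -----------------------------------------------------------

def _local_cv(q: QuantizedROI) -> float:
    """Mean over kept voxels of local SD / |local mean| in 3x3 in-slice
    neighbourhoods restricted to kept ROI voxels; neighbourhoods with
    |mean| < 1 HU are skipped."""
    kept = q.kept_mask.astype(float)
    vals = np.where(q.kept_mask, q.raw_volume, 0.0)
    ratios = []
    for iz in range(kept.shape[0]):
        if not q.kept_mask[iz].any():
            continue
        n = uniform_filter(kept[iz], size=3) * 9.0
        s1 = uniform_filter(vals[iz], size=3) * 9.0
        s2 = uniform_filter(vals[iz] ** 2, size=3) * 9.0
        centres = q.kept_mask[iz] & (np.rint(n).astype(int) >= 1)
        nn = np.rint(n[centres])
        mean = s1[centres] / nn
        var = np.maximum(s2[centres] / nn - mean**2, 0.0)
        ok = np.abs(mean) >= 1.0
        if ok.any():
            ratios.append(np.sqrt(var[ok]) / np.abs(mean[ok]))
    if not ratios:
        return 0.0
    return float(np.mean(np.concatenate(ratios)))


def first_order_features(q: QuantizedROI) -> dict:
    """The 13 first-order features of the kept ROI grey levels.

    Population (biased) moment conventions throughout; quantiles use linear
    interpolation between order statistics.  Uniformity ``u`` and entropy
    ``e`` are computed on the quantized-level histogram; everything else on
    raw post-trim HU.  Skewness and kurtosis of a zero-variance ROI are
    reported as 0 (kurtosis is the non-excess, Pearson form: 3 for a
    Gaussian).
    """
    x = q.raw
    if x.size < 1:
        raise ValueError("no kept voxels")
    m = float(np.mean(x))
    std = float(np.std(x))
    q90 = np.quantile(x, 0.9)
    top = x[x >= q90]
    if std > 0:
        z = (x - m) / std
        s = float(np.mean(z**3))
        k = float(np.mean(z**4))
    else:
        s = k = 0.0
    levels = q.levels[q.kept_mask]
    counts = np.bincount(levels, minlength=q.n_levels + 1)[1:]
    p = counts[counts > 0] / levels.size
    return {
        "m": m,
        "M": float(np.median(x)),
        "s": s,
        "max": float(np.max(x)),
        "m90th": float(np.mean(top)),
        "M90th": float(np.median(top)),
        "std": std,
        "MAD": float(np.median(np.abs(x - np.median(x)))),
        "iqr": float(np.quantile(x, 0.75) - np.quantile(x, 0.25)),
        "lCV": _local_cv(q),
        "u": float(np.sum(p**2)),
        "e": float(-np.sum(p * np.log2(p))),
        "k": k,
    }


# --- co-occurrence ---------------------------------------------------------

def _count_pairs(levels: np.ndarray, offset: tuple, n_levels: int) -> np.ndarray:
    """Ordered co-occurrence counts at one displacement; 0 marks non-kept."""
    sl_a = tuple(
        slice(max(-o, 0), levels.shape[ax] - max(o, 0)) for ax, o in enumerate(offset)
    )
    sl_b = tuple(
        slice(max(o, 0), levels.shape[ax] + min(o, 0)) for ax, o in enumerate(offset)
    )
    a = levels[sl_a].ravel()
    b = levels[sl_b].ravel()
    ok = (a > 0) & (b > 0)
    if not ok.any():
        return np.zeros((n_levels, n_levels), dtype=np.int64)
    flat = (a[ok] - 1) * n_levels + (b[ok] - 1)
    counts = np.bincount(flat, minlength=n_levels * n_levels)
    return counts.reshape(n_levels, n_levels)


def glcm_accumulate(
    q: QuantizedROI, delta: int, mode: str, slice_index: int | None = None,
    directions: tuple | None = None,
) -> CooccurrenceMatrix:
    """Direction-summed co-occurrence matrix of the kept ROI voxels.

    2D mode counts within-slice pairs over the four in-plane directions
    (optionally restricted to one slice); 3D mode counts pairs over the 13
    sign-unique directions of the 26-neighbourhood.  Counts are summed over
    directions (pass ``directions`` to restrict the set), symmetrized by
    adding the transpose, and normalized.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    n = q.n_levels
    if mode == "2D-slice":
        dirs = directions if directions is not None else DIRECTIONS_2D
        offsets = [(0, dy * delta, dx * delta) for dy, dx in dirs]
        levels = q.levels if slice_index is None else q.levels[slice_index][None]
    elif mode == "3D":
        dirs = directions if directions is not None else directions_3d()
        offsets = [tuple(delta * c for c in v) for v in dirs]
        levels = q.levels
    else:
        raise ValueError(f"unknown GLCM mode {mode!r}")
    counts = np.zeros((n, n), dtype=np.int64)
    for off in offsets:
        counts += _count_pairs(levels, off, n)
    n_pairs = int(counts.sum())
    sym = counts + counts.T
    total = sym.sum()
    P = sym / total if total > 0 else sym.astype(float)
    return CooccurrenceMatrix(P=P, delta=delta, mode=mode, n_pairs=n_pairs)


def glcm_features(cm: CooccurrenceMatrix) -> dict:
    """The 19 co-occurrence texture features of a normalized matrix.

    ``i, j`` run over 1..N (1-based levels).  Sum/difference features use the
    distributions of ``i+j`` and ``|i-j|``; correlation of a single-level
    matrix (zero marginal variance) is reported as 0.
    """
    if cm.empty:
        raise ValueError("empty co-occurrence matrix (no valid pairs)")
    P = cm.P
    n = P.shape[0]
    i = np.arange(1, n + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = float(np.sum(i * px))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    sd_x = np.sqrt(var_x)

    def _ent(p):
        p = p[p > 0]
        return float(-np.sum(p * np.log2(p)))

    # sum distribution p_{x+y}(k), k = 2..2N, and difference |i-j|, k = 0..N-1
    ksum = np.arange(2, 2 * n + 1)
    p_sum = np.array([P[(I + J) == k].sum() for k in ksum])
    kdif = np.arange(0, n)
    p_dif = np.array([P[np.abs(I - J) == k].sum() for k in kdif])

    autoc = float(np.sum(I * J * P))
    corr = (autoc - mu_x * mu_x) / var_x if var_x > 0 else 0.0
    savgh = float(np.sum(ksum * p_sum))
    svarh = float(np.sum((ksum - savgh) ** 2 * p_sum))
    mu_d = float(np.sum(kdif * p_dif))
    dvarh = float(np.sum((kdif - mu_d) ** 2 * p_dif))

    hx = _ent(px)
    hxy = _ent(P.ravel())
    outer = np.outer(px, px)
    mask = (P > 0) & (outer > 0)
    hxy1 = float(-np.sum(P[mask] * np.log2(outer[mask])))
    # symmetric P gives HX == HY, so max(HX, HY) = HX
    inf1h = (hxy - hxy1) / hx if hx > 0 else 0.0

    return {
        "autoc": autoc,
        "corr": float(corr),
        "cprom": float(np.sum((I + J - 2 * mu_x) ** 4 * P)),
        "homom": float(np.sum(P / (1.0 + np.abs(I - J)))),
        "maxpr": float(P.max()),
        "contr": float(np.sum((I - J) ** 2 * P)),
        "cshade": float(np.sum((I + J - 2 * mu_x) ** 3 * P)),
        "sosvh": float(np.sum((I - mu_x) ** 2 * P)),
        "dissi": float(np.sum(np.abs(I - J) * P)),
        "energ": float(np.sum(P**2)),
        "entro": hxy,
        "dvarh": dvarh,
        "denth": _ent(p_dif),
        "inf1h": float(inf1h),
        "indnc": float(np.sum(P / (1.0 + np.abs(I - J) / n))),
        "idmnc": float(np.sum(P / (1.0 + ((I - J) / n) ** 2))),
        "savgh": savgh,
        "svarh": svarh,
        "senth": _ent(p_sum),
    }


def _features_with_weighting(q, delta, mode, cfg, slice_index=None):
    """Features under the configured direction weighting.

    ``pair-count`` (default) sums raw directional counts before normalizing;
    ``mean-of-features`` computes the 19 features per direction and averages
    over directions with at least one valid pair.
    """
    if cfg.direction_weighting == "pair-count":
        cm = glcm_accumulate(q, delta, mode, slice_index=slice_index)
        return None if cm.empty else glcm_features(cm)
    if cfg.direction_weighting != "mean-of-features":
        raise ValueError(f"unknown direction weighting {cfg.direction_weighting!r}")
    dirs = DIRECTIONS_2D if mode == "2D-slice" else directions_3d()
    per_dir = []
    for v in dirs:
        cm = glcm_accumulate(q, delta, mode, slice_index=slice_index, directions=(v,))
        if not cm.empty:
            per_dir.append(glcm_features(cm))
    if not per_dir:
        return None
    return {fid: float(np.mean([f[fid] for f in per_dir])) for fid in GLCM_IDS}


def glcm2d_case_features(q: QuantizedROI, delta: int, cfg: GLCMConfig) -> dict:
    """Per-slice 2D GLCM features, averaged (unweighted) over usable slices."""
    per_slice = []
    for iz in range(q.levels.shape[0]):
        if not (q.levels[iz] > 0).any():
            continue
        feats = _features_with_weighting(q, delta, "2D-slice", cfg, slice_index=iz)
        if feats is not None:
            per_slice.append(feats)
    if not per_slice:
        raise ValueError(f"no slice has valid 2D pairs at delta={delta}")
    return {fid: float(np.mean([f[fid] for f in per_slice])) for fid in GLCM_IDS}


def glcm3d_case_features(q: QuantizedROI, delta: int, cfg: GLCMConfig) -> dict:
    feats = _features_with_weighting(q, delta, "3D", cfg)
    if feats is None:
        raise ValueError(f"no valid 3D pairs at delta={delta}")
    return feats


def extract_all(vol: CTVolume, mask: ROIMask, cfg: GLCMConfig | None = None) -> dict:
    """Full feature vector for one (volume, ROI) pair.

    Keys: ``FO:<id>`` for the 13 first-order features and
    ``GLCM2D:<id>:d<δ>`` / ``GLCM3D:<id>:d<δ>`` for the texture features.
    """
    cfg = cfg or GLCMConfig()
    q = trim_and_quantize(vol, mask, cfg)
    out = {f"FO:{fid}": v for fid, v in first_order_features(q).items()}
    for d in cfg.distances:
        f2 = glcm2d_case_features(q, d, cfg)
        f3 = glcm3d_case_features(q, d, cfg)
        for fid in GLCM_IDS:
            out[f"GLCM2D:{fid}:d{d}"] = f2[fid]
            out[f"GLCM3D:{fid}:d{d}"] = f3[fid]
    return out


def canonical_feature_ids(cfg: GLCMConfig | None = None) -> list:
    """Canonical feature identifiers: 13 FO + 19 GLCM x 5 distances = 108.

    A distance-specific GLCM feature counts once even though it is rendered
    in both 2D and 3D.
    """
    cfg = cfg or GLCMConfig()
    ids = [f"FO:{fid}" for fid in FO_IDS]
    ids += [f"GLCM:{fid}:d{d}" for d in cfg.distances for fid in GLCM_IDS]
    return ids


def feature_class(feature_id: str) -> str:
    """Feature class by id prefix: FO, GLCM2D or GLCM3D."""
    return feature_id.split(":", 1)[0]
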