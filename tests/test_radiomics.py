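"""First-order and GLCM features against brute-force oracles."""

import numpy as np
import pytest

from radstab.core import CTVolume, ROIMask
from radstab.phantom import AcquisitionSpec, generate_case, toy_fixtures
from radstab.radiomics import (
    DIRECTIONS_2D,
    FO_IDS,
    GLCM_IDS,
    CooccurrenceMatrix,
    GLCMConfig,
    canonical_feature_ids,
    directions_3d,
    extract_all,
    first_order_features,
    glcm2d_case_features,
    glcm_accumulate,
    glcm_features,
    trim_and_quantize,
)

from conftest import as_volume, full_mask


# --- oracles ----------------------------------------------------------------

def brute_glcm(levels, offsets, n_levels):
    """Exhaustive ordered-pair enumeration over kept voxels (level 0 = out)."""
    levels = np.asarray(levels)
    C = np.zeros((n_levels, n_levels))
    for off in offsets:
        it = np.ndindex(levels.shape)
        for idx in it:
            jdx = tuple(i + o for i, o in zip(idx, off))
            if any(j < 0 or j >= s for j, s in zip(jdx, levels.shape)):
                continue
            a, b = levels[idx], levels[jdx]
            if a > 0 and b > 0:
                C[a - 1, b - 1] += 1
    C = C + C.T
    total = C.sum()
    return C / total if total else C


def brute_glcm_features(P):
    """Direct loop evaluation of all 19 texture formulas."""
    n = P.shape[0]
    px = P.sum(axis=1)
    mu = sum((i + 1) * px[i] for i in range(n))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(n))
    f = {k: 0.0 for k in GLCM_IDS}
    psum = np.zeros(2 * n + 1)
    pdif = np.zeros(n)
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            if p == 0:
                continue
            I, J = i + 1, j + 1
            psum[I + J] += p
            pdif[abs(I - J)] += p
            f["autoc"] += I * J * p
            f["cprom"] += (I + J - 2 * mu) ** 4 * p
            f["cshade"] += (I + J - 2 * mu) ** 3 * p
            f["contr"] += (I - J) ** 2 * p
            f["dissi"] += abs(I - J) * p
            f["energ"] += p * p
            f["entro"] -= p * np.log2(p)
            f["homom"] += p / (1 + abs(I - J))
            f["sosvh"] += (I - mu) ** 2 * p
            f["indnc"] += p / (1 + abs(I - J) / n)
            f["idmnc"] += p / (1 + ((I - J) / n) ** 2)
    f["maxpr"] = P.max()
    f["corr"] = (f["autoc"] - mu * mu) / var if var > 0 else 0.0
    ks = np.arange(2 * n + 1)
    f["savgh"] = float((ks * psum).sum())
    f["svarh"] = float(((ks - f["savgh"]) ** 2 * psum).sum())
    f["senth"] = float(-sum(p * np.log2(p) for p in psum if p > 0))
    kd = np.arange(n)
    mud = float((kd * pdif).sum())
    f["dvarh"] = float(((kd - mud) ** 2 * pdif).sum())
    f["denth"] = float(-sum(p * np.log2(p) for p in pdif if p > 0))
    hx = -sum(p * np.log2(p) for p in px if p > 0)
    hxy1 = -sum(
        P[i, j] * np.log2(px[i] * px[j])
        for i in range(n) for j in range(n)
        if P[i, j] > 0 and px[i] * px[j] > 0
    )
    f["inf1h"] = (f["entro"] - hxy1) / hx if hx > 0 else 0.0
    return f


def quantized(img, mask, n_levels, trim=0.0):
    vol = as_volume(img)
    m = ROIMask(
        np.asarray(mask, bool)[None] if np.asarray(mask).ndim == 2 else np.asarray(mask, bool),
        vol.spacing,
    )
    if m.voxels.shape[0] < vol.voxels.shape[0]:
        m = ROIMask(np.repeat(m.voxels, vol.voxels.shape[0], axis=0), vol.spacing)
    return trim_and_quantize(vol, m, GLCMConfig(n_levels=n_levels, trim_fraction=trim))


# --- direction sets ---------------------------------------------------------

def test_direction_sets_match_neighbourhood_enumeration():
    assert len(DIRECTIONS_2D) == 4
    d3 = directions_3d()
    assert len(d3) == 13
    # independent enumeration of the 26-neighbourhood modulo sign
    seen = set()
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                pair = frozenset([(dz, dy, dx), (-dz, -dy, -dx)])
                seen.add(pair)
    assert len(seen) == 13
    assert {frozenset([v, tuple(-c for c in v)]) for v in d3} == seen
    # the 2D set is the 8-neighbourhood modulo sign
    pairs2d = {frozenset([v, (-v[0], -v[1])]) for v in DIRECTIONS_2D}
    assert len(pairs2d) == 4


# --- trimming & quantization ------------------------------------------------

def test_trim_keeps_exactly_950_of_1000_distinct_values(rng):
    vals = rng.permutation(np.arange(1000.0)).reshape(10, 10, 10)
    vol = CTVolume(vals, (1, 1, 1))
    q = trim_and_quantize(vol, full_mask(vol), GLCMConfig())
    assert int(q.kept_mask.sum()) == 950
    kept = vals[q.kept_mask]
    assert kept.min() == 25 and kept.max() == 974


def test_constant_roi_single_level():
    vol = as_volume(np.full((2, 6, 6), 50))
    q = trim_and_quantize(vol, full_mask(vol), GLCMConfig())
    assert q.kept_mask.all()
    assert (q.levels[q.kept_mask] == 1).all()


def test_quantization_levels_in_range(rng):
    vol = as_volume(rng.integers(-100, 300, (4, 12, 12)))
    q = trim_and_quantize(vol, full_mask(vol), GLCMConfig())
    lv = q.levels[q.kept_mask]
    assert lv.min() >= 1 and lv.max() <= 32
    assert (np.diff(q.level_edges) > 0).all()
    with pytest.raises(ValueError):
        trim_and_quantize(vol, ROIMask(np.zeros_like(vol.voxels, bool), vol.spacing), GLCMConfig())


# --- first order ------------------------------------------------------------

def test_first_order_brute_force(rng):
    vals = rng.normal(50, 20, size=(3, 9, 9))
    vol = CTVolume(vals.round(), (1, 1, 1))
    q = trim_and_quantize(vol, full_mask(vol), GLCMConfig(trim_fraction=0.0))
    fo = first_order_features(q)
    x = q.raw
    assert fo["m"] == pytest.approx(x.mean())
    assert fo["M"] == pytest.approx(np.median(x))
    assert fo["max"] == x.max()
    assert fo["std"] == pytest.approx(x.std())
    z = (x - x.mean()) / x.std()
    assert fo["s"] == pytest.approx((z**3).mean())
    assert fo["k"] == pytest.approx((z**4).mean())
    top = x[x >= np.quantile(x, 0.9)]
    assert fo["m90th"] == pytest.approx(top.mean())
    assert fo["M90th"] == pytest.approx(np.median(top))
    assert fo["MAD"] == pytest.approx(np.median(np.abs(x - np.median(x))))
    assert fo["iqr"] == pytest.approx(np.quantile(x, 0.75) - np.quantile(x, 0.25))
    lv = q.levels[q.kept_mask]
    p = np.bincount(lv)[1:] / lv.size
    p = p[p > 0]
    assert fo["u"] == pytest.approx((p**2).sum())
    assert fo["e"] == pytest.approx(-(p * np.log2(p)).sum())
    assert set(fo) == set(FO_IDS)


def test_first_order_one_to_ten():
    vol = as_volume(np.arange(1, 11).reshape(1, 1, 10))
    q = trim_and_quantize(vol, full_mask(vol), GLCMConfig(trim_fraction=0.0))
    fo = first_order_features(q)
    assert fo["m"] == 5.5 and fo["M"] == 5.5 and fo["max"] == 10
    # linear-interpolation quantiles on 1..10 (duplicated over 2 slices)
    x = q.raw
    assert fo["iqr"] == pytest.approx(np.quantile(x, 0.75) - np.quantile(x, 0.25))


def test_first_order_constant_roi_degenerate():
    vol = as_volume(np.full((2, 5, 5), 80))
    q = trim_and_quantize(vol, full_mask(vol), GLCMConfig())
    fo = first_order_features(q)
    assert fo["std"] == 0 and fo["iqr"] == 0 and fo["MAD"] == 0
    assert fo["u"] == 1 and fo["e"] == 0
    assert fo["s"] == 0 and fo["k"] == 0


# --- co-occurrence ----------------------------------------------------------

def test_constant_region_glcm_is_delta():
    img = np.full((1, 3, 3), 7)
    q = quantized(img, np.ones((3, 3)), 4)
    cm = glcm_accumulate(q, 1, "2D-slice")
    assert cm.P[0, 0] == 1.0
    assert cm.P.sum() == 1.0


@pytest.mark.parametrize("delta", [1, 3])
def test_toy_fixture_matches_brute_force_2d(delta):
    img, mask = toy_fixtures()["four_level"]
    q = quantized(img, mask, 4)
    cm = glcm_accumulate(q, delta, "2D-slice", slice_index=0)
    offsets = [(0, dy * delta, dx * delta) for dy, dx in DIRECTIONS_2D]
    oracle = brute_glcm(q.levels[:1], offsets, 4)
    assert np.abs(cm.P - oracle).max() < 1e-12


def test_random_volume_matches_brute_force_3d(rng):
    levels = rng.integers(0, 5, size=(4, 5, 5))  # 0 = not kept
    q = type("Q", (), {})()
    q.levels = levels.astype(np.int32)
    q.n_levels = 4
    cm = glcm_accumulate(q, 1, "3D")
    oracle = brute_glcm(levels, directions_3d(), 4)
    assert np.abs(cm.P - oracle).max() < 1e-12


def test_matches_skimage_on_unmasked_image(rng):
    """Independent cross-check: direction-summed symmetric GLCM equals
    scikit-image's graycomatrix summed over its four 2D angles."""
    from skimage.feature import graycomatrix

    img = rng.integers(0, 6, size=(12, 12)).astype(np.uint8)
    q = type("Q", (), {})()
    q.levels = (img + 1).astype(np.int32)[None]
    q.n_levels = 6
    ours = glcm_accumulate(q, 1, "2D-slice")
    sk = graycomatrix(
        img, distances=[1], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=6, symmetric=True, normed=False,
    )
    sk_sum = sk[:, :, 0, :].sum(axis=2).astype(float)
    sk_sum /= sk_sum.sum()
    assert np.abs(ours.P - sk_sum).max() < 1e-12


def test_glcm_features_degenerate_and_uniform():
    P = np.zeros((4, 4))
    P[0, 0] = 1.0
    f = glcm_features(CooccurrenceMatrix(P, 1, "3D", 8))
    assert f["energ"] == 1 and f["entro"] == 0 and f["contr"] == 0
    assert f["dissi"] == 0 and f["maxpr"] == 1 and f["homom"] == 1

    U = np.full((2, 2), 0.25)
    fu = glcm_features(CooccurrenceMatrix(U, 1, "3D", 8))
    assert fu["entro"] == pytest.approx(2.0)
    # contrast: (i-j)^2 averages to 0.5 over the uniform 2x2 matrix
    assert fu["contr"] == pytest.approx(0.5)
    assert set(fu) == set(GLCM_IDS) and len(GLCM_IDS) == 19


def test_glcm_features_brute_force_random(rng):
    for _ in range(5):
        A = rng.random((6, 6))
        P = A + A.T
        P /= P.sum()
        ours = glcm_features(CooccurrenceMatrix(P, 1, "3D", 100))
        oracle = brute_glcm_features(P)
        for k in GLCM_IDS:
            assert ours[k] == pytest.approx(oracle[k], abs=1e-10), k


def test_feature_ranges(rng):
    img = rng.integers(0, 200, size=(3, 10, 10))
    vol = as_volume(img)
    q = trim_and_quantize(vol, full_mask(vol), GLCMConfig())
    f = glcm_features(glcm_accumulate(q, 1, "3D"))
    for k in ("energ", "maxpr", "homom", "indnc", "idmnc"):
        assert 0 <= f[k] <= 1, k
    assert 0 <= f["entro"] <= 2 * np.log2(32)


def test_rotation_consistency_2d(rng):
    img = rng.integers(0, 50, size=(8, 8))
    q1 = quantized(img[None], np.ones((8, 8)), 8)
    q2 = quantized(np.rot90(img)[None].copy(), np.ones((8, 8)), 8)
    cm1 = glcm_accumulate(q1, 1, "2D-slice", slice_index=0)
    cm2 = glcm_accumulate(q2, 1, "2D-slice", slice_index=0)
    assert np.abs(cm1.P - cm2.P).max() < 1e-12


def test_symmetry_and_normalization_property(rng):
    for _ in range(10):
        shape = (int(rng.integers(2, 5)), int(rng.integers(4, 9)), int(rng.integers(4, 9)))
        levels = rng.integers(0, 9, size=shape).astype(np.int32)
        if not (levels > 0).any():
            continue
        q = type("Q", (), {})()
        q.levels = levels
        q.n_levels = 8
        for mode in ("2D-slice", "3D"):
            cm = glcm_accumulate(q, 1, mode)
            if cm.empty:
                continue
            assert np.abs(cm.P - cm.P.T).max() < 1e-12
            assert cm.P.sum() == pytest.approx(1.0, abs=1e-12)
            assert (cm.P >= 0).all()


def test_slice_averaging(rng):
    img = rng.integers(0, 30, size=(8, 8))
    same = np.stack([img, img])
    q = quantized(same, np.ones_like(same, bool), 8)
    per_case = glcm2d_case_features(q, 1, GLCMConfig(n_levels=8))
    single = glcm_features(glcm_accumulate(q, 1, "2D-slice", slice_index=0))
    for k in GLCM_IDS:
        assert per_case[k] == pytest.approx(single[k])

    other = rng.integers(0, 30, size=(8, 8))
    two = np.stack([img, other])
    q2 = quantized(two, np.ones_like(two, bool), 8)
    avg = glcm2d_case_features(q2, 1, GLCMConfig(n_levels=8))
    f1 = glcm_features(glcm_accumulate(q2, 1, "2D-slice", slice_index=0))
    f2 = glcm_features(glcm_accumulate(q2, 1, "2D-slice", slice_index=1))
    for k in GLCM_IDS:
        assert avg[k] == pytest.approx((f1[k] + f2[k]) / 2)


def test_extract_all_id_counts_and_constant_roi():
    ids = canonical_feature_ids()
    assert len(ids) == 108
    assert sum(i.startswith("FO:") for i in ids) == 13
    assert sum(i.startswith("GLCM:") for i in ids) == 95

    vol, tum, kid = generate_case(AcquisitionSpec(), seed=21)
    feats = extract_all(vol, tum)
    assert len(feats) == 13 + 2 * 95
    assert sum(k.startswith("GLCM2D:") for k in feats) == 95
    assert sum(k.startswith("GLCM3D:") for k in feats) == 95
    assert all(np.isfinite(v) for v in feats.values())

    cvol = as_volume(np.full((4, 10, 10), 60))
    cfeats = extract_all(cvol, full_mask(cvol), GLCMConfig(distances=(1,)))
    assert cfeats["FO:u"] == 1 and cfeats["FO:e"] == 0
    assert cfeats["GLCM2D:entro:d1"] == 0 and cfeats["GLCM3D:entro:d1"] == 0


def test_direction_weighting_modes(rng):
    """mean-of-features equals pair-count on a constant region (every
    direction sees the same degenerate matrix) and stays finite on texture."""
    img = np.full((1, 5, 5), 9)
    q = quantized(img, np.ones((5, 5)), 4)
    a = glcm2d_case_features(q, 1, GLCMConfig(n_levels=4, direction_weighting="pair-count"))
    b = glcm2d_case_features(q, 1, GLCMConfig(n_levels=4, direction_weighting="mean-of-features"))
    for k in GLCM_IDS:
        assert a[k] == pytest.approx(b[k])

    tex = rng.integers(0, 40, size=(2, 8, 8))
    qt = quantized(tex, np.ones_like(tex, bool), 8)
    fm = glcm2d_case_features(qt, 1, GLCMConfig(n_levels=8, direction_weighting="mean-of-features"))
    assert all(np.isfinite(v) for v in fm.values())
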