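"""Resampling kernels, the EME-IQ local-contrast score and interpolator ranking.

Heterogeneous in-plane voxel sizes force a resampling step before any
radiomic comparison across cases, and the interpolation kernel itself alters
the grey-level distribution.  Three kernels are compared — linear, Akima
cubic Hermite spline, and Lanczos windowed sinc (a = 3) — by resampling each
case to the cohort's smallest (upsampling) and largest (downsampling)
in-plane spacing and scoring the results with EME-IQ, a no-reference measure
of local contrast: the image is partitioned into blocks and the score is the
block-average of ``20*log10(Bmax/Bmin)``.  The kernel that wins the most
cases is used for all voxel-size perturbations downstream.

Grid convention: voxel centres at ``(i + 1/2) * spacing``; the output grid
spans the same physical extent with ``round(extent / dst_spacing)`` samples.
All kernels use edge replication at the borders, and grey levels are rounded
to the nearest integer when a volume leaves the resampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import Akima1DInterpolator

from .core import CTVolume, ROIMask

__all__ = [
    "METHODS",
    "ResamplingGrid",
    "resample_slice",
    "resample_volume",
    "resample_mask",
    "eme_iq",
    "eme_iq_case",
    "clamp_to_percentiles",
    "rank_interpolators",
]

#: tie-break priority for interpolator selection (first wins ties)
METHODS = ("lanczos", "akima", "linear")

_LANCZOS_A = 3


@dataclass
class ResamplingGrid:
    """The 3 x 5 voxel-size ladder for the voxel-size perturbation family.

    ``vs_s < vs_M < vs_l`` are the smallest, median and largest in-plane
    spacings of the cohort (mm); slice-spacing targets run from 1 mm up to
    the native 5 mm in 1 mm steps, giving 15 combinations.
    """

    vs_s: float = 0.541
    vs_M: float = 0.741
    vs_l: float = 0.957
    z_targets: tuple = (1.0, 2.0, 3.0, 4.0, 5.0)
    native_vz: float = 5.0

    def __post_init__(self) -> None:
        if not (self.vs_s < self.vs_M < self.vs_l):
            raise ValueError("require vs_s < vs_M < vs_l")
        zt = tuple(float(z) for z in self.z_targets)
        if any(b <= a for a, b in zip(zt, zt[1:])):
            raise ValueError("z_targets must be strictly increasing")
        if zt[-1] != self.native_vz:
            raise ValueError("largest z target must equal the native slice spacing")
        self.z_targets = zt

    @property
    def vs_targets(self) -> dict:
        return {"vss": self.vs_s, "vsM": self.vs_M, "vsl": self.vs_l}

    @property
    def combos(self) -> list:
        """All 15 (vs_name, vz) combinations."""
        return [(name, z) for name in ("vss", "vsM", "vsl") for z in self.z_targets]

    @classmethod
    def from_cohort(cls, cohort) -> "ResamplingGrid":
        """Grid anchored at the cohort's spacing extremes and median."""
        vss = [vol.vs for vol, _, _ in cohort.cases]
        vz = cohort.cases[0][0].vz
        return cls(
            vs_s=float(min(vss)), vs_M=cohort.median_vs, vs_l=float(max(vss)),
            z_targets=tuple(float(z) for z in range(1, int(round(vz)) + 1)),
            native_vz=vz,
        )


def _out_positions(n_src: int, src: float, dst: float) -> np.ndarray:
    """Continuous source-index coordinates of the output voxel centres."""
    extent = n_src * src
    m = max(int(round(extent / dst)), 1)
    centers = (np.arange(m) + 0.5) * dst
    return centers / src - 0.5


def _lanczos_kernel(t: np.ndarray) -> np.ndarray:
    out = np.sinc(t) * np.sinc(t / _LANCZOS_A)
    out[np.abs(t) >= _LANCZOS_A] = 0.0
    return out


def _weight_matrix(n_src: int, u: np.ndarray, method: str) -> np.ndarray:
    """Dense (m_out, n_src) resampling matrix for the data-independent kernels."""
    uc = np.clip(u, 0.0, n_src - 1.0)  # edge replication
    W = np.zeros((len(u), n_src))
    if method == "linear":
        lo = np.floor(uc).astype(int)
        lo = np.minimum(lo, n_src - 2) if n_src > 1 else lo
        frac = uc - lo
        W[np.arange(len(u)), lo] = 1.0 - frac
        if n_src > 1:
            W[np.arange(len(u)), lo + 1] += frac
    elif method == "lanczos":
        for i, x in enumerate(uc):
            j0 = int(np.floor(x)) - _LANCZOS_A + 1
            taps = np.arange(j0, j0 + 2 * _LANCZOS_A)
            w = _lanczos_kernel(x - taps)
            s = w.sum()
            if s != 0:
                w = w / s  # unit DC gain: constants are preserved exactly
            np.add.at(W[i], np.clip(taps, 0, n_src - 1), w)
    else:  # pragma: no cover
        raise ValueError(f"no weight matrix for method {method!r}")
    return W


def _resample_axis(
    arr: np.ndarray, axis: int, src: float, dst: float, method: str
) -> np.ndarray:
    """Resample one axis of an ND array from spacing `src` to `dst` (mm)."""
    if dst <= 0 or src <= 0:
        raise ValueError("spacings must be positive")
    if method not in METHODS:
        raise ValueError(f"unknown interpolation method {method!r}")
    n = arr.shape[axis]
    u = _out_positions(n, src, dst)
    if len(u) == n and np.allclose(u, np.arange(n)):
        return np.asarray(arr, dtype=float).copy()
    if method == "akima":
        uc = np.clip(u, 0.0, n - 1.0)
        interp = Akima1DInterpolator(np.arange(n), np.asarray(arr, dtype=float), axis=axis)
        return interp(uc)
    W = _weight_matrix(n, u, method)
    moved = np.moveaxis(np.asarray(arr, dtype=float), axis, 0)
    out = np.tensordot(W, moved, axes=(1, 0))
    return np.moveaxis(out, 0, axis)


def _resample_slice_float(
    sl: np.ndarray, src: float, dst: float, method: str
) -> np.ndarray:
    out = _resample_axis(sl, 0, src, dst, method)
    out = _resample_axis(out, 1, src, dst, method)
    return out


def resample_slice(sl: np.ndarray, src_spacing: float, dst_spacing: float, method: str) -> np.ndarray:
    """Resample a 2D HU slice to a new square spacing; grey levels rounded."""
    sl = np.asarray(sl)
    if sl.ndim != 2 or min(sl.shape) < 4:
        raise ValueError("slice must be 2D and at least 4x4")
    out = _resample_slice_float(sl, src_spacing, dst_spacing, method)
    return np.rint(out).astype(np.int32)


def resample_volume(vol: CTVolume, target: tuple[float, float], method: str) -> CTVolume:
    """Resample a volume to ``(vs, vz)``: slice-wise in-plane, then a 1D z pass.

    No z pass is applied when the target slice spacing equals the native one.
    Rounding to integer HU happens once, at the end.
    """
    vs_t, vz_t = float(target[0]), float(target[1])
    if vs_t <= 0 or vz_t <= 0:
        raise ValueError("target spacings must be positive")
    same_z = np.isclose(vz_t, vol.vz)
    if vol.voxels.shape[0] < 2 and not same_z:
        raise ValueError("cannot resample a single-slice volume along z")
    data = np.asarray(vol.voxels, dtype=float)
    if not np.isclose(vs_t, vol.vs):
        slices = [_resample_slice_float(data[i], vol.vs, vs_t, method) for i in range(data.shape[0])]
        data = np.stack(slices, axis=0)
    if not same_z:
        data = _resample_axis(data, 0, vol.vz, vz_t, method)
        vz_out = vz_t
    else:
        vz_out = vol.vz
    return CTVolume(np.rint(data).astype(np.int32), (vs_t, vs_t, vz_out), vol.case_id)


def resample_mask(mask: ROIMask, target: tuple[float, float]) -> ROIMask:
    """Nearest-neighbour resampling of a binary mask onto the target grid."""
    vs_t, vz_t = float(target[0]), float(target[1])
    data = mask.voxels.astype(np.uint8)

    def _nn(arr, axis, src, dst):
        n = arr.shape[axis]
        u = _out_positions(n, src, dst)
        idx = np.clip(np.rint(u).astype(int), 0, n - 1)
        return np.take(arr, idx, axis=axis)

    out = data
    if not np.isclose(vs_t, mask.spacing[0]):
        out = _nn(out, 1, mask.spacing[0], vs_t)
        out = _nn(out, 2, mask.spacing[0], vs_t)
    if not np.isclose(vz_t, mask.spacing[2]):
        out = _nn(out, 0, mask.spacing[2], vz_t)
    return ROIMask(out > 0, (vs_t, vs_t, vz_t), mask.label)


# --- EME-IQ ----------------------------------------------------------------

def eme_iq(sl: np.ndarray, block: tuple[int, int] = (8, 8)) -> float:
    """Block-based measure of local contrast of one slice.

    The slice is offset by ``1 - min`` so every value is >= 1 (HU are
    signed), partitioned into non-overlapping ``block``-sized blocks
    (trailing partial blocks dropped), and the score is the mean over blocks
    of ``20*log10(Bmax/Bmin)``.  A constant slice scores 0.
    """
    sl = np.asarray(sl, dtype=float)
    br, bc = block
    if br < 2 or bc < 2:
        raise ValueError("block dims must be >= 2")
    if sl.shape[0] < br or sl.shape[1] < bc:
        raise ValueError("block larger than slice")
    off = sl + (1.0 - sl.min())
    k1, k2 = sl.shape[0] // br, sl.shape[1] // bc
    blocks = off[: k1 * br, : k2 * bc].reshape(k1, br, k2, bc)
    bmax = blocks.max(axis=(1, 3))
    bmin = blocks.min(axis=(1, 3))
    return float(np.mean(20.0 * np.log10(bmax / bmin)))


def eme_iq_case(vol: CTVolume, block: tuple[int, int] = (8, 8)) -> float:
    """Mean EME-IQ over all slices of a volume."""
    return float(np.mean([eme_iq(vol.voxels[i], block) for i in range(vol.voxels.shape[0])]))


def clamp_to_percentiles(
    vol: CTVolume, body_mask: ROIMask | None = None, tail: float = 0.025
) -> CTVolume:
    """Clamp grey levels to the [tail, 1-tail] percentile band.

    Standard outlier handling before the interpolation comparison; clamping
    (rather than removal) keeps the voxel grid dense.  Percentiles are taken
    over the body region when a mask is given, else over the whole volume.
    """
    vals = vol.voxels[body_mask.voxels] if body_mask is not None else vol.voxels
    lo, hi = np.quantile(vals, [tail, 1.0 - tail])
    return CTVolume(np.clip(vol.voxels, lo, hi).astype(vol.voxels.dtype), vol.spacing, vol.case_id)


def rank_interpolators(
    cohort, grid: ResamplingGrid, block: tuple[int, int] = (8, 8),
    body_threshold: float = -200.0,
) -> dict:
    """Rank the three kernels by EME-IQ over a cohort.

    Each case is clamped to its body-region 2.5/97.5 percentiles, resampled
    in-plane to ``vs_s`` (upsample) and ``vs_l`` (downsample) with each
    kernel, and scored with the slice-averaged EME-IQ; the kernel with the
    highest score wins the case.  Returns per-direction win fractions, the
    overall winner (ties broken lanczos > akima > linear) and a tie flag.
    """
    from .core import body_mask_from_hu

    if len(cohort.cases) < 1:
        raise ValueError("cohort must contain at least one case")
    wins = {d: {m: 0 for m in METHODS} for d in ("upsample", "downsample")}
    reports = []  # per-case, per-method slice-averaged scores
    tie_seen = False
    for vol, _, _ in cohort.cases:
        clamped = clamp_to_percentiles(vol, body_mask_from_hu(vol, body_threshold))
        for direction, vs_t in (("upsample", grid.vs_s), ("downsample", grid.vs_l)):
            scores = {}
            for m in METHODS:
                res = resample_volume(clamped, (vs_t, clamped.vz), m)
                scores[m] = eme_iq_case(res, block)
                reports.append(
                    {"case_id": vol.case_id, "method": m,
                     "direction": direction, "score": scores[m]}
                )
            best = max(scores.values())
            winners = [m for m in METHODS if scores[m] == best]
            if len(winners) > 1:
                tie_seen = True
            wins[direction][winners[0]] += 1  # METHODS order is the tie rule
    n = len(cohort.cases)
    fractions = {d: {m: wins[d][m] / n for m in METHODS} for d in wins}
    totals = {m: wins["upsample"][m] + wins["downsample"][m] for m in METHODS}
    best_total = max(totals.values())
    selected = next(m for m in METHODS if totals[m] == best_total)
    if tie_seen:
        warnings.warn("EME-IQ ties encountered; broken by fixed kernel order", stacklevel=2)
    return {"fractions": fractions, "selected": selected, "tie": tie_seen,
            "reports": reports}
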