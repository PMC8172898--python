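"""Image and ROI perturbations: the N / V / R families and the 29 scenarios.

Three perturbation families probe feature reproducibility:

* **N** — additive white Gaussian noise at the case's own noise level,
  estimated slice-wise from homogeneous regions (mode of the local-SD
  histogram inside the body);
* **V** — voxel-size changes: the 15 combinations of three in-plane spacings
  (smallest, median, largest of the cohort) with slice spacings 1–5 mm;
* **R** — segmentation variability: slice-wise morphological dilation
  (+10 %) or erosion (−10 / −15 / −20 %) with a 3 x 3 square structuring
  element and random contourization of the final shell so the target volume
  change is met exactly.

The 29 scenarios combine these variants into the measurement sets entering
the intraclass-correlation analysis: 1 N, 15 single voxel-size scenarios,
1 global scenario over all 15, 3 fixed-in-plane scenarios across the z
ladder, 5 fixed-z scenarios across the three in-plane spacings, and 4 R
scenarios.  Every scenario includes the original image as one measurement,
so a scenario with ``v`` variants has ``k = 1 + v`` repeated measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, uniform_filter

from .core import CTVolume, ROIMask
from .resample import ResamplingGrid

__all__ = [
    "NoiseEstimate",
    "ROIPerturbationSpec",
    "PerturbationScenario",
    "estimate_noise_sigma",
    "add_awgn",
    "perturb_roi",
    "enumerate_scenarios",
    "ROI_TARGETS",
]

#: allowed segmentation volume-change targets (percent)
ROI_TARGETS = (10.0, -10.0, -15.0, -20.0)


@dataclass
class NoiseEstimate:
    """Per-case noise level: mean over slices of per-slice sigma (HU)."""

    sigma: float
    per_slice_sigma: list

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.per_slice_sigma):
            raise ValueError("per-slice sigmas must be >= 0")


@dataclass
class ROIPerturbationSpec:
    """One segmentation perturbation: target volume change (%) and seed."""

    target_volume_change: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not -100 < self.target_volume_change < 100:
            raise ValueError("|target| must be < 100%")


@dataclass
class PerturbationScenario:
    """One robustness scenario: family tag, variant keys, measurement count."""

    scenario_id: str
    family: str  # N / V / R
    variant_keys: list

    def __post_init__(self) -> None:
        if self.family not in ("N", "V", "R"):
            raise ValueError("family must be one of N, V, R")
        if len(self.variant_keys) < 1:
            raise ValueError("scenario needs at least one variant")

    @property
    def k(self) -> int:
        """Measurements per subject: original + variants."""
        return 1 + len(self.variant_keys)


def estimate_noise_sigma(
    vol: CTVolume, body_mask: ROIMask, window: int = 7, bin_width: float = 0.1
) -> NoiseEstimate:
    """Estimate scan noise as the mode of local standard deviations.

    Per slice, the SD of each ``window x window`` neighbourhood fully inside
    the body is computed; the histogram mode of those local SDs (bin width
    0.1 HU) estimates the slice noise, since homogeneous regions dominate the
    low-SD mode while edges and texture spread into the tail.  The case sigma
    is the mean over usable slices.
    """
    per_slice = []
    skipped = 0
    for iz in range(vol.voxels.shape[0]):
        sl = vol.voxels[iz].astype(float)
        m = body_mask.voxels[iz]
        # centres whose full window lies inside the body
        valid = binary_erosion(m, structure=np.ones((window, window), bool))
        if not valid.any():
            skipped += 1
            continue
        mean = uniform_filter(sl, size=window)
        mean_sq = uniform_filter(sl * sl, size=window)
        var = np.maximum(mean_sq - mean * mean, 0.0)
        local_sd = np.sqrt(var)[valid]
        hi = max(local_sd.max(), bin_width)
        edges = np.arange(0.0, hi + bin_width, bin_width)
        counts, _ = np.histogram(local_sd, bins=edges)
        mode_bin = int(np.argmax(counts))
        in_bin = (local_sd >= edges[mode_bin]) & (local_sd <= edges[mode_bin + 1])
        per_slice.append(float(local_sd[in_bin].mean()))
    if not per_slice:
        raise ValueError("no slice has a full estimation window inside the body mask")
    if skipped:
        warnings.warn(f"{skipped} slice(s) skipped in noise estimation", stacklevel=2)
    return NoiseEstimate(sigma=float(np.mean(per_slice)), per_slice_sigma=per_slice)


def add_awgn(vol: CTVolume, sigma: float, seed: int) -> CTVolume:
    """Additive white Gaussian noise, rounded back to integer HU."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return vol.copy()
    rng = np.random.default_rng(seed)
    noisy = vol.voxels + rng.normal(0.0, sigma, size=vol.voxels.shape)
    return CTVolume(np.rint(noisy).astype(np.int32), vol.spacing, vol.case_id)


def _slicewise(mask: np.ndarray, op) -> np.ndarray:
    se = np.ones((3, 3), dtype=bool)
    out = np.zeros_like(mask)
    for iz in range(mask.shape[0]):
        if mask[iz].any():
            out[iz] = op(mask[iz], structure=se)
    return out


def perturb_roi(mask: ROIMask, spec: ROIPerturbationSpec) -> ROIMask:
    """Grow or shrink a mask to an exact target volume change.

    Full slice-wise 3x3 dilation (positive target) or erosion (negative)
    passes are applied while they do not overshoot the target count
    ``round(N * (1 + t/100))``; the final pass's boundary shell is then
    randomly subsampled (seeded) so the output voxel count matches the target
    exactly.  Erosion that would empty a populated slice raises.
    """
    t = spec.target_volume_change
    if t == 0:
        return mask.copy()
    cur = mask.voxels.copy()
    n0 = int(cur.sum())
    if n0 == 0:
        raise ValueError("cannot perturb an empty mask")
    target = int(round(n0 * (1.0 + t / 100.0)))
    if target < 1:
        raise ValueError("target removes the whole ROI")
    rng = np.random.default_rng(spec.seed)
    grow = t > 0
    op = binary_dilation if grow else binary_erosion

    while True:
        n_cur = int(cur.sum())
        if n_cur == target:
            break
        nxt = _slicewise(cur, op)
        if not grow:
            for iz in range(cur.shape[0]):
                if cur[iz].any() and not nxt[iz].any() and int(nxt.sum()) > target:
                    raise ValueError(f"erosion empties slice {iz} before reaching the target")
        n_nxt = int(nxt.sum())
        done = (n_nxt >= target) if grow else (n_nxt <= target)
        if not done:
            cur = nxt
            if n_nxt == n_cur:  # morphology saturated without reaching target
                raise ValueError("target volume change unreachable by 3x3 morphology")
            continue
        # partial final pass: randomly subsample the shell
        shell = np.argwhere(nxt ^ cur)
        need = abs(target - n_cur)
        pick = rng.choice(len(shell), size=need, replace=False)
        chosen = shell[pick]
        cur = cur.copy()
        cur[tuple(chosen.T)] = grow
        break

    assert int(cur.sum()) == target
    return ROIMask(cur, mask.spacing, mask.label)


def variant_key_v(vs_name: str, vz: float) -> str:
    return f"V:{vs_name}-Z{int(round(vz))}"


def variant_key_r(target: float) -> str:
    return f"R:{'+' if target > 0 else '-'}{int(round(abs(target)))}"


def enumerate_scenarios(grid: ResamplingGrid) -> list:
    """The default 29-scenario design: 1 N, 24 V, 4 R."""
    scen = [PerturbationScenario("N", "N", ["noise"])]
    combo_keys = {(name, z): variant_key_v(name, z) for name, z in grid.combos}
    # 15 single voxel-size scenarios (k = 2)
    for (name, z), key in combo_keys.items():
        scen.append(PerturbationScenario(key, "V", [key]))
    # global assessment over all 15 (k = 16)
    scen.append(PerturbationScenario("V:global", "V", list(combo_keys.values())))
    # 3 fixed in-plane spacing scenarios across the z ladder (k = 6)
    for name in ("vss", "vsM", "vsl"):
        keys = [combo_keys[(name, z)] for z in grid.z_targets]
        scen.append(PerturbationScenario(f"V:{name}", "V", keys))
    # 5 fixed-z scenarios across the three in-plane spacings (k = 4)
    for z in grid.z_targets:
        keys = [combo_keys[(name, z)] for name in ("vss", "vsM", "vsl")]
        scen.append(PerturbationScenario(f"V:Z{int(round(z))}", "V", keys))
    # 4 segmentation scenarios (k = 2)
    for t in ROI_TARGETS:
        scen.append(PerturbationScenario(variant_key_r(t), "R", [variant_key_r(t)]))
    assert len(scen) == 29
    return scen
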