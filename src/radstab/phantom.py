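"""Synthetic CT phantom cohorts.

The real study images (contrast-enhanced renal CT with a tumour and the
contralateral kidney) are not deposited, so every downstream stage is driven
by a generator that emulates their acquisition statistics: square in-plane
voxel spacing drawn per case from 0.541–0.957 mm, 5 mm slice spacing, and
additive Gaussian scan noise with sigma in 2.9–5.9 HU.

Each case contains a soft-tissue body ellipsoid on an air background plus two
regions of interest with distinct texture phenotypes, modelled as stationary
correlated Gaussian random fields (white noise convolved with an isotropic
Gaussian kernel) added to a constant tissue mean:

* a *tumour-like* ROI — short correlation length, high amplitude
  (heterogeneous, like renal cell carcinoma on contrast-enhanced CT);
* a *kidney-like* ROI — longer correlation length, low amplitude (smooth
  parenchyma).

Between-case variability (tissue mean HU and texture amplitude jitter) is
included because intraclass correlation is meaningless without real
between-subject variance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, label as cc_label

from .core import CTVolume, ROIMask, write_mask, write_volume

__all__ = [
    "AcquisitionSpec",
    "SyntheticCohort",
    "generate_case",
    "generate_cohort",
    "toy_fixtures",
]

TUMOUR = "tumour-like"
KIDNEY = "kidney-like"


@dataclass
class AcquisitionSpec:
    """Acquisition statistics the generator reproduces.

    Defaults follow the study population: in-plane spacing uniform on
    [0.541, 0.957] mm, 5 mm slices, noise sigma uniform on [2.9, 5.9] HU.
    Tissue means are contrast-enhanced-like HU values; texture parameters
    give the tumour ROI visibly higher grey-level variance than the kidney
    ROI.
    """

    in_plane_spacing_range: tuple[float, float] = (0.541, 0.957)
    slice_spacing: float = 5.0
    noise_sigma_range: tuple[float, float] = (2.9, 5.9)
    hu_background: float = -1000.0
    hu_tissue_means: dict = field(
        default_factory=lambda: {"body": 20.0, TUMOUR: 60.0, KIDNEY: 35.0}
    )
    # correlation length (mm) and amplitude (HU, field SD) per phenotype
    texture_correlation_length: dict = field(
        default_factory=lambda: {TUMOUR: 1.5, KIDNEY: 3.5}
    )
    texture_amplitude: dict = field(default_factory=lambda: {TUMOUR: 30.0, KIDNEY: 8.0})
    # between-case variability: tissue mean HU, texture amplitude and
    # correlation length, ROI size all vary per case, as across patients
    hu_case_sd: float = 12.0
    amplitude_rel_jitter: float = 0.25
    corr_length_rel_jitter: float = 0.3
    # geometry (voxels / mm)
    shape: tuple[int, int, int] = (10, 88, 88)  # (z, y, x)
    roi_radius_range_mm: tuple[float, float] = (6.0, 9.0)
    roi_z_halfheight_range_mm: tuple[float, float] = (8.0, 13.0)
    lobe_amplitude: float = 0.10

    def __post_init__(self) -> None:
        lo, hi = self.in_plane_spacing_range
        if not (0 < lo <= hi):
            raise ValueError("in_plane_spacing_range must satisfy 0 < low <= high")
        slo, shi = self.noise_sigma_range
        if not (0 <= slo <= shi):
            raise ValueError("noise_sigma_range must satisfy 0 <= low <= high")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be positive")
        if any(a < 0 for a in self.texture_amplitude.values()):
            raise ValueError("texture_amplitude must be >= 0")


@dataclass
class SyntheticCohort:
    """A list of (volume, tumour mask, kidney mask) triples plus provenance."""

    cases: list
    seed: int
    spec: AcquisitionSpec

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def median_vs(self) -> float:
        """Empirical median in-plane spacing, used as the resampling target."""
        return float(np.median([vol.vs for vol, _, _ in self.cases]))


def _lobulated_roi(
    shape, vs: float, vz: float, centre, r_mm: float, rz_mm: float,
    lobe_amp: float, rng: np.random.Generator,
) -> np.ndarray:
    """Per-slice disc with a smooth axial radius profile and lobulated boundary.

    The axial profile is an ellipsoid cap floored at 55% of the maximal
    radius, so every slice keeps a cross-section thick enough to survive
    3x3 morphological erosion (polar one-pixel caps would not).
    """
    nz, ny, nx = shape
    cz, cy, cx = centre
    n_lobes = int(rng.integers(3, 6))
    phase = float(rng.uniform(0, 2 * np.pi))
    zz = (np.arange(nz) - cz) * vz
    yy = (np.arange(ny) - cy) * vs
    xx = (np.arange(nx) - cx) * vs
    mask = np.zeros(shape, dtype=bool)
    for iz in range(nz):
        if abs(zz[iz]) >= rz_mm:
            continue
        frac = np.sqrt(max(1.0 - (zz[iz] / rz_mm) ** 2, 0.55**2))
        r = r_mm * frac
        Y, X = np.meshgrid(yy, xx, indexing="ij")
        theta = np.arctan2(Y, X)
        r_theta = r * (1.0 + lobe_amp * np.cos(n_lobes * theta + phase))
        mask[iz] = np.hypot(Y, X) <= r_theta
    return mask


def _grf(shape, spacing, corr_length_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary Gaussian random field with isotropic physical
    correlation length (mm)."""
    white = rng.standard_normal(shape)
    sigmas = [corr_length_mm / s for s in (spacing[2], spacing[1], spacing[0])]
    f = gaussian_filter(white, sigma=sigmas, mode="wrap")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return f / sd


def generate_case(
    spec: AcquisitionSpec, seed: int, include_noise: bool = True
) -> tuple[CTVolume, ROIMask, ROIMask]:
    """Generate one synthetic case: volume plus tumour-like and kidney-like ROIs.

    Deterministic: identical ``(spec, seed)`` give bit-identical output.
    ``include_noise=False`` reproduces the same case without the final scan
    noise (the "noiseless twin"), which tests use to measure injected sigma.
    """
    # independent child streams so the noiseless twin shares geometry/texture
    rng_geom = np.random.default_rng([seed, 0])
    rng_tex_t = np.random.default_rng([seed, 1])
    rng_tex_k = np.random.default_rng([seed, 2])
    rng_noise = np.random.default_rng([seed, 3])

    nz, ny, nx = spec.shape
    vs = float(rng_geom.uniform(*spec.in_plane_spacing_range))
    vz = spec.slice_spacing
    sigma = float(rng_geom.uniform(*spec.noise_sigma_range))

    # body ellipsoid filling most of the FOV
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    zz = (np.arange(nz) - cz) / (nz / 2)
    yy = (np.arange(ny) - cy) / (ny * 0.48)
    xx = (np.arange(nx) - cx) / (nx * 0.48)
    body = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    ) <= 1.0

    vol = np.full((nz, ny, nx), spec.hu_background, dtype=float)
    vol[body] = spec.hu_tissue_means["body"] + spec.hu_case_sd * rng_geom.standard_normal()

    masks = {}
    textures = {TUMOUR: rng_tex_t, KIDNEY: rng_tex_k}
    for label, side in ((TUMOUR, -1), (KIDNEY, +1)):
        # per-case ROI size, like tumour volumes across patients
        r_mm = float(rng_geom.uniform(*spec.roi_radius_range_mm))
        rz_mm = float(rng_geom.uniform(*spec.roi_z_halfheight_range_mm))
        r_vox = r_mm / vs
        jy = rng_geom.uniform(-2, 2)
        jx = rng_geom.uniform(-1.5, 1.5)
        centre = (cz, cy + jy, cx + side * (1.15 * r_vox + 3 + jx))
        m = _lobulated_roi(
            (nz, ny, nx), vs, vz, centre, r_mm,
            rz_mm, spec.lobe_amplitude, rng_geom,
        )
        if not m.any():
            raise ValueError(f"{label} ROI is empty: volume too small for ROI size")
        zs, ys, xs = np.nonzero(m)
        if (
            ys.min() == 0 or xs.min() == 0
            or ys.max() == ny - 1 or xs.max() == nx - 1
        ):
            raise ValueError(f"{label} ROI does not fit inside the volume")
        mean = spec.hu_tissue_means[label] + spec.hu_case_sd * rng_geom.standard_normal()
        amp = spec.texture_amplitude[label] * (
            1.0 + spec.amplitude_rel_jitter * rng_geom.uniform(-1, 1)
        )
        corr_len = spec.texture_correlation_length[label] * (
            1.0 + spec.corr_length_rel_jitter * rng_geom.uniform(-1, 1)
        )
        if amp > 0:
            field3d = _grf((nz, ny, nx), (vs, vs, vz), corr_len, textures[label])
            vol[m] = mean + amp * field3d[m]
        else:
            textures[label].standard_normal((nz, ny, nx))  # keep stream aligned
            vol[m] = mean
        masks[label] = m

    if (masks[TUMOUR] & masks[KIDNEY]).any():
        raise ValueError("tumour-like and kidney-like ROIs overlap; widen the volume")

    if include_noise and sigma > 0:
        vol = vol + sigma * rng_noise.standard_normal(vol.shape)

    voxels = np.rint(vol).astype(np.int32)
    spacing = (vs, vs, vz)
    ct = CTVolume(voxels, spacing, case_id=f"case{seed:04d}")
    return (
        ct,
        ROIMask(masks[TUMOUR], spacing, TUMOUR),
        ROIMask(masks[KIDNEY], spacing, KIDNEY),
    )


def generate_cohort(spec: AcquisitionSpec, n_cases: int, seed: int) -> SyntheticCohort:
    """Generate ``n_cases`` independent cases; per-case seed = master + index."""
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2 (ICC needs at least 2 subjects)")
    cases = [generate_case(spec, seed + i) for i in range(n_cases)]
    return SyntheticCohort(cases=cases, seed=seed, spec=spec)


def is_single_component(mask: np.ndarray) -> bool:
    """True when the mask is one 6-connected 3D component."""
    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1, 1, :] = structure[1, :, 1] = structure[:, 1, 1] = True
    _, n = cc_label(mask, structure=structure)
    return n == 1


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Serialize a cohort: NIfTI volumes/masks plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "vs", "vz", "seed"])
        for i, (vol, tum, kid) in enumerate(cohort.cases):
            write_volume(vol, outdir / f"{vol.case_id}_ct.nii.gz")
            write_mask(tum, outdir / f"{vol.case_id}_tumour.nii.gz")
            write_mask(kid, outdir / f"{vol.case_id}_kidney.nii.gz")
            w.writerow([vol.case_id, f"{vol.vs:.6f}", f"{vol.vz:.6f}", cohort.seed + i])
    return manifest


# --- tiny hand-checkable fixtures -----------------------------------------

_TOY_4X4 = np.array(
    [
        [1, 2, 3, 4],
        [2, 2, 3, 3],
        [3, 3, 2, 1],
        [4, 3, 2, 1],
    ],
    dtype=np.int32,
)


def toy_fixtures() -> dict:
    """Hard-coded oracle inputs for the texture-matrix tests.

    Returns a mapping of name -> (image, mask):

    * ``"four_level"`` — 4x4 single-slice image with grey levels 1..4, for
      hand-countable co-occurrence pairs;
    * ``"constant"`` — constant 8x8x3 region;
    * ``"checkerboard"`` — 8x8 two-level checkerboard slice.

    All masks are all-true.
    """
    four = _TOY_4X4[None, :, :].copy()
    const = np.full((3, 8, 8), 100, dtype=np.int32)
    yy, xx = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
    checker = np.where((yy + xx) % 2 == 0, 0, 100).astype(np.int32)[None, :, :]
    return {
        "four_level": (four, np.ones_like(four, dtype=bool)),
        "constant": (const, np.ones_like(const, dtype=bool)),
        "checkerboard": (checker, np.ones_like(checker, dtype=bool)),
    }
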