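#!/usr/bin/env python
"""Generate the synthetic CT cohort that drives the whole analysis.

Twenty cases are drawn with the study's acquisition statistics (in-plane
spacing 0.541–0.957 mm, 5 mm slices, noise sigma 2.9–5.9 HU), each with a
heterogeneous tumour-like ROI and a smoother kidney-like ROI.  Volumes and
masks go to scratch/cohort (NIfTI); the manifest and per-case summary go to
results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from radstab.phantom import AcquisitionSpec, generate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-cases", type=int, default=20)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    cohort = generate_cohort(AcquisitionSpec(), args.n_cases, args.seed)
    outdir = ROOT / "scratch" / "cohort"
    write_cohort(cohort, outdir)

    rows = []
    for vol, tum, kid in cohort.cases:
        rows.append(
            dict(case_id=vol.case_id, vs_mm=vol.vs, vz_mm=vol.vz,
                 tumour_voxels=tum.n_voxels, kidney_voxels=kid.n_voxels,
                 tumour_var=float(vol.voxels[tum.voxels].var()),
                 kidney_var=float(vol.voxels[kid.voxels].var()))
        )
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "cohort_summary.csv", index=False)

    print(f"generated {len(cohort)} cases -> {outdir}")
    print(f"in-plane spacing: median {cohort.median_vs:.3f} mm, "
          f"range [{df.vs_mm.min():.3f}, {df.vs_mm.max():.3f}] mm")
    print(f"tumour ROI grey-level variance exceeds kidney in "
          f"{(df.tumour_var > df.kidney_var).mean():.0%} of cases")


if __name__ == "__main__":
    main()
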