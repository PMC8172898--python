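#!/usr/bin/env python
"""Classify every (feature, scenario) pair as robust / non-robust /
indeterminate from its ICC(1,1) 95% CI, and summarize by scenario, family
and feature class for each tissue.
"""

from pathlib import Path

import pandas as pd

from radstab.perturb import enumerate_scenarios
from radstab.phantom import KIDNEY, TUMOUR
from radstab.pipeline import load_cohort
from radstab.resample import ResamplingGrid
from radstab.robustness import classify_all, summarize

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    table = pd.read_csv(ROOT / "results" / "features.csv")
    cohort = load_cohort(ROOT / "scratch" / "cohort")
    scenarios = enumerate_scenarios(ResamplingGrid.from_cohort(cohort))

    for tissue, short in ((TUMOUR, "tumour"), (KIDNEY, "kidney")):
        sub = table[table["tissue"] == tissue]
        icc = classify_all(sub, scenarios)
        icc.to_csv(ROOT / "results" / f"icc_{short}.csv", index=False)
        ok = icc[icc["label"] != "failed"]
        print(f"\n{tissue}: {len(ok)} (feature, scenario) cells; "
              f"overall {100 * (ok.label == 'r').mean():.1f}% robust")
        for g in ("family", "feature_class"):
            summ = summarize(icc, group_by=g)
            summ.to_csv(ROOT / "results" / f"summary_{short}_{g}.csv", index=False)
            print(summ.round(1).to_string(index=False))


if __name__ == "__main__":
    main()
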