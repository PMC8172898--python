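"""Robustness classification: ICC(1,1), the r/nr/i trichotomy, summaries and
cross-distance redundancy.

Reproducibility of a feature under a perturbation scenario is quantified by
the one-way random-effects intraclass correlation for single measurements,
ICC(1,1): subjects (cases) are rows, the original plus perturbed measurements
are columns, and

    ICC = (MSB - MSW) / (MSB + (k - 1) * MSW)

with MSB/MSW the between/within-subject mean squares.  The 95% confidence
interval comes from the F pivot: with ``F = MSB/MSW``,

    lower = (F/Fu - 1) / (F/Fu + k - 1),   upper = (F*Fl - 1) / (F*Fl + k - 1)

where ``Fu``/``Fl`` are the upper 1-α/2 quantiles of F(n-1, n(k-1)) and
F(n(k-1), n-1).  A feature is *robust* (r) when the CI lower bound is
>= 0.90, *non-robust* (nr) when the CI upper bound is < 0.90, and
*indeterminate* (i) when 0.90 lies strictly inside the CI.

Redundancy of GLCM features across displacement distances is assessed with
pairwise Pearson correlation across cases and a one-way fixed-effects ANOVA
over the distance groups (significance at p <= 0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .perturb import PerturbationScenario
from .radiomics import feature_class

__all__ = [
    "MeasurementMatrix",
    "ICCResult",
    "DistanceCorrelationResult",
    "icc_1_1",
    "build_measurement_matrix",
    "classify_all",
    "summarize",
    "distance_redundancy",
    "ROBUST_THRESHOLD",
]

ROBUST_THRESHOLD = 0.90


@dataclass
class MeasurementMatrix:
    """n_subjects x k matrix: column 0 = original, then scenario variants."""

    values: np.ndarray
    feature_id: str = ""
    scenario_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (subjects x measurements)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need n >= 2 subjects and k >= 2 measurements")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("measurement matrix contains non-finite entries")


@dataclass
class ICCResult:
    """ICC(1,1) point estimate, 95% CI and robustness label for one cell."""

    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    label: str  # r / nr / i
    degenerate: bool = False
    feature_id: str = ""
    scenario_id: str = ""


@dataclass
class DistanceCorrelationResult:
    feature_id: str
    delta_pair: tuple | None
    pearson_rho: float | None
    anova_p: float | None


def _label(ci_low: float, ci_high: float) -> str:
    if ci_low >= ROBUST_THRESHOLD:
        return "r"
    if ci_high < ROBUST_THRESHOLD:
        return "nr"
    return "i"


def icc_1_1(m: MeasurementMatrix, alpha: float = 0.05) -> ICCResult:
    """One-way random-effects ICC for single measurements, with F-pivot CI.

    Degenerate inputs: an all-identical matrix has no defined ICC and is
    labelled ``i`` with the degeneracy flag; perfect within-subject agreement
    with between-subject variance gives ICC = 1 with CI [1, 1].
    """
    X = m.values
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    ssb = k * np.sum((row_means - grand) ** 2)
    ssw = np.sum((X - row_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msw == 0 and msb == 0:
        return ICCResult(np.nan, np.nan, np.nan, n, k, "i", degenerate=True,
                         feature_id=m.feature_id, scenario_id=m.scenario_id)
    if msw == 0:
        return ICCResult(1.0, 1.0, 1.0, n, k, "r",
                         feature_id=m.feature_id, scenario_id=m.scenario_id)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    F = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    fu = stats.f.ppf(1 - alpha / 2, df1, df2)
    fl = stats.f.ppf(1 - alpha / 2, df2, df1)
    low = (F / fu - 1) / (F / fu + k - 1)
    high = (F * fl - 1) / (F * fl + k - 1)
    return ICCResult(float(icc), float(low), float(high), n, k, _label(low, high),
                     feature_id=m.feature_id, scenario_id=m.scenario_id)


def build_measurement_matrix(
    table: pd.DataFrame, scenario: PerturbationScenario, feature_id: str,
    original_key: str = "orig",
) -> MeasurementMatrix:
    """Pivot a tidy feature table into a subjects x measurements matrix.

    ``table`` columns: case_id, variant_key, feature_id, value.  Column 0 of
    the result is the original variant; the remaining columns follow the
    scenario's variant-key order.  Cases missing any required variant are
    dropped whole-row (logged as a warning).
    """
    keys = [original_key] + list(scenario.variant_keys)
    sub = table[(table["feature_id"] == feature_id) & table["variant_key"].isin(keys)]
    wide = sub.pivot_table(index="case_id", columns="variant_key", values="value")
    missing_cols = [c for c in keys if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks variants {missing_cols}")
    wide = wide[keys].sort_index()
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        warnings.warn(
            f"{dropped} case(s) dropped for {feature_id}/{scenario.scenario_id}",
            stacklevel=2,
        )
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete cases")
    return MeasurementMatrix(
        complete.to_numpy(), feature_id=feature_id, scenario_id=scenario.scenario_id
    )


def classify_all(
    table: pd.DataFrame, scenarios: list, feature_ids: list | None = None,
    original_key: str = "orig",
) -> pd.DataFrame:
    """ICC classification over the full feature x scenario grid.

    Returns a tidy frame (feature_id, scenario_id, family, icc, ci_low,
    ci_high, n, k, label).  Cells that cannot be computed are reported with
    label ``failed`` rather than aborting the grid.
    """
    if feature_ids is None:
        feature_ids = sorted(table["feature_id"].unique())
    rows = []
    # one pivot per feature, then column slices per scenario
    wide_by_feature = {
        fid: sub.pivot_table(index="case_id", columns="variant_key", values="value")
        for fid, sub in table.groupby("feature_id")
        if fid in set(feature_ids)
    }
    for fid in feature_ids:
        wide = wide_by_feature.get(fid)
        for scen in scenarios:
            keys = [original_key] + list(scen.variant_keys)
            try:
                if wide is None or any(c not in wide.columns for c in keys):
                    raise ValueError("missing variants")
                complete = wide[keys].dropna()
                if len(complete) < 2:
                    raise ValueError("fewer than 2 complete cases")
                mm = MeasurementMatrix(
                    complete.to_numpy(), feature_id=fid, scenario_id=scen.scenario_id
                )
                res = icc_1_1(mm)
                rows.append(
                    dict(feature_id=fid, scenario_id=scen.scenario_id,
                         family=scen.family, icc=res.icc, ci_low=res.ci_low,
                         ci_high=res.ci_high, n=res.n, k=res.k, label=res.label)
                )
            except ValueError as err:
                rows.append(
                    dict(feature_id=fid, scenario_id=scen.scenario_id,
                         family=scen.family, icc=np.nan, ci_low=np.nan,
                         ci_high=np.nan, n=0, k=scen.k, label="failed")
                )
                warnings.warn(f"{fid}/{scen.scenario_id}: {err}", stacklevel=2)
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame, group_by: str = "scenario") -> pd.DataFrame:
    """Percentage of r / nr / i labels per group.

    ``group_by`` is one of ``scenario``, ``feature_class`` or ``family``.
    Percentages within a group sum to 100.
    """
    if results.empty:
        raise ValueError("no results to summarize")
    res = results[results["label"] != "failed"].copy()
    if group_by == "scenario":
        key = res["scenario_id"]
    elif group_by == "family":
        key = res["family"]
    elif group_by == "feature_class":
        key = res["feature_id"].map(feature_class)
    else:
        raise ValueError(f"unknown grouping {group_by!r}")
    res["group"] = key
    out = []
    for g, sub in res.groupby("group"):
        total = len(sub)
        if total == 0:
            warnings.warn(f"empty group {g!r} omitted", stacklevel=2)
            continue
        counts = sub["label"].value_counts()
        out.append(
            dict(
                group=g,
                n=total,
                r_pct=100.0 * counts.get("r", 0) / total,
                nr_pct=100.0 * counts.get("nr", 0) / total,
                i_pct=100.0 * counts.get("i", 0) / total,
            )
        )
    return pd.DataFrame(out)


def distance_redundancy(
    table: pd.DataFrame, feature_family: str, variant_key: str = "orig",
    distances: tuple = (1, 3, 5, 7, 9),
) -> tuple[list, float]:
    """Cross-distance redundancy of one GLCM feature family.

    ``feature_family`` is e.g. ``"GLCM2D:sosvh"``; per-case values at each
    distance are correlated pairwise (Pearson) and compared with a one-way
    fixed-effects ANOVA across the distance groups.  Returns the pairwise
    results and the ANOVA p-value.
    """
    groups = {}
    for d in distances:
        fid = f"{feature_family}:d{d}"
        sub = table[(table["feature_id"] == fid) & (table["variant_key"] == variant_key)]
        groups[d] = sub.sort_values("case_id")["value"].to_numpy()
    lengths = {len(v) for v in groups.values()}
    if lengths == {0} or min(lengths) < 3:
        raise ValueError("need at least 3 cases with all distances present")
    pair_results = []
    for d1, d2 in combinations(distances, 2):
        a, b = groups[d1], groups[d2]
        if np.std(a) == 0 or np.std(b) == 0:
            pair_results.append(
                DistanceCorrelationResult(feature_family, (d1, d2), None, None)
            )
            continue
        rho, _ = stats.pearsonr(a, b)
        pair_results.append(
            DistanceCorrelationResult(feature_family, (d1, d2), float(rho), None)
        )
    arrays = [groups[d] for d in distances]
    if all(np.allclose(a, arrays[0]) for a in arrays[1:]):
        p = 1.0  # identical groups: F = 0
    else:
        _, p = stats.f_oneway(*arrays)
    return pair_results, float(p)
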