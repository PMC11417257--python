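"""Group statistics and the dose-response report.

All group values are expressed as mean +/- standard error of the mean (SEM,
sd/sqrt(n) with the n-1 denominator), with the *fiber* as the experimental
unit: per-fiber values are averaged before any group statistic.  Comparisons
against the undyed control use the classic pooled-variance two-tailed
Student's t-test (df = nA + nB - 2); Welch's correction is available behind a
flag.  Significance stars use the inclusive thresholds *p<=0.05, **p<=0.01,
***p<=0.001, ****p<=0.0001.  No multiple-testing correction is applied by
default; a Bonferroni option exists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ComparisonResult, GroupSummary
from .errors import AnalysisError, InvalidParameterError

__all__ = [
    "summarize",
    "t_test",
    "stars_for_p",
    "percent_change",
    "dose_response_report",
]

_STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    """Significance stars with inclusive thresholds (p = 0.05 earns '*')."""
    for threshold, stars in _STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


def summarize(values: np.ndarray, group: int) -> GroupSummary:
    """Mean +/- SEM of per-fiber values; requires n >= 2."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise AnalysisError("SEM undefined for fewer than 2 fibers")
    return GroupSummary(
        group=group,
        n=n,
        mean=float(values.mean()),
        sem=float(values.std(ddof=1) / np.sqrt(n)),
    )


def t_test(a: np.ndarray, b: np.ndarray, welch: bool = False) -> ComparisonResult:
    """Two-sample two-tailed Student's t-test (pooled variance by default).

    Degenerate inputs: zero pooled variance with equal means gives t = 0,
    p = 1; zero variance with unequal means gives p = 0 flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("t-test requires n >= 2 per group")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        if a.mean() == b.mean():
            return ComparisonResult(t=0.0, p=1.0, stars="ns")
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return ComparisonResult(t=sign * np.inf, p=0.0, stars="****", degenerate=True)
    import warnings

    with warnings.catch_warnings():
        # nearly-identical groups trigger a harmless precision warning in the
        # moment computation; the degenerate exact-tie cases are handled above
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = sps.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    return ComparisonResult(t=float(res.statistic), p=p, stars=stars_for_p(p))


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Signed percent change 100*(treated - control)/control.

    Reports of a 'reduction' quote the magnitude of a negative change.
    """
    if control_mean == 0:
        raise InvalidParameterError("percent change undefined for zero control mean")
    return 100.0 * (treated_mean - control_mean) / control_mean


def dose_response_report(
    features: pd.DataFrame,
    metrics: list[str] | None = None,
    manifest: pd.DataFrame | None = None,
    recovery_map: dict[str, str] | None = None,
    control_group: int = 0,
    welch: bool = False,
    bonferroni: bool = False,
) -> dict[str, object]:
    """Per-metric dose-response tables and an optional truth-recovery table.

    ``features`` has one row per fiber with ``dye_count`` plus metric columns.
    Each metric table lists group, n, mean +/- SEM, percent change vs control,
    p and stars.  When a generator ``manifest`` and a ``recovery_map``
    (metric column -> manifest truth column) are supplied, a recovery table of
    per-group truth vs estimate with relative errors is added.
    """
    if "dye_count" not in features.columns:
        raise InvalidParameterError("features must carry a 'dye_count' column")
    groups = sorted(features["dye_count"].unique())
    if control_group not in groups:
        raise AnalysisError(f"control group (dye count {control_group}) missing")
    if metrics is None:
        metrics = [
            c
            for c in features.columns
            if c not in ("dye_count", "fiber_id") and pd.api.types.is_numeric_dtype(features[c])
        ]

    n_tests = max(1, len(metrics) * (len(groups) - 1))
    tables: dict[str, pd.DataFrame] = {}
    for metric in metrics:
        control_vals = features.loc[
            features["dye_count"] == control_group, metric
        ].dropna().to_numpy()
        rows = []
        for g in groups:
            vals = features.loc[features["dye_count"] == g, metric].dropna().to_numpy()
            if len(vals) < 2:
                continue
            summary = summarize(vals, group=g)
            if g == control_group:
                pct, p, stars = 0.0, np.nan, ""
            else:
                control_mean = float(control_vals.mean())
                # e.g. a band absent in the control: no percent change defined
                pct = (
                    percent_change(control_mean, summary.mean)
                    if control_mean != 0
                    else np.nan
                )
                comp = t_test(control_vals, vals, welch=welch)
                p = min(1.0, comp.p * n_tests) if bonferroni else comp.p
                stars = stars_for_p(p)
            rows.append(
                {
                    "dye_count": g,
                    "n": summary.n,
                    "mean": summary.mean,
                    "sem": summary.sem,
                    "pct_change_vs_control": pct,
                    "p": p,
                    "stars": stars,
                }
            )
        tables[metric] = pd.DataFrame(rows)

    recovery = None
    if manifest is not None and recovery_map:
        rec_rows = []
        truth_by_group = manifest.groupby("dye_count").first()
        for metric, truth_col in recovery_map.items():
            if metric not in features.columns or truth_col not in manifest.columns:
                continue
            for g in groups:
                vals = features.loc[features["dye_count"] == g, metric].dropna()
                if vals.empty or g not in truth_by_group.index:
                    continue
                truth = float(truth_by_group.loc[g, truth_col])
                if truth == 0:
                    continue
                estimate = float(vals.mean())
                rec_rows.append(
                    {
                        "metric": metric,
                        "dye_count": g,
                        "truth": truth,
                        "estimate": estimate,
                        "rel_error": (estimate - truth) / truth,
                    }
                )
        recovery = pd.DataFrame(rec_rows)

    return {"tables": tables, "recovery": recovery}
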