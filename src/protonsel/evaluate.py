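"""Diagnostic evaluation of the tool against actual plan-comparison outcomes.

The positive class is "qualifies for proton therapy".  Sensitivity,
specificity, PPV, NPV and accuracy are computed from the confusion matrix
with 95% confidence intervals (Wilson score by default, Clopper–Pearson
by flag).  Subgroup robustness is assessed by splitting the cohort in
treatment order (learning-curve check) or by tumor location, flagging
subgroup values that fall outside the whole-cohort 95% CI.  Calibration
of continuous predictions (per-OAR D_mean, per-endpoint NTCP) is
summarised as the squared Pearson correlation between predicted and
actual plus residual (predicted − actual) mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .exceptions import ValidationError

CI_METHODS = {"wilson": "wilson", "clopper_pearson": "beta"}

MEASURES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


def confusion(
    predicted: Sequence[bool], actual: Sequence[bool]
) -> tuple[int, int, int, int]:
    """Confusion counts ``(tp, fp, fn, tn)``; positive = qualifies."""
    pred = np.asarray(predicted, dtype=bool)
    act = np.asarray(actual, dtype=bool)
    if pred.shape != act.shape or pred.ndim != 1:
        raise ValidationError("predicted and actual must be equal-length 1-D")
    if pred.size == 0:
        raise ValidationError("empty decision vectors")
    tp = int(np.sum(pred & act))
    fp = int(np.sum(pred & ~act))
    fn = int(np.sum(~pred & act))
    tn = int(np.sum(~pred & ~act))
    return tp, fp, fn, tn


@dataclass(frozen=True)
class Measure:
    """A proportion with its 95% CI; ``value`` None when undefined
    (zero denominator)."""

    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def contains(self, other: float) -> bool:
        if not self.defined:
            return True
        return self.ci_low <= other <= self.ci_high


@dataclass
class DiagnosticReport:
    tp: int
    fp: int
    fn: int
    tn: int
    n: int
    sensitivity: Measure
    specificity: Measure
    ppv: Measure
    npv: Measure
    accuracy: Measure
    subgroup_label: str | None = None
    outside_reference: tuple[str, ...] = ()

    def measure(self, name: str) -> Measure:
        if name not in MEASURES:
            raise ValidationError(f"unknown measure {name!r}")
        return getattr(self, name)

    def to_dict(self) -> dict:
        out: dict = {
            "subgroup": self.subgroup_label,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "n": self.n,
        }
        for name in MEASURES:
            m = self.measure(name)
            out[name] = (
                None
                if not m.defined
                else {"value": m.value, "ci_low": m.ci_low, "ci_high": m.ci_high}
            )
        if self.outside_reference:
            out["outside_reference"] = list(self.outside_reference)
        return out


def _proportion(count: int, denom: int, ci_method: str) -> Measure:
    if denom == 0:
        return Measure(None)
    lo, hi = proportion_confint(count, denom, alpha=0.05, method=CI_METHODS[ci_method])
    return Measure(count / denom, float(lo), float(hi))


def diagnostics_with_ci(
    counts: tuple[int, int, int, int],
    ci_method: str = "wilson",
    subgroup_label: str | None = None,
) -> DiagnosticReport:
    """Diagnostic measures with 95% CIs from confusion counts."""
    if ci_method not in CI_METHODS:
        raise ValidationError(
            f"unknown ci_method {ci_method!r}; expected one of {sorted(CI_METHODS)}"
        )
    tp, fp, fn, tn = (int(c) for c in counts)
    if min(tp, fp, fn, tn) < 0:
        raise ValidationError("confusion counts must be non-negative")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValidationError("empty confusion matrix")
    return DiagnosticReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        n=n,
        sensitivity=_proportion(tp, tp + fn, ci_method),
        specificity=_proportion(tn, tn + fp, ci_method),
        ppv=_proportion(tp, tp + fp, ci_method),
        npv=_proportion(tn, tn + fn, ci_method),
        accuracy=_proportion(tp + tn, n, ci_method),
        subgroup_label=subgroup_label,
    )


def _flag_outside(report: DiagnosticReport, reference: DiagnosticReport) -> DiagnosticReport:
    outside = tuple(
        name
        for name in MEASURES
        if report.measure(name).defined
        and reference.measure(name).defined
        and not reference.measure(name).contains(report.measure(name).value)
    )
    report.outside_reference = outside
    return report


def subgroup_evaluation(
    cohort: pd.DataFrame,
    grouping: str,
    ci_method: str = "wilson",
) -> list[DiagnosticReport]:
    """Whole-cohort report plus one per subgroup.

    ``grouping`` is ``"split"`` (first vs. second half in treatment
    order, sizes n//2 and n − n//2) or ``"tumor_location"``.  Subgroup
    measures outside the whole-cohort 95% CI are flagged in
    ``outside_reference``.  Requires columns ``predicted_qualifies``,
    ``actual_qualifies`` and the grouping variable.
    """
    for col in ("predicted_qualifies", "actual_qualifies"):
        if col not in cohort.columns:
            raise ValidationError(f"cohort table missing column {col!r}")
    whole = diagnostics_with_ci(
        confusion(cohort["predicted_qualifies"], cohort["actual_qualifies"]),
        ci_method,
        subgroup_label="all",
    )
    reports = [whole]
    if grouping == "split":
        if "treatment_order" not in cohort.columns:
            raise ValidationError("split grouping needs a treatment_order column")
        ordered = cohort.sort_values("treatment_order", kind="stable")
        half = len(ordered) // 2
        groups = [("first_half", ordered.iloc[:half]), ("second_half", ordered.iloc[half:])]
    elif grouping == "tumor_location":
        if "tumor_location" not in cohort.columns:
            raise ValidationError("tumor_location grouping needs a tumor_location column")
        groups = [
            (str(loc), sub) for loc, sub in cohort.groupby("tumor_location", sort=True)
        ]
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    for label, sub in groups:
        if sub.empty:
            reports.append(
                DiagnosticReport(
                    0, 0, 0, 0, 0,
                    Measure(None), Measure(None), Measure(None), Measure(None),
                    Measure(None), subgroup_label=label,
                )
            )
            continue
        rep = diagnostics_with_ci(
            confusion(sub["predicted_qualifies"], sub["actual_qualifies"]),
            ci_method,
            subgroup_label=label,
        )
        reports.append(_flag_outside(rep, whole))
    return reports


def calibration_summary(
    values: pd.DataFrame,
    group_cols: Sequence[str] = ("quantity", "modality"),
    method: str = "pearson",
) -> pd.DataFrame:
    """Predicted-vs-actual calibration per quantity and modality.

    ``values`` needs ``predicted`` and ``actual`` columns plus the
    grouping columns.  ``r_squared`` is the squared Pearson correlation
    (``method="pearson"``, default) or the regression R² of actual on
    predicted (``method="regression"``).  Residual = predicted − actual.
    Groups with fewer than 3 pairs report NaN.
    """
    if method not in ("pearson", "regression"):
        raise ValidationError(f"unknown r_squared method {method!r}")
    for col in ("predicted", "actual", *group_cols):
        if col not in values.columns:
            raise ValidationError(f"calibration table missing column {col!r}")
    rows = []
    for keys, sub in values.groupby(list(group_cols), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        pred = sub["predicted"].to_numpy(dtype=float)
        act = sub["actual"].to_numpy(dtype=float)
        finite = np.isfinite(pred) & np.isfinite(act)
        pred, act = pred[finite], act[finite]
        resid = pred - act
        if pred.size < 3 or np.std(pred) == 0 or np.std(act) == 0:
            r2 = np.nan
        elif method == "pearson":
            r2 = float(np.corrcoef(pred, act)[0, 1] ** 2)
        else:
            ss_res = float(np.sum(resid**2))
            ss_tot = float(np.sum((act - act.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot
        rows.append(
            {
                **dict(zip(group_cols, keys)),
                "n": int(pred.size),
                "r_squared": r2,
                "residual_mean": float(resid.mean()) if resid.size else np.nan,
                "residual_sd": float(resid.std(ddof=1)) if resid.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def plot_predicted_vs_actual(values: pd.DataFrame, path: str, by: str = "modality") -> None:
    """Scatter of predicted vs. actual values, one panel per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(values.groupby(by, sort=True))
    fig, axes = plt.subplots(1, max(len(groups), 1), figsize=(5 * max(len(groups), 1), 4.5))
    axes = np.atleast_1d(axes)
    for ax, (label, sub) in zip(axes, groups):
        ax.scatter(sub["actual"], sub["predicted"], s=12, alpha=0.6)
        lims = [
            min(sub["actual"].min(), sub["predicted"].min()),
            max(sub["actual"].max(), sub["predicted"].max()),
        ]
        ax.plot(lims, lims, "r-", lw=1)
        ax.set_xlabel("actual")
        ax.set_ylabel("predicted")
        ax.set_title(str(label))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_residual_box(values: pd.DataFrame, path: str, by: str = "quantity") -> None:
    """Boxplots of predicted − actual residuals per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    resid = values["predicted"] - values["actual"]
    labels, data = [], []
    for label, idx in values.groupby(by, sort=True).groups.items():
        labels.append(str(label))
        data.append(resid.loc[idx].dropna().to_numpy())
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(labels)), 4.5))
    ax.boxplot(data, tick_labels=labels)
    ax.axhline(0.0, color="r", lw=1)
    ax.set_ylabel("predicted − actual")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
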