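"""Per-OAR, per-modality linear mean-dose prediction models.

For each organ at risk (OAR) and each modality (photon VMAT, proton IMPT)
an ordinary-least-squares model predicts the organ mean dose from two
overlap features measured at one target-expansion margin::

    D_mean = b0 + b1 * pct_in70 + b2 * pct_in54_out70        [Gy]

Models are screened over the full margin grid (8 OARs x 6 margins x 2
modalities = 96 candidate fits on the default configuration) and, per
OAR and modality, the margin whose model attains the highest in-sample
R^2 is selected; ties go to the smallest margin.

The screening-and-selection step is exposed as a statsmodels-style pair:
:class:`DoseModelGrid` (the model, built from cohort data) whose
``fit()`` returns :class:`DoseModelGridResults` (estimates, per-cell
diagnostics, margin selection, ``summary()``, JSON round-trip).

Three post-hoc sensitivity adjustments can be applied to predictions to
trade specificity for sensitivity: a multiplicative rescale of proton
doses, re-prediction from a chosen 95% CI bound of every coefficient
(lower bound for protons, upper for photons), and a downward shift of
proton doses by a multiple of the residual SD.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    DegenerateResponseError,
    SelectionError,
    SingularFitError,
    ValidationError,
)
from .structures import DEFAULT_MARGINS_MM, OAR_NAMES

MODALITIES: tuple[str, str] = ("VMAT", "IMPT")

#: Predictions are clamped to the physically meaningful dose range:
#: 0 Gy to the 70 Gy boost prescription.
DOSE_BOUNDS_GY: tuple[float, float] = (0.0, 70.0)

_COEF_NAMES = ("intercept", "coef_in70", "coef_in54_out70")


@dataclass(frozen=True)
class DmeanModel:
    """A fitted mean-dose regression for one OAR, modality and margin."""

    oar: str
    modality: str
    margin_mm: float
    intercept: float
    coef_in70: float
    coef_in54_out70: float
    r_squared: float
    residual_sd: float
    coef_ci95: Mapping[str, tuple[float, float]]
    n_fit: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError(f"r_squared outside [0,1]: {self.r_squared}")
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be >= 0")
        for name in _COEF_NAMES:
            lo, hi = self.coef_ci95[name]
            point = getattr(self, name)
            if not (lo <= point + 1e-9 and point - 1e-9 <= hi):
                raise ValidationError(
                    f"CI bound ({lo}, {hi}) does not bracket {name}={point}"
                )

    def coefficients(self, bound: str | None = None) -> tuple[float, float, float]:
        """Point coefficients, or all-lower / all-upper 95% CI bounds."""
        if bound is None:
            return self.intercept, self.coef_in70, self.coef_in54_out70
        if bound not in ("lower", "upper"):
            raise ValidationError(f"bound must be 'lower' or 'upper', got {bound!r}")
        idx = 0 if bound == "lower" else 1
        return tuple(self.coef_ci95[name][idx] for name in _COEF_NAMES)

    def predict(
        self,
        pct_in70: float,
        pct_in54_out70: float,
        bound: str | None = None,
    ) -> float:
        """Predicted D_mean (Gy), clamped to :data:`DOSE_BOUNDS_GY`.

        Absent-OAR features (NaN) propagate as NaN.
        """
        if math.isnan(pct_in70) or math.isnan(pct_in54_out70):
            return float("nan")
        for value in (pct_in70, pct_in54_out70):
            if not (0.0 <= value <= 100.0):
                raise ValidationError(f"overlap percentage outside [0,100]: {value}")
        b0, b1, b2 = self.coefficients(bound)
        raw = b0 + b1 * pct_in70 + b2 * pct_in54_out70
        return float(min(max(raw, DOSE_BOUNDS_GY[0]), DOSE_BOUNDS_GY[1]))

    def to_dict(self) -> dict:
        return {
            "oar": self.oar,
            "modality": self.modality,
            "margin_mm": self.margin_mm,
            "intercept": self.intercept,
            "coef_in70": self.coef_in70,
            "coef_in54_out70": self.coef_in54_out70,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "coef_ci95": {k: list(v) for k, v in self.coef_ci95.items()},
            "n_fit": self.n_fit,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DmeanModel":
        return cls(
            oar=d["oar"],
            modality=d["modality"],
            margin_mm=float(d["margin_mm"]),
            intercept=float(d["intercept"]),
            coef_in70=float(d["coef_in70"]),
            coef_in54_out70=float(d["coef_in54_out70"]),
            r_squared=float(d["r_squared"]),
            residual_sd=float(d["residual_sd"]),
            coef_ci95={k: tuple(v) for k, v in d["coef_ci95"].items()},
            n_fit=int(d["n_fit"]),
        )


def fit_dmean_model(
    pct_in70: Sequence[float],
    pct_in54_out70: Sequence[float],
    dmeans: Sequence[float],
    oar: str,
    modality: str,
    margin_mm: float,
) -> DmeanModel:
    """OLS fit of the two-feature mean-dose model for one grid cell.

    ``residual_sd`` uses the n - 3 denominator (three estimated
    parameters); 95% coefficient CIs are the standard t-based OLS
    intervals.  A zero-variance response makes R^2 undefined and raises
    :class:`DegenerateResponseError`; a rank-deficient design raises
    :class:`SingularFitError` naming the cell.
    """
    x1 = np.asarray(pct_in70, dtype=float)
    x2 = np.asarray(pct_in54_out70, dtype=float)
    y = np.asarray(dmeans, dtype=float)
    if not (x1.shape == x2.shape == y.shape) or y.ndim != 1:
        raise ValidationError("feature and dose vectors must be equal-length 1-D")
    if y.size < 4:
        raise ValidationError(f"need >= 4 patients to fit, got {y.size}")
    if not (np.isfinite(x1).all() and np.isfinite(x2).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in regression inputs")
    X = sm.add_constant(np.column_stack([x1, x2]), has_constant="add")
    if np.linalg.matrix_rank(X) < 3:
        raise SingularFitError(
            f"rank-deficient design for {oar}/{modality} at margin {margin_mm} mm"
        )
    if np.ptp(y) == 0.0:
        raise DegenerateResponseError(
            f"constant D_mean response for {oar}/{modality} at margin {margin_mm} mm; "
            "R^2 undefined"
        )
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return DmeanModel(
        oar=oar,
        modality=modality,
        margin_mm=float(margin_mm),
        intercept=float(res.params[0]),
        coef_in70=float(res.params[1]),
        coef_in54_out70=float(res.params[2]),
        r_squared=float(min(max(res.rsquared, 0.0), 1.0)),
        residual_sd=float(np.sqrt(res.scale)),  # scale = SS_res / (n - 3)
        coef_ci95={
            name: (float(ci[i][0]), float(ci[i][1]))
            for i, name in enumerate(_COEF_NAMES)
        },
        n_fit=int(y.size),
    )


class DoseModelGrid:
    """Margin-grid dose model over a cohort (model object; call ``fit``).

    Parameters
    ----------
    features
        Long table with columns ``patient_id, oar, margin_mm, pct_in70,
        pct_in54_out70`` covering every configured margin for every
        patient (absent-OAR rows may carry NaN and are excluded from that
        OAR's fits).
    dmeans
        Long table with columns ``patient_id, oar, modality, dmean_gy``
        holding the actual planned mean doses used as the response.
    margins, oars, modalities
        Grid to fit; default is every margin/OAR/modality present in the
        canonical configuration.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        dmeans: pd.DataFrame,
        margins: Sequence[float] = DEFAULT_MARGINS_MM,
        oars: Sequence[str] = OAR_NAMES,
        modalities: Sequence[str] = MODALITIES,
    ) -> None:
        for col in ("patient_id", "oar", "margin_mm", "pct_in70", "pct_in54_out70"):
            if col not in features.columns:
                raise ValidationError(f"features table missing column {col!r}")
        for col in ("patient_id", "oar", "modality", "dmean_gy"):
            if col not in dmeans.columns:
                raise ValidationError(f"dmeans table missing column {col!r}")
        self.features = features
        self.dmeans = dmeans
        self.margins = tuple(sorted(float(m) for m in set(margins)))
        self.oars = tuple(oars)
        self.modalities = tuple(modalities)
        present = set(np.round(features["margin_mm"].astype(float), 9))
        missing = [m for m in self.margins if round(m, 9) not in present]
        if missing:
            raise ValidationError(f"features lack margins {missing}")

    def fit(self) -> "DoseModelGridResults":
        """Fit every OAR x margin x modality cell; failures are recorded
        per cell and do not abort the grid."""
        models: dict[tuple[str, str, float], DmeanModel] = {}
        failures: dict[tuple[str, str, float], str] = {}
        feat = self.features
        dm = self.dmeans
        for oar in self.oars:
            foar = feat[feat["oar"] == oar]
            for modality in self.modalities:
                resp = dm[(dm["oar"] == oar) & (dm["modality"] == modality)]
                resp = resp.set_index("patient_id")["dmean_gy"]
                for margin in self.margins:
                    cell = (oar, modality, margin)
                    rows = foar[np.isclose(foar["margin_mm"].astype(float), margin)]
                    rows = rows.set_index("patient_id")
                    common = rows.index.intersection(resp.index)
                    x1 = rows.loc[common, "pct_in70"].to_numpy(dtype=float)
                    x2 = rows.loc[common, "pct_in54_out70"].to_numpy(dtype=float)
                    y = resp.loc[common].to_numpy(dtype=float)
                    keep = np.isfinite(x1) & np.isfinite(x2) & np.isfinite(y)
                    try:
                        models[cell] = fit_dmean_model(
                            x1[keep], x2[keep], y[keep], oar, modality, margin
                        )
                    except (ValidationError, SingularFitError, DegenerateResponseError) as exc:
                        failures[cell] = str(exc)
        return DoseModelGridResults(
            models=models,
            failures=failures,
            margins=self.margins,
            oars=self.oars,
            modalities=self.modalities,
        )


def select_margin(
    candidates: Sequence[DmeanModel],
) -> tuple[float, DmeanModel]:
    """Pick the margin with the highest R^2; ties go to the smallest margin."""
    if not candidates:
        raise SelectionError("no successfully fitted model to select from")
    best = None
    for model in sorted(candidates, key=lambda m: m.margin_mm):
        if best is None or model.r_squared > best.r_squared + 0.0:
            best = model
    assert best is not None
    return best.margin_mm, best


@dataclass
class DoseModelGridResults:
    """Fitted margin grid: per-cell models, failures, and selection."""

    models: dict[tuple[str, str, float], DmeanModel]
    failures: dict[tuple[str, str, float], str]
    margins: tuple[float, ...]
    oars: tuple[str, ...]
    modalities: tuple[str, ...]

    def select(self, oar: str, modality: str) -> DmeanModel:
        """Best-R^2 model for one OAR/modality (smallest margin on ties)."""
        row = [
            self.models[(oar, modality, m)]
            for m in self.margins
            if (oar, modality, m) in self.models
        ]
        if not row:
            raise SelectionError(f"all fits failed for {oar}/{modality}")
        _, best = select_margin(row)
        return best

    def selected(self) -> dict[tuple[str, str], DmeanModel]:
        out: dict[tuple[str, str], DmeanModel] = {}
        for oar in self.oars:
            for modality in self.modalities:
                try:
                    out[(oar, modality)] = self.select(oar, modality)
                except SelectionError:
                    continue
        return out

    def r2_table(self, modality: str) -> pd.DataFrame:
        """OAR x margin table of R^2 values (the margin-screening heatmap)."""
        data = {
            margin: [
                self.models[(oar, modality, margin)].r_squared
                if (oar, modality, margin) in self.models
                else np.nan
                for oar in self.oars
            ]
            for margin in self.margins
        }
        return pd.DataFrame(data, index=list(self.oars))

    def pooled_residual_sd(self, modality: str | None = None) -> float:
        """Residual SD pooled over the selected models
        (sqrt of summed SS_res over summed residual df)."""
        ssr = 0.0
        df = 0
        for (oar, mod), model in self.selected().items():
            if modality is not None and mod != modality:
                continue
            ssr += model.residual_sd**2 * (model.n_fit - 3)
            df += model.n_fit - 3
        if df == 0:
            raise SelectionError("no selected models to pool")
        return float(np.sqrt(ssr / df))

    def summary(self) -> str:
        lines = [
            "Margin-grid D_mean models "
            f"({len(self.models)} fitted, {len(self.failures)} failed cells)",
            f"{'OAR':<20s} {'modality':<8s} {'margin':>6s} {'R^2':>7s} "
            f"{'intercept':>9s} {'b_in70':>8s} {'b_54o70':>8s} {'resid SD':>8s}",
        ]
        for (oar, modality), m in self.selected().items():
            lines.append(
                f"{oar:<20s} {modality:<8s} {m.margin_mm:6.1f} {m.r_squared:7.3f} "
                f"{m.intercept:9.3f} {m.coef_in70:8.4f} {m.coef_in54_out70:8.4f} "
                f"{m.residual_sd:8.3f}"
            )
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "margins": list(self.margins),
            "oars": list(self.oars),
            "modalities": list(self.modalities),
            "models": [m.to_dict() for m in self.models.values()],
            "failures": [
                {"oar": k[0], "modality": k[1], "margin_mm": k[2], "error": v}
                for k, v in self.failures.items()
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DoseModelGridResults":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        models = {}
        for d in doc["models"]:
            m = DmeanModel.from_dict(d)
            models[(m.oar, m.modality, m.margin_mm)] = m
        failures = {
            (f["oar"], f["modality"], float(f["margin_mm"])): f["error"]
            for f in doc.get("failures", [])
        }
        return cls(
            models=models,
            failures=failures,
            margins=tuple(doc["margins"]),
            oars=tuple(doc["oars"]),
            modalities=tuple(doc["modalities"]),
        )


ADJUSTMENT_METHODS = ("rescale", "ci_bound", "sd_shift")


@dataclass(frozen=True)
class AdjustmentSpec:
    """Post-hoc sensitivity adjustment of predicted doses.

    method
        ``rescale``: multiply predictions by ``factor`` (e.g. 0.85 on
        proton doses).  ``ci_bound``: re-predict with the ``bound_side``
        95% CI bound of all three coefficients (lower for protons, upper
        for photons).  ``sd_shift``: subtract ``k_sd`` residual SDs,
        clamped at 0 Gy; uses each model's own residual SD unless a
        ``pooled_sd`` (Gy) is supplied.
    target_oars
        Restrict the adjustment to these OARs (e.g. the salivary glands);
        ``None`` means all.
    """

    method: str
    factor: float | None = None
    k_sd: float | None = None
    bound_side: str | None = None
    target_oars: tuple[str, ...] | None = None
    pooled_sd: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ADJUSTMENT_METHODS:
            raise ValidationError(
                f"unknown adjustment method {self.method!r}; "
                f"expected one of {ADJUSTMENT_METHODS}"
            )
        if self.method == "rescale":
            if self.factor is None or not (self.factor > 0):
                raise ValidationError("rescale requires factor > 0")
        elif self.method == "ci_bound":
            if self.bound_side not in ("lower", "upper"):
                raise ValidationError("ci_bound requires bound_side 'lower' or 'upper'")
        elif self.method == "sd_shift":
            if self.k_sd is None:
                raise ValidationError("sd_shift requires k_sd")
        if self.target_oars is not None:
            object.__setattr__(self, "target_oars", tuple(self.target_oars))

    def applies_to(self, oar: str) -> bool:
        return self.target_oars is None or oar in self.target_oars


def apply_adjustment(
    predicted: Mapping[str, float],
    models: Mapping[str, DmeanModel],
    spec: AdjustmentSpec,
    features: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Apply one post-hoc adjustment to per-OAR predicted doses.

    ``features`` (per-OAR ``(pct_in70, pct_in54_out70)``) is required for
    ``ci_bound``, which re-predicts from the CI-bound coefficients.
    Non-target OARs pass through unchanged; NaN (absent organ) propagates.
    """
    out: dict[str, float] = {}
    for oar, value in predicted.items():
        if not spec.applies_to(oar) or (isinstance(value, float) and math.isnan(value)):
            out[oar] = value
            continue
        if spec.method == "rescale":
            adjusted = value * spec.factor
        elif spec.method == "sd_shift":
            sd = spec.pooled_sd if spec.pooled_sd is not None else models[oar].residual_sd
            adjusted = value - spec.k_sd * sd
        else:  # ci_bound
            if features is None or oar not in features:
                raise ValidationError(
                    f"ci_bound adjustment needs overlap features for {oar!r}"
                )
            adjusted = models[oar].predict(*features[oar], bound=spec.bound_side)
        out[oar] = float(min(max(adjusted, DOSE_BOUNDS_GY[0]), DOSE_BOUNDS_GY[1]))
    return out
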