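"""End-to-end decision support: geometry → predicted doses → ΔNTCP → decision.

:class:`DecisionTool` bundles the selected per-OAR dose models, the four
NTCP models, the qualification thresholds and optional post-hoc dose
adjustments, and runs single patients (:meth:`DecisionTool.run_patient`)
or whole cohorts (:meth:`DecisionTool.run_cohort`).

Two comparison modes exist.  ``"predicted"`` compares the predicted
photon plan against the predicted proton plan — the pure delineation-only
tool.  ``"hybrid"`` substitutes the *actual* photon plan doses for the
VMAT side (the proton side stays predicted), for referring centers that
already hold a clinical VMAT plan.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose import AdjustmentSpec, DmeanModel, apply_adjustment
from .exceptions import ValidationError
from .ntcp import (
    ENDPOINTS,
    DecisionResult,
    NTCPModel,
    ThresholdConfig,
    decide,
    delta_profile,
    ntcp_profile,
)
from .structures import StructureSet, extract_features

COMPARISON_MODES = ("predicted", "hybrid")

#: Baseline covariate columns expected in cohort tables.
BASELINE_COLUMNS = ("baseline_xerostomia", "baseline_dysphagia")


def _features_frame(
    features: pd.DataFrame | StructureSet,
    margins: Sequence[float],
) -> pd.DataFrame:
    if isinstance(features, StructureSet):
        return extract_features(features, margins=margins)
    for col in ("oar", "margin_mm", "pct_in70", "pct_in54_out70"):
        if col not in features.columns:
            raise ValidationError(f"features table missing column {col!r}")
    return features


class DecisionTool:
    """The configured decision support tool.

    Parameters
    ----------
    dose_models
        Mapping ``(oar, modality) -> DmeanModel`` — one selected model per
        OAR and modality (the output of
        :meth:`~protonsel.dose.DoseModelGridResults.selected`).
    ntcp_models
        Mapping endpoint name -> :class:`~protonsel.ntcp.NTCPModel`,
        covering all four endpoints.
    thresholds
        Qualification thresholds; national-protocol defaults.
    adjustments
        Optional per-modality post-hoc adjustment, e.g.
        ``{"IMPT": AdjustmentSpec("rescale", factor=0.85)}``.
    missing_policy
        ``"error"`` (default) or ``"impute_zero"`` for absent OARs.
    """

    def __init__(
        self,
        dose_models: Mapping[tuple[str, str], DmeanModel],
        ntcp_models: Mapping[str, NTCPModel],
        thresholds: ThresholdConfig = ThresholdConfig(),
        adjustments: Mapping[str, AdjustmentSpec] | None = None,
        missing_policy: str = "error",
    ) -> None:
        self.dose_models = dict(dose_models)
        self.ntcp_models = dict(ntcp_models)
        self.thresholds = thresholds
        self.adjustments = dict(adjustments or {})
        self.missing_policy = missing_policy
        missing = set(ENDPOINTS) - set(self.ntcp_models)
        if missing:
            raise ValidationError(f"NTCP model set missing endpoints: {sorted(missing)}")
        for modality in self.adjustments:
            if modality not in ("VMAT", "IMPT"):
                raise ValidationError(f"adjustment for unknown modality {modality!r}")

    @property
    def margins_needed(self) -> tuple[float, ...]:
        return tuple(sorted({m.margin_mm for m in self.dose_models.values()}))

    def predict_dmeans(
        self,
        features: pd.DataFrame | StructureSet,
        modality: str,
    ) -> tuple[dict[str, float], dict[str, dict]]:
        """Per-OAR predicted D_mean (Gy) at each OAR's selected margin.

        Returns the predictions and an audit record of the features used.
        Absent-OAR feature rows produce NaN predictions.
        """
        feat = _features_frame(features, self.margins_needed)
        predictions: dict[str, float] = {}
        audit: dict[str, dict] = {}
        for (oar, mod), model in self.dose_models.items():
            if mod != modality:
                continue
            rows = feat[
                (feat["oar"] == oar)
                & np.isclose(feat["margin_mm"].astype(float), model.margin_mm)
            ]
            if rows.empty:
                raise ValidationError(
                    f"no features for {oar!r} at selected margin {model.margin_mm} mm"
                )
            p70 = float(rows["pct_in70"].iloc[0])
            p54 = float(rows["pct_in54_out70"].iloc[0])
            predictions[oar] = model.predict(p70, p54)
            audit[oar] = {
                "margin_mm": model.margin_mm,
                "pct_in70": p70,
                "pct_in54_out70": p54,
            }
        spec = self.adjustments.get(modality)
        if spec is not None:
            models_by_oar = {
                oar: m for (oar, mod), m in self.dose_models.items() if mod == modality
            }
            feature_pairs = {
                oar: (a["pct_in70"], a["pct_in54_out70"]) for oar, a in audit.items()
            }
            predictions = apply_adjustment(predictions, models_by_oar, spec, feature_pairs)
        return predictions, audit

    def run_patient(
        self,
        features: pd.DataFrame | StructureSet,
        baseline: Mapping[str, str],
        mode: str = "predicted",
        actual_vmat_dmeans: Mapping[str, float] | None = None,
    ) -> DecisionResult:
        """Full pipeline for one patient; intermediates kept for audit."""
        if mode not in COMPARISON_MODES:
            raise ValidationError(f"unknown comparison mode {mode!r}")
        warnings: list[str] = []
        dmeans_impt, audit = self.predict_dmeans(features, "IMPT")
        if mode == "hybrid":
            if actual_vmat_dmeans is None:
                raise ValidationError("hybrid mode requires actual VMAT D_means")
            dmeans_vmat = {k: float(v) for k, v in actual_vmat_dmeans.items()}
        else:
            dmeans_vmat, _ = self.predict_dmeans(features, "VMAT")
        prof_vmat = ntcp_profile(
            self.ntcp_models, dmeans_vmat, baseline, self.missing_policy, warnings
        )
        prof_impt = ntcp_profile(
            self.ntcp_models, dmeans_impt, baseline, self.missing_policy, warnings
        )
        delta = delta_profile(prof_vmat, prof_impt)
        result = decide(delta, self.thresholds, comparison_mode=mode)
        result.ntcp_vmat = prof_vmat
        result.ntcp_impt = prof_impt
        result.dmeans_vmat = dmeans_vmat
        result.dmeans_impt = dmeans_impt
        result.features_used = audit
        result.warnings = warnings
        return result

    def run_cohort(
        self,
        features: pd.DataFrame,
        baseline: pd.DataFrame,
        mode: str = "predicted",
        actual_vmat: pd.DataFrame | None = None,
    ) -> tuple[pd.DataFrame, dict[str, DecisionResult]]:
        """Run every patient of a cohort.

        ``features`` is the long per-patient overlap table (must carry
        ``patient_id``); ``baseline`` has one row per patient with the
        baseline covariate columns; ``actual_vmat`` (hybrid mode) is long
        ``patient_id, oar, dmean_gy``.  Returns a tidy decision table and
        the per-patient audit results.
        """
        if "patient_id" not in features.columns:
            raise ValidationError("cohort features need a patient_id column")
        base = baseline.set_index("patient_id") if "patient_id" in baseline.columns else baseline
        actual_by_patient: dict[str, dict[str, float]] = {}
        if actual_vmat is not None:
            for pid, group in actual_vmat.groupby("patient_id"):
                actual_by_patient[str(pid)] = dict(
                    zip(group["oar"], group["dmean_gy"].astype(float))
                )
        rows = []
        results: dict[str, DecisionResult] = {}
        for pid, group in features.groupby("patient_id", sort=False):
            pid = str(pid)
            covariates = {c: base.loc[pid, c] for c in BASELINE_COLUMNS if c in base.columns}
            result = self.run_patient(
                group,
                covariates,
                mode=mode,
                actual_vmat_dmeans=actual_by_patient.get(pid),
            )
            results[pid] = result
            rows.append(
                {
                    "patient_id": pid,
                    "mode": mode,
                    **{f"delta_{e}": result.delta_ntcp[e] for e in ENDPOINTS},
                    "qualifies": result.qualifies,
                    "criteria": "|".join(result.triggered_criteria),
                }
            )
        return pd.DataFrame(rows), results


def decide_cohort(
    predicted: pd.DataFrame,
    ntcp_models: Mapping[str, NTCPModel],
    thresholds: ThresholdConfig,
    baseline: pd.DataFrame,
    mode: str = "predicted",
    actual_vmat: pd.DataFrame | None = None,
    missing_policy: str = "error",
) -> tuple[pd.DataFrame, dict[str, DecisionResult]]:
    """Decision stage alone, from already-predicted doses.

    ``predicted`` is long ``patient_id, oar, modality, dmean_gy`` (doses
    already adjusted if an adjustment applies).  In hybrid mode the VMAT
    doses are taken from ``actual_vmat`` instead of ``predicted``.
    """
    if mode not in COMPARISON_MODES:
        raise ValidationError(f"unknown comparison mode {mode!r}")
    if mode == "hybrid" and actual_vmat is None:
        raise ValidationError("hybrid mode requires an actual VMAT dose table")
    base = baseline.set_index("patient_id") if "patient_id" in baseline.columns else baseline

    def doses_of(frame: pd.DataFrame, pid: str, modality: str | None = None) -> dict:
        sub = frame[frame["patient_id"].astype(str) == pid]
        if modality is not None:
            sub = sub[sub["modality"] == modality]
        return dict(zip(sub["oar"], sub["dmean_gy"].astype(float)))

    rows = []
    results: dict[str, DecisionResult] = {}
    for pid in predicted["patient_id"].astype(str).unique():
        covariates = {c: base.loc[pid, c] for c in BASELINE_COLUMNS if c in base.columns}
        dmeans_impt = doses_of(predicted, pid, "IMPT")
        if mode == "hybrid":
            dmeans_vmat = doses_of(actual_vmat, pid)
        else:
            dmeans_vmat = doses_of(predicted, pid, "VMAT")
        warnings: list[str] = []
        prof_vmat = ntcp_profile(ntcp_models, dmeans_vmat, covariates, missing_policy, warnings)
        prof_impt = ntcp_profile(ntcp_models, dmeans_impt, covariates, missing_policy, warnings)
        delta = delta_profile(prof_vmat, prof_impt)
        result = decide(delta, thresholds, comparison_mode=mode)
        result.ntcp_vmat, result.ntcp_impt = prof_vmat, prof_impt
        result.dmeans_vmat, result.dmeans_impt = dmeans_vmat, dmeans_impt
        result.warnings = warnings
        results[pid] = result
        rows.append(
            {
                "patient_id": pid,
                "mode": mode,
                **{f"delta_{e}": result.delta_ntcp[e] for e in ENDPOINTS},
                "qualifies": result.qualifies,
                "criteria": "|".join(result.triggered_criteria),
            }
        )
    return pd.DataFrame(rows), results


def load_ntcp_models(path: str | Path) -> dict[str, NTCPModel]:
    """Read an NTCP model set from a JSON config (list of model dicts)."""
    doc = json.loads(Path(path).read_text())
    models = [NTCPModel.from_dict(d) for d in doc]
    out: dict[str, NTCPModel] = {}
    for model in models:
        if model.endpoint in out:
            raise ValidationError(f"duplicate NTCP model for {model.endpoint}")
        out[model.endpoint] = model
    return out


def save_ntcp_models(models: Mapping[str, NTCPModel], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([models[e].to_dict() for e in ENDPOINTS if e in models], indent=1)
    )
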