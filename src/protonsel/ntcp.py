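"""NTCP models, ΔNTCP profiles and the proton-therapy qualification rule.

Four logistic normal-tissue-complication-probability (NTCP) models — grade
≥2 and grade ≥3 dysphagia and xerostomia — score each plan from the eight
organ mean doses plus a baseline-complaint covariate::

    NTCP = 1 / (1 + exp(-S)),
    S = intercept + sum_oar beta_oar * D_mean_oar + beta_baseline(level)

The ΔNTCP profile is the photon-minus-proton difference per endpoint in
percentage points.  A patient qualifies for proton therapy under the
national-protocol thresholds when any of four criteria fires:

1. any grade ≥2 endpoint ΔNTCP ≥ 10;
2. any grade ≥3 endpoint ΔNTCP ≥ 5;
3. summed grade ≥2 ΔNTCP ≥ 15, counting only endpoints individually ≥ 5;
4. summed grade ≥3 ΔNTCP ≥ 5, counting only endpoints individually ≥ 3.75.

All comparisons are inclusive (≥).  The per-endpoint minima act as a
contribution filter: an endpoint below its minimum simply does not count
toward the sum.  Negative ΔNTCP values are kept as-is; they can never
satisfy a criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import MissingDoseError, ValidationError
from .structures import OAR_NAMES

ENDPOINTS: tuple[str, ...] = (
    "dysphagia_g2",
    "dysphagia_g3",
    "xerostomia_g2",
    "xerostomia_g3",
)
G2_ENDPOINTS: tuple[str, str] = ("dysphagia_g2", "xerostomia_g2")
G3_ENDPOINTS: tuple[str, str] = ("dysphagia_g3", "xerostomia_g3")

CRITERIA: tuple[str, ...] = ("single_g2", "single_g3", "sum_g2", "sum_g3")

MISSING_OAR_POLICIES = ("error", "impute_zero")


@dataclass(frozen=True)
class NTCPModel:
    """Logistic toxicity model for one endpoint.

    ``dose_betas`` maps OAR names (subset of the canonical eight) to
    per-Gy coefficients; ``baseline_betas`` maps levels of the single
    baseline covariate (``baseline_covariate``, e.g. baseline xerostomia
    grade) to additive logit terms, with the reference level at 0.
    """

    endpoint: str
    intercept: float
    dose_betas: Mapping[str, float]
    baseline_covariate: str
    baseline_betas: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(
                f"unknown endpoint {self.endpoint!r}; expected one of {ENDPOINTS}"
            )
        unknown = set(self.dose_betas) - set(OAR_NAMES)
        if unknown:
            raise ValidationError(f"dose_betas for non-canonical OARs: {sorted(unknown)}")
        object.__setattr__(self, "dose_betas", dict(self.dose_betas))
        object.__setattr__(self, "baseline_betas", dict(self.baseline_betas))

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "intercept": self.intercept,
            "dose_betas": dict(self.dose_betas),
            "baseline_covariate": self.baseline_covariate,
            "baseline_betas": dict(self.baseline_betas),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NTCPModel":
        return cls(
            endpoint=d["endpoint"],
            intercept=float(d["intercept"]),
            dose_betas={k: float(v) for k, v in d["dose_betas"].items()},
            baseline_covariate=d["baseline_covariate"],
            baseline_betas={k: float(v) for k, v in d["baseline_betas"].items()},
        )


def compute_ntcp(
    model: NTCPModel,
    dmeans: Mapping[str, float],
    baseline: Mapping[str, str],
    missing_policy: str = "error",
    warnings_sink: list | None = None,
) -> float:
    """Evaluate one logistic NTCP model; result strictly in (0, 1).

    ``missing_policy`` governs OARs that carry a nonzero coefficient but
    no dose (or NaN): ``"error"`` aborts, ``"impute_zero"`` substitutes
    0 Gy and records an audit warning in ``warnings_sink``.
    """
    if missing_policy not in MISSING_OAR_POLICIES:
        raise ValidationError(f"unknown missing policy {missing_policy!r}")
    s = model.intercept
    for oar, beta in model.dose_betas.items():
        if beta == 0.0:
            continue
        dose = dmeans.get(oar)
        if dose is None or (isinstance(dose, float) and math.isnan(dose)):
            if missing_policy == "error":
                raise MissingDoseError(
                    f"no D_mean for {oar!r} needed by {model.endpoint} model"
                )
            if warnings_sink is not None:
                warnings_sink.append(
                    f"{model.endpoint}: imputed 0 Gy for missing OAR {oar!r}"
                )
            dose = 0.0
        s += beta * float(dose)
    level = baseline.get(model.baseline_covariate)
    if level not in model.baseline_betas:
        raise ValidationError(
            f"baseline level {level!r} unknown to {model.endpoint} model "
            f"(covariate {model.baseline_covariate!r})"
        )
    s += model.baseline_betas[level]
    return 1.0 / (1.0 + math.exp(-s))


def ntcp_profile(
    models: Mapping[str, NTCPModel],
    dmeans: Mapping[str, float],
    baseline: Mapping[str, str],
    missing_policy: str = "error",
    warnings_sink: list | None = None,
) -> dict[str, float]:
    """All four endpoint probabilities for one plan."""
    missing = set(ENDPOINTS) - set(models)
    if missing:
        raise ValidationError(f"NTCP model set missing endpoints: {sorted(missing)}")
    return {
        endpoint: compute_ntcp(
            models[endpoint], dmeans, baseline, missing_policy, warnings_sink
        )
        for endpoint in ENDPOINTS
    }


def delta_profile(
    ntcp_vmat: Mapping[str, float],
    ntcp_impt: Mapping[str, float],
) -> dict[str, float]:
    """Per-endpoint ΔNTCP = 100·(NTCP_VMAT − NTCP_IMPT), percentage points.

    Negative values (proton plan worse) are preserved.
    """
    if set(ntcp_vmat) != set(ntcp_impt):
        raise ValidationError("VMAT and IMPT profiles cover different endpoints")
    return {e: 100.0 * (ntcp_vmat[e] - ntcp_impt[e]) for e in ntcp_vmat}


@dataclass(frozen=True)
class ThresholdConfig:
    """Qualification thresholds (percentage points of ΔNTCP)."""

    single_g2: float = 10.0
    single_g3: float = 5.0
    sum_g2: float = 15.0
    min_g2: float = 5.0
    sum_g3: float = 5.0
    min_g3: float = 3.75

    def __post_init__(self) -> None:
        for name in ("single_g2", "single_g3", "sum_g2", "min_g2", "sum_g3", "min_g3"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"threshold {name} must be > 0")
        if self.min_g2 > self.sum_g2:
            raise ValidationError("min_g2 must not exceed sum_g2")
        if self.min_g3 > self.sum_g3:
            raise ValidationError("min_g3 must not exceed sum_g3")

    def to_dict(self) -> dict:
        return {
            "single_g2": self.single_g2,
            "single_g3": self.single_g3,
            "sum_g2": self.sum_g2,
            "min_g2": self.min_g2,
            "sum_g3": self.sum_g3,
            "min_g3": self.min_g3,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThresholdConfig":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class DecisionResult:
    """Qualification outcome for one patient and comparison mode.

    ``delta_ntcp`` is per-endpoint in percentage points;
    ``triggered_criteria`` lists the fired criteria in canonical order
    (``qualifies`` iff non-empty).  The optional audit fields retain every
    intermediate of the end-to-end run.
    """

    delta_ntcp: dict[str, float]
    qualifies: bool
    triggered_criteria: tuple[str, ...]
    comparison_mode: str = "predicted"
    ntcp_vmat: dict[str, float] | None = None
    ntcp_impt: dict[str, float] | None = None
    dmeans_vmat: dict[str, float] | None = None
    dmeans_impt: dict[str, float] | None = None
    features_used: dict[str, dict] | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "comparison_mode": self.comparison_mode,
            "delta_ntcp": self.delta_ntcp,
            "qualifies": self.qualifies,
            "triggered_criteria": list(self.triggered_criteria),
        }
        for name in ("ntcp_vmat", "ntcp_impt", "dmeans_vmat", "dmeans_impt", "features_used"):
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        if self.warnings:
            out["warnings"] = list(self.warnings)
        return out


def decide(
    delta: Mapping[str, float],
    thresholds: ThresholdConfig = ThresholdConfig(),
    comparison_mode: str = "predicted",
) -> DecisionResult:
    """Apply the four-criterion qualification rule to a ΔNTCP profile."""
    missing = set(ENDPOINTS) - set(delta)
    if missing:
        raise ValidationError(f"Δ profile missing endpoints: {sorted(missing)}")
    triggered: list[str] = []
    if any(delta[e] >= thresholds.single_g2 for e in G2_ENDPOINTS):
        triggered.append("single_g2")
    if any(delta[e] >= thresholds.single_g3 for e in G3_ENDPOINTS):
        triggered.append("single_g3")
    sum_g2 = sum(delta[e] for e in G2_ENDPOINTS if delta[e] >= thresholds.min_g2)
    if sum_g2 >= thresholds.sum_g2:
        triggered.append("sum_g2")
    sum_g3 = sum(delta[e] for e in G3_ENDPOINTS if delta[e] >= thresholds.min_g3)
    if sum_g3 >= thresholds.sum_g3:
        triggered.append("sum_g3")
    return DecisionResult(
        delta_ntcp={e: float(delta[e]) for e in ENDPOINTS},
        qualifies=bool(triggered),
        triggered_criteria=tuple(triggered),
        comparison_mode=comparison_mode,
    )
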