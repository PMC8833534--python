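"""Synthetic phantoms and cohorts with the statistical structure the tool assumes.

Two generator tiers share one generative dose model:

* **Voxel phantoms** — ellipsoidal targets and organs rasterized onto a
  :class:`~protonsel.structures.VoxelGrid` (voxel-center-inside test),
  exercising the geometry pipeline end to end at small n.
* **Feature-level cohorts** — per-patient overlap-percentage curves drawn
  directly (no voxels), so the regression, margin-selection, decision and
  evaluation machinery can be exercised at clinical cohort sizes cheaply.

The cohort generator emulates a head-and-neck plan-comparison cohort:
each organ's containment fraction grows smoothly with the expansion
margin (a probit curve in the margin, positioned by a latent organ-target
distance shared across margins), the *actual* planned mean dose is the
true linear dose–overlap model evaluated at that organ's true margin plus
homoscedastic Gaussian noise, and the actual qualification label is
obtained by running the NTCP models and threshold rule on the actual
doses.  Default parameters are chosen so that roughly 70% of patients
qualify for proton therapy, matching the selection rate reported for
model-based selection cohorts.

Random number consumption order (fixed so seeds are portable): for each
patient in index order — tumor location; patient-level proximity shift;
per OAR in canonical order: latent distance, target gap, amplitude; per
OAR in canonical order the VMAT then IMPT dose noise; baseline xerostomia
level; baseline dysphagia level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ValidationError
from .ntcp import NTCPModel, ThresholdConfig, decide, delta_profile, ntcp_profile
from .structures import (
    DEFAULT_MARGINS_MM,
    OAR_NAMES,
    TARGET_HIGH,
    TARGET_LOW,
    StructureSet,
    VoxelGrid,
)

# --------------------------------------------------------------------------
# voxel phantoms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in physical coordinates (mm)."""

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(not (a > 0) for a in self.semiaxes_mm):
            raise ValidationError(f"semi-axes must be positive, got {self.semiaxes_mm}")


@dataclass
class PhantomSpec:
    """Ellipsoidal phantom: two nested targets plus organ ellipsoids."""

    grid: VoxelGrid
    ptv_7000: Ellipsoid
    ptv_5425: Ellipsoid
    oars: Mapping[str, Ellipsoid] = field(default_factory=dict)


def rasterize_ellipsoid(grid: VoxelGrid, ellipsoid: Ellipsoid) -> np.ndarray:
    """Boolean mask of voxels whose center lies inside the ellipsoid."""
    axes = grid.axis_coordinates()
    terms = [
        ((axes[i] - ellipsoid.center_mm[i]) / ellipsoid.semiaxes_mm[i]) ** 2
        for i in range(3)
    ]
    return (
        terms[0][:, None, None] + terms[1][None, :, None] + terms[2][None, None, :]
    ) <= 1.0


def _check_inside_grid(grid: VoxelGrid, ellipsoid: Ellipsoid, name: str) -> None:
    for i in range(3):
        lo = grid.origin[i] - 0.5 * grid.spacing[i]
        hi = grid.origin[i] + (grid.shape[i] - 0.5) * grid.spacing[i]
        if ellipsoid.center_mm[i] - ellipsoid.semiaxes_mm[i] < lo or (
            ellipsoid.center_mm[i] + ellipsoid.semiaxes_mm[i] > hi
        ):
            raise ValidationError(f"structure {name!r} exceeds the grid along axis {i}")


def generate_phantom(spec: PhantomSpec) -> StructureSet:
    """Rasterize a phantom spec into a structure set (deterministic)."""
    _check_inside_grid(spec.grid, spec.ptv_7000, TARGET_HIGH)
    _check_inside_grid(spec.grid, spec.ptv_5425, TARGET_LOW)
    masks: dict[str, np.ndarray] = {
        TARGET_HIGH: rasterize_ellipsoid(spec.grid, spec.ptv_7000),
        TARGET_LOW: rasterize_ellipsoid(spec.grid, spec.ptv_5425),
    }
    if np.any(masks[TARGET_HIGH] & ~masks[TARGET_LOW]):
        raise ValidationError("PTV_7000 ellipsoid is not contained in PTV_5425")
    for name, ellipsoid in spec.oars.items():
        _check_inside_grid(spec.grid, ellipsoid, name)
        masks[name] = rasterize_ellipsoid(spec.grid, ellipsoid)
    return StructureSet(spec.grid, masks)


def default_phantom_spec() -> PhantomSpec:
    """A head-and-neck-like phantom on an anisotropic 3 x 2 x 2 mm grid.

    Organs sit at heterogeneous distances from the nested targets so the
    overlap features span the low/partial/full containment regimes.
    """
    grid = VoxelGrid(shape=(40, 48, 48), spacing=(3.0, 2.0, 2.0))
    center = (58.0, 47.0, 47.0)
    return PhantomSpec(
        grid=grid,
        ptv_7000=Ellipsoid(center, (18.0, 15.0, 13.0)),
        ptv_5425=Ellipsoid(center, (30.0, 26.0, 24.0)),
        oars={
            "oral_cavity": Ellipsoid((58.0, 20.0, 47.0), (12.0, 14.0, 14.0)),
            "parotid_left": Ellipsoid((52.0, 47.0, 84.0), (10.0, 8.0, 8.0)),
            "parotid_right": Ellipsoid((52.0, 47.0, 10.0), (10.0, 8.0, 8.0)),
            "submandibular_left": Ellipsoid((82.0, 60.0, 70.0), (8.0, 7.0, 7.0)),
            "submandibular_right": Ellipsoid((82.0, 60.0, 24.0), (8.0, 7.0, 7.0)),
            "pcm_superior": Ellipsoid((38.0, 60.0, 47.0), (8.0, 6.0, 10.0)),
            "pcm_medius": Ellipsoid((58.0, 68.0, 47.0), (8.0, 6.0, 10.0)),
            "pcm_inferior": Ellipsoid((82.0, 72.0, 47.0), (10.0, 6.0, 10.0)),
        },
    )


# --------------------------------------------------------------------------
# feature-level cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueDoseModel:
    """Generative linear dose–overlap truth for one OAR and modality."""

    margin_mm: float
    intercept: float
    coef_in70: float
    coef_in54_out70: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def mean(self, pct_in70: float, pct_in54_out70: float) -> float:
        return self.intercept + self.coef_in70 * pct_in70 + (
            self.coef_in54_out70 * pct_in54_out70
        )


@dataclass(frozen=True)
class GeometryParams:
    """Latent organ-target geometry for one OAR.

    ``d70_mean``/``d70_sd`` (mm) position the probit containment curve of
    the boost target: at margin ``d70`` half the reachable organ volume is
    inside the expanded PTV_7000.  ``gap_range`` (mm) is how much earlier
    the elective target reaches the organ; ``amp_range`` the maximum
    containment fraction; ``slope_mm`` the curve width.
    """

    d70_mean: float
    d70_sd: float = 5.0
    slope_mm: float = 5.0
    gap_range: tuple[float, float] = (2.0, 6.0)
    amp_range: tuple[float, float] = (0.7, 1.0)


LOCATIONS: tuple[str, ...] = ("pharynx", "larynx", "others")

#: Location-specific shifts (mm) added to each OAR's latent distance:
#: laryngeal tumors sit low (far from salivary glands, close to the
#: inferior constrictor); "others" are on average less extensive.
LOCATION_SHIFTS: dict[str, dict[str, float]] = {
    "pharynx": {},
    "larynx": {
        "parotid_left": 7.0,
        "parotid_right": 7.0,
        "submandibular_left": 4.0,
        "submandibular_right": 4.0,
        "oral_cavity": 5.0,
        "pcm_inferior": -6.0,
    },
    "others": {name: 3.0 for name in OAR_NAMES},
}

BASELINE_LEVELS: dict[str, tuple[str, ...]] = {
    "baseline_xerostomia": ("none", "a_bit", "severe"),
    "baseline_dysphagia": ("grade0_1", "grade2", "grade3plus"),
}


def default_geometry() -> dict[str, GeometryParams]:
    return {
        "oral_cavity": GeometryParams(d70_mean=13.0, d70_sd=7.0),
        "parotid_left": GeometryParams(d70_mean=19.0, d70_sd=7.0),
        "parotid_right": GeometryParams(d70_mean=19.0, d70_sd=7.0),
        "submandibular_left": GeometryParams(d70_mean=12.0, d70_sd=7.0),
        "submandibular_right": GeometryParams(d70_mean=12.0, d70_sd=7.0),
        "pcm_superior": GeometryParams(d70_mean=8.0, d70_sd=7.0),
        "pcm_medius": GeometryParams(d70_mean=11.0, d70_sd=7.0),
        "pcm_inferior": GeometryParams(d70_mean=15.0, d70_sd=7.0),
    }


_VMAT_INTERCEPTS = {
    "oral_cavity": 6.6,
    "parotid_left": 3.6,
    "parotid_right": 3.6,
    "submandibular_left": 7.6,
    "submandibular_right": 7.6,
    "pcm_superior": 6.6,
    "pcm_medius": 5.8,
    "pcm_inferior": 5.0,
}
_IMPT_INTERCEPTS = {
    "oral_cavity": 3.0,
    "parotid_left": 1.5,
    "parotid_right": 1.5,
    "submandibular_left": 4.0,
    "submandibular_right": 4.0,
    "pcm_superior": 3.0,
    "pcm_medius": 2.5,
    "pcm_inferior": 2.0,
}


def default_dose_truth(
    vmat_noise_sd: float = 2.5,
    impt_noise_sd: float = 1.5,
) -> dict[tuple[str, str], TrueDoseModel]:
    """Per-OAR/modality linear truths.

    Photon plans carry a sizeable dose bath (large intercepts, true
    margin 10 mm); proton plans conform tightly (small intercepts,
    steeper overlap slopes, true margin 5 mm).
    """
    truth: dict[tuple[str, str], TrueDoseModel] = {}
    for oar in OAR_NAMES:
        truth[(oar, "VMAT")] = TrueDoseModel(
            margin_mm=10.0,
            intercept=_VMAT_INTERCEPTS[oar],
            coef_in70=0.52,
            coef_in54_out70=0.36,
            noise_sd=vmat_noise_sd,
        )
        truth[(oar, "IMPT")] = TrueDoseModel(
            margin_mm=5.0,
            intercept=_IMPT_INTERCEPTS[oar],
            coef_in70=0.62,
            coef_in54_out70=0.40,
            noise_sd=impt_noise_sd,
        )
    return truth


def example_ntcp_models() -> dict[str, NTCPModel]:
    """Synthetic fixture NTCP model set (NOT clinical coefficients).

    Plausible logistic models: the dysphagia endpoints load on the oral
    cavity and the pharyngeal constrictors, the xerostomia endpoints on
    the salivary glands; grade ≥3 models are rarer events (more negative
    intercepts).  Baseline complaints add positive logit shifts.
    """
    return {
        "dysphagia_g2": NTCPModel(
            endpoint="dysphagia_g2",
            intercept=-2.6,
            dose_betas={
                "oral_cavity": 0.015,
                "pcm_superior": 0.025,
                "pcm_medius": 0.020,
                "pcm_inferior": 0.012,
            },
            baseline_covariate="baseline_dysphagia",
            baseline_betas={"grade0_1": 0.0, "grade2": 0.9, "grade3plus": 1.5},
        ),
        "dysphagia_g3": NTCPModel(
            endpoint="dysphagia_g3",
            intercept=-5.2,
            dose_betas={
                "oral_cavity": 0.012,
                "pcm_superior": 0.022,
                "pcm_medius": 0.018,
                "pcm_inferior": 0.012,
            },
            baseline_covariate="baseline_dysphagia",
            baseline_betas={"grade0_1": 0.0, "grade2": 1.0, "grade3plus": 1.6},
        ),
        "xerostomia_g2": NTCPModel(
            endpoint="xerostomia_g2",
            intercept=-1.8,
            dose_betas={
                "parotid_left": 0.025,
                "parotid_right": 0.025,
                "submandibular_left": 0.010,
                "submandibular_right": 0.010,
                "oral_cavity": 0.005,
            },
            baseline_covariate="baseline_xerostomia",
            baseline_betas={"none": 0.0, "a_bit": 0.5, "severe": 1.0},
        ),
        "xerostomia_g3": NTCPModel(
            endpoint="xerostomia_g3",
            intercept=-4.0,
            dose_betas={
                "parotid_left": 0.020,
                "parotid_right": 0.020,
                "submandibular_left": 0.008,
                "submandibular_right": 0.008,
                "oral_cavity": 0.004,
            },
            baseline_covariate="baseline_xerostomia",
            baseline_betas={"none": 0.0, "a_bit": 0.6, "severe": 1.2},
        ),
    }


@dataclass
class CohortSpec:
    """Parameters of the feature-level cohort generator."""

    n_patients: int = 151
    seed: int = 0
    margins: tuple[float, ...] = DEFAULT_MARGINS_MM
    dose_truth: Mapping[tuple[str, str], TrueDoseModel] = field(
        default_factory=default_dose_truth
    )
    geometry: Mapping[str, GeometryParams] = field(default_factory=default_geometry)
    patient_shift_sd: float = 10.0
    location_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"pharynx": 0.55, "larynx": 0.25, "others": 0.20}
    )
    baseline_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "baseline_xerostomia": {"none": 0.70, "a_bit": 0.25, "severe": 0.05},
            "baseline_dysphagia": {"grade0_1": 0.75, "grade2": 0.20, "grade3plus": 0.05},
        }
    )
    ntcp_models: Mapping[str, NTCPModel] = field(default_factory=example_ntcp_models)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    clamp_doses: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for name, freqs in {
            "location_freqs": self.location_freqs,
            **{f"baseline_freqs[{k}]": v for k, v in self.baseline_freqs.items()},
        }.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1, got {total}")
        for (oar, modality), model in self.dose_truth.items():
            if model.margin_mm not in self.margins:
                raise ValidationError(
                    f"true margin {model.margin_mm} of {oar}/{modality} "
                    "not on the margin grid"
                )

    def noiseless(self) -> "CohortSpec":
        """Copy of the spec with all dose noise removed."""
        truth = {
            key: TrueDoseModel(
                m.margin_mm, m.intercept, m.coef_in70, m.coef_in54_out70, 0.0
            )
            for key, m in self.dose_truth.items()
        }
        return CohortSpec(
            n_patients=self.n_patients,
            seed=self.seed,
            margins=self.margins,
            dose_truth=truth,
            geometry=self.geometry,
            patient_shift_sd=self.patient_shift_sd,
            location_freqs=self.location_freqs,
            baseline_freqs=self.baseline_freqs,
            ntcp_models=self.ntcp_models,
            thresholds=self.thresholds,
            clamp_doses=self.clamp_doses,
        )


@dataclass
class SyntheticCohort:
    """Generated cohort tables (interface-identical to real-data inputs)."""

    spec: CohortSpec
    features: pd.DataFrame  # patient_id, oar, margin_mm, pct_in70, pct_in54_out70, absent
    dmeans: pd.DataFrame    # patient_id, oar, modality, dmean_gy (actual plans)
    baseline: pd.DataFrame  # patient_id, baselines, tumor_location, treatment_order
    labels: pd.DataFrame    # patient_id, actual_qualifies, criteria


def _containment_curves(
    margins: np.ndarray,
    d70: float,
    gap: float,
    amp: float,
    slope: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(pct_in70, pct_in54_out70) over the margin grid; both >= 0,
    pct_in70 non-decreasing, sum <= 100."""
    p70 = 100.0 * amp * norm.cdf((margins - d70) / slope)
    p54 = 100.0 * amp * norm.cdf((margins - (d70 - gap)) / slope)
    return p70, p54 - p70


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    margins = np.asarray(sorted(set(spec.margins)), dtype=float)
    loc_names = list(spec.location_freqs)
    loc_probs = np.array([spec.location_freqs[k] for k in loc_names])

    feature_rows, dose_rows, base_rows, label_rows = [], [], [], []
    for idx in range(spec.n_patients):
        pid = f"sim_{idx:04d}"
        location = loc_names[rng.choice(len(loc_names), p=loc_probs)]
        shift = rng.normal(0.0, spec.patient_shift_sd)
        curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for oar in OAR_NAMES:
            geom = spec.geometry[oar]
            d70 = rng.normal(
                geom.d70_mean + LOCATION_SHIFTS[location].get(oar, 0.0) + shift,
                geom.d70_sd,
            )
            gap = rng.uniform(*geom.gap_range)
            amp = rng.uniform(*geom.amp_range)
            p70, p54o70 = _containment_curves(margins, d70, gap, amp, geom.slope_mm)
            curves[oar] = (p70, p54o70)
            for j, margin in enumerate(margins):
                feature_rows.append(
                    {
                        "patient_id": pid,
                        "oar": oar,
                        "margin_mm": float(margin),
                        "pct_in70": float(p70[j]),
                        "pct_in54_out70": float(p54o70[j]),
                        "absent": False,
                    }
                )
        actual: dict[str, dict[str, float]] = {"VMAT": {}, "IMPT": {}}
        for oar in OAR_NAMES:
            for modality in ("VMAT", "IMPT"):
                truth = spec.dose_truth[(oar, modality)]
                k = int(np.searchsorted(margins, truth.margin_mm))
                p70, p54o70 = curves[oar]
                dose = truth.mean(p70[k], p54o70[k]) + rng.normal(0.0, 1.0) * truth.noise_sd
                if spec.clamp_doses:
                    dose = min(max(dose, 0.0), 70.0)
                actual[modality][oar] = float(dose)
                dose_rows.append(
                    {
                        "patient_id": pid,
                        "oar": oar,
                        "modality": modality,
                        "dmean_gy": float(dose),
                    }
                )
        covariates = {}
        for cov, levels in BASELINE_LEVELS.items():
            probs = np.array([spec.baseline_freqs[cov][lvl] for lvl in levels])
            covariates[cov] = levels[rng.choice(len(levels), p=probs)]
        base_rows.append(
            {
                "patient_id": pid,
                **covariates,
                "tumor_location": location,
                "treatment_order": idx,
            }
        )
        prof_vmat = ntcp_profile(spec.ntcp_models, actual["VMAT"], covariates)
        prof_impt = ntcp_profile(spec.ntcp_models, actual["IMPT"], covariates)
        decision = decide(delta_profile(prof_vmat, prof_impt), spec.thresholds)
        label_rows.append(
            {
                "patient_id": pid,
                "actual_qualifies": decision.qualifies,
                "criteria": "|".join(decision.triggered_criteria),
            }
        )

    return SyntheticCohort(
        spec=spec,
        features=pd.DataFrame(feature_rows),
        dmeans=pd.DataFrame(dose_rows),
        baseline=pd.DataFrame(base_rows),
        labels=pd.DataFrame(label_rows),
    )
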