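"""Structure masks, physical margin expansion and target-overlap features.

The decision support tool works from delineation geometry alone: for every
organ at risk (OAR) it measures which fraction of the organ volume falls
inside the high-dose target (PTV_7000) and inside the elective target
(PTV_5425) after both targets have been expanded by a physical margin that
emulates the dose penumbra.  Two features result per OAR and margin:

``pct_in70``
    % of the OAR volume inside the margin-expanded PTV_7000.
``pct_in54_out70``
    % of the OAR volume inside the margin-expanded PTV_5425 but outside
    the margin-expanded PTV_7000.

Margins are Euclidean distances in millimetres between voxel centers,
honouring anisotropic voxel spacing (CT slices are typically thicker than
in-plane pixels); expansion is fully 3-D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DegenerateInputError, ValidationError

#: Canonical organ-at-risk names of the four-model NTCP set, in the fixed
#: reporting order used throughout the package.
OAR_NAMES: tuple[str, ...] = (
    "oral_cavity",
    "parotid_left",
    "parotid_right",
    "submandibular_left",
    "submandibular_right",
    "pcm_superior",
    "pcm_medius",
    "pcm_inferior",
)

TARGET_HIGH = "PTV_7000"  # 70 Gy prescription
TARGET_LOW = "PTV_5425"   # 54.25 Gy prescription
TARGET_NAMES: tuple[str, str] = (TARGET_HIGH, TARGET_LOW)

#: Margin grid (mm) over which the dose models are screened.
DEFAULT_MARGINS_MM: tuple[float, ...] = (0.0, 3.0, 5.0, 7.0, 10.0, 15.0)

# Absolute slack (mm) on the voxel-center distance criterion; guards
# against float rounding at exact-tie distances, far below any spacing.
_DIST_TOL_MM = 1e-6


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel lattice with physical spacing.

    Parameters
    ----------
    shape
        Voxels per axis, matching ``numpy`` array index order.
    spacing
        Millimetres per voxel along each axis (all > 0).
    origin
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValidationError("VoxelGrid requires 3-component shape/spacing/origin")
        if any(int(s) != s or s < 1 for s in self.shape):
            raise ValidationError(f"grid shape must be positive integers, got {self.shape}")
        if any(not (sp > 0) for sp in self.spacing):
            raise ValidationError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinates along each axis (mm)."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        )


def _check_mask(mask: np.ndarray, grid: VoxelGrid, name: str = "mask") -> np.ndarray:
    arr = np.asarray(mask)
    if arr.shape != grid.shape:
        raise ValidationError(
            f"{name} shape {arr.shape} does not match grid shape {grid.shape}"
        )
    return arr.astype(bool, copy=False)


def expand_mask(mask: np.ndarray, grid: VoxelGrid, margin_mm: float) -> np.ndarray:
    """Dilate a binary mask by a physical margin.

    A voxel belongs to the result iff its center lies within Euclidean
    distance ``margin_mm`` (in mm, anisotropic spacing honoured) of the
    center of some voxel in the input mask.  The result therefore always
    contains the input.
    """
    arr = _check_mask(mask, grid)
    if margin_mm < 0:
        raise ValidationError(f"margin_mm must be >= 0, got {margin_mm}")
    if margin_mm == 0 or not arr.any():
        return arr.copy()
    dist = ndimage.distance_transform_edt(~arr, sampling=grid.spacing)
    return dist <= margin_mm + _DIST_TOL_MM


def overlap_percentages(
    oar_mask: np.ndarray,
    ptv70_expanded: np.ndarray,
    ptv54_expanded: np.ndarray,
    grid: VoxelGrid,
) -> tuple[float, float]:
    """Overlap-volume percentages of an OAR with the two expanded targets.

    Returns ``(pct_in70, pct_in54_out70)`` by voxel counting (uniform
    voxel volume).  Raises :class:`DegenerateInputError` on an empty OAR.
    """
    oar = _check_mask(oar_mask, grid, "oar_mask")
    p70 = _check_mask(ptv70_expanded, grid, "ptv70_expanded")
    p54 = _check_mask(ptv54_expanded, grid, "ptv54_expanded")
    n_oar = int(oar.sum())
    if n_oar == 0:
        raise DegenerateInputError("overlap percentages undefined for empty OAR mask")
    n_in70 = int((oar & p70).sum())
    n_in54_out70 = int((oar & p54 & ~p70).sum())
    return 100.0 * n_in70 / n_oar, 100.0 * n_in54_out70 / n_oar


class StructureSet:
    """A voxel grid plus named binary masks for targets and OARs.

    The two targets ``PTV_7000`` and ``PTV_5425`` are required.  At load
    time ``PTV_5425`` is replaced by its union with ``PTV_7000`` so the
    "inside the elective target but outside the boost target" feature is
    well defined even when input masks are exclusive rings (the clinical
    targets are nested).  OARs absent in a patient (e.g. a resected
    gland) are declared through ``absent`` and carried explicitly rather
    than silently dropped.
    """

    def __init__(
        self,
        grid: VoxelGrid,
        masks: Mapping[str, np.ndarray],
        absent: Iterable[str] = (),
        allow_extra: bool = False,
    ) -> None:
        self.grid = grid
        self.absent = frozenset(absent)
        known = set(OAR_NAMES) | set(TARGET_NAMES)
        checked: dict[str, np.ndarray] = {}
        for name, mask in masks.items():
            if not allow_extra and name not in known:
                raise ValidationError(f"unknown structure name {name!r}")
            checked[name] = _check_mask(mask, grid, name).copy()
        for target in TARGET_NAMES:
            if target not in checked:
                raise ValidationError(f"required target {target!r} missing")
        for name in self.absent:
            if name not in OAR_NAMES:
                raise ValidationError(f"absent flag on non-OAR name {name!r}")
        # nested targets: elective target includes the boost target
        checked[TARGET_LOW] = checked[TARGET_LOW] | checked[TARGET_HIGH]
        for name in OAR_NAMES:
            if name in checked and name not in self.absent and not checked[name].any():
                raise ValidationError(
                    f"OAR {name!r} mask is empty; declare it absent explicitly"
                )
        self.masks = checked

    @property
    def oars(self) -> tuple[str, ...]:
        """Present OAR names in canonical order."""
        return tuple(n for n in OAR_NAMES if n in self.masks and n not in self.absent)

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


def extract_features(
    structures: StructureSet,
    margins: Sequence[float] = DEFAULT_MARGINS_MM,
    patient_id: str | None = None,
) -> pd.DataFrame:
    """Overlap features for every OAR at every expansion margin.

    Both targets are expanded by each margin and
    :func:`overlap_percentages` is evaluated for every OAR present in the
    canonical set.  Absent OARs yield rows with ``absent=True`` and NaN
    percentages.  Row order is canonical OAR order, then ascending margin.
    """
    margins = [float(m) for m in margins]
    if not margins:
        raise ValidationError("margins must be non-empty")
    if any(m < 0 for m in margins):
        raise ValidationError("margins must be >= 0")
    covered = [n for n in OAR_NAMES if n in structures.masks or n in structures.absent]
    if not covered:
        raise ValidationError("structure set contains no OAR")

    grid = structures.grid
    by_margin: dict[float, dict[str, tuple[float, float]]] = {}
    for margin in sorted(set(margins)):
        p70 = expand_mask(structures[TARGET_HIGH], grid, margin)
        p54 = expand_mask(structures[TARGET_LOW], grid, margin)
        row: dict[str, tuple[float, float]] = {}
        for oar in covered:
            if oar in structures.absent:
                continue
            row[oar] = overlap_percentages(structures[oar], p70, p54, grid)
        by_margin[margin] = row

    records = []
    for oar in covered:
        for margin in sorted(set(margins)):
            absent = oar in structures.absent
            p70pct, p54pct = (np.nan, np.nan) if absent else by_margin[margin][oar]
            rec = {
                "oar": oar,
                "margin_mm": margin,
                "pct_in70": p70pct,
                "pct_in54_out70": p54pct,
                "absent": absent,
            }
            if patient_id is not None:
                rec = {"patient_id": patient_id, **rec}
            records.append(rec)
    return pd.DataFrame.from_records(records)
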