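"""Mask and manifest I/O.

Masks are single-label binary volumes in NRRD (``.nrrd``) or NIfTI
(``.nii``/``.nii.gz``), one file per structure, read and written through
SimpleITK.  Arrays use numpy index order; SimpleITK stores spacing and
origin in (x, y, z) order, so both are reversed on the way in and out.

A YAML/JSON manifest maps structure names to files:

.. code-block:: yaml

    patients:
      - patient_id: p001
        structures:
          PTV_7000: p001/ptv70.nrrd
          parotid_left: p001/parotid_l.nii.gz
        absent: [submandibular_left]

Paths are resolved relative to the manifest file.  A single-patient
manifest (top-level ``structures``) is also accepted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from .exceptions import ValidationError
from .structures import StructureSet, VoxelGrid


def read_mask(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a binary mask volume; non-zero voxels are foreground."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"mask file not found: {path}")
    image = sitk.ReadImage(str(path))
    array = sitk.GetArrayFromImage(image) != 0
    grid = VoxelGrid(
        shape=array.shape,
        spacing=tuple(reversed(image.GetSpacing())),
        origin=tuple(reversed(image.GetOrigin())),
    )
    return array, grid


def write_mask(path: str | Path, mask: np.ndarray, grid: VoxelGrid) -> None:
    image = sitk.GetImageFromArray(np.asarray(mask, dtype=np.uint8))
    image.SetSpacing(tuple(reversed(grid.spacing)))
    image.SetOrigin(tuple(reversed(grid.origin)))
    sitk.WriteImage(image, str(path))


def _load_config(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_manifest(path: str | Path) -> list[tuple[str, StructureSet]]:
    """Load all patients of a mask manifest into structure sets.

    All masks of one patient must share the same grid (shape and spacing);
    resampling to a common grid is upstream of this package.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"manifest not found: {path}")
    doc = _load_config(path)
    if not isinstance(doc, dict):
        raise ValidationError("manifest must be a mapping")
    if "structures" in doc:
        entries = [doc]
    else:
        entries = doc.get("patients")
        if not isinstance(entries, list) or not entries:
            raise ValidationError("manifest must define 'patients' or 'structures'")

    out: list[tuple[str, StructureSet]] = []
    for i, entry in enumerate(entries):
        patient_id = str(entry.get("patient_id", f"patient_{i}"))
        mapping = entry.get("structures")
        if not isinstance(mapping, dict) or not mapping:
            raise ValidationError(f"patient {patient_id!r}: no structures mapping")
        masks: dict[str, np.ndarray] = {}
        grid: VoxelGrid | None = None
        for name, rel in mapping.items():
            mask, mask_grid = read_mask(path.parent / rel)
            if grid is None:
                grid = mask_grid
            elif mask_grid.shape != grid.shape or not np.allclose(
                mask_grid.spacing, grid.spacing
            ):
                raise ValidationError(
                    f"patient {patient_id!r}: structure {name!r} is on a different "
                    "grid; masks must be pre-resampled to a shared grid"
                )
            masks[name] = mask
        assert grid is not None
        out.append(
            (patient_id, StructureSet(grid, masks, absent=entry.get("absent", ())))
        )
    return out
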