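"""Volumetric grids: the common carrier for CT, MR, normalized images, doses.

A :class:`VolumeGrid` is a 3-D scalar field with axis order ``(slice, row,
column)``, voxel spacing in mm per axis and a world origin at the center of
voxel ``(0, 0, 0)``.  World coordinates are in mm; indexing is 0-based.
Modalities carry their physical range invariants (CT in Hounsfield units,
normalized images in [-1, 1], doses non-negative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0


class Modality(str, Enum):
    CT_HU = "CT_HU"
    MR_AU = "MR_AU"
    NORMALIZED = "NORMALIZED"
    DOSE_GY = "DOSE_GY"
    DENSITY = "DENSITY"


@dataclass
class VolumeGrid:
    """3-D scalar field with geometry metadata.

    Parameters
    ----------
    values:
        Array of shape ``(n_slices, n_rows, n_cols)``.
    spacing:
        mm per axis, same order as ``values`` axes; all components positive.
    origin:
        World mm coordinate of the center of voxel (0, 0, 0).
    modality:
        Physical interpretation of ``values``; range invariants are enforced.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.CT_HU

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3-D values, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        self.modality = Modality(self.modality)
        self._check_range()

    def _check_range(self) -> None:
        v = self.values
        if self.modality is Modality.CT_HU:
            if v.size and (v.min() < HU_MIN - 1e-6 or v.max() > HU_MAX + 1e-6):
                raise ValueError("CT_HU values outside [-1024, 3071]")
        elif self.modality is Modality.NORMALIZED:
            if v.size and (v.min() < -1 - 1e-6 or v.max() > 1 + 1e-6):
                raise ValueError("NORMALIZED values outside [-1, 1]")
        elif self.modality is Modality.DOSE_GY:
            if v.size and v.min() < -1e-9:
                raise ValueError("DOSE_GY values must be >= 0")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world mm coordinates of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, modality: Modality | None = None) -> "VolumeGrid":
        return replace(self, values=values, modality=modality or self.modality)

    # -- NIfTI I/O --------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        # nibabel expects (x, y, z) = (col, row, slice)
        data = np.ascontiguousarray(self.values.transpose(2, 1, 0))
        affine = np.diag([self.spacing[2], self.spacing[1], self.spacing[0], 1.0])
        affine[:3, 3] = [self.origin[2], self.origin[1], self.origin[0]]
        img = nib.Nifti1Image(data.astype(np.float32), affine)
        img.header.set_xyzt_units("mm")
        img.header["descrip"] = self.modality.value.encode()
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, modality: Modality | None = None) -> "VolumeGrid":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected 3-D NIfTI, got {data.ndim}-D")
        aff = img.affine
        spacing = (abs(aff[2, 2]), abs(aff[1, 1]), abs(aff[0, 0]))
        origin = (aff[2, 3], aff[1, 3], aff[0, 3])
        if modality is None:
            desc = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
            try:
                modality = Modality(desc)
            except ValueError:
                modality = Modality.CT_HU
        return cls(data.transpose(2, 1, 0), spacing, origin, modality)


@dataclass
class LabelGrid:
    """Integer tissue labels on a :class:`VolumeGrid` geometry."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from legend")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, name: str) -> np.ndarray:
        """Binary mask of all labels whose legend entry equals ``name``."""
        ids = [k for k, v in self.legend.items() if v == name]
        if not ids:
            raise KeyError(f"tissue {name!r} not in legend")
        return np.isin(self.labels, ids)

    def to_nifti(self, path: str | Path, legend_path: str | Path | None = None) -> None:
        vg = VolumeGrid(
            self.labels.astype(np.float64), self.spacing, self.origin, Modality.DENSITY
        )
        vg.to_nifti(path)
        if legend_path is not None:
            Path(legend_path).write_text(
                json.dumps({str(k): v for k, v in self.legend.items()}, indent=2)
            )

    @classmethod
    def from_nifti(cls, path: str | Path, legend_path: str | Path) -> "LabelGrid":
        vg = VolumeGrid.from_nifti(path, Modality.DENSITY)
        legend = {int(k): v for k, v in json.loads(Path(legend_path).read_text()).items()}
        return cls(np.rint(vg.values).astype(np.int32), vg.spacing, vg.origin, legend)
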