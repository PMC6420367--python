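"""3-D volume container shared by every imaging stage.

A :class:`VolumeGrid` wraps a numpy array plus voxel spacing and a semantic
``kind`` tag (activity, suvr, fraction, label, stat or mask).  Scalar volumes
use ``NaN`` to mark invalid voxels (e.g. voxels excluded by the tissue-fraction
floor of the partial-volume correction); label volumes are non-negative
integers with 0 meaning background.  All volumes entering one analysis must
share shape and spacing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

VOLUME_KINDS = ("activity", "suvr", "fraction", "label", "stat", "mask")


@dataclass
class VolumeGrid:
    """A 3-D scalar or integer-label image with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kind: str = "activity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        if self.kind not in VOLUME_KINDS:
            raise ValueError(f"unknown volume kind {self.kind!r}; expected one of {VOLUME_KINDS}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if self.kind in ("label", "mask"):
            if not np.issubdtype(self.values.dtype, np.integer):
                if not np.all(np.equal(np.mod(self.values, 1), 0)):
                    raise ValueError(f"{self.kind} volume must hold integers")
                self.values = self.values.astype(np.int32)
            if self.values.min() < 0:
                raise ValueError(f"{self.kind} volume must be non-negative")
        else:
            self.values = self.values.astype(np.float64)
            if self.kind == "fraction":
                finite = self.values[np.isfinite(self.values)]
                if finite.size and (finite.min() < 0 or finite.max() > 1):
                    raise ValueError("fraction volume must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of valid (finite) voxels; all-true for integer volumes."""
        if np.issubdtype(self.values.dtype, np.integer):
            return np.ones(self.values.shape, dtype=bool)
        return np.isfinite(self.values)

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "VolumeGrid":
        return VolumeGrid(values, spacing=self.spacing, kind=kind or self.kind)

    # ------------------------------------------------------------------ I/O
    def save(self, path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        data = self.values
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.int32)
        nib.save(nib.Nifti1Image(data, affine), str(path))

    @classmethod
    def load(cls, path, kind: str = "activity") -> "VolumeGrid":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if kind in ("label", "mask"):
            data = np.rint(np.asarray(data)).astype(np.int32)
        return cls(data, spacing=spacing, kind=kind)


def check_common_grid(*volumes: VolumeGrid) -> None:
    """Raise if the volumes do not share one shape and spacing."""
    first = volumes[0]
    for v in volumes[1:]:
        if not first.same_grid(v):
            raise ValueError(
                f"volumes must share shape and spacing: {first.shape}/{first.spacing} "
                f"vs {v.shape}/{v.spacing}"
            )
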