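"""Voxel-grid containers shared by the whole pipeline.

All geometry is physical and lives in micrometres (μm).  The convention is
voxel-centred: the physical position of voxel index ``(i, j, k)`` is
``origin_um + (i, j, k) * spacing_um``, with 0-based indices.  Every
measurement downstream (lengths, volumes, centres of mass, registration)
is expressed in these physical coordinates, so anisotropic voxels are
handled transparently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledVolume", "BinaryMask"]


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.broadcast_to(np.asarray(x, dtype=float), (3,)).copy()
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return v


@dataclass
class LabeledVolume:
    """A segmented 3D volume: one non-negative integer label per voxel.

    Parameters
    ----------
    labels
        3D integer array; 0 is background.
    spacing_um
        Physical voxel size per axis in μm (scalar broadcasts to all axes).
    origin_um
        Physical coordinate of the centre of voxel ``(0, 0, 0)``.
    label_names
        Optional map from label integer to organ name
        (e.g. ``{1: "scala_media"}``).
    """

    labels: np.ndarray
    spacing_um: np.ndarray
    origin_um: np.ndarray = None  # type: ignore[assignment]
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.bool_):
                self.labels = self.labels.astype(np.uint8)
            else:
                raise ValueError(
                    "labels must be an integer array (got "
                    f"{self.labels.dtype}); grayscale volumes are not labels"
                )
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing_um = _as_vec3(self.spacing_um, "spacing_um")
        if np.any(self.spacing_um <= 0):
            raise ValueError(f"spacing_um must be strictly positive, got {self.spacing_um}")
        if self.origin_um is None:
            self.origin_um = np.zeros(3)
        self.origin_um = _as_vec3(self.origin_um, "origin_um")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    def physical_points(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (μm) of voxel indices, shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin_um + idx * self.spacing_um

    def indices_of(self, points_um: np.ndarray) -> np.ndarray:
        """Nearest voxel indices of physical points; not bounds-checked."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        return np.rint((pts - self.origin_um) / self.spacing_um).astype(np.int64)

    def present_labels(self) -> np.ndarray:
        """Sorted array of nonzero labels present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]

    def name_of(self, label: int) -> str:
        return self.label_names.get(int(label), f"label_{int(label)}")


@dataclass
class BinaryMask:
    """A single-structure boolean mask with the same spatial conventions
    as :class:`LabeledVolume`."""

    mask: np.ndarray
    spacing_um: np.ndarray
    origin_um: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.mask.shape}")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        self.spacing_um = _as_vec3(self.spacing_um, "spacing_um")
        if np.any(self.spacing_um <= 0):
            raise ValueError(f"spacing_um must be strictly positive, got {self.spacing_um}")
        if self.origin_um is None:
            self.origin_um = np.zeros(3)
        self.origin_um = _as_vec3(self.origin_um, "origin_um")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    def count(self) -> int:
        return int(self.mask.sum())

    def volume_um3(self) -> float:
        """Foreground voxel count times physical voxel volume."""
        return self.count() * self.voxel_volume_um3

    def physical_points(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin_um + idx * self.spacing_um

    def with_mask(self, mask: np.ndarray) -> "BinaryMask":
        """Same grid geometry, new voxel values."""
        return BinaryMask(mask=mask, spacing_um=self.spacing_um.copy(), origin_um=self.origin_um.copy())
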