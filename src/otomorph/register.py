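"""Rigid 2D-section-to-3D-volume registration by label overlap.

A semi-thin histological section carries label masks (scala media,
vestibuli, tympani); the same compartments are labeled in the micro-CT
volume.  The section's pixel plane is mapped into volume physical space
by a 6-DOF rigid transform; registration refines a caller-supplied rough
("manual pre-alignment") transform by derivative-free local optimization
of the mean Dice overlap between the section and the corresponding
virtual slice of the volume.  Labels are categorical, so the volume is
sampled with nearest-neighbour interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .grids import LabeledVolume

__all__ = [
    "RigidTransform3D",
    "SectionImage",
    "RegistrationResult",
    "RegistrationOptions",
    "sample_plane",
    "overlap_score",
    "register_section",
    "apply_transform",
]


@dataclass
class RigidTransform3D:
    """6-DOF rotation + translation mapping section-plane coordinates
    ``(u * px, v * px, 0)`` (μm) into volume physical space (μm).

    The rotation is stored as a unit quaternion in scipy's scalar-last
    ``(x, y, z, w)`` order.
    """

    quaternion: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))
    translation_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternion, dtype=float)
        if q.shape != (4,):
            raise ValueError("quaternion must have shape (4,) in (x, y, z, w) order")
        n = np.linalg.norm(q)
        if n == 0:
            raise ValueError("quaternion must be nonzero")
        self.quaternion = q / n
        self.translation_um = np.asarray(self.translation_um, dtype=float).reshape(3)

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls()

    @classmethod
    def from_rotvec(cls, rotvec_rad, translation_um=(0.0, 0.0, 0.0)) -> "RigidTransform3D":
        """Axis-angle rotation (radians) + translation (μm)."""
        r = Rotation.from_rotvec(np.asarray(rotvec_rad, dtype=float))
        return cls(quaternion=r.as_quat(), translation_um=np.asarray(translation_um, dtype=float))

    @classmethod
    def from_matrix(cls, matrix, translation_um=(0.0, 0.0, 0.0)) -> "RigidTransform3D":
        r = Rotation.from_matrix(np.asarray(matrix, dtype=float))
        return cls(quaternion=r.as_quat(), translation_um=np.asarray(translation_um, dtype=float))

    # -- algebra -----------------------------------------------------------

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to 3D points, shape (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return self.rotation.apply(pts.reshape(-1, 3)).reshape(pts.shape) + self.translation_um

    def compose(self, other: "RigidTransform3D") -> "RigidTransform3D":
        """self ∘ other: apply ``other`` first, then ``self``."""
        r = self.rotation * other.rotation
        t = self.rotation.apply(other.translation_um) + self.translation_um
        return RigidTransform3D(quaternion=r.as_quat(), translation_um=t)

    def inverse(self) -> "RigidTransform3D":
        rinv = self.rotation.inv()
        return RigidTransform3D(
            quaternion=rinv.as_quat(), translation_um=-rinv.apply(self.translation_um)
        )

    def rotation_angle_to(self, other: "RigidTransform3D") -> float:
        """Relative rotation magnitude in degrees."""
        rel = self.rotation.inv() * other.rotation
        return float(np.degrees(rel.magnitude()))


@dataclass
class SectionImage:
    """A 2D labeled section: integer label per pixel, square pixels.

    Pixel ``(u, v)`` sits at plane coordinate ``(u * pixel_spacing_um,
    v * pixel_spacing_um, 0)``.
    """

    labels: np.ndarray
    pixel_spacing_um: float
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"section labels must be 2D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("section labels must be integers")
        self.pixel_spacing_um = float(self.pixel_spacing_um)
        if self.pixel_spacing_um <= 0:
            raise ValueError("pixel_spacing_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def plane_center_um(self) -> np.ndarray:
        """Plane coordinate (μm) of the image centre, z = 0."""
        nu, nv = self.shape
        return np.array([(nu - 1) / 2.0 * self.pixel_spacing_um, (nv - 1) / 2.0 * self.pixel_spacing_um, 0.0])

    def present_labels(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]


def apply_transform(
    t: RigidTransform3D, points_2d: np.ndarray, pixel_spacing_um: float
) -> np.ndarray:
    """Map section pixel coordinates (u, v) into volume physical space (μm)."""
    px = np.atleast_2d(np.asarray(points_2d, dtype=float))
    plane = np.zeros((len(px), 3))
    plane[:, :2] = px * pixel_spacing_um
    return t.apply(plane)


def sample_plane(
    vol: LabeledVolume,
    t: RigidTransform3D,
    extent_px: tuple[int, int],
    pixel_spacing_um: float,
) -> SectionImage:
    """Virtual section: nearest-neighbour sampling of the volume's labels
    at the transformed pixel centres; out-of-volume pixels are background."""
    nu, nv = int(extent_px[0]), int(extent_px[1])
    uu, vv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    px = np.stack([uu.ravel(), vv.ravel()], axis=1)
    pts = apply_transform(t, px, pixel_spacing_um)
    idx = np.rint((pts - vol.origin_um) / vol.spacing_um).astype(np.int64)
    shape = np.array(vol.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(nu * nv, dtype=vol.labels.dtype)
    out[ok] = vol.labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return SectionImage(
        labels=out.reshape(nu, nv),
        pixel_spacing_um=float(pixel_spacing_um),
        label_names=dict(vol.label_names),
    )


def overlap_score(
    a: SectionImage, b: SectionImage, labels: list[int] | None = None
) -> tuple[dict[int, float], float]:
    """Per-label Dice overlap and its mean over the requested labels.

    Dice = 2|A∩B| / (|A| + |B|); a label empty in both images scores 1 by
    convention.  Requires identical grids and pixel spacing.
    """
    if a.shape != b.shape:
        raise ValueError(f"section grids differ: {a.shape} vs {b.shape}")
    if not np.isclose(a.pixel_spacing_um, b.pixel_spacing_um):
        raise ValueError(
            f"pixel spacings differ: {a.pixel_spacing_um} vs {b.pixel_spacing_um}"
        )
    if labels is None:
        labels = sorted(set(a.present_labels().tolist()) | set(b.present_labels().tolist()))
        if not labels:
            labels = [1]
    dice: dict[int, float] = {}
    for lab in labels:
        ma = a.labels == lab
        mb = b.labels == lab
        denom = int(ma.sum()) + int(mb.sum())
        if denom == 0:
            dice[int(lab)] = 1.0
        else:
            dice[int(lab)] = 2.0 * int((ma & mb).sum()) / denom
    return dice, float(np.mean(list(dice.values())))


@dataclass
class RegistrationOptions:
    """Nelder-Mead settings for the fine-alignment search.

    The search runs in stages with shrinking initial simplexes (degrees,
    voxel multiples), which makes the piecewise-constant Dice objective
    tractable without any global search.
    """

    stage_steps: tuple[tuple[float, float], ...] = (
        (6.0, 6.0),
        (3.0, 3.0),
        (1.5, 1.5),
        (0.75, 0.75),
        (0.3, 0.3),
        (0.12, 0.12),
    )
    max_iter_per_stage: int = 600
    xatol: float = 1e-3
    fatol: float = 1e-5


@dataclass
class RegistrationResult:
    transform: RigidTransform3D
    mean_dice: float
    dice_per_label: dict[int, float]
    trace: list[float]
    n_evaluations: int
    improved: bool


def register_section(
    vol: LabeledVolume,
    section: SectionImage,
    init: RigidTransform3D,
    labels: list[int] | None = None,
    opts: RegistrationOptions | None = None,
) -> RegistrationResult:
    """Refine a rough section-to-volume transform by maximizing mean Dice.

    ``init`` is the manual pre-alignment: its plane must already overlap
    the labeled region (zero overlap raises).  The optimizer perturbs a
    rotation (about the section centre) and a translation; it is local,
    derivative-free (Nelder-Mead) and deterministic given ``init`` and
    ``opts``.  If no candidate improves on ``init``, the initial transform
    is returned with a warning.
    """
    if opts is None:
        opts = RegistrationOptions()
    if labels is None:
        labels = sorted(section.present_labels().tolist())
        if not labels:
            raise ValueError("section contains no labels to register")
    c_plane = section.plane_center_um()
    voxel = float(np.min(vol.spacing_um))

    def transform_from_params(x: np.ndarray) -> RigidTransform3D:
        rot = Rotation.from_rotvec(x[:3])
        r = init.rotation * rot
        # Rotate about the section centre so rotation and translation stay
        # decoupled; then add the translation offset.
        c_world = init.apply(c_plane)
        t = c_world + x[3:] - r.apply(c_plane)
        return RigidTransform3D(quaternion=r.as_quat(), translation_um=t)

    trace: list[float] = []
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        cand = transform_from_params(x)
        virt = sample_plane(vol, cand, section.shape, section.pixel_spacing_um)
        _, mean_dice = overlap_score(section, virt, labels)
        best = trace[-1] if trace else -np.inf
        trace.append(max(best, mean_dice))
        return -mean_dice

    f0 = -objective(np.zeros(6))
    init_virt = sample_plane(vol, init, section.shape, section.pixel_spacing_um)
    inter = sum(
        int(((section.labels == lab) & (init_virt.labels == lab)).sum()) for lab in labels
    )
    if inter == 0:
        raise ValueError(
            "no label overlap at the initial transform; improve the manual "
            "pre-alignment before fine registration"
        )

    x_best = np.zeros(6)
    f_best = f0
    for rot_step_deg, trans_step_vox in opts.stage_steps:
        simplex = np.tile(x_best, (7, 1))
        for d in range(3):
            simplex[d + 1, d] += np.deg2rad(rot_step_deg)
            simplex[d + 4, d + 3] += trans_step_vox * voxel
        res = minimize(
            objective,
            x_best,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxiter": opts.max_iter_per_stage,
                "xatol": opts.xatol,
                "fatol": opts.fatol,
            },
        )
        if -res.fun > f_best:
            f_best = -res.fun
            x_best = res.x
    improved = f_best > f0
    if not improved:
        warnings.warn(
            "registration did not improve on the initial transform; "
            "returning the pre-alignment",
            stacklevel=2,
        )
        x_best = np.zeros(6)
        f_best = f0
    best_t = transform_from_params(x_best)
    virt = sample_plane(vol, best_t, section.shape, section.pixel_spacing_um)
    dice_per_label, mean_dice = overlap_score(section, virt, labels)
    return RegistrationResult(
        transform=best_t,
        mean_dice=mean_dice,
        dice_per_label=dice_per_label,
        trace=trace,
        n_evaluations=n_eval,
        improved=improved,
    )
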