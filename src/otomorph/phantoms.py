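"""Synthetic labeled inner-ear volumes with analytically known geometry.

Real fetal inner-ear micro-CT segmentations are produced by manual,
slice-wise labeling and are not redistributable, so every stage of this
package is validated against voxel phantoms whose centerline length, tube
volume and organ centres are known in closed form (or by numerical
quadrature of a closed-form integrand).

The cochlear duct is modelled as a tapering tube swept along a conical
helico-spiral: the plan-view radius interpolates linearly in turn angle
from ``base_radius_um`` to ``apex_radius_um`` while the height rises
linearly (``pitch_um`` per full turn).  The duct lumen radius tapers
linearly along arc length.  The five vestibular sensory epithelia
(three cristae ampullares, utricular and saccular maculae) are spheres.

A voxel belongs to the duct iff the distance from its centre to the
analytic centerline is at most the local tube radius; voxelization
realises this by stamping balls along a densely sampled centerline with a
sampling step whose sagitta error is far below the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, ndimage
from scipy.spatial import cKDTree

from .centerline import Polyline3D
from .grids import LabeledVolume

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "DEFAULT_BLOB_CENTERS_UM",
    "DEFAULT_BLOB_RADII_UM",
    "VESTIBULAR_ORGANS",
    "spiral_arc_length",
    "spiral_tube_volume",
    "make_spiral_duct_phantom",
    "make_cylinder_phantom",
    "make_vestibular_phantom",
    "make_registration_fixture",
    "make_inner_ear_phantom",
    "make_blob_volume",
    "make_section_fixture",
]

VESTIBULAR_ORGANS = (
    "crista_anterior",
    "crista_lateral",
    "crista_posterior",
    "macula_utriculi",
    "macula_sacculi",
)

# Default organ layout: a compact vestibule sitting behind/above the coil,
# organ separations of roughly 0.7-1.5 mm as in mid-gestation specimens.
DEFAULT_BLOB_CENTERS_UM: dict[str, tuple[float, float, float]] = {
    "crista_anterior": (500.0, 2700.0, 1300.0),
    "crista_lateral": (1400.0, 2400.0, 500.0),
    "crista_posterior": (-400.0, 3100.0, 300.0),
    "macula_utriculi": (400.0, 2200.0, 400.0),
    "macula_sacculi": (-300.0, 1900.0, 1200.0),
}
DEFAULT_BLOB_RADII_UM: dict[str, float] = {
    "crista_anterior": 180.0,
    "crista_lateral": 170.0,
    "crista_posterior": 190.0,
    "macula_utriculi": 250.0,
    "macula_sacculi": 220.0,
}

DUCT_LABEL = 1
_ORGAN_LABELS = {name: i + 2 for i, name in enumerate(VESTIBULAR_ORGANS)}


@dataclass
class PhantomSpec:
    """Parametric description of a spiral cochlear duct plus vestibular
    sensory organs.

    Geometry defaults describe a mid-gestation-scale duct: 2.5 turns,
    plan radius tapering 2000 -> 500 μm, 400 μm rise per turn, lumen
    radius tapering 150 -> 70 μm, voxelized at 10 μm isotropic spacing.
    """

    n_turns: float = 2.5
    base_radius_um: float = 2000.0
    apex_radius_um: float = 500.0
    pitch_um: float = 400.0
    tube_radius_base_um: float = 150.0
    tube_radius_apex_um: float = 70.0
    voxel_spacing_um: float = 10.0
    blob_centers_um: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BLOB_CENTERS_UM)
    )
    blob_radii_um: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BLOB_RADII_UM))
    seed: int = 0
    jitter_p: float = 0.0
    margin_voxels: int = 10
    spacing_range_um: tuple[float, float] = (4.67, 14.50)

    def __post_init__(self) -> None:
        if self.n_turns < 0.25:
            raise ValueError(f"n_turns must be >= 0.25, got {self.n_turns}")
        if self.apex_radius_um > self.base_radius_um:
            raise ValueError("apex_radius_um must be <= base_radius_um")
        for name in (
            "base_radius_um",
            "apex_radius_um",
            "pitch_um",
            "tube_radius_base_um",
            "tube_radius_apex_um",
            "voxel_spacing_um",
        ):
            if getattr(self, name) <= 0 and name != "pitch_um":
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.pitch_um < 0:
            raise ValueError("pitch_um must be >= 0")
        lo, hi = self.spacing_range_um
        if not lo <= self.voxel_spacing_um <= hi:
            raise ValueError(
                f"voxel_spacing_um = {self.voxel_spacing_um} outside the allowed "
                f"range [{lo}, {hi}] μm"
            )
        if not 0.0 <= self.jitter_p < 1.0:
            raise ValueError("jitter_p must be in [0, 1)")

    # -- analytic spiral geometry -----------------------------------------

    @property
    def theta_max(self) -> float:
        return 2.0 * np.pi * self.n_turns

    def plan_radius(self, theta):
        """Plan-view spiral radius at turn angle theta (linear taper)."""
        t = np.asarray(theta, dtype=float) / self.theta_max
        return self.base_radius_um + (self.apex_radius_um - self.base_radius_um) * t

    def centerline_point(self, theta):
        theta = np.asarray(theta, dtype=float)
        r = self.plan_radius(theta)
        z = self.pitch_um * theta / (2.0 * np.pi)
        return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=-1)

    def speed(self, theta):
        """|d(centerline)/d theta|, the closed-form quadrature integrand."""
        r = self.plan_radius(theta)
        dr = (self.apex_radius_um - self.base_radius_um) / self.theta_max
        c = self.pitch_um / (2.0 * np.pi)
        return np.sqrt(dr * dr + r * r + c * c)


@dataclass
class PhantomGroundTruth:
    """Analytic truth stored alongside a generated phantom."""

    length_um: float
    volume_um3: float
    centerline: Polyline3D


# ---------------------------------------------------------------------------
# analytic quantities


def spiral_arc_length(spec: PhantomSpec, theta_end: float | None = None) -> float:
    """Arc length of the analytic spiral centerline by adaptive quadrature
    of the speed function (μm)."""
    end = spec.theta_max if theta_end is None else theta_end
    val, _ = integrate.quad(spec.speed, 0.0, end, limit=400)
    return float(val)


def _trim_bounds(spec: PhantomSpec, length: float) -> tuple[float, float]:
    """Arc-length positions of the blind-end cap centres.

    The duct solid ends blind (hemispherical caps), like the scala media;
    the swept tube is trimmed by one local radius at each end so the cap
    apexes coincide with the analytic curve endpoints and the solid spans
    exactly the analytic arc length.
    """
    rb, ra = spec.tube_radius_base_um, spec.tube_radius_apex_um

    def r_at(s: float) -> float:
        return rb + (ra - rb) * s / length

    s_lo = r_at(0.0)
    s_hi = length - r_at(length)
    for _ in range(8):  # fixed-point refinement; r varies slowly in s
        s_lo = r_at(s_lo)
        s_hi = length - r_at(s_hi)
    if s_hi <= s_lo:
        raise ValueError(
            "duct too short for its tube radius: the two blind-end caps overlap"
        )
    return s_lo, s_hi


def spiral_tube_volume(spec: PhantomSpec) -> float:
    """Analytic volume of the duct solid (μm^3).

    The solid is a circular tube with a linearly tapering radius swept
    along the trimmed centerline, closed by hemispherical caps whose
    apexes sit at the analytic curve endpoints: the swept-section integral
    pi * (s_hi - s_lo) * (r_lo^2 + r_lo*r_hi + r_hi^2) / 3 plus cap
    volumes (2/3) * pi * (r_lo^3 + r_hi^3)."""
    length = spiral_arc_length(spec)
    rb, ra = spec.tube_radius_base_um, spec.tube_radius_apex_um
    s_lo, s_hi = _trim_bounds(spec, length)
    r_lo = rb + (ra - rb) * s_lo / length
    r_hi = rb + (ra - rb) * s_hi / length
    tube = np.pi * (s_hi - s_lo) * (r_lo * r_lo + r_lo * r_hi + r_hi * r_hi) / 3.0
    caps = 2.0 / 3.0 * np.pi * (r_lo**3 + r_hi**3)
    return float(tube + caps)


def _dense_spiral_samples(spec: PhantomSpec, step_um: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centerline points at ~equal arc-length steps.

    Returns (points (n,3), arc_lengths (n,), tube_radii (n,)).  Inverts the
    cumulative arc-length function on a fine angular grid.
    """
    n_fine = max(2000, int(200 * spec.n_turns))
    theta = np.linspace(0.0, spec.theta_max, n_fine)
    speed = spec.speed(theta)
    s_cum = integrate.cumulative_trapezoid(speed, theta, initial=0.0)
    total = s_cum[-1]
    n_samples = max(int(np.ceil(total / step_um)) + 1, int(np.ceil(50 * spec.n_turns)) + 1)
    s_target = np.linspace(0.0, total, n_samples)
    theta_at_s = np.interp(s_target, s_cum, theta)
    pts = spec.centerline_point(theta_at_s)
    rb, ra = spec.tube_radius_base_um, spec.tube_radius_apex_um
    radii = rb + (ra - rb) * s_target / total
    return pts, s_target, radii


# ---------------------------------------------------------------------------
# voxelization helpers


def _stamp_balls(
    points: np.ndarray,
    radii: np.ndarray,
    spacing: float,
    margin_voxels: int,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
    out: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Union of balls on a voxel grid; returns (mask, origin_um).

    The grid is voxel-centred: voxel (0,0,0) sits at ``origin``.  If a grid
    is not supplied it is sized to enclose the balls plus a margin.
    """
    points = np.atleast_2d(points)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(points),))
    if origin is None:
        lo = (points - radii[:, None]).min(axis=0) - margin_voxels * spacing
        hi = (points + radii[:, None]).max(axis=0) + margin_voxels * spacing
        origin = np.floor(lo / spacing) * spacing
        shape = tuple(np.ceil((hi - origin) / spacing).astype(int) + 1)
    mask = out if out is not None else np.zeros(shape, dtype=bool)
    shp = np.array(mask.shape)
    for p, r in zip(points, radii):
        lo_idx = np.maximum(np.floor((p - r - origin) / spacing).astype(int), 0)
        hi_idx = np.minimum(np.ceil((p + r - origin) / spacing).astype(int), shp - 1)
        if np.any(hi_idx < lo_idx):
            continue
        ax = [origin[a] + np.arange(lo_idx[a], hi_idx[a] + 1) * spacing - p[a] for a in range(3)]
        d2 = (
            (ax[0] ** 2)[:, None, None]
            + (ax[1] ** 2)[None, :, None]
            + (ax[2] ** 2)[None, None, :]
        )
        sub = mask[lo_idx[0] : hi_idx[0] + 1, lo_idx[1] : hi_idx[1] + 1, lo_idx[2] : hi_idx[2] + 1]
        sub |= d2 <= r * r
    return mask, np.asarray(origin, dtype=float)


def _trimmed_samples(
    spec: PhantomSpec, pts: np.ndarray, s: np.ndarray, radii: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Restrict dense centerline samples to the trimmed span between the
    blind-end cap centres (see :func:`_trim_bounds`)."""
    length = float(s[-1])
    s_lo, s_hi = _trim_bounds(spec, length)
    keep = (s >= s_lo) & (s <= s_hi)
    s_t = np.concatenate([[s_lo], s[keep], [s_hi]])
    pts_t = np.vstack(
        [
            [np.interp(s_lo, s, pts[:, a]) for a in range(3)],
            pts[keep],
            [np.interp(s_hi, s, pts[:, a]) for a in range(3)],
        ]
    )
    radii_t = np.interp(s_t, s, radii)
    return pts_t, s_t, radii_t


def _stamp_step(spec: PhantomSpec) -> float:
    """Centerline sampling step for ball stamping: sagitta error bounded at
    5% of the voxel size."""
    r_min = min(spec.tube_radius_base_um, spec.tube_radius_apex_um)
    step = np.sqrt(0.4 * spec.voxel_spacing_um * r_min)
    return float(min(step, r_min, 2.0 * spec.voxel_spacing_um))


def _check_tube_self_intersection(
    points: np.ndarray, s: np.ndarray, radii: np.ndarray
) -> None:
    """Reject specs whose tube touches itself across turns."""
    r_max = float(radii.max())
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=2.0 * r_max, output_type="ndarray")
    if len(pairs) == 0:
        return
    i, j = pairs.T
    arc_sep = np.abs(s[i] - s[j])
    eucl = np.linalg.norm(points[i] - points[j], axis=1)
    allowed = radii[i] + radii[j]
    # Neighbouring samples along the tube are always close; only flag pairs
    # whose arc separation is far beyond their Euclidean distance.
    offending = (arc_sep > 4.0 * allowed) & (eucl < allowed)
    if np.any(offending):
        raise ValueError(
            "tube self-intersection: turn spacing is smaller than twice the "
            "tube radius; reduce tube radius or increase pitch/taper"
        )


def _apply_boundary_jitter(mask: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Flip surface voxels (both sides of the boundary) with probability p,
    emulating manual-segmentation noise."""
    if p <= 0:
        return mask
    inner = mask & ~ndimage.binary_erosion(mask)
    outer = ndimage.binary_dilation(mask) & ~mask
    flips = rng.random(mask.shape)
    out = mask.copy()
    out[inner & (flips < p)] = False
    out[outer & (flips < p)] = True
    return out


# ---------------------------------------------------------------------------
# phantom constructors


def make_spiral_duct_phantom(
    spec: PhantomSpec,
) -> tuple[LabeledVolume, PhantomGroundTruth]:
    """Voxelize a tapering spiral cochlear duct with analytic ground truth.

    Returns the labeled volume (duct label 1) and the ground truth:
    quadrature arc length, analytic tube volume, and a densely sampled
    (>= 50 points/turn) analytic centerline.
    """
    spacing = spec.voxel_spacing_um
    pts, s, radii = _dense_spiral_samples(spec, _stamp_step(spec))
    _check_tube_self_intersection(pts, s, radii)
    pts_t, _, radii_t = _trimmed_samples(spec, pts, s, radii)
    mask, origin = _stamp_balls(pts_t, radii_t, spacing, spec.margin_voxels)
    if spec.jitter_p > 0:
        rng = np.random.default_rng(spec.seed)
        mask = _apply_boundary_jitter(mask, spec.jitter_p, rng)
    vol = LabeledVolume(
        labels=mask.astype(np.int32) * DUCT_LABEL,
        spacing_um=spacing,
        origin_um=origin,
        label_names={DUCT_LABEL: "scala_media"},
    )
    gt = PhantomGroundTruth(
        length_um=spiral_arc_length(spec),
        volume_um3=spiral_tube_volume(spec),
        centerline=Polyline3D(points=pts),
    )
    return vol, gt


def make_cylinder_phantom(
    length_um: float,
    tube_radius_um: float,
    voxel_spacing_um: float,
    axis: int = 0,
    margin_voxels: int = 10,
) -> tuple[LabeledVolume, PhantomGroundTruth]:
    """Straight-tube degenerate phantom: a cylinder along a grid axis.

    Ground truth: length = ``length_um``, volume = pi r^2 L (closed form).
    """
    if length_um <= 0 or tube_radius_um <= 0 or voxel_spacing_um <= 0:
        raise ValueError("length, radius and spacing must be > 0")
    step = min(voxel_spacing_um / 2.0, tube_radius_um / 2.0)
    n = int(np.ceil(length_um / step)) + 1
    t = np.linspace(0.0, length_um, n)
    pts = np.zeros((n, 3))
    pts[:, axis] = t
    mask, origin = _stamp_balls(
        pts, np.full(n, tube_radius_um), voxel_spacing_um, margin_voxels
    )
    # Clip the rounded ends so the solid is a true finite cylinder and the
    # closed-form volume pi r^2 L is exact in the fine-spacing limit.
    coords = origin[axis] + np.arange(mask.shape[axis]) * voxel_spacing_um
    inside = (coords >= 0.0) & (coords <= length_um)
    sl = [slice(None)] * 3
    sl[axis] = ~inside
    mask[tuple(sl)] = False
    vol = LabeledVolume(
        labels=mask.astype(np.int32) * DUCT_LABEL,
        spacing_um=voxel_spacing_um,
        origin_um=origin,
        label_names={DUCT_LABEL: "scala_media"},
    )
    gt = PhantomGroundTruth(
        length_um=float(length_um),
        volume_um3=float(np.pi * tube_radius_um**2 * length_um),
        centerline=Polyline3D(points=pts[:: max(1, n // 200)] if n > 400 else pts),
    )
    return vol, gt


def _validate_blobs(
    centers: dict[str, tuple[float, float, float]], radii: dict[str, float]
) -> None:
    names = sorted(centers)
    for name in names:
        if name not in radii:
            raise ValueError(f"blob {name!r} has a centre but no radius")
        if radii[name] <= 0:
            raise ValueError(f"blob {name!r} has non-positive radius")
    for a_i, a in enumerate(names):
        for b in names[a_i + 1 :]:
            d = np.linalg.norm(np.subtract(centers[a], centers[b]))
            if d <= radii[a] + radii[b]:
                raise ValueError(
                    f"blobs {a!r} and {b!r} overlap: centre distance {d:.1f} μm "
                    f"<= radius sum {radii[a] + radii[b]:.1f} μm"
                )


def make_blob_volume(
    centers_um: dict[str, tuple[float, float, float]],
    radii_um: dict[str, float | tuple[float, float, float]],
    voxel_spacing_um: float,
    margin_voxels: int = 10,
    first_label: int = 1,
) -> LabeledVolume:
    """Voxelize named spheres / axis-aligned ellipsoids, one label each.

    ``radii_um`` values may be scalars (spheres) or per-axis semi-axes
    (ellipsoids).  Labels are assigned in sorted name order starting at
    ``first_label``.  Overlapping blobs are rejected (conservatively, by
    bounding spheres).
    """
    names = sorted(centers_um)
    if not names:
        raise ValueError("no blobs given")
    semi = {n: np.broadcast_to(np.asarray(radii_um[n], dtype=float), (3,)) for n in names}
    _validate_blobs(centers_um, {n: float(semi[n].max()) for n in names})
    spacing = float(voxel_spacing_um)
    centers = np.array([centers_um[n] for n in names], dtype=float)
    maxr = np.array([semi[n] for n in names])
    lo = (centers - maxr).min(axis=0) - margin_voxels * spacing
    hi = (centers + maxr).max(axis=0) + margin_voxels * spacing
    origin = np.floor(lo / spacing) * spacing
    shape = tuple(np.ceil((hi - origin) / spacing).astype(int) + 1)
    labels = np.zeros(shape, dtype=np.int32)
    label_names: dict[int, str] = {}
    for k, name in enumerate(names):
        lab = first_label + k
        c, ax_r = centers[k], semi[name]
        lo_idx = np.maximum(np.floor((c - ax_r - origin) / spacing).astype(int), 0)
        hi_idx = np.minimum(np.ceil((c + ax_r - origin) / spacing).astype(int), np.array(shape) - 1)
        ax = [
            (origin[a] + np.arange(lo_idx[a], hi_idx[a] + 1) * spacing - c[a]) / ax_r[a]
            for a in range(3)
        ]
        d2 = (
            (ax[0] ** 2)[:, None, None]
            + (ax[1] ** 2)[None, :, None]
            + (ax[2] ** 2)[None, None, :]
        )
        sub = labels[lo_idx[0] : hi_idx[0] + 1, lo_idx[1] : hi_idx[1] + 1, lo_idx[2] : hi_idx[2] + 1]
        sub[d2 <= 1.0] = lab
        label_names[lab] = name
    return LabeledVolume(labels=labels, spacing_um=spacing, origin_um=origin, label_names=label_names)


def make_vestibular_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Voxelize the five vestibular sensory epithelia as labeled spheres.

    Requires all five organs (three cristae, two maculae) in the spec;
    overlapping spheres are rejected.
    """
    missing = [n for n in VESTIBULAR_ORGANS if n not in spec.blob_centers_um]
    if missing:
        raise ValueError(f"missing vestibular organs in spec: {missing}")
    centers = {n: spec.blob_centers_um[n] for n in VESTIBULAR_ORGANS}
    radii = {n: spec.blob_radii_um[n] for n in VESTIBULAR_ORGANS}
    vol = make_blob_volume(centers, radii, spec.voxel_spacing_um, spec.margin_voxels)
    # Re-key labels to the canonical organ order rather than sorted names.
    remap = np.zeros(int(vol.labels.max()) + 1, dtype=np.int32)
    new_names: dict[int, str] = {}
    for old, name in vol.label_names.items():
        new = _ORGAN_LABELS[name]
        remap[old] = new
        new_names[new] = name
    return LabeledVolume(
        labels=remap[vol.labels],
        spacing_um=vol.spacing_um,
        origin_um=vol.origin_um,
        label_names=new_names,
    )


def make_inner_ear_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, PhantomGroundTruth]:
    """Combined phantom: spiral duct (label 1) plus the five vestibular
    organs (labels 2-6) in one volume.

    Blob spheres must be pairwise disjoint and disjoint from the duct tube.
    """
    missing = [n for n in VESTIBULAR_ORGANS if n not in spec.blob_centers_um]
    if missing:
        raise ValueError(f"missing vestibular organs in spec: {missing}")
    radii_map = {n: float(spec.blob_radii_um[n]) for n in VESTIBULAR_ORGANS}
    _validate_blobs({n: spec.blob_centers_um[n] for n in VESTIBULAR_ORGANS}, radii_map)
    spacing = spec.voxel_spacing_um
    pts, s, tube_radii = _dense_spiral_samples(spec, _stamp_step(spec))
    _check_tube_self_intersection(pts, s, tube_radii)
    pts_t, _, radii_t = _trimmed_samples(spec, pts, s, tube_radii)
    tree = cKDTree(pts)
    for name in VESTIBULAR_ORGANS:
        c = np.asarray(spec.blob_centers_um[name], dtype=float)
        d, idx = tree.query(c)
        if d <= radii_map[name] + tube_radii[idx] + spacing:
            raise ValueError(
                f"blob {name!r} intersects (or nearly touches) the duct tube: "
                f"centre is {d:.1f} μm from the centerline"
            )
    centers = np.array([spec.blob_centers_um[n] for n in VESTIBULAR_ORGANS])
    blob_r = np.array([radii_map[n] for n in VESTIBULAR_ORGANS])
    lo = np.minimum(
        (pts - tube_radii[:, None]).min(axis=0), (centers - blob_r[:, None]).min(axis=0)
    ) - spec.margin_voxels * spacing
    hi = np.maximum(
        (pts + tube_radii[:, None]).max(axis=0), (centers + blob_r[:, None]).max(axis=0)
    ) + spec.margin_voxels * spacing
    origin = np.floor(lo / spacing) * spacing
    shape = tuple(np.ceil((hi - origin) / spacing).astype(int) + 1)
    duct_mask, _ = _stamp_balls(pts_t, radii_t, spacing, 0, origin=origin, shape=shape)
    if spec.jitter_p > 0:
        rng = np.random.default_rng(spec.seed)
        duct_mask = _apply_boundary_jitter(duct_mask, spec.jitter_p, rng)
    labels = duct_mask.astype(np.int32) * DUCT_LABEL
    blob_mask = np.zeros(shape, dtype=bool)
    for name in VESTIBULAR_ORGANS:
        blob_mask[:] = False
        _stamp_balls(
            np.asarray(spec.blob_centers_um[name])[None, :],
            np.array([radii_map[name]]),
            spacing,
            0,
            origin=origin,
            shape=shape,
            out=blob_mask,
        )
        labels[blob_mask] = _ORGAN_LABELS[name]
    names = {DUCT_LABEL: "scala_media", **{v: k for k, v in _ORGAN_LABELS.items()}}
    vol = LabeledVolume(labels=labels, spacing_um=spacing, origin_um=origin, label_names=names)
    gt = PhantomGroundTruth(
        length_um=spiral_arc_length(spec),
        volume_um3=spiral_tube_volume(spec),
        centerline=Polyline3D(points=pts),
    )
    return vol, gt


def make_registration_fixture(
    voxel_spacing_um: float = 10.0,
    extent_px: tuple[int, int] = (170, 170),
    pixel_spacing_um: float = 10.0,
    plane_offset_um: float = 130.0,
):
    """Three-compartment registration phantom with ground-truth transform.

    Three axis-aligned ellipsoids of distinct semi-axes stand in for the
    scala media, scala vestibuli and scala tympani masks of a cochlear
    mid-modiolar section.  The ground-truth section plane passes near all
    three centres but is offset along the plane normal by
    ``plane_offset_um``, so each compartment is cut off-centre and every
    rigid degree of freedom (including out-of-plane tilt) changes the
    label overlap at first order — the fixture has no degenerate
    registration directions.

    Returns ``(volume, true_transform, section)``.
    """
    from scipy.spatial.transform import Rotation

    from .register import RigidTransform3D

    centers = {
        "scala_media": np.array([0.0, 0.0, 0.0]),
        "scala_vestibuli": np.array([900.0, 300.0, 150.0]),
        "scala_tympani": np.array([-300.0, 1100.0, -200.0]),
    }
    semi_axes = {
        "scala_media": (500.0, 350.0, 250.0),
        "scala_vestibuli": (300.0, 450.0, 350.0),
        "scala_tympani": (400.0, 300.0, 450.0),
    }
    vol = make_blob_volume(centers, semi_axes, voxel_spacing_um)
    a, b, c = centers["scala_media"], centers["scala_vestibuli"], centers["scala_tympani"]
    normal = np.cross(b - a, c - a)
    normal /= np.linalg.norm(normal)
    u = (b - a) / np.linalg.norm(b - a)
    v = np.cross(normal, u)
    rot = Rotation.from_matrix(np.stack([u, v, normal], axis=1))
    c_plane = np.array(
        [(extent_px[0] - 1) / 2.0 * pixel_spacing_um, (extent_px[1] - 1) / 2.0 * pixel_spacing_um, 0.0]
    )
    centroid = (a + b + c) / 3.0 + plane_offset_um * normal
    truth = RigidTransform3D(
        quaternion=rot.as_quat(), translation_um=centroid - rot.apply(c_plane)
    )
    section = make_section_fixture(vol, truth, extent_px, pixel_spacing_um)
    return vol, truth, section


def make_section_fixture(
    vol: LabeledVolume,
    true_transform,
    plane_extent_px: tuple[int, int],
    pixel_spacing_um: float,
):
    """Virtual 2D section of a labeled volume for registration tests.

    Nearest-neighbour sampling along the plane defined by
    ``true_transform``; the transform is the registration ground truth and
    is kept by the caller.  Raises if the plane misses every label.
    """
    from .register import sample_plane

    section = sample_plane(vol, true_transform, plane_extent_px, pixel_spacing_um)
    if not np.any(section.labels):
        raise ValueError("section plane misses all labels; choose a transform through the structure")
    return section
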