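"""Volumes, centres of mass, inter-organ distances and growth trends.

All quantities are measured on the raw segmented labels — never on
conditioned masks: conditioning exists only so that skeletonization
yields a clean centerline.  Label volume is exact (voxel count times
physical voxel volume); centres of mass are unweighted means of voxel
centres; organ separations are Euclidean distances between centres;
growth trends over gestational weeks are ordinary least-squares lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centerline import DuctMeasurement, measure_duct_length
from .grids import LabeledVolume

__all__ = [
    "UM3_PER_UL",
    "UM_PER_MM",
    "DistanceMatrix",
    "TrendFit",
    "MorphometryReport",
    "label_volume",
    "center_of_mass",
    "pairwise_distances",
    "volume_length_ratio",
    "fit_trend",
    "growth_report",
    "parse_gestational_week",
]

UM3_PER_UL = 1e9  # 1 μl = 1 mm^3 = 1e9 μm^3
UM_PER_MM = 1e3


def _require_label(vol: LabeledVolume, label: int) -> np.ndarray:
    m = vol.labels == int(label)
    if not m.any():
        raise ValueError(
            f"label {int(label)} ({vol.name_of(label)}) not present in volume"
        )
    return m


def label_volume(vol: LabeledVolume, label: int) -> float:
    """Exact physical volume of a label in μm^3: voxel count times voxel
    volume, computed on the raw (unconditioned) labels."""
    m = _require_label(vol, label)
    return float(int(m.sum()) * vol.voxel_volume_um3)


def center_of_mass(vol: LabeledVolume, label: int) -> np.ndarray:
    """Unweighted mean of the physical centres of the label's voxels (μm)."""
    m = _require_label(vol, label)
    idx = np.argwhere(m)
    return vol.origin_um + idx.mean(axis=0) * vol.spacing_um


@dataclass
class DistanceMatrix:
    """Pairwise Euclidean distances (μm) between organ centres of mass."""

    names: list[str]
    matrix: np.ndarray  # (n, n), symmetric, zero diagonal
    centers_um: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.names)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape must match the number of names")

    def distance(self, a: str, b: str) -> float:
        return float(self.matrix[self.names.index(a), self.names.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.names, columns=self.names)

    def pairs(self) -> list[tuple[str, str, float]]:
        out = []
        for i, a in enumerate(self.names):
            for j in range(i + 1, len(self.names)):
                out.append((a, self.names[j], float(self.matrix[i, j])))
        return out


def pairwise_distances(vol: LabeledVolume, labels: list[int]) -> DistanceMatrix:
    """Full symmetric matrix of centre-of-mass distances for the given
    labels ("vector magnitude" between region centres)."""
    labels = [int(l) for l in labels]
    if len(labels) < 2:
        raise ValueError("need at least 2 labels for a distance matrix")
    missing = [l for l in labels if not np.any(vol.labels == l)]
    if missing:
        raise ValueError(
            f"labels absent from volume: {missing} "
            f"({[vol.name_of(l) for l in missing]})"
        )
    names = [vol.name_of(l) for l in labels]
    centers = np.array([center_of_mass(vol, l) for l in labels])
    diff = centers[:, None, :] - centers[None, :, :]
    mat = np.linalg.norm(diff, axis=-1)
    return DistanceMatrix(
        names=names, matrix=mat, centers_um={n: c for n, c in zip(names, centers)}
    )


def volume_length_ratio(volume_um3: float, length_um: float) -> float:
    """Endolymph volume per unit duct length, in μl/mm."""
    if length_um <= 0:
        raise ValueError(f"length must be > 0, got {length_um}")
    return (volume_um3 / UM3_PER_UL) / (length_um / UM_PER_MM)


@dataclass
class TrendFit:
    """Ordinary least-squares growth trend over gestational weeks."""

    slope: float  # measurement units per gestational week
    intercept: float
    r_squared: float
    n_points: int
    stderr_slope: float = float("nan")

    def predict(self, week):
        return self.slope * np.asarray(week, dtype=float) + self.intercept


def fit_trend(points: list[tuple[float, float]]) -> TrendFit:
    """Closed-form OLS line through (gestational_week, measurement) points.

    Needs at least two distinct weeks.  When the measurements have zero
    total variance, r^2 is defined as 0 (flat-line convention).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >= 2 (week, measurement) points")
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("all gestational weeks identical; trend undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    n = len(pts)
    stderr = float("nan")
    if n > 2:
        stderr = float(np.sqrt(ss_res / (n - 2) / sxx))
    return TrendFit(slope=slope, intercept=intercept, r_squared=r2, n_points=n, stderr_slope=stderr)


def parse_gestational_week(stage_label: str) -> float:
    """Numeric gestational week from a stage label like ``"GW19"``."""
    m = re.search(r"(\d+(?:\.\d+)?)", str(stage_label))
    if not m:
        raise ValueError(f"cannot parse a gestational week from stage label {stage_label!r}")
    return float(m.group(1))


@dataclass
class MorphometryReport:
    """Per-stage morphometry: duct length, per-label volumes and centres,
    volume/length ratio, and the organ distance matrix."""

    stage: str
    gestational_week: float
    duct_length_um: float
    duct_volume_um3: float
    volume_length_ratio_ul_per_mm: float
    label_volumes_um3: dict[str, float]
    label_voxel_counts: dict[str, int]
    centers_um: dict[str, np.ndarray]
    distances: DistanceMatrix | None
    duct: DuctMeasurement | None = None

    @property
    def duct_length_mm(self) -> float:
        return self.duct_length_um / UM_PER_MM

    @property
    def duct_volume_ul(self) -> float:
        return self.duct_volume_um3 / UM3_PER_UL

    def to_row(self) -> dict:
        row = {
            "stage": self.stage,
            "gestational_week": self.gestational_week,
            "duct_length_um": self.duct_length_um,
            "duct_length_mm": self.duct_length_mm,
            "duct_volume_um3": self.duct_volume_um3,
            "duct_volume_ul": self.duct_volume_ul,
            "volume_length_ratio_ul_per_mm": self.volume_length_ratio_ul_per_mm,
        }
        for name, v in sorted(self.label_volumes_um3.items()):
            row[f"volume_{name}_um3"] = v
        if self.distances is not None:
            for a, b, d in self.distances.pairs():
                row[f"dist_{a}__{b}_um"] = d
        return row


def analyze_stage(
    stage: str,
    vol: LabeledVolume,
    duct_label: int,
    organ_labels: list[int],
    conditioning=None,
    smoothing=None,
) -> MorphometryReport:
    """Full morphometry of one stage volume (duct + vestibular organs)."""
    missing = [
        l for l in [duct_label, *organ_labels] if not np.any(vol.labels == int(l))
    ]
    if missing:
        raise ValueError(
            f"stage {stage!r}: labels absent from volume: "
            f"{[(int(l), vol.name_of(l)) for l in missing]}"
        )
    duct = measure_duct_length(vol, duct_label, conditioning, smoothing)
    duct_vol = label_volume(vol, duct_label)
    all_labels = [duct_label, *organ_labels]
    volumes = {vol.name_of(l): label_volume(vol, l) for l in all_labels}
    counts = {vol.name_of(l): int((vol.labels == int(l)).sum()) for l in all_labels}
    centers = {vol.name_of(l): center_of_mass(vol, l) for l in all_labels}
    distances = pairwise_distances(vol, organ_labels) if len(organ_labels) >= 2 else None
    return MorphometryReport(
        stage=stage,
        gestational_week=parse_gestational_week(stage),
        duct_length_um=duct.length_um,
        duct_volume_um3=duct_vol,
        volume_length_ratio_ul_per_mm=volume_length_ratio(duct_vol, duct.length_um),
        label_volumes_um3=volumes,
        label_voxel_counts=counts,
        centers_um=centers,
        distances=distances,
        duct=duct,
    )


def growth_report(
    stages: list[tuple[str, LabeledVolume]],
    duct_label: int,
    organ_labels: list[int],
    conditioning=None,
    smoothing=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Morphometry table over a developmental series plus trend fits.

    Returns ``(table, trends)``: one table row per stage (length, volume,
    ratio, organ distances) and, when at least two stages are present, one
    OLS trend fit per measured quantity (duct length/volume/ratio and each
    organ distance pair) against gestational week.
    """
    if not stages:
        raise ValueError("no stages given")
    reports = [
        analyze_stage(stage, vol, duct_label, organ_labels, conditioning, smoothing)
        for stage, vol in stages
    ]
    table = pd.DataFrame([r.to_row() for r in reports])
    trend_rows = []
    if len(reports) >= 2:
        weeks = [r.gestational_week for r in reports]
        quantities = {
            "duct_length_um": [r.duct_length_um for r in reports],
            "duct_volume_ul": [r.duct_volume_ul for r in reports],
            "volume_length_ratio_ul_per_mm": [
                r.volume_length_ratio_ul_per_mm for r in reports
            ],
        }
        if reports[0].distances is not None:
            for a, b, _ in reports[0].distances.pairs():
                quantities[f"dist_{a}__{b}_um"] = [
                    r.distances.distance(a, b) for r in reports
                ]
        for name, values in quantities.items():
            fit = fit_trend(list(zip(weeks, values)))
            trend_rows.append(
                {
                    "quantity": name,
                    "slope_per_week": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                }
            )
    trends = pd.DataFrame(
        trend_rows,
        columns=["quantity", "slope_per_week", "intercept", "r_squared", "n_points"],
    )
    return table, trends
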