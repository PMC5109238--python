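"""Spindle-angle geometry against a best-fitting surface plane.

A dividing cell at the apical surface of a pseudostratified epithelium is
annotated by the 3D positions of its two centrosomes (spindle poles) and a
handful of points sampled on the adjacent ventricular surface.  The surface
is summarised by the plane minimising the summed squared *orthogonal*
distances to the sampled points (orthogonal distance regression); the
spindle angle ``alpha`` is the angle between the centrosome-centrosome axis
and that plane, folded to [0, 90] degrees because pole labelling is
arbitrary.  ``alpha = 0`` is a planar (surface-parallel) division,
``alpha = 90`` a vertical one.

Spindle rotation over a metaphase track is quantified from the per-interval
angles between successive (undirected) pole-pole axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError

__all__ = [
    "PlaneFit",
    "SpindleAngle",
    "AnaphaseAnnotation",
    "SpindleTrack",
    "AngleGroupSummary",
    "fit_plane_odr",
    "spindle_angle",
    "axis_rotation",
    "quantify_rotation",
    "angle_group_summary",
]

ROTATION_STATISTICS = ("cumulative", "mean-velocity", "max-interval")


@dataclass(frozen=True)
class PlaneFit:
    """Orthogonal-distance-regression plane.

    Attributes
    ----------
    centroid : (3,) ndarray
        Point on the plane (mean of the fitted points), micrometres.
    normal : (3,) ndarray
        Unit normal; sign canonicalised so its largest-magnitude component
        is positive.
    residual_rms : float
        Root-mean-square orthogonal distance of the points to the plane.
    """

    centroid: np.ndarray
    normal: np.ndarray
    residual_rms: float


@dataclass(frozen=True)
class SpindleAngle:
    """Spindle orientation of one dividing cell.

    ``alpha_deg`` is the angle between the spindle axis and the surface
    plane; ``normal_angle_deg`` is the complementary angle between the axis
    and the plane normal (the quantity described in many methods texts).
    Both are folded to [0, 90] degrees.
    """

    alpha_deg: float
    normal_angle_deg: float


@dataclass
class AnaphaseAnnotation:
    """One dividing cell: a centrosome pair plus surface sample points."""

    cell_id: str
    centrosome_1: np.ndarray
    centrosome_2: np.ndarray
    surface_points: np.ndarray  # (n, 3), n >= 3, micrometres
    group: str = "default"

    def __post_init__(self) -> None:
        self.centrosome_1 = np.asarray(self.centrosome_1, dtype=float)
        self.centrosome_2 = np.asarray(self.centrosome_2, dtype=float)
        self.surface_points = np.asarray(self.surface_points, dtype=float)
        if self.surface_points.ndim != 2 or self.surface_points.shape[1] != 3:
            raise ValueError("surface_points must be an (n, 3) array")
        if self.surface_points.shape[0] < 3:
            raise ValueError("need at least 3 surface points")


@dataclass
class SpindleTrack:
    """Time-ordered spindle-pole pair positions (micrometres, minutes)."""

    times_min: np.ndarray
    pole_1: np.ndarray  # (n, 3)
    pole_2: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.pole_1 = np.asarray(self.pole_1, dtype=float)
        self.pole_2 = np.asarray(self.pole_2, dtype=float)
        if not (len(self.times_min) == len(self.pole_1) == len(self.pole_2)):
            raise ValueError("times and pole arrays must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def axes(self) -> np.ndarray:
        """Unit spindle axes per time point (direction is arbitrary)."""
        d = self.pole_2 - self.pole_1
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise DegenerateGeometryError("coincident poles in spindle track")
        return d / norms

    @property
    def interval_rotations_deg(self) -> np.ndarray:
        """Axis rotation between successive time points, degrees in [0, 90]."""
        ax = self.axes
        cosang = np.abs(np.sum(ax[:-1] * ax[1:], axis=1))
        return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def fit_plane_odr(points: np.ndarray) -> PlaneFit:
    """Fit a plane by orthogonal distance regression.

    The plane passes through the centroid of ``points`` and its normal is
    the direction of least variance of the centred points (smallest right
    singular vector), which minimises the sum of squared orthogonal
    distances.

    Parameters
    ----------
    points : (n, 3) array_like, n >= 3

    Raises
    ------
    DegenerateGeometryError
        If the points are collinear (or otherwise do not determine a plane).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("points must be an (n, 3) array with n >= 3")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    # SVD of the centred cloud: singular values sorted descending.
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    scale = max(s[0], 1.0)
    if s[1] <= 1e-12 * scale:
        raise DegenerateGeometryError(
            "surface points are collinear; plane is undetermined"
        )
    normal = vt[2]
    # Canonical sign: largest-magnitude component positive.
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    residual_rms = float(s[2] / np.sqrt(pts.shape[0]))
    return PlaneFit(centroid=centroid, normal=normal, residual_rms=residual_rms)


def spindle_angle(c1: np.ndarray, c2: np.ndarray, plane: PlaneFit) -> SpindleAngle:
    """Angle of the centrosome-centrosome axis relative to a plane.

    Returns the angle ``alpha`` between the spindle axis and the plane
    (``alpha = 90 - angle(axis, normal)``), folded to [0, 90] degrees; the
    normal-relative angle is retained alongside.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    axis = c2 - c1
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise DegenerateGeometryError("centrosomes coincide; spindle axis undefined")
    u = axis / norm
    sin_alpha = abs(float(np.dot(u, plane.normal)))
    alpha = float(np.degrees(np.arcsin(np.clip(sin_alpha, 0.0, 1.0))))
    return SpindleAngle(alpha_deg=alpha, normal_angle_deg=90.0 - alpha)


def axis_rotation(axis_a: np.ndarray, axis_b: np.ndarray) -> float:
    """Angle between two undirected 3D axes, degrees in [0, 90].

    Invariant to the sign of either vector (pole labelling is arbitrary).
    """
    a = np.asarray(axis_a, dtype=float)
    b = np.asarray(axis_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateGeometryError("zero-length axis")
    cosang = abs(float(np.dot(a, b)) / (na * nb))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def quantify_rotation(track: SpindleTrack, statistic: str = "mean-velocity") -> float:
    """Summarise spindle rotation over a track.

    Parameters
    ----------
    track : SpindleTrack
        At least two time points.
    statistic : {"cumulative", "mean-velocity", "max-interval"}
        ``cumulative``: summed per-interval axis rotation, degrees.
        ``mean-velocity``: cumulative rotation / elapsed time, degrees/min.
        ``max-interval``: largest single-interval rotation, degrees.
    """
    if statistic not in ROTATION_STATISTICS:
        raise ValueError(f"statistic must be one of {ROTATION_STATISTICS}")
    if len(track.times_min) < 2:
        raise ValueError("rotation requires at least 2 time points")
    rots = track.interval_rotations_deg
    if statistic == "cumulative":
        return float(rots.sum())
    if statistic == "max-interval":
        return float(rots.max())
    elapsed = float(track.times_min[-1] - track.times_min[0])
    return float(rots.sum() / elapsed)


@dataclass
class AngleGroupSummary:
    """Per-cell spindle angles with optional between-group comparison."""

    table: pd.DataFrame
    excluded_cells: list = field(default_factory=list)
    comparisons: list = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_cells)

    def group_means(self) -> pd.Series:
        return self.table.groupby("group")["alpha_deg"].mean()


def annotation_angle(annotation: AnaphaseAnnotation) -> tuple[SpindleAngle, PlaneFit]:
    """Spindle angle of one annotation via its ODR surface plane."""
    plane = fit_plane_odr(annotation.surface_points)
    return spindle_angle(annotation.centrosome_1, annotation.centrosome_2, plane), plane


def angle_group_summary(
    annotations: Iterable[AnaphaseAnnotation],
    alpha: float = 0.05,
) -> AngleGroupSummary:
    """Compute per-cell angles and compare groups.

    Degenerate annotations (collinear surface points, coincident
    centrosomes) are excluded with a logged count rather than aborting the
    whole set.  With two or more groups of at least 3 cells each, group
    pairs are compared with the screening-statistics test-selection rule
    (normality and variance checks, then Student or Welch t-test, Bonferroni
    across pairs when there are more than two groups).
    """
    from .screen import compare_groups  # local import: screen does not import geometry

    rows = []
    excluded = []
    for ann in annotations:
        try:
            angle, plane = annotation_angle(ann)
        except DegenerateGeometryError as exc:
            excluded.append((ann.cell_id, str(exc)))
            continue
        rows.append(
            {
                "cell_id": ann.cell_id,
                "group": ann.group,
                "alpha_deg": angle.alpha_deg,
                "normal_angle_deg": angle.normal_angle_deg,
                "residual_um": plane.residual_rms,
                "n_surface_points": ann.surface_points.shape[0],
            }
        )
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} degenerate annotation(s): "
            + ", ".join(cid for cid, _ in excluded),
            stacklevel=2,
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "group",
            "alpha_deg",
            "normal_angle_deg",
            "residual_um",
            "n_surface_points",
        ],
    )
    summary = AngleGroupSummary(table=table, excluded_cells=excluded)
    groups = {g: sub["alpha_deg"].to_numpy() for g, sub in table.groupby("group")}
    eligible = {g: v for g, v in groups.items() if len(v) >= 3}
    if len(eligible) >= 2:
        names = sorted(eligible)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        m = len(pairs) if len(pairs) > 1 else None
        for a, b in pairs:
            rep = compare_groups(
                eligible[a], eligible[b], alpha=alpha, m_comparisons=m,
                labels=(a, b),
            )
            summary.comparisons.append(rep)
    return summary
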