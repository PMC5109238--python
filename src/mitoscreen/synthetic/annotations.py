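"""Synthetic 3D anaphase annotations and rotating spindle-pole tracks.

Annotations emulate manual 3D point picking on confocal stacks of dividing
cells at a curved, noisy epithelial surface: two centrosome coordinates
plus a handful of surface sample points per cell, with the drawn spindle
angle recorded as ground truth.  Spindle tracks emulate pole-pair
positions of a metaphase spindle rotating at a constant angular rate
within a random plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..errors import GenerationError
from ..geometry import AnaphaseAnnotation, SpindleTrack

__all__ = ["SurfaceModel", "gen_anaphase_annotations", "gen_spindle_track"]


@dataclass
class SurfaceModel:
    """Reference surface: a plane with optional bowl curvature and noise.

    The surface height above the reference plane at in-plane distance
    ``d`` from ``point`` is ``curvature_amplitude_um * (d / 10 um)**2``;
    sampled points additionally receive Gaussian noise of
    ``point_noise_sd_um`` along the normal.  Zero curvature and zero noise
    reduce to the exact plane.
    """

    point: np.ndarray = None
    normal: np.ndarray = None
    curvature_amplitude_um: float = 0.0
    point_noise_sd_um: float = 0.0

    def __post_init__(self) -> None:
        self.point = (
            np.zeros(3) if self.point is None else np.asarray(self.point, dtype=float)
        )
        n = (
            np.array([0.0, 0.0, 1.0])
            if self.normal is None
            else np.asarray(self.normal, dtype=float)
        )
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("surface normal must be nonzero")
        self.normal = n / norm

    def in_plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, self.normal)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(self.normal, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(self.normal, e1)
        return e1, e2


def _truncnorm_angles(
    n: int, mean: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (90.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def gen_anaphase_annotations(
    n: int,
    surface: SurfaceModel | None = None,
    angle_mean_deg: float = 15.0,
    angle_sd_deg: float = 8.0,
    centrosome_noise_sd_um: float = 0.0,
    n_surface_points: int = 5,
    spindle_half_length_um: float = 2.5,
    patch_radius_um: float = 5.0,
    field_radius_um: float = 20.0,
    group: str = "synthetic",
    angles_deg: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[list[AnaphaseAnnotation], np.ndarray]:
    """Generate dividing-cell annotations with known spindle angles.

    Angles are drawn from a normal distribution truncated to [0, 90]
    degrees (or taken verbatim from ``angles_deg``).  Each annotation
    carries two centrosomes and ``n_surface_points`` surface samples in a
    patch around the cell; degenerate (collinear) surface draws are
    regenerated, never emitted.

    Returns the annotation list and the array of true angles relative to
    the reference plane.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_surface_points < 3:
        raise ValueError("need at least 3 surface points")
    surface = surface if surface is not None else SurfaceModel()
    rng = np.random.default_rng(seed)
    if angles_deg is None:
        angles = _truncnorm_angles(n, angle_mean_deg, angle_sd_deg, rng)
    else:
        angles = np.asarray(angles_deg, dtype=float)
        if angles.shape != (n,):
            raise ValueError("angles_deg must have length n")
        if np.any((angles < 0) | (angles > 90)):
            raise ValueError("angles must lie in [0, 90] degrees")
    e1, e2 = surface.in_plane_basis()

    def surface_point(offset_2d: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(offset_2d)
        height = surface.curvature_amplitude_um * (d / 10.0) ** 2
        height += rng.normal(0.0, surface.point_noise_sd_um)
        return (
            surface.point
            + offset_2d[0] * e1
            + offset_2d[1] * e2
            + height * surface.normal
        )

    annotations = []
    for i in range(n):
        alpha = np.radians(angles[i])
        anchor_2d = rng.uniform(-field_radius_um, field_radius_um, size=2)
        for _attempt in range(100):
            offs = []
            for _ in range(n_surface_points):
                r = patch_radius_um * np.sqrt(rng.uniform())
                phi = rng.uniform(0, 2 * np.pi)
                offs.append(anchor_2d + r * np.array([np.cos(phi), np.sin(phi)]))
            offs2d = np.asarray(offs)
            centred = offs2d - offs2d.mean(axis=0)
            s = np.linalg.svd(centred, compute_uv=False)
            if s[1] > 1e-9:
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise GenerationError("could not draw non-collinear surface points")
        pts = np.array([surface_point(o) for o in offs2d])
        phi = rng.uniform(0, 2 * np.pi)
        in_plane = np.cos(phi) * e1 + np.sin(phi) * e2
        axis = np.cos(alpha) * in_plane + np.sin(alpha) * surface.normal
        midpoint = (
            surface.point
            + anchor_2d[0] * e1
            + anchor_2d[1] * e2
            + 1.5 * surface.normal  # cell body sits just apical of the surface
        )
        c1 = midpoint + spindle_half_length_um * axis
        c2 = midpoint - spindle_half_length_um * axis
        if centrosome_noise_sd_um > 0:
            c1 = c1 + rng.normal(0.0, centrosome_noise_sd_um, size=3)
            c2 = c2 + rng.normal(0.0, centrosome_noise_sd_um, size=3)
        annotations.append(
            AnaphaseAnnotation(
                cell_id=f"cell_{i + 1:04d}",
                centrosome_1=c1,
                centrosome_2=c2,
                surface_points=pts,
                group=group,
            )
        )
    return annotations, angles


def gen_spindle_track(
    duration_min: float,
    frame_interval_min: float,
    rotation_rate_deg_per_min: float,
    noise_sd_um: float = 0.0,
    spindle_half_length_um: float = 4.0,
    seed: int = 0,
) -> tuple[SpindleTrack, np.ndarray]:
    """Pole-pair track rotating at a constant rate within a random plane.

    With zero noise, every per-interval axis rotation equals
    ``rotation_rate_deg_per_min * frame_interval_min``.  Returns the track
    and the true per-interval rotations (degrees).
    """
    if duration_min < 2 * frame_interval_min:
        raise ValueError("duration must span at least 2 frame intervals")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 1e-9, frame_interval_min)
    # random orthonormal rotation plane
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    v = rng.normal(size=3)
    v -= np.dot(v, u) * u
    v /= np.linalg.norm(v)
    thetas = np.radians(rotation_rate_deg_per_min) * times
    axes = np.outer(np.cos(thetas), u) + np.outer(np.sin(thetas), v)
    centre = rng.uniform(-10, 10, size=3)
    p1 = centre + spindle_half_length_um * axes
    p2 = centre - spindle_half_length_um * axes
    if noise_sd_um > 0:
        p1 = p1 + rng.normal(0.0, noise_sd_um, size=p1.shape)
        p2 = p2 + rng.normal(0.0, noise_sd_um, size=p2.shape)
    track = SpindleTrack(times_min=times, pole_1=p1, pole_2=p2)
    true_rot = np.full(len(times) - 1, rotation_rate_deg_per_min * frame_interval_min)
    return track, true_rot
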