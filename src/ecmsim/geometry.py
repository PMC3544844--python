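"""Exact geometric primitives for fiber networks.

Fibers are straight line segments and cells are spheres, both living in
continuous 3D space measured in micrometres.  Everything downstream (matrix
generation, remodeling, rasterization) is built on the distance queries and
random-orientation samplers defined here.

Axis convention for spherical coordinates: ``theta`` is the elevation angle
measured from the +z axis (``0 <= theta <= pi``) and ``phi`` the azimuth
measured from +x in the xy-plane (``0 <= phi < 2*pi``), i.e. standard physics
spherical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Orientation",
    "point_segment_distance",
    "point_to_segments",
    "segment_to_points",
    "sphere_segment_intersects",
    "random_unit_vector",
    "random_orientation",
    "endpoint_from",
    "sample_in_cone",
]


@dataclass(frozen=True)
class Orientation:
    """A direction in 3D given by elevation ``theta`` and azimuth ``phi`` (radians)."""

    theta: float
    phi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= np.pi):
            raise ValueError(f"theta must lie in [0, pi], got {self.theta}")
        if not (0.0 <= self.phi < 2.0 * np.pi):
            raise ValueError(f"phi must lie in [0, 2*pi), got {self.phi}")

    def unit_vector(self) -> np.ndarray:
        st = np.sin(self.theta)
        return np.array(
            [st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta)]
        )


def point_segment_distance(point, p1, p2) -> float:
    """Minimum Euclidean distance from ``point`` to the segment ``p1 -> p2``.

    The segment must have positive length (enforced where fibers are created,
    not here).
    """
    point = np.asarray(point, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    denom = float(d @ d)
    t = np.clip(((point - p1) @ d) / denom, 0.0, 1.0)
    return float(np.linalg.norm(point - (p1 + t * d)))


def point_to_segments(point, p1s: np.ndarray, p2s: np.ndarray) -> np.ndarray:
    """Distances from a single point to ``N`` segments given as (N, 3) arrays."""
    point = np.asarray(point, dtype=float)
    if len(p1s) == 0:
        return np.empty(0)
    d = p2s - p1s
    denom = np.einsum("ij,ij->i", d, d)
    t = np.einsum("ij,ij->i", point - p1s, d) / denom
    np.clip(t, 0.0, 1.0, out=t)
    closest = p1s + t[:, None] * d
    diff = closest - point
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def segment_to_points(p1, p2, points: np.ndarray) -> np.ndarray:
    """Distances from one segment ``p1 -> p2`` to each of ``N`` points (N, 3)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return np.empty(0)
    d = p2 - p1
    denom = float(d @ d)
    t = (points - p1) @ d / denom
    np.clip(t, 0.0, 1.0, out=t)
    closest = p1[None, :] + t[:, None] * d[None, :]
    diff = points - closest
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def sphere_segment_intersects(center, radius: float, p1, p2) -> bool:
    """Whether the segment passes through (or touches) a sphere of ``radius``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return point_segment_distance(center, p1, p2) <= radius


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Isotropic random direction."""
    return random_orientation(rng).unit_vector()


def random_orientation(rng: np.random.Generator, mode: str = "sphere") -> Orientation:
    """Draw a random orientation.

    mode="sphere" (default) samples directions uniformly on the unit sphere
    (``cos(theta)`` uniform on [-1, 1]).  mode="angles" samples ``theta``
    uniformly on [0, pi], which is the literal reading of picking elevation and
    azimuth at random but biases directions towards the poles; it is kept as an
    option for fidelity comparisons.
    """
    phi = rng.uniform(0.0, 2.0 * np.pi)
    if mode == "sphere":
        theta = float(np.arccos(1.0 - 2.0 * rng.random()))
    elif mode == "angles":
        theta = rng.uniform(0.0, np.pi)
    else:
        raise ValueError(f"unknown orientation mode {mode!r}")
    # np.arccos is inclusive of both ends; phi may equal 2*pi only with
    # probability zero, but guard against rounding.
    if phi >= 2.0 * np.pi:
        phi = 0.0
    return Orientation(theta=theta, phi=phi)


def endpoint_from(p1, orientation: Orientation, length: float) -> np.ndarray:
    """Second endpoint of a segment starting at ``p1`` with given direction/length."""
    if length <= 0:
        raise ValueError("length must be positive")
    return np.asarray(p1, dtype=float) + length * orientation.unit_vector()


def sample_in_cone(
    rng: np.random.Generator, axis: np.ndarray, max_angle: float, n: int
) -> np.ndarray:
    """Sample ``n`` unit vectors uniformly from the spherical cap of half-angle
    ``max_angle`` around ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cos_max = np.cos(max_angle)
    cos_a = rng.uniform(cos_max, 1.0, size=n)
    sin_a = np.sqrt(1.0 - cos_a**2)
    az = rng.uniform(0.0, 2.0 * np.pi, size=n)
    local = np.column_stack(
        [sin_a * np.cos(az), sin_a * np.sin(az), cos_a]
    )
    # Build an orthonormal frame whose z-axis is `axis`.
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    frame = np.column_stack([u, v, axis])
    return local @ frame.T
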