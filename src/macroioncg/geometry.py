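"""Sphere point placement and quaternion helpers.

Quaternions are stored ``(w, x, y, z)`` and normalised; ``quat_to_matrix(q)``
returns the body->space rotation matrix.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fibonacci_sphere",
    "place_beads_on_sphere",
    "quat_multiply",
    "quat_to_matrix",
    "quat_from_axis_angle",
    "random_quaternion",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class EmptyTemplateError(ValueError):
    """Raised when a shell with zero beads is requested."""


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Near-uniform deterministic lattice of ``n`` points on a sphere.

    Uses the golden-spiral construction; the minimal pairwise distance is
    within a few percent of the optimum for all n of practical interest.
    """
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = _GOLDEN_ANGLE * i
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return radius * pts


def place_beads_on_sphere(n: int, radius: float, mode: str = "fibonacci") -> np.ndarray:
    """Place ``n`` bead centers on a sphere of ``radius`` (A).

    Deterministic for fixed ``(n, mode)``.  ``n == 1`` gives a single pole
    point, ``n == 2`` an antipodal pair; larger shells use the Fibonacci
    lattice.
    """
    if n < 1:
        raise EmptyTemplateError("a macroion template needs at least one bead")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if mode != "fibonacci":
        raise ValueError(f"unknown placement mode {mode!r}")
    if n == 1:
        return np.array([[0.0, 0.0, radius]])
    if n == 2:
        return np.array([[0.0, 0.0, radius], [0.0, 0.0, -radius]])
    pts = fibonacci_sphere(n, radius)
    # The raw lattice has a small centroid offset; re-center and re-project
    # so every bead sits at exactly `radius` from the shell's center of mass
    # (rigid bodies rotate about the COM, so the two must coincide).
    for _ in range(200):
        shift = pts.mean(axis=0)
        pts = pts - shift
        pts *= radius / np.linalg.norm(pts, axis=1)[:, None]
        if np.linalg.norm(shift) < 1e-13 * radius:
            break
    return pts


# --- quaternions -----------------------------------------------------------

def quats_to_matrices(q: np.ndarray) -> np.ndarray:
    """Vectorised body->space rotation matrices for a (B, 4) quaternion array."""
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    rot = np.empty((len(q), 3, 3))
    rot[:, 0, 0] = 1 - 2 * (y * y + z * z)
    rot[:, 0, 1] = 2 * (x * y - w * z)
    rot[:, 0, 2] = 2 * (x * z + w * y)
    rot[:, 1, 0] = 2 * (x * y + w * z)
    rot[:, 1, 1] = 1 - 2 * (x * x + z * z)
    rot[:, 1, 2] = 2 * (y * z - w * x)
    rot[:, 2, 0] = 2 * (x * z - w * y)
    rot[:, 2, 1] = 2 * (y * z + w * x)
    rot[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return rot


def quat_multiply_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Hamilton product of two (B, 4) quaternion arrays."""
    aw, ax, ay, az = a[:, 0], a[:, 1], a[:, 2], a[:, 3]
    bw, bx, by, bz = b[:, 0], b[:, 1], b[:, 2], b[:, 3]
    return np.column_stack([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ])


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    h = 0.5 * angle
    return np.concatenate([[np.cos(h)], np.sin(h) * axis])


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Shoemake's method)."""
    u1, u2, u3 = rng.random(3)
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    return np.array([
        a * np.sin(2 * np.pi * u2),
        a * np.cos(2 * np.pi * u2),
        b * np.sin(2 * np.pi * u3),
        b * np.cos(2 * np.pi * u3),
    ])
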