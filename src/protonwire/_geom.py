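"""Small vector-geometry helpers (internal)."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two vectors in degrees."""
    c = float(np.dot(unit(v1), unit(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def any_perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to ``v``."""
    u = unit(v)
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return unit(np.cross(u, ref))


def rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about ``axis``."""
    k = unit(axis)
    return (
        v * np.cos(angle_rad)
        + np.cross(k, v) * np.sin(angle_rad)
        + k * np.dot(k, v) * (1.0 - np.cos(angle_rad))
    )


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, approximately uniform points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
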