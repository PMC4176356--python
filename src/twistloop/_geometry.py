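"""Frame-transport geometry for twistable discrete rings.

The material twist bookkeeping follows the discrete elastic rod picture:
each segment of a closed polygonal chain carries a reference director that
is parallel-transported (no added twist) between consecutive tangents, and
a material director obtained by rotating the reference director about the
tangent by a per-segment frame angle.  The twist at a junction is the
signed rotation needed to carry the transported material director of one
segment into the material director of the next, measured about the shared
downstream tangent.  Parallel transport between tangents is the minimal
rotation about their mutual perpendicular, which is exact to first order
in the bending angle and remains well defined up to antiparallel tangents
(in particular at 90 degree bends).
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "rotate_about",
    "parallel_transport",
    "signed_angle",
    "ring_edges",
    "ring_tangents",
    "bishop_frames",
    "reference_twists",
    "junction_twists_from_theta",
    "theta_from_junction_twists",
]

_DEGENERATE = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised for zero-length segments or antiparallel-tangent transport."""


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalise vectors along ``axis``; raise on (near-)zero length."""
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < _DEGENERATE):
        raise DegenerateGeometryError("zero-length segment")
    return v / n


def rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit vector ``axis`` by ``angle``."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def parallel_transport(v: np.ndarray, t_from: np.ndarray, t_to: np.ndarray) -> np.ndarray:
    """Transport ``v`` by the minimal rotation taking unit tangent ``t_from``
    to ``t_to`` (rotation about ``t_from x t_to``).

    Identity when the tangents coincide; raises for antiparallel tangents,
    where the minimal rotation is ambiguous.
    """
    k = np.cross(t_from, t_to)
    s2 = float(np.dot(k, k))
    c = float(np.dot(t_from, t_to))
    if s2 < _DEGENERATE:
        if c < 0.0:
            raise DegenerateGeometryError("antiparallel tangents: transport undefined")
        return v.copy()
    # Rodrigues with axis k (unnormalised), sin = |k|, cos = c
    return v * c + np.cross(k, v) + k * (np.dot(k, v) * (1.0 - c) / s2)


def signed_angle(a: np.ndarray, b: np.ndarray, about: np.ndarray) -> float:
    """Signed angle in (-pi, pi] carrying ``a`` into ``b`` about unit ``about``.

    Both vectors are assumed (close to) perpendicular to ``about``; only their
    perpendicular components matter.
    """
    return float(np.arctan2(np.dot(about, np.cross(a, b)), np.dot(a, b)))


def ring_edges(positions: np.ndarray) -> np.ndarray:
    """Edge vectors e_i = x_{i+1 mod N} - x_i of a closed ring, shape (N, 3)."""
    return np.roll(positions, -1, axis=0) - positions


def ring_tangents(positions: np.ndarray) -> np.ndarray:
    return unit(ring_edges(positions))


def _perpendicular_seed(t: np.ndarray) -> np.ndarray:
    probe = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return unit(np.cross(t, probe))


def bishop_frames(positions: np.ndarray, a0: np.ndarray | None = None) -> np.ndarray:
    """Reference directors built by space parallel transport along the ring.

    Returns an (N, 3) array of unit directors, one per segment, with
    ``a[i+1] = P(a[i]; t[i] -> t[i+1])`` for i = 0..N-2.  The transport
    around the closure junction is *not* applied: its mismatch with ``a[0]``
    is the holonomy of the closed tangent path (equal to -2*pi*Wr mod 2*pi).
    """
    t = ring_tangents(positions)
    n = len(t)
    a = np.empty_like(t)
    a[0] = _perpendicular_seed(t[0]) if a0 is None else unit(a0 - np.dot(a0, t[0]) * t[0])
    for i in range(n - 1):
        a[i + 1] = parallel_transport(a[i], t[i], t[i + 1])
        a[i + 1] = unit(a[i + 1] - np.dot(a[i + 1], t[i + 1]) * t[i + 1])
    return a


def reference_twists(positions: np.ndarray, directors: np.ndarray) -> np.ndarray:
    """Per-junction twist of the reference directors, shape (N,).

    ``ref[i]`` is the signed angle from the transported director
    ``P(a_i; t_i -> t_{i+1})`` to ``a_{i+1}``, about ``t_{i+1}``
    (junction i sits at bead i+1, between segments i and i+1 mod N).
    """
    t = ring_tangents(positions)
    n = len(t)
    ref = np.empty(n)
    for i in range(n):
        j = (i + 1) % n
        moved = parallel_transport(directors[i], t[i], t[j])
        ref[i] = signed_angle(moved, directors[j], t[j])
    return ref


def junction_twists_from_theta(
    positions: np.ndarray, theta: np.ndarray, directors: np.ndarray
) -> np.ndarray:
    """Material junction twists phi_i = theta_{i+1} - theta_i + ref_i."""
    ref = reference_twists(positions, directors)
    return np.roll(theta, -1) - theta + ref


def theta_from_junction_twists(
    positions: np.ndarray, phi: np.ndarray, directors: np.ndarray, tol: float = 0.3
) -> np.ndarray:
    """Per-segment frame angles realising the requested junction twists.

    Inverts ``phi_i = theta_{i+1} - theta_i + ref_i`` with theta_0 = 0.  A
    closed ring constrains sum(phi) to equal the reference holonomy modulo
    2*pi; any (small) residual is spread uniformly over the junctions so the
    reconstruction is always consistent.  Raises if the residual exceeds
    ``tol`` radians, which signals a genuinely unrealisable twist assignment.
    """
    ref = reference_twists(positions, directors)
    n = len(phi)
    defect = float(np.sum(phi) - np.sum(ref))
    defect -= 2.0 * np.pi * np.round(defect / (2.0 * np.pi))
    if abs(defect) > tol:
        raise ValueError(
            f"junction twists inconsistent with ring geometry (defect {defect:.3f} rad)"
        )
    phi_adj = phi - defect / n
    theta = np.zeros(n)
    for i in range(n - 1):
        theta[i + 1] = theta[i] + phi_adj[i] - ref[i]
    return theta
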