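"""Shared crystallographic and rotation geometry.

Conventions used throughout the package:

* reciprocal vectors carry no 2*pi factor, so ``|g| = 1/d``;
* pixels are 0-based, ``x`` is the column index and ``y`` the row index;
* the lab frame is right-handed with ``+z`` along the electron beam;
* the tilt axis lies in the detector plane at azimuth ``phi`` degrees,
  measured counterclockwise from ``+x``:  ``u = (cos phi, sin phi, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UnitCell",
    "rotation_about_axis",
    "tilt_axis_vector",
    "real_space_matrix",
    "reciprocal_matrix",
    "cell_from_real_matrix",
    "cell_from_reciprocal_matrix",
]


@dataclass(frozen=True)
class UnitCell:
    """Real-space unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if np.linalg.det(real_space_matrix(self)) <= 0:
            raise ValueError("degenerate cell: metric not positive definite")

    @property
    def volume(self) -> float:
        return float(np.linalg.det(real_space_matrix(self)))

    def parameters(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.alpha, self.beta, self.gamma])


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``axis``.

    Positive angle rotates counterclockwise when viewed from the axis tip.
    """
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    ux, uy, uz = u
    cross = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * cross + (1.0 - c) * np.outer(u, u)


def tilt_axis_vector(azimuth_deg: float) -> np.ndarray:
    """Unit vector of the tilt axis in the detector plane.

    The axis is a line, so the azimuth is taken modulo 180 degrees; phi and
    phi + 180 give the identical vector.
    """
    phi = np.deg2rad(azimuth_deg % 180.0)
    return np.array([np.cos(phi), np.sin(phi), 0.0])


def real_space_matrix(cell: UnitCell) -> np.ndarray:
    """3x3 matrix with rows a, b, c in a Cartesian crystal frame.

    Standard orientation: a along +x, b in the xy plane.
    """
    al, be, ga = np.deg2rad([cell.alpha, cell.beta, cell.gamma])
    cos_al, cos_be, cos_ga = np.cos([al, be, ga])
    sin_ga = np.sin(ga)
    a_vec = np.array([cell.a, 0.0, 0.0])
    b_vec = np.array([cell.b * cos_ga, cell.b * sin_ga, 0.0])
    cx = cell.c * cos_be
    cy = cell.c * (cos_al - cos_be * cos_ga) / sin_ga
    cz_sq = cell.c**2 - cx**2 - cy**2
    if cz_sq <= 0:
        raise ValueError("degenerate cell: angles incompatible")
    c_vec = np.array([cx, cy, np.sqrt(cz_sq)])
    return np.vstack([a_vec, b_vec, c_vec])


def reciprocal_matrix(cell: UnitCell) -> np.ndarray:
    """3x3 matrix with rows a*, b*, c* (1/d convention, Angstrom^-1)."""
    a_mat = real_space_matrix(cell)
    # rows of inv(A)^T satisfy a_i . a*_j = delta_ij
    return np.linalg.inv(a_mat).T


def cell_from_real_matrix(a_mat: np.ndarray) -> UnitCell:
    """Cell parameters from a 3x3 matrix whose rows are a, b, c."""
    a_mat = np.asarray(a_mat, dtype=float)
    lengths = np.linalg.norm(a_mat, axis=1)

    def angle(i: int, j: int) -> float:
        cosv = a_mat[i] @ a_mat[j] / (lengths[i] * lengths[j])
        return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))

    return UnitCell(
        a=float(lengths[0]),
        b=float(lengths[1]),
        c=float(lengths[2]),
        alpha=angle(1, 2),
        beta=angle(0, 2),
        gamma=angle(0, 1),
    )


def cell_from_reciprocal_matrix(b_mat: np.ndarray) -> UnitCell:
    """Cell parameters from a 3x3 matrix whose rows are a*, b*, c*."""
    b_mat = np.asarray(b_mat, dtype=float)
    if abs(np.linalg.det(b_mat)) < 1e-12:
        raise ValueError("singular reciprocal basis")
    a_mat = np.linalg.inv(b_mat).T
    return cell_from_real_matrix(a_mat)
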