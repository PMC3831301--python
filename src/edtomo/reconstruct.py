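"""Reciprocal-space reconstruction from 2D spot lists.

Each detected spot, measured relative to the shift-corrected direct beam,
is lifted onto the Ewald sphere (``gz = 1/lambda - sqrt(1/lambda^2 -
g_perp^2)``) and rotated about the tilt axis by the frame's combined tilt.
The tilt-axis azimuth is refined by scanning trial orientations and
scoring how tightly the short difference vectors of the reconstruction
cluster -- a bent lattice (wrong axis) smears the clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import lattice
from .geometry import rotation_about_axis, tilt_axis_vector
from .io import ExperimentInfo

__all__ = [
    "TiltAxis",
    "back_project_spot",
    "back_project",
    "map_to_3d",
    "refine_tilt_axis",
    "cut_section",
]

SPOT3D_COLUMNS = ["gx", "gy", "gz", "intensity", "frame", "x", "y"]


@dataclass(frozen=True)
class TiltAxis:
    """Tilt-axis line in the detector plane; azimuth stored in [0, 180)."""

    azimuth: float  # degrees ccw from +x

    def __post_init__(self) -> None:
        object.__setattr__(self, "azimuth", float(self.azimuth) % 180.0)

    @property
    def vector(self) -> np.ndarray:
        return tilt_axis_vector(self.azimuth)


def back_project(xy: np.ndarray, info: ExperimentInfo) -> np.ndarray:
    """Lift beam-relative detector positions (px) onto the Ewald sphere.

    Returns (n, 3) points satisfying ``|p - (0,0,1/lambda)| = 1/lambda``.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    g_perp = xy / info.pixels_per_inv_angstrom
    inv_lambda = 1.0 / info.wavelength
    perp_sq = np.sum(g_perp**2, axis=1)
    if np.any(perp_sq >= inv_lambda**2):
        raise ValueError("spot outside the Ewald sphere (g_perp >= 1/lambda)")
    gz = inv_lambda - np.sqrt(inv_lambda**2 - perp_sq)
    return np.column_stack([g_perp, gz])


def back_project_spot(x: float, y: float, info: ExperimentInfo) -> np.ndarray:
    """Scalar convenience wrapper around :func:`back_project`."""
    return back_project(np.array([[x, y]]), info)[0]


def _dedup_frame_selector(info: ExperimentInfo) -> np.ndarray:
    """Boolean mask of frames to keep: first occurrence of each combined tilt."""
    seen: set[float] = set()
    keep = np.zeros(len(info.frames), dtype=bool)
    for i, fr in enumerate(info.frames):
        if fr.combined_tilt not in seen:
            seen.add(fr.combined_tilt)
            keep[i] = True
    return keep


def map_to_3d(
    spots: pd.DataFrame,
    info: ExperimentInfo,
    axis: TiltAxis,
    beam_positions: np.ndarray | None = None,
    intensity_column: str = "integrated",
) -> pd.DataFrame:
    """Rotate back-projected spots into reciprocal space.

    ``spots`` must have columns frame, x, y (absolute px) and the intensity
    column.  ``beam_positions`` gives the direct-beam position per frame
    (defaults to the detector centre for all frames).  Overlap frames --
    repeated combined tilts -- are dropped, keeping the first occurrence.
    Rotation preserves norms exactly.
    """
    rows_det, cols_det = info.detector_shape
    if beam_positions is None:
        beam_positions = np.tile(
            np.array([cols_det / 2.0, rows_det / 2.0]), (len(info.frames), 1)
        )
    beam_positions = np.asarray(beam_positions, dtype=float)
    keep_frames = _dedup_frame_selector(info)
    frames = spots["frame"].to_numpy().astype(int)
    sel = keep_frames[frames]
    spots = spots.loc[sel]
    frames = frames[sel]
    xy_rel = spots[["x", "y"]].to_numpy() - beam_positions[frames]
    on_sphere = back_project(xy_rel, info)
    u = axis.vector
    tilts_rad = np.deg2rad(info.combined_tilts)
    g = np.empty_like(on_sphere)
    for fi in np.unique(frames):
        rot = rotation_about_axis(u, tilts_rad[fi])
        m = frames == fi
        g[m] = on_sphere[m] @ rot.T
    out = pd.DataFrame(
        {
            "gx": g[:, 0],
            "gy": g[:, 1],
            "gz": g[:, 2],
            "intensity": spots[intensity_column].to_numpy(),
            "frame": frames,
            "x": spots["x"].to_numpy(),
            "y": spots["y"].to_numpy(),
        }
    )
    if "saturated" in spots:
        out["saturated"] = spots["saturated"].to_numpy()
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# tilt-axis refinement


def _straightness_score(
    on_sphere: np.ndarray,
    frames: np.ndarray,
    xy: np.ndarray,
    intensities: np.ndarray,
    tilts_rad: np.ndarray,
    azimuth_deg: float,
    merge_3d_radius: float,
    merge_2d_radius: float,
    max_frame_gap: int,
    cluster_eps: float | None,
    max_diff_len: float | None,
    min_diff_len: float | None = None,
) -> float:
    """Mean spread (covariance trace) of the three shortest difference-vector
    clusters of the reconstruction at a trial azimuth; low = straight."""
    u = tilt_axis_vector(azimuth_deg)
    g = np.empty_like(on_sphere)
    for fi in np.unique(frames):
        rot = rotation_about_axis(u, tilts_rad[fi])
        m = frames == fi
        g[m] = on_sphere[m] @ rot.T
    labels = lattice.group_spots(
        g, frames, xy, merge_2d_radius, merge_3d_radius, max_frame_gap
    )
    order = np.argsort(labels, kind="stable")
    bounds = np.flatnonzero(np.diff(labels[order])) + 1
    merged = []
    for grp in np.split(order, bounds):
        w = intensities[grp]
        tot = w.sum()
        merged.append((w @ g[grp]) / tot if tot > 0 else g[grp].mean(axis=0))
    merged = np.asarray(merged)
    if len(merged) < 10:
        return np.inf
    try:
        clusters = lattice.difference_vector_clusters(
            merged, cluster_eps=cluster_eps, max_diff_len=max_diff_len,
            min_diff_len=min_diff_len, max_vectors=8000,
        )
    except ValueError:
        return np.inf
    if len(clusters) < 3:
        return np.inf
    # pick the three shortest noncollinear-ish clusters by length order
    return float(clusters["spread"].to_numpy()[:3].mean())


def refine_tilt_axis(
    spots: pd.DataFrame,
    info: ExperimentInfo,
    scan: tuple[float, float, float, float] = (0.0, 180.0, 0.5, 0.1),
    beam_positions: np.ndarray | None = None,
    intensity_column: str = "integrated",
    max_spots: int = 5000,
    merge_3d_radius: float = 0.02,
    merge_2d_radius: float = 8.0,
    max_frame_gap: int = 3,
) -> tuple[TiltAxis, pd.DataFrame]:
    """Find the tilt-axis azimuth that un-bends the reconstruction.

    Scans trial azimuths on a coarse grid over [start, stop), then refines
    on a fine grid around the best coarse value.  Returns the refined axis
    and the full score-vs-azimuth table.  Deterministic: when the spot list
    exceeds ``max_spots`` the strongest spots are used.
    """
    start, stop, coarse, fine = scan
    if len(spots) < 100:
        warnings.warn("fewer than 100 spots: tilt-axis refinement has low confidence")
    work = spots
    if len(work) > max_spots:
        idx = np.argsort(-work[intensity_column].to_numpy(), kind="stable")[:max_spots]
        work = work.iloc[np.sort(idx)]

    rows_det, cols_det = info.detector_shape
    if beam_positions is None:
        beam_positions = np.tile(
            np.array([cols_det / 2.0, rows_det / 2.0]), (len(info.frames), 1)
        )
    beam_positions = np.asarray(beam_positions, dtype=float)
    keep_frames = _dedup_frame_selector(info)
    frames = work["frame"].to_numpy().astype(int)
    sel = keep_frames[frames]
    work, frames = work.loc[sel], frames[sel]
    xy_abs = work[["x", "y"]].to_numpy()
    xy_rel = xy_abs - beam_positions[frames]
    on_sphere = back_project(xy_rel, info)
    intensities = work[intensity_column].to_numpy().astype(float)
    tilts_rad = np.deg2rad(info.combined_tilts)

    # fix the clustering scale once, from per-frame spot spacings (rotation
    # preserves distances, so this is independent of the trial azimuth)
    spacing_probe = _probe_spacing(on_sphere, frames)
    cluster_eps = 0.25 * spacing_probe
    max_diff_len = 1.6 * spacing_probe
    min_diff_len = 0.4 * spacing_probe

    def score(phi: float) -> float:
        return _straightness_score(
            on_sphere, frames, xy_abs, intensities, tilts_rad, phi,
            merge_3d_radius, merge_2d_radius, max_frame_gap,
            cluster_eps, max_diff_len, min_diff_len,
        )

    coarse_grid = np.arange(start, stop, coarse)
    coarse_scores = np.array([score(p) for p in coarse_grid])
    best = coarse_grid[int(np.argmin(coarse_scores))]
    fine_grid = np.arange(best - coarse, best + coarse + fine / 2, fine)
    fine_scores = np.array([score(p) for p in fine_grid])
    best_fine = fine_grid[int(np.argmin(fine_scores))]
    curve = pd.DataFrame(
        {
            "azimuth": np.concatenate([coarse_grid, fine_grid]),
            "score": np.concatenate([coarse_scores, fine_scores]),
            "stage": ["coarse"] * len(coarse_grid) + ["fine"] * len(fine_grid),
        }
    )
    return TiltAxis(azimuth=float(best_fine)), curve


def _probe_spacing(on_sphere: np.ndarray, frames: np.ndarray) -> float:
    """Shortest-spacing estimate from within-frame nearest neighbours.

    Spots on one frame are lattice nodes sliced by the Ewald sphere; their
    mutual distances are true reciprocal-lattice distances regardless of
    the (unknown) tilt axis, so the median within-frame nearest-neighbour
    distance is a stable scale for cluster parameters."""
    dists = []
    for fi in np.unique(frames):
        pts = on_sphere[frames == fi]
        if len(pts) < 3:
            continue
        d, _ = cKDTree(pts).query(pts, k=2)
        dists.append(d[:, 1])
    if not dists:
        return lattice.estimate_shortest_spacing(on_sphere)
    # low percentile: within a frame the nearest neighbour is only sometimes
    # along the globally shortest lattice direction
    return float(np.percentile(np.concatenate(dists), 10.0))


# ---------------------------------------------------------------------------
# sections


def cut_section(
    spots3d: pd.DataFrame,
    normal: np.ndarray | None = None,
    basis: "lattice.ReciprocalBasis | None" = None,
    axis: int = 2,
    offset: int = 0,
    thickness: float = 0.5,
) -> pd.DataFrame:
    """Spots in a slab perpendicular to a direction.

    With a ``basis``, the slab is taken along fractional index ``axis``
    (0 = h, 1 = k, 2 = l), e.g. ``axis=2, offset=1`` is an h k 1 cut.
    Alternatively ``normal`` defines the layer vector directly: the
    fractional coordinate is ``g . n / |n|^2``.  The slab is the half-open
    interval [offset - thickness/2, offset + thickness/2), so unit-thickness
    integer-offset cuts partition the cloud.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    g = spots3d[["gx", "gy", "gz"]].to_numpy()
    if basis is not None:
        frac = np.linalg.solve(basis.vectors.T, g.T).T[:, axis]
    elif normal is not None:
        normal = np.asarray(normal, dtype=float)
        frac = g @ normal / (normal @ normal)
    else:
        raise ValueError("either basis or normal is required")
    lo, hi = offset - thickness / 2.0, offset + thickness / 2.0
    return spots3d.loc[(frac >= lo) & (frac < hi)]
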