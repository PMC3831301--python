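"""Reflection merging, 3D integration, basis determination and indexing.

Spots lifted into reciprocal space are merged into reflections by
single-linkage grouping, the reciprocal basis is found by density
clustering of short difference vectors, the unit cell follows from the
basis, and reflections are indexed adaptively (each reflection is indexed
relative to its nearest already-indexed neighbour, which tolerates a
slowly bending lattice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .geometry import UnitCell, cell_from_reciprocal_matrix

__all__ = [
    "Reflections",
    "ReciprocalBasis",
    "IndexParams",
    "LatticeError",
    "merge_spots",
    "integrate_reflection_3d",
    "difference_vector_clusters",
    "find_reciprocal_basis",
    "cell_parameters_from_basis",
    "index_reflections",
    "absence_statistics",
]

REFLECTION_COLUMNS = [
    "gx", "gy", "gz", "I_max", "I_3d", "single_member",
    "frame_of_max", "x", "y", "d", "n_members", "saturated",
]


_MAX_DIFF_VECTORS = 40000


class LatticeError(RuntimeError):
    """Raised when no valid reciprocal basis can be determined."""

    def __init__(self, message: str, diagnostics: pd.DataFrame | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class Reflections:
    """Merged reflections: one row per lattice node observation."""

    table: pd.DataFrame  # REFLECTION_COLUMNS
    members: list[np.ndarray] = field(default_factory=list)  # spot row indices

    def __len__(self) -> int:
        return len(self.table)

    @property
    def g(self) -> np.ndarray:
        return self.table[["gx", "gy", "gz"]].to_numpy()


@dataclass(frozen=True)
class ReciprocalBasis:
    """Rows are the basis vectors a*, b*, c* in 1/Angstrom."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", v)
        if v.shape != (3, 3):
            raise ValueError("basis must be 3x3")
        lens = np.linalg.norm(v, axis=1)
        if abs(np.linalg.det(v)) <= 0.01 * np.prod(lens):
            raise ValueError("basis vectors are (near) coplanar")

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)


def group_spots(
    g: np.ndarray,
    frames: np.ndarray,
    xy: np.ndarray,
    merge_2d_radius: float,
    merge_3d_radius: float,
    max_frame_gap: int,
) -> np.ndarray:
    """Single-linkage component label per spot.

    Two spots link iff their frame gap <= max_frame_gap AND their 3D
    distance <= merge_3d_radius AND their 2D detector distance <=
    merge_2d_radius.
    """
    n = len(g)
    if n == 0:
        return np.zeros(0, dtype=int)
    pairs = cKDTree(g).query_pairs(merge_3d_radius, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        ok = (np.abs(frames[i] - frames[j]) <= max_frame_gap) & (
            np.linalg.norm(xy[i] - xy[j], axis=1) <= merge_2d_radius
        )
        pairs = pairs[ok]
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    return labels


def integrate_reflection_3d(
    positions: np.ndarray, intensities: np.ndarray
) -> tuple[float, bool]:
    """Integrate a merged reflection over its path through the sphere.

    ``I_3d = sum_{i=2..n} I_i * |K_i - K_{i-1}|`` with members ordered by
    frame.  A single-member reflection falls back to its own intensity and
    is flagged.
    """
    positions = np.asarray(positions, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if len(intensities) == 0:
        raise ValueError("empty reflection")
    if len(intensities) == 1:
        return float(intensities[0]), True
    steps = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    return float(np.sum(intensities[1:] * steps)), False


def merge_spots(
    spots3d: pd.DataFrame,
    merge_2d_radius: float = 8.0,
    merge_3d_radius: float = 0.02,
    max_frame_gap: int = 3,
    intensity_column: str = "intensity",
) -> Reflections:
    """Merge multi-frame spot observations into reflections.

    ``spots3d`` needs columns gx gy gz frame x y and the intensity column.
    The merged position is the intensity-weighted mean of the members.
    """
    if merge_2d_radius <= 0 or merge_3d_radius <= 0:
        raise ValueError("merge radii must be positive")
    g = spots3d[["gx", "gy", "gz"]].to_numpy()
    frames = spots3d["frame"].to_numpy()
    xy = spots3d[["x", "y"]].to_numpy()
    inten = spots3d[intensity_column].to_numpy().astype(float)
    sat = (
        spots3d["saturated"].to_numpy()
        if "saturated" in spots3d
        else np.zeros(len(spots3d), dtype=bool)
    )
    labels = group_spots(g, frames, xy, merge_2d_radius, merge_3d_radius, max_frame_gap)
    rows = []
    members: list[np.ndarray] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = idx[np.argsort(frames[idx], kind="stable")]
        gi, ii = g[idx], inten[idx]
        wsum = ii.sum()
        g_final = (ii @ gi) / wsum if wsum > 0 else gi.mean(axis=0)
        imax_pos = int(np.argmax(ii))
        i3d, single = integrate_reflection_3d(gi, ii)
        norm = np.linalg.norm(g_final)
        rows.append(
            {
                "gx": g_final[0], "gy": g_final[1], "gz": g_final[2],
                "I_max": float(ii[imax_pos]),
                "I_3d": i3d,
                "single_member": single,
                "frame_of_max": int(frames[idx][imax_pos]),
                "x": float(xy[idx][imax_pos, 0]),
                "y": float(xy[idx][imax_pos, 1]),
                "d": float(1.0 / norm) if norm > 0 else np.inf,
                "n_members": len(idx),
                "saturated": bool(sat[idx].any()),
            }
        )
        members.append(spots3d.index.to_numpy()[idx])
    table = pd.DataFrame(rows, columns=REFLECTION_COLUMNS)
    return Reflections(table=table, members=members)


# ---------------------------------------------------------------------------
# basis determination


def estimate_shortest_spacing(points: np.ndarray) -> float:
    """Robust estimate of the shortest lattice spacing: the median
    nearest-neighbour distance of the point cloud."""
    if len(points) < 2:
        raise ValueError("need at least two points")
    dist, _ = cKDTree(points).query(points, k=2)
    return float(np.median(dist[:, 1]))


def _canonical_sign(vecs: np.ndarray) -> np.ndarray:
    """Flip each vector so its largest-magnitude component is positive."""
    idx = np.argmax(np.abs(vecs), axis=1)
    signs = np.sign(vecs[np.arange(len(vecs)), idx])
    signs[signs == 0] = 1.0
    return vecs * signs[:, None]


def difference_vector_clusters(
    points: np.ndarray,
    cluster_eps: float | None = None,
    min_pts: int | None = None,
    max_diff_len: float | None = None,
    min_diff_len: float | None = None,
    max_vectors: int | None = None,
) -> pd.DataFrame:
    """Cluster short pairwise difference vectors of a reciprocal point cloud.

    Difference vectors are sign-canonicalized and density-clustered
    (DBSCAN-style).  Vectors shorter than ``min_diff_len`` (default a third
    of the estimated lattice spacing) are discarded first: they come from
    imperfectly merged duplicate observations, not from the lattice.
    Returns one row per cluster -- centroid, length, member count and
    spread (trace of the member covariance) -- sorted by centroid length.
    """
    points = np.asarray(points, dtype=float)
    spacing = estimate_shortest_spacing(points)
    if max_diff_len is None:
        max_diff_len = 3.0 * spacing
    if cluster_eps is None:
        cluster_eps = 0.15 * spacing
    if min_diff_len is None:
        min_diff_len = spacing / 3.0
    pairs = cKDTree(points).query_pairs(max_diff_len, output_type="ndarray")
    if len(pairs) == 0:
        return pd.DataFrame(columns=["vx", "vy", "vz", "length", "n", "spread"])
    diffs = _canonical_sign(points[pairs[:, 1]] - points[pairs[:, 0]])
    diffs = diffs[np.linalg.norm(diffs, axis=1) >= min_diff_len]
    if len(diffs) == 0:
        return pd.DataFrame(columns=["vx", "vy", "vz", "length", "n", "spread"])
    cap = max_vectors if max_vectors is not None else _MAX_DIFF_VECTORS
    if len(diffs) > cap:  # deterministic decimation, keeps density
        step = int(np.ceil(len(diffs) / cap))
        diffs = diffs[::step]
    if min_pts is None:
        min_pts = max(5, int(0.002 * len(diffs)))
    labels = DBSCAN(eps=cluster_eps, min_samples=min_pts).fit_predict(diffs)
    rows = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        cl = diffs[labels == lab]
        centroid = cl.mean(axis=0)
        spread = float(np.trace(np.cov(cl.T))) if len(cl) > 1 else 0.0
        rows.append([centroid, len(cl), spread])
    # a lattice vector whose largest component is ambiguous can split into
    # +-v halves under sign canonicalization; fold such duplicates together
    rows.sort(key=lambda r: -r[1])
    folded: list[list] = []
    for centroid, n, spread in rows:
        for f in folded:
            if (
                np.linalg.norm(centroid - f[0]) < cluster_eps
                or np.linalg.norm(centroid + f[0]) < cluster_eps
            ):
                flip = -1.0 if np.linalg.norm(centroid + f[0]) < np.linalg.norm(
                    centroid - f[0]
                ) else 1.0
                tot = f[1] + n
                f[0] = (f[0] * f[1] + flip * centroid * n) / tot
                f[2] = (f[2] * f[1] + spread * n) / tot
                f[1] = tot
                break
        else:
            folded.append([centroid.copy(), n, spread])
    out_rows = [
        {
            "vx": c[0], "vy": c[1], "vz": c[2],
            "length": float(np.linalg.norm(c)), "n": n, "spread": spread,
        }
        for c, n, spread in folded
    ]
    return (
        pd.DataFrame(out_rows, columns=["vx", "vy", "vz", "length", "n", "spread"])
        .sort_values("length", kind="stable")
        .reset_index(drop=True)
    )


def _buerger_reduce(basis: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Shorten basis vectors by adding/subtracting the others, to fixpoint."""
    b = basis.copy()
    for _ in range(max_iter):
        changed = False
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                for sign in (1.0, -1.0):
                    cand = b[i] + sign * b[j]
                    if np.linalg.norm(cand) < np.linalg.norm(b[i]) - 1e-12:
                        b[i] = cand
                        changed = True
        if not changed:
            break
    return b[np.argsort(np.linalg.norm(b, axis=1), kind="stable")]


def find_reciprocal_basis(
    reflections: Reflections | np.ndarray,
    cluster_eps: float | None = None,
    min_pts: int | None = None,
    max_diff_len: float | None = None,
) -> tuple[ReciprocalBasis, pd.DataFrame]:
    """Reciprocal basis from the three shortest noncoplanar difference-vector
    cluster centroids, followed by a shortest-vector reduction pass.

    Returns the basis and the cluster table (diagnostics)."""
    points = reflections.g if isinstance(reflections, Reflections) else np.asarray(reflections)
    clusters = difference_vector_clusters(points, cluster_eps, min_pts, max_diff_len)
    if len(clusters) < 3:
        raise LatticeError(
            f"only {len(clusters)} difference-vector clusters found; "
            "try a larger max_diff_len",
            clusters,
        )
    cents = clusters[["vx", "vy", "vz"]].to_numpy()
    lens = clusters["length"].to_numpy()
    # selection uses a stiffer coplanarity margin than the basis invariant so
    # that residually duplicated or smeared clusters cannot slip through
    margin = 0.05
    chosen: list[int] = []
    for i in range(len(cents)):
        if len(chosen) == 0:
            chosen.append(i)
        elif len(chosen) == 1:
            cross = np.cross(cents[chosen[0]], cents[i])
            if np.linalg.norm(cross) > margin * lens[chosen[0]] * lens[i]:
                chosen.append(i)
        else:
            trial = np.vstack([cents[chosen[0]], cents[chosen[1]], cents[i]])
            if abs(np.linalg.det(trial)) > margin * np.prod(np.linalg.norm(trial, axis=1)):
                chosen.append(i)
                break
    if len(chosen) < 3:
        raise LatticeError(
            "no three noncoplanar difference-vector clusters; "
            "try a larger max_diff_len",
            clusters,
        )
    basis = _buerger_reduce(cents[chosen])
    return ReciprocalBasis(vectors=basis), clusters


def cell_parameters_from_basis(
    basis: ReciprocalBasis, transform: np.ndarray | None = None
) -> UnitCell:
    """Real-space cell parameters from a reciprocal basis.

    ``transform`` is an optional integer matrix (|det| >= 1) applied to the
    basis rows first, for re-expressing the reduced cell in a conventional
    setting."""
    vecs = basis.vectors
    if transform is not None:
        transform = np.asarray(transform, dtype=float)
        if abs(np.linalg.det(transform)) < 1.0 - 1e-9:
            raise ValueError("transform must have |det| >= 1")
        vecs = transform @ vecs
    return cell_from_reciprocal_matrix(vecs)


# ---------------------------------------------------------------------------
# indexing


@dataclass
class IndexParams:
    threshold: float | tuple[float, float, float] = 0.1  # per-axis rounding limit
    neighbor_radius: float | None = None  # default: 1.5 x longest basis vector
    resolution_ordered: bool = True

    def thresholds(self) -> np.ndarray:
        t = np.broadcast_to(np.asarray(self.threshold, dtype=float), (3,)).copy()
        if np.any(t <= 0) or np.any(t >= 0.5):
            raise ValueError("thresholds must lie in (0, 0.5)")
        return t


def index_reflections(
    reflections: Reflections,
    basis: ReciprocalBasis,
    params: IndexParams | None = None,
) -> pd.DataFrame:
    """Adaptively index merged reflections against a reciprocal basis.

    Reflections are processed from low to high resolution.  Each one is
    indexed relative to its nearest already-accepted neighbour (the origin,
    carrying indices (0,0,0), is always available), which makes the
    assignment tolerant to slow lattice bending.  A reflection is accepted
    when every fractional index is within the per-axis threshold of an
    integer; rejected reflections are kept with ``accepted=False``.
    """
    params = params or IndexParams()
    thr = params.thresholds()
    table = reflections.table
    g = table[["gx", "gy", "gz"]].to_numpy()
    n = len(g)
    bt = basis.vectors.T  # solve bt @ coeff = vector
    radius = params.neighbor_radius
    if radius is None:
        radius = 1.5 * float(np.max(basis.lengths))
    order = np.argsort(np.linalg.norm(g, axis=1), kind="stable") if params.resolution_ordered \
        else np.arange(n)
    frame_of_max = table["frame_of_max"].to_numpy() if "frame_of_max" in table else np.zeros(n)

    anchor_pos = [np.zeros(3)]  # origin of the reciprocal lattice
    anchor_hkl = [np.zeros(3)]
    anchor_frame = [-1]
    frac = np.zeros((n, 3))
    hkl = np.zeros((n, 3), dtype=int)
    dev = np.zeros(n)
    accepted = np.zeros(n, dtype=bool)
    for row in order:
        apos = np.asarray(anchor_pos)
        dists = np.linalg.norm(apos - g[row], axis=1)
        eligible = np.flatnonzero(dists <= radius)
        if len(eligible) == 0:
            eligible = np.array([0])  # fall back to the origin
        best = np.min(dists[eligible])
        ties = eligible[dists[eligible] <= best + 1e-12]
        if len(ties) > 1:  # deterministic tie-break: earliest frame of max
            ties = ties[np.argsort([anchor_frame[t] for t in ties], kind="stable")]
        pick = int(ties[0])
        coeff = np.linalg.solve(bt, g[row] - apos[pick])
        f = np.asarray(anchor_hkl[pick]) + coeff
        r = np.rint(f)
        frac[row] = f
        hkl[row] = r.astype(int)
        dev[row] = float(np.max(np.abs(f - r)))
        if np.all(np.abs(f - r) <= thr):
            accepted[row] = True
            anchor_pos.append(g[row])
            anchor_hkl.append(r)
            anchor_frame.append(int(frame_of_max[row]))

    out = table.copy()
    out["h_frac"], out["k_frac"], out["l_frac"] = frac[:, 0], frac[:, 1], frac[:, 2]
    out["h"], out["k"], out["l"] = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    out["deviation"] = dev
    out["accepted"] = accepted
    return out


# ---------------------------------------------------------------------------
# systematic-absence statistics

_ABSENCE_CLASSES: list[tuple[str, callable]] = [
    ("h+k+l odd", lambda h, k, l: (h + k + l) % 2 != 0),
    ("h+k odd", lambda h, k, l: (h + k) % 2 != 0),
    ("h+l odd", lambda h, k, l: (h + l) % 2 != 0),
    ("k+l odd", lambda h, k, l: (k + l) % 2 != 0),
    ("h0l: h odd", lambda h, k, l: (k == 0) & (h % 2 != 0)),
    ("h0l: l odd", lambda h, k, l: (k == 0) & (l % 2 != 0)),
    ("h0l: h+l odd", lambda h, k, l: (k == 0) & ((h + l) % 2 != 0)),
    ("0kl: k odd", lambda h, k, l: (h == 0) & (k % 2 != 0)),
    ("0kl: l odd", lambda h, k, l: (h == 0) & (l % 2 != 0)),
    ("0kl: k+l odd", lambda h, k, l: (h == 0) & ((k + l) % 2 != 0)),
    ("hk0: h odd", lambda h, k, l: (l == 0) & (h % 2 != 0)),
    ("hk0: k odd", lambda h, k, l: (l == 0) & (k % 2 != 0)),
    ("hk0: h+k odd", lambda h, k, l: (l == 0) & ((h + k) % 2 != 0)),
    ("h00: h odd", lambda h, k, l: (k == 0) & (l == 0) & (h % 2 != 0)),
    ("0k0: k odd", lambda h, k, l: (h == 0) & (l == 0) & (k % 2 != 0)),
    ("00l: l odd", lambda h, k, l: (h == 0) & (k == 0) & (l % 2 != 0)),
]


def absence_statistics(
    indexed: pd.DataFrame, intensity_column: str = "I_max"
) -> pd.DataFrame:
    """Reflection statistics per potential systematic-absence class.

    For each class the number of (accepted) reflections, their mean
    intensity and mean I/sigma with sigma = sqrt(I) are reported; empty
    classes yield NaN means."""
    sel = indexed[indexed["accepted"]] if "accepted" in indexed else indexed
    h = sel["h"].to_numpy()
    k = sel["k"].to_numpy()
    l = sel["l"].to_numpy()
    inten = sel[intensity_column].to_numpy().astype(float)
    with np.errstate(invalid="ignore"):
        i_over_sig = np.where(inten > 0, np.sqrt(inten), np.nan)
    rows = []
    for name, rule in _ABSENCE_CLASSES:
        mask = rule(h, k, l)
        cnt = int(mask.sum())
        rows.append(
            {
                "class": name,
                "n": cnt,
                "mean_I": float(inten[mask].mean()) if cnt else np.nan,
                "mean_I_over_sigma": float(np.nanmean(i_over_sig[mask])) if cnt else np.nan,
            }
        )
    return pd.DataFrame(rows)
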