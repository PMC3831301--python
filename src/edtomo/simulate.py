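"""Forward simulator of rotation electron diffraction experiments.

Produces MRC frames, an information file and full ground truth (per-frame
spot lists, true reciprocal basis, drift track, reference intensities), so
the whole processing chain can be validated without instrument data.

The geometry is the exact inverse of the reconstruction: a reciprocal
lattice point ``p`` (lab frame at combined tilt zero) observed at tilt
``theta`` sits at ``q = R(-theta) p``; it diffracts when its excitation
error -- the signed distance along the beam from the Ewald sphere -- is
within three rocking halfwidths, and its transverse components map to the
detector by a flat scaling of ``pixels_per_inv_angstrom``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .geometry import UnitCell, reciprocal_matrix, rotation_about_axis, tilt_axis_vector
from .io import (
    ExperimentInfo,
    FrameRecord,
    TiltSchedule,
    build_tilt_schedule,
    write_info_file,
    write_mrc,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "enumerate_reflections",
    "frame_projection",
    "render_dataset",
    "random_orientation",
    "extinct_p21n",
]

SPOT_COLUMNS = ["frame", "h", "k", "l", "x", "y", "intensity", "gx", "gy", "gz"]


def extinct_p21n(hkl: np.ndarray) -> np.ndarray:
    """Systematic-absence mask in the style of an n-glide plus screw axis:
    h0l with h+l odd, and 0k0 with k odd, are extinct."""
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    glide = (k == 0) & ((h + l) % 2 != 0)
    screw = (h == 0) & (l == 0) & (k % 2 != 0)
    return glide | screw


@dataclass
class SimConfig:
    cell: UnitCell
    schedule: TiltSchedule
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    tilt_axis_azimuth_true: float = 48.5
    wavelength: float = 0.0251
    pixels_per_inv_angstrom: float = 280.0
    detector_shape: tuple[int, int] = (512, 512)
    bit_depth: int = 12
    d_min: float = 1.2
    rocking_halfwidth: float = 0.002  # excitation-error scale zeta, 1/Angstrom
    psf_sigma: float = 1.5  # px
    background_level: float = 20.0
    poisson_noise: bool = True
    drift_step_sigma: float = 0.0  # px per frame, random walk of direct beam
    intensity_range: tuple[float, float] = (50.0, 3000.0)
    extinction: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.d_min <= self.wavelength:
            raise ValueError("d_min must exceed the wavelength")
        if self.rocking_halfwidth <= 0 or self.psf_sigma <= 0:
            raise ValueError("rocking_halfwidth and psf_sigma must be positive")

    @property
    def beam_centre(self) -> np.ndarray:
        # (x, y) = (col, row), 0-based
        return np.array([self.detector_shape[1] / 2.0, self.detector_shape[0] / 2.0])

    @property
    def saturation_level(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    spots: pd.DataFrame  # per-frame recorded spots, SPOT_COLUMNS
    basis: np.ndarray  # rows a*, b*, c* in the lab frame at combined tilt 0
    drift: np.ndarray  # (n_frames, 2) direct-beam offset from nominal centre
    ref_intensities: pd.DataFrame  # columns h k l intensity (Friedel symmetric)


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def enumerate_reflections(
    cell: UnitCell, d_min: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All reflections hkl (except 000) with ``|g| <= 1/d_min``.

    Returns ``(hkl, g, d)`` where ``g`` are row vectors in the crystal
    frame (1/Angstrom) and ``d = 1/|g|``.  Since ``h = g . a``, the index
    bounds ``|h| <= a/d_min`` (etc.) are exact.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    b_mat = reciprocal_matrix(cell)
    hmax = int(np.floor(cell.a / d_min))
    kmax = int(np.floor(cell.b / d_min))
    lmax = int(np.floor(cell.c / d_min))
    hh, kk, ll = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    g = hkl @ b_mat
    norms = np.linalg.norm(g, axis=1)
    keep = norms <= (1.0 / d_min) * (1 + 1e-12)
    hkl, g, norms = hkl[keep], g[keep], norms[keep]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order], g[order], 1.0 / norms[order]


def _lab_points(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    hkl, g, _ = enumerate_reflections(config.cell, config.d_min)
    if config.extinction is not None:
        keep = ~config.extinction(hkl)
        hkl, g = hkl[keep], g[keep]
    return hkl, g @ config.orientation.T


def frame_projection(
    config: SimConfig, combined_tilt: float, _points: tuple[np.ndarray, np.ndarray] | None = None
) -> pd.DataFrame:
    """Spots visible on one frame at the given combined tilt (degrees).

    A reflection appears iff its excitation error ``s`` satisfies
    ``|s| <= 3 * rocking_halfwidth``; its relative intensity is
    ``exp(-s^2 / (2 zeta^2))``.  Detector coordinates are relative to the
    nominal (undrifted) beam centre.  Columns ``gx gy gz`` hold the
    on-sphere point rotated into reciprocal space -- what an ideal
    reconstruction recovers for this spot.
    """
    hkl, p = _points if _points is not None else _lab_points(config)
    zeta = config.rocking_halfwidth
    u = tilt_axis_vector(config.tilt_axis_azimuth_true)
    theta = np.deg2rad(combined_tilt)
    q = p @ rotation_about_axis(u, -theta).T
    inv_lambda = 1.0 / config.wavelength
    perp_sq = q[:, 0] ** 2 + q[:, 1] ** 2
    inside = perp_sq < inv_lambda**2
    sphere_z = np.full(len(q), np.inf)
    sphere_z[inside] = inv_lambda - np.sqrt(inv_lambda**2 - perp_sq[inside])
    s = q[:, 2] - sphere_z
    keep = np.abs(s) <= 3.0 * zeta
    hkl, q, s, sphere_z = hkl[keep], q[keep], s[keep], sphere_z[keep]
    rel = np.exp(-(s**2) / (2.0 * zeta**2))
    ppa = config.pixels_per_inv_angstrom
    cx, cy = config.beam_centre
    x = q[:, 0] * ppa + cx
    y = q[:, 1] * ppa + cy
    # on-sphere point rotated back into reciprocal space (ideal reconstruction)
    q_sphere = np.column_stack([q[:, 0], q[:, 1], sphere_z])
    g_rot = q_sphere @ rotation_about_axis(u, theta).T
    margin = 3.0 * config.psf_sigma
    rows, cols = config.detector_shape
    on_det = (
        (x >= margin) & (x <= cols - 1 - margin) & (y >= margin) & (y <= rows - 1 - margin)
    )
    return pd.DataFrame(
        {
            "h": hkl[on_det, 0],
            "k": hkl[on_det, 1],
            "l": hkl[on_det, 2],
            "x": x[on_det],
            "y": y[on_det],
            "rel_intensity": rel[on_det],
            "gx": g_rot[on_det, 0],
            "gy": g_rot[on_det, 1],
            "gz": g_rot[on_det, 2],
        }
    )


def _reference_intensities(config: SimConfig, hkl: np.ndarray, rng: np.random.Generator) -> dict:
    """Log-uniform reference intensities assigned per Friedel pair."""
    lo, hi = config.intensity_range
    ref: dict[tuple[int, int, int], float] = {}
    for row in hkl:
        key = tuple(int(v) for v in row)
        mate = tuple(-v for v in key)
        if mate in ref:
            ref[key] = ref[mate]
        else:
            ref[key] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return ref


def _stamp(img: np.ndarray, x: float, y: float, amplitude: float, sigma: float) -> None:
    """Add a 2D Gaussian whose brightest pixel equals ``amplitude``."""
    rows, cols = img.shape
    half = int(np.ceil(4.0 * sigma))
    x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
    y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
    x0c, x1c = max(x0, 0), min(x1, cols)
    y0c, y1c = max(y0, 0), min(y1, rows)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - x
    ys = np.arange(y0c, y1c) - y
    patch = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma**2))
    peak = patch.max()
    if peak > 0:
        img[y0c:y1c, x0c:x1c] += (amplitude / peak) * patch


def render_dataset(config: SimConfig, outdir: str | Path) -> tuple[ExperimentInfo, GroundTruth]:
    """Render the full dataset: MRC frames, info file, ground-truth TSV.

    Identical config (including seed) yields byte-identical output files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    hkl, p = _lab_points(config)
    ref = _reference_intensities(config, hkl, rng)
    triples = build_tilt_schedule(config.schedule)
    n = len(triples)

    if config.drift_step_sigma > 0:
        steps = rng.normal(0.0, config.drift_step_sigma, size=(n, 2))
        steps[0] = 0.0
        drift = np.cumsum(steps, axis=0)
    else:
        drift = np.zeros((n, 2))

    sat = config.saturation_level
    records = []
    truth_frames = []
    for i, (gonio, beam, comb) in enumerate(triples):
        proj = frame_projection(config, comb, _points=(hkl, p))
        img = np.full(config.detector_shape, float(config.background_level))
        amps = np.array(
            [ref[(int(h), int(k), int(l))] for h, k, l in proj[["h", "k", "l"]].to_numpy()]
        )
        amps = amps * proj["rel_intensity"].to_numpy() if len(proj) else amps
        xs = proj["x"].to_numpy() + drift[i, 0]
        ys = proj["y"].to_numpy() + drift[i, 1]
        for x, y, a in zip(xs, ys, amps):
            _stamp(img, x, y, a, config.psf_sigma)
        bx, by = config.beam_centre + drift[i]
        _stamp(img, bx, by, float(sat), 2.0 * config.psf_sigma)
        if config.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        img = np.clip(np.rint(img), 0, sat).astype(np.uint16)
        fname = f"frame_{i:04d}.mrc"
        write_mrc(outdir / fname, img)
        records.append(FrameRecord(fname, gonio, beam, gonio + beam))
        tf = pd.DataFrame(
            {
                "frame": i,
                "h": proj["h"],
                "k": proj["k"],
                "l": proj["l"],
                "x": xs,
                "y": ys,
                "intensity": amps,
                "gx": proj["gx"],
                "gy": proj["gy"],
                "gz": proj["gz"],
            }
        )
        truth_frames.append(tf)

    info = ExperimentInfo(
        wavelength=config.wavelength,
        pixels_per_inv_angstrom=config.pixels_per_inv_angstrom,
        tilt_axis_azimuth=config.tilt_axis_azimuth_true,
        frames=tuple(records),
        detector_shape=config.detector_shape,
        bit_depth=config.bit_depth,
    )
    write_info_file(info, outdir / "experiment.info")

    spots = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(columns=SPOT_COLUMNS)
    )
    b_mat = reciprocal_matrix(config.cell)
    basis_lab = b_mat @ config.orientation.T
    ref_df = pd.DataFrame(
        [(h, k, l, v) for (h, k, l), v in sorted(ref.items())],
        columns=["h", "k", "l", "intensity"],
    )
    truth = GroundTruth(spots=spots, basis=basis_lab, drift=drift, ref_intensities=ref_df)
    spots.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return info, truth
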