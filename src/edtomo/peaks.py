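"""Diffraction-spot detection and intensity extraction.

Spots are found by a difference-of-Gaussians scheme: the frame smoothed
with a wide Gaussian acts as background, the frame smoothed with a narrow
Gaussian as the (noise-reduced) signal, and pixels where signal exceeds
background by a user threshold are grouped into connected components, one
spot per component at its brightest pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PeakHuntParams",
    "hunt_peaks",
    "hunt_peaks_stack",
    "extract_intensities",
    "SPOT2D_COLUMNS",
]

SPOT2D_COLUMNS = [
    "frame",
    "x",
    "y",
    "raw",
    "smoothed",
    "integrated",
    "saturated",
    "partial",
]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class PeakHuntParams:
    background_sigma: float = 12.0  # px; wide blur, the background estimate
    signal_sigma: float = 1.0  # px; narrow blur, the denoised signal
    threshold: float = 10.0  # counts above background
    min_separation: float = 3.0  # px, reserved for duplicate suppression
    exclusion_radius: float = 20.0  # px around the direct beam

    def __post_init__(self) -> None:
        if not self.background_sigma > self.signal_sigma > 0:
            raise ValueError("need background_sigma > signal_sigma > 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def smoothed_frame(frame: np.ndarray, signal_sigma: float) -> np.ndarray:
    """Narrow-Gaussian smoothed frame (kernel truncated at 4 sigma)."""
    return ndimage.gaussian_filter(frame.astype(float), signal_sigma, truncate=4.0)


def hunt_peaks(
    frame: np.ndarray,
    params: PeakHuntParams,
    beam_centre: tuple[float, float] | None = None,
    sat_mask: np.ndarray | None = None,
    frame_index: int = 0,
) -> pd.DataFrame:
    """Detect diffraction spots on one frame.

    Returns a DataFrame with one row per spot: absolute pixel position of
    the brightest pixel of each 8-connected component (ties broken toward
    the lowest (y, x)), the raw and smoothed intensity there, and a
    saturation flag if the component touches a saturated pixel.  Components
    within ``exclusion_radius`` of ``beam_centre`` are dropped.
    """
    frame = np.asarray(frame, dtype=float)
    background = ndimage.gaussian_filter(frame, params.background_sigma, truncate=4.0)
    signal = ndimage.gaussian_filter(frame, params.signal_sigma, truncate=4.0)
    mask = signal > background + params.threshold
    labels, n_comp = ndimage.label(mask, structure=_EIGHT_CONN)
    rows: list[dict] = []
    if n_comp:
        # argmax of the smoothed signal within each component; np.argmax on the
        # flattened array takes the first (lowest y, then x) among ties
        peak_flat = ndimage.labeled_comprehension(
            signal, labels, np.arange(1, n_comp + 1),
            lambda vals, pos: pos[np.argmax(vals)], int, 0, pass_positions=True,
        )
        ys, xs = np.unravel_index(peak_flat, frame.shape)
        if sat_mask is not None:
            sat_hit = ndimage.labeled_comprehension(
                sat_mask.astype(bool), labels, np.arange(1, n_comp + 1), np.any, bool, False
            )
        else:
            sat_hit = np.zeros(n_comp, dtype=bool)
        for x, y, sat in zip(xs, ys, sat_hit):
            if beam_centre is not None:
                if np.hypot(x - beam_centre[0], y - beam_centre[1]) <= params.exclusion_radius:
                    continue
            rows.append(
                {
                    "frame": frame_index,
                    "x": float(x),
                    "y": float(y),
                    "raw": float(frame[y, x]),
                    "smoothed": float(signal[y, x]),
                    "integrated": np.nan,
                    "saturated": bool(sat),
                    "partial": False,
                }
            )
    return pd.DataFrame(rows, columns=SPOT2D_COLUMNS).astype(
        {"frame": int, "saturated": bool, "partial": bool}
    )


def hunt_peaks_stack(
    stack_data: np.ndarray,
    params: PeakHuntParams,
    beam_centres: np.ndarray | None = None,
    sat_masks: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run :func:`hunt_peaks` over a whole stack; beam centre per frame."""
    frames = []
    for i in range(stack_data.shape[0]):
        bc = None if beam_centres is None else tuple(beam_centres[i])
        sm = None if sat_masks is None else sat_masks[i]
        frames.append(hunt_peaks(stack_data[i], params, bc, sm, frame_index=i))
    return pd.concat(frames, ignore_index=True)


def extract_intensities(
    frame: np.ndarray,
    spots: pd.DataFrame,
    mode: str = "integrated",
    window_radius: float = 5.0,
    annulus_width: float = 3.0,
    signal_sigma: float = 1.0,
) -> pd.DataFrame:
    """Fill the intensity column of ``spots`` (rows for this frame).

    ``smoothed`` mode reads the narrow-Gaussian smoothed frame at the spot
    position.  ``integrated`` mode sums (pixel - local background) over the
    disc of ``window_radius``; the background is the mean over the annulus
    (window_radius, window_radius + annulus_width].  Spots whose window is
    clipped by the frame edge are flagged partial.
    """
    if mode not in ("smoothed", "integrated"):
        raise ValueError(f"unknown intensity mode {mode!r}")
    frame = np.asarray(frame, dtype=float)
    out = spots.copy()
    if mode == "smoothed":
        sm = smoothed_frame(frame, signal_sigma)
        vals = [sm[int(round(y)), int(round(x))] for x, y in zip(out["x"], out["y"])]
        out["smoothed"] = vals
        return out

    nrows, ncols = frame.shape
    r_in = window_radius
    r_out = window_radius + annulus_width
    half = int(np.ceil(r_out))
    integ = np.empty(len(out))
    partial = np.zeros(len(out), dtype=bool)
    for j, (x, y) in enumerate(zip(out["x"].to_numpy(), out["y"].to_numpy())):
        xi, yi = int(round(x)), int(round(y))
        x0, x1 = xi - half, xi + half + 1
        y0, y1 = yi - half, yi + half + 1
        if x0 < 0 or y0 < 0 or x1 > ncols or y1 > nrows:
            partial[j] = True
            x0, x1 = max(x0, 0), min(x1, ncols)
            y0, y1 = max(y0, 0), min(y1, nrows)
        win = frame[y0:y1, x0:x1]
        yy, xx = np.mgrid[y0:y1, x0:x1]
        rr = np.hypot(xx - x, yy - y)
        disc = rr <= r_in
        ann = (rr > r_in) & (rr <= r_out)
        bg = win[ann].mean() if np.any(ann) else 0.0
        integ[j] = float((win[disc] - bg).sum())
    out["integrated"] = integ
    out["partial"] = out["partial"].to_numpy() | partial
    return out
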