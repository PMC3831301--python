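"""Direct-beam drift detection and correction.

The beam (and with it the whole pattern) drifts slowly through a dataset.
Each frame's shift is found by cross-correlating a small region around the
direct beam against the running sum of all previously aligned frames, then
refined to sub-pixel precision with a quadratic fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import FrameStack

__all__ = ["ShiftTable", "estimate_shifts", "apply_shifts"]


@dataclass
class ShiftTable:
    """Per-frame (dx, dy) displacement of the pattern relative to frame 0."""

    shifts: np.ndarray  # (n_frames, 2), columns dx, dy, px
    roi_centre: tuple[float, float]  # (x, y)
    roi_halfsize: int
    clamped: np.ndarray  # bool flags: correlation peak hit the ROI border

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("frame\tdx\tdy\n")
            for i, (dx, dy) in enumerate(self.shifts):
                fh.write(f"{i}\t{dx:.6f}\t{dy:.6f}\n")


def _preprocess(roi: np.ndarray) -> np.ndarray:
    """Background-subtract and clip so stray Bragg spots cannot dominate."""
    out = roi - np.median(roi)
    hi = np.percentile(out, 99.9)
    if hi > 0:
        out = np.clip(out, None, hi)
    return out


def _quadratic_peak_1d(cm: float, c0: float, cp: float) -> float:
    denom = cm + cp - 2.0 * c0
    if denom >= 0:  # flat or non-concave: no refinement
        return 0.0
    delta = 0.5 * (cm - cp) / denom
    return float(np.clip(delta, -0.5, 0.5))


def _correlate_shift(ref: np.ndarray, img: np.ndarray) -> tuple[float, float, bool]:
    """Translation (dx, dy) of ``img`` relative to ``ref`` by FFT
    cross-correlation with 3x3 quadratic sub-pixel refinement."""
    f_ref = np.fft.rfft2(ref)
    f_img = np.fft.rfft2(img)
    corr = np.fft.irfft2(f_img * np.conj(f_ref), s=ref.shape)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    rows, cols = corr.shape
    clamped = False
    # wrap-around indices for the 3x3 neighbourhood
    cxs = corr[iy, [(ix - 1) % cols, ix, (ix + 1) % cols]]
    cys = corr[[(iy - 1) % rows, iy, (iy + 1) % rows], ix]
    dx = ix + _quadratic_peak_1d(cxs[0], cxs[1], cxs[2])
    dy = iy + _quadratic_peak_1d(cys[0], cys[1], cys[2])
    if dx > cols / 2:
        dx -= cols
    if dy > rows / 2:
        dy -= rows
    half_x, half_y = cols // 2 - 1, rows // 2 - 1
    if abs(dx) >= half_x or abs(dy) >= half_y:
        clamped = True
        dx = float(np.clip(dx, -half_x, half_x))
        dy = float(np.clip(dy, -half_y, half_y))
    return float(dx), float(dy), clamped


def estimate_shifts(
    stack: FrameStack,
    roi_centre: tuple[float, float] | None = None,
    roi_halfsize: int = 128,
) -> ShiftTable:
    """Estimate per-frame pattern shifts from the direct-beam region.

    Frame ``i`` is cross-correlated against the running sum of frames
    ``0..i-1`` after their own shifts were corrected, which suppresses noise
    in the reference as the stack progresses.  The direct beam must be the
    strongest feature inside the ROI.  Deterministic; frame 0 defines the
    origin, so its shift is (0, 0).
    """
    n, rows, cols = stack.data.shape
    if roi_centre is None:
        roi_centre = (cols / 2.0, rows / 2.0)
    cx, cy = int(round(roi_centre[0])), int(round(roi_centre[1]))
    h = int(roi_halfsize)
    if not (h <= cx <= cols - h and h <= cy <= rows - h):
        raise ValueError("ROI extends outside the detector")

    def roi_of(img: np.ndarray) -> np.ndarray:
        return _preprocess(img[cy - h : cy + h, cx - h : cx + h].astype(float))

    shifts = np.zeros((n, 2))
    clamped = np.zeros(n, dtype=bool)
    running = roi_of(stack.data[0]).copy()
    for i in range(1, n):
        roi = roi_of(stack.data[i])
        dx, dy, clip = _correlate_shift(running / i, roi)
        shifts[i] = (dx, dy)
        clamped[i] = clip
        running += ndimage.shift(roi, (-dy, -dx), order=1, mode="constant", cval=0.0)
    return ShiftTable(
        shifts=shifts, roi_centre=(float(roi_centre[0]), float(roi_centre[1])),
        roi_halfsize=h, clamped=clamped,
    )


def apply_shifts(stack: FrameStack, table: ShiftTable) -> FrameStack:
    """Resample every frame so the pattern sits at the frame-0 position.

    Bilinear interpolation for counts (edge values extended, which keeps the
    total count of a flat-background frame conserved); nearest-neighbour for
    the saturation mask.  Zero shifts return the data unchanged
    (bit-identical)."""
    n = stack.data.shape[0]
    data = np.empty_like(stack.data)
    sat = np.empty_like(stack.saturated)
    for i in range(n):
        dx, dy = table.shifts[i]
        if dx == 0.0 and dy == 0.0:
            data[i] = stack.data[i]
            sat[i] = stack.saturated[i]
        else:
            data[i] = ndimage.shift(
                stack.data[i].astype(float), (-dy, -dx), order=1, mode="nearest"
            )
            sat[i] = (
                ndimage.shift(
                    stack.saturated[i].astype(float), (-dy, -dx), order=0,
                    mode="constant", cval=0.0,
                )
                > 0.5
            )
    return FrameStack(data=data, saturated=sat, info=stack.info)
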