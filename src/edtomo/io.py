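"""Experiment-information files, MRC frame stacks and tilt schedules.

The information file is a small plain-text dialect::

    WAVELENGTH 0.0251
    PIXELS_PER_RECIPROCAL_ANGSTROM 280.0
    TILT_AXIS_DEG 48.5
    DETECTOR 512 512
    BIT_DEPTH 12

    frame_0000.mrc -60.0 -0.9 -60.9
    frame_0001.mrc -60.0 -0.7 -60.7
    ...

one row per frame: filename, goniometer tilt, beam tilt and combined tilt,
all in degrees.  Frame order is defined solely by this file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import mrcfile
import numpy as np

__all__ = [
    "FrameRecord",
    "ExperimentInfo",
    "TiltSchedule",
    "FrameStack",
    "InfoFormatError",
    "parse_info_file",
    "write_info_file",
    "read_frame_stack",
    "build_tilt_schedule",
    "write_mrc",
    "read_mrc",
]

_TILT_ADDITIVITY_TOL = 1e-6
_HEADER_KEYS = (
    "WAVELENGTH",
    "PIXELS_PER_RECIPROCAL_ANGSTROM",
    "TILT_AXIS_DEG",
    "DETECTOR",
    "BIT_DEPTH",
)


class InfoFormatError(ValueError):
    """Raised when an information file does not conform to the dialect."""


@dataclass(frozen=True)
class FrameRecord:
    filename: str
    goniometer_tilt: float
    beam_tilt: float
    combined_tilt: float

    def __post_init__(self) -> None:
        resid = abs(self.combined_tilt - self.goniometer_tilt - self.beam_tilt)
        if resid >= _TILT_ADDITIVITY_TOL:
            raise ValueError(
                f"combined tilt {self.combined_tilt} is not goniometer+beam "
                f"({self.goniometer_tilt}+{self.beam_tilt}), residual {resid:g}"
            )


@dataclass(frozen=True)
class ExperimentInfo:
    """Metadata of one rotation-ED dataset."""

    wavelength: float  # Angstrom
    pixels_per_inv_angstrom: float  # detector sampling, px * Angstrom
    tilt_axis_azimuth: float  # degrees ccw from +x, axis in detector plane
    frames: tuple[FrameRecord, ...]
    detector_shape: tuple[int, int]  # (rows, cols)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", tuple(self.frames))
        object.__setattr__(
            self, "detector_shape", (int(self.detector_shape[0]), int(self.detector_shape[1]))
        )
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixels_per_inv_angstrom <= 0:
            raise ValueError("pixels_per_inv_angstrom must be positive")
        if not self.frames:
            raise ValueError("frames must be nonempty")
        if self.bit_depth < 1 or self.bit_depth > 32:
            raise ValueError("bit_depth out of range")
        tilts = [f.combined_tilt for f in self.frames]
        deduped = [tilts[0]]
        for t in tilts[1:]:
            if t != deduped[-1]:
                deduped.append(t)
        diffs = np.diff(deduped)
        if len(deduped) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("combined tilts not strictly ordered after deduplication")

    @property
    def saturation_level(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def combined_tilts(self) -> np.ndarray:
        return np.array([f.combined_tilt for f in self.frames])


@dataclass(frozen=True)
class TiltSchedule:
    """Beam-within-goniometer tilt plan: fine beam sweeps of +-alpha nested
    in coarse goniometer steps."""

    goniometer_start: float
    goniometer_stop: float
    goniometer_step: float
    beam_half_range: float  # alpha, degrees
    beam_step: float

    def __post_init__(self) -> None:
        if self.beam_step <= 0:
            raise ValueError("beam_step must be positive")
        if self.beam_half_range < 0:
            raise ValueError("beam_half_range must be nonnegative")
        if self.goniometer_step <= 0:
            raise ValueError("goniometer_step must be positive")
        if self.goniometer_stop < self.goniometer_start:
            raise ValueError("goniometer_stop must be >= goniometer_start")

    @property
    def n_beam_positions(self) -> int:
        return int(round(2.0 * self.beam_half_range / self.beam_step)) + 1

    @property
    def n_goniometer_positions(self) -> int:
        span = self.goniometer_stop - self.goniometer_start
        return int(round(span / self.goniometer_step)) + 1


@dataclass
class FrameStack:
    """Frame images as float32 counts plus a per-frame saturation mask."""

    data: np.ndarray  # (n_frames, rows, cols) float32
    saturated: np.ndarray  # same shape, bool
    info: ExperimentInfo | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]


def build_tilt_schedule(sched: TiltSchedule) -> list[tuple[float, float, float]]:
    """Expand a schedule into (goniometer, beam, combined) tilt triples.

    Within each goniometer position, beam tilts run from -alpha to +alpha
    inclusive in beam_step increments, so combined tilts are monotone within
    a sweep.  When alpha exceeds half the goniometer step, consecutive
    sweeps overlap in combined tilt.
    """
    out: list[tuple[float, float, float]] = []
    n_beam = sched.n_beam_positions
    for ig in range(sched.n_goniometer_positions):
        gonio = sched.goniometer_start + ig * sched.goniometer_step
        for ib in range(n_beam):
            beam = -sched.beam_half_range + ib * sched.beam_step
            out.append((gonio, beam, gonio + beam))
    return out


# ---------------------------------------------------------------------------
# information file


def _fmt(x: float) -> str:
    """Shortest exact decimal representation (round-trips bit-exactly)."""
    return repr(float(x))


def write_info_file(info: ExperimentInfo, path: str | os.PathLike) -> None:
    lines = [
        f"WAVELENGTH {_fmt(info.wavelength)}",
        f"PIXELS_PER_RECIPROCAL_ANGSTROM {_fmt(info.pixels_per_inv_angstrom)}",
        f"TILT_AXIS_DEG {_fmt(info.tilt_axis_azimuth)}",
        f"DETECTOR {info.detector_shape[0]} {info.detector_shape[1]}",
        f"BIT_DEPTH {info.bit_depth}",
        "",
    ]
    for fr in info.frames:
        lines.append(
            f"{fr.filename} {_fmt(fr.goniometer_tilt)} {_fmt(fr.beam_tilt)} "
            f"{_fmt(fr.combined_tilt)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def parse_info_file(path: str | os.PathLike) -> ExperimentInfo:
    text = Path(path).read_text(encoding="utf-8")
    header: dict[str, list[str]] = {}
    frame_lines: list[str] = []
    in_header = True
    for raw in text.splitlines():
        line = raw.strip()
        if in_header:
            if not line:
                in_header = False
                continue
            parts = line.split()
            if parts[0] not in _HEADER_KEYS:
                raise InfoFormatError(f"unknown header key {parts[0]!r}")
            header[parts[0]] = parts[1:]
        elif line:
            frame_lines.append(line)
    for key in _HEADER_KEYS:
        if key not in header:
            raise InfoFormatError(f"missing key {key}")
    if not frame_lines:
        raise InfoFormatError("no frame rows")
    frames = []
    for line in frame_lines:
        parts = line.split()
        if len(parts) != 4:
            raise InfoFormatError(f"malformed frame row: {line!r}")
        gonio, beam, comb = (float(p) for p in parts[1:])
        if abs(comb - gonio - beam) >= _TILT_ADDITIVITY_TOL:
            raise InfoFormatError(
                f"frame row {parts[0]}: combined tilt {comb} != {gonio} + {beam}"
            )
        frames.append(FrameRecord(parts[0], gonio, beam, comb))
    try:
        det = (int(header["DETECTOR"][0]), int(header["DETECTOR"][1]))
        return ExperimentInfo(
            wavelength=float(header["WAVELENGTH"][0]),
            pixels_per_inv_angstrom=float(header["PIXELS_PER_RECIPROCAL_ANGSTROM"][0]),
            tilt_axis_azimuth=float(header["TILT_AXIS_DEG"][0]),
            frames=tuple(frames),
            detector_shape=det,
            bit_depth=int(header["BIT_DEPTH"][0]),
        )
    except (IndexError, ValueError) as exc:
        raise InfoFormatError(str(exc)) from exc


# ---------------------------------------------------------------------------
# MRC


def write_mrc(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write one image (or stack) to MRC2014 with a deterministic header."""
    image = np.ascontiguousarray(image)
    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(image)
        # mrcfile stamps a creation time into the label; blank it so that
        # identical data yields identical bytes
        mrc.header.label[0] = b""
        mrc.header.nlabl = 0


def read_mrc(path: str | os.PathLike) -> np.ndarray:
    with mrcfile.open(str(path), permissive=False) as mrc:
        return np.array(mrc.data)


def read_frame_stack(info: ExperimentInfo, directory: str | os.PathLike) -> FrameStack:
    """Load the frames referenced by ``info`` in info-file order.

    16-bit integer or 32-bit float MRC data is promoted to float32.  Pixels
    at the saturation level (2**bit_depth - 1) are flagged.
    """
    directory = Path(directory)
    rows, cols = info.detector_shape
    n = len(info.frames)
    data = np.empty((n, rows, cols), dtype=np.float32)
    cache: dict[str, np.ndarray] = {}
    occurrence: dict[str, int] = {}
    for i, fr in enumerate(info.frames):
        if fr.filename not in cache:
            fpath = directory / fr.filename
            if not fpath.exists():
                raise FileNotFoundError(f"missing MRC file {fpath}")
            cache[fr.filename] = read_mrc(fpath)
        img = cache[fr.filename]
        if img.ndim == 3:  # stack file: successive records take successive sections
            k = occurrence.get(fr.filename, 0)
            occurrence[fr.filename] = k + 1
            img = img[k]
        if img.shape != (rows, cols):
            raise ValueError(
                f"frame {fr.filename}: shape {img.shape} != detector {info.detector_shape}"
            )
        data[i] = img.astype(np.float32)
    if np.any(data < 0):
        raise ValueError("negative counts in frame stack")
    saturated = data >= info.saturation_level
    return FrameStack(data=data, saturated=saturated, info=info)
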