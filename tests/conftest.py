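"""Shared fixtures: small synthetic datasets rendered once per session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from edtomo import align, peaks, simulate
from edtomo.geometry import UnitCell
from edtomo.io import ExperimentInfo, FrameStack, TiltSchedule, read_frame_stack

SMALL_CELL = UnitCell(a=12.0, b=14.0, c=10.0)
SMALL_AXIS = 30.0


def small_sim_config(
    seed: int = 7,
    poisson_noise: bool = False,
    drift_step_sigma: float = 0.0,
    schedule: TiltSchedule | None = None,
    **overrides,
) -> simulate.SimConfig:
    rng = np.random.default_rng(seed)
    kwargs = dict(
        cell=SMALL_CELL,
        schedule=schedule
        or TiltSchedule(
            goniometer_start=-40.0,
            goniometer_stop=40.0,
            goniometer_step=2.0,
            beam_half_range=0.9,
            beam_step=0.3,
        ),
        orientation=simulate.random_orientation(rng),
        tilt_axis_azimuth_true=SMALL_AXIS,
        d_min=1.5,
        detector_shape=(256, 256),
        pixels_per_inv_angstrom=160.0,
        poisson_noise=poisson_noise,
        drift_step_sigma=drift_step_sigma,
        seed=seed,
    )
    kwargs.update(overrides)
    return simulate.SimConfig(**kwargs)


@dataclass
class SimDataset:
    config: simulate.SimConfig
    info: ExperimentInfo
    truth: simulate.GroundTruth
    stack: FrameStack
    directory: str

    def truth_spots(self) -> pd.DataFrame:
        """Ground-truth spot list shaped like a detected-spot table."""
        ts = self.truth.spots.copy()
        ts["integrated"] = ts["intensity"]
        ts["smoothed"] = ts["intensity"]
        ts["saturated"] = False
        return ts


def _render(config: simulate.SimConfig, directory) -> SimDataset:
    info, truth = simulate.render_dataset(config, directory)
    stack = read_frame_stack(info, directory)
    return SimDataset(
        config=config, info=info, truth=truth, stack=stack, directory=str(directory)
    )


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory) -> SimDataset:
    """Noiseless, driftless reference for geometric recovery tests."""
    return _render(small_sim_config(), tmp_path_factory.mktemp("clean_sim"))


@pytest.fixture(scope="session")
def noisy_sim(tmp_path_factory) -> SimDataset:
    """Poisson noise plus direct-beam drift."""
    return _render(
        small_sim_config(seed=11, poisson_noise=True, drift_step_sigma=0.15),
        tmp_path_factory.mktemp("noisy_sim"),
    )


@pytest.fixture(scope="session")
def clean_spots(clean_sim) -> pd.DataFrame:
    """Detected + integrated spots of the clean dataset (all frames)."""
    params = peaks.PeakHuntParams(threshold=10.0)
    frames = []
    for i in range(clean_sim.stack.n_frames):
        sp = peaks.hunt_peaks(
            clean_sim.stack.data[i],
            params,
            beam_centre=(128.0, 128.0),
            sat_mask=clean_sim.stack.saturated[i],
            frame_index=i,
        )
        sp = peaks.extract_intensities(clean_sim.stack.data[i], sp)
        frames.append(sp)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def tiny_sim(tmp_path_factory) -> SimDataset:
    """Very small dataset for fast pipeline-level tests."""
    config = small_sim_config(
        seed=3,
        schedule=TiltSchedule(-30.0, 30.0, 3.0, 1.35, 0.45),
        detector_shape=(192, 192),
        pixels_per_inv_angstrom=120.0,
        d_min=1.8,
    )
    return _render(config, tmp_path_factory.mktemp("tiny_sim"))
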