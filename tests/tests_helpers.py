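"""Small constructors shared by tests (importable under hypothesis)."""

from edtomo.io import ExperimentInfo, FrameRecord


def default_info(n_frames: int = 2) -> ExperimentInfo:
    frames = tuple(
        FrameRecord(f"f{i}.mrc", float(i), 0.0, float(i)) for i in range(n_frames)
    )
    return ExperimentInfo(
        wavelength=0.0251,
        pixels_per_inv_angstrom=280.0,
        tilt_axis_azimuth=48.5,
        frames=frames,
        detector_shape=(512, 512),
        bit_depth=12,
    )
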