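# edtomo

Rotation electron diffraction (3D ED) data processing: from a stack of 2D
electron-diffraction frames to a reconstructed 3D reciprocal lattice, a
refined tilt-axis orientation, unit-cell parameters, indexed reflections
and a SHELX HKLF4 intensity file.

A dataset is a directory of MRC frames plus a plain-text experiment
information file (electron wavelength, detector sampling in pixels per
reciprocal angstrom, tilt-axis azimuth, and per-frame goniometer / beam /
combined tilt angles). A forward simulator renders physically plausible
synthetic datasets — Gaussian-PSF spots where the rotated reciprocal
lattice meets the Ewald sphere, Gaussian rocking attenuation in excitation
error, Poisson noise, flat background, 12-bit saturation, and a drifting
direct beam — together with full ground truth, so every processing stage
is testable without instrument data.

## Modules

| module              | what it does |
|---------------------|--------------|
| `edtomo.io`         | information-file dialect, MRC stacks, beam/goniometer tilt schedules |
| `edtomo.simulate`   | forward model: reflection enumeration, Ewald-slice projection, frame rendering, ground truth |
| `edtomo.align`      | direct-beam drift estimation (running-sum cross-correlation, sub-pixel) and correction |
| `edtomo.peaks`      | difference-of-Gaussians peak hunting; smoothed / 2D-integrated intensity extraction |
| `edtomo.reconstruct`| Ewald-sphere back-projection, 3D mapping, tilt-axis refinement by a lattice-straightness score, section cuts |
| `edtomo.lattice`    | spot merging, 3D intensity integration, difference-vector clustering for the reciprocal basis, cell parameters, adaptive indexing, systematic-absence statistics |
| `edtomo.export`     | HKLF4 writer (sigma = sqrt I), reflection tables, Friedel-pair R_int |
| `edtomo.cli`        | `red-sim` / `red-process` console scripts and `run_pipeline` orchestration |

## CLI

Simulate a dataset and process it:

```sh
red-sim --out scratch/demo --seed 7 --cell 12 14 10 90 90 90 \
        --gonio -30 30 3 --beam 1.35 0.45 --detector 192 192 \
        --ppa 120 --d-min 1.8
red-process --info scratch/demo/experiment.info --frames scratch/demo \
            --out scratch/run
```

`red-process` writes `shifts.tsv`, `spots.tsv`, `spots3d.tsv`,
`axis_score.tsv`, `cell.yaml`, `reflections.tsv`, `absences.tsv`,
`output.hkl`, `summary.json` and a log into the run directory. A YAML
config (`--config`) can replace the flags; identical config and input give
byte-identical outputs.

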