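# vesselflow

Analysis toolkit for volumetric two-photon vascular imaging with an
axially extended (Bessel) excitation focus. A single 2D scan of a Bessel
focus projects a ~100-µm-thick tissue volume into one frame, which makes
a vessel's fluorescence brightness proportional to its size and lets one
movie carry both vasodilation dynamics and red-blood-cell flow for every
vessel in the volume. The package implements the full analysis chain
together with an optics calculator and a ground-truthed scene simulator,
so every stage is testable without microscope data.

## What's inside

| Module | Purpose |
| --- | --- |
| `vesselflow.optics` | Axial profile of an annular-aperture (Bessel) focus, FWHM measurement, inverse design of the mask radius ratio, bead-PSF measurement |
| `vesselflow.scene` | Synthetic phantoms: 3D vessel networks (pial / penetrating / capillary), advecting dye-excluding RBCs, vasomotion and arousal-coupled dilation, pupil videos, Poisson noise, rigid drift — all with exact ground truth |
| `vesselflow.preprocess` | Rigid registration, moving averages, temporal binning, local background subtraction, sqrt display normalization |
| `vesselflow.metrics` | Thresholded vessel size and brightness probes, diameter time series, ΔF/F, std/mean variation maps |
| `vesselflow.corrmap` | ROI-grid binning and signed ±10-frame lagged correlation maps against a reference ROI or pupil trace |
| `vesselflow.pupil` | Pupil oval segmentation (moment fit of the dark component) and diameter traces |
| `vesselflow.flow` | Kymograph extraction, 3D skeletonization, 2D→3D arc-length remapping, Sobel + iterative-Radon streak-slope velocimetry in 0.5-s blocks, median speeds and rejection rules |
| `vesselflow.io`, `vesselflow.cli`, `vesselflow.pipeline` | Calibrated TIFF/CSV I/O, YAML-configured runs, command-line entry points |

## CLI

```bash
# design an annular mask for an 85-µm axial FWHM at NA 0.4, 920 nm in water
vesselflow psf design --target-fwhm 85 --na 0.4 --wavelength 0.92 --n 1.33

# write the axial profile as CSV
vesselflow psf profile --na 0.4 --ratio 0.92 --out profile.csv

# simulate a phantom scene (movie + structural stack + pupil video + truth)
vesselflow simulate --config scene.yaml --seed 1 --out out/

# register + smooth a movie
vesselflow preprocess --movie bessel.tif --smooth 5 --out reg.tif

# diameter time series from probe definitions
vesselflow dilate --movie reg.tif --probes probes.csv --out traces.csv

# lagged correlation map against a reference ROI
vesselflow correlate --movie reg.tif --reference 12 40 --out ccmap.csv

# pupil diameter trace from an eye video
vesselflow pupil --video pupil.tif --out pupil.csv

# 3D blood-flow speeds for traced segments
vesselflow flowspeed --movie bessel.tif --stack gaussian_stack.tif \
    --traces traces.csv --out flow/
```

A scene YAML is a mapping with a `stages` list and a `scene` section whose
keys mirror `vesselflow.scene.SceneConfig` (volume size, pixel size, frame
rate, vessel counts, vasomotion/arousal parameters, noise, seed).

## Conventions

- Movies are `(frame, row, column)`, stacks `(plane, row, column)`;
  row index increases downward; positions in µm with the origin at the
  volume corner; 0-based indices.
- Speeds are mm/s, lengths µm, rates Hz. Positive kymograph speed means
  streaks advance toward larger arc length over time.
- All randomness is driven by named streams derived from a single seed;
  outputs are bit-reproducible for a fixed seed.
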