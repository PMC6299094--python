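# mucoquant

Quantitative image analysis and assay statistics for mucociliary-function
and fibrosis studies, exercised end to end on synthetic data with known
ground truth.

The package implements, as tested reusable components:

- **`mucoquant.synthetic`** — seeded generators for every input the pipeline
  consumes: 2-D Brownian/subdiffusive bead trajectories (fractional Gaussian
  noise, optional drift and localization jitter) rendered to movies of
  Gaussian spots; B-scan phantoms with an epithelial surface, an oscillating
  periciliary band, a mucus layer and advected particulates; fibrillar
  SHG-like fields at controlled area fractions; linear colorimetric plates;
  negative-binomial lavage counts and survival tables; systematic uniform
  random field sampling. Every object carries the `GroundTruth` that made it.
- **`mucoquant.microrheology`** — spot detection and nearest-neighbour
  linking, linear drift correction, overlapping-window mean squared
  displacement (per bead and ensemble), log-log scaling fits, and the
  dose-response ANOVA with Holm-Sidak pairwise comparisons.
- **`mucoquant.muoct`** — airway-surface-liquid and periciliary-layer depths
  from a time-averaged B-scan, ciliary beat frequency from Hann-windowed
  averaged periodograms, and mucociliary transport rate from the dominant
  streak orientation of a kymograph built within 50 um of the epithelium.
- **`mucoquant.shg`** — thresholded collagen area fractions, lung-volume
  normalization, Cavalieri volume estimation, point counting,
  least-chi-square Gaussian-mixture histogram fitting with automatic peak
  count selection, and the one-sided rejection-region t comparison.
- **`mucoquant.assays`** — standard-curve interpolation, pseudo-first-order
  reduction kinetics, acute endogenous clearance, survival chi-square,
  stress-sweep linear-regime complex viscosity, viscosity-vs-mass
  regression, and a shared group-comparison front end (Welch t,
  Mann-Whitney, ANOVA + Holm-Sidak).
- **`mucoquant.study` / `mucoquant.cli`** — a configuration-driven driver
  that generates a full synthetic study, runs every stage and writes a
  deterministic JSON report (single master seed fanned out per stage).

## CLI

```sh
mucoquant simulate --kind muoct --seed 1 --out stack.tif
mucoquant muoct --stack stack.tif --out metrics.json

mucoquant simulate --kind beads --seed 1 --out tracks.csv
mucoquant msd --trajectories tracks.csv --out msd.csv

mucoquant simulate --kind shg --seed 1 --out fields.tif
mucoquant shg --fields fields.tif --threshold 0.5 --out fractions.csv

mucoquant assays --survival 10:20,2:20 --out assays.json
mucoquant study --seed 1 --out study_out/      # full synthetic study
```

Image stacks are multi-page TIFFs with a JSON sidecar carrying pixel size,
frame rate, seed and ground truth; tables are headered CSV; reports are
JSON. `mucoquant study` accepts `--config config.yaml` to override any block
of `mucoquant.study.DEFAULT_CONFIG`.

## Conventions

Images are `(time, row, column)` with depth increasing downward; positions
are micrometres, rates um/s, frequencies Hz. All stochastic code takes an
explicit integer seed and is bit-reproducible. The localization-noise floor
of detected trajectories (MSD offset `4*sigma_loc^2`) means scaling fits
should start above the lag where the true MSD dominates that floor; fit
ranges are explicit parameters throughout.
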