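# tau3dquant

Quantification of cellular tau pathology in two-channel 3D microscopy
volumes (a cell-marker channel plus a pathology-marker channel), built and
validated entirely on synthetic phantoms.

The package covers the full analysis chain for a tube-shaped, cell-dense
nucleus ("core") with surrounding low-density subregions:

- **`tau3dquant.phantom`** — synthetic two-channel volume generator:
  labelled region masks (core cylinder, shell annulus, dorsomedial band,
  ventrolateral satellites), seeded point patterns (uniform/CSR, Thomas
  cluster process, lattice), ellipsoidal somas with dendrite/axon tubes,
  stage-dependent pathological fractions, dorsal bias, and microscope noise —
  with a per-cell ground-truth table and truth compartment masks.
- **`tau3dquant.imageproc`** — cell-body detection (background subtraction →
  threshold → volume band-pass → watershed split of merged somas),
  morphological body/process decomposition of the pathology channel (an
  exact partition), per-component morphometrics (volume, voxel-face surface
  area, skeleton branch count), and coarse cell-form classification.
- **`tau3dquant.geometry`** — region bookkeeping, equal-volume dorso-ventral
  splitting, and concentric shell zoning of process signal around cell
  bodies (inner band 0–50 μm, then 100 μm-wide shells, assignment by
  nearest centroid).
- **`tau3dquant.pointstats`** — nearest-neighbour distances, Monte-Carlo
  nearest-neighbour index (NNI) against a uniform-random null in the same
  mask, dense-cell flags at 75 % of the mean NN distance, duo (2) /
  minigroup (3–9) component splitting, neighbouring-cell flags, and per-100
  normalizations.
- **`tau3dquant.quantify`** — per-subregion burden tables with three
  normalizations (per subregion volume, per mm³, per 100 reference cells),
  dorso-ventral variants, body/process proportions, five-grade
  semiquantitative scores, and group mean ± SEM summaries.
- **`tau3dquant.report`** — two-way ANOVA (Type-II SS), ANCOVA with an age
  covariate, Pearson correlation, paired t-test of simulated vs observed NN
  distances, Tukey post-hoc, and figure-style plots.

All geometry is computed in physical micrometres, so results are invariant
to (anisotropic) voxel size. Arrays are `(z, y, x)`; the dorso-ventral axis
is `y` by default, with smaller `y` dorsal.

## CLI

```sh
tau3dquant all --outdir run/ --seed 1                 # full pipeline
tau3dquant simulate --outdir run/ --config cfg.yaml   # phantom only
tau3dquant segment --outdir run/ --threshold 1200
tau3dquant quantify --outdir run/
tau3dquant spatialstats --outdir run/
tau3dquant report --outdir run/
```

Each stage writes into one working directory (TIFF volumes, CSV tables,
JSON stats, SVG figures) plus a manifest recording the seed, a configuration
hash, and the files produced; CSVs carry a `# seed=… config_hash=…` header.
Reruns with the same seed are byte-identical.

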