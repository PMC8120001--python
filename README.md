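# immunotrack

Quantification of innate immune-cell behaviour and cell–lesion
interactions in calibrated multi-channel time-lapse microscopy.

The package implements the full analysis chain for movies of neutrophils
(cytoplasmic marker) and macrophages (nuclear marker) responding to a
lesion — a wound margin or a pre-neoplastic clone outline:

- **movie_io** — calibrated TIFF/OME-TIFF reading/writing, ImageJ
  `.roi`/`.zip` and JSON lesion annotations, CSV result tables.
- **synthetic** — a simulator producing movies with known cell tracks,
  lesion geometry and ground-truth interaction events (persistent random
  walks with optional chemotactic bias, anti-aliased rendering, Gaussian
  noise, deterministic per seed).
- **detection** — threshold + connected-components segmentation of
  cytoplasmic signal; trainable pixel classification (multi-scale feature
  bank, probabilistic classifier) for nuclei; area filters; manual
  correction directives (delete / merge / split / add).
- **tracking** — per-frame-pair optimal assignment linking with a
  distance cap and gap closing; mean speed and directionality ratio
  (net displacement / path length) per track.
- **lesion** — time-keyed polygon outlines held piecewise-constant,
  rasterised with the pixel-centre rule; exact signed Euclidean distance
  fields (negative inside, zero on the surface).
- **interactions** — per-frame surface-to-surface distances, contact /
  close-proximity event extraction with lineage-specific strict
  thresholds (< 20 μm neutrophil margin, < 50 μm macrophage nuclear
  margin), durations, per-movie summaries, field-of-view counts.
- **stats / report** — per-fish aggregation, normality-routed group
  comparisons (D'Agostino–Pearson / Shapiro–Wilk → t-test / Mann–Whitney /
  ANOVA+Tukey / Kruskal–Wallis+Dunn), Fisher's exact test, column-scatter
  plots with significance annotation.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the oracle-based acceptance suite
(end-to-end ground-truth recovery on seeded simulated movies, brute-force
oracle equivalence for labelling / distance fields / tracking, threshold
semantics, statistics calibration, determinism).

## Command-line usage

```sh
# simulate a movie with ground truth
immunotrack simulate --config examples/sim.yaml --out sim_out/

# full analysis chain: segmentation -> tracking -> distances -> events
immunotrack run --movie sim_out/movie.tif --annotations sim_out/annotations.json \
    --config examples/config.yaml --out analysis/

# summary plots and routed statistics
immunotrack report --metrics analysis/metrics.csv --distances analysis/distances.csv \
    --out report/
```

Individual stages (`segment`, `track`, `interactions`) are also exposed;
`segment --objects objects.npz` saves per-frame label images that the
later stages consume. Configuration is YAML; see `examples/`.

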