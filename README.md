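# plvnet

Phase-locking-value (PLV) brain-network analysis of multichannel EEG, built
to compare a "comfort" and a "fatigue" recording condition:

- **synthetic data** (`plvnet.synth`): multichannel EEG-like signals with
  analytically controlled pairwise phase locking per band and condition
  (closed-form ground truth `exp(-(σx² + σy²)/2)`), plus artifact injection;
- **preprocessing** (`plvnet.preprocess`): zero-phase 0.5–30 Hz band-pass,
  50 Hz notch, polyphase resampling to 250 Hz, 2 s epoching, ±100 µV
  amplitude rejection, common average reference, delta/theta/alpha band
  filters;
- **connectivity** (`plvnet.connectivity`): Hilbert instantaneous phases and
  epoch-averaged (or pooled) PLV matrices over all electrode pairs;
- **network construction** (`plvnet.network`): threshold grid
  (0.72…0.76) or adaptive top-20 %-sparsity thresholding into weighted
  undirected brain graphs;
- **graph metrics** (`plvnet.metrics`): Floyd–Warshall shortest paths with
  path multiplicities, betweenness centrality, nodal efficiency,
  local/global clustering, characteristic path length (finite paths only),
  in binary / `1−PLV` / `1/PLV` distance modes;
- **statistics** (`plvnet.stats`): Shapiro–Wilk-gated paired t /
  Wilcoxon signed-rank comparisons, Benjamini–Hochberg FDR over the 276
  electrode pairs, per-threshold and per-channel difference maps with a
  five-region scalp montage roll-up;
- **pipeline** (`plvnet.pipeline`): deterministic end-to-end orchestration
  producing CSV report tables.

## CLI

```sh
# generate a synthetic 18-participant two-condition study
plvnet synth --out study/ --participants 18 --comfort-sigma 0.9 --fatigue-sigma 0.5 --seed 1

# preprocess one recording to band-limited epochs
plvnet preprocess --in study/sub00_comfort.txt --band alpha --out pre/

# PLV matrices for every recording in a manifest
plvnet plv --manifest study/manifest.csv --band alpha --out plv/

# full pipeline from a YAML config
plvnet run --config config.yml
```

A minimal `config.yml`:

```yaml
manifest: study/manifest.csv
out_dir: results/
bands: [delta, theta, alpha]
threshold_mode: grid          # or: sparsity
threshold_grid: [0.72, 0.73, 0.74, 0.75, 0.76]
distance_mode: one_minus_w    # or: binary, inverse_w
plv_pooling: epoch            # or: pooled
tail: two                     # or: one (fatigue > comfort)
```

Recordings are plain text channel × sample matrices (µV) with a JSON
sidecar (`sfreq`, `channel_labels`, `condition`, `participant`); the
manifest is a CSV with `participant, condition, path` columns.

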