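# hubburst

Quantitative analysis of **transcription-factor hubs** and **transcriptional
bursting** in two-channel 4D live-imaging of early *Drosophila* embryos.

Morphogen transcription factors such as Dorsal accumulate in localized,
high-concentration sub-nuclear microenvironments ("hubs"). Whether a hub is
parked at a gene — and how bright and long-lived it is — varies between
target genes (*snail*, *sog*) and non-targets (*hunchback*), and those
differences track transcriptional kinetics. `hubburst` implements the full
measurement chain needed to quantify this from movies in which channel 1
carries a fluorescently tagged transcription factor and channel 2 carries an
MCP/MS2 nascent-transcription reporter:

- **nuclei** — per-slice segmentation (a simple intensity stand-in that
  accepts externally produced label volumes), 3D stitching with shape
  interpolation of missing slices, and greedy nearest-neighbour tracking;
- **hubs** — nuclear-mean normalization, then median filter → grayscale
  erosion → morphological reconstruction → residual thresholding → local
  maxima → marker-controlled watershed, with sizes and intensities per hub;
- **ms2** — median + difference-of-Gaussians spot detection with a
  percentile threshold, brightest-spot selection, tracking, and gap filling
  in nucleus-relative coordinates (with up to 20 frames of pre-appearance
  extrapolation);
- **interactions** — hub overlap volume/intensity inside a **0.5 µm
  interaction sphere** around the MS2 weighted centroid, contiguous
  hub-contact runs, three-component Gaussian-mixture dwell-time
  classification (short/mid/long-lived), and survival curves;
- **bursts** — burst calling from the derivative of the Gaussian-smoothed
  MS2 trace (amplitude, duration, output, RNAPII loading rate, frequency),
  burst–hub linking (hub arrival lead, dwell after burst start,
  high-intensity-hub splits), normalized cross-correlation with peak-lag
  extraction, Mann-Whitney group comparisons and Pearson regressions;
- **synthetic** — ground-truthed generators for both full 4D two-channel
  movies and trace-level time series, so every stage is testable without
  any imaging data.

Key quantities, in the field's notation: a dwell-time sample is fit with
`Σ_k w_k N(µ_k, σ_k²)` (k = 3, truncated at zero); the interaction sphere is
`{v : ‖x_v − x_MS2‖ ≤ 0.5 µm}` in physical units on the anisotropic grid;
burst output is `∫ (I(t) − baseline) dt`; the cross-correlation at lag ℓ is
the Pearson coefficient of the overlapping trace windows, with **positive
lag meaning the hub signal follows the MS2 signal**.

## Worked example

`examples/` contains one short script per capability. For instance, dwell
classification (`python examples/01_dwell_time_mixture.py`):

```
snail nc14 dwell-time mixture (minutes)
  short: recovered  0.300  generating   0.30  weight 0.45
  mid  : recovered  1.349  generating   1.35  weight 0.35
  long : recovered 10.031  generating  10.04  weight 0.20
  class boundaries at [0.5  2.44] min
  fraction of contacts lasting >=  0.5 min: 0.552
  fraction of contacts lasting >=  2.0 min: 0.203
  fraction of contacts lasting >= 10.0 min: 0.103
```

2,000 hub-contact durations are drawn from the *snail* nc14 reference
mixture and re-fit from scratch; the recovered component means match the
generating values to ≲0.5%, and the survival fractions show the long-lived
tail (~10% of contacts persist ≥10 min) that distinguishes a hub-retaining
target gene. Lag recovery (`02`), burst calling against closed forms (`03`),
hub detection with sub-voxel centroids (`04`), and the full movie-level
chain (`05`) follow the same pattern.

A thin CLI mirrors the stages for shell use:

```bash
hubburst simulate --config sim.json --out run/sim
hubburst segment-nuclei --movie run/sim/movie.ome.tif --out run/nuc
hubburst detect-hubs --movie ... --labels ... --out run/hubs
hubburst track-ms2 ... ; hubburst interactions ... ; hubburst bursts ... ; hubburst report ...
```

Every stage writes plain CSV/JSON plus the exact config and seed that
produced it; rerunning with the same seed reproduces every table
byte-for-byte.

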