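# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `hubburst`. Units are micrometres and minutes throughout;
frame indices are 0-based; arrays are ordered `(z, y, x)` with voxel sizes
given as `(dx, dy, dz)`. The default acquisition geometry is one two-channel
volume every 11.56 s with z-planes 0.3 µm apart; the lateral pixel pitch is
not part of the acquisition spec and defaults to 0.104 µm (typical for the
instrument class) — only its ratio to the 0.5 µm interaction radius matters
for the analysis.

## Synthetic data

The generators define the conditions every stage is validated under. They
come in two fidelities.

**Trace level** (`simulate_traces`). Each nucleus gets a deterministic
multi-burst MS2 waveform: linear rise at the loading rate to the peak
amplitude, a plateau, then a decay (exponential by default; linear decay is
used where closed-form trapezoid areas are wanted). Burst starts are snapped
to the acquisition grid so waveform onsets coincide with sampling times, and
a configuration whose waveform span (rise + plateau + decay to 1% of peak)
reaches the inter-burst spacing is rejected rather than silently overlapped.
Two mutually exclusive coupling modes tie a hub signal to the MS2 signal:

- *lag coupling*: the hub-intensity trace is a smoothed copy of the MS2
  trace shifted by a configurable lag (positive lag = hub follows MS2) —
  the regime the cross-correlation analysis probes;
- *arrival coupling*: hub presence switches ON a fixed lead before each
  non-first burst start and OFF a fixed dwell after that start — the regime
  the burst–hub linking probes. Lead + dwell must be smaller than the
  inter-burst spacing or the configuration is rejected.

Trace noise is additive Gaussian with a standard deviation expressed as a
fraction of the peak amplitude (default 5%). The real detection chain's
noise is not characterised here; this is a configurable placeholder.

**Movie level** (`simulate_embryo_movie`). Ellipsoidal nuclei (default
semi-axes 1.6 × 1.6 × 2.2 µm — kept small so test volumes stay light; real
blastoderm nuclei are larger) are placed with a ≥0.4-radius inter-nuclear
gap plus room for the whole drift, and drift coherently (one shared
direction with small per-nucleus jitter, as blastoderm nuclei flow
collectively) at 0.3 µm/min by default. The nucleoplasmic level follows a
rise-and-fall half-sine over the cycle (import outpacing export, then
reversing) with a configurable modulation depth. Hubs are a birth–death
process per nucleus: births are Poisson with rate density × nuclear volume /
mean dwell (so the stationary mean count equals density × volume; a burn-in
of five long-component means precedes frame 0), lifetimes are drawn from the
dwell mixture, positions are uniform in the inner 80% of the ellipsoid and
co-move with the nucleus, and each hub is rendered as an isotropic Gaussian
blob (σ = 0.15 µm) whose peak amplitude scales with the nucleoplasmic level
(hub intensity tracking nuclear concentration) unless decoupled. The MS2
spot is one axially elongated Gaussian per nucleus (σ = 0.15 µm lateral,
0.45 µm axial, mimicking the PSF) whose *summed* intensity equals the burst
waveform value at that frame. Poisson shot noise plus Gaussian read noise is
applied last. Hub events whose lifetime falls entirely between frames are
dropped from the ground-truth inventory, which therefore exactly matches
what was rendered.

The dwell mixture default and the per-gene presets in
`hubburst.conditions` use three components. The mid- and long-lived
component means are the nc14 reference values per gene (sna 1.35/10.04,
sog 1.55/5.39, hb(v) 0.90/3.00, hb(l) 0.88/2.77 min); the short-lived mean
is never reported and defaults to 0.3 min (frame-scale transient contacts).
Preset spreads are 10% of each mean — the separable regime the recovery
protocol prescribes — and weights are (0.45, 0.35, 0.20), chosen once as a
plausible contact-frequency ordering.

## Nuclei

The per-slice segmenter is an intentionally simple stand-in for a learned
model: Gaussian smoothing (σ = 0.5 µm), a threshold (Otsu computed once on
the whole smoothed volume, so nucleus-free slices never threshold camera
noise; standalone slice calls add a foreground/background contrast guard),
a size filter, and an optional distance-transform-seeded watershed (EDT
lightly smoothed to one peak per convex body; minimum peak separation
2.5 µm) that splits touching cross-sections. `stitch_and_interpolate` and
`track_nuclei` accept any label input, so externally produced label volumes
drop in unchanged.

Stitching merges a slice region into the nucleus above when their IoU is
≥0.5 **or** when 80% of the smaller region is contained in the larger: pure
IoU detaches the shrinking polar cross-sections of an ellipsoid (consecutive
cap slices have IoU < 0.5), spawning spurious fragments. Gaps of up to two
missing slices inside a nucleus are filled by signed-distance shape
interpolation between the flanking masks. A region overlapping two nuclei is
assigned to the max-overlap one and logged.

Tracking is greedy nearest-centroid: candidate pairs sorted by ascending
distance, matched one-to-one, pairs beyond 2 µm (per 11.56 s frame — far
above real interphase motion) open new tracks. Simultaneous position swaps
resolve by distance order; this is a documented arbitrary tie-break.
Per-axis "equivalent radii" come from mask second moments via the uniform
ellipsoid inversion `a = sqrt(5 ⟨x²⟩)`.

## Hubs

Nuclear intensity is normalized to its in-mask mean, so hub intensities are
in units of the nucleoplasmic average and the whole detection chain is
invariant to global intensity rescaling. Detection: median filter (3×3×1
default — one z-plane, because hubs can be thinner than the 0.3 µm z step) →
grayscale erosion (0.15 µm box, per-axis conversion to voxels) →
morphological reconstruction by dilation (seed = eroded, mask = median) →
residual = median − reconstruction → threshold (Otsu on the positive
residual, floored at 0.1 normalized units so hub-free nuclei yield zero
hubs; a fixed threshold can be supplied) → markers = connected plateaus of
local maxima within a 0.3 µm separation footprint on a lightly blurred
residual (the blur breaks the exact ties median filtering leaves, so each
blob contributes one marker) → watershed on the negated residual constrained
to the thresholded mask → discard labels under 4 voxels. Raising the
residual threshold can only shrink the mask, so hub count is monotonically
non-increasing in it.

## MS2

Spot detection: median filter (3×3×1) → difference of Gaussians (σ₁ = 0.1,
σ₂ = 0.3 µm, per-axis anisotropic) → percentile threshold (default 99.5) on
the in-mask band-pass distribution → connected components with
DoG-weighted centroids. The nuclear rim is itself a step edge with a strong
band-pass response, so a boundary shell of ~2σ₂ is eroded off the analysis
mask; loci closer to the edge than that are not detectable (the equivalent
manual criterion is excluding nuclei whose spot sits too near the edge).
Each candidate carries its raw integrated intensity and a
background-corrected value (integrated − in-mask median × component size);
the corrected value is the burst-calling signal because it removes the
component-size-dependent nucleoplasmic contribution. The brightest candidate
per nucleus is the locus; ties break to the larger component, then the lower
label.

Gap filling works in nucleus-relative coordinates
`r = (x − centroid) / radii` per axis: linear interpolation of `r` between
flanking detections, mapped back through each frame's nucleus geometry —
exact under rigid translation and isotropic size change. Up to 20
pre-appearance frames hold the first detected `r` fixed. An optional edits
mapping (frame → position) reproduces manual track corrections
deterministically. Frames without nucleus coverage stay uncovered and are
logged.

## Interactions

A voxel belongs to the 0.5 µm interaction sphere when its **center** is
within the radius in physical distance (anisotropy-aware; partial-voxel
weighting rejected for simplicity and oracle-checkability — an exhaustive
per-voxel distance check reproduces the membership exactly, and the
occupied volume converges to 4/3·π·0.5³ ≈ 0.5236 µm³ as voxels shrink).
Per frame the record holds the sphere mean channel-1 intensity (normalized
units), hub overlap volume, overlap mean hub intensity (NaN when no hub
overlaps), and presence flags; spheres clipped by the volume edge are
computed over in-bounds voxels and flagged.

Runs are maximal stretches of hub presence; `gap_tolerance` (default 0 —
"consistently present" read literally) optionally bridges short dropouts.
Duration counts the frames in the run: `(end − start + 1) ×` frame interval.
A departing and returning hub is a new run; hub identity is not tracked.

The dwell mixture is fit by EM on the raw durations (scikit-learn
`GaussianMixture`, k-means init, 5 restarts from a fixed seed, variance
floor 1e-8), components relabeled ascending so indices 0/1/2 are the
short/mid/long classes, runs hardened to argmax responsibility, and
empirical class boundaries read off a fine grid. Fitting on samples rather
than on the cumulative curve is a declared reading of an ambiguous
description. Degenerate inputs (zero spread) are flagged; non-convergence
returns the best-so-far fit flagged unconverged. Whether durations should be
pooled per gene × cycle or per embryo is configurable; the default pools.

## Bursts

Calling: Gaussian-smooth the trace (σ = 1.5 frames), differentiate, and open
a burst at an upward crossing of the derivative threshold while the smoothed
signal sits above the local baseline (rolling minimum, window 20 frames).
The threshold is k × 1.4826 × MAD of the derivative (k = 2), floored at 5%
and capped at 30% of the maximum derivative — the floor handles noiseless
traces whose MAD is zero, the cap handles short traces where bursts occupy
most frames and inflate the MAD. A burst closes when the smoothed signal
returns to within ε of baseline, or when a new rise begins after the
derivative has collapsed. Start and end are then refined on the *raw* trace
against a noise-scaled ε (3 × a MAD noise estimate, with a tiny floor): the
start walks to the last at-baseline frame before the rise, the end to the
first at-baseline frame after the peak. On noiseless grid-aligned waveforms
the recovered amplitude, duration, output (trapezoidal integral of the
baseline-subtracted raw trace), and loading rate (amplitude over start→peak
time, the initial-rise-slope reading of "RNAPII loading rate"; peak = first
raw frame within ε of the burst maximum) equal their closed forms exactly.
Bursts shorter than 2 frames are discarded. Burst frequency divides the
count by the observed trace span.

Linking: presence at the burst-start frame comes from the interaction
record there (`any` mode) or additionally requires the overlap mean hub
intensity to reach the high-intensity threshold (`high` mode; the threshold
is the average ventral hub mean intensity). Arrival lead = burst start −
start of the containing run; dwell after = end of the containing run −
burst start; both NaN when no hub is present at the start. First bursts are
flagged so arrival-lead summaries can exclude them. The pre-burst intensity
is the mean sphere intensity over the 5 frames before the start.

Cross-correlation: both traces are smoothed identically and, at each lag
within ±max-lag, the value is the Pearson coefficient of the two overlapping
windows. This contains the usual 1/(n − |lag|) finite-overlap correction but
normalizes by the windows' own norms, keeping values exactly in [−1, 1];
normalizing by global z-scores instead lets values exceed 1 away from the
true lag and measurably biases the argmax on smooth traces. **Sign
convention: positive lag = the hub signal follows the MS2 signal**; swapping
the inputs negates the peak lag. Zero-variance input returns a missing
result with a warning.

Statistics: two-sided Mann-Whitney U (normal approximation with tie
correction) with the star coding *p* < 0.05/0.01/0.001; Pearson r², p, and a
least-squares line per burst parameter against a hub predictor. Regression
results are always reported with a significance flag rather than gated on a
p-value cut-off.

## Report

Aggregation is two-level — nuclei are averaged within each embryo, then
embryos into the cohort — so the reported spread is the standard deviation
between embryo replicates; it is omitted (NaN) when fewer than two embryos
contribute. The mid-interphase window for box-plot-style summaries is the
middle third of the cycle (the qualitative "middle of interphase" is not
otherwise quantified). Rendering is deterministic: identical inputs yield
byte-identical tables, an empty cohort yields an explicit no-data report,
and every run directory carries the config and seed that produced it
(tables are written with `%.17g` floats so values round-trip exactly).

## Problem sizes and validation scope

The test suite validates on deliberately small problems: movies of 2 nuclei
× 10–30 frames at 24 × 110 × 110 voxels, trace cohorts of 20–200 nuclei,
dwell samples of 2,000, hub-detection sweeps of 550 planted-blob volumes at
16 × 64 × 64. The benchmark script (`scripts/acceptance.py`) uses the same
scales and runs in minutes on one CPU.

What passing tests show — and what they do not: the synthetic movies have
ellipsoidal nuclei, Gaussian hubs, a single spot per nucleus, and
Poisson-Gaussian noise. They do not model a real PSF, deconvolution
artifacts, mitotic divisions, chromatin texture, photobleaching, or
segmentation-model failure modes, so green tests certify the *analysis
chain* (geometry, normalization, run/burst logic, statistics, determinism),
not the adequacy of the simple stand-in segmenter on real embryo data. For
real data, drop externally produced nuclear label volumes into
`stitch_and_interpolate`/`track_nuclei` and tune the per-nucleus MS2
detection parameters, which the configs expose for exactly that reason.

## Known limitations

- One MS2 spot per nucleus (single-allele reporters); no multi-spot support.
- Sub-voxel localization is intensity-weighted centroiding, not Gaussian
  fitting.
- Hubs are not tracked as identities through the nucleoplasm; only
  locus-proximal presence is analysed.
- The greedy tracker does not handle mitosis; tracks are per-interphase.
- The dwell-time mixture is Gaussian by construction of the classifier, not
  a mechanistic residence-time model; components are a classification
  device, truncation at zero is handled in the generator but not in the fit.
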