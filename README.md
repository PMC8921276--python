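# spiketexture

Tools for asking a central question in tactile neural coding: **is texture
identity carried in millisecond-precise temporal spiking patterns, in
firing rates, or in both?**  Neurons in primate somatosensory cortex
respond to a texture scanned across the fingertip with spike trains whose
fine temporal structure repeats across presentations.  This package
implements the full analysis chain used to quantify that claim, together
with a synthetic spike-train generator with known ground truth so every
estimator can be validated by parameter recovery.

Who it is for: computational neuroscientists analyzing trial-structured
spike-time data (neuron × stimulus × repeat × scanning condition) who need
rate-versus-timing decoding comparisons with proper rate-matched controls.

## What it computes

- **Victor–Purpura spike distance** `D(a, b)`: the minimum cost of editing
  one spike train into another, with insertion/deletion cost 1 and shift
  cost `q·|Δt|` (q in 1/s).  `q = 0` compares spike counts; `q = 500`
  corresponds to a 2-ms temporal resolution (1000/q ms).
- **Temporal precision (repeatability analysis)**: for each neuron ×
  texture, the mean pairwise distance among measured repeats is compared
  with that of count-matched, Gaussian-jittered copies of the neuron's own
  response over a jitter grid σ ∈ [0.1, 200] ms; the bracketing jitter
  levels are averaged (measured 15 between 13 at 1 ms and 21 at 2 ms →
  1.5 ms), and the per-neuron resolution is the median over textures.
- **Nearest-neighbor texture decoding** (leave-one-repeat-out): rate
  (|Δ firing rate| to each candidate's training mean), timing (max of the
  zero-mean cross-correlation between demeaned Gaussian-smoothed PSTHs,
  swept over kernel SDs 0.1–500 ms), and their optimal weighted
  combination of z-scored distance tables; population decoding averages
  z-scored tables over sampled neurons, and schemes are compared with a
  one-sided permutation test.
- **Controls**: homogeneous Poisson surrogates (`P = r·dt`, dt = 0.1 ms)
  that keep rates but destroy timing, and jittered surrogates with imposed
  temporal noise.
- **Speed warping**: spike times multiplied by scanning speed give
  responses in spikes/mm; cross-speed classifiers (train at one speed,
  test at another) quantify how much texture information survives speed
  changes with and without warping.
- **Submodality profiling**: standardized regression of a neuron's
  texture rate profile onto SA1/RA/PC afferent class rates over a shared
  texture set (label = class with coefficient > 0.8).
- **Perceptual link**: leave-one-pair-out cross-validated regression of
  human dissimilarity ratings (78 pairs of 13 textures) on per-subpopulation
  rate-difference and timing-correlation features.

## Worked example

```python
from spiketexture import PrecisionModel, TextureDecoder, StudyConfig, simulate_study

cfg = StudyConfig(n_neurons=8, n_textures=12, n_repeats=5)
rs, truth = simulate_study(cfg, seed=1)

print(PrecisionModel(rs, q=500).fit(seed=0).summary())
dec = TextureDecoder(rs, scheme="combined", resolutions=[1, 2, 5, 10, 20, 50]).fit(seed=0)
print(dec.summary())
print(dec.per_neuron.head(3).to_string(index=False))
```

prints

```
Temporal-resolution estimates (repeatability analysis)
  spike-distance cost q = 500/s (nominal resolution 2 ms)
  jitter grid: [1.00e-01 2.00e-01 3.98e-01 7.95e-01 1.59e+00 3.17e+00 6.32e+00 1.26e+01
 2.52e+01 5.02e+01 1.00e+02 2.00e+02] ms
  neurons: 8; per-texture estimates: 96
  median neuron resolution: 23.6 ms
  censored estimates: 9 of 96

combined texture decoding over 8 neurons (12 textures, chance 8.3%)
  single-cell accuracy: median 37.5%, max 96.7%

neuron_id  resolution_ms  weight  accuracy
     n000              2    0.25  0.966667
     n001             10    0.80  0.350000
     n002              2    0.85  0.400000
```

Reading this: the population's median temporal resolution is coarse
because most of these eight synthetic neurons are weakly patterned, but
neuron `n000` (a PC-like cell with sub-millisecond planted jitter) is
decoded at 96.7% versus 8.3% chance, at a 2-ms resolution, with an
intermediate rate/timing weight — rate and timing each contribute.

A command-line interface mirrors the library
(`spiketexture simulate | validate | surrogate | precision | decode |
speed-decode | submodality | perception`); every stage takes `--seed` and
reproduces its output byte-for-byte.

## Layout

| module | contents |
|---|---|
| `spiketexture.data_model` | SpikeTrain / ResponseSet / window & rate extraction |
| `spiketexture.io` | CSV dialect and HDF5 container, bit-exact round-trips |
| `spiketexture.synthetic` | texture templates, master-pattern spike generator, afferent rates, rating generator |
| `spiketexture.surrogates` | Poisson and jittered count-matched controls |
| `spiketexture.metrics` | Victor–Purpura distance, PSTHs, lagged cross-correlation |
| `spiketexture.precision` | repeatability analysis (`PrecisionModel`) |
| `spiketexture.decoding` | rate/timing/combined NN decoders, population analyses (`TextureDecoder`) |
| `spiketexture.speed` | warping and cross-speed classification |
| `spiketexture.submodality` | SA1/RA/PC profiling (`SubmodalityModel`) |
| `spiketexture.perception` | dissimilarity regression (`DissimilarityRegression`) |

See `docs/methods.md` for the generative model, estimator conventions,
numerical choices, and known limitations.
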