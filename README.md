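# mck

Quantification of mitochondrial dynamic tubulation (MDT), mtDNA-nucleoid
transport, and ER–mitochondria contact dynamics in calibrated fluorescence
time-lapse microscopy.

Mitochondrial DNA is packaged into ~100-nm nucleoids that, beyond passive
redistribution by fusion and fission, can be actively carried inside thin
tubules that motors pull out of mitochondria, with the extension events
concentrated at ER–mitochondria contact sites. Establishing that picture
quantitatively requires a small set of bespoke image statistics that are not
part of the standard colocalization/tracking toolbox. This package
implements them as a tested, reusable library with a command line, for
microscopists analysing multi-channel 2D time-lapse data (mitochondria, ER,
nucleoid channels) at super-resolution pixel sizes:

- **Linescan shift-correlation colocalization.** Intensity profiles of two
  channels are sampled along polylines through mitochondria; the Pearson
  correlation is recomputed while one channel is displaced along the arc in
  32-nm increments and averaged over linescans. The largest displacement *d*
  at which the 95% CI of the mean correlation stays above 0 for all
  |s| ≤ *d* is the distance threshold for calling two point signals
  colocalized; the observed colocalization frequency (fraction of A-points
  with a B-neighbour strictly within the threshold) is tested against a
  null in which the B-points are redrawn uniformly inside the organelle
  mask (two-tailed unpaired Student's *t*-test).
- **Contact index and stability.** *R* = (mitochondrial perimeter pixels
  overlapped by the ER mask) / (all perimeter pixels), computed per frame
  after rolling-ball background subtraction and thresholding; contact
  stability is the mean of |ΔR|/R₀ over consecutive frame pairs.
- **Tracking and anomalous MSD.** LoG spot detection with sub-pixel
  refinement, greedy nearest-neighbour linking, tip/nucleoid speed
  cross-correlation (`corrcoef`-style, zero lag), time-averaged
  MSD(τ) ∝ τ^α with α fitted as the log–log slope over short lags, and
  kymographs along drawn lines.
- **Morphometrics.** Tubule diameters as PSF-corrected Gaussian-fit FWHM
  (d = √(FWHM² − FWHM_PSF²)), thin (≤ 200 nm) vs thick (> 200 nm)
  classification, transported/retained and tip-located scoring of tubule
  extension events over ≥ 2-min windows, initiation-site–nucleoid proximity
  fractions (1-µm radius), and nucleoid densities per zone mask.
- **Synthetic scenes with ground truth.** A simulator renders tubes of
  known diameter, paired two-channel spots with controlled offsets, and
  scripted tubule-extension events with coupled / unsynchronized / retained
  nucleoid motion through a Gaussian PSF with optional Poisson–Gaussian
  noise, so every stage has a recovery test without any raw data.

## Worked example

Recover a colocalization distance threshold from a synthetic two-channel
scene of 100 point pairs with 50-nm true offsets, then compare the observed
colocalization frequency with the randomized null:

```python
import numpy as np
from mck import (SceneSpec, generate_spot_pair_scene, sample_linescan,
                 shift_correlation_curve, colocalization_threshold,
                 randomized_frequency, Polyline)

spec = SceneSpec(field_size=(512, 512), seed=1)          # 32 nm/pixel
stack, truth = generate_spot_pair_scene(spec, n_pairs=100, offset_sd=50.0)

half, wn = 800.0, 512 * 32.0
scans = []
for i in range(100):
    x, y = truth.object_tracks[f"spots_a_{i}"].xy[0]
    if x - half < 32 or x + half > wn - 32:
        continue
    line = Polyline([[x - half, y], [x + half, y]], sampling_step=32.0)
    scans.append(sample_linescan(stack, line))
curve = shift_correlation_curve(scans, "spots_a", "spots_b", max_shift=640.0)
threshold = colocalization_threshold(curve, confidence=0.95)
print(f"zero-shift Pearson R = {curve.at(0.0)[0]:.2f}")
print(f"colocalization threshold = {threshold:.0f} nm")

pts_a = np.array([truth.object_tracks[f"spots_a_{i}"].xy[0] for i in range(100)])
pts_b = np.array([truth.object_tracks[f"spots_b_{i}"].xy[0] for i in range(100)])
res = randomized_frequency(pts_a, pts_b, np.ones((512, 512), bool),
                           threshold, n_perm=1000, seed=1, pixel_size=32.0)
print(f"observed: {100*res.observed_fraction:.0f}%  "
      f"scrambled: {100*res.null_mean:.0f}%  (p = {res.p_value:.1e})")
```

This prints:

```
zero-shift Pearson R = 0.72
colocalization threshold = 128 nm
observed: 98%  scrambled: 2%  (p = 0.0e+00)
```

The mean shift curve decays with displacement and its 95% CI stays positive
out to 128 nm (four 32-nm steps — the PSF plus the 50-nm pair offsets);
within that radius nearly all A-spots have a true partner, while uniformly
scrambled B-positions almost never land that close, so the association is
highly significant.

## Command line

`mck` exposes each stage as a subcommand over TIFF stacks, CSV point/track
tables, and YAML configs:

```
mck simulate|linescan|shiftcurve|coloc|contact|track|msd|kymo|diameter|events|density|run
```

`mck run --config run.yaml --seed 4 --out out/` executes a multi-stage
pipeline (e.g. `simulate → shiftcurve → coloc`) with one seed feeding all
stochastic stages; every artifact carries a provenance sidecar with the
config hash and seed, and a rerun with the same config and seed is
byte-identical.

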