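# Methods

This note records the models, estimators and numerical choices behind
`cortexstate`, and what the synthetic benchmarks do and do not establish
about real recordings.

## The generative model

A recording is an alternation of two cortical states.  Epoch durations are
exponential with configurable means, left-truncated at 10 s — the floor
avoids slivers no analysis could use, and by memorylessness it simply
shifts the realized mean by +10 s.  Defaults encode two conditions:
anesthetized (synchronized 167 s / desynchronized 165 s) and unanesthetized
(197 s / 423 s).  Inside synchronized epochs, up and down phases alternate
with exponential durations (defaults 0.5 s / 0.5 s; labels are emitted at
10 ms resolution while spike placement uses the exact continuous
boundaries).  The in-vivo literature rarely quantifies these phase
durations; 0.5 s is a typical slow-oscillation half-period under urethane
and both means are user-overridable.

**Spike trains.**  Each unit is an inhomogeneous Poisson process: rate
`baseline / u` inside up phases (u = configured up fraction,
up_mean/(up_mean+down_mean)), zero in down phases, and
`baseline x gain` (tonic) in desynchronized epochs.  The design up
fraction is deliberately the *configured* ratio rather than the realized
one: normalizing by the realized up time would pin every realization's
mean synchronized rate exactly to baseline, deleting the up-time component
of sampling variance and making the per-cell t-test spuriously
conservative.  With the configured ratio, rates recover the class
baselines in expectation and the test is calibrated (measured type-I error
0.057 at α = 0.05 over 1000 null replicates).  Class defaults use the
published baselines: anesthetized 0.9 / 3.0 / 5.8 / 5.1 Hz and
unanesthetized 2.2 / 4.5 / 7.5 / 13.5 Hz for sPC / dPC / sFS / dFS.
Bursts are doublets: each spike independently triggers one extra spike
with probability `burst_prob` at an exponential lag (mean 4 ms).  The
expected fraction of within-state ISIs ≤ w then has a closed form
(`expected_burst_fraction`): for up-phase firing at rate r with up-phase
hazard h = 1/up_mean,

    q = r/(r+h) · (1 − e^{−(r+h)w}),   frac = (p·P(lag ≤ w) + q)/(1+p),

which `solve_burst_prob` inverts to hit a target fraction.  The
approximation ignores the rare case where the doublet lag outlives the
next seed spike (relative error ~p·r·lag, < 1% at the defaults); tests
check it against simulation at Monte-Carlo resolution.

**Waveforms.**  Templates are sums of three Gaussians (negative trough,
two positive flanks) refined by fixed-point iteration against the
package's own feature extractor until trough-to-peak, half-width and
asymmetry match the request to a quarter sample / 0.005.  Defaults: PCs
0.70 ms / 0.30 ms / 0.10, FSs 0.35 ms / 0.18 ms / 0.40 at 20 kHz.  Only
shape, not absolute amplitude, is constrained; amplitude decays across
channels as a Gaussian in depth distance (σ = 50 μm against 100 μm site
spacing — only the ordering matters for depth estimation).

**LFP.**  During synchronized epochs the slow component is a
rectified-sine carrier at the slow-oscillation fundamental
(1/(up_mean+down_mean) ≈ 1 Hz) whose polarity is locked to the current
phase (negative in up), smoothed with a 50 ms Gaussian; broadband Gaussian
noise is added everywhere.  The carrier matters: a plain phase-locked
square wave has *no* in-band power in the ~14% of 1-s bins that fall
entirely inside one exponential phase, which caps attainable segmentation
accuracy.  With the default 10:1 amplitude ratio the two states' per-bin
log-power distributions are disjoint.

All randomness flows from one integer seed through named, independent
substreams (`simulate.substream`), so identical configurations are
bit-reproducible.

## Estimators and numerical choices

* **Band power**: per-1-s bin, demeaned, Hann-tapered periodogram summed
  over (0, 7] Hz (density scaling × frequency step; DC excluded).  An
  in-band unit sinusoid recovers its variance (0.5) to < 5%.
* **State split**: 1-D 2-means on log power with centers initialized at
  the data extremes — deterministic and parameter-free; 5-bin median
  smoothing; runs shorter than 10 s merged (shortest first).  Cluster
  separation below 1% of the range, or a single surviving label, yields
  status "no state alternation detected" (such recordings are excluded
  from recovery experiments, mirroring the inclusion rule used with
  in-vivo datasets).  Labels are invariant to affine LFP rescaling.
* **Up/down detection**: pooled MUA in 10-ms bins, Gaussian-smoothed
  (σ = 30 ms), thresholded at 50% of the up-phase mean rate, iterated
  twice.  50% is the unbiased crossing for a smoothed step between a
  silent down phase and a constant-rate up phase; a lower threshold
  (e.g. 20%) inflates the detected up fraction by ~0.8 σ per edge
  (~+0.07 at the defaults).  Pooled rates below 0.5 Hz flag the epoch
  and label it down.
* **Waveform features**: baseline = mean of the leading 20% of samples;
  half-width crossings linearly interpolated; flanking peak amplitudes
  clipped at zero (flagged); a post-trough "peak" under 1% of the trough
  depth counts as absent and excludes the unit.
* **FS/PC clustering**: features z-scored (they carry incommensurate
  units), k-means k = 2 with 50 restarts at a fixed seed; the
  narrower-spike cluster is FS.  Fewer than 4 units, or an identical
  feature cloud, labels everything PC with a warning.
* **Depth/layers**: depth = channel maximizing waveform peak-to-trough
  span, ties to the shallower channel; layer windows closed:
  [0, 500] μm superficial, [800, 1100] μm deep, otherwise unassigned.
* **Isolation distance**: squared Mahalanobis distance (cluster's own
  covariance) from the centroid to the n-th closest non-member; +inf when
  non-members are fewer than members; singular covariances get a
  1e-6 × trace ridge with a warning.
* **Modulation statistics**: MI undefined (and excluded from population
  tests) only when both rates are zero.  Spontaneous significance uses
  the Welch unpaired t-test on 1-s bin counts (bins are heteroscedastic
  across states); evoked uses the paired t-test on per-event post − pre
  counts, effective events only by default.  Signed-rank tests are exact
  for n ≤ 25 without ties (zeros dropped).  Burst ISIs spanning epoch
  boundaries are discarded.  Post-hoc rank-sums carry no multiplicity
  correction, matching conventional reporting.  The rate–MI regression is
  on log10 FR_s (zero-rate units excluded).  α = 0.05 throughout.
* **Epoch-duration recovery** reports the right-censored MLE of the
  exponential scale above the 10 s floor: (total epoch time beyond the
  floor, censored final epochs included) / (number of complete epochs).
  A naive mean of complete epochs is biased upward by the floor and
  downward by window completeness; the cancellation of the two depends on
  the window length and is not relied upon.

## Benchmark experiment sizes

Recovery experiments (`cortexstate.validation`, driven by
`scripts/acceptance.py`) use single-channel recordings at 200 Hz — ample
for a 0–7 Hz statistic — with 30 recordings of 1800–3600 s for epoch
durations and 30 units for rate and burst recovery.  Units are placed in
independent recordings (one or two per recording) because units sharing a
recording share its realized up-phase fraction; an across-unit standard
error inside one recording would understate the true uncertainty.  At
these sizes the epoch-duration estimate itself carries ~8.5% sampling
error (σ/√n of an exponential-mean estimate from ~140 epochs), so
individual draws of that experiment scatter correspondingly; the test
suite averages three replicates when checking its calibration.

## What the synthetic benchmarks do not show

The generator reproduces the statistical skeleton the analysis assumes,
not cortical biophysics: no spike sorting errors or overlapping spikes
(isolation distances are simulated metadata), no waveform drift, no
non-exponential epoch or phase durations, no travelling waves or
depth-dependent LFP structure, no sensory-evoked responses, and
stimulation is modeled only as a timestamped switch into the
desynchronized state.  Passing benchmarks therefore establish estimator
correctness and calibration under the stated model — not that the model
captures any particular in-vivo dataset.  Morphological identification
(e.g. thick- vs slender-tufted deep PCs) exists only as simulation
metadata and plays no role in the analysis.
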