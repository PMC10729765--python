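# Methods

## Scope and data model

The package analyzes continuous multichannel scalp EEG (microvolts) and
compares two groups of subjects. Its stages are: channel selection →
broadband filtering (0.5–45 Hz) → common average reference → per-band
filtering (δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz) → non-overlapping
2-s epoching → per-epoch wPLI connectivity → weighted graph metrics →
edgewise and metric-wise group statistics. The default study geometry is 19
electrodes of the 10–20 system (Fp1 … O2), 500 Hz sampling, 20-min
recordings, 10 vs 5 subjects; a reduced geometry (8 channels, 250 Hz,
2 min) is used for fast runs and most tests.

Artifact screening and ICA-based cleaning are expert, human-in-the-loop
steps and are deliberately not automated; `preprocess()` accepts an already
cleaned recording, which is the natural insertion point for any cleaning
procedure.

## Preprocessing choices

* **Filter.** 4th-order Butterworth bandpass applied forward–backward
  (`sosfiltfilt`): zero phase, effective 8th order, flat passband. The
  analytic forward–backward response at 10 Hz through the alpha band is
  ≥ 0.999; a 50-Hz tone through the 0.5–45 Hz filter retains amplitude
  |H|² ≈ 0.25 — adequate for separating the defined bands, not a notch
  filter.
* **Order of operations.** Selection → broadband filter → average reference
  → band filter → epoching. Filtering and average-referencing are both
  linear and time-invariant, so their order is immaterial (asserted in the
  tests); the order is fixed only for reproducibility.
* **Epoching** starts at sample 0, is non-overlapping, and drops a trailing
  remainder shorter than one epoch (no zero-padding). A 20-min 500-Hz
  recording yields exactly 600 two-second epochs.
* **EDF I/O.** A compact 16-bit EDF reader/writer is included (1-s data
  records, per-channel physical scaling); round-trip error is at most one
  quantization step of the channel's physical range. Channels with mixed
  sampling rates are rejected explicitly rather than silently resampled.
  The reader is cross-validated against MNE's EDF reader in the test suite.

## wPLI estimation

wPLI = |E[Im Y]| / E[|Im Y|] with Y(t) = a_i(t)·a_j(t)*, computed on
Hilbert analytic signals of the band-filtered epoch. Choices:

* The expectation is over time samples within one epoch; the subject-level
  matrix is the mean over epochs. (The alternative — expectation over
  epochs per frequency bin from tapered FFT cross-spectra — is a
  recognized config option left unimplemented.)
* The first and last 5% of samples of each epoch are excluded to suppress
  Hilbert edge artifacts (`EDGE_TRIM_FRACTION`).
* 0/0 guard: when E[|Im Y|] is zero the estimator is defined as 0 (zero
  evidence of lagged synchronization — the volume-conduction case). The
  guard uses a relative floor of 64·eps·E[|a_i||a_j|] because vectorized
  complex products leave O(10⁻¹⁶) rounding residue in Im(a·a*) even at
  exactly zero lag.
* The estimator is positively biased under independence; the bias shrinks
  with the number of independent samples per epoch (≈ bandwidth × epoch
  length) and is therefore band- and epoch-length-dependent but nearly
  sampling-rate-independent. The sensitivity harness measures exactly this.

## Graph metrics

On each subject-band wPLI matrix (symmetric, non-negative, zero diagonal):

* **D** — mean node strength, (1/N)·Σ w_ij over ordered pairs.
* **CC** — the printed binary clustering definition is degenerate on dense
  weighted graphs (every triangle exists), so the default is the Onnela
  geometric-mean-of-triangle-weights coefficient on weights normalized by
  the matrix maximum; nodes with fewer than two neighbors contribute 0. The
  literal binary coefficient on a thresholded graph is available via
  `variant="binary"`.
* **CPL / GE** — all-pairs shortest paths (Dijkstra) under the
  weight-to-length map `length = 1/w` (the −log w alternative is documented
  but not default). Disconnected pairs make CPL infinite and raise a
  warning; `finite_only=True` averages connected pairs instead (this
  changes the estimand and is off by default). GE uses 1/∞ = 0 and is
  finite for any graph.
* No density thresholding is applied before metric computation; the
  top-10% edge cut is presentational only.

Scaling all weights by k > 0 multiplies D and GE by k, divides CPL by k,
and leaves CC unchanged; all four metrics are label-permutation invariant
(both asserted numerically).

## Group statistics

* **Edgewise:** Welch (unequal-variance) t-test per edge — chosen because
  the group sizes are unequal (10 vs 5) and no variance homogeneity is
  assumed — with Benjamini–Hochberg FDR at q = 0.05 applied within each
  band across its N(N−1)/2 edges (each band is its own analysis family).
  Observations are subject-level epoch-mean wPLI values by default;
  epoch-level pooling is first-class via `level="epoch"` and is reported
  with the level used. Zero-variance equal-mean edges are flagged
  degenerate (t = 0, p = 1).
* **Metrics:** two-sided Wilcoxon–Mann–Whitney per (band, metric); exact
  null distribution when both groups have ≤ 8 observations and no ties,
  mid-rank normal approximation with tie correction otherwise. Significance
  level 0.05 throughout.
* **Top-fraction selection:** among FDR-significant edges, at most
  ⌈fraction × total edges⌉ are kept, ranked by adjusted p (ties by |t|);
  if fewer are significant, all are kept.
* A band "verdict" summarizes the edgewise table: `ns` if nothing survives
  FDR, otherwise the majority direction of significant edges.

## Synthetic cohorts

Each channel is a sum over the five bands of unit-variance narrowband
Gaussian processes (white noise spectrally masked to the band) plus
unit-variance 1/f^1.0 background noise, scaled to ~10 µV. A
`CouplingSpec(pair, band, lag, strength)` replaces a fraction `strength` of
both channels' band-component *power* with a common source (amplitude
weights √strength and √(1−strength), variance-preserving); the second
channel's copy is the analytic signal rotated by `lag`, so the lag is
constant across the band and the wPLI limiting values are analytic:
strength 1 with a quarter-cycle lag drives the pair's wPLI toward 1, and
strength 0 (or lag 0) leaves it at the independence bias.

Cohort defaults are the package's own empirical choices (no effect sizes
are prescribed by any external source): shared-power fractions 0.25 (group
A) vs 0.55 (group B) in delta, 0.40/0.40 in theta, 0.55/0.25 in alpha,
beta, and gamma; three disjoint coupled pairs per band with lags cycling
through π/2, π/3, 2π/3; between-subject strength jitter SD 0.05. Group A
therefore plays the patient role of the intended qualitative pattern:
decreased delta synchronization, no theta change, increased
alpha/beta/gamma synchronization — which also drives D and GE up and CPL
down in the strengthened bands. With disjoint planted pairs the coupling
adds no triangles, so the direction of the weighted CC is not controlled
by construction; CC is reported but not part of the recovery checks.

Per-subject sub-seeds are spawned from the master seed with
`numpy.random.SeedSequence.spawn` (counter-based), so any subject is
reproducible in isolation; recordings are bitwise-deterministic given the
seed.

What the simulator does **not** model: volume-conduction forward physics
(a zero-lag common source can be added manually, and the tests do), ocular
and muscle artifacts, epileptiform discharges, inter-channel distance
structure, and non-stationarity. Passing the recovery tests therefore shows
the pipeline correctly detects lagged band-specific coupling differences of
realistic magnitude at the study's sample sizes — not that any particular
clinical population behaves this way.

## Problem sizes and numerical tolerances

Tests and the acceptance script use reduced problem sizes chosen as the
smallest that leave the qualitative behavior unambiguous: the recovery
check runs 20 cohorts of 10 vs 5 subjects at the fast geometry (8 channels,
250 Hz, 2 min → 60 epochs) and requires the full five-band direction
pattern in ≥ 18 of 20 runs; null FDR calibration uses 200 five-vs-five
cohorts (4 channels, 20 s) with identical coupling in both groups, with a
two-binomial-SE Monte-Carlo tolerance on the mean false-discovery
proportion; the sensitivity harness uses 12 regenerated recordings per
(rate, epoch-length) cell at 4 channels × 240 s. Oracle equivalences
(Dijkstra vs Floyd–Warshall, clustering vs triangle enumeration, wPLI vs
the literal defining formula, exact rank-sum vs enumeration) are asserted
to 1e-12; analytic limits of wPLI to 1e-6; filter responses to 5%.

## Known limitations

* No source-space projection, notch filtering, resampling, or bad-channel
  interpolation; input is assumed cleaned and uniformly sampled.
* The EDF codec supports continuous 16-bit recordings with one sampling
  rate and whole-second durations — sufficient for this pipeline, not a
  general EDF+ implementation.
* CPL is infinite for disconnected graphs by default; dense wPLI matrices
  are effectively always connected, so this matters only for thresholded
  or degenerate inputs.
* Epoch-level pooling treats epochs as exchangeable observations and
  ignores within-subject correlation; it is provided for comparability,
  while subject-level aggregation remains the statistically defensible
  default.
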