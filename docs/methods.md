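# Methods

This note documents the models, estimators and design choices behind
`spindlesep`, in the order the pipeline applies them, together with the
synthetic data the tests rely on and the limits of what those tests
demonstrate.

## Surface Laplacian (current source density)

Scalp potentials are spatially high-pass filtered with the spherical
spline surface Laplacian. For electrodes at unit-sphere positions, the
interpolation kernel g and Laplacian kernel h are Legendre series in the
cosine of the inter-electrode angle with coefficients
(2n+1)/(n(n+1))^m and −(2n+1)/(n(n+1))^(m−1); the spline system
(G + λI) is solved under a zero-mean constraint and mapped through H.
The whole transform reduces to one channels × channels matrix whose rows
sum to zero, so the output is invariant to the recording reference.

Defaults m = 4, λ = 10⁻⁵, 50 Legendre terms are the established CSD
toolbox settings; none are critical, and all are configurable. Head
radius is fixed at 1, which makes the absolute µV/cm² scale
conventional — acceptable because every downstream quantity is
normalized, rescaled, or thresholded relative to the data itself.
Correctness is checked against an independent dense oracle that
evaluates a 200-term Legendre series pointwise and solves the
constrained system in augmented (KKT) form.

## Derivative-Welch spectra

Power spectra are estimated not from the signal but from its first
difference x[t+1] − x[t]. Differencing multiplies the PSD by
|1 − e^{−iω∆t}|², which grows ≈ ω² at low frequency and thereby
counteracts the 1/f trend, making sigma peaks stand out; the exact gain
is exposed as `difference_filter_gain` and verified against scipy's
Welch estimate in the tests. Welch parameters: 5 s Hamming windows, 50%
overlap, constant detrend, averaged within and across 30 s stage
epochs; at 400 Hz this gives a 0.2 Hz grid, matching the one-decimal
precision at which peak frequencies are reported. The estimator itself
is a vectorized batch implementation equal to `scipy.signal.welch` to
machine precision (asserted in tests); it exists because the pipeline
evaluates hundreds of multi-component spectra.

Per-electrode spectra of both N2 and N3 are divided by that electrode's
mean N2 power over 0–4 Hz, giving both stages one common baseline and
making per-electrode values comparable across channels and subjects.
For peak detection, spectra are rescaled to [0, 1] over 0–20 Hz, and
local maxima are ranked by topographic prominence (scipy's
`find_peaks`, the same definition as Matlab's `findpeaks`), with the
liberal threshold 0.01 for channel-level peaks. Prominence is computed
on the full 0–20 Hz spectrum before restricting to the 9–16 Hz search
range, so range edges cannot inflate it. Sigma peaks are classed slow
below 12.5 Hz and fast at or above it; a peak sitting exactly on the
boundary inherits the side of the same subject's peak in the other
sleep stage when one exists, and defaults to fast otherwise.

## GED peak separation

The covariance matrices come from zero-phase Hamming-windowed-sinc FIR
filtering (order 13 200; constructed as the difference of two unity-DC
low-passes so the DC null is exact) of the Laplacian EEG in the slow
(9–12 Hz) and fast (12–16 Hz) ranges; per-channel means are removed
after filtering and the first/last order/2 samples are excluded to
avoid edge transients. The generalized symmetric eigenproblem
SW = WFΛ is solved with F shrunk toward a scaled identity,
(1−γ)F + γ·tr(F)/n·I with γ = 0.01, guarding against rank deficiency on
short records (γ = 0 reproduces the literal decomposition). Eigenvector
scale and sign are arbitrary; filters are unit-normalized with the
largest-magnitude weight positive so results are reproducible.
Correctness is cross-checked against a dense random search over unit
vectors maximizing the Rayleigh quotient wᵀSw / wᵀFw.

Component spectra are derivative-Welch spectra of the broadband
Laplacian data projected through the filters, rescaled to [0, 1]; by
default only the first and last ten components — the ones the selection
policy scans — are computed.

### Automated component selection

Done by hand, component selection is a visual judgment of peak
"quality"; this package operationalizes that judgment, and
two properties of GED make a naive automation unsound:

* rescaling a nearly flat spectrum to [0, 1] turns sampling wiggles
  into peaks of large nominal prominence, and
* a GED filter is free to overfit: with 58 channels it can concentrate
  whatever narrowband noise happened to be strongest in its training
  band, which then *genuinely* looks like a spectral peak.

Selection therefore works as follows. Covariances (and hence W) are
estimated on the odd-numbered epochs and component spectra on the
held-out even-numbered epochs — the standard cross-validation guard for
eigenvector methods; an overfitted direction shows its peak only on the
training half. A candidate peak must (a) have rescaled prominence
≥ 0.05, (b) beat every sigma-range peak of the other class in the same
component, and (c) reach at least twice the local background — the
lower quartile of the raw spectrum in a 0.5–2.5 Hz surround — in
*both* the held-out and the training-half spectrum at the same
frequency (±1 bin). The factor two sits far above Welch sampling
fluctuations at these record lengths (tens of windows → excursions of a
few tens of percent) and far below genuine rhythm peaks (≥ 10× local
background in all regimes tested). Among candidates within the scanned
first/last ten components, the one with the largest held-out contrast
wins; "none found" is a valid and honest result, and a manual override
by explicit component index keeps a by-eye workflow available.
GED is computed per stage × night; nothing is pooled.

## Individualized bands and exclusions

A subject's slow or fast sigma band is the 1.3 Hz window centered on
the arithmetic mean of the available stage × night component peaks
(missing entries are simply omitted). Subjects whose night-averaged N2
and N3 slow peaks differ by more than 0.7 Hz are excluded from slow
analyses. Subjects whose slow and fast bands overlap are excluded from
topographical analyses; the default overlap test uses the 1.3 Hz
passbands themselves, because the stricter variant that also counts the
0.5 Hz filter transition zones as overlap would discard roughly a
quarter of a typical cohort (any subject whose centers are less than
2.3 Hz apart), which is out of keeping with how rarely the rule fires
in practice; the strict variant remains available as a configuration
option. Whether the 0.7 Hz rule should see per-night or night-averaged
peaks is genuinely open; night-averaged is used.

## Spindle detection

Per channel and class, the Laplacian signal is zero-phase filtered with
a least-squares FIR of order 3000 (1.3 Hz passband, 0.5 Hz
transitions) at the subject's band center; the envelope is the
magnitude of the analytic signal smoothed by a 200 ms centered moving
average. Thresholds per channel and class are mean + 3 SD (upper) and
mean + 1 SD (lower) of the artifact-free N2 envelope, with the sample
SD (n−1; configurable) — the N2-anchored thresholds are reused for N3
so stage differences in sigma power cannot confound detection. Each
upper-threshold excursion is expanded to the nearest flanking
lower-threshold crossings; identical delimitations merge; events must
last 0.4–3.0 s; excursions that cannot be delimited against the record
edge are discarded. Rejection runs in a fixed order: broadband first —
an event is dropped when any 20–80 Hz bin of a periodogram of the raw
segment (zero-padded to 2 s, i.e. 0.5 Hz bins) reaches the weakest bin
of the subject's sigma band — then amplitude outliers (mean envelope
amplitude > 4 SD above that channel's event mean, per night across
stages; vacuous below two events). Density (events/min) and mean peak
envelope amplitude are reported per channel × stage × class; channels
without events get density 0 and a missing amplitude.

## Topographic statistics

Sigma-power maps are per-electrode means of normalized power over the
subject's 1.3 Hz band. Electrodes are adjacent when their angular
distance is below a cutoff chosen (deterministically, per montage) to
give mean degree ≈ 7, keeping the graph in the 5–9 range. Paired
condition comparisons use the cluster-mass permutation test:
per-electrode paired t, cluster-forming threshold at the two-tailed
clusteralpha = 0.1 critical value, sign-consistent connected clusters,
cluster mass = summed t, and a sign-flip permutation null (1000 flips
by default, observed labeling included, so p ≥ 1/(n+1) and results are
bit-reproducible under a fixed seed). Each tail keeps its own null —
positive clusters are referred to the distribution of the maximum
positive cluster mass per permutation, negative clusters to the
maximum negative mass — which attains the nominal ~5% family-wise rate
of the 0.025-per-tail convention; a pooled max-|mass| null would halve
it. Electrodes with missing values (e.g. amplitude on zero-spindle
channels) in more than 20% of subjects are dropped from the test; all
clusters are reported with their p so the caller decides what to call
significant.

## Similarity and fingerprinting

Within-subject profile similarity is the Pearson correlation between
two spectra (0–20 Hz bins) or two topographies (per-electrode values),
with the two-sided p from the t distribution (n−2 df; spatial/spectral
autocorrelation is acknowledged, not corrected). Group-level: a
one-sample t test of the N correlation coefficients against zero,
applied to the raw R values (a Fisher-z option exists but is off, to
keep the literal procedure). The share of subjects with BH-FDR-adjusted
p < 0.05 is reported alongside. Fingerprinting trains a k = 1 nearest
neighbor classifier under correlation distance (1 − R) on one
condition's profiles and tests on the other, in both directions; ties
go to the lowest subject index; significance is the one-sided exact
binomial tail against chance 1/N (one-sided because only
above-chance identification is meaningful).

## Synthetic NREM EEG

The generator plants known structure to make every stage testable:

* **Background.** Per-channel independent 1/f^α Gaussian noise
  (α = 2, so the derivative spectrum is near flat — a deliberately
  hard regime for peak detection), SD 10 µV, plus three shared smooth
  spatial modes (Gaussian bumps at random orientations, SD 5 µV) so
  channel covariance is realistically non-diagonal. Normalization is
  analytic (Parseval), not per-realization.
* **Slow oscillations.** N3 epochs add a 0.8 Hz sinusoid, amplitude
  40 µV, with a fresh random phase per epoch; no phase coupling to
  spindles (coupling analyses are out of scope).
* **Spindle sources.** Two oscillators — slow and fast — each a train
  of Hann-windowed sinusoid bursts (durations uniform on 0.5–2.0 s,
  Poisson onsets at 3/min within eligible epochs, non-overlapping per
  class, random phase per burst, 15 µV at the strongest channel) mixed
  through nonnegative per-channel topographies.
* **Cohorts.** The default sampler draws slow ~ U(9.5, 12.0) and fast
  ~ U(12.6, 15.0) Hz, redrawn until they differ by ≥ 1.3 Hz, and
  Gaussian-bump topographies centered near Fz (slow) and Pz (fast) with
  jittered centers and widths, redrawn until their cosine similarity
  lies in [0.5, 0.8] — enough overlap that channel-averaged spectra
  tend to merge or miss the slow peak, which is the regime the method
  exists for. Subject traits (frequencies, topographies) are
  night-invariant; noise and event times are redrawn per night.
  Per-subject seed streams are independent substreams of the master
  seed, so subject i is identical regardless of cohort size.

What the generator does **not** emulate: sleep microarchitecture
(K-complexes, arousals, cycles), REM/wake content, spindle frequency
chirp, slow-oscillation–spindle coupling, electrode artifacts, or
inter-channel noise structure beyond the low-rank modes. Passing tests
therefore demonstrate the pipeline's correctness and its claimed
robustness properties under controlled conditions — not performance on
clinical recordings.

## Benchmark problem sizes and numerical conventions

The planted-truth benchmarks use 20-subject cohorts with 5 minutes each
of N2 and N3 (robustness of selected peaks to ±0.5 Hz shifts of the
initial filter bands; recovery of both planted frequencies within
0.2 Hz, judged on the stage-averaged subject-level peak; honest "none"
on slow-silenced records), 3 × 10-minute subjects for detector
recall/precision (events matched by onset within ±0.5 s on each class's
maximal-topography channel), 100 null cohorts × 200 permutations for
cluster-test calibration, and 20 subjects × 2 nights × 3 minutes for
cross-night fingerprinting. These sizes keep the full suite in the
minutes range while leaving each property's pass margin wide.

Conventions worth knowing: onsets are seconds from recording start with
half-open event intervals; artifact epochs are dropped at selection
time, never by mutating the recording; TSV artifacts are tab-separated
UTF-8 with six significant digits and fixed column order, so identical
inputs yield byte-identical outputs; EDF is written as 16-bit with
per-channel auto-scaled physical ranges (round-trip error is bounded by
one quantization step and checked against an independent reader); all
randomness flows from explicit seeds through named substreams.

## Known limitations

* Selected peak frequencies live on the 0.2 Hz Welch grid; no
  sub-bin interpolation is attempted, and the ω²-shaped derivative gain
  can bias broad burst peaks upward by up to one bin.
* The split-half selection uses half the data per estimate; on very
  short records (a handful of epochs) held-out spectra are noisy and
  selection becomes conservative before it becomes wrong.
* The automated quality judgment (contrast ≥ 2× local background in
  both halves) replaces human inspection; its constants are motivated
  by sampling arithmetic, not fitted to data, but records whose true
  peaks are weaker than twice the local background will be reported as
  absent.
* The cluster test assumes exchangeability of the paired difference
  maps under sign flips; heavy-tailed or strongly heteroscedastic maps
  are outside its guarantees.
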