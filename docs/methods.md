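# Methods

This note documents the models and procedures implemented in `oscillonet`,
the choices made where the analysis conventions were genuinely open, and
what the synthetic validation does and does not establish.

## Setting

The package analyzes multichannel local field potential (LFP) recordings
from the amygdalo-hippocampal circuit of anesthetized rats (dorsal,
intermediate and ventral hippocampus plus basolateral amygdala) acquired
under a fixed protocol: a 300-s baseline, a 300-s saline control, 15 min
after administration of an anxiogenic drug (FG-7142, a benzodiazepine-site
inverse partial agonist), one hour of infralimbic deep brain stimulation
(DBS-IL), and a 300-s post-stimulation epoch.  The stimulation hour is
analyzed as five contiguous 720-s periods (DBS1–DBS5); one hour divided
into the five analyzed periods with no stated durations makes equal
fifths the minimal assumption.  Epoch intervals are half-open
`[start, end)` in seconds with 0-based sample indices, so contiguous
epochs concatenate sample-exactly.

Under urethane anesthesia the baseline LFP is dominated by slow waves
(< 1.5 Hz); the anxiogenic drug elicits sustained "type 2" low theta
(2.5–5 Hz), which DBS-IL progressively reverses.  The analyses quantify
this state structure spectrally, in time–frequency, and through
inter-regional coupling.

## Spectral analysis

Power spectral density uses Welch's method with 5-s Hamming-tapered
segments at 50% overlap and `nfft = 1024`.  Because a 5-s segment at the
1 kHz acquisition rate holds 5000 samples, `nfft = 1024` is shorter than
the segment; we reproduce the MATLAB `pwelch` behavior of wrapping each
tapered segment modulo `nfft` (`datawrap`) before the FFT, giving a bin
width of `fs/1024` (≈ 0.98 Hz at 1 kHz, ≈ 0.24 Hz at 250 Hz).  Two
consequences are worth knowing: the effective frequency grid samples the
segment DTFT at steps wider than the 5-s Hamming mainlobe, so tones
between grid points are scalloped; and estimates at neighboring bins are
essentially independent.  A `pad_to_window` policy (plain scipy Welch
with `nfft ≥ ` segment length) is available when fidelity to the legacy
grid is not needed.

Band powers integrate the PSD with a per-bin rectangle rule (bin value ×
bin width) over half-open bands: slow [0, 1.5), delta [1.5, 2.5), low
theta [2.5, 5), high theta [5, 12), beta [16, 30), low/mid/high gamma
[30, 60)/[60, 90)/[90, 120).  The rectangle rule is used because the
delta band holds a single bin at the legacy 1-kHz grid and because it
makes disjoint bands exactly additive.  Relative power divides by total
power in [0, 250) Hz (or [0, fs/2) with a warning when the sampling rate
is below 500 Hz).  Peak frequency is the argmax bin within a 0.5–12 Hz
search range — all state-dependent peaks of interest live below theta
and an unrestricted search would land on gamma in high-gamma regimes —
with ties broken toward the lowest frequency.  Timecourses use
consecutive non-overlapping 60-s windows; epoch summaries average the
five windows of a representative 300-s span, taken as the *final* 300 s
of epochs longer than 300 s (late windows carry the settled drug or
stimulation effect).

## Theta segments

A complex Morlet continuous wavelet transform (ω₀ = 6) is evaluated on a
log-spaced 0.5–120 Hz grid.  Coefficients are divided by √scale so a
unit-amplitude sinusoid produces the same magnitude at every analyzed
frequency; without this normalization low frequencies dominate any
cross-frequency magnitude ratio.  At each time point the theta ratio is
the summed magnitude over 2.5–5 Hz divided by the summed magnitude over
the full analyzed grid (the literal reading of "total oscillatory
activity"); points with ratio ≥ 0.30 are marked, and contiguous marked
runs of at least 0.5 s (≈ two cycles at 4 Hz, suppressing single-point
crossings) become theta segments.  Cone-of-influence cells (within one
wavelet e-folding time of an edge) are excluded from numerator and
denominator.  Per 60-s window we report the temporal ratio (marked time /
window length), mean segment width in seconds, and segment count;
boundary-straddling segments are clipped and counted once in each window
they touch, keeping ratio, width and count internally consistent.
Magnitude (not power) ratios make the detector amplitude-scale
invariant; threshold, minimum width and the denominator range are
configurable.

## Phase coupling

Band-limited instantaneous phase and envelope come from a zero-phase
4th-order Butterworth band-pass (forward–backward) followed by the
Hilbert analytic signal.  PLV is the magnitude of the mean unit phasor of
the phase difference in 10-s windows.  WPLI weights phase leads and lags
by the imaginary cross-spectrum magnitude: within an estimation window,
1-s Hamming sub-segments at 50% overlap yield cross-spectra `S_ab`; per
frequency bin the index is `|E[Im S_ab]| / E[|Im S_ab|]`, averaged over
the band's bins.  Windows with identically zero imaginary cross-spectrum
are reported missing.  Both metrics are symmetric and invariant to
amplitude scaling; WPLI is insensitive to zero-lag (volume-conducted)
coupling, which is why it is the default reported phase metric with PLV
retained alongside.  A debiased (squared) WPLI variant is available
behind a flag.  For epoch-level values we use a single window spanning
the epoch: slow phase drift between *independent* same-frequency
oscillators decorrelates only over tens of seconds, so short windows
cannot average it away and would report a spuriously high floor.
Wavelet coherograms (magnitude-squared coherence of smoothed
cross-scalograms, ~1 s × 3 scales) serve visualization.

## Mutual information

Between-channel "communication" per band is quantified as normalized
mutual information between the two band *envelopes* — the envelope (not
phase) carries the band's activation strength, matching the
information-flow reading, and yields a natural [0, 1] normalization.  The
estimator uses equal-count (quantile) binning with ⌈N^(1/3)⌉ bins per
axis, Miller–Madow bias correction of each entropy term, and
normalization by the smaller marginal entropy, clipped to [0, 1].
Quantile binning makes the estimate invariant under strictly monotone
transforms of either envelope and forces identical channels to score
exactly 1.  This estimator choice is the main interpretive decision in
the package: published pairwise MI values depend on the estimator,
input series, and normalization, none of which are standardized.

## Phase–amplitude coupling

The modulation index bins the slow band's instantaneous phase into 18
equal bins (the standard convention), averages the fast band's envelope
per bin, normalizes the profile to sum 1, and reports the KL divergence
from uniform scaled by `log 18`, so MI ∈ [0, 1] with 0 for a flat profile
and 1 for a single-bin concentration.  Natural logarithms are used; the
normalization makes the base irrelevant.  Significance uses 200
surrogates obtained by circularly time-shifting the envelope by uniform
random offsets of at least 1 s — circular shifts preserve the envelope
autocorrelation and avoid the anti-conservative null that full sample
shuffling produces; a `shuffle` mode implements the cruder permutation
for comparison.  An observed MI is significant when it exceeds the
surrogate mean by more than two surrogate standard deviations.  The
canonical analyzed pairs are slow→theta, slow→gamma, delta→beta and low
theta→gamma; PAC is evaluated over each epoch's representative 300-s
span.  Comodulograms scan 2-Hz-wide phase bands against 10-Hz-wide
amplitude bands.

## Group statistics

Metrics enter inference as subjects × conditions tables.  A Shapiro–Wilk
gate documents non-normality (the pipeline always runs the nonparametric
battery regardless).  Within-cohort state effects use the Friedman
chi-square on within-subject mid-ranks with tie correction, followed by
Conover–Iman all-pairs t-statistics on rank sums with the residual rank
variance, df = (n−1)(k−1), two-sided, Holm-adjusted (raw p-values are
retained since no particular correction is canonical here).  Group
comparisons use tie-corrected Kruskal–Wallis; sex contrasts use
two-sided Mann–Whitney U — exact when min(n₁, n₂) ≤ 8 without ties (the
study's n = 5–6 sits in this regime), normal approximation with tie
correction otherwise — with Bonferroni adjustment whose multiplicity m
defaults to the nine compared epochs.  α = 0.05 throughout; summaries
print mean ± SEM with the */**/*** convention at 0.05/0.01/0.001.

## Synthetic LFP generator

Each channel is a sum of narrow-band oscillators at configurable center
frequencies (defaults: slow 1.0, delta 2.0, low theta 4.0, high theta 7,
beta 20, low/mid/high gamma 45/75/105 Hz) plus 1/f^α Gaussian noise
(default α = 1, amplitude 0.3 in oscillator units).  Oscillator phases
carry Wiener (random-walk) drift, diffusion 1.0 rad²/s by default: pure
tones would make phase metrics degenerate, and mean-reverting (OU) drift
was rejected because it leaves independent same-frequency oscillators
phase-locked at a random constant offset, contradicting the requirement
that unshared channels show a low WPLI floor.  With random-walk drift the
phase difference of independent channels decorrelates within seconds
while shared components keep their configured lag exactly.

The low-theta component is gated by an alternating exponential on/off
process (mean on-run 2 s; mean off-run scaled to the target occupancy;
0.25-s raised-cosine edge smoothing), reproducing scattered short theta
at low occupancy and sustained theta near occupancy 1.  Phase–amplitude
coupling multiplies a gamma component's amplitude by `1 + κ·cos(φ)`
against a slow or theta oscillator's phase — exactly the construction
the modulation index detects.  Inter-channel structure duplicates a
shared band oscillator into both channels of a pair at a configurable
power fraction and phase lag (remaining power independent); pairwise
lags are resolved to per-channel offsets over a spanning tree, and the
bundled presets specify lags as potential differences along the
dorsoventral axis (0, 0.5, 1.0, 1.5 rad) so all six pairwise constraints
are simultaneously realizable.

The male/female protocol presets encode the *directions* of the study's
findings, not fitted magnitudes — they are the test harness, not a
biophysical model.  Baseline (and saline, post): slow wave amplitude 1.0
at 1 Hz, theta bursts at 20% occupancy, small delta/beta/gamma; female
gamma amplitudes 2.5× male in all channels.  The theta burst amplitude
(1.6) exceeds the slow wave so that bursts clear the 30% detector
threshold while contributing less total power than slow at 20%
occupancy, consistent with baseline temporal ratios ≈ occupancy.  Male
drug state: slow suppressed (0.25), sustained low theta at 3.3 Hz and
85% occupancy in all channels, delta and beta raised outside HPCd, gamma
raised in HPCv/BLA, and strong shared low theta (fraction 0.8) across
all pairs with delta/beta sharing among the ventral pairs.  Female drug
state: changes confined to the dorsal pole (HPCd occupancy 0.45 with a
slow wave reduced to 0.9 at 1.3 Hz; HPCi slow mildly reduced), ventral
channels and BLA untouched.  DBS1–DBS5 interpolate linearly from the
drug state back to baseline with weights 0.8/0.5/0.25/0.1/0, plus a 2×
gamma elevation in males persisting into post.  All generation is
deterministic given (config, seed).

What the generator does *not* emulate: DBS stimulation artifacts,
non-stationary drug pharmacokinetics within an epoch, volume-conducted
common signals (beyond explicit zero-lag sharing), spike contamination,
electrode drift, and any biophysical (conductance-based) dynamics.
Passing tests therefore demonstrate estimator correctness and pipeline
sensitivity to the encoded effect structure, not performance on real
recordings.

## Validation, problem sizes and numerical choices

Validation runs the generator and analyses at 250 Hz sampling (the
generator's minimum; every analyzed band lies below the 125-Hz Nyquist)
with 300-s signals and six subjects per simulated cohort, matching the
study's group size; the 1 kHz acquisition rate remains the default for
simulation output.  The suite checks, among others: dual-route
equivalence of Welch, WPLI, the modulation index and all rank statistics
against independently written brute-force oracles; closed-form limits
(PLV = 1 under constant lag, MI ∈ {0, 1} at profile extremes, relative
power 1 on the full band, WPLI suppression of zero-lag coupling);
recovery of generator ground truth (theta occupancy across 0.1–0.9,
configured spectral peaks, PAC detection at κ = 0.8 with false-positive
control at κ = 0 under the 2-SD surrogate rule); empirical type-I error
of Friedman (6 × 9), Kruskal–Wallis (3 × 5) and Mann–Whitney (6 vs 6)
within [0.03, 0.07] over 1000 null simulations — the Kruskal–Wallis null
uses three groups because the chi-square approximation is measurably
conservative at four groups of five, a property of the asymptotic test
itself — and reproduction of the sex- and state-dependent pattern by the
simulated cohorts as sign/order constraints on cohort means.

Numerical conventions: argmax ties resolve to the lowest frequency;
empty phase bins, zero/constant envelopes, degenerate groups and
misaligned schedules raise errors rather than returning silent defaults;
WPLI windows with zero imaginary cross-spectrum become missing values;
NaN in loaded recordings is an error; repeated-measures tables drop
subjects with missing cells with a warning.  CSV recordings round-trip
bit-exactly (`%.17g` writing, `round_trip` parsing); EDF export
quantizes to 16 bits over the per-channel physical range (one
quantization step of error at most).

## Known limitations

The wrap-mode Welch grid scallops off-grid tones (inherited from the
stated legacy parameters).  The theta detector's temporal ratio
underestimates occupancy when the theta-to-background magnitude ratio
sits near the 30% threshold, as mixture states do; the recovery contract
(±0.12) is stated for single-band signals.  Preset magnitudes were
chosen for test power, not biological fidelity, and the mutual
information stage's absolute values are estimator-dependent by
construction.  EDF writing requires integer sampling rates and
whole-second recordings.
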