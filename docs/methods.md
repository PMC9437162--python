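# Methods

## Stimuli

Pulse trains are generated additively: the waveform is
Σ_k w(k·F0)·sin(2π k F0 t + φ_k), with φ_k = 0 for all k (SINE) or φ_k =
π/2 for even k (ALT). The passband weight w(f) is 1 inside
[center·2^−q, center·2^+q] (center 8000 Hz, q = ¼ octave → 6727.2 and
9513.7 Hz) and falls linearly in dB with octave distance beyond the
cut-offs (48 dB/octave). Harmonics are dropped below a −80 dB weight
floor or above Nyquist, whichever comes first; the contribution of a
−80 dB component is inaudible and the truncation keeps cost bounded. The
passband is realised as per-harmonic weighting rather than a time-domain
filter: it matches the additive-synthesis reading of the design exactly
and is reproducible to machine precision. A warning flags any
configuration whose lowest in-band harmonic number falls below 15, the
conventional resolvability boundary for these stimuli.

Rate switching: each segment spans an integer number of pulse periods and
is synthesised with a phase origin that puts the envelope maximum at
mid-period (the maximum is located numerically from the analytic-signal
magnitude over one period). Segment edges therefore fall at the
inter-pulse envelope minimum, which eliminates spectral splatter at the
switch; realised (snapped) switch times are what the event log stores.
Higher-rate segments are rescaled to the base segment's RMS (equalisation
is exact by construction; the test suite enforces 0.1 dB). Levels are in
dB re full scale throughout — absolute SPL calibration is a hardware
concern outside this package.

The alternating paradigm uses 1-s base / 1-s higher sweeps, 6 sweeps per
12-s block, 25 blocks separated by 2-s silences (348 s ≈ 5.8 min per
condition), polarity inverted on successive sweeps, and Gaussian block
onset jitter (SD 1 s, clipped to ±0.9 of the silent gap so blocks cannot
overlap). The hold-release paradigm plays the base rate for the hold time
and the higher rate for 1.2 s.

The pink masker is synthesised in the frequency domain (amplitude ∝
f^−1/2, seeded random phases). Its 1-Hz-band spectrum level at 8 kHz is
set to 47 dB below the pulse-train RMS *before* the low-pass at
6727.2 Hz, which follows the stated order of operations; the spectrum
level is defined in a 1-Hz band, the conventional reading. The low-pass
is the same forward–backward Butterworth family used by the analysis
modules.

Pulse rates are screened against harmonics 1–12 of 50 and 60 Hz with a
5-Hz margin. The standard rate tables are shipped verbatim rather than
re-derived: the published rates embed rounding plus the clearance rule,
but the exact selection algorithm is not recoverable (and the
supplementary rate 658 pps demonstrably was not screened — it lies 2 Hz
from 11×60 Hz).

## Behavioral analysis

Scoring windows relative to the rate change: release in (0, 600] ms →
hit; (−600, 0] → false alarm; ≤ −600 ms → early release (excluded from
every rate); later or no release → miss. The boundary assignment (0 to
FA, +600 to hit) makes the windows half-open and scoring deterministic.

Because consecutive hold times differ by exactly the 600-ms criterion,
the FA window of a Hold N+1 trial occupies the same stimulus time as the
hit window of a Hold N trial. P_FA is therefore computed per hold over
Holds 2–4 and combined as a weighted mean with the hit+miss count at Hold
N weighting the FA rate at Hold N+1 (the matched-catch-window reading).
The literal same-index weighting is available via
`pooled_rates(..., alignment="same-index")`. Proportions of exactly 0 or
1 are replaced by 1/(2n) and 1 − 1/(2n) before the probit — the standard
finite-sample SDT convention, which caps the behavioral d′ rather than
letting it diverge.

The permutation null shuffles the assignment of hold times to trials
while holding each trial's absolute release time fixed, re-scores with
the same windows, and recomputes the weighted d′; the 95th percentile is
the chance level. Inside permutation and bootstrap resamples, a hold cell
with no scored trials is dropped with weight renormalisation (never
silently discarded at the resample level), and an empty hit denominator
falls back to the clip rule. All resampling procedures take explicit
seeds.

Session QC keeps sessions with ≥ 10 scored trials, pooled P_Hit > 0.5 and
pooled P_FA < 0.5 (simple pooled proportions across conditions), which
requires d′ > 0 while rejecting heavily biased response strategies.

## ACC analysis

Recordings (12 207 samples/s, two active channels averaged) are bandpass
filtered 2–20 Hz with a second-order Butterworth run forward–backward
(zero phase, fourth-order magnitude response, reflective edge padding).
Epochs span −400 to +2000 ms around each base-rate onset, so one epoch
holds a full higher→base (decreasing, 0 ms) and base→higher (increasing,
1000 ms) sweep; the first sweep of every block is discarded (onset
response) and no DC correction is applied.

Artifact rejection removes epochs whose absolute amplitude inside the two
15–250 ms post-change windows exceeds a factor times the RMS of those
windows pooled across epochs (pooling across both windows; the
normalisation is otherwise underdetermined). The factor is calibrated per
session by bisection so the mean rejection fraction across conditions
lands in 4–6 %. Rejection fractions are monotone in the factor but
piecewise constant, so bisection stops as soon as the mean enters the
band; an unreachable band returns the boundary factor with a warning.
Because the peak-to-RMS statistic depends on window length and bandwidth,
the broadband 1-s FFR epochs get their own factor calibrated the same
way.

P1 is the maximum in 15–65 ms and N1 the minimum in 40–130 ms after the
change; magnitude = P1 − N1. The per-peak noise floor is implemented
literally as across-epoch amplitude variance at the peak latency divided
by √n (averaged over the two peaks); the dimensionally conventional
SD/√n is available behind `use_sd=True` since the literal formula mixes
units.

Detectability: 500 bootstrap response magnitudes (P1 − N1 on the mean of
50 epochs drawn with replacement) against 500 noise magnitudes (max −
min over −110 to −10 ms before the change, independent draws, one seed
driving both streams). The empirical ROC uses thresholds at every
observed magnitude with trapezoidal integration — algebraically identical
to the pairwise-count (Mann–Whitney) AUC with ties counted half, which
the tests verify to 10⁻⁹. AUC is clipped to [1/(2·500), 1 − 1/(2·500)]
before d′ = √2·z(AUC), bounding |d′| at 4.37.

## FFR analysis

Filtering 50–3000 Hz (same filter family), segmentation into 1000-ms
epochs per rate segment, rejection over the whole epoch, then random
removal of excess epochs of the majority stimulus polarity (seeded) so
polarity counts match and the transducer artifact cancels in the average.
Base-rate responses are analysed from the 66 %-change runs only, since
they repeat across change sizes.

At the native 12 207 samples/s a 1000-ms epoch holds an integer number of
samples per second, so the Fourier transform of the averaged, 50-ms
Hann-ramped epoch already lands every pulse-rate harmonic on an exact
1-Hz bin; non-integer sample rates are resampled to ⌊fs⌋ samples first.
The 50-ms ramps cost ≈ 5 % of a full-scale component's amplitude, which
is why spectral-amplitude tests carry a 6 % tolerance.

Composite amplitude sums the spectral magnitudes at the pulse rate and
its first four harmonics. The noise floor takes, at each of those five
peaks, the mean of six bins per side — skipping the peak bin itself and
any bin belonging to another harmonic (windows shift outward on
collision, which matters at low rates where peaks are < 13 bins apart) —
and sums the five means, mirroring the composite's construction.

Phase-locking significance is a one-sample Hotelling T² on the per-epoch
(real, imaginary) pairs at the pulse-rate bin: T² = n·m̄ᵀS⁻¹m̄, p from
T²(n−2)/(2(n−1)) ~ F(2, n−2); a singular covariance is ridge-regularised
with a warning. Latency is the group delay −(dφ/df)/2π from a
least-squares fit to phases unwrapped over increasing pulse rate,
restricted to 94–640 pps; above 640 pps adjacent rate spacings reach
120 pps and the inter-rate phase step for a ~5-ms delay exceeds π, so
unwrapping is ambiguous and the result is flagged unreliable. Up to two
points with post-unwrap residual > π may be excluded automatically, each
logged — the automated replacement for manual phase exclusions.

## Synthetic data

The virtual responder is an equal-variance SDT observer. Its false-alarm
process is a linear hazard h(t) = h₀ + h₁t (defaults 0.20 s⁻¹ and
0.02 s⁻², so FA probability grows with hold time — the impatience effect
seen in real sessions and the reason the weighted P_FA exists). The
decision criterion c is set so Φ(−c) equals the mean hazard-implied FA
probability in one 600-ms catch window; hits then occur with probability
Φ(d_true − c) and hit latencies are truncated-normal (mean 250 ms, SD
100 ms) inside the window. A 2 % lapse process produces early releases.
This makes the weighted-P_FA estimator consistent by construction, which
is exactly what the recovery tests check (mean bias ≤ 0.2 at d_true ∈
{0, 1, 2} with 120-trial sessions).

The scalp simulator mixes, in microvolts: (i) background noise, 70 %
1/f-power and 30 % white at 20 µV RMS broadband — chosen to put the
in-band 2–20 Hz noise at a few µV per epoch, the regime in which real
change responses of 2–10 µV are detectable but not trivially so; (ii) a
change-response template of two Gaussians (positive 5 µV at 50 ms, σ
8 ms; negative 4 µV at 100 ms, σ 12 ms), scaled 1.0 for increasing-rate
and 0.1 for decreasing-rate changes to reproduce the strong direction
asymmetry of the real preparation; (iii) a pulse-locked component: the
stimulus pulse-time train convolved with a zero-centred Gaussian kernel
(peak 2 µV, σ 0.4 ms — sharp enough to carry energy past 3 kHz, like a
far-field brainstem unit response) delayed by the conduction latency τ
(default 5.28 ms) with gain decaying as exp(−rate/800 pps); the envelope-
locked component does not invert with stimulus polarity; (iv) an optional
transducer artifact, the same pulse-locked shape with zero delay that
*does* flip with polarity and must cancel after balancing. Both channels
share the evoked content and carry independent noise.

What the simulator does not emulate: cochlear and synaptic nonlinearity,
rate-dependent latency shifts, multi-generator phase interference (the
spectral ripple of real composite-amplitude curves), non-stationary
artifacts, or inter-subject variability. Passing tests therefore show
that the analysis recovers what the generative model injects under
realistic SNR — not that the biology behaves like the model.

## Problem sizes and numerical choices

The test suite runs everything at desk scale: recordings of 1–10 blocks
(6–60 sweeps) instead of 25, sessions of 120 trials, 200–1000 resamples.
These sizes keep the full suite under a minute of simulation per module
while leaving every statistic far from its small-sample limits; the
bookkeeping tests that need the full 25-block protocol use an all-zero
recording, since counts depend only on the event schedule. Group-delay
recovery at fixture SNR uses 3 blocks per condition and only rates whose
Hotelling test is significant, recovering an injected 5.28 ms delay
within 0.3 ms (0.1 ms noise-free).

Tie-breaks and degenerate inputs: argmax/argmin peak picking takes the
first extremum on exact ties; empirical-ROC ties contribute half;
identical epochs defeat rejection calibration and return the boundary
factor with a warning; a single-polarity epoch set is an error rather
than a silent pass-through. Bisection tolerances and iteration caps are
fixed constants in the source.
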