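"""Frequency-following response (FFR): spectra, composite amplitude,
Hotelling T² significance and group delay.

The FFR is the scalp potential phase-locked to the envelope periodicity of
the pulse train, dominated by rostral-brainstem generators.  Recordings
are zero-phase bandpass filtered at 50-3000 Hz, segmented into 1000-ms
epochs per pulse-rate segment of the alternating paradigm, screened with
the same adaptive RMS rejection as the cortical analysis, and balanced
across the two stimulus polarities so that polarity-locked transducer
artifacts cancel in the average.  The averaged epoch gets 50-ms Hann
on/off ramps and is resampled to an integer number of samples per second,
so the discrete Fourier transform yields exact 1-Hz bins with every
pulse-rate harmonic on a bin centre.

Response strength is the composite amplitude (sum of spectral magnitudes
at the pulse rate and its first four harmonics) against a 12-bin
neighbourhood noise floor; per-epoch real/imaginary components at the
pulse-rate frequency feed a one-sample Hotelling T² test; and response
latency is the group delay, -dphi/df / 2*pi, from a least-squares fit to
the phase unwrapped over pulse rate (94-640 pps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.stats import f as f_dist

from .acc import (ContinuousRecording, EpochSet, _rejection_mask,
                  _zero_phase_bandpass)

FFR_BAND_HZ = (50.0, 3000.0)
EPOCH_MS = (0.0, 1000.0)
RAMP_MS = 50.0
NOISE_BINS_PER_SIDE = 6
N_COMPOSITE_HARMONICS = 5           # pulse rate + first four harmonics
GROUP_DELAY_RATE_RANGE = (94.0, 640.0)
MAX_POLARITY_TRIM = 7               # random removals allowed for balancing
MAX_UNWRAP_EXCLUSIONS = 2


def filter_ffr(recording: ContinuousRecording,
               band: tuple[float, float] = FFR_BAND_HZ) -> ContinuousRecording:
    """50-3000 Hz zero-phase filtering; active channels averaged to one."""
    filtered = _zero_phase_bandpass(recording.channels, band,
                                    recording.sample_rate)
    merged = filtered.mean(axis=0, keepdims=True)
    return ContinuousRecording(channels=merged,
                               sample_rate=recording.sample_rate,
                               events=recording.events)


def segment_ffr(recording: ContinuousRecording,
                rejection_factor: float | None = None,
                seed: int | None = None,
                balance: bool = True) -> dict[float, EpochSet]:
    """One 1000-ms epoch per rate segment, keyed by pulse rate.

    Every sweep contributes a base-rate epoch (from ``t_base``) and a
    higher-rate epoch (from ``t_higher``); polarity labels are carried
    along.  Rejection uses the whole 0-1000 ms interval; after rejection,
    a small random selection (< 7, seeded) is removed per rate to equalise
    the polarity counts.  Which rates are analysed (e.g. base rates only
    from the 66 % runs) is decided by the caller across conditions.
    """
    x = recording.channels.mean(axis=0)
    fs = recording.sample_rate
    # exactly one second of samples, so 12207 samples at the native EEG rate
    n_samp = int(round((EPOCH_MS[1] - EPOCH_MS[0]) / 1000.0 * fs))
    by_rate: dict[float, list] = {}
    pol_by_rate: dict[float, list] = {}
    for ev in recording.events:
        for key_t, key_r, pol_sign in ((ev["t_base"], ev["base_pps"], +1),
                                       (ev["t_higher"], ev["higher_pps"], +1)):
            i = int(round(key_t * fs))
            if i < 0 or i + n_samp > x.size:
                warnings.warn("FFR epoch exceeds recording bounds; skipped",
                              stacklevel=2)
                continue
            by_rate.setdefault(key_r, []).append(x[i:i + n_samp])
            pol_by_rate.setdefault(key_r, []).append(ev.get("polarity", +1))
    rng = np.random.default_rng(seed)
    out: dict[float, EpochSet] = {}
    for rate, rows in sorted(by_rate.items()):
        epochs = np.array(rows)
        pols = np.array(pol_by_rate[rate], dtype=int)
        mask = np.ones(len(epochs), dtype=bool)
        if rejection_factor is not None:
            mask = _rejection_mask(epochs, [slice(0, n_samp)], rejection_factor)
        if balance:
            mask = _balance_polarity(mask, pols, rng)
        out[rate] = EpochSet(epochs=epochs, sample_rate=fs,
                             span_ms=EPOCH_MS, retained=mask,
                             rejection_factor=rejection_factor, polarity=pols)
    return out


def apply_screening(epoch_set: EpochSet, rejection_factor: float,
                    seed: int | None = None) -> EpochSet:
    """Re-apply noise rejection and polarity balancing to segmented epochs."""
    n_samp = epoch_set.epochs.shape[1]
    mask = _rejection_mask(epoch_set.epochs, [slice(0, n_samp)],
                           rejection_factor)
    mask = _balance_polarity(mask, epoch_set.polarity,
                             np.random.default_rng(seed))
    return EpochSet(epochs=epoch_set.epochs, sample_rate=epoch_set.sample_rate,
                    span_ms=epoch_set.span_ms, retained=mask,
                    rejection_factor=rejection_factor,
                    polarity=epoch_set.polarity)


def _balance_polarity(mask: np.ndarray, pols: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Randomly drop retained epochs of the majority polarity until counts
    match.  Errors if one polarity has no epochs at all."""
    mask = mask.copy()
    n_pos = int(np.sum(mask & (pols > 0)))
    n_neg = int(np.sum(mask & (pols < 0)))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cannot balance polarities: one polarity has no epochs")
    excess = abs(n_pos - n_neg)
    if excess == 0:
        return mask
    if excess >= MAX_POLARITY_TRIM:
        warnings.warn(
            f"polarity imbalance of {excess} exceeds the usual n < "
            f"{MAX_POLARITY_TRIM}; balancing anyway", stacklevel=3)
    major = +1 if n_pos > n_neg else -1
    candidates = np.flatnonzero(mask & (pols == major))
    drop = rng.choice(candidates, size=excess, replace=False)
    mask[drop] = False
    return mask


@dataclass
class FFRSpectrum:
    """One-sided complex amplitude spectrum on an exact 1-Hz grid.

    ``amplitude[k]`` is the peak amplitude (2|X_k|/N) of the component at
    ``k`` Hz in the averaged epoch.
    """

    complex_amplitude: np.ndarray     # 2 X_k / N, one-sided
    rate_pps: float
    df_hz: float = 1.0
    per_epoch_complex: np.ndarray | None = None   # value at rate bin, per epoch

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.complex_amplitude)

    def phase_at(self, freq_hz: float) -> float:
        return float(np.angle(self.complex_amplitude[int(round(freq_hz))]))


def _ramped(x: np.ndarray, fs: float, ramp_ms: float = RAMP_MS) -> np.ndarray:
    n_ramp = int(round(ramp_ms / 1000.0 * fs))
    w = np.ones(x.shape[-1])
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    w[:n_ramp] = ramp
    w[-n_ramp:] = ramp[::-1]
    return x * w


def spectrum(epoch_set: EpochSet, rate_pps: float,
             min_epochs: int = 30) -> FFRSpectrum:
    """Averaged-epoch spectrum with 1-Hz bins.

    Retained epochs (both polarities together, cancelling the transducer
    artifact) are averaged, 50-ms raised-cosine ramps applied, and the
    epoch resampled to an integer-second length before the FFT so the
    pulse-rate harmonics land on exact bins.  The per-epoch complex value
    at the pulse-rate bin is kept for the Hotelling test.
    """
    kept = epoch_set.kept
    if len(kept) < min_epochs:
        raise ValueError(f"need >= {min_epochs} retained epochs, have {len(kept)}")
    dur_s = (epoch_set.span_ms[1] - epoch_set.span_ms[0]) / 1000.0
    if abs(dur_s - 1.0) > 1e-6:
        raise ValueError("FFR epochs must span exactly 1000 ms")
    fs = epoch_set.sample_rate
    n_target = int(np.floor(fs))  # integer samples per second -> 1-Hz bins
    avg = kept.mean(axis=0)
    avg = _ramped(avg, fs)
    resampled = _sig.resample(avg, n_target)
    X = np.fft.rfft(resampled)
    comp = 2.0 * X / n_target
    # per-epoch complex value at the pulse-rate bin (same window + resample)
    k_rate = int(round(rate_pps))
    per_epoch = np.empty(len(kept), dtype=complex)
    t = np.arange(n_target) / n_target  # 1-second grid
    probe = np.exp(-2j * np.pi * k_rate * t)
    for i, ep in enumerate(kept):
        r = _sig.resample(_ramped(ep, fs), n_target)
        per_epoch[i] = 2.0 * np.dot(r, probe) / n_target
    return FFRSpectrum(complex_amplitude=comp, rate_pps=rate_pps,
                       per_epoch_complex=per_epoch)


def composite_amplitude(spec: FFRSpectrum) -> float:
    """Sum of spectral magnitudes at the pulse rate and its first four
    harmonics (nearest 1-Hz bins)."""
    top = (spec.complex_amplitude.size - 1) * spec.df_hz
    ks = np.arange(1, N_COMPOSITE_HARMONICS + 1) * spec.rate_pps
    if ks[-1] > top:
        raise ValueError("rate x 5 exceeds the spectrum range")
    bins = np.round(ks / spec.df_hz).astype(int)
    return float(np.sum(spec.amplitude[bins]))


def spectral_noise_floor(spec: FFRSpectrum,
                         bins_per_side: int = NOISE_BINS_PER_SIDE) -> float:
    """12-bin neighbourhood noise floor, summed over the five peaks.

    At each harmonic peak, the mean magnitude of the six bins on each side
    is taken, excluding the peak bin itself and any bin belonging to
    another harmonic peak; colliding windows are shifted outward with a
    warning.  The five per-peak means are summed, mirroring the composite.
    """
    amp = spec.amplitude
    peak_bins = set(
        int(round(k * spec.rate_pps / spec.df_hz))
        for k in range(1, N_COMPOSITE_HARMONICS + 1)
    )
    total = 0.0
    for k in range(1, N_COMPOSITE_HARMONICS + 1):
        pb = int(round(k * spec.rate_pps / spec.df_hz))
        picked: list[int] = []
        for direction in (-1, +1):
            got, step = 0, 1
            while got < bins_per_side:
                b = pb + direction * step
                step += 1
                if b <= 0 or b >= amp.size:
                    break
                if b in peak_bins:
                    if step == 2:  # immediate neighbour is a peak: shift outward
                        warnings.warn("noise window collides with another peak; "
                                      "shifted outward", stacklevel=2)
                    continue
                picked.append(b)
                got += 1
        total += float(np.mean(amp[picked]))
    return total


def hotelling_t2(per_epoch_complex: np.ndarray,
                 ridge: float = 1e-12) -> tuple[float, float]:
    """One-sample Hotelling T² on the (real, imag) pairs at one frequency.

    Tests whether the mean 2-D vector differs from the origin, i.e.
    whether there is coherent phase-locked activity above the incoherent
    background.  T² = n m' S^-1 m with the sample covariance S; the p-value
    comes from T² (n-2)/(2(n-1)) ~ F(2, n-2).  A singular covariance is
    ridge-regularised with a warning.
    """
    z = np.asarray(per_epoch_complex)
    n = z.size
    if n < 3:
        raise ValueError("Hotelling T² needs at least 3 epochs")
    xy = np.column_stack([z.real, z.imag])
    m = xy.mean(axis=0)
    S = np.cov(xy, rowvar=False, ddof=1)
    if np.linalg.cond(S) > 1e12 or not np.isfinite(np.linalg.cond(S)):
        warnings.warn("singular covariance; ridge-regularising", stacklevel=2)
        S = S + ridge * np.eye(2) * max(np.trace(S), 1.0)
    t2 = float(n * m @ np.linalg.solve(S, m))
    f_stat = t2 * (n - 2) / (2.0 * (n - 1))
    p = float(f_dist.sf(f_stat, 2, n - 2))
    return t2, max(p, np.finfo(float).tiny)


@dataclass
class FFRResult:
    """Per-rate FFR summary."""

    rate_pps: float
    composite_amp: float
    noise_floor: float
    t2: float
    p_value: float
    phase_at_rate: float
    n_epochs: int


def analyze_rate(epoch_set: EpochSet, rate_pps: float,
                 min_epochs: int = 30) -> FFRResult:
    spec = spectrum(epoch_set, rate_pps, min_epochs=min_epochs)
    t2, p = hotelling_t2(spec.per_epoch_complex)
    return FFRResult(
        rate_pps=rate_pps,
        composite_amp=composite_amplitude(spec),
        noise_floor=spectral_noise_floor(spec),
        t2=t2,
        p_value=p,
        phase_at_rate=spec.phase_at(rate_pps),
        n_epochs=int(np.sum(epoch_set.retained)),
    )


@dataclass
class GroupDelayResult:
    delay_ms: float
    rates_pps: np.ndarray
    unwrapped_phase: np.ndarray
    excluded_rates: list = field(default_factory=list)
    reliable: bool = True


def group_delay(rates_pps, phases_rad,
                rate_range: tuple[float, float] = GROUP_DELAY_RATE_RANGE,
                max_exclusions: int = MAX_UNWRAP_EXCLUSIONS) -> GroupDelayResult:
    """Group delay from the slope of phase unwrapped over pulse rate.

    Phases at rates inside ``rate_range`` (94-640 pps by default) are
    unwrapped over increasing frequency and fitted by least squares; the
    delay is -slope / 2*pi in ms.  Points whose residual exceeds pi after
    unwrapping may be excluded (at most two, each logged); adjacent rate
    spacings >= 120 pps make the unwrap ambiguous for delays of several
    ms, so the result is flagged unreliable in that case.
    """
    rates = np.asarray(rates_pps, dtype=float)
    phases = np.asarray(phases_rad, dtype=float)
    sel = (rates >= rate_range[0]) & (rates <= rate_range[1])
    rates, phases = rates[sel], phases[sel]
    order = np.argsort(rates)
    rates, phases = rates[order], phases[order]
    if rates.size < 5:
        raise ValueError("need >= 5 rates with significant FFR for a group delay")
    reliable = True
    if np.any(np.diff(rates) >= 120.0):
        warnings.warn("adjacent rate spacing >= 120 pps: unwrap may be "
                      "ambiguous; result flagged unreliable", stacklevel=2)
        reliable = False
    excluded: list[float] = []
    for _ in range(max_exclusions + 1):
        unwrapped = np.unwrap(phases)
        slope, intercept = np.polyfit(rates, unwrapped, 1)
        resid = unwrapped - (slope * rates + intercept)
        worst = int(np.argmax(np.abs(resid)))
        if np.abs(resid[worst]) <= np.pi or len(excluded) >= max_exclusions:
            break
        excluded.append(float(rates[worst]))
        warnings.warn(f"excluding rate {rates[worst]:.0f} pps from the "
                      "group-delay fit (unwrap residual > pi)", stacklevel=2)
        keep = np.ones(rates.size, dtype=bool)
        keep[worst] = False
        rates, phases = rates[keep], phases[keep]
    unwrapped = np.unwrap(phases)
    slope = np.polyfit(rates, unwrapped, 1)[0]
    delay_ms = -slope / (2.0 * np.pi) * 1000.0
    return GroupDelayResult(delay_ms=float(delay_ms), rates_pps=rates,
                            unwrapped_phase=unwrapped,
                            excluded_rates=excluded, reliable=reliable)
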