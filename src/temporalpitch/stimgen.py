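"""Synthesis of bandpass harmonic-complex pulse trains and pink-noise maskers.

The stimuli are acoustic pulse trains built by summing harmonics of a
fundamental F0, restricted to a high-frequency passband so that no
individual harmonic is resolved by the peripheral auditory system.  Pitch
is then carried purely by the envelope repetition rate ("temporal pitch"):
F0 pulses per second when all harmonics are in sine phase (SINE), or 2*F0
when odd harmonics are in sine and even harmonics in cosine phase (ALT),
which doubles the envelope rate without changing the amplitude spectrum.

Rate changes are introduced by switching between a base pulse rate and a
higher rate at the zero-amplitude midpoint between consecutive pulses, with
the higher-rate segment attenuated so that its RMS matches the base
segment.  A continuous pink-noise masker covers distortion products below
the passband.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

DEFAULT_SAMPLE_RATE = 97_656.0          # acoustic generation rate, samples/s
DEFAULT_CENTER_HZ = 8_000.0
DEFAULT_OCTAVE_FRACTION = 0.25
DEFAULT_SKIRT_SLOPE_DB_PER_OCT = 48.0
HARMONIC_WEIGHT_FLOOR_DB = -80.0        # harmonics weaker than this are dropped
MAX_HARMONICS = 8192                    # safety cap on retained components
MIN_UNRESOLVED_HARMONIC = 15            # lowest harmonic number considered unresolved
CAT_ERB_AT_LOW_CUTOFF_HZ = 975.0        # feline auditory-filter ERB at 6727.2 Hz


class InvalidParameterError(ValueError):
    """Raised when a stimulus parameter violates its precondition."""


class PhaseMode(str, enum.Enum):
    SINE = "SINE"
    ALT = "ALT"


class Paradigm(str, enum.Enum):
    HOLD_RELEASE = "HOLD_RELEASE"
    ALTERNATING = "ALTERNATING"


def band_edges(center_hz: float, octave_fraction: float) -> tuple[float, float]:
    """Passband cut-off frequencies a fixed octave fraction around ``center_hz``.

    Returns ``(low, high) = (center * 2**-f, center * 2**+f)`` rounded to
    0.1 Hz.  The default quarter-octave band around 8 kHz gives
    (6727.2, 9513.7) Hz.
    """
    if center_hz <= 0:
        raise InvalidParameterError(f"center_hz must be positive, got {center_hz}")
    if octave_fraction < 0:
        raise InvalidParameterError("octave_fraction must be >= 0")
    low = center_hz * 2.0 ** (-octave_fraction)
    high = center_hz * 2.0 ** (+octave_fraction)
    return round(low, 1), round(high, 1)


@dataclass(frozen=True)
class BandpassSpec:
    """Passband with linear-in-octaves attenuation skirts beyond the cut-offs."""

    center_hz: float = DEFAULT_CENTER_HZ
    octave_fraction: float = DEFAULT_OCTAVE_FRACTION
    skirt_slope_db_per_octave: float = DEFAULT_SKIRT_SLOPE_DB_PER_OCT

    def __post_init__(self):
        if self.center_hz <= 0:
            raise InvalidParameterError("center_hz must be positive")
        if self.skirt_slope_db_per_octave < 0:
            raise InvalidParameterError("skirt slope must be >= 0")

    @property
    def low_hz(self) -> float:
        return band_edges(self.center_hz, self.octave_fraction)[0]

    @property
    def high_hz(self) -> float:
        return band_edges(self.center_hz, self.octave_fraction)[1]


def harmonic_weight(freq_hz, spec: BandpassSpec):
    """Linear amplitude gain of the passband at ``freq_hz`` (vectorised).

    Unity inside [low, high]; outside, attenuated by ``skirt_slope`` dB per
    octave of distance from the nearer cut-off.
    """
    f = np.asarray(freq_hz, dtype=float)
    low, high = spec.low_hz, spec.high_hz
    octaves_out = np.zeros_like(f)
    below = f < low
    above = f > high
    with np.errstate(divide="ignore"):
        octaves_out[below] = np.log2(low / f[below])
    octaves_out[above] = np.log2(f[above] / high)
    gain = 10.0 ** (-spec.skirt_slope_db_per_octave * octaves_out / 20.0)
    return gain if gain.shape else float(gain)


def harmonics_per_erb(f0_hz: float, erb_hz: float = CAT_ERB_AT_LOW_CUTOFF_HZ) -> float:
    """Average number of harmonic components per auditory-filter ERB.

    For F0 = 560 Hz and the feline 975-Hz ERB at the lower passband edge
    this is ~1.7 components, a resolvability audit for SINE-phase stimuli.
    """
    if f0_hz <= 0:
        raise InvalidParameterError("f0_hz must be positive")
    return erb_hz / f0_hz


@dataclass(frozen=True)
class ComplexToneSpec:
    """One harmonic complex: F0, phase design, level, passband, sample rate."""

    f0_hz: float
    phase_mode: PhaseMode = PhaseMode.SINE
    level_db: float = -20.0             # target RMS in dB re full scale
    bandpass: BandpassSpec = field(default_factory=BandpassSpec)
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self):
        if self.f0_hz <= 0:
            raise InvalidParameterError("f0_hz must be positive")
        if self.sample_rate <= 2 * self.bandpass.high_hz:
            raise InvalidParameterError("sample_rate must exceed twice the passband top")

    @property
    def pulse_rate_pps(self) -> float:
        """Envelope pulse rate: F0 for SINE phase, 2*F0 for ALT phase."""
        return self.f0_hz * (2.0 if self.phase_mode is PhaseMode.ALT else 1.0)


def _retained_harmonics(spec: ComplexToneSpec):
    """Harmonic numbers and weights kept for synthesis.

    Truncation at the weight floor (default -80 dB) or Nyquist, whichever
    comes first.  Warns when harmonics below number 15 carry weight, since
    those may be spectrally resolved.
    """
    nyquist = spec.sample_rate / 2.0
    k_max = int(np.floor(nyquist / spec.f0_hz))
    if k_max < 1:
        raise InvalidParameterError("f0 above Nyquist")
    k = np.arange(1, k_max + 1)
    w = harmonic_weight(k * spec.f0_hz, spec.bandpass)
    floor = 10.0 ** (HARMONIC_WEIGHT_FLOOR_DB / 20.0)
    keep = w >= floor
    k, w = k[keep], w[keep]
    if k.size == 0:
        raise InvalidParameterError("no harmonics retained in the passband")
    if k.size > MAX_HARMONICS:
        raise InvalidParameterError(
            f"f0={spec.f0_hz} Hz retains {k.size} harmonics (> cap {MAX_HARMONICS})"
        )
    in_band = k[k * spec.f0_hz >= spec.bandpass.low_hz]
    lowest_in_band = int(in_band.min()) if in_band.size else int(k.min())
    if lowest_in_band < MIN_UNRESOLVED_HARMONIC:
        warnings.warn(
            f"passband contains harmonic number {lowest_in_band} < "
            f"{MIN_UNRESOLVED_HARMONIC}: components may be resolvable",
            stacklevel=3,
        )
    return k, w


def _phase_offsets(k: np.ndarray, mode: PhaseMode) -> np.ndarray:
    """Per-harmonic phase offsets: sin(x) == Im e^{ix}, cos(x) == Im e^{i(x+pi/2)}."""
    if mode is PhaseMode.SINE:
        return np.zeros_like(k, dtype=float)
    return np.where(k % 2 == 0, np.pi / 2.0, 0.0)  # ALT: even harmonics cosine


def _envelope_peak_offset(spec: ComplexToneSpec) -> float:
    """Time of the first envelope maximum, in seconds, for phase origin t=0.

    Found numerically from the analytic-signal magnitude over one pulse
    period; used to place pulse peaks at segment mid-periods so that
    segment edges fall at envelope minima.
    """
    k, w = _retained_harmonics(spec)
    ph = _phase_offsets(k, spec.phase_mode)
    period = 1.0 / spec.pulse_rate_pps
    t = np.linspace(0.0, period, 2048, endpoint=False)
    env = np.abs(
        (w * np.exp(1j * (2 * np.pi * np.outer(t, k * spec.f0_hz) + ph))).sum(axis=1)
    )
    return float(t[np.argmax(env)])


@dataclass
class StimulusWaveform:
    """Sampled pressure waveform plus the event schedule that produced it."""

    samples: np.ndarray
    sample_rate: float
    events: list = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


def synthesize_complex(
    spec: ComplexToneSpec,
    duration_s: float,
    start_phase_origin_s: float = 0.0,
) -> StimulusWaveform:
    """Additive synthesis of one harmonic complex scaled to its target RMS.

    ``start_phase_origin_s`` shifts the time argument of every harmonic,
    i.e. the waveform equals the infinite-duration complex evaluated from
    that origin; segments of a longer train are cut this way so that their
    edges land on envelope minima.
    """
    period = 1.0 / spec.pulse_rate_pps
    if duration_s < period:
        raise InvalidParameterError("duration shorter than one pulse period")
    k, w = _retained_harmonics(spec)
    ph = _phase_offsets(k, spec.phase_mode)
    n = int(round(duration_s * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate + start_phase_origin_s
    # Im(sum w e^{i(2 pi k f0 t + ph)}) = sum w sin(...), odd/even split for ALT
    x = np.zeros(n)
    for ki, wi, pi_ in zip(k, w, ph):
        x += wi * np.sin(2 * np.pi * ki * spec.f0_hz * t + pi_)
    rms = np.sqrt(np.mean(x**2))
    x *= 10.0 ** (spec.level_db / 20.0) / rms
    return StimulusWaveform(samples=x, sample_rate=spec.sample_rate)


def _aligned_segment(spec: ComplexToneSpec, n_periods: int) -> np.ndarray:
    """One rate segment spanning an integer number of pulse periods.

    The phase origin is chosen so pulse peaks sit at mid-period, hence the
    first and last samples fall at the zero-amplitude inter-pulse midpoint.
    """
    period = 1.0 / spec.pulse_rate_pps
    peak = _envelope_peak_offset(spec)
    origin = peak - 0.5 * period          # shifts the peak to t = period/2
    wf = synthesize_complex(spec, n_periods * period, start_phase_origin_s=origin)
    return wf.samples


@dataclass
class SweepEvent:
    """One base->higher sweep of a rate-change train (times in seconds)."""

    block: int
    sweep: int
    t_base: float
    t_higher: float
    base_dur: float
    higher_dur: float
    polarity: int = +1


@dataclass
class RateChangeSchedule:
    """Timing plan for a rate-change run (event times are nominal; the
    synthesizer snaps segment edges to inter-pulse midpoints)."""

    base: ComplexToneSpec
    higher: ComplexToneSpec
    paradigm: Paradigm
    events: list  # list[SweepEvent]
    total_duration_s: float
    segment_s: float = 1.0
    n_blocks: int = 25
    sweeps_per_block: int = 6
    inter_block_s: float = 2.0
    onset_jitter_sd_s: float = 1.0
    hold_s: float | None = None


def make_alternating_schedule(
    base: ComplexToneSpec,
    higher: ComplexToneSpec,
    n_blocks: int = 25,
    segment_s: float = 1.0,
    sweeps_per_block: int = 6,
    inter_block_s: float = 2.0,
    onset_jitter_sd_s: float = 1.0,
    seed: int | None = None,
) -> RateChangeSchedule:
    """Alternating-pattern run: blocks of base/higher 1-s sweeps.

    Each block holds ``sweeps_per_block`` base->higher sweeps (12 s at the
    defaults), blocks are separated by 2-s silences, block onsets carry
    Gaussian jitter (SD 1 s, clipped to the silent gap) to decorrelate
    ongoing oscillations from the epoch grid, and waveform polarity flips
    on successive sweeps to let transducer artifacts cancel in averages.
    """
    rng = np.random.default_rng(seed)
    events: list[SweepEvent] = []
    t = 0.0
    block_len = 2 * segment_s * sweeps_per_block
    for b in range(n_blocks):
        jitter = 0.0
        if b > 0:
            jitter = float(np.clip(rng.normal(0.0, onset_jitter_sd_s),
                                   -0.9 * inter_block_s, 0.9 * inter_block_s))
        onset = t + (inter_block_s + jitter if b > 0 else 0.0)
        for s in range(sweeps_per_block):
            tb = onset + 2 * segment_s * s
            events.append(
                SweepEvent(
                    block=b,
                    sweep=s,
                    t_base=tb,
                    t_higher=tb + segment_s,
                    base_dur=segment_s,
                    higher_dur=segment_s,
                    polarity=+1 if (b * sweeps_per_block + s) % 2 == 0 else -1,
                )
            )
        t = onset + block_len
    return RateChangeSchedule(
        base=base,
        higher=higher,
        paradigm=Paradigm.ALTERNATING,
        events=events,
        total_duration_s=t,
        segment_s=segment_s,
        n_blocks=n_blocks,
        sweeps_per_block=sweeps_per_block,
        inter_block_s=inter_block_s,
        onset_jitter_sd_s=onset_jitter_sd_s,
    )


def make_hold_release_schedule(
    base: ComplexToneSpec,
    higher: ComplexToneSpec,
    hold_s: float,
    post_change_s: float = 1.2,
) -> RateChangeSchedule:
    """Single-trial schedule: base rate for the hold time, then the higher
    rate until the post-change timeout."""
    ev = SweepEvent(block=0, sweep=0, t_base=0.0, t_higher=hold_s,
                    base_dur=hold_s, higher_dur=post_change_s)
    return RateChangeSchedule(
        base=base,
        higher=higher,
        paradigm=Paradigm.HOLD_RELEASE,
        events=[ev],
        total_duration_s=hold_s + post_change_s,
        hold_s=hold_s,
        n_blocks=1,
        sweeps_per_block=1,
    )


def make_rate_change_train(schedule: RateChangeSchedule) -> StimulusWaveform:
    """Render a schedule to audio with midpoint switching and RMS matching.

    Every segment spans an integer number of pulse periods (durations are
    snapped, realised switch times are written back into the returned
    events), begins/ends at the envelope minimum between pulses, and each
    higher-rate segment is rescaled so its RMS equals the base segment's.
    """
    base, higher = schedule.base, schedule.higher
    if base.sample_rate != higher.sample_rate:
        raise InvalidParameterError("base and higher must share a sample rate")
    if base.bandpass != higher.bandpass:
        raise InvalidParameterError("base and higher must share a bandpass")
    fs = base.sample_rate
    for ev in schedule.events:
        if ev.base_dur < 1.0 / base.pulse_rate_pps or ev.higher_dur < 1.0 / higher.pulse_rate_pps:
            raise InvalidParameterError("segment shorter than one pulse period")

    n_total = int(round(schedule.total_duration_s * fs))
    out = np.zeros(n_total)
    realized: list[dict] = []
    # segment prototypes are cached per (spec, n_periods)
    cache: dict[tuple, np.ndarray] = {}

    def seg(spec: ComplexToneSpec, dur: float) -> np.ndarray:
        n_per = max(1, int(round(dur * spec.pulse_rate_pps)))
        key = (id(spec), n_per)
        if key not in cache:
            cache[key] = _aligned_segment(spec, n_per)
        return cache[key]

    base_rms = None
    for ev in schedule.events:
        sb = seg(base, ev.base_dur)
        sh = seg(higher, ev.higher_dur).copy()
        if base_rms is None:
            base_rms = float(np.sqrt(np.mean(sb**2)))
        sh *= base_rms / np.sqrt(np.mean(sh**2))
        i0 = int(round(ev.t_base * fs))
        pol = ev.polarity
        nb, nh = len(sb), len(sh)
        if i0 + nb + nh > n_total:
            out = np.concatenate([out, np.zeros(i0 + nb + nh - n_total)])
            n_total = len(out)
        out[i0:i0 + nb] += pol * sb
        out[i0 + nb:i0 + nb + nh] += pol * sh
        realized.append(
            {
                "block": ev.block,
                "sweep": ev.sweep,
                "t_base": i0 / fs,
                "t_higher": (i0 + nb) / fs,
                "t_end": (i0 + nb + nh) / fs,
                "base_pps": base.pulse_rate_pps,
                "higher_pps": higher.pulse_rate_pps,
                "polarity": pol,
            }
        )
    peak = np.max(np.abs(out))
    if peak > 1.0:
        warnings.warn(f"waveform clipped at |x|={peak:.3f} > 1; rescaling", stacklevel=2)
        out /= peak
    return StimulusWaveform(samples=out, sample_rate=fs, events=realized)


@dataclass(frozen=True)
class NoiseSpec:
    """Pink masker calibration: spectrum level at 8 kHz re the pulse-train
    RMS, measured before low-pass filtering at the passband low edge."""

    spectrum_level_offset_db: float = -47.0
    lp_cutoff_hz: float = 6727.2
    reference_hz: float = 8000.0

    def __post_init__(self):
        if self.spectrum_level_offset_db >= 0:
            raise InvalidParameterError("masker offset must be negative")


def make_pink_masker(
    duration_s: float,
    sample_rate: float,
    pulse_rms_db: float,
    spec: NoiseSpec = NoiseSpec(),
    seed: int | None = None,
    lowpass: bool = True,
) -> StimulusWaveform:
    """Seeded pink (1/f-power) noise calibrated to a 1-Hz spectrum level.

    Synthesised in the frequency domain with random phases and amplitude
    proportional to f^-1/2; the level in the 1-Hz band at ``reference_hz``
    is set to ``pulse_rms_db + offset`` (default 47 dB below the pulse
    train RMS); the calibration is applied before the low-pass filter at
    the passband's low edge (``lowpass=False`` skips the filter, e.g. for
    calibration checks).
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = spectrum[-1].real
    x = np.fft.irfft(spectrum, n=n)
    # rfft(x) round-trips to `spectrum`, so the one-sided periodogram PSD is
    # S(f_k) = 2 |spectrum_k|^2 / (fs * n); set S(ref) to the target level.
    df = sample_rate / n
    i_ref = int(round(spec.reference_hz / df))
    band = slice(max(1, i_ref - 2), i_ref + 3)
    psd_ref = 2.0 * np.mean(np.abs(spectrum[band]) ** 2) / (sample_rate * n)
    target_level_db = pulse_rms_db + spec.spectrum_level_offset_db
    x *= np.sqrt(10.0 ** (target_level_db / 10.0) / psd_ref)
    if lowpass:
        sos = _sig.butter(4, spec.lp_cutoff_hz, btype="low", fs=sample_rate,
                          output="sos")
        x = _sig.sosfiltfilt(sos, x)
    return StimulusWaveform(samples=x, sample_rate=sample_rate)


def mains_clearance(
    rate_pps: float,
    mains_hz: tuple[float, ...] = (50.0, 60.0),
    n_harmonics: int = 12,
    min_sep_hz: float = 5.0,
) -> bool:
    """True iff the pulse rate clears every mains harmonic by >= min_sep.

    Rates are screened against harmonics 1..12 of the 50-Hz (Europe) and
    60-Hz (USA) domestic supplies so mains pickup cannot masquerade as a
    pulse-rate-locked response.
    """
    for m in mains_hz:
        h = np.arange(1, n_harmonics + 1) * m
        if np.min(np.abs(rate_pps - h)) < min_sep_hz:
            return False
    return True


def standard_conditions():
    """The standard and supplementary rate conditions as a DataFrame.

    Columns: table, condition, base_pps, base_f0, base_phase, change_pct,
    higher_pps, higher_f0, higher_phase.  Table "1" holds the six standard
    base rates with +36 % and +66 % changes; "2" the SINE-to-ALT /
    ALT-to-SINE spectral-control conditions; "3" the extended high rates
    with +20 % changes.
    """
    import pandas as pd

    rows = []
    t1 = [
        # base_pps, base_f0, phase, pct, higher_pps, higher_f0
        (94, 94, "SINE", 36, 128, 128), (94, 94, "SINE", 66, 156, 156),
        (188, 188, "SINE", 36, 256, 256), (188, 188, "SINE", 66, 312, 312),
        (280, 280, "SINE", 36, 380, 380), (280, 280, "SINE", 66, 464, 464),
        (376, 188, "ALT", 36, 512, 256), (376, 188, "ALT", 66, 624, 312),
        (472, 236, "ALT", 36, 640, 320), (472, 236, "ALT", 66, 784, 392),
        (560, 280, "ALT", 36, 760, 380), (560, 280, "ALT", 66, 928, 464),
    ]
    for b, bf, ph, pct, h, hf in t1:
        rows.append(("1", f"base{b}_pct{pct}", b, bf, ph, pct, h, hf, ph))
    # Table 2: phase-shift controls.  SINE-to-ALT: +100 % pulse rate, F0 fixed.
    rows.append(("2", "sine_to_alt_280", 280, 280, "SINE", 100, 560, 280, "ALT"))
    # ALT-to-SINE: 0 % rate change, F0 doubled.
    rows.append(("2", "alt_to_sine_472", 472, 236, "ALT", 0, 472, 472, "SINE"))
    rows.append(("2", "alt_to_sine_560", 560, 280, "ALT", 0, 560, 560, "SINE"))
    t3 = [(560, 280, 672, 336), (658, 329, 790, 395), (752, 376, 902, 451)]
    for b, bf, h, hf in t3:
        rows.append(("3", f"base{b}_pct20", b, bf, "ALT", 20, h, hf, "ALT"))
    return pd.DataFrame(
        rows,
        columns=[
            "table", "condition", "base_pps", "base_f0", "base_phase",
            "change_pct", "higher_pps", "higher_f0", "higher_phase",
        ],
    )


def condition_specs(condition: str, level_db: float = -20.0,
                    sample_rate: float = DEFAULT_SAMPLE_RATE):
    """Resolve a named condition to (base, higher) ComplexToneSpec pair."""
    table = standard_conditions()
    row = table[table["condition"] == condition]
    if row.empty:
        raise InvalidParameterError(f"unknown condition {condition!r}")
    r = row.iloc[0]
    base = ComplexToneSpec(f0_hz=float(r.base_f0), phase_mode=PhaseMode(r.base_phase),
                           level_db=level_db, sample_rate=sample_rate)
    higher = ComplexToneSpec(f0_hz=float(r.higher_f0), phase_mode=PhaseMode(r.higher_phase),
                             level_db=level_db, sample_rate=sample_rate)
    return base, higher
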