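"""Ground-truth generators: a virtual hold-release responder and a scalp-
recording simulator.

These stand in for the animal subjects so every analysis stage can be
exercised against known parameters.  The responder is an equal-variance
signal-detection observer with a configurable sensitivity d_true, a
false-alarm hazard that (by default) grows with elapsed hold time (the
impatience effect seen in real sessions), and latency distributions for
hits.  The recording simulator mixes 1/f-plus-white background noise, a
two-Gaussian P1/N1 change-response template at each rate change, a
pulse-locked kernel response delayed by a configurable latency tau (the
quantity the group-delay analysis should recover), and a polarity-locked
transducer artifact that must cancel when epochs of both stimulus
polarities are averaged.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, truncnorm

from . import stimgen
from .acc import EEG_SAMPLE_RATE, ContinuousRecording
from .behavior import HoldSchedule, SessionRecord, TrialRecord, score_trial


@dataclass(frozen=True)
class ResponderModel:
    """Equal-variance SDT observer for the hold-release task.

    ``fa_hazard_per_s`` is the instantaneous release rate while waiting; a
    positive ``fa_hazard_slope_per_s2`` makes false alarms more likely at
    longer hold times.  The decision criterion is fitted internally so the
    observer's hit probability Phi(d_true - c) is consistent with the FA
    probability its hazard implies in one 600-ms catch window.
    """

    d_true: float = 1.5
    hit_latency_mean_s: float = 0.25
    hit_latency_sd_s: float = 0.10
    fa_hazard_per_s: float = 0.20          # at the start of the hold
    fa_hazard_slope_per_s2: float = 0.02   # impatience: hazard grows with time
    early_lapse_rate: float = 0.02         # spontaneous very-early releases

    def hazard(self, t_s: float) -> float:
        return max(0.0, self.fa_hazard_per_s + self.fa_hazard_slope_per_s2 * t_s)

    def _window_fa_prob(self, t_start: float, width: float) -> float:
        """P(release inside [t_start, t_start+width) | survived to t_start)."""
        # linear hazard integrates in closed form
        h0 = self.hazard(t_start)
        h1 = self.hazard(t_start + width)
        return 1.0 - np.exp(-0.5 * (h0 + h1) * width)

    def criterion(self, schedule: HoldSchedule) -> float:
        """c such that Phi(-c) equals the mean FA probability over the
        catch windows of Holds 2..N."""
        c_win = schedule.criterion_s
        probs = [self._window_fa_prob(h - c_win, c_win)
                 for h in schedule.hold_times_s[1:]]
        p_fa = float(np.clip(np.mean(probs), 1e-6, 1 - 1e-6))
        return float(-norm.ppf(p_fa))


def simulate_session(
    model: ResponderModel,
    schedule: HoldSchedule = HoldSchedule(),
    n_trials: int = 120,
    seed: int | None = None,
    condition_id: str = "sim",
    session_id: str = "sim-session",
) -> SessionRecord:
    """Simulate one behavioral session of ``n_trials`` hold-release trials.

    Hold indices are sampled uniformly.  During the hold, releases arrive
    from the (possibly time-varying) hazard plus a small early-lapse
    process; a trial that survives to the change becomes a hit with
    probability Phi(d_true - c), with hit latencies drawn from a truncated
    normal inside the 600-ms window, and a miss (no release) otherwise.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 <= model.early_lapse_rate <= 1):
        raise ValueError("early_lapse_rate must be a probability")
    if model.fa_hazard_per_s < 0:
        raise ValueError("fa_hazard_per_s must be >= 0")
    rng = np.random.default_rng(seed)
    c = model.criterion(schedule)
    p_hit = float(norm.cdf(model.d_true - c))
    a = (0.0 - model.hit_latency_mean_s) / model.hit_latency_sd_s
    b = (schedule.criterion_s - model.hit_latency_mean_s) / model.hit_latency_sd_s
    trials: list[TrialRecord] = []
    for _ in range(n_trials):
        hold_idx = int(rng.integers(1, schedule.n_holds + 1))
        hold = schedule.hold_times_s[hold_idx - 1]
        release_abs: float | None = None
        if rng.random() < model.early_lapse_rate:
            release_abs = float(rng.uniform(0.2, max(0.3, hold - schedule.criterion_s)))
        else:
            # draw a hazard release time by discretising the linear hazard
            dt = 0.01
            grid = np.arange(0.0, hold, dt)
            hz = np.maximum(0.0, model.fa_hazard_per_s
                            + model.fa_hazard_slope_per_s2 * grid)
            fired = rng.random(grid.size) < hz * dt
            if fired.any():
                release_abs = float(grid[np.argmax(fired)] + 0.5 * dt)
        if release_abs is None:
            if rng.random() < p_hit:
                lat = float(truncnorm.rvs(a, b, loc=model.hit_latency_mean_s,
                                          scale=model.hit_latency_sd_s,
                                          random_state=rng))
                release_abs = hold + lat
            # else: miss, pedal held to stimulus end
        latency = None if release_abs is None else release_abs - hold
        trials.append(
            TrialRecord(
                condition_id=condition_id,
                hold_index=hold_idx,
                hold_s=hold,
                change_time_s=hold,
                release_latency_s=latency,
                score=score_trial(latency, schedule),
            )
        )
    return SessionRecord(session_id=session_id, trials=trials,
                         schedule=schedule,
                         meta={"d_true": model.d_true, "seed": seed})


@dataclass(frozen=True)
class ScalpModel:
    """Generative model of the two-channel scalp recording (microvolts).

    The change-response template is a positive Gaussian bump (P1) plus a
    negative one (N1); per-direction amplitude scales let increasing-rate
    changes evoke larger responses than decreasing ones, as observed.  The
    pulse-locked component convolves the stimulus pulse-time train with a
    zero-centred Gaussian kernel delayed by ``ffr_latency_ms`` and scaled
    by a rate-dependent gain; the transducer artifact is the same kind of
    pulse-locked term but flips sign with the stimulus polarity and
    carries no neural delay.
    """

    noise_rms_uv: float = 20.0            # broadband scalp background
    noise_pink_fraction: float = 0.7      # share of power in the 1/f component
    acc_p1_amp_uv: float = 5.0
    acc_n1_amp_uv: float = 4.0
    acc_p1_latency_ms: float = 50.0
    acc_n1_latency_ms: float = 100.0
    acc_p1_sigma_ms: float = 8.0
    acc_n1_sigma_ms: float = 12.0
    acc_gain_increase: float = 1.0
    acc_gain_decrease: float = 0.1
    ffr_gain_uv: float = 2.0              # kernel peak amplitude at rate -> 0
    ffr_latency_ms: float = 5.28
    ffr_kernel_sigma_ms: float = 0.4      # sharp, ABR-like unit response
    ffr_rate_gain_scale_pps: float = 800.0  # gain decays as exp(-rate/scale)
    artifact_amp_uv: float = 0.0

    def rate_gain(self, rate_pps: float) -> float:
        return float(self.ffr_gain_uv * np.exp(-rate_pps / self.ffr_rate_gain_scale_pps))


def _background_noise(n: int, fs: float, model: ScalpModel,
                      rng: np.random.Generator) -> np.ndarray:
    """1/f + white noise mixture scaled to the model's RMS."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** -0.5
    pink = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * shape, n=n)
    pink /= np.std(pink)
    p = model.noise_pink_fraction
    x = np.sqrt(p) * pink + np.sqrt(1 - p) * white
    return model.noise_rms_uv * x / np.std(x)


def _gaussian_bump(t: np.ndarray, mu_ms: float, sigma_ms: float) -> np.ndarray:
    mu, sg = mu_ms / 1000.0, sigma_ms / 1000.0
    return np.exp(-0.5 * ((t - mu) / sg) ** 2)


def simulate_recording(
    model: ScalpModel,
    schedule: stimgen.RateChangeSchedule,
    seed: int | None = None,
    n_channels: int = 2,
    sample_rate: float = EEG_SAMPLE_RATE,
) -> ContinuousRecording:
    """Simulate the two-channel scalp recording for an alternating run.

    Each channel receives the same evoked content plus independent
    background noise.  The returned events list matches what the analysis
    modules consume.
    """
    if schedule.paradigm is not stimgen.Paradigm.ALTERNATING:
        raise ValueError("recording simulation expects an ALTERNATING schedule")
    rng = np.random.default_rng(seed)
    fs = sample_rate
    pad_s = 0.5
    n = int(round((schedule.total_duration_s + pad_s) * fs))
    evoked = np.zeros(n)

    # change-response templates at every transition
    tmpl_span_s = 0.30
    n_tmpl = int(round(tmpl_span_s * fs))
    t_tmpl = np.arange(n_tmpl) / fs
    template = (model.acc_p1_amp_uv
                * _gaussian_bump(t_tmpl, model.acc_p1_latency_ms,
                                 model.acc_p1_sigma_ms)
                - model.acc_n1_amp_uv
                * _gaussian_bump(t_tmpl, model.acc_n1_latency_ms,
                                 model.acc_n1_sigma_ms))

    # pulse-locked kernel: zero-centred Gaussian, shifted by the neural delay
    half_w = int(round(5 * model.ffr_kernel_sigma_ms / 1000.0 * fs)) + 1
    k_t = (np.arange(-half_w, half_w + 1)) / fs * 1000.0  # ms
    kernel = np.exp(-0.5 * (k_t / model.ffr_kernel_sigma_ms) ** 2)

    def add_pulses(t0: float, dur: float, rate: float, gain: float,
                   delay_s: float, sign: float):
        n_pulses = int(round(dur * rate))
        times = t0 + (np.arange(n_pulses) + 0.5) / rate + delay_s
        idx = np.round(times * fs).astype(int)
        idx = idx[(idx >= half_w) & (idx < n - half_w - 1)]
        for i in idx:
            evoked[i - half_w:i + half_w + 1] += sign * gain * kernel

    events_out = []
    for ev in schedule.events:
        pol = ev.polarity
        # decreasing-rate change at each base onset except the block's first
        if ev.sweep > 0:
            i = int(round(ev.t_base * fs))
            evoked[i:i + n_tmpl] += model.acc_gain_decrease * template[: max(0, min(n_tmpl, n - i))]
        i = int(round(ev.t_higher * fs))
        evoked[i:i + n_tmpl] += model.acc_gain_increase * template[: max(0, min(n_tmpl, n - i))]
        # pulse-locked neural response and transducer artifact
        base_rate = schedule.base.pulse_rate_pps
        high_rate = schedule.higher.pulse_rate_pps
        tau = model.ffr_latency_ms / 1000.0
        # the envelope-locked neural response does not invert with stimulus
        # polarity; only the transducer artifact does
        add_pulses(ev.t_base, ev.base_dur, base_rate,
                   model.rate_gain(base_rate), tau, sign=+1)
        add_pulses(ev.t_higher, ev.higher_dur, high_rate,
                   model.rate_gain(high_rate), tau, sign=+1)
        if model.artifact_amp_uv:
            add_pulses(ev.t_base, ev.base_dur, base_rate,
                       model.artifact_amp_uv, 0.0, sign=pol)
            add_pulses(ev.t_higher, ev.higher_dur, high_rate,
                       model.artifact_amp_uv, 0.0, sign=pol)
        events_out.append({
            "block": ev.block, "sweep": ev.sweep,
            "t_base": ev.t_base, "t_higher": ev.t_higher,
            "base_pps": base_rate, "higher_pps": high_rate,
            "polarity": pol,
        })

    channels = np.stack([
        evoked + _background_noise(n, fs, model, rng)
        for _ in range(n_channels)
    ])
    return ContinuousRecording(channels=channels, sample_rate=fs,
                               events=events_out)


def make_fixture_suite(seed: int, out_dir: str | pathlib.Path,
                       n_blocks: int = 2, n_trials: int = 60,
                       level_db: float = -20.0) -> dict:
    """Write a deterministic, desk-scale fixture set and its manifest.

    One behavioral session (CSV) and one reduced-epoch recording
    (WAV + events JSON) per standard base x change condition; everything
    derives from ``seed`` so regeneration is byte-identical.
    """
    from . import cli_io

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = stimgen.standard_conditions()
    table = table[table["table"] == "1"]
    manifest: dict = {"seed": seed, "conditions": []}
    rng = np.random.default_rng(seed)
    for _, row in table.iterrows():
        cond = row["condition"]
        s_seed = int(rng.integers(2**31))
        r_seed = int(rng.integers(2**31))
        session = simulate_session(ResponderModel(), n_trials=n_trials,
                                   seed=s_seed, condition_id=cond,
                                   session_id=f"fix-{cond}")
        trials_path = out / f"trials_{cond}.csv"
        cli_io.write_trials_csv(trials_path, session)
        base, higher = stimgen.condition_specs(cond, level_db=level_db)
        schedule = stimgen.make_alternating_schedule(base, higher,
                                                     n_blocks=n_blocks,
                                                     seed=r_seed)
        rec = simulate_recording(ScalpModel(), schedule, seed=r_seed)
        wav_path = out / f"rec_{cond}.wav"
        ev_path = out / f"events_{cond}.json"
        cli_io.write_recording_wav(wav_path, rec)
        cli_io.write_events_json(ev_path, rec.events, rec.sample_rate)
        manifest["conditions"].append({
            "condition": cond,
            "trials": trials_path.name,
            "recording": wav_path.name,
            "events": ev_path.name,
            "session_seed": s_seed,
            "recording_seed": r_seed,
        })
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
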