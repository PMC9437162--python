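"""Scoring and signal-detection analysis of hold-release sessions.

In the hold-release task the subject presses a pedal to start a base-rate
pulse train, the rate steps up after a variable hold time (2.6, 3.2, 3.8 or
4.4 s -- spaced by exactly the 600-ms response window), and a release
within 600 ms of the change earns a reward.  Because the hold times are
spaced by the criterion window, the false-alarm window of a Hold N+1 trial
coincides in stimulus time with the hit window of a Hold N trial, so Hold
N+1 trials double as catch trials for Hold N.

Sensitivity is d' = z(P_Hit) - z(P_FA) with P_Hit pooled over Holds 1-3 and
P_FA computed per hold over Holds 2-4 then combined as a weighted mean,
weighting each hold's FA rate by the proportion of hit+miss trials in its
matched catch window (the impatience-bias correction).  Chance level is the
95th percentile of a permutation null (hold times shuffled against the
actual release times); precision is a trial bootstrap SE.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

DEFAULT_HOLD_TIMES_S = (2.6, 3.2, 3.8, 4.4)
CRITERION_S = 0.6               # response window after the rate change
POST_CHANGE_TIMEOUT_S = 1.2     # stimulus end after an unanswered change


class UndefinedRateError(ValueError):
    """A required hit/FA rate has a zero denominator."""


class Score(str, enum.Enum):
    HIT = "HIT"
    MISS = "MISS"
    FA = "FA"
    EARLY_RELEASE = "EARLY_RELEASE"


@dataclass(frozen=True)
class HoldSchedule:
    """Hold-time grid and response window of a session.

    Consecutive hold times must differ by exactly ``criterion_s``; a
    per-subject shift (e.g. +0.4 s) is allowed but the spacing is what
    makes the N+1 <-> N catch-window logic exact.
    """

    hold_times_s: tuple[float, ...] = DEFAULT_HOLD_TIMES_S
    criterion_s: float = CRITERION_S
    post_change_timeout_s: float = POST_CHANGE_TIMEOUT_S

    def __post_init__(self):
        diffs = np.diff(self.hold_times_s)
        if not np.allclose(diffs, self.criterion_s, atol=1e-9):
            raise ValueError(
                "consecutive hold times must differ by exactly the criterion window"
            )

    @property
    def n_holds(self) -> int:
        return len(self.hold_times_s)


def score_trial(release_latency_s: float | None,
                schedule: HoldSchedule = HoldSchedule()) -> Score:
    """Score one trial from the release latency relative to the rate change.

    (0, 0.6] s -> HIT; (-0.6, 0] -> FA; <= -0.6 -> EARLY_RELEASE (excluded
    from all rates); > 0.6 or no release -> MISS.  Boundaries follow the
    "600 to 0 ms before" reading: 0 belongs to FA, +600 ms to HIT.
    """
    c = schedule.criterion_s
    if release_latency_s is None or np.isnan(release_latency_s):
        return Score.MISS
    if release_latency_s <= -c:
        return Score.EARLY_RELEASE
    if release_latency_s <= 0.0:
        return Score.FA
    if release_latency_s <= c:
        return Score.HIT
    return Score.MISS


@dataclass
class TrialRecord:
    """One hold-release trial."""

    condition_id: str
    hold_index: int                   # 1-based
    hold_s: float
    change_time_s: float              # == hold_s re trial start
    release_latency_s: float | None   # re the rate change; None if held
    score: Score

    @property
    def release_time_s(self) -> float | None:
        """Absolute release time re trial start."""
        if self.release_latency_s is None:
            return None
        return self.change_time_s + self.release_latency_s


@dataclass
class SessionRecord:
    session_id: str
    trials: list = field(default_factory=list)
    schedule: HoldSchedule = field(default_factory=HoldSchedule)
    meta: dict = field(default_factory=dict)


def _count_table(hold_idx: np.ndarray, codes: np.ndarray, n_holds: int):
    """Per-hold (hit, miss, fa) counts; codes 0=HIT 1=MISS 2=FA 3=EARLY."""
    counts = np.zeros((n_holds, 3), dtype=int)
    for h in range(n_holds):
        sel = hold_idx == h + 1
        counts[h, 0] = np.sum(codes[sel] == 0)
        counts[h, 1] = np.sum(codes[sel] == 1)
        counts[h, 2] = np.sum(codes[sel] == 2)
    return counts


_CODE = {Score.HIT: 0, Score.MISS: 1, Score.FA: 2, Score.EARLY_RELEASE: 3}


def _pooled_rates_from_counts(counts: np.ndarray, alignment: str = "matched",
                              strict: bool = True):
    """Weighted hit/FA proportions from a per-hold (hit, miss, fa) table.

    ``alignment='matched'`` weights the FA rate at Hold N+1 by the hit+miss
    count at Hold N (the matched catch window); ``'same-index'`` weights it
    by the hit+miss count at the same hold.  With ``strict=False`` holds
    whose FA denominator is zero are dropped and the weights renormalised
    (used inside permutation/bootstrap resampling).
    """
    n_holds = counts.shape[0]
    hit, miss, fa = counts[:, 0], counts[:, 1], counts[:, 2]
    hm = hit + miss
    hit_denom = hm[: n_holds - 1].sum()
    if hit_denom == 0:
        if strict:
            raise UndefinedRateError("no hit/miss trials at Holds 1..N-1")
        p_hit = 0.0  # resolved by the 1/(2n) clipping rule downstream
    else:
        p_hit = hit[: n_holds - 1].sum() / hit_denom

    fa_holds = np.arange(1, n_holds)          # Holds 2..N (0-based index)
    fa_denom = (hit + miss + fa)[fa_holds]
    if alignment == "matched":
        w = hm[fa_holds - 1].astype(float)    # hit+miss at Hold N for FA at N+1
    elif alignment == "same-index":
        w = hm[fa_holds].astype(float)
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    ok = fa_denom > 0
    if not np.all(ok):
        if strict:
            bad = fa_holds[~ok] + 1
            raise UndefinedRateError(f"no scored trials at Hold(s) {list(bad)}")
        fa_holds, fa_denom, w = fa_holds[ok], fa_denom[ok], w[ok]
        if fa_holds.size == 0:
            raise UndefinedRateError("no scored trials in any FA hold")
    fa_rate = fa[fa_holds] / fa_denom
    if w.sum() == 0:
        w = np.ones_like(w)
    p_fa = float(np.average(fa_rate, weights=w))
    return float(p_hit), p_fa


def pooled_rates(trials, alignment: str = "matched", strict: bool = True,
                 n_holds: int | None = None):
    """(P_Hit, weighted P_FA) for one base-rate condition's trials.

    P_Hit is hits/(hits+misses) over Holds 1..N-1; P_FA is the per-hold FA
    proportion over Holds 2..N combined with catch-window weights.  Early
    releases never enter any denominator.
    """
    hold_idx = np.array([t.hold_index for t in trials])
    codes = np.array([_CODE[t.score] for t in trials])
    nh = n_holds or int(hold_idx.max())
    return _pooled_rates_from_counts(_count_table(hold_idx, codes, nh),
                                     alignment=alignment, strict=strict)


def dprime(p_hit: float, p_fa: float, clip_n: tuple[int, int]) -> float:
    """d' = z(P_Hit) - z(P_FA) with the 1/(2n) extreme-proportion correction.

    Proportions of exactly 0 or 1 are replaced by 1/(2n) or 1 - 1/(2n)
    (n = the relevant trial count) before the probit transform, the
    standard convention for finite-sample SDT estimates.
    """
    n_hit, n_fa = clip_n
    if n_hit <= 0 or n_fa <= 0:
        raise ValueError("clip_n counts must be positive")

    def _clip(p, n):
        if p <= 0.0:
            return 1.0 / (2 * n)
        if p >= 1.0:
            return 1.0 - 1.0 / (2 * n)
        return p

    return float(norm.ppf(_clip(p_hit, n_hit)) - norm.ppf(_clip(p_fa, n_fa)))


def _trial_arrays(trials):
    hold = np.array([t.hold_s for t in trials])
    hold_idx = np.array([t.hold_index for t in trials])
    rel = np.array(
        [np.nan if t.release_time_s is None else t.release_time_s for t in trials]
    )
    return hold, hold_idx, rel


def _score_codes(latency: np.ndarray, criterion: float) -> np.ndarray:
    """Vectorised trial scoring; NaN latency means the pedal was held."""
    codes = np.full(latency.shape, 1, dtype=int)            # MISS default
    with np.errstate(invalid="ignore"):
        codes[latency <= -criterion] = 3                     # EARLY
        codes[(latency > -criterion) & (latency <= 0)] = 2   # FA
        codes[(latency > 0) & (latency <= criterion)] = 0    # HIT
    return codes


def _dprime_from_counts(counts, alignment="matched"):
    p_hit, p_fa = _pooled_rates_from_counts(counts, alignment=alignment,
                                            strict=False)
    n_holds = counts.shape[0]
    n_hit = int(counts[: n_holds - 1, :2].sum())
    n_fa = int(counts[1:, :].sum())
    return dprime(p_hit, p_fa, (max(n_hit, 1), max(n_fa, 1)))


def condition_dprime(trials, alignment: str = "matched") -> float:
    """Weighted-P_FA d' for one condition's trials."""
    p_hit, p_fa = pooled_rates(trials, alignment=alignment)
    hold_idx = np.array([t.hold_index for t in trials])
    codes = np.array([_CODE[t.score] for t in trials])
    nh = int(hold_idx.max())
    counts = _count_table(hold_idx, codes, nh)
    n_hit = int(counts[: nh - 1, :2].sum())
    n_fa = int(counts[1:, :].sum())
    return dprime(p_hit, p_fa, (n_hit, n_fa))


def chance_level(trials, schedule: HoldSchedule = HoldSchedule(),
                 n_perm: int = 1000, percentile: float = 95.0,
                 seed: int | None = None, alignment: str = "matched",
                 return_null: bool = False):
    """Permutation chance level for d'.

    Hold times are shuffled against the subject's actual (absolute) release
    times, trials are re-scored with the same windows, and d' is recomputed
    for each of ``n_perm`` permutations; the requested percentile of that
    null distribution (typically centred near zero) is the chance level.
    """
    if len(trials) < 20:
        raise ValueError("need at least 20 trials for a permutation null")
    hold, hold_idx, rel = _trial_arrays(trials)
    if np.all(np.isnan(rel)):
        raise ValueError("degenerate session: no releases to permute against")
    rng = np.random.default_rng(seed)
    nh = schedule.n_holds
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(trials))
        h, hi = hold[perm], hold_idx[perm]
        latency = rel - h
        codes = _score_codes(latency, schedule.criterion_s)
        null[i] = _dprime_from_counts(_count_table(hi, codes, nh),
                                      alignment=alignment)
    q = float(np.percentile(null, percentile))
    return (q, null) if return_null else q


def bootstrap_se(trials, n_boot: int = 1000, seed: int | None = None,
                 alignment: str = "matched") -> float:
    """Bootstrap SE of d': resample trials with replacement, SD over resamples.

    Resamples with degenerate cells fall back to the clipping rule and the
    renormalised FA weights rather than being dropped.
    """
    if len(trials) < 20:
        raise ValueError("need at least 20 trials for a bootstrap SE")
    hold_idx = np.array([t.hold_index for t in trials])
    codes = np.array([_CODE[t.score] for t in trials])
    nh = int(hold_idx.max())
    rng = np.random.default_rng(seed)
    n = len(trials)
    vals = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[i] = _dprime_from_counts(_count_table(hold_idx[idx], codes[idx], nh),
                                      alignment=alignment)
    return float(np.std(vals))


def session_qc(session: SessionRecord, min_trials: int = 10) -> bool:
    """Session inclusion: >= 10 scored trials, pooled P_Hit > 0.5, P_FA < 0.5.

    Pooled rates here are simple proportions over all scored (non-early)
    trials of the session, combined across conditions; the bound pair
    requires d' > 0 while screening out extreme response bias.
    """
    codes = np.array([_CODE[t.score] for t in session.trials])
    scored = codes[codes != 3]
    if scored.size == 0:
        warnings.warn(f"session {session.session_id}: no scored trials",
                      stacklevel=2)
        return False
    if scored.size < min_trials:
        return False
    hits = np.sum(scored == 0)
    misses = np.sum(scored == 1)
    fas = np.sum(scored == 2)
    if hits + misses == 0:
        return False
    p_hit = hits / (hits + misses)
    p_fa = fas / scored.size
    return bool(p_hit > 0.5 and p_fa < 0.5)


@dataclass
class SDTSummary:
    """Sensitivity statistics for one base-rate x change-size condition."""

    condition_id: str
    p_hit: float
    p_fa_weighted: float
    dprime: float
    chance_dprime_95: float
    se_boot: float
    n_trials: int


def analyze_condition(trials, schedule: HoldSchedule = HoldSchedule(),
                      n_perm: int = 1000, n_boot: int = 1000,
                      seed: int | None = None,
                      alignment: str = "matched") -> SDTSummary:
    """Full per-condition summary: rates, d', permutation chance, bootstrap SE."""
    p_hit, p_fa = pooled_rates(trials, alignment=alignment)
    d = condition_dprime(trials, alignment=alignment)
    rng = np.random.default_rng(seed)
    chance = chance_level(trials, schedule, n_perm=n_perm,
                          seed=int(rng.integers(2**31)), alignment=alignment)
    se = bootstrap_se(trials, n_boot=n_boot, seed=int(rng.integers(2**31)),
                      alignment=alignment)
    return SDTSummary(
        condition_id=trials[0].condition_id if trials else "",
        p_hit=p_hit,
        p_fa_weighted=p_fa,
        dprime=d,
        chance_dprime_95=chance,
        se_boot=se,
        n_trials=len(trials),
    )
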