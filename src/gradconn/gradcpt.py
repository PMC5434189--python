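"""Gradual-onset continuous performance task (gradCPT) sequences and scoring.

The gradCPT presents round grayscale scenes that cross-fade linearly from one
to the next over 800 ms.  Participants press to frequent city scenes (90%) and
withhold to rare mountain scenes (10%).  Because stimuli never pause, a button
press must be assigned to a trial after the fact; reaction time is measured
from the start of the image transition, so an RT of 800 ms means the press
landed exactly when the image reached full coherence.

This module builds trial sequences, assigns press streams to trials with a
deterministic greedy rule, and summarizes performance into signal-detection
(d', criterion), RT-variability (CV) and attention-lapse statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "TRANSITION_MS",
    "TrialSequence",
    "PressLog",
    "TrialOutcomes",
    "PerformanceSummary",
    "build_trial_sequence",
    "coherence_at",
    "assign_presses",
    "summarize_performance",
    "check_inclusion",
]

#: Duration of one image transition (and hence one trial), in ms.
TRANSITION_MS = 800.0

#: Presses are candidates for a trial only if the RT falls in this open window (ms).
RT_WINDOW_MS = (0.0, 2 * TRANSITION_MS)

# Trial outcome labels.
CORRECT_COMMISSION = "correct_commission"
OMISSION_ERROR = "omission_error"
CORRECT_REJECTION = "correct_rejection"
COMMISSION_ERROR = "commission_error"


@dataclass(frozen=True)
class TrialSequence:
    """A timed stream of gradCPT trials.

    Attributes
    ----------
    onset_ms : array of transition-start times; trial ``n`` starts at
        ``n * 800`` ms.
    image_id : integer scene identity in 1..20 (1-10 city, 11-20 mountain);
        identical scenes never repeat on consecutive trials.
    is_target : True for mountain (withhold) trials, ~10% of trials.
    """

    onset_ms: np.ndarray
    image_id: np.ndarray
    is_target: np.ndarray

    def __post_init__(self) -> None:
        if len(self.onset_ms) == 0:
            raise ValueError("empty trial sequence")
        d = np.diff(self.onset_ms)
        if len(d) and not (np.all(d > 0) and np.allclose(d, d[0])):
            raise ValueError("onsets must be strictly increasing with constant spacing")
        if np.any(self.image_id[1:] == self.image_id[:-1]):
            raise ValueError("identical scenes must not repeat on consecutive trials")

    @property
    def n_trials(self) -> int:
        return len(self.onset_ms)

    @property
    def category(self) -> np.ndarray:
        return np.where(self.is_target, "mountain", "city")

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table (onset/duration in seconds)."""
        return pd.DataFrame(
            {
                "onset": self.onset_ms / 1000.0,
                "duration": TRANSITION_MS / 1000.0,
                "trial_type": self.category,
                "image_id": self.image_id,
            }
        )

    @classmethod
    def from_events(cls, events: pd.DataFrame) -> "TrialSequence":
        return cls(
            onset_ms=events["onset"].to_numpy(float) * 1000.0,
            image_id=events["image_id"].to_numpy(int),
            is_target=(events["trial_type"].to_numpy() == "mountain"),
        )


@dataclass(frozen=True)
class PressLog:
    """Sorted button-press timestamps (ms from run start)."""

    press_time_ms: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.press_time_ms, float)
        object.__setattr__(self, "press_time_ms", t)
        if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("press times must be non-negative and strictly increasing")

    def __len__(self) -> int:
        return len(self.press_time_ms)


@dataclass
class TrialOutcomes:
    """Per-trial press assignment and outcome labels.

    ``press_ms``/``rt_ms`` are NaN for unpressed trials; ``outcome`` holds one
    of the four outcome labels; ``unassigned_press_ms`` lists presses that no
    trial absorbed.
    """

    seq: TrialSequence
    press_ms: np.ndarray
    rt_ms: np.ndarray
    outcome: np.ndarray
    unassigned_press_ms: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_ms": self.seq.onset_ms,
                "trial_type": self.seq.category,
                "press_ms": self.press_ms,
                "rt_ms": self.rt_ms,
                "outcome": self.outcome,
            }
        )


@dataclass(frozen=True)
class PerformanceSummary:
    """Subject-level gradCPT performance metrics.

    Hit rate is 1 - commission-error rate (correctly withheld targets) and the
    false-alarm rate is the omission-error rate, following the task's
    signal-detection convention for withhold responses.
    """

    rt_mean_s: float
    rt_cv: float
    dprime: float
    criterion: float
    ce_rate: float
    oe_rate: float
    hit_rate: float
    fa_rate: float
    n_oe_lapses: int
    mean_oe_lapse_trials: float
    includes: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def build_trial_sequence(n_trials: int, target_rate: float = 0.1, seed: int = 0) -> TrialSequence:
    """Draw a random gradCPT sequence.

    Categories are i.i.d. Bernoulli(``target_rate``) mountain; the scene
    identity is uniform over the 10 images of the drawn category, excluding
    the immediately preceding trial's image.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 <= target_rate < 1:
        raise ValueError("target_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    is_target = rng.random(n_trials) < target_rate
    image_id = np.empty(n_trials, dtype=int)
    prev = -1
    for i in range(n_trials):
        pool = np.arange(11, 21) if is_target[i] else np.arange(1, 11)
        pool = pool[pool != prev]
        image_id[i] = rng.choice(pool)
        prev = image_id[i]
    onsets = np.arange(n_trials, dtype=float) * TRANSITION_MS
    return TrialSequence(onset_ms=onsets, image_id=image_id, is_target=is_target)


def coherence_at(rt_ms: float) -> float:
    """Coherence of the current image at a press ``rt_ms`` after transition onset.

    The transition is a linear cross-fade completing at 800 ms, so a press at
    720 ms sees the current image at 90% coherence and a press at or beyond
    800 ms sees it fully coherent.
    """
    if not np.isfinite(rt_ms):
        raise ValueError("rt_ms must be finite")
    if rt_ms < 0:
        raise ValueError("rt_ms must be non-negative")
    return float(np.clip(rt_ms / TRANSITION_MS, 0.0, 1.0))


def assign_presses(seq: TrialSequence, presses: PressLog) -> TrialOutcomes:
    """Assign button presses to trials with a deterministic greedy rule.

    Candidate (press, trial) pairs are those with RT = press - onset inside
    the open window (0, 1600) ms.  Pairs are processed globally in ascending
    |RT - 800| (presses nearest full coherence first); each press and each
    trial is used at most once.  Ties break toward the earlier trial, then the
    earlier press.  The result is independent of input press order.
    """
    n_trials = seq.n_trials
    n_press = len(presses)
    press_ms = np.full(n_trials, np.nan)
    rt_ms = np.full(n_trials, np.nan)

    if n_press:
        # All candidate pairs within the RT window.
        rt = presses.press_time_ms[:, None] - seq.onset_ms[None, :]  # press x trial
        ok = (rt > RT_WINDOW_MS[0]) & (rt < RT_WINDOW_MS[1])
        pi, ti = np.nonzero(ok)
        score = np.abs(rt[pi, ti] - TRANSITION_MS)
        order = np.lexsort((pi, ti, score))  # score, then earlier trial, then earlier press
        press_used = np.zeros(n_press, bool)
        trial_used = np.zeros(n_trials, bool)
        for k in order:
            p, t = pi[k], ti[k]
            if press_used[p] or trial_used[t]:
                continue
            press_used[p] = trial_used[t] = True
            press_ms[t] = presses.press_time_ms[p]
            rt_ms[t] = rt[p, t]
        unassigned = presses.press_time_ms[~press_used]
    else:
        unassigned = np.array([])

    pressed = ~np.isnan(press_ms)
    outcome = np.where(
        seq.is_target,
        np.where(pressed, COMMISSION_ERROR, CORRECT_REJECTION),
        np.where(pressed, CORRECT_COMMISSION, OMISSION_ERROR),
    )
    return TrialOutcomes(seq=seq, press_ms=press_ms, rt_ms=rt_ms, outcome=outcome,
                         unassigned_press_ms=unassigned)


def _adjust_rate(k: int, n: int) -> float:
    """Empirical rate with the 1/(2n) correction at the 0 and 1 extremes."""
    if n <= 0:
        raise ValueError("rate denominator must be positive")
    r = k / n
    if r == 0.0:
        r = 1.0 / (2 * n)
    elif r == 1.0:
        r = 1.0 - 1.0 / (2 * n)
    return r


def _oe_lapse_runs(outcomes: TrialOutcomes) -> list[int]:
    """Maximal runs of consecutive omission-error nontarget trials.

    A run is broken by a target trial (withholding there is not a lapse) or by
    any trial that received a press.
    """
    runs: list[int] = []
    cur = 0
    for is_t, out in zip(outcomes.seq.is_target, outcomes.outcome):
        if (not is_t) and out == OMISSION_ERROR:
            cur += 1
        else:
            if cur:
                runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs


def summarize_performance(outcomes: TrialOutcomes) -> PerformanceSummary:
    """Score assigned trials into d', criterion, RT mean/CV and lapse metrics.

    RT mean and CV use correct-commission trials only (sample SD, n-1
    denominator).  d' = z(HR) - z(FAR) and criterion = -(z(HR) + z(FAR))/2
    with HR = 1 - CE rate and FAR = OE rate; rates of exactly 0 or 1 are
    nudged by 1/(2n) before the normal quantile transform.
    """
    is_target = outcomes.seq.is_target
    out = outcomes.outcome
    n_target = int(is_target.sum())
    n_nontarget = int((~is_target).sum())
    if n_target == 0 or n_nontarget == 0:
        missing = "target" if n_target == 0 else "nontarget"
        raise ValueError(f"need at least one {missing} trial to score performance")

    cc_rts = outcomes.rt_ms[(out == CORRECT_COMMISSION)]
    if len(cc_rts) < 2:
        raise ValueError("need at least 2 correct commissions for RT variability")
    rt_mean_ms = float(np.mean(cc_rts))
    rt_sd_ms = float(np.std(cc_rts, ddof=1))

    n_ce = int(np.sum(out == COMMISSION_ERROR))
    n_oe = int(np.sum(out == OMISSION_ERROR))
    ce_rate = n_ce / n_target
    oe_rate = n_oe / n_nontarget
    hit = 1.0 - _adjust_rate(n_ce, n_target)
    fa = _adjust_rate(n_oe, n_nontarget)
    z_hit = norm.ppf(hit)
    z_fa = norm.ppf(fa)

    runs = _oe_lapse_runs(outcomes)
    return PerformanceSummary(
        rt_mean_s=rt_mean_ms / 1000.0,
        rt_cv=rt_sd_ms / rt_mean_ms,
        dprime=float(z_hit - z_fa),
        criterion=float(-(z_hit + z_fa) / 2.0),
        ce_rate=ce_rate,
        oe_rate=oe_rate,
        hit_rate=1.0 - ce_rate,
        fa_rate=oe_rate,
        n_oe_lapses=len(runs),
        mean_oe_lapse_trials=float(np.mean(runs)) if runs else 0.0,
        includes=check_inclusion(outcomes, outcomes.seq),
    )


def check_inclusion(outcomes: TrialOutcomes, seq: TrialSequence,
                    max_gap_s: float = 30.0) -> bool:
    """Inclusion rule: no period of 30 s or more without a response.

    With 800-ms trials a pressless period of >= 38 consecutive trials spans
    >= 30.4 s and excludes the subject; 37 trials (29.6 s) does not.
    """
    pressed = ~np.isnan(outcomes.press_ms)
    longest = 0
    cur = 0
    for p in pressed:
        cur = 0 if p else cur + 1
        longest = max(longest, cur)
    return longest * TRANSITION_MS < max_gap_s * 1000.0
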