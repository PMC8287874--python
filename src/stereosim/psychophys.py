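"""QUEST adaptive staircases and simulated observers.

The staircase maintains a Bayesian posterior over the log10 threshold of a
Weibull psychometric function and places every trial at the current
posterior-mean threshold, tracking the 82%-correct point of a 2-AFC task.
Two task variants are supported: the signal-in-noise (SNR) task, whose
intensity is the stimulus SNR in [0, 1], and the fine-feature task, whose
intensity is a disparity offset in arcsec within [0, 150].

The threshold parameter ``alpha`` is defined directly as the log10
intensity at the criterion (82% correct) point, so posterior summaries are
criterion-level thresholds without further conversion.

Simulated observers are Weibull functions with known threshold, slope,
guess and lapse rates, optionally timing out (scored incorrect).  The
module also implements the in-bore rule that converts a finished staircase
into the per-condition SNR sampling range used during scanning: the mean
+/- 1 SD of the last 30 test values, with an 80%-SNR fallback when the
staircase fails reliability checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PsychometricObserver",
    "QuestState",
    "StaircaseProtocol",
    "ThresholdEstimate",
    "StaircaseResult",
    "SamplingRange",
    "weibull_prob",
    "make_quest",
    "quest_update",
    "quest_recommend",
    "run_staircase",
    "run_session",
    "condition_thresholds",
    "derive_fmri_sampling_range",
    "sample_trial_snr",
]

CRITERION_82 = 0.82
SNR_TASK_RANGE = (1e-3, 1.0)
FEATURE_TASK_RANGE = (1e-2, 150.0)
FALLBACK_SNR = 0.8


def _criterion_shift(beta: float, gamma: float, lapse: float,
                     criterion: float) -> float:
    """Log10 distance from the Weibull scale parameter to the criterion point."""
    if not gamma < criterion < 1.0 - lapse:
        raise ValueError("criterion must lie strictly between gamma and 1 - lambda")
    return math.log10(math.log((1.0 - gamma - lapse) / (1.0 - lapse - criterion))) / beta


def weibull_prob(x_log10: np.ndarray | float, alpha_log10: np.ndarray | float,
                 beta: float = 3.5, gamma: float = 0.5, lapse: float = 0.01,
                 criterion: float = CRITERION_82) -> np.ndarray | float:
    """P(correct) of a Weibull on log10 intensity, anchored at the criterion.

    psi(x) = gamma + (1 - gamma - lambda) * (1 - exp(-10^(beta (x - T))))
    with the scale T placed so that psi(alpha) = criterion exactly.
    """
    t = np.asarray(alpha_log10, dtype=float) - _criterion_shift(beta, gamma, lapse, criterion)
    exponent = np.clip(beta * (np.asarray(x_log10, dtype=float) - t), -300, 300)
    return gamma + (1.0 - gamma - lapse) * (1.0 - np.exp(-(10.0 ** exponent)))


@dataclass
class PsychometricObserver:
    """Ground-truth Weibull observer for staircase simulation.

    ``threshold_alpha`` is the log10 intensity at the criterion point
    (log10 SNR for the SNR task, log10 arcsec for the feature task).
    """

    threshold_alpha: float
    slope_beta: float = 3.5
    guess_gamma: float = 0.5
    lapse_lambda: float = 0.01
    nonresponse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.guess_gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if not 0.0 <= self.lapse_lambda <= 0.1:
            raise ValueError("lambda must lie in [0, 0.1]")
        if self.slope_beta <= 0:
            raise ValueError("beta must be positive")

    def p_correct(self, x_log10: float, criterion: float = CRITERION_82) -> float:
        return float(weibull_prob(x_log10, self.threshold_alpha, self.slope_beta,
                                  self.guess_gamma, self.lapse_lambda, criterion))

    def respond(self, intensity: float, rng: np.random.Generator,
                criterion: float = CRITERION_82) -> str:
        if self.nonresponse_rate > 0 and rng.random() < self.nonresponse_rate:
            return "timeout"
        p = self.p_correct(math.log10(intensity), criterion)
        return "correct" if rng.random() < p else "incorrect"


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    phase: str  # practice | test
    intensity: float  # linear units (SNR or arcsec), post-clipping
    outcome: str  # correct | incorrect | timeout


@dataclass
class QuestState:
    """Posterior over candidate log10 thresholds plus trial history."""

    grid: np.ndarray
    posterior: np.ndarray
    beta: float = 3.5
    gamma: float = 0.5
    lapse: float = 0.01
    criterion: float = CRITERION_82
    intensity_range: tuple[float, float] = SNR_TASK_RANGE
    history: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        total = self.posterior.sum()
        if not math.isfinite(total) or total <= 0:
            raise ValueError("posterior must have positive finite mass")
        self.posterior = self.posterior / total
        if not self.gamma < self.criterion < 1.0 - self.lapse:
            raise ValueError("criterion outside (gamma, 1 - lambda)")

    def posterior_mean(self) -> float:
        return float(np.dot(self.grid, self.posterior))

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        cdf = np.cumsum(self.posterior)
        lo = float(self.grid[np.searchsorted(cdf, (1 - level) / 2)])
        hi = float(self.grid[min(np.searchsorted(cdf, 1 - (1 - level) / 2),
                                 self.grid.size - 1)])
        return lo, hi


@dataclass(frozen=True)
class StaircaseProtocol:
    """Trial structure of one staircase (4 practice + 60 test = 64 trials)."""

    task: str = "snr"  # snr | feature
    n_practice: int = 4
    n_test: int = 60
    initial_value: float | None = None  # linear; default 0.8 SNR or 120 arcsec
    stimulus_condition: str = "upright"
    response_window_ms: float = 3000.0

    def __post_init__(self) -> None:
        if self.task not in ("snr", "feature"):
            raise ValueError("task must be 'snr' or 'feature'")
        if self.n_practice < 0 or self.n_test < 1:
            raise ValueError("invalid trial counts")

    @property
    def n_trials(self) -> int:
        return self.n_practice + self.n_test

    @property
    def start_value(self) -> float:
        if self.initial_value is not None:
            return self.initial_value
        return 0.8 if self.task == "snr" else 120.0

    @property
    def intensity_range(self) -> tuple[float, float]:
        return SNR_TASK_RANGE if self.task == "snr" else FEATURE_TASK_RANGE


@dataclass
class ThresholdEstimate:
    """Posterior summary of one finished staircase, in linear units."""

    value: float
    ci95: tuple[float, float]
    converged: bool
    staircase_id: str = ""


@dataclass
class StaircaseResult:
    estimate: ThresholdEstimate
    history: list[TrialRecord]
    state: QuestState


def make_quest(initial_value: float, task: str = "snr",
               prior_sd: float = 2.0, n_grid: int = 201,
               beta: float = 3.5, gamma: float = 0.5, lapse: float = 0.01,
               criterion: float = CRITERION_82) -> QuestState:
    """Fresh QUEST state: Gaussian prior on log10 threshold at the start value.

    The grid spans +/- 3 prior SDs around log10(initial_value) with 201
    points, wide enough that any plausible threshold is interior.
    """
    mean = math.log10(initial_value)
    grid = np.linspace(mean - 3 * prior_sd, mean + 3 * prior_sd, n_grid)
    prior = np.exp(-0.5 * ((grid - mean) / prior_sd) ** 2)
    rng_range = SNR_TASK_RANGE if task == "snr" else FEATURE_TASK_RANGE
    return QuestState(grid=grid, posterior=prior, beta=beta, gamma=gamma,
                      lapse=lapse, criterion=criterion, intensity_range=rng_range)


def quest_update(state: QuestState, intensity: float, outcome: str,
                 phase: str = "test") -> QuestState:
    """Bayes update of the posterior after one trial.

    ``outcome`` is correct/incorrect/timeout; a timeout is scored as
    incorrect.  The likelihood of the outcome is evaluated under every
    candidate threshold, multiplied into the posterior and renormalized.
    Raises on numerical underflow (all posterior mass lost).
    """
    if not math.isfinite(intensity) or intensity <= 0:
        raise ValueError("intensity must be positive and finite")
    if outcome not in ("correct", "incorrect", "timeout"):
        raise ValueError(f"unknown outcome {outcome!r}")
    p = weibull_prob(math.log10(intensity), state.grid, state.beta,
                     state.gamma, state.lapse, state.criterion)
    like = p if outcome == "correct" else 1.0 - p
    updated = state.posterior * like
    total = updated.sum()
    if total <= 0 or not math.isfinite(total):
        raise FloatingPointError("posterior mass lost (numerical underflow)")
    state.posterior = updated / total
    state.history.append(TrialRecord(len(state.history), phase, intensity, outcome))
    return state


def quest_recommend(state: QuestState) -> float:
    """Next test intensity: the criterion point at the posterior-mean threshold.

    Because the threshold grid is parameterized at the criterion point,
    this is 10^posterior_mean, clipped to the task's physical range
    ([0, 1] for SNR; [0, 150] arcsec for the feature task).
    """
    value = 10.0 ** state.posterior_mean()
    lo, hi = state.intensity_range
    return float(min(max(value, lo), hi))


def _estimate_from_state(state: QuestState, staircase_id: str = "") -> ThresholdEstimate:
    lo, hi = state.credible_interval()
    mean = state.posterior_mean()
    converged = lo > state.grid[0] + 1e-12
    return ThresholdEstimate(value=10.0 ** mean, ci95=(10.0 ** lo, 10.0 ** hi),
                             converged=converged, staircase_id=staircase_id)


def run_staircase(observer: PsychometricObserver, protocol: StaircaseProtocol,
                  seed: int | np.random.Generator | None = None,
                  staircase_id: str = "") -> StaircaseResult:
    """Run one 64-trial adaptive staircase against a simulated observer.

    The first trial is placed at the protocol's initial value (80% SNR or
    120 arcsec); subsequent placements follow QUEST.  The posterior is
    carried over from the practice phase, so the first test value derives
    from the threshold implied by the practice trials.
    """
    rng = np.random.default_rng(seed)
    state = make_quest(protocol.start_value, protocol.task)
    for i in range(protocol.n_trials):
        phase = "practice" if i < protocol.n_practice else "test"
        intensity = protocol.start_value if i == 0 else quest_recommend(state)
        outcome = observer.respond(intensity, rng, state.criterion)
        quest_update(state, intensity, outcome, phase=phase)
    return StaircaseResult(estimate=_estimate_from_state(state, staircase_id),
                           history=list(state.history), state=state)


def run_session(observers: dict[str, PsychometricObserver], task: str = "snr",
                seed: int | np.random.Generator | None = None,
                conditions: tuple[str, ...] = ("upright", "inverted", "random"),
                identities: tuple[str, ...] = ("A", "B"),
                genders: tuple[str, ...] = ("female", "male"),
                subject: str = "sim") -> tuple[pd.DataFrame, dict[str, StaircaseResult]]:
    """Simulate one observer session: 6 runs with 2 interleaved staircases each.

    Runs are the 3 conditions x 2 stimulus identities in random order; in
    each run two staircases (one per stimulus gender) interleave in strict
    alternation, yielding 12 threshold estimates.  Returns a tidy table of
    per-staircase estimates plus the full results keyed by staircase id.
    """
    rng = np.random.default_rng(seed)
    runs = [(c, i) for c in conditions for i in identities]
    rng.shuffle(runs)
    rows = []
    results: dict[str, StaircaseResult] = {}
    schedules: dict[int, list[str]] = {}
    for run_idx, (condition, identity) in enumerate(runs):
        observer = observers[condition]
        protocol = StaircaseProtocol(task=task, stimulus_condition=condition)
        ids = [f"{subject}_{condition}_{identity}_{g}" for g in genders]
        states = {sid: make_quest(protocol.start_value, task) for sid in ids}
        trial_counter = {sid: 0 for sid in ids}
        schedule = []
        for t in range(protocol.n_trials * len(ids)):
            sid = ids[t % len(ids)]  # strict alternation
            state = states[sid]
            k = trial_counter[sid]
            phase = "practice" if k < protocol.n_practice else "test"
            intensity = protocol.start_value if k == 0 else quest_recommend(state)
            outcome = observer.respond(intensity, rng, state.criterion)
            quest_update(state, intensity, outcome, phase=phase)
            trial_counter[sid] = k + 1
            schedule.append(sid)
        schedules[run_idx] = schedule
        for sid in ids:
            res = StaircaseResult(estimate=_estimate_from_state(states[sid], sid),
                                  history=list(states[sid].history),
                                  state=states[sid])
            results[sid] = res
            rows.append({
                "subject": subject, "condition": condition, "run": run_idx,
                "identity": identity, "staircase": sid,
                "threshold": res.estimate.value,
                "converged": res.estimate.converged,
            })
    table = pd.DataFrame(rows)
    table.attrs["interleave_schedules"] = schedules
    return table, results


def condition_thresholds(table: pd.DataFrame) -> pd.Series:
    """Per-condition threshold: mean of that condition's staircase estimates."""
    return table.groupby("condition")["threshold"].mean()


@dataclass(frozen=True)
class SamplingRange:
    """SNR sampling range for scanner trials, or the 80%-SNR fallback."""

    low: float
    high: float
    fallback: bool = False


def derive_fmri_sampling_range(history: list[TrialRecord],
                               state: QuestState | None = None,
                               n_last: int = 30,
                               slope_tolerance: float = 0.005) -> SamplingRange:
    """Convert staircase history into the per-condition scanner SNR range.

    Takes the mean of the last 30 test-trial intensities and returns
    (mean - SD, mean + SD).  The staircase is deemed unreliable — mapping
    to the 80%-SNR fallback — if (a) it has not converged asymptotically
    (|OLS slope| of the last 30 test values >= ``slope_tolerance``
    intensity units/trial) or (b) its 95% credible interval reaches the
    grid floor.  Raises if fewer than 30 test trials exist.
    """
    test_vals = np.array([t.intensity for t in history if t.phase == "test"])
    if test_vals.size < n_last:
        raise ValueError(f"need >= {n_last} test trials, got {test_vals.size}")
    last = test_vals[-n_last:]
    mean = float(last.mean())
    sd = float(last.std(ddof=1))
    slope = float(np.polyfit(np.arange(n_last), last, 1)[0])
    reliable = abs(slope) < slope_tolerance
    if state is not None:
        ci_lo, _ = state.credible_interval()
        reliable = reliable and ci_lo > state.grid[0] + 1e-12
    if not reliable:
        return SamplingRange(FALLBACK_SNR, FALLBACK_SNR, fallback=True)
    return SamplingRange(mean - sd, mean + sd)


def sample_trial_snr(sampling: SamplingRange,
                     seed: int | np.random.Generator | None = None) -> float:
    """Draw the SNR for one scanner trial: uniform in-range, clipped to [0, 1]."""
    if sampling.fallback:
        return FALLBACK_SNR
    rng = np.random.default_rng(seed)
    return float(np.clip(rng.uniform(sampling.low, sampling.high), 0.0, 1.0))
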