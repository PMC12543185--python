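"""Staircase psychophysics, Weibull threshold estimation, behavioral saliency.

The behavioral task is a 2AFC localization of a salient foreground (left vs
right of fixation) at a bar luminance contrast adaptively controlled by a
3-down-1-up staircase with geometric 15% steps. Sensitivity is the reciprocal
of the contrast threshold at 80% accuracy on a fitted Weibull psychometric
function, and the behavioral saliency score contrasts sensitivity between
large (90 deg) and small (15 deg) orientation-contrast foregrounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .exceptions import FitFailureError, InvalidArgumentError

__all__ = [
    "ObserverModel",
    "Trial",
    "StaircaseRecord",
    "Staircase",
    "PsychometricFit",
    "BehavioralSaliency",
    "WeibullPsychometric",
    "michelson_contrast",
    "staircase_step",
    "run_staircase_session",
    "fit_weibull",
    "behavioral_saliency",
]

#: Printed starting contrast of the staircase (configurable; close to the
#: Michelson contrast of the 78.9 / 43.8 cd/m^2 luminance pair).
DEFAULT_START_CONTRAST = 0.2863


def michelson_contrast(l_bar: float, l0: float) -> float:
    """Michelson contrast (l_bar - l0) / (l_bar + l0) of bars vs background.

    Bars darker than the background are not modeled; ``l_bar >= l0 > 0``.
    """
    if l_bar <= 0 or l0 <= 0:
        raise InvalidArgumentError("luminances must be positive")
    if l_bar < l0:
        raise InvalidArgumentError("bar luminance below background is not modeled")
    return (l_bar - l0) / (l_bar + l0)


@dataclass(frozen=True)
class ObserverModel:
    """Weibull observer: p(correct|C) = gamma + (1-gamma-lambda)(1-exp(-(C/alpha)^beta))."""

    alpha: float
    beta: float
    gamma: float = 0.5     # 2AFC guess rate
    lapse: float = 0.01

    def __post_init__(self):
        if not (0.0 <= self.gamma < 1.0 - self.lapse <= 1.0):
            raise InvalidArgumentError("require 0 <= gamma < 1 - lapse <= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidArgumentError("alpha and beta must be positive")

    def p_correct(self, contrast):
        c = np.asarray(contrast, dtype=float)
        return self.gamma + (1.0 - self.gamma - self.lapse) * (
            1.0 - np.exp(-np.power(c / self.alpha, self.beta)))

    def threshold(self, p: float) -> float:
        """Contrast at which the true function reaches accuracy ``p``."""
        span = 1.0 - self.gamma - self.lapse
        q = (p - self.gamma) / span
        if not (0.0 < q < 1.0):
            raise InvalidArgumentError("requested accuracy outside the attainable range")
        return self.alpha * (-math.log(1.0 - q)) ** (1.0 / self.beta)


class Trial(NamedTuple):
    index: int
    contrast: float
    correct: bool
    reversal: bool


@dataclass
class StaircaseRecord:
    """Trial-by-trial record of one adaptive staircase."""

    trials: list = field(default_factory=list)
    condition: float | None = None
    rule: str = "3-down-1-up"

    @property
    def contrasts(self) -> np.ndarray:
        return np.array([t.contrast for t in self.trials])

    @property
    def responses(self) -> np.ndarray:
        return np.array([t.correct for t in self.trials], dtype=bool)

    def reversal_contrasts(self) -> np.ndarray:
        return np.array([t.contrast for t in self.trials if t.reversal])


def staircase_step(
    contrast: float,
    correct: bool,
    n_consecutive_correct: int,
    step_fraction: float = 0.15,
    rule_down: int = 3,
    rule_up: int = 1,
) -> tuple:
    """One transition of the m-down-1-up staircase.

    After ``rule_down`` consecutive correct responses the contrast is divided
    by (1 + step_fraction) and the counter resets; after ``rule_up``
    consecutive errors (default: any error) it is multiplied by
    (1 + step_fraction). Contrast is clipped to (0, 1].

    Returns ``(next_contrast, next_counter)``.
    """
    if not (0.0 < step_fraction < 1.0):
        raise InvalidArgumentError("step_fraction must lie in (0, 1)")
    if rule_down < 1 or rule_up < 1:
        raise InvalidArgumentError("rules must be >= 1")
    factor = 1.0 + step_fraction
    if correct:
        counter = n_consecutive_correct + 1
        if counter >= rule_down:
            return min(1.0, contrast / factor), 0
        return contrast, counter
    return min(1.0, contrast * factor), 0


class Staircase:
    """Stateful 3-down-1-up staircase driving a contrast sequence."""

    def __init__(self, start_contrast: float = DEFAULT_START_CONTRAST,
                 step_fraction: float = 0.15, rule_down: int = 3,
                 rule_up: int = 1, condition: float | None = None):
        if not (0.0 < start_contrast <= 1.0):
            raise InvalidArgumentError("start contrast must lie in (0, 1]")
        self.contrast = start_contrast
        self.step_fraction = step_fraction
        self.rule_down = rule_down
        self.rule_up = rule_up
        self.counter = 0
        self._last_direction = 0
        self.record = StaircaseRecord(condition=condition,
                                      rule=f"{rule_down}-down-{rule_up}-up")

    def update(self, correct: bool) -> float:
        """Record a response at the current contrast; return the next contrast."""
        prev = self.contrast
        self.contrast, self.counter = staircase_step(
            self.contrast, correct, self.counter,
            self.step_fraction, self.rule_down, self.rule_up)
        direction = int(np.sign(self.contrast - prev))
        reversal = direction != 0 and self._last_direction != 0 and \
            direction != self._last_direction
        if direction != 0:
            self._last_direction = direction
        self.record.trials.append(
            Trial(len(self.record.trials), prev, bool(correct), reversal))
        return self.contrast


def run_staircase_session(
    observer: ObserverModel,
    n_staircases: int = 4,
    trials_each: int = 60,
    seed: int = 0,
    start_contrast: float = DEFAULT_START_CONTRAST,
    condition: float | None = None,
    staircases_per_block: int = 2,
) -> list:
    """Simulate one condition's staircase session for a Weibull observer.

    Staircases are grouped into blocks of ``staircases_per_block`` whose
    trials are randomly intermixed (as when two independent staircases share a
    trial block); responses are Bernoulli draws from the observer's
    psychometric function at the presented contrast. Deterministic given
    ``seed``.
    """
    if trials_each < 10:
        raise InvalidArgumentError("trials_each must be >= 10")
    if n_staircases < 1:
        raise InvalidArgumentError("need at least one staircase")
    rng = np.random.default_rng(seed)
    stairs = [Staircase(start_contrast, condition=condition)
              for _ in range(n_staircases)]
    for block_start in range(0, n_staircases, staircases_per_block):
        block = stairs[block_start:block_start + staircases_per_block]
        order = np.repeat(np.arange(len(block)), trials_each)
        rng.shuffle(order)
        for j in order:
            sc = block[j]
            p = observer.p_correct(sc.contrast)
            sc.update(bool(rng.random() < p))
    return [sc.record for sc in stairs]


class WeibullPsychometric(BaseEstimator):
    """Maximum-likelihood Weibull psychometric function with fixed asymptotes.

    Estimates the scale ``alpha`` and slope ``beta`` of
    ``p(C) = gamma + (1 - gamma - lapse) * (1 - exp(-(C/alpha)**beta))``
    from Bernoulli trial outcomes, with the guess rate ``gamma`` (0.5 for
    2AFC) and lapse rate fixed. The likelihood is maximized over
    (log alpha, log beta) from ``n_starts`` starting points to avoid local
    optima.

    Parameters
    ----------
    gamma : float, guess rate (lower asymptote).
    lapse : float, lapse rate (1 - upper asymptote).
    threshold_accuracy : float, raw accuracy defining the threshold contrast.
    n_starts : int, number of multi-start optimizations.

    Attributes
    ----------
    alpha_, beta_ : fitted Weibull parameters.
    c_threshold_ : contrast at ``threshold_accuracy`` on the fitted curve.
    sensitivity_ : 1 / c_threshold_.
    nll_ : negative log-likelihood at the optimum.
    """

    def __init__(self, gamma: float = 0.5, lapse: float = 0.01,
                 threshold_accuracy: float = 0.8, n_starts: int = 5):
        self.gamma = gamma
        self.lapse = lapse
        self.threshold_accuracy = threshold_accuracy
        self.n_starts = n_starts

    def _curve(self, c, alpha, beta):
        return self.gamma + (1.0 - self.gamma - self.lapse) * (
            1.0 - np.exp(-np.power(np.asarray(c, float) / alpha, beta)))

    def fit(self, C, y):
        C = np.asarray(C, dtype=float)
        y = np.asarray(y, dtype=float)
        if C.ndim != 1 or C.shape != y.shape:
            raise InvalidArgumentError("C and y must be 1-D and aligned")
        if (C <= 0).any():
            raise InvalidArgumentError("contrasts must be positive")
        if np.unique(C).size < 2:
            raise FitFailureError("need at least 2 distinct contrast levels")
        if y.min() == y.max():
            raise FitFailureError("responses are all identical; threshold unidentifiable")
        span = 1.0 - self.gamma - self.lapse
        if not (self.gamma < self.threshold_accuracy < 1.0 - self.lapse):
            raise InvalidArgumentError("threshold accuracy outside attainable range")

        def nll(params):
            la, lb = params
            p = self._curve(C, math.exp(la), math.exp(lb))
            p = np.clip(p, 1e-9, 1.0 - 1e-9)
            return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum()

        qs = np.quantile(C, np.linspace(0.2, 0.8, self.n_starts))
        betas0 = np.resize([3.0, 1.5, 5.0, 1.0, 8.0], self.n_starts)
        best = None
        for a0, b0 in zip(qs, betas0):
            res = minimize(nll, x0=[math.log(a0), math.log(b0)],
                           method="Nelder-Mead",
                           options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        self.alpha_ = math.exp(best.x[0])
        self.beta_ = math.exp(best.x[1])
        self.nll_ = float(best.fun)
        q = (self.threshold_accuracy - self.gamma) / span
        self.c_threshold_ = self.alpha_ * (-math.log(1.0 - q)) ** (1.0 / self.beta_)
        self.sensitivity_ = 1.0 / self.c_threshold_
        self.n_trials_ = int(C.size)
        return self

    def predict(self, C):
        return self._curve(C, self.alpha_, self.beta_)


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted Weibull summary: threshold at 80% accuracy and sensitivity 1/C."""

    alpha_hat: float
    beta_hat: float
    gamma: float
    lapse: float
    c_threshold: float
    sensitivity: float
    nll: float
    n_trials: int

    def predict(self, contrast):
        c = np.asarray(contrast, dtype=float)
        return self.gamma + (1.0 - self.gamma - self.lapse) * (
            1.0 - np.exp(-np.power(c / self.alpha_hat, self.beta_hat)))


def fit_weibull(records: Sequence[StaircaseRecord], gamma: float = 0.5,
                lapse: float = 0.01, threshold_accuracy: float = 0.8) -> PsychometricFit:
    """Pool trials across staircases and fit the Weibull psychometric curve."""
    C = np.concatenate([r.contrasts for r in records])
    y = np.concatenate([r.responses for r in records]).astype(float)
    est = WeibullPsychometric(gamma=gamma, lapse=lapse,
                              threshold_accuracy=threshold_accuracy).fit(C, y)
    return PsychometricFit(est.alpha_, est.beta_, gamma, lapse,
                           est.c_threshold_, est.sensitivity_, est.nll_,
                           est.n_trials_)


@dataclass(frozen=True)
class BehavioralSaliency:
    """Sensitivities to the 90 and 15 degree foregrounds and their normalized difference."""

    s90: float
    s15: float
    ss_behavior: float


def behavioral_saliency(s90: float, s15: float) -> BehavioralSaliency:
    """SS_behavior = (S90 - S15) / mean(S90, S15); antisymmetric, in [-2, 2]."""
    if s90 <= 0 or s15 <= 0:
        raise InvalidArgumentError("sensitivities must be positive")
    ss = (s90 - s15) / ((s90 + s15) / 2.0)
    return BehavioralSaliency(s90, s15, ss)
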