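"""Seedable synthetic ICU-style cohorts for the forecasting analysis.

Real bedside data of the kind this analysis targets (dense multivariate
monitoring with a rare binary failure state) sits behind credentialed
access, so the package ships a simulator with the same statistical
structure:

* a two-state Markov chain per individual for the 0/1 failure state, with
  per-step onset probability ``p_onset`` and recovery probability
  ``p_recover`` (``p_onset < p_recover`` makes failure the rare state; the
  stationary failure fraction is ``p_onset / (p_onset + p_recover)``);
* ``k_vars`` monitored variables drawn from state-conditional unit-variance
  Gaussians whose means differ by ``effect_size`` standard deviations
  between states, with alternating signs so some variables run high and
  some low during failure (as vitals do);
* a linear pre-onset *drift*: during the ``drift_lead`` grid steps before
  each 0 -> 1 transition the variable means ramp linearly toward their
  failure-state direction, reaching ``drift_size`` standard deviations just
  before onset (with the default ``drift_size == effect_size`` the ramp
  lands exactly on the failure-state mean — a smooth deterioration).  This
  is the mechanism that makes upcoming transitions predictable before they
  happen;
* baseline covariates (sex, age, weight, height) that multiplicatively
  modulate an individual's signal strength, giving the subgroup analysis
  something real to detect;
* the last variable is binarized by thresholding its latent Gaussian,
  mimicking a drug-presence indicator.

All randomness derives from ``SimConfig.seed`` through per-individual
``SeedSequence`` substreams, so a cohort is byte-reproducible and each
individual is reproducible on its own.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .errors import ConfigurationError

_AGE_LOW, _AGE_HIGH = 18.0, 90.0
_AGE_MEAN = (_AGE_LOW + _AGE_HIGH) / 2.0
_AGE_SD = (_AGE_HIGH - _AGE_LOW) / math.sqrt(12.0)  # sd of Uniform[18, 90]


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults define the package's study conditions.

    ``t_min``/``t_max`` bound the per-individual series length T_n (drawn
    uniformly).  The transition rates give a stationary failure prevalence
    of ~0.21 with mean episode length 1/p_recover ~ 33 grid steps, so a
    failure episode outlasts the largest forecasting horizon (20 steps) —
    the persistence that makes long-horizon forecasting possible at all.
    ``drift_lead`` (25 steps) likewise exceeds the largest gap so that
    onset precursors are visible at every horizon.
    """

    n_individuals: int = 100
    t_min: int = 150
    t_max: int = 400
    k_vars: int = 18
    p_onset: float = 0.008
    p_recover: float = 0.03
    drift_lead: int = 25
    effect_size: float = 2.0
    drift_size: float = 2.0
    baseline_effect: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_individuals, (int, np.integer)) or self.n_individuals < 0:
            raise ConfigurationError("n_individuals must be a non-negative integer")
        if self.t_min < 50:
            raise ConfigurationError("t_min must be >= 50")
        if self.t_max < self.t_min:
            raise ConfigurationError("t_max must be >= t_min")
        if self.k_vars < 2:
            raise ConfigurationError("k_vars must be >= 2")
        # p_onset = 0 is permitted as a degenerate no-onset chain
        if not (0.0 <= self.p_onset < 1.0):
            raise ConfigurationError("p_onset must lie in [0, 1)")
        if not (0.0 < self.p_recover < 1.0):
            raise ConfigurationError("p_recover must lie in (0, 1)")
        if self.p_onset >= self.p_recover:
            raise ConfigurationError(
                "p_onset must be < p_recover (failure must be the rare state)"
            )
        if self.drift_lead < 1:
            raise ConfigurationError("drift_lead must be >= 1")
        if self.effect_size < 0 or self.drift_size < 0:
            raise ConfigurationError("effect_size and drift_size must be >= 0")
        if not math.isfinite(self.baseline_effect):
            raise ConfigurationError("baseline_effect must be finite")


@dataclasses.dataclass(frozen=True)
class BaselineRecord:
    sex: str  # "male" | "female"
    age: float  # years
    weight: float  # kg
    height: float  # cm


@dataclasses.dataclass
class IndividualRecord:
    id: str
    monitors: np.ndarray  # (T_n, k_vars) float; last column binary
    states: np.ndarray  # (T_n,) int in {0, 1}
    baseline: BaselineRecord

    @property
    def t_n(self) -> int:
        return self.states.size


def stationary_failure_fraction(cfg: SimConfig) -> float:
    """Long-run fraction of time in state 1 for the two-state chain."""
    denom = cfg.p_onset + cfg.p_recover
    return cfg.p_onset / denom if denom > 0 else 0.0


def _effect_multiplier(cfg: SimConfig, baseline: BaselineRecord) -> float:
    # age and sex scale the individual's signal strength (subgroup signal)
    z_age = (baseline.age - _AGE_MEAN) / _AGE_SD
    mult = (1.0 + cfg.baseline_effect * z_age) * (
        1.0 + 0.5 * cfg.baseline_effect * (baseline.sex == "male")
    )
    return max(mult, 0.0)


def _variable_directions(k: int) -> np.ndarray:
    d = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    d[-1] = 1.0  # drug-presence latent: usage rises during failure
    return d


def _simulate_states(cfg: SimConfig, rng: np.random.Generator, t_n: int) -> np.ndarray:
    states = np.empty(t_n, dtype=np.int64)
    states[0] = 1 if rng.random() < stationary_failure_fraction(cfg) else 0
    u = rng.random(t_n - 1)
    for i in range(1, t_n):
        if states[i - 1] == 0:
            states[i] = 1 if u[i - 1] < cfg.p_onset else 0
        else:
            states[i] = 0 if u[i - 1] < cfg.p_recover else 1
    return states


def _apply_drift(mu: np.ndarray, states: np.ndarray, cfg: SimConfig, shift: np.ndarray) -> None:
    """Ramp means linearly over the state-0 steps preceding each onset.

    ``shift`` is the per-variable mean displacement reached at the step just
    before onset.  The ramp stops early at any state-1 step so a previous
    failure episode is never overwritten.
    """
    onsets = np.flatnonzero((states[1:] == 1) & (states[:-1] == 0)) + 1
    lead = cfg.drift_lead
    for tau in onsets:
        for back in range(1, lead + 1):
            t = tau - back
            if t < 0 or states[t] == 1:
                break
            mu[t] += shift * (lead - back + 1) / lead


def simulate_individual(
    cfg: SimConfig,
    baseline: BaselineRecord,
    rng: np.random.Generator,
    ident: str = "P0000",
) -> IndividualRecord:
    """Simulate one individual's state sequence and monitored matrix."""
    cfg.validate()
    t_n = int(rng.integers(cfg.t_min, cfg.t_max + 1))
    states = _simulate_states(cfg, rng, t_n)

    mult = _effect_multiplier(cfg, baseline)
    directions = _variable_directions(cfg.k_vars)
    mu = np.zeros((t_n, cfg.k_vars))
    mu[states == 1] = cfg.effect_size * mult * directions
    if cfg.drift_size > 0:
        _apply_drift(mu, states, cfg, cfg.drift_size * mult * directions)

    monitors = mu + rng.standard_normal((t_n, cfg.k_vars))
    monitors[:, -1] = (monitors[:, -1] > 0.5).astype(float)  # drug indicator
    return IndividualRecord(id=ident, monitors=monitors, states=states, baseline=baseline)


def _draw_baseline(rng: np.random.Generator) -> BaselineRecord:
    sex = "male" if rng.random() < 0.5 else "female"
    age = float(rng.uniform(_AGE_LOW, _AGE_HIGH))
    weight = float(rng.normal(75.0, 15.0))
    while weight <= 30.0:  # truncate implausibly low body weights
        weight = float(rng.normal(75.0, 15.0))
    height = float(rng.normal(170.0, 10.0))
    return BaselineRecord(sex=sex, age=age, weight=weight, height=height)


def simulate_cohort(cfg: SimConfig) -> list[IndividualRecord]:
    """Simulate ``cfg.n_individuals`` records from independent substreams."""
    cfg.validate()
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_individuals)
    cohort = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        baseline = _draw_baseline(rng)
        cohort.append(simulate_individual(cfg, baseline, rng, ident=f"P{i:04d}"))
    return cohort
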