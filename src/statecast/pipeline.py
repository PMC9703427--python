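"""Gap-ahead supervised forecasting of the failure state, per individual.

For individual n with monitored matrix M (T_n x K) and state sequence s,
the model forecasts ``gap`` grid steps ahead: features at time t predict the
response at time t + gap.  Two response modes exist:

* ``original``    — the raw binary state ``s_{t+gap}``;
* ``transformed`` — the 4-class transition code ``s*_{t+gap}`` (see
  :mod:`statecast.transitions`), whose predictions are decoded back to 0/1
  before evaluation so both modes are scored on the same scale.

Each individual gets its own model, trained on the chronologically first
``train_fraction`` of its supervised pairs and evaluated on the remainder
(no shuffling, no leakage: a feature row uses only the time-t monitored
values).  The transformed response has one fewer usable target (the final
transition is undefined), so for paired method comparison the final target
index is dropped from the *original* mode as well; both modes then share
identical test target times.

Classifier backends are interchangeable behind one contract: deterministic
given a seed, class-probability output, and tolerance of training sets that
miss some of the four transition classes (absent classes get probability 0).
Defaults: multinomial logistic regression (no penalty, 1000 iterations),
AdaBoost with 100 stumps (SAMME), and XGBoost with 100 trees of depth 6 at
learning rate 0.3.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from . import transitions
from .errors import (
    BackendError,
    ConfigurationError,
    DataError,
    DegenerateTrainingError,
    ExperimentError,
    LengthError,
    SplitError,
)
from .metrics import evaluate_predictions
from .synthetic import IndividualRecord

logger = logging.getLogger(__name__)

MODELS = ("logistic", "adaboost", "xgboost")
MODES = ("original", "transformed")
DEFAULT_GAPS = (1, 5, 10, 20)
METRIC_NAMES = ("auc", "f1", "sensitivity", "specificity", "precision")


@dataclasses.dataclass(frozen=True)
class ForecastConfig:
    gap: int
    mode: str
    model: str
    train_fraction: float = 0.7
    backend_settings: Mapping | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap < 1:
            raise ConfigurationError("gap must be >= 1")
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.model not in MODELS:
            raise ConfigurationError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError("train_fraction must lie in (0, 1)")


@dataclasses.dataclass
class SupervisedPairs:
    features: np.ndarray  # (n, K)
    targets: np.ndarray  # (n,) {0,1} original / {0..3} transformed
    target_times: np.ndarray  # (n,) absolute 0-based target indices

    @property
    def n(self) -> int:
        return self.targets.size


@dataclasses.dataclass
class PredictionResult:
    target_times: np.ndarray
    true_states: np.ndarray
    pred_states: np.ndarray
    scores: np.ndarray
    individual_id: str | None = None
    config: ForecastConfig | None = None


@dataclasses.dataclass
class ExperimentResult:
    metrics: pd.DataFrame
    predictions: pd.DataFrame | None
    skipped: list  # (individual_id, config, reason)


def make_supervised(
    individual: IndividualRecord, gap: int, mode: str, drop_last: bool = False
) -> SupervisedPairs:
    """Lag features against gap-ahead targets for one individual.

    Original mode yields ``T_n - gap`` pairs (targets ``s_{gap+1..T_n}``);
    transformed mode yields ``T_n - gap - 1`` (the final transition needs an
    unobserved successor).  ``drop_last`` removes the final pair, used to
    align the original mode's target times with the transformed mode's.
    """
    t_n = individual.t_n
    if t_n <= gap + 1:
        raise LengthError(
            f"individual {individual.id}: length {t_n} too short for gap {gap}"
        )
    if mode == "original":
        n = t_n - gap
        targets = individual.states[gap:].astype(np.int64)
    elif mode == "transformed":
        n = t_n - gap - 1
        codes = transitions.encode_transitions(individual.states)
        targets = codes[gap : gap + n]
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    features = individual.monitors[:n]
    times = np.arange(gap, gap + n)
    if drop_last:
        features, targets, times = features[:-1], targets[:-1], times[:-1]
    return SupervisedPairs(features=features, targets=targets, target_times=times)


def chronological_split(
    pairs: SupervisedPairs, train_fraction: float
) -> tuple[SupervisedPairs, SupervisedPairs]:
    """First floor(train_fraction * n) pairs train, remainder test."""
    if pairs.n == 0:
        raise SplitError("cannot split empty supervised pairs")
    n_train = math.floor(train_fraction * pairs.n)
    if n_train < 1 or n_train >= pairs.n:
        raise SplitError(
            f"split of {pairs.n} pairs at fraction {train_fraction} leaves an empty side"
        )

    def _take(sl: slice) -> SupervisedPairs:
        return SupervisedPairs(
            features=pairs.features[sl],
            targets=pairs.targets[sl],
            target_times=pairs.target_times[sl],
        )

    return _take(slice(0, n_train)), _take(slice(n_train, pairs.n))


# ---------------------------------------------------------------------------
# cohort filtering


def _removal_reason(states: np.ndarray, train_fraction: float, gap: int) -> str | None:
    if len(np.unique(states)) < 2:
        return "single_state_sequence"
    t_n = states.size
    n_pairs = t_n - gap - 1  # comparable pair count shared by both modes
    if n_pairs < 2:
        return "too_short"
    n_train = math.floor(train_fraction * n_pairs)
    if n_train < 1 or n_train >= n_pairs:
        return "degenerate_split"
    if len(np.unique(states[gap : gap + n_train])) < 2:
        return "single_state_training"
    codes = transitions.encode_transitions(states)
    if len(np.unique(codes[gap : gap + n_train])) < 2:
        return "single_class_transition_training"
    return None


def filter_cohort(
    cohort: Sequence[IndividualRecord],
    train_fraction: float = 0.7,
    gap: int | Sequence[int] = 1,
) -> tuple[list[IndividualRecord], list[tuple[str, str]]]:
    """Drop individuals that cannot support both response modes.

    An individual is kept only if, for every requested gap, its whole state
    sequence contains both states and the chronological training portion of
    its supervised targets contains at least two distinct classes in *both*
    modes.  Returns the retained records and ``(id, reason)`` removals.
    """
    if not cohort:
        raise DataError("cannot filter an empty cohort")
    gaps = [gap] if isinstance(gap, (int, np.integer)) else list(gap)
    kept: list[IndividualRecord] = []
    removed: list[tuple[str, str]] = []
    for rec in cohort:
        reason = None
        for g in gaps:
            reason = _removal_reason(rec.states, train_fraction, int(g))
            if reason is not None:
                reason = f"{reason} (gap={g})"
                break
        if reason is None:
            kept.append(rec)
        else:
            removed.append((rec.id, reason))
    if not kept:
        raise DataError("no individuals remain after single-state filtering")
    return kept, removed


# ---------------------------------------------------------------------------
# classifier backends


def _make_backend(model: str, settings: Mapping | None, seed: int):
    settings = dict(settings or {})
    if model == "logistic":
        # C=inf: unpenalized (ridge-free) maximum-likelihood fit
        kwargs = dict(C=np.inf, max_iter=1000, solver="lbfgs")
        kwargs.update(settings)
        # standardization is internal to the backend; it stabilizes lbfgs
        return make_pipeline(StandardScaler(), LogisticRegression(**kwargs))
    if model == "adaboost":
        kwargs = dict(n_estimators=100, random_state=seed)
        kwargs.update(settings)
        return AdaBoostClassifier(**kwargs)
    if model == "xgboost":
        kwargs = dict(
            n_estimators=100,
            max_depth=6,
            learning_rate=0.3,
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
        kwargs.update(settings)
        return XGBClassifier(**kwargs)
    raise ConfigurationError(f"unknown model {model!r}")


def _derive_seed(root_seed: int, individual_id: str, model: str, gap: int, mode: str) -> int:
    """Stable per-(individual, cell) substream seed below 2**31."""
    tag = zlib.crc32(f"{individual_id}|{model}|{gap}|{mode}".encode())
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def fit_and_predict(
    train: SupervisedPairs,
    test: SupervisedPairs,
    model: str,
    mode: str,
    backend_settings: Mapping | None = None,
    seed: int = 0,
    convention: str = "current",
) -> PredictionResult:
    """Fit one backend on the training pairs and predict the test pairs.

    Returns decoded binary predictions, state-1 scores, and the true binary
    states at the test target times.  Training sets missing some of the four
    transition classes are handled by assigning those classes probability 0.
    """
    classes_present = np.unique(train.targets)
    if classes_present.size < 2:
        raise DegenerateTrainingError(
            "training targets contain a single class; filter the cohort first"
        )
    n_classes_total = 2 if mode == "original" else 4
    backend = _make_backend(model, backend_settings, seed)
    y_enc = np.searchsorted(classes_present, train.targets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        backend.fit(train.features, y_enc)
        proba_present = backend.predict_proba(test.features)
    proba = np.zeros((test.n, n_classes_total))
    proba[:, classes_present] = proba_present
    # xgboost emits float32 rows that can miss 1 by ~1e-7; renormalize
    proba /= proba.sum(axis=1, keepdims=True)

    pred_class = np.argmax(proba, axis=1)
    if mode == "original":
        pred_states = pred_class
        scores = proba[:, 1]
        true_states = test.targets.astype(np.int64)
    else:
        pred_states = transitions.decode_states(pred_class, convention)
        scores = np.asarray(transitions.score_state1(proba, convention))
        true_states = transitions.decode_states(test.targets, convention)
    return PredictionResult(
        target_times=test.target_times.copy(),
        true_states=true_states,
        pred_states=pred_states.astype(np.int64),
        scores=scores.astype(float),
    )


def forecast_individual(
    individual: IndividualRecord, config: ForecastConfig, convention: str = "current"
) -> PredictionResult:
    """Pairs -> chronological split -> fit -> decoded test predictions.

    The original mode drops its final supervised pair so both modes share
    identical target times (paired comparison contract).
    """
    pairs = make_supervised(
        individual, config.gap, config.mode, drop_last=(config.mode == "original")
    )
    train, test = chronological_split(pairs, config.train_fraction)
    seed = _derive_seed(config.seed, individual.id, config.model, config.gap, config.mode)
    try:
        result = fit_and_predict(
            train, test, config.model, config.mode, config.backend_settings, seed, convention
        )
    except DegenerateTrainingError:
        raise
    except Exception as exc:  # backend failure: attach context
        raise BackendError(
            f"backend {config.model!r} failed for individual {individual.id} "
            f"(gap={config.gap}, mode={config.mode}): {exc}"
        ) from exc
    result.individual_id = individual.id
    result.config = config
    return result


def run_experiment(
    cohort: Sequence[IndividualRecord],
    configs: Sequence[ForecastConfig],
    collect_predictions: bool = False,
    convention: str = "current",
) -> ExperimentResult:
    """Fit every (config x individual) cell and collect test-set metrics.

    Per-individual failures (degenerate training windows, backend errors)
    are logged and skipped; only a fully failed experiment raises.
    """
    rows = []
    pred_parts = []
    skipped = []
    for config in configs:
        for ind in cohort:
            try:
                result = forecast_individual(ind, config, convention)
            except (LengthError, SplitError, DegenerateTrainingError, BackendError) as exc:
                logger.warning("skipping %s for %s: %s", ind.id, config, exc)
                skipped.append((ind.id, config, str(exc)))
                continue
            m = evaluate_predictions(result.true_states, result.pred_states, result.scores)
            rows.append(
                {
                    "individual_id": ind.id,
                    "model": config.model,
                    "gap": config.gap,
                    "mode": config.mode,
                    **m,
                }
            )
            if collect_predictions:
                pred_parts.append(
                    pd.DataFrame(
                        {
                            "individual_id": ind.id,
                            "model": config.model,
                            "gap": config.gap,
                            "mode": config.mode,
                            "time": result.target_times,
                            "true_state": result.true_states,
                            "pred_state": result.pred_states,
                            "score_state1": result.scores,
                        }
                    )
                )
    if not rows:
        raise ExperimentError("every individual failed for every configuration")
    metrics = pd.DataFrame(rows)
    predictions = (
        pd.concat(pred_parts, ignore_index=True) if collect_predictions and pred_parts else None
    )
    return ExperimentResult(metrics=metrics, predictions=predictions, skipped=skipped)


def grid_configs(
    models: Sequence[str] = MODELS,
    gaps: Sequence[int] = DEFAULT_GAPS,
    modes: Sequence[str] = MODES,
    train_fraction: float = 0.7,
    seed: int = 0,
    backend_settings: Mapping | None = None,
) -> list[ForecastConfig]:
    """The full model x gap x mode experiment grid."""
    return [
        ForecastConfig(
            gap=int(g),
            mode=mode,
            model=model,
            train_fraction=train_fraction,
            backend_settings=backend_settings,
            seed=seed,
        )
        for model in models
        for g in gaps
        for mode in modes
    ]
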