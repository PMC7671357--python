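"""The increasingly-learning core: self-training SVM over divergent pairs.

Starting from a small set of validated positive pairs, each iteration

1. resamples fresh negatives from the nearby-pair pool at a 1:5
   positive:negative ratio,
2. grid-searches an RBF-kernel SVM (penalty C, kernel width gamma) by
   stratified 3-fold cross-validation maximising AUPR, then refits on all
   training data with Platt-calibrated probability output,
3. scores the remaining candidates and promotes every candidate whose
   predicted probability exceeds the admission threshold (0.9) into the
   positive set.

The loop stops once at most one new positive has been admitted in each of
two consecutive iterations (or, under the strict rule, exactly one), or at
the ``max_iterations`` safeguard.  All randomness flows from one master
seed; the per-iteration seed is derived with ``numpy.random.SeedSequence``
spawned on ``(master_seed, iteration)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from irdl.genome import PairRecord

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = tuple(2.0**e for e in range(-3, 8, 2))  # 2^-3 .. 2^7
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-7, 2, 2))  # 2^-7 .. 2^1

FeatureTable = dict[tuple[str, str], tuple[float, float, float, float]]


@dataclass(frozen=True)
class LearnerConfig:
    """Tunable parameters of the self-training loop."""

    score_threshold: float = 0.9
    negative_fold: int = 5
    cv_folds: int = 3
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    max_iterations: int = 50
    strict_stopping: bool = False  # stop only on exactly-one additions twice in a row

    def __post_init__(self) -> None:
        if not 0.0 < self.score_threshold < 1.0:
            raise ValueError(f"score_threshold must be in (0, 1), got {self.score_threshold}")
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.negative_fold < 1 or self.cv_folds < 2 or self.max_iterations < 1:
            raise ValueError("negative_fold >= 1, cv_folds >= 2 and max_iterations >= 1 required")


@dataclass
class IterationRecord:
    iteration: int
    n_positives_before: int
    n_added: int
    C: float
    gamma: float
    cv_aupr: float


@dataclass
class LearnerState:
    """Evolving state of a self-training run."""

    positives: list[PairRecord] = field(default_factory=list)
    negatives_current: list[PairRecord] = field(default_factory=list)
    candidates_remaining: list[PairRecord] = field(default_factory=list)
    iteration_log: list[IterationRecord] = field(default_factory=list)
    converged: bool = False


@dataclass
class ClassifierModel:
    """A fitted RBF-SVM with standardisation baked in.

    ``score`` returns the Platt-calibrated probability of the positive
    class; deterministic for a fitted model.
    """

    pipeline: Pipeline
    C: float
    gamma: float
    cv_aupr: float

    def score(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        positive_col = int(np.flatnonzero(self.pipeline.classes_ == 1)[0])
        return self.pipeline.predict_proba(features)[:, positive_col]


def derive_iteration_seed(master_seed: int, iteration: int) -> int:
    """Deterministic per-iteration seed below 2**31."""
    return int(np.random.SeedSequence((master_seed, iteration)).generate_state(1)[0] % (2**31))


def sample_negatives(
    nearby_pool: list[PairRecord],
    n_positives: int,
    fold: int,
    seed: int,
    exclude: set[tuple[str, str]] | None = None,
) -> list[PairRecord]:
    """Uniform sample (without replacement) of ``fold * n_positives`` pairs.

    Reproducible under the same seed; never returns a pair whose key is in
    ``exclude``.
    """
    exclude = exclude or set()
    eligible = [p for p in nearby_pool if p.key not in exclude]
    needed = fold * n_positives
    if len(eligible) < needed:
        raise ValueError(
            f"nearby pool too small: need {needed} negatives "
            f"({fold} x {n_positives} positives), only {len(eligible)} available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=needed, replace=False)
    return [eligible[i] for i in sorted(idx)]


def evaluate_aupr(scores, labels) -> float:
    """Area under the precision-recall curve.

    Computed by a descending-score threshold sweep with tied scores treated
    as one block (average precision).  Requires at least one positive label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError(f"scores and labels must align, got {scores.shape} vs {labels.shape}")
    if not np.any(labels == 1):
        raise ValueError("AUPR undefined: no positive labels")
    return float(np.clip(average_precision_score(labels, scores), 0.0, 1.0))


def _stack(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    return X, y


def fit_classifier(
    positives: np.ndarray,
    negatives: np.ndarray,
    config: LearnerConfig,
    seed: int,
) -> ClassifierModel:
    """Grid-search (C, gamma) by stratified CV on AUPR, refit on all data.

    Features are z-scored with training-set statistics inside the returned
    pipeline, so scoring applies the same transform.  Ties in CV AUPR are
    broken by the smallest C, then the smallest gamma.
    """
    positives = np.atleast_2d(np.asarray(positives, dtype=float))
    negatives = np.atleast_2d(np.asarray(negatives, dtype=float))
    if len(positives) < config.cv_folds:
        raise ValueError(
            f"need at least {config.cv_folds} positives for {config.cv_folds}-fold CV, "
            f"got {len(positives)}"
        )
    X, y = _stack(positives, negatives)
    if not np.isfinite(X).all():
        raise ValueError("non-finite value in feature matrix")

    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    best: tuple[float, float, float] | None = None  # (aupr, C, gamma)
    for C in sorted(config.c_grid):
        for gamma in sorted(config.gamma_grid):
            fold_scores = np.empty_like(y, dtype=float)
            for train_idx, test_idx in splits:
                clf = Pipeline(
                    [
                        ("scale", StandardScaler()),
                        ("svm", SVC(kernel="rbf", C=C, gamma=gamma)),
                    ]
                )
                clf.fit(X[train_idx], y[train_idx])
                fold_scores[test_idx] = clf.decision_function(X[test_idx])
            aupr = evaluate_aupr(fold_scores, y)
            if best is None or aupr > best[0] + 1e-12:
                best = (aupr, C, gamma)
    assert best is not None
    cv_aupr, C, gamma = best
    # Platt-style sigmoid calibration on cross-validated decision values, so
    # the 0.9 admission threshold applies to a probability, not a raw margin.
    calibrated = CalibratedClassifierCV(
        SVC(kernel="rbf", C=C, gamma=gamma),
        method="sigmoid",
        cv=StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed),
        ensemble=False,
    )
    final = Pipeline([("scale", StandardScaler()), ("svm", calibrated)])
    final.fit(X, y)
    return ClassifierModel(pipeline=final, C=C, gamma=gamma, cv_aupr=cv_aupr)


def run_increasing_learning(
    positives0: list[PairRecord],
    nearby_pool: list[PairRecord],
    candidates: list[PairRecord],
    features: FeatureTable,
    config: LearnerConfig,
    master_seed: int,
) -> tuple[list[PairRecord], LearnerState]:
    """Run the self-training loop; return (identified associations, state).

    The identified associations are the grown positive set minus the seed
    positives, each carrying its admission iteration and score.  Promoted
    candidates leave the scoring pool and are never used as negatives.
    """
    if not positives0:
        raise ValueError("need at least one seed positive pair")
    pos_keys = {p.key for p in positives0}
    cand_keys = {c.key for c in candidates}
    pool_keys = {n.key for n in nearby_pool}
    if pos_keys & cand_keys or pos_keys & pool_keys or cand_keys & pool_keys:
        raise ValueError("positives, candidates and nearby pool must be pairwise disjoint")

    def fvec(pair: PairRecord) -> np.ndarray:
        try:
            v = np.asarray(features[pair.key], dtype=float)
        except KeyError:
            raise KeyError(f"no feature vector for pair {pair.key}") from None
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite feature for pair {pair.key}: {v}")
        return v

    state = LearnerState(
        positives=list(positives0),
        candidates_remaining=list(candidates),
    )
    recent_additions: list[int] = []

    for t in range(1, config.max_iterations + 1):
        seed_t = derive_iteration_seed(master_seed, t)
        n_pos = len(state.positives)
        excluded = {p.key for p in state.positives} | {c.key for c in state.candidates_remaining}
        state.negatives_current = sample_negatives(
            nearby_pool, n_pos, config.negative_fold, seed_t, exclude=excluded
        )
        model = fit_classifier(
            np.array([fvec(p) for p in state.positives]),
            np.array([fvec(n) for n in state.negatives_current]),
            config,
            seed_t,
        )
        if state.candidates_remaining:
            scores = model.score(np.array([fvec(c) for c in state.candidates_remaining]))
        else:
            scores = np.empty(0)
        admitted = [
            (cand, float(s))
            for cand, s in zip(state.candidates_remaining, scores)
            if s > config.score_threshold
        ]
        admitted_keys = {c.key for c, _ in admitted}
        state.positives.extend(c.promoted(t, s) for c, s in admitted)
        state.candidates_remaining = [
            c for c in state.candidates_remaining if c.key not in admitted_keys
        ]
        state.iteration_log.append(
            IterationRecord(
                iteration=t,
                n_positives_before=n_pos,
                n_added=len(admitted),
                C=model.C,
                gamma=model.gamma,
                cv_aupr=model.cv_aupr,
            )
        )
        logger.info(
            "iteration %d: %d positives, %d admitted (C=%g, gamma=%g, cv AUPR=%.3f)",
            t, n_pos, len(admitted), model.C, model.gamma, model.cv_aupr,
        )
        recent_additions.append(len(admitted))
        if len(recent_additions) >= 2:
            last_two = recent_additions[-2:]
            if config.strict_stopping:
                done = all(a == 1 for a in last_two)
            else:
                done = all(a <= 1 for a in last_two)
            if done:
                state.converged = True
                break

    identified = [p for p in state.positives if p.admission_iteration is not None]
    return identified, state
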