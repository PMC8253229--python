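"""Accuracy matrices, concordance statistics, correlations, cross-validation.

Classification accuracy follows the field-scoring convention

    accuracy = 100 * (samples classified correctly) / (samples in the set),

with three correctness rules for ordinal scores: ``first`` (top-probability
score must equal the visual score), ``second_probability`` (either of the
two highest-probability scores may match), and ``nearest_score`` (the top
score may be off by one).  The contingency counts always tally
(visual score, top score), so the matrix itself is rule-independent.

The c-statistic is the concordance probability over all observation pairs
with different truth labels; for binary truth it equals the trapezoidal
ROC AUC.  For ordinal truth the scalar score is the probability-weighted
expected level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import EvaluationError, FitError, InputError
from .models import (
    TURGID,
    WILTED,
    WiltingPrediction,
    fit_binary,
    fit_ordinal,
    predict,
    stepwise_select,
)

logger = logging.getLogger(__name__)

ACCURACY_METHODS = ("first", "second_probability", "nearest_score")


@dataclass
class AccuracyMatrix:
    """Visual x estimated contingency counts with per-method accuracies."""

    levels: tuple
    counts: np.ndarray  # (n_levels, n_levels), rows = visual truth
    method: str
    overall_pct: float
    per_class_pct: np.ndarray  # NaN for levels with no visual samples

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.levels), columns=list(self.levels))


def _correct_mask(levels, counts, method):
    """Boolean cell mask of (visual i, estimated j) pairs the rule accepts."""
    n = len(levels)
    idx = np.arange(n)
    if method == "first":
        return np.eye(n, dtype=bool)
    if method == "nearest_score":
        return np.abs(idx[:, None] - idx[None, :]) <= 1
    raise EvaluationError(
        "second-probability accuracy needs full probability vectors, "
        "not a count matrix"
    )


def _finish_matrix(levels, counts, correct_by_class, method) -> AccuracyMatrix:
    row_totals = counts.sum(axis=1)
    n_total = counts.sum()
    if n_total == 0:
        raise EvaluationError("empty prediction set")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_totals > 0, 100.0 * correct_by_class / row_totals, np.nan)
    overall = 100.0 * correct_by_class.sum() / n_total
    return AccuracyMatrix(tuple(levels), counts, method, float(overall), per_class)


def accuracy_matrix_from_counts(levels, counts, method: str = "first") -> AccuracyMatrix:
    """Accuracy from a printed visual x estimated count matrix.

    Supports ``first`` and ``nearest_score``; ``second_probability`` is
    refused because a count matrix cannot reveal second-ranked scores.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (len(levels), len(levels)):
        raise InputError("counts must be square over the level set")
    accepted = _correct_mask(levels, counts, method)
    correct_by_class = (counts * accepted).sum(axis=1)
    return _finish_matrix(levels, counts, correct_by_class, method)


def accuracy_matrix(
    truth, predictions: list[WiltingPrediction], method: str = "first"
) -> AccuracyMatrix:
    """Accuracy matrix from visual scores and model predictions."""
    if method not in ACCURACY_METHODS:
        raise EvaluationError(f"unknown method {method!r}; choose from {ACCURACY_METHODS}")
    if len(truth) != len(predictions):
        raise InputError(
            f"{len(truth)} truth labels vs {len(predictions)} predictions"
        )
    levels = tuple(predictions[0].levels)
    pos = {lev: i for i, lev in enumerate(levels)}
    counts = np.zeros((len(levels), len(levels)), dtype=int)
    correct_by_class = np.zeros(len(levels), dtype=int)
    for t, pred in zip(truth, predictions):
        if t not in pos:
            raise InputError(f"truth level {t!r} outside model levels {levels}")
        i, j = pos[t], pos[pred.top_score]
        counts[i, j] += 1
        if method == "first":
            ok = i == j
        elif method == "second_probability":
            ok = t in (pred.top_score, pred.second_score)
        else:  # nearest_score; boundary levels only have their existing neighbors
            ok = abs(i - j) <= 1
        correct_by_class[i] += ok
    return _finish_matrix(levels, counts, correct_by_class, method)


def binary_accuracy_matrix(truth, predicted) -> AccuracyMatrix:
    """2x2 turgid/wilted accuracy matrix from hard labels."""
    if len(truth) != len(predicted):
        raise InputError("truth and predicted label lists differ in length")
    levels = (TURGID, WILTED)
    pos = {lev: i for i, lev in enumerate(levels)}
    counts = np.zeros((2, 2), dtype=int)
    for t, p in zip(truth, predicted):
        counts[pos[t], pos[p]] += 1
    return _finish_matrix(levels, counts, np.diag(counts), "first")


@dataclass
class ROCResult:
    auc: float
    points: list[tuple[float, float]]  # (FPR, TPR); empty for ordinal truth
    n_pairs: tuple[int, int, int]  # concordant, discordant, tied


def c_statistic(truth, scores) -> ROCResult:
    """Concordance over all pairs with different truth labels.

    A pair is concordant when the observation with the higher truth level
    has the higher score; ties in score count half.  Binary truth also
    yields the empirical ROC curve (where it equals trapezoidal AUC).
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise InputError("truth and scores must align")
    uniq = np.unique(truth)
    if len(uniq) < 2:
        raise EvaluationError("no informative pairs: all truth labels equal")
    # rank truth labels (works for numeric levels and turgid/wilted strings)
    order = {lev: i for i, lev in enumerate(sorted(uniq, key=_level_key))}
    t = np.array([order[v] for v in truth])
    dt = t[:, None] - t[None, :]
    ds = scores[:, None] - scores[None, :]
    informative = dt > 0  # each unordered pair counted once
    concordant = int((informative & (ds > 0)).sum())
    discordant = int((informative & (ds < 0)).sum())
    tied = int((informative & (ds == 0)).sum())
    total = concordant + discordant + tied
    auc = (concordant + 0.5 * tied) / total
    points: list[tuple[float, float]] = []
    if len(uniq) == 2:
        fpr, tpr, _ = roc_curve(t, scores)
        points = list(zip(fpr.tolist(), tpr.tolist()))
    return ROCResult(float(auc), points, (concordant, discordant, tied))


def _level_key(v):
    # wilted ranks above turgid so that higher score = more wilted
    if isinstance(v, str):
        return {TURGID: 0, WILTED: 1}.get(v, v)
    return v


def pearson_correlation(values, wilting) -> float:
    """Product-moment correlation of one index column with wilting scores."""
    values = np.asarray(values, dtype=float)
    wilting = np.asarray(wilting, dtype=float)
    if len(values) < 3:
        raise EvaluationError("need at least 3 observations")
    if np.std(values) == 0 or np.std(wilting) == 0:
        raise EvaluationError("zero variance; correlation undefined")
    return float(stats.pearsonr(values, wilting)[0])


def correlation_table(table: pd.DataFrame, index_cols, score_col: str = "score") -> pd.Series:
    """Pearson r of every index column with the wilting score."""
    return pd.Series(
        {c: pearson_correlation(table[c], table[score_col]) for c in index_cols},
        name="r",
    )


@dataclass
class CVReport:
    scheme: str  # kfold | loocv
    k: int
    seed: int | None
    per_fold_auc: list[float]
    mean_auc: float
    fold_sizes: list[int]
    predictors: list[str]
    excluded_folds: list[int] = dc_field(default_factory=list)


def _held_out_scores(model, table: pd.DataFrame):
    preds = [predict(model, row) for row in table.to_dict("records")]
    if model.family == "ordinal":
        return np.array([p.expected_score for p in preds])
    return np.array([p.probabilities[list(p.levels).index(WILTED)] for p in preds])


def _outcome_col(family: str) -> str:
    return "score" if family == "ordinal" else "status"


def _fit(family, table, predictors, outcome_col):
    if family == "ordinal":
        levels = tuple(sorted(table[outcome_col].unique()))
        return fit_ordinal(table, predictors, score_col=outcome_col, levels=levels)
    return fit_binary(table, predictors, label_col=outcome_col)


def _resolve_predictors(table, family, predictors, outcome_col):
    if predictors is not None:
        return list(predictors)
    selected = stepwise_select(table, family, outcome_col=outcome_col).predictors
    if not selected:
        raise EvaluationError("stepwise selection retained no predictors")
    return selected


def kfold_cv(
    table: pd.DataFrame,
    family: str,
    k: int = 10,
    seed: int = 0,
    predictors=None,
) -> CVReport:
    """Seeded k-fold cross-validation of the concordance statistic.

    Folds partition the rows; ``n mod k`` folds get one extra row.  Every
    fold's model refits the full-data predictor set (selection is not
    re-run per fold).  Folds without informative pairs are excluded from
    the mean and logged.
    """
    n = len(table)
    if not 2 <= k <= n:
        raise EvaluationError(f"need 2 <= k <= n, got k={k}, n={n}")
    outcome_col = _outcome_col(family)
    predictors = _resolve_predictors(table, family, predictors, outcome_col)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(perm[start:start + size])
        start += size
    per_fold, excluded = [], []
    for i, fold in enumerate(folds):
        train = table.drop(table.index[fold])
        test = table.iloc[fold]
        try:
            model = _fit(family, train, predictors, outcome_col)
            scores = _held_out_scores(model, test)
            truth = test[outcome_col].to_numpy()
            if family == "binary":
                truth = np.asarray([t for t in truth])
            roc = c_statistic(truth, scores)
            per_fold.append(roc.auc)
        except (FitError, EvaluationError) as exc:
            logger.warning("fold %d excluded: %s", i, exc)
            excluded.append(i)
            per_fold.append(float("nan"))
    valid = [a for a in per_fold if not np.isnan(a)]
    if not valid:
        raise EvaluationError("every fold failed")
    return CVReport(
        scheme="kfold", k=k, seed=seed, per_fold_auc=per_fold,
        mean_auc=float(np.mean(valid)), fold_sizes=[len(f) for f in folds],
        predictors=predictors, excluded_folds=excluded,
    )


def loocv(table: pd.DataFrame, family: str, predictors=None) -> CVReport:
    """Leave-one-out CV: n fits, held-out scores pooled into one c-statistic."""
    n = len(table)
    if n < 3:
        raise EvaluationError("need at least 3 observations for leave-one-out")
    outcome_col = _outcome_col(family)
    predictors = _resolve_predictors(table, family, predictors, outcome_col)
    pooled = np.full(n, np.nan)
    excluded = []
    for i in range(n):
        train = table.drop(table.index[i])
        try:
            model = _fit(family, train, predictors, outcome_col)
            pooled[i] = _held_out_scores(model, table.iloc[[i]])[0]
        except FitError as exc:
            logger.warning("left-out observation %d excluded: %s", i, exc)
            excluded.append(i)
    ok = ~np.isnan(pooled)
    if ok.sum() < 3:
        raise EvaluationError("too few successful leave-one-out fits")
    roc = c_statistic(table[outcome_col].to_numpy()[ok], pooled[ok])
    return CVReport(
        scheme="loocv", k=n, seed=None, per_fold_auc=[roc.auc],
        mean_auc=roc.auc, fold_sizes=[1] * n, predictors=predictors,
        excluded_folds=excluded,
    )
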