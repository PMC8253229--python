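"""Cumulative-logit and binary logistic wilting models.

The ordinal model is the proportional-odds form written directly in the
published parameterization

    logit P(Y <= j) = eps + alpha_j,      alpha_0 < alpha_1 < ... ,

where ``eps`` is a linear predictor over the 11 color indices and the
``alpha_j`` are boundary thresholds; category probabilities follow by
telescoping differences, the last category as the complement.  The binary
model is ``P(turgid) = logistic(eps + intercept)``.

Four published models ship as presets (:data:`REGISTRY`): two ordinal
(proximal 0-3, aerial 0-5) and two binary (turgid/wilted), with the
printed coefficients held as literal constants.  New models are fitted by
maximum likelihood (statsmodels under the hood, parameters converted to
the parameterization above), with classical p-value stepwise selection
and AIC/SC reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .errors import FitError, InputError
from .indices import INDEX_COLUMNS, ColorIndexVector

logger = logging.getLogger(__name__)

TURGID, WILTED = "turgid", "wilted"


def binarize_score(score: int) -> str:
    """Collapse the 0-5 ordinal scale: 0-1 -> turgid, 2-5 -> wilted.

    Score 2 — almost all leaves folded — is the proposed irrigation trigger,
    hence the binary boundary.
    """
    if score not in (0, 1, 2, 3, 4, 5):
        raise InputError(f"wilting score must be an integer 0-5, got {score!r}")
    return TURGID if score <= 1 else WILTED


@dataclass
class WiltingPrediction:
    """Per-plot probability vector with first- and second-ranked scores."""

    levels: tuple
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.levels) != len(self.probabilities):
            raise ValueError("levels and probabilities must align")
        if abs(self.probabilities.sum() - 1.0) > 1e-9 or (self.probabilities < -1e-12).any():
            raise ValueError("probabilities must be nonnegative and sum to 1")

    def _ranked(self) -> list:
        # stable sort on descending probability; ties go to the lower level
        order = sorted(range(len(self.levels)), key=lambda i: (-self.probabilities[i], i))
        return [self.levels[i] for i in order]

    @property
    def top_score(self):
        return self._ranked()[0]

    @property
    def second_score(self):
        return self._ranked()[1]

    @property
    def expected_score(self) -> float:
        """Probability-weighted mean level (requires numeric levels)."""
        return float(np.dot(self.probabilities, np.asarray(self.levels, dtype=float)))


@dataclass
class OrdinalLogisticModel:
    thresholds: np.ndarray  # increasing, one per cumulative boundary
    coefficients: dict[str, float]
    levels: tuple
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.levels = tuple(self.levels)
        if len(self.thresholds) != len(self.levels) - 1:
            raise ValueError("need one threshold per cumulative boundary")
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")
        _check_coefficient_names(self.coefficients)

    family = "ordinal"


@dataclass
class BinaryLogisticModel:
    intercept: float
    coefficients: dict[str, float]
    positive_label: str = TURGID
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_coefficient_names(self.coefficients)

    family = "binary"
    levels = (TURGID, WILTED)


def _check_coefficient_names(coefficients: dict[str, float]) -> None:
    unknown = set(coefficients) - set(INDEX_COLUMNS)
    if unknown:
        raise ValueError(f"unknown index names in coefficients: {sorted(unknown)}")


#: The four published models, coefficients exactly as printed.
REGISTRY: dict[str, OrdinalLogisticModel | BinaryLogisticModel] = {
    # proximal ordinal; scores 4-5 were absent in the proximal training data
    "model1": OrdinalLogisticModel(
        thresholds=[-11.75, -7.19, -4.28],
        coefficients={"u_star": 1.70, "a_star": -1.77, "csi": -0.15},
        levels=(0, 1, 2, 3),
    ),
    # aerial ordinal, full 0-5 scale
    "model2": OrdinalLogisticModel(
        thresholds=[25.93, 27.54, 29.61, 31.04, 33.07],
        coefficients={
            "intensity": 78.45,
            "saturation": 6.96,
            "lightness": -1.08,
            "a_star": -2.62,
            "u_star": 1.44,
            "gga": -45.09,
            "csi": -0.34,
        },
        levels=(0, 1, 2, 3, 4, 5),
    ),
    # proximal binary (turgid vs wilted)
    "model3": BinaryLogisticModel(
        intercept=-0.43,
        coefficients={"saturation": 11.70, "csi": -0.07},
    ),
    # aerial binary
    "model4": BinaryLogisticModel(
        intercept=-31.74,
        coefficients={"lightness": -0.21, "a_star": -0.65, "gga": -37.90, "csi": -0.28},
    ),
}


def get_model(name: str):
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(REGISTRY)}")


def linear_predictor(model, indices) -> float:
    """Dot product of the model's coefficients with the named indices."""
    if isinstance(indices, ColorIndexVector):
        indices = indices.as_dict()
    eps = 0.0
    for name, weight in model.coefficients.items():
        try:
            value = float(indices[name])
        except (KeyError, TypeError, ValueError):
            raise InputError(f"index {name!r} is missing from the input")
        if not math.isfinite(value):
            raise InputError(f"index {name!r} is non-finite ({value})")
        eps += weight * value
    return eps


def predict_ordinal(model: OrdinalLogisticModel, indices) -> WiltingPrediction:
    """Category probabilities by the telescoping cumulative-logit form."""
    eps = linear_predictor(model, indices)
    cumulative = expit(eps + model.thresholds)
    probs = np.empty(len(model.levels))
    probs[0] = cumulative[0]
    probs[1:-1] = np.diff(cumulative)
    probs[-1] = 1.0 - cumulative[-1]
    return WiltingPrediction(model.levels, probs)


def predict_binary(model: BinaryLogisticModel, indices) -> tuple[float, float]:
    """(P_turgid, P_wilted) for one index vector."""
    pt = float(expit(linear_predictor(model, indices) + model.intercept))
    return pt, 1.0 - pt


def predict(model, indices) -> WiltingPrediction:
    """Uniform prediction interface over both families."""
    if model.family == "ordinal":
        return predict_ordinal(model, indices)
    pt, pw = predict_binary(model, indices)
    return WiltingPrediction(model.levels, [pt, pw])


def classify(prediction: WiltingPrediction, method: str = "first"):
    """Top score (``first``) or the (top, second) pair (``second``)."""
    if method == "first":
        return prediction.top_score
    if method == "second":
        return prediction.top_score, prediction.second_score
    raise ValueError(f"method must be 'first' or 'second', got {method!r}")


def information_criteria(loglik: float, k_params: int, n: int) -> tuple[float, float]:
    """AIC = -2 ll + 2k and Schwarz criterion SC = -2 ll + k ln n."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return -2.0 * loglik + 2.0 * k_params, -2.0 * loglik + k_params * math.log(n)


def _design(table: pd.DataFrame, predictors) -> pd.DataFrame:
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise InputError(f"index columns missing from table: {missing}")
    X = table.loc[:, list(predictors)].astype(float)
    if not np.isfinite(X.to_numpy()).all():
        raise InputError("non-finite values in predictor columns")
    return X

# Separation pushes ML estimates toward infinity; flag absurd magnitudes.
_SEPARATION_LIMIT = 1e4


def fit_ordinal(
    table: pd.DataFrame,
    predictors,
    score_col: str = "score",
    levels=None,
) -> OrdinalLogisticModel:
    """Maximum-likelihood proportional-odds fit on an index table.

    ``table`` holds one row per plot with index columns and an integer
    score column.  Returns the model in the published parameterization
    with log-likelihood, AIC and SC in ``diagnostics``.
    """
    X = _design(table, predictors)
    y = table[score_col].to_numpy()
    if levels is None:
        levels = tuple(sorted(np.unique(y)))
    levels = tuple(levels)
    if len(levels) < 2:
        raise FitError("need at least two outcome levels")
    y_cat = pd.Categorical(y, categories=list(levels), ordered=True)
    if pd.isna(y_cat).any():
        raise InputError(f"scores outside the declared levels {levels}")
    model = OrderedModel(y_cat, X, distr="logit")
    try:
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    except Exception as exc:
        raise FitError(f"ordinal fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError(
            "ordinal fit did not converge "
            f"(last |score| {np.abs(res.model.score(res.params)).max():.3g})"
        )
    k = len(predictors)
    params_arr = np.asarray(res.params, dtype=float)
    beta = params_arr[:k]
    thresholds = model.transform_threshold_params(params_arr)[1:-1]
    if np.abs(beta).max(initial=0.0) > _SEPARATION_LIMIT:
        raise FitError("coefficients diverged; data are likely completely separated")
    n = len(table)
    k_params = k + len(levels) - 1
    aic, sc = information_criteria(res.llf, k_params, n)
    # statsmodels fits P(Y<=j) = F(theta_j - x'beta); flip beta's sign for
    # the published form F(eps + alpha_j)
    return OrdinalLogisticModel(
        thresholds=np.asarray(thresholds, dtype=float),
        coefficients={p: -float(b) for p, b in zip(predictors, beta)},
        levels=levels,
        diagnostics={"loglik": float(res.llf), "aic": aic, "sc": sc,
                     "n": n, "k_params": k_params},
    )


def fit_binary(
    table: pd.DataFrame,
    predictors,
    label_col: str = "status",
    positive_label: str = TURGID,
) -> BinaryLogisticModel:
    """Maximum-likelihood binary logistic fit; outcome 1 = ``positive_label``."""
    X = _design(table, predictors)
    labels = table[label_col]
    y = (labels == positive_label).astype(int).to_numpy()
    if y.min() == y.max():
        raise FitError("outcome has a single class; nothing to fit")
    design = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, design).fit(method="lbfgs", maxiter=500, disp=False)
    except Exception as exc:
        raise FitError(f"binary fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.isfinite(params).all() or np.abs(params[1:]).max(initial=0.0) > _SEPARATION_LIMIT:
        raise FitError("coefficients diverged; data are likely completely separated")
    n = len(table)
    k_params = len(predictors) + 1
    aic, sc = information_criteria(res.llf, k_params, n)
    return BinaryLogisticModel(
        intercept=float(params[0]),
        coefficients={p: float(b) for p, b in zip(predictors, params[1:])},
        positive_label=positive_label,
        diagnostics={"loglik": float(res.llf), "aic": aic, "sc": sc,
                     "n": n, "k_params": k_params},
    )


def _null_loglik_ordinal(y: np.ndarray) -> tuple[float, int]:
    _, counts = np.unique(y, return_counts=True)
    n = counts.sum()
    return float((counts * np.log(counts / n)).sum()), len(counts) - 1


def _null_loglik_binary(y01: np.ndarray) -> tuple[float, int]:
    n1, n = int(y01.sum()), len(y01)
    n0 = n - n1
    ll = 0.0
    for c in (n0, n1):
        if c:
            ll += c * math.log(c / n)
    return ll, 1


def _rank_ok(X: np.ndarray) -> bool:
    Xc = X - X.mean(axis=0)
    return np.linalg.matrix_rank(Xc, tol=1e-8 * max(1.0, np.abs(Xc).max())) == X.shape[1]


@dataclass
class StepwiseResult:
    model: OrdinalLogisticModel | BinaryLogisticModel
    predictors: list[str]
    trace: list[dict]
    report: pd.DataFrame  # AIC/SC for selected, full, null


def stepwise_select(
    table: pd.DataFrame,
    family: str,
    candidates=INDEX_COLUMNS,
    outcome_col: str | None = None,
    slentry: float = 0.05,
    slstay: float = 0.05,
) -> StepwiseResult:
    """Classical p-value stepwise selection with an AIC/SC model report.

    Forward entry and backward elimination by likelihood-ratio tests at
    ``slentry``/``slstay``; the report compares the selected model with the
    null (all coefficients zero) and full (all candidates) models.
    """
    if family not in ("ordinal", "binary"):
        raise ValueError("family must be 'ordinal' or 'binary'")
    if outcome_col is None:
        outcome_col = "score" if family == "ordinal" else "status"
    candidates = [c for c in candidates if c in table.columns]
    if len(candidates) < 2:
        raise InputError("need at least two candidate predictors")

    if family == "ordinal":
        fit = lambda preds: fit_ordinal(table, preds, score_col=outcome_col)
        y = table[outcome_col].to_numpy()
        ll_null, k_null = _null_loglik_ordinal(y)
    else:
        fit = lambda preds: fit_binary(table, preds, label_col=outcome_col)
        y01 = (table[outcome_col] == TURGID).astype(int).to_numpy()
        ll_null, k_null = _null_loglik_binary(y01)

    n = len(table)
    included: list[str] = []
    ll_current = ll_null
    trace: list[dict] = []
    current_model = None
    changed = True
    while changed:
        changed = False
        # forward step
        best = None
        for cand in [c for c in candidates if c not in included]:
            cols = included + [cand]
            if not _rank_ok(table[cols].to_numpy(dtype=float)):
                logger.info("skipping %s: collinear with included predictors", cand)
                continue
            try:
                m = fit(cols)
            except FitError as exc:
                logger.info("skipping %s: %s", cand, exc)
                continue
            lr = 2.0 * (m.diagnostics["loglik"] - ll_current)
            p = float(chi2.sf(max(lr, 0.0), df=1))
            if p < slentry and (best is None or p < best[1]):
                best = (cand, p, m)
        if best is not None:
            cand, p, m = best
            included.append(cand)
            ll_current = m.diagnostics["loglik"]
            current_model = m
            trace.append({"action": "enter", "predictor": cand, "p_value": p})
            changed = True
        # backward step
        if len(included) > 1:
            worst = None
            for pred in included:
                reduced = [c for c in included if c != pred]
                try:
                    m_red = fit(reduced)
                except FitError:
                    continue
                lr = 2.0 * (ll_current - m_red.diagnostics["loglik"])
                p = float(chi2.sf(max(lr, 0.0), df=1))
                if p > slstay and (worst is None or p > worst[1]):
                    worst = (pred, p, m_red)
            if worst is not None:
                pred, p, m_red = worst
                included.remove(pred)
                ll_current = m_red.diagnostics["loglik"]
                current_model = m_red
                trace.append({"action": "remove", "predictor": pred, "p_value": p})
                changed = True

    aic_null, sc_null = information_criteria(ll_null, k_null, n)
    try:
        full_model = fit(list(candidates)) if _rank_ok(
            table[list(candidates)].to_numpy(dtype=float)
        ) else None
    except FitError:
        full_model = None

    if current_model is None:
        # no predictor entered: report the intercept/threshold-only model
        levels = tuple(sorted(np.unique(table[outcome_col]))) if family == "ordinal" else None
        if family == "ordinal":
            counts = pd.Series(table[outcome_col]).value_counts().sort_index()
            cum = np.log(counts.cumsum()[:-1] / (n - counts.cumsum()[:-1]))
            current_model = OrdinalLogisticModel(
                thresholds=np.asarray(cum, dtype=float), coefficients={}, levels=levels,
                diagnostics={"loglik": ll_null, "aic": aic_null, "sc": sc_null,
                             "n": n, "k_params": k_null},
            )
        else:
            n1 = int((table[outcome_col] == TURGID).sum())
            current_model = BinaryLogisticModel(
                intercept=math.log(n1 / (n - n1)), coefficients={},
                diagnostics={"loglik": ll_null, "aic": aic_null, "sc": sc_null,
                             "n": n, "k_params": k_null},
            )

    rows = {
        "selected": (current_model.diagnostics["aic"], current_model.diagnostics["sc"]),
        "null": (aic_null, sc_null),
    }
    if full_model is not None:
        rows["full"] = (full_model.diagnostics["aic"], full_model.diagnostics["sc"])
    report = pd.DataFrame.from_dict(rows, orient="index", columns=["AIC", "SC"])
    return StepwiseResult(model=current_model, predictors=included, trace=trace, report=report)


# -- plain-text model files -------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Write a model as a human-diffable key = value text file."""
    lines = [f"family = {model.family}"]
    if model.family == "ordinal":
        lines.append("levels = " + ",".join(str(l) for l in model.levels))
        for j, a in enumerate(model.thresholds):
            lines.append(f"threshold_{j} = {float(a)!r}")
    else:
        lines.append(f"positive_label = {model.positive_label}")
        lines.append(f"intercept = {float(model.intercept)!r}")
    for name, w in model.coefficients.items():
        lines.append(f"coef_{name} = {float(w)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path):
    """Read a model file written by :func:`save_model`."""
    entries: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    family = entries.pop("family", None)
    coefficients = {
        k[len("coef_"):]: float(v) for k, v in entries.items() if k.startswith("coef_")
    }
    if family == "ordinal":
        levels = tuple(int(l) for l in entries["levels"].split(","))
        thresholds = [float(entries[f"threshold_{j}"]) for j in range(len(levels) - 1)]
        return OrdinalLogisticModel(thresholds, coefficients, levels)
    if family == "binary":
        return BinaryLogisticModel(
            intercept=float(entries["intercept"]),
            coefficients=coefficients,
            positive_label=entries.get("positive_label", TURGID),
        )
    raise ValueError(f"unrecognized model file {path}: family={family!r}")
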