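"""Linear discriminant analysis for two-group classification.

Includes Box's M test for covariance equality, stepwise variable selection by
Wilks' lambda with F-to-enter / F-to-remove thresholds, leave-one-out
cross-validation, and the five published fixed discriminant formulas.

The fitted discriminant is the Fisher raw-score linear function with the
decision boundary at the midpoint of the two group score means (equal
priors), oriented so that a negative score predicts the patient group; a
score of exactly zero is classified healthy.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingInputError, StatisticsError

__all__ = [
    "DiscriminantModel",
    "PublishedClassifier",
    "CVReport",
    "boxs_m_test",
    "wilks_lambda",
    "stepwise_lda",
    "fit_lda",
    "loocv",
    "PUBLISHED_CLASSIFIERS",
    "evaluate_published_classifier",
]

logger = logging.getLogger(__name__)

PATIENT, HEALTHY = "patient", "healthy"


@dataclass
class DiscriminantModel:
    """A fitted two-group linear discriminant (negative score => patient)."""

    variables: list[str]
    coefficients: np.ndarray
    constant: float
    wilks_lambda: float
    lambda_path: list[float] = field(default_factory=list)
    step_log: list[str] = field(default_factory=list)

    def score(self, inputs: Mapping[str, float] | pd.DataFrame) -> np.ndarray:
        if isinstance(inputs, pd.DataFrame):
            X = inputs[self.variables].to_numpy(float)
        else:
            X = np.array([[float(inputs[v]) for v in self.variables]])
        return X @ self.coefficients + self.constant

    def classify(self, inputs) -> np.ndarray:
        s = self.score(inputs)
        return np.where(s < 0, PATIENT, HEALTHY)

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "coefficients": [float(c) for c in self.coefficients],
            "constant": float(self.constant),
            "sign_convention": "negative score => patient",
            "wilks_lambda": float(self.wilks_lambda),
            "lambda_path": [float(x) for x in self.lambda_path],
        }


@dataclass(frozen=True)
class PublishedClassifier:
    """A frozen printed discriminant formula (score < 0 => patient)."""

    name: str
    terms: tuple[tuple[float, str], ...]
    constant: float
    incomplete: bool = False  # printed with an ellipsis; terms may be missing

    @property
    def variables(self) -> list[str]:
        return [v for _, v in self.terms]

    def score(self, inputs: Mapping[str, float]) -> float:
        total = self.constant
        for coef, var in self.terms:
            if var not in inputs:
                raise MissingInputError(f"classifier {self.name} requires input {var!r}")
            total += coef * float(inputs[var])
        return total


#: The five published classifiers.  Inputs are task-averaged functional-task
#: features: M_/R_ = median/range under the named normalization, NZC/EWL =
#: rescaled waveform parameters; trailing digit = sensor index.
PUBLISHED_CLASSIFIERS: dict[str, PublishedClassifier] = {
    "F_MAX": PublishedClassifier(
        "F_MAX", ((8.901, "R_MAX2"), (-20.053, "M_MAX4")), -0.586
    ),
    "F_MVC": PublishedClassifier(
        "F_MVC", ((-11.308, "M_MVC4"), (4.729, "R_MVC4"), (2.971, "R_MVC7")), -2.931
    ),
    "F_GRASP": PublishedClassifier(
        "F_GRASP",
        ((7.755, "M_GRASP3"), (3.302, "R_GRASP5"), (-3.184, "R_GRASP6"), (4.160, "R_GRASP7")),
        -3.27,
    ),
    "F_Waveform": PublishedClassifier(
        "F_Waveform", ((-8.738, "EWL1"), (9.624, "NZC4")), -1.481
    ),
    # Printed with an ellipsis between the amplitude and waveform terms; only
    # the four printed terms are frozen here.
    "F_NoMVC": PublishedClassifier(
        "F_NoMVC",
        ((-4.407, "R_MAX2"), (14.673, "M_MAX4"), (7.508, "EWL1"), (-8.740, "NZC4")),
        1.109,
        incomplete=True,
    ),
}


def evaluate_published_classifier(
    name: str, inputs: Mapping[str, float]
) -> tuple[float, str]:
    """Score a published formula and classify (score < 0 => patient)."""
    if name not in PUBLISHED_CLASSIFIERS:
        raise MissingInputError(
            f"unknown classifier {name!r}; choose from {sorted(PUBLISHED_CLASSIFIERS)}"
        )
    score = PUBLISHED_CLASSIFIERS[name].score(inputs)
    return score, (PATIENT if score < 0 else HEALTHY)


# ---------------------------------------------------------------------------
# Box's M
# ---------------------------------------------------------------------------

def boxs_m_test(X: np.ndarray, labels: Sequence[str]) -> tuple[float, float]:
    """Box's M test of equal group covariance matrices (chi-square approx.)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    g = len(groups)
    if g < 2:
        raise StatisticsError("Box's M needs at least two groups")
    p = X.shape[1]
    ns, covs = [], []
    for gl in groups:
        sub = X[labels == gl]
        if len(sub) <= p:
            raise StatisticsError(
                f"group {gl!r} has n={len(sub)} <= {p} variables; covariance is singular"
            )
        ns.append(len(sub))
        covs.append(np.cov(sub, rowvar=False, ddof=1).reshape(p, p))
    N = sum(ns)
    pooled = sum((n - 1) * S for n, S in zip(ns, covs)) / (N - g)
    sign, logdet_pooled = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise StatisticsError(
            "pooled covariance is singular; reduce the number of variables"
        )
    M = (N - g) * logdet_pooled
    for n, S in zip(ns, covs):
        sgn, ld = np.linalg.slogdet(S)
        if sgn <= 0:
            raise StatisticsError(
                "a group covariance matrix is singular; reduce the number of variables"
            )
        M -= (n - 1) * ld
    c1 = (
        (2 * p**2 + 3 * p - 1)
        / (6.0 * (p + 1) * (g - 1))
        * (sum(1.0 / (n - 1) for n in ns) - 1.0 / (N - g))
    )
    chi2 = M * (1 - c1)
    df = p * (p + 1) * (g - 1) / 2.0
    p_value = float(stats.chi2.sf(max(chi2, 0.0), df))
    return float(M), p_value


# ---------------------------------------------------------------------------
# Wilks' lambda and stepwise selection
# ---------------------------------------------------------------------------

def _sscp(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group and total sums-of-squares-and-cross-products matrices."""
    total = X - X.mean(axis=0)
    T = total.T @ total
    W = np.zeros_like(T)
    for gl in np.unique(y):
        sub = X[y == gl]
        c = sub - sub.mean(axis=0)
        W += c.T @ c
    return W, T


def wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for the given variable set."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == len(np.asarray(y)):
        pass
    else:
        X = X.T
    W, T = _sscp(X, np.asarray(y))
    sign_t, ld_t = np.linalg.slogdet(T)
    if sign_t <= 0 or np.linalg.cond(T) > 1e10:
        raise StatisticsError("total SSCP is singular (collinear variables)")
    sign_w, ld_w = np.linalg.slogdet(W)
    if sign_w <= 0:
        return 0.0
    return float(np.exp(ld_w - ld_t))


def _partial_f(lam_small: float, lam_big: float, n: int, g: int, q: int) -> tuple[float, float]:
    """F test for adding one variable to a q-variable model (two+ groups).

    lam_small: lambda of the q-variable model; lam_big: with the extra
    variable.  df = (g-1, n-g-q).
    """
    df2 = n - g - q
    if df2 <= 0 or lam_big <= 0:
        return np.inf, 0.0
    f = (df2 / (g - 1.0)) * (lam_small / lam_big - 1.0)
    p = float(stats.f.sf(max(f, 0.0), g - 1, df2))
    return float(f), p


_SENSOR_RE = re.compile(r"(\d+)$")


def _tie_key(name: str, p_value: float) -> tuple:
    m = _SENSOR_RE.search(name)
    sensor = int(m.group(1)) if m else 0
    is_waveform = name.startswith(("NZC", "EWL"))
    return (p_value, sensor, int(is_waveform), name)


def stepwise_lda(
    table: pd.DataFrame,
    candidates: Sequence[str],
    group_column: str = "group",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> DiscriminantModel | None:
    """Stepwise Wilks'-lambda variable selection followed by an LDA fit.

    At each step the candidate minimizing the partial Wilks' lambda enters if
    its F-test p-value is below ``p_enter``; after every entry, included
    variables whose removal p-value exceeds ``p_remove`` exit (worst first).
    Collinear candidates (singular total SSCP) are skipped.  Returns ``None``
    when no variable meets the entry criterion.
    """
    y = table[group_column].to_numpy()
    if len(np.unique(y)) != 2:
        raise StatisticsError("stepwise_lda expects exactly two groups")
    n, g = len(y), 2
    data = {v: table[v].to_numpy(float) for v in candidates}

    selected: list[str] = []
    lam_current = 1.0
    lambda_path: list[float] = []
    log: list[str] = []
    just_removed: str | None = None
    max_steps = 2 * len(candidates) + 1

    def lam_of(vars_: Sequence[str]) -> float:
        if not vars_:
            return 1.0
        X = np.column_stack([data[v] for v in vars_])
        return wilks_lambda(X, y)

    for _ in range(max_steps):
        # --- entry ---
        entries = []
        for v in candidates:
            if v in selected or v == just_removed:
                continue
            try:
                lam_new = lam_of(selected + [v])
            except StatisticsError:
                continue  # collinear with the current model
            f, p = _partial_f(lam_current, lam_new, n, g, len(selected))
            entries.append((v, lam_new, p))
        just_removed = None
        entered = False
        if entries:
            entries.sort(key=lambda t: _tie_key(t[0], t[2]))
            v, lam_new, p = entries[0]
            if p < p_enter:
                selected.append(v)
                lam_current = lam_new
                lambda_path.append(lam_new)
                log.append(f"enter {v} (lambda={lam_new:.4f}, p={p:.4g})")
                entered = True
        if not entered:
            break
        # --- removal ---
        while len(selected) > 1:
            removals = []
            for v in selected:
                rest = [u for u in selected if u != v]
                lam_rest = lam_of(rest)
                f, p = _partial_f(lam_rest, lam_current, n, g, len(rest))
                removals.append((v, lam_rest, p))
            removals.sort(key=lambda t: -t[2])
            v, lam_rest, p = removals[0]
            if p > p_remove:
                selected.remove(v)
                lam_current = lam_rest
                lambda_path.append(lam_rest)
                log.append(f"remove {v} (lambda={lam_rest:.4f}, p={p:.4g})")
                just_removed = v
            else:
                break

    if not selected:
        logger.info("stepwise_lda: no variable met the entry criterion")
        return None
    X = np.column_stack([data[v] for v in selected])
    coef, const = fit_lda(X, y)
    return DiscriminantModel(
        variables=selected,
        coefficients=coef,
        constant=const,
        wilks_lambda=lam_current,
        lambda_path=lambda_path,
        step_log=log,
    )


def fit_lda(X: np.ndarray, y: Sequence[str]) -> tuple[np.ndarray, float]:
    """Fisher raw-score coefficients and constant, patient mean score < 0.

    The cut point is the midpoint of the two group mean scores (equal
    priors); the orientation is flipped if needed so patients score negative.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.unique(y)
    if len(groups) != 2:
        raise StatisticsError("fit_lda expects exactly two groups")
    mu = {gl: X[y == gl].mean(axis=0) for gl in groups}
    W, _ = _sscp(X, y)
    pooled = W / (len(y) - 2)
    other = [gl for gl in groups if gl != PATIENT]
    healthy_label = other[0] if PATIENT in groups else groups[0]
    patient_label = PATIENT if PATIENT in groups else groups[1]
    try:
        w = np.linalg.solve(pooled, mu[healthy_label] - mu[patient_label])
    except np.linalg.LinAlgError as exc:
        raise StatisticsError("singular pooled covariance in LDA fit") from exc
    const = -0.5 * float(w @ (mu[healthy_label] + mu[patient_label]))
    if float(X[y == patient_label].mean(axis=0) @ w + const) > 0:
        w, const = -w, -const
    return w, const


@dataclass
class CVReport:
    accuracy: float  # percent
    sensitivity: float  # percent of patients detected
    specificity: float  # percent of healthy detected
    predictions: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": float(self.accuracy),
            "sensitivity_pct": float(self.sensitivity),
            "specificity_pct": float(self.specificity),
        }


def loocv(
    table: pd.DataFrame,
    variables: Sequence[str],
    group_column: str = "group",
    strict: bool = False,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> CVReport:
    """Leave-one-out cross-validation of the linear discriminant.

    By default the variable set stays fixed and only the coefficients are
    refit on each fold's n-1 cases; ``strict=True`` re-runs the stepwise
    selection inside every fold (sensitivity analysis).
    """
    y = table[group_column].to_numpy()
    n = len(table)
    preds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = table.iloc[mask]
        if len(np.unique(train[group_column])) < 2:
            raise StatisticsError(f"fold {i}: a group is empty in the training split")
        if strict:
            model = stepwise_lda(
                train, variables, group_column, p_enter=p_enter, p_remove=p_remove
            )
            if model is None:
                preds.append(HEALTHY)  # no discriminant: default to majority-free call
                continue
            vars_i, coef, const = model.variables, model.coefficients, model.constant
        else:
            Xtr = train[list(variables)].to_numpy(float)
            coef, const = fit_lda(Xtr, train[group_column].to_numpy())
            vars_i = list(variables)
        x = table.iloc[i][vars_i].to_numpy(float)
        score = float(x @ coef + const)
        preds.append(PATIENT if score < 0 else HEALTHY)
    preds = np.array(preds)
    is_patient = y == PATIENT
    sens = 100.0 * np.mean(preds[is_patient] == PATIENT) if is_patient.any() else np.nan
    spec = 100.0 * np.mean(preds[~is_patient] == HEALTHY) if (~is_patient).any() else np.nan
    acc = 100.0 * np.mean(preds == y)
    out = pd.DataFrame(
        {
            "participant_id": table.get("participant_id", pd.RangeIndex(n)),
            "group": y,
            "predicted": preds,
        }
    )
    return CVReport(accuracy=acc, sensitivity=sens, specificity=spec, predictions=out)
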