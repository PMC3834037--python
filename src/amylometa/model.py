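"""The logistic meta-classifier and its model-selection machinery.

The meta-predictor stacks several hexapeptide window scorers: for a window
with component scores S_1..S_k it models

    P(amyloid | S) = 1 / (1 + exp(-(b0 + sum_j b_j S_j)))

with coefficients estimated by maximum likelihood (iteratively reweighted
least squares). Components are chosen from a candidate pool by bidirectional
stepwise search under the Bayesian information criterion, which on the
hexapeptide training sets typically discards candidates that merely
duplicate (correlate with) already-selected scorers. Held-out probabilities
come from leave-one-out or k-fold cross-validation so that downstream
thresholds and performance summaries are not inflated by overfitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import qr
from sklearn.base import BaseEstimator, ClassifierMixin

from .scorers import FeatureStandardizer

__all__ = [
    "LogisticMetaClassifier",
    "SeparationWarning",
    "CVScheme",
    "StepwiseStep",
    "StepwiseTrace",
    "fit_logistic",
    "bic",
    "stepwise_select",
    "cross_validated_scores",
    "save_model",
    "load_model",
]


class SeparationWarning(UserWarning):
    """The likelihood is unbounded (complete or quasi-complete separation)."""


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _check_collinear(design: np.ndarray, names: Sequence[str]) -> None:
    # rank-revealing QR; pivots beyond the numerical rank name the offenders
    if design.shape[1] <= 1:
        return
    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < design.shape[1]:
        cols = ["(intercept)"] + list(names)
        bad = [cols[i] for i in piv[rank:]]
        raise ValueError(f"perfectly collinear column(s): {bad}")


class LogisticMetaClassifier(ClassifierMixin, BaseEstimator):
    """Binary logistic regression fitted by IRLS with an always-present intercept.

    Parameters
    ----------
    standardize : bool, default False
        Standardise feature columns to sample mean 0 / sd 1 before fitting;
        the transform is recorded and applied to prediction inputs.
    tol : float, default 1e-8
        Convergence tolerance on the relative change in log-likelihood.
    max_iter : int, default 100
        Maximum number of IRLS iterations.

    Fitted attributes
    -----------------
    intercept_ : float
    coef_ : ndarray of shape (k,)
    feature_names_in_ : ndarray of column names
    loglik_ : float -- maximised log-likelihood
    loglik_path_ : list of per-iteration log-likelihoods (non-decreasing)
    n_iter_ : int
    converged_ : bool
    separation_ : bool -- True when the fit was stopped on a diverging
        (separated) likelihood; coefficients are then not MLEs.
    """

    def __init__(self, standardize: bool = False, tol: float = 1e-8, max_iter: int = 100):
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise ValueError(f"X has {len(X)} rows but y has {len(y)}")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("need at least one positive and one negative label")
        if X.isna().to_numpy().any():
            raise ValueError("feature matrix contains missing values")
        if len(set(map(str, X.columns))) != X.shape[1]:
            raise ValueError("duplicate feature column names")

        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]

        if self.standardize and X.shape[1] > 0:
            self.standardizer_ = FeatureStandardizer().fit(X)
            Xw = self.standardizer_.transform(X)
        else:
            self.standardizer_ = None
            Xw = X

        n = len(y)
        design = np.column_stack([np.ones(n), Xw.to_numpy(dtype=float)])
        _check_collinear(design, [str(c) for c in X.columns])

        beta = np.zeros(design.shape[1])
        ll = self._loglik(design, y, beta)
        path = [ll]
        converged = False
        separated = False
        for _ in range(self.max_iter):
            eta = design @ beta
            p = _expit(eta)
            w = p * (1.0 - p)
            # Newton step on the log-likelihood, damped to keep it monotone
            grad = design.T @ (y - p)
            hess = design.T @ (design * np.maximum(w, 1e-10)[:, None])
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            new_ll, new_beta = ll, beta
            t = 1.0
            for _half in range(30):
                cand = beta + t * step
                cand_ll = self._loglik(design, y, cand)
                if cand_ll >= ll:
                    new_ll, new_beta = cand_ll, cand
                    break
                t /= 2.0
            beta = new_beta
            path.append(new_ll)
            rel = abs(new_ll - ll) / (abs(new_ll) + 1.0)
            ll = new_ll
            if rel < self.tol:
                converged = True
                break

        eta = design @ beta
        fitted = _expit(eta)
        # Complete/quasi-complete separation: the likelihood has no finite
        # maximiser. Symptoms: the iteration either runs out its budget while
        # the coefficients diverge, or stalls numerically with every point
        # classified perfectly at saturated probability.
        perfect = np.all((eta > 0) == (y == 1))
        if not converged and (np.max(np.abs(eta)) > 30 or np.all(np.abs(eta) > 30)):
            separated = True
        if perfect and np.min(np.abs(eta)) > 10:
            separated = True
            converged = False
        if separated:
            warnings.warn(
                "complete or quasi-complete separation detected: the MLE does not "
                "exist; coefficients are the last (diverging) iterate",
                SeparationWarning,
                stacklevel=2,
            )

        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.loglik_ = float(ll)
        self.loglik_path_ = [float(v) for v in path]
        self.n_iter_ = len(path) - 1
        self.converged_ = bool(converged)
        self.separation_ = bool(separated)
        self.n_obs_ = n
        self.n_pos_ = int(y.sum())
        return self

    @staticmethod
    def _loglik(design: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
        eta = design @ beta
        # log(1+exp(eta)) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    # -- prediction --------------------------------------------------------
    def _design(self, X) -> np.ndarray:
        self._check_fitted()
        X = _as_frame(X)
        want = [str(c) for c in self.feature_names_in_]
        have = [str(c) for c in X.columns]
        if want != have:
            missing = set(want) - set(have)
            if missing:
                raise ValueError(f"missing scorer column(s): {sorted(missing)}")
            X = X[list(self.feature_names_in_)]
        if self.standardizer_ is not None:
            X = self.standardizer_.transform(X)
        return X.to_numpy(dtype=float)

    def decision_function(self, X) -> np.ndarray:
        Xv = self._design(X)
        return self.intercept_ + Xv @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        p = _expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def proba_from_scores(self, scores: Mapping[str, float]) -> float:
        """Meta-probability for a single window given named component scores."""
        self._check_fitted()
        row = pd.DataFrame([scores])
        return float(self.predict_proba(row)[:, 1][0])

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")

    @property
    def coefficients(self) -> dict[str, float]:
        """Named slope coefficients (the intercept is separate)."""
        self._check_fitted()
        return {str(n): float(b) for n, b in zip(self.feature_names_in_, self.coef_)}

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "intercept": self.intercept_,
            "coefficients": self.coefficients,
            "standardization": None
            if self.standardizer_ is None
            else self.standardizer_.to_dict(),
            "fit": {
                "loglik": self.loglik_,
                "n": self.n_obs_,
                "n_pos": self.n_pos_,
                "n_iter": self.n_iter_,
                "converged": self.converged_,
                "separation": self.separation_,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticMetaClassifier":
        obj = cls()
        names = list(d["coefficients"])
        obj.classes_ = np.array([0, 1])
        obj.feature_names_in_ = np.asarray(names, dtype=object)
        obj.n_features_in_ = len(names)
        obj.intercept_ = float(d["intercept"])
        obj.coef_ = np.array([d["coefficients"][n] for n in names], dtype=float)
        obj.standardizer_ = (
            None
            if d.get("standardization") is None
            else FeatureStandardizer.from_dict(d["standardization"])
        )
        fit = d.get("fit", {})
        obj.loglik_ = float(fit.get("loglik", float("nan")))
        obj.loglik_path_ = []
        obj.n_obs_ = int(fit.get("n", 0))
        obj.n_pos_ = int(fit.get("n_pos", 0))
        obj.n_iter_ = int(fit.get("n_iter", 0))
        obj.converged_ = bool(fit.get("converged", True))
        obj.separation_ = bool(fit.get("separation", False))
        return obj


def _expit(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def fit_logistic(X, y, **kwargs) -> LogisticMetaClassifier:
    """Fit a :class:`LogisticMetaClassifier`; keyword arguments are its parameters."""
    return LogisticMetaClassifier(**kwargs).fit(X, y)


def bic(model: LogisticMetaClassifier, X=None, y=None) -> float:
    """Bayesian information criterion: -2 logL + p ln(n), intercept included in p.

    Uses the stored fit when ``X``/``y`` are omitted; otherwise the
    log-likelihood is re-evaluated on the supplied data.
    """
    model._check_fitted()
    if X is None:
        if model.n_obs_ < 2:
            raise ValueError("BIC needs n >= 2 observations")
        ll, n = model.loglik_, model.n_obs_
    else:
        X = _as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) < 2:
            raise ValueError("BIC needs n >= 2 observations")
        eta = model.decision_function(X)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        n = len(y)
    p = 1 + len(model.coef_)
    return -2.0 * ll + p * np.log(n)


# ---------------------------------------------------------------------------
# Stepwise selection


@dataclass(frozen=True)
class StepwiseStep:
    action: str  # "add" or "drop"
    name: str
    bic_before: float
    bic_after: float


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep] = field(default_factory=list)

    def append(self, step: StepwiseStep) -> None:
        if step.bic_after >= step.bic_before:
            raise ValueError("accepted stepwise moves must strictly improve BIC")
        self.steps.append(step)

    @property
    def bics(self) -> list[float]:
        return [s.bic_after for s in self.steps]


def stepwise_select(
    X,
    y,
    candidates: Sequence[str] | None = None,
    direction: str = "both",
    standardize: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[list[str], StepwiseTrace]:
    """Bidirectional stepwise scorer selection under BIC.

    Starts from the intercept-only model; at each step every single addition
    and single deletion is refitted and the move with the lowest BIC is
    accepted if it improves on the current BIC; the search stops when no move
    improves. Ties prefer the move leaving fewer parameters, then the
    lexicographically smaller scorer name.

    Returns the selected scorer names (in X's column order) and the trace of
    accepted moves.
    """
    if direction != "both":
        raise ValueError("only direction='both' is supported")
    X = _as_frame(X)
    y = np.asarray(y, dtype=float).ravel()
    pool = [str(c) for c in (candidates if candidates is not None else X.columns)]
    if not pool:
        raise ValueError("need at least one candidate scorer")
    missing = set(pool) - set(map(str, X.columns))
    if missing:
        raise ValueError(f"candidate(s) not in feature matrix: {sorted(missing)}")

    kw = dict(standardize=standardize, tol=tol, max_iter=max_iter)

    def fit_bic(cols: Sequence[str]) -> float:
        m = LogisticMetaClassifier(**kw).fit(X[list(cols)], y)
        return bic(m)

    current: list[str] = []
    current_bic = fit_bic(current)
    trace = StepwiseTrace()
    while True:
        moves: list[tuple[float, int, str, str]] = []  # (bic, n_params, name, action)
        for name in pool:
            if name in current:
                cols = [c for c in current if c != name]
                try:
                    b = fit_bic(cols)
                except ValueError:
                    continue
                moves.append((b, len(cols) + 1, name, "drop"))
            else:
                cols = current + [name]
                try:
                    b = fit_bic(cols)
                except ValueError:  # e.g. collinear with current set
                    continue
                moves.append((b, len(cols) + 1, name, "add"))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best_bic, _, best_name, best_action = moves[0]
        if best_bic >= current_bic:
            break
        trace.append(StepwiseStep(best_action, best_name, current_bic, best_bic))
        if best_action == "add":
            current = current + [best_name]
        else:
            current = [c for c in current if c != best_name]
        current_bic = best_bic
    ordered = [str(c) for c in X.columns if str(c) in current]
    return ordered, trace


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation layout: leave-one-out or seeded k-fold."""

    kind: str = "loo"
    k: int | None = None
    seed: int = 0

    def folds(self, n: int) -> list[np.ndarray]:
        if self.kind == "loo":
            return [np.array([i]) for i in range(n)]
        if self.kind != "kfold":
            raise ValueError(f"unknown CV kind {self.kind!r}")
        k = self.k
        if k is None or not 2 <= k <= n:
            raise ValueError(f"kfold needs 2 <= k <= n, got k={k}, n={n}")
        order = np.random.default_rng(self.seed).permutation(n)
        return [np.sort(chunk) for chunk in np.array_split(order, k)]


def cross_validated_scores(
    X, y, scheme: CVScheme = CVScheme("loo"), **fit_kwargs
) -> np.ndarray:
    """Held-out meta-probabilities: row i is scored by a model fitted without
    row i's fold. Output is aligned with the input rows."""
    X = _as_frame(X)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    out = np.full(n, np.nan)
    for fold in scheme.folds(n):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        y_tr = y[mask]
        if y_tr.sum() == 0 or y_tr.sum() == len(y_tr):
            raise ValueError(
                "degenerate training fold with a single class; use fewer folds"
            )
        m = LogisticMetaClassifier(**fit_kwargs).fit(X.iloc[mask], y_tr)
        out[fold] = m.predict_proba(X.iloc[fold])[:, 1]
    return out


# ---------------------------------------------------------------------------
# Persistence


def save_model(model: LogisticMetaClassifier, path: str | Path) -> None:
    """Serialise a fitted model to YAML (scorer names, coefficients, metadata)."""
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def load_model(path: str | Path) -> LogisticMetaClassifier:
    return LogisticMetaClassifier.from_dict(yaml.safe_load(Path(path).read_text()))
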