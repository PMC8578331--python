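"""Multivariate adaptive regression splines (MARS/EARTH), from scratch.

The model is a weighted sum of basis functions

    y_hat(x) = sum_j C_j B_j(x)

where each B_j is the constant 1 (intercept), a hinge max(0, +-(x_v - t)),
or a product of hinges on distinct variables.  Fitting proceeds in two
passes: a forward pass greedily adds the mirrored hinge pair that most
reduces the residual sum of squares (coefficients refit by OLS after every
addition), and a backward pass deletes terms stepwise, scoring every visited
sub-model with generalized cross-validation

    GCV = (RSS / n) / (1 - C(m)/n)^2,   C(m) = m + d (m - 1) / 2

and returning the sub-model with minimum GCV.  The effective-parameter
penalty d defaults to 3 when interactions are allowed and 2 for additive
models, the standard MARS convention.

An optional holdout split (default 10%) reports test RMSE for model-quality
gating downstream.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "MarsRegressor",
    "forward_pass",
    "backward_prune",
    "gcv",
    "fit_mars",
]

# a hinge factor: (variable index, knot, sign); a basis is a tuple of factors
Factor = tuple[int, float, int]
Basis = tuple[Factor, ...]

_NORM_EPS = 1e-10


def gcv(rss: float, n: int, n_terms: int, penalty: float) -> float:
    """Generalized cross-validation criterion with effective parameter count
    C(m) = m + penalty * (m - 1) / 2."""
    c = n_terms + penalty * (n_terms - 1) / 2.0
    if c >= n:
        raise ValueError(
            f"effective parameters C(m)={c} >= n={n}: model too large for data")
    return (rss / n) / (1.0 - c / n) ** 2


def _eval_basis(X: np.ndarray, basis: Basis) -> np.ndarray:
    col = np.ones(X.shape[0])
    for v, t, sign in basis:
        col = col * np.maximum(sign * (X[:, v] - t), 0.0)
    return col


def _design(X: np.ndarray, bases: Sequence[Basis]) -> np.ndarray:
    return np.column_stack([_eval_basis(X, b) for b in bases])


def _candidate_knots(values: np.ndarray, max_knots: int | None) -> np.ndarray:
    u = np.unique(values)
    if max_knots is not None and u.size > max_knots:
        idx = np.unique(np.round(np.linspace(0, u.size - 1, max_knots)).astype(int))
        u = u[idx]
    return u


def _lstsq_rss(D: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    return beta, float(resid @ resid)


def _forward(X: np.ndarray, y: np.ndarray, max_terms: int, max_degree: int,
             tol: float, max_knots: int | None):
    """Greedy mirrored-pair forward pass.  Returns the list of bases."""
    n, p = X.shape
    bases: list[Basis] = [()]
    cols: list[np.ndarray] = [np.ones(n)]
    Q = np.full((n, 1), 1.0 / np.sqrt(n))
    yr = y - Q @ (Q.T @ y)
    rss = float(yr @ yr)
    y_scale = float(y @ y) + 1e-30

    while len(bases) < max_terms:
        if rss <= 1e-12 * y_scale:
            break
        best_red = 0.0
        best = None  # (parent index, var, knot)
        for pi, basis in enumerate(bases):
            if len(basis) >= max_degree:
                continue
            pcol = cols[pi]
            support = pcol != 0.0
            if not support.any():
                continue
            used_vars = {f[0] for f in basis}
            for v in range(p):
                if v in used_vars:
                    continue
                xv = X[:, v]
                knots = _candidate_knots(xv[support], max_knots)
                if knots.size == 0:
                    continue
                Hp = np.clip(xv[:, None] - knots[None, :], 0.0, None) * pcol[:, None]
                Hm = np.clip(knots[None, :] - xv[:, None], 0.0, None) * pcol[:, None]
                # project out the current fitted space
                Hp -= Q @ (Q.T @ Hp)
                Hm -= Q @ (Q.T @ Hm)
                a = np.einsum("ij,ij->j", Hp, Hp)
                bdot = yr @ Hp
                scale_p = np.maximum(a, _NORM_EPS * n)
                red = np.where(a > _NORM_EPS * n, bdot**2 / scale_p, 0.0)
                # orthogonalize the mirror against its partner
                cross = np.einsum("ij,ij->j", Hp, Hm)
                coef = np.where(a > _NORM_EPS * n, cross / scale_p, 0.0)
                m2 = np.einsum("ij,ij->j", Hm, Hm) - coef * cross
                mdot = (yr @ Hm) - coef * bdot
                red = red + np.where(m2 > _NORM_EPS * n, mdot**2 / np.maximum(m2, _NORM_EPS * n), 0.0)
                ki = int(np.argmax(red))
                if red[ki] > best_red:
                    best_red = float(red[ki])
                    best = (pi, v, float(knots[ki]))
        if best is None or best_red / rss < tol:
            break
        pi, v, t = best
        parent = bases[pi]
        pcol = cols[pi]
        for sign in (1, -1):
            if len(bases) >= max_terms + 1:
                break
            raw = np.maximum(sign * (X[:, v] - t), 0.0) * pcol
            raw_norm2 = float(raw @ raw)
            if raw_norm2 <= _NORM_EPS * n:
                continue  # degenerate (e.g. knot at the variable's extreme)
            q = raw - Q @ (Q.T @ raw)
            q -= Q @ (Q.T @ q)  # re-orthogonalize for stability
            norm2 = float(q @ q)
            if norm2 <= _NORM_EPS * raw_norm2:
                continue  # collinear with current design
            q /= np.sqrt(norm2)
            bases.append(parent + ((v, t, sign),))
            cols.append(raw)
            Q = np.column_stack([Q, q])
            yr = yr - q * (q @ yr)
        new_rss = float(yr @ yr)
        if rss > 0 and (rss - new_rss) / max(rss, 1e-30) < tol:
            rss = new_rss
            break
        rss = new_rss
    return bases


def _backward(bases: list[Basis], X: np.ndarray, y: np.ndarray,
              penalty: float):
    """Stepwise deletion; returns (best bases, best gcv, trace of
    (n_terms, rss, gcv) for every visited sub-model)."""
    n = len(y)
    D_full = _design(X, bases)
    current = list(range(len(bases)))
    _, rss = _lstsq_rss(D_full, y)
    best_gcv = gcv(rss, n, len(current), penalty)
    best_set = list(current)
    trace = [(len(current), rss, best_gcv)]
    while len(current) > 1:
        best_rss, drop = None, None
        for j in current:
            if j == 0:
                continue  # the intercept is never removed
            subset = [i for i in current if i != j]
            _, rss_j = _lstsq_rss(D_full[:, subset], y)
            if best_rss is None or rss_j < best_rss:
                best_rss, drop = rss_j, j
        if drop is None:
            break
        current.remove(drop)
        g = gcv(best_rss, n, len(current), penalty)
        trace.append((len(current), best_rss, g))
        if g <= best_gcv:
            best_gcv = g
            best_set = list(current)
    return [bases[i] for i in best_set], best_gcv, trace


class MarsRegressor(RegressorMixin, BaseEstimator):
    """Piecewise-linear hinge-basis regression with GCV pruning.

    Parameters
    ----------
    max_terms : forward-pass cap on basis functions (incl. intercept).
    max_degree : maximum hinge-product order (1 = additive).
    penalty : GCV effective-parameter penalty d; None selects 3 when
        interactions are allowed, 2 for additive models.
    tol : forward pass stops when the relative RSS improvement of the best
        candidate falls below this.
    max_knots : cap on candidate knots per variable (evenly spaced over the
        sorted unique observed values); None keeps every unique value.
    prune : run the backward GCV pass (disable to inspect the forward model).
    validation_fraction : fraction held out (seeded by random_state) for the
        test-RMSE report; 0 fits on all rows.
    """

    def __init__(self, max_terms: int = 21, max_degree: int = 2,
                 penalty: float | None = None, tol: float = 1e-4,
                 max_knots: int | None = 64, prune: bool = True,
                 validation_fraction: float = 0.1,
                 random_state: int | None = None):
        self.max_terms = max_terms
        self.max_degree = max_degree
        self.penalty = penalty
        self.tol = tol
        self.max_knots = max_knots
        self.prune = prune
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _validate_X(self, X, fitting: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if fitting:
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            elif hasattr(self, "feature_names_in_"):
                missing = [c for c in self.feature_names_in_ if c not in X.columns]
                if missing:
                    raise ValueError(f"missing covariates: {missing}")
                X = X[list(self.feature_names_in_)]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if not np.isfinite(X).all():
            raise ValueError("covariate matrix contains non-finite values")
        if not fitting and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fit on "
                f"{self.n_features_in_}")
        return X

    @property
    def _penalty(self) -> float:
        if self.penalty is not None:
            return float(self.penalty)
        return 3.0 if self.max_degree > 1 else 2.0

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = self._validate_X(X, fitting=True)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("X and y have different lengths")
        if not np.isfinite(y).all():
            raise ValueError("y contains non-finite values")
        n = X.shape[0]
        self.n_features_in_ = X.shape[1]
        if not hasattr(self, "feature_names_in_"):
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(X.shape[1])], dtype=object)
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        vf = float(self.validation_fraction)
        if vf > 0:
            if n < 20:
                raise ValueError("need >= 20 samples for a holdout split")
            n_test = int(round(n * vf))
            if n_test == 0 or n_test == n:
                raise ValueError(f"degenerate split: validation_fraction={vf}")
            rng = np.random.default_rng(self.random_state)
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
        else:
            if n < 10:
                raise ValueError("need >= 10 samples")
            train_idx = np.arange(n)
            test_idx = np.empty(0, dtype=int)
        Xtr, ytr = X[train_idx], y[train_idx]

        bases = _forward(Xtr, ytr, self.max_terms, self.max_degree,
                         self.tol, self.max_knots)
        D = _design(Xtr, bases)
        _, rss_fwd = _lstsq_rss(D, ytr)
        self.forward_gcv_ = gcv(rss_fwd, len(ytr), len(bases), self._penalty)
        self.forward_n_terms_ = len(bases)
        if self.prune:
            bases, best_gcv, trace = _backward(bases, Xtr, ytr, self._penalty)
            self.prune_trace_ = trace
            self.gcv_ = best_gcv
        else:
            self.prune_trace_ = [(len(bases), rss_fwd, self.forward_gcv_)]
            self.gcv_ = self.forward_gcv_

        D = _design(Xtr, bases)
        coef, rss = _lstsq_rss(D, ytr)
        self.bases_ = list(bases)
        self.coef_ = coef
        self.rss_ = rss
        self.n_train_ = len(ytr)
        self.rmse_train_ = float(np.sqrt(rss / len(ytr)))
        if test_idx.size:
            pred = _design(X[test_idx], bases) @ coef
            self.rmse_test_ = float(np.sqrt(np.mean((y[test_idx] - pred) ** 2)))
        else:
            self.rmse_test_ = float("nan")
        used = sorted({f[0] for b in self.bases_ for f in b})
        self.selected_covariates_ = [str(self.feature_names_in_[v]) for v in used]
        return self

    def predict(self, X):
        if not hasattr(self, "bases_"):
            raise ValueError("model is not fitted")
        X = self._validate_X(X, fitting=False)
        return _design(X, self.bases_) @ self.coef_

    # -- reporting / serialization ----------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "csc-mars-model",
            "version": 1,
            "params": self.get_params(),
            "feature_names": list(map(str, self.feature_names_in_)),
            "bases": [[list(f) for f in b] for b in self.bases_],
            "coefficients": self.coef_.tolist(),
            "gcv": self.gcv_,
            "rss": self.rss_,
            "n_train": self.n_train_,
            "rmse_train": self.rmse_train_,
            "rmse_test": self.rmse_test_,
            "selected_covariates": self.selected_covariates_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarsRegressor":
        if d.get("format") != "csc-mars-model":
            raise ValueError("not a serialized MARS model")
        model = cls(**d["params"])
        model.feature_names_in_ = np.asarray(d["feature_names"], dtype=object)
        model.n_features_in_ = len(d["feature_names"])
        model.bases_ = [tuple((int(v), float(t), int(s)) for v, t, s in b)
                        for b in d["bases"]]
        model.coef_ = np.asarray(d["coefficients"], dtype=float)
        model.gcv_ = d["gcv"]
        model.rss_ = d["rss"]
        model.n_train_ = d["n_train"]
        model.rmse_train_ = d["rmse_train"]
        model.rmse_test_ = d["rmse_test"]
        model.selected_covariates_ = list(d["selected_covariates"])
        return model

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "MarsRegressor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def describe_basis(self, basis: Basis) -> str:
        if not basis:
            return "1"
        parts = []
        for v, t, sign in basis:
            name = self.feature_names_in_[v]
            if sign > 0:
                parts.append(f"max(0, {name} - {t:g})")
            else:
                parts.append(f"max(0, {t:g} - {name})")
        return " * ".join(parts)

    def report_text(self) -> str:
        lines = [
            "MARS model report",
            f"  n_train: {self.n_train_}",
            f"  terms: {len(self.bases_)} (forward pass: {self.forward_n_terms_})",
            f"  GCV: {self.gcv_:.6g}",
            f"  RMSE train: {self.rmse_train_:.6g}",
            f"  RMSE test: {self.rmse_test_:.6g}",
            f"  selected covariates: {', '.join(self.selected_covariates_) or '(none)'}",
            "  basis functions:",
        ]
        for b, c in zip(self.bases_, self.coef_):
            lines.append(f"    {c:+.6g} * {self.describe_basis(b)}")
        return "\n".join(lines)


# -- module-level operations ----------------------------------------------

def forward_pass(X, y, max_terms: int = 21, max_degree: int = 2,
                 tol: float = 1e-4, max_knots: int | None = 64,
                 penalty: float | None = None) -> MarsRegressor:
    """Forward pass only (no pruning, no holdout)."""
    return MarsRegressor(max_terms=max_terms, max_degree=max_degree, tol=tol,
                         max_knots=max_knots, penalty=penalty, prune=False,
                         validation_fraction=0.0).fit(X, y)


def backward_prune(model: MarsRegressor, X, y) -> MarsRegressor:
    """Backward GCV pruning of a forward-pass model on the given data."""
    X_arr = model._validate_X(X, fitting=False)
    y = np.asarray(y, dtype=float).ravel()
    pruned = MarsRegressor(**model.get_params())
    pruned.feature_names_in_ = model.feature_names_in_
    pruned.n_features_in_ = model.n_features_in_
    bases, best_gcv, trace = _backward(list(model.bases_), X_arr, y,
                                       model._penalty)
    D = _design(X_arr, bases)
    coef, rss = _lstsq_rss(D, y)
    pruned.bases_ = bases
    pruned.coef_ = coef
    pruned.gcv_ = best_gcv
    pruned.prune_trace_ = trace
    pruned.rss_ = rss
    pruned.n_train_ = len(y)
    pruned.rmse_train_ = float(np.sqrt(rss / len(y)))
    pruned.rmse_test_ = float("nan")
    pruned.forward_n_terms_ = getattr(model, "forward_n_terms_", len(model.bases_))
    used = sorted({f[0] for b in bases for f in b})
    pruned.selected_covariates_ = [str(pruned.feature_names_in_[v]) for v in used]
    return pruned


def fit_mars(X, y, train_frac: float = 0.9, seed: int | None = None,
             **params) -> MarsRegressor:
    """Seeded 90/10 split, forward + backward on the training part, holdout
    RMSE on the rest."""
    return MarsRegressor(validation_fraction=1.0 - train_frac,
                         random_state=seed, **params).fit(X, y)
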