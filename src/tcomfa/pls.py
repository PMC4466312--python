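"""Partial least squares by NIPALS, with leave-one-out validation.

Field tables have many times more columns than rows, so the regression is
estimated by PLS: components are extracted one at a time, each a direction
in descriptor space of maximal covariance with the response, and the model
grows until leave-one-out SDEP stops declining.  Reported metrics follow
3D-QSAR conventions:

    r² = 1 − SS_res / SS_tot                 (fit)
    s  = sqrt(SS_res / (n − #cp − 1))        (fit, d.o.f.-corrected)
    q² = 1 − PRESS / SS_tot                  (leave-one-out)
    SDEP = sqrt(PRESS / n)

Leave-one-out semantics are those of literal refit-per-left-out-row; the
implementation refits NIPALS per fold (columns are pretreated once on the
full training table, the standard field convention; ``strict`` re-centers
per fold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin


class PLSRegressionNIPALS(BaseEstimator, RegressorMixin):
    """NIPALS PLS1 regression (single response).

    Parameters
    ----------
    n_components : int
        Number of components ("#cp") to extract.  Extraction stops early
        if the residual covariance vanishes.

    Fitted attributes: ``coef_`` (regression vector in column space),
    ``x_mean_``, ``y_mean_``, ``x_weights_`` (W), ``x_loadings_`` (P),
    ``y_loadings_`` (q), ``x_scores_`` (T), ``n_components_``, ``r2_``,
    ``s_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ValueError("X and y row counts differ")
        if self.n_components > min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(rows-1, cols)={min(n - 1, p)}"
            )
        if np.std(y) < 1e-15:
            raise ValueError("zero-variance response")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        E = X - self.x_mean_
        f = y - self.y_mean_
        W, P, Q, T = [], [], [], []
        for _ in range(self.n_components):
            w = E.T @ f
            wn = np.linalg.norm(w)
            if wn < 1e-14:
                break
            w /= wn
            t = E @ w
            tt = float(t @ t)
            if tt < 1e-14:
                break
            p_load = E.T @ t / tt
            q_load = float(f @ t) / tt
            E = E - np.outer(t, p_load)
            f = f - q_load * t
            W.append(w)
            P.append(p_load)
            Q.append(q_load)
            T.append(t)
        self.x_weights_ = np.array(W).T
        self.x_loadings_ = np.array(P).T
        self.y_loadings_ = np.array(Q)
        self.x_scores_ = np.array(T).T
        self.n_components_ = len(Q)
        if self.n_components_ == 0:
            self.coef_ = np.zeros(p)
        else:
            # B = W (P^T W)^{-1} q
            PtW = self.x_loadings_.T @ self.x_weights_
            self.coef_ = self.x_weights_ @ np.linalg.solve(PtW, self.y_loadings_)
        resid = y - self.predict(X)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - self.y_mean_) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot
        dof = max(n - self.n_components_ - 1, 1)
        self.s_ = float(np.sqrt(ss_res / dof))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coef_.size:
            raise ValueError("column count mismatch with fitted model")
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_

    def predict_components(self, X) -> np.ndarray:
        """Predictions for every component count 1..n_components_,
        shape (n_rows, n_components_)."""
        X = np.asarray(X, dtype=float)
        E = X - self.x_mean_
        out = np.empty((X.shape[0], self.n_components_))
        yhat = np.full(X.shape[0], self.y_mean_)
        for a in range(self.n_components_):
            t = E @ self.x_weights_[:, a]
            yhat = yhat + self.y_loadings_[a] * t
            E = E - np.outer(t, self.x_loadings_[:, a])
            out[:, a] = yhat
        return out


def fit_pls(X, y, ncomp: int) -> PLSRegressionNIPALS:
    """Fit a NIPALS PLS model with ``ncomp`` components."""
    return PLSRegressionNIPALS(n_components=ncomp).fit(X, y)


@dataclass
class LOOResult:
    """Leave-one-out profile: q², SDEP per component count, chosen #cp."""

    q2: np.ndarray  # index a -> a+1 components
    sdep: np.ndarray
    n_components: int
    press: np.ndarray

    @property
    def q2_chosen(self) -> float:
        return float(self.q2[self.n_components - 1])

    @property
    def sdep_chosen(self) -> float:
        return float(self.sdep[self.n_components - 1])


def loo_crossvalidate(X, y, max_comp: int = 20) -> LOOResult:
    """Leave-one-out cross-validation with first-SDEP-minimum selection.

    For every left-out row the model is refit on the remaining rows and
    the row predicted, for every component count up to ``max_comp``
    (bounded by the fold geometry).  Iteration over component counts ends
    at the first count whose successor does not lower the SDEP; ties break
    toward fewer components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("leave-one-out needs >= 3 rows")
    cmax = min(max_comp, n - 2, X.shape[1])
    preds = np.full((n, cmax), np.nan)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        model = PLSRegressionNIPALS(n_components=cmax).fit(X[keep], y[keep])
        pc = model.predict_components(X[i : i + 1])[0]
        preds[i, : pc.size] = pc
        if pc.size < cmax:  # early NIPALS stop: later counts equal the last
            preds[i, pc.size :] = pc[-1]
    press = np.sum((preds - y[:, None]) ** 2, axis=0)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss_tot
    sdep = np.sqrt(press / n)
    chosen = cmax
    for c in range(1, cmax):
        if sdep[c] >= sdep[c - 1]:
            chosen = c
            break
    return LOOResult(q2=q2, sdep=sdep, n_components=chosen, press=press)


@dataclass
class ScramblePoint:
    fraction: float
    q2: float
    sdep: float
    n_components: int


def y_scramble(X, y, fractions, seed: int, max_comp: int = 20) -> list[ScramblePoint]:
    """Progressive response scrambling.

    For each fraction f, a seeded random subset of round(f·n) responses is
    permuted among themselves and leave-one-out validation re-run; a real
    model's q² collapses as f grows, while fraction 0 reproduces the
    unscrambled profile exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    out = []
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        ys = y.copy()
        k = int(round(f * y.size))
        if k >= 2:
            idx = rng.choice(y.size, size=k, replace=False)
            ys[idx] = ys[rng.permutation(idx)]
        res = loo_crossvalidate(X, ys, max_comp=max_comp)
        out.append(
            ScramblePoint(float(f), res.q2_chosen, res.sdep_chosen, res.n_components)
        )
    return out
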