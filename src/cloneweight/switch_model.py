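"""Pooled logistic model for the probability of switching to second-line ART.

Discrete-time hazard model on person-intervals alive and on first-line ART,
fitted by maximum likelihood. The fitted probabilities feed the
inverse-probability weights: ``p_A(k) = 1 - P(switch in k | history)`` is
the probability of *not* switching in interval k.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DesignMatrix, build_design

log = logging.getLogger(__name__)


class ModelFitError(RuntimeError):
    """Zero events, separation, or other informative fitting failure."""


@dataclass
class PooledLogisticFit:
    params: pd.Series
    k_knots: tuple | None
    columns: list
    n_events: int
    n_rows: int
    converged: bool
    model: str = "switch"

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ModelFitError(f"design is missing fitted columns: {missing}")
        return X[self.columns].to_numpy(dtype=float) @ self.params.to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(X))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model": self.model,
                    "params": self.params.to_dict(),
                    "k_knots": list(self.k_knots) if self.k_knots else None,
                    "n_events": self.n_events,
                    "n_rows": self.n_rows,
                    "converged": self.converged,
                },
                fh,
                indent=2,
            )


def _newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
    ridge: float = 1e-6,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Weighted logistic maximum likelihood by Newton-Raphson with
    step-halving; assumes a full-rank design (constant columns are dropped
    upstream). Convergence: relative deviance change below ``tol``.

    Columns are standardized internally (the first column is assumed to be
    the intercept) so that spline terms with very different scales do not
    ill-condition the Hessian; coefficients are returned on the original
    scale. A tiny ridge penalty (``ridge`` on the standardized scale, never
    on the intercept) pins quasi-separated flat directions of the
    likelihood without measurably moving identified coefficients; the
    intercept score equation — predicted events sum to observed events —
    remains exact.
    """
    n, p = X.shape
    center = X.mean(axis=0)
    center[0] = 0.0
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    scale[0] = 1.0
    X = (X - center) / scale

    beta = np.zeros(p)
    if start is not None:
        # warm start (original scale -> standardized scale)
        beta = np.asarray(start, dtype=float) * scale
        beta[0] = start[0] + float(center @ (np.asarray(start) ))
    else:
        # start from the weighted marginal rate on the intercept
        ybar = float(np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6))
        beta[0] = np.log(ybar / (1 - ybar))

    pen = np.full(p, ridge)
    pen[0] = 0.0

    def negll(b: np.ndarray) -> float:
        eta = X @ b
        # log(1 + exp(eta)) - y*eta, stably
        return float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta))) + 0.5 * float(
            pen @ (b * b)
        )

    nll = negll(beta)
    converged = False
    for _ in range(max_iter):
        mu = expit(X @ beta)
        grad = X.T @ (w * (y - mu)) - pen * beta
        wdiag = w * mu * (1.0 - mu)
        H = (X * wdiag[:, None]).T @ X
        H[np.diag_indices(p)] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving line search on the negative log-likelihood
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            cand_nll = negll(cand)
            if cand_nll <= nll + 1e-12:
                break
            lam *= 0.5
        if abs(nll - cand_nll) <= tol * (abs(nll) + 1.0):
            beta, nll = cand, cand_nll
            converged = True
            break
        beta, nll = cand, cand_nll
    beta = beta / scale
    beta[0] -= float(center @ beta)
    return beta, converged


def fit_pooled_logistic(
    X: pd.DataFrame,
    y: pd.Series,
    weights: np.ndarray | None = None,
    model: str = "switch",
    k_knots: tuple | None = None,
    start: np.ndarray | None = None,
    tol: float = 1e-10,
) -> PooledLogisticFit:
    yv = np.asarray(y, dtype=float)
    w = np.ones(len(yv)) if weights is None else np.asarray(weights, dtype=float)
    n_events = float((yv * w).sum())
    if n_events == 0:
        raise ModelFitError(f"no {model} events: pooled logistic model is undefined")
    if ((yv > 0) | (w == 0)).all():
        raise ModelFitError(f"all rows are {model} events: model is undefined")
    beta, converged = _newton_logistic(
        X.to_numpy(dtype=float), yv, w, tol=tol, start=start
    )
    n_events = int(round(n_events))
    params = pd.Series(beta, index=X.columns)
    if not converged:
        log.warning("%s model did not converge in 50 Newton iterations", model)
    if np.abs(params.to_numpy()).max() > 50:
        log.warning(
            "%s model: extreme coefficients suggest separation: %s",
            model,
            params[params.abs() > 50].to_dict(),
        )
    return PooledLogisticFit(
        params=params,
        k_knots=k_knots,
        columns=list(X.columns),
        n_events=n_events,
        n_rows=len(X),
        converged=converged,
        model=model,
    )


def fit_switch_model(cohort: pd.DataFrame) -> PooledLogisticFit:
    """Fit the switch model on first-line person-intervals of the cohort."""
    dm = build_design(cohort, model="switch")
    return fit_pooled_logistic(dm.X, dm.y, model="switch", k_knots=dm.k_knots)


def fit_ltfu_model(cohort: pd.DataFrame) -> PooledLogisticFit | None:
    """Fit the loss-to-follow-up model; returns None when there are no
    dropout events (all retention probabilities are exactly 1)."""
    if int(cohort["ltfu"].sum()) == 0:
        return None
    dm = build_design(cohort, model="ltfu")
    return fit_pooled_logistic(dm.X, dm.y, model="ltfu", k_knots=dm.k_knots)


def predict_switch_prob(fit: PooledLogisticFit, X: pd.DataFrame) -> np.ndarray:
    """P(switch during k | history) for pre-built design rows."""
    return fit.predict(X)


def switch_probabilities(cohort: pd.DataFrame, fit: PooledLogisticFit | None) -> pd.Series:
    """Per person-interval switch probability aligned to ``cohort``.

    Rows outside the switch risk set (already on second line) get NaN.
    ``fit=None`` encodes a cohort with no switches: probability 0 everywhere.
    """
    out = pd.Series(np.nan, index=cohort.index, name="p_switch")
    risk = cohort["on_first_line"]
    if fit is None:
        out[risk] = 0.0
        return out
    dm = build_design(cohort, model="switch", k_knots=fit.k_knots)
    out[risk] = fit.predict(dm.X)
    return out


def ltfu_probabilities(cohort: pd.DataFrame, fit: PooledLogisticFit | None) -> pd.Series:
    """Per person-interval dropout probability (0 when ``fit`` is None)."""
    if fit is None:
        return pd.Series(0.0, index=cohort.index, name="p_ltfu")
    dm = build_design(cohort, model="ltfu", k_knots=fit.k_knots)
    return pd.Series(fit.predict(dm.X), index=cohort.index, name="p_ltfu")
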