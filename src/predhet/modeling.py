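"""Unpenalized maximum-likelihood logistic regression.

The fit is a damped Newton iteration (iteratively reweighted least squares)
on the full log-likelihood, without any shrinkage: the simulation study
deliberately isolates measurement effects from overfitting, so models are
fitted by plain ML at sample sizes where separation is essentially
impossible.  Non-convergence (including separation) is flagged rather than
raised so that callers can exclude and count affected replications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

__all__ = ["FittedLogistic", "fit_logistic", "linear_predictor"]

MAX_ITER = 100
LLF_RTOL = 1e-10
# |linear predictor| beyond which fitted probabilities are numerically 0/1;
# used to detect (quasi-)complete separation.
SEPARATION_LP = 30.0


@dataclass(frozen=True)
class FittedLogistic:
    """Maximum-likelihood logistic fit: intercept, coefficients, diagnostics."""

    intercept_hat: float
    coef_hat: np.ndarray
    converged: bool
    n_iterations: int
    llf: float

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.intercept_hat], self.coef_hat])


def _log_likelihood(y: np.ndarray, lp: np.ndarray) -> float:
    # log L = sum y*lp - log(1 + exp(lp)), computed stably
    return float(np.sum(y * lp + log_expit(-lp)))


def fit_logistic(
    y: np.ndarray,
    M: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = LLF_RTOL,
) -> FittedLogistic:
    """Fit logit(y) = alpha + beta' m by maximum likelihood.

    Parameters
    ----------
    y
        Binary outcome vector.
    M
        (n, P) predictor matrix (a 1-d vector is treated as one column).

    Raises
    ------
    ValueError
        If only one outcome class is present or a predictor column is
        constant.  Separation is *not* raised: the fit is returned with
        ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[0] != y.shape[0]:
        raise ValueError("y and M must have matching lengths")
    n_events = y.sum()
    if n_events == 0 or n_events == y.shape[0]:
        raise ValueError("both outcome classes must be present")
    if np.any(M.std(axis=0) == 0.0):
        raise ValueError("constant predictor column")

    X = np.column_stack([np.ones(y.shape[0]), M])
    beta = np.zeros(X.shape[1])
    lp = X @ beta
    llf = _log_likelihood(y, lp)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(lp)
        w = p * (1.0 - p)
        # Newton step; ridge-free, the likelihood is concave
        xtw = X * w[:, None]
        try:
            step = np.linalg.solve(xtw.T @ X, X.T @ (y - p))
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the iteration monotone in the log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            lp_cand = X @ cand
            llf_cand = _log_likelihood(y, lp_cand)
            if np.isfinite(llf_cand) and llf_cand >= llf - 1e-14:
                break
            scale *= 0.5
        beta, lp = cand, lp_cand
        if abs(llf_cand - llf) <= tol * (abs(llf) + 1e-300):
            llf = llf_cand
            converged = True
            break
        llf = llf_cand

    if converged and np.abs(lp).max() > SEPARATION_LP:
        # fitted probabilities at the 0/1 boundary: treat as separated
        p = expit(lp)
        if np.all((p > 1 - 1e-10) == (y == 1)):
            converged = False
    return FittedLogistic(
        intercept_hat=float(beta[0]),
        coef_hat=beta[1:].copy(),
        converged=converged,
        n_iterations=it,
        llf=llf,
    )


def linear_predictor(model: FittedLogistic, M: np.ndarray) -> np.ndarray:
    """Evaluate lp_i = alpha + beta' m_i.

    Applying derivation-sample coefficients to validation measurements gives
    the *transported* linear predictor; refitting on validation data first
    gives the *re-estimated* one.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[1] != model.coef_hat.shape[0]:
        raise ValueError(
            f"M has {M.shape[1]} columns, model has {model.coef_hat.shape[0]} coefficients"
        )
    return model.intercept_hat + M @ model.coef_hat
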