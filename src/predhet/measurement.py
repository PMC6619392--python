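"""Measurement-error models linking exact and pragmatic measurements.

A pragmatic measurement W of an exact predictor X follows the general
linear measurement model, with parameters that may depend on case status:

    W | Y=y  =  psi_y + theta_y * X + eps_y,    eps_y ~ N(0, sigma2_eps_y).

``psi`` is an additive shift, ``theta`` a multiplicative association, and
``sigma2_eps`` the variance of the random measurement deviation.  The
taxonomy of error structures is:

* random (classical): psi = 0, theta = 1, nondifferential;
* systematic: psi != 0 and/or theta != 1, identical in cases and noncases;
* differential: any parameter differs between cases and noncases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MeasurementSpec", "apply_measurement", "classify_spec"]


@dataclass(frozen=True)
class MeasurementSpec:
    """Parameters of the general measurement model, per outcome class.

    The ``*0`` fields apply to noncases (Y=0), the ``*1`` fields to cases
    (Y=1).  ``err_var*`` are variances of the random deviation; the
    corresponding standard deviations are ``sqrt(err_var*)``.
    """

    psi0: float = 0.0
    psi1: float = 0.0
    theta0: float = 1.0
    theta1: float = 1.0
    err_var0: float = 0.0
    err_var1: float = 0.0

    def __post_init__(self) -> None:
        if self.err_var0 < 0 or self.err_var1 < 0:
            raise ValueError("error variances must be non-negative")

    @classmethod
    def nondifferential(
        cls, psi: float = 0.0, theta: float = 1.0, err_var: float = 0.0
    ) -> "MeasurementSpec":
        """A spec with identical parameters in cases and noncases."""
        return cls(psi, psi, theta, theta, err_var, err_var)

    @classmethod
    def from_sd(
        cls, psi: float = 0.0, theta: float = 1.0, err_sd: float = 0.0
    ) -> "MeasurementSpec":
        """Nondifferential spec with the noise given as a standard deviation."""
        return cls.nondifferential(psi, theta, float(err_sd) ** 2)

    @classmethod
    def identity(cls) -> "MeasurementSpec":
        """The error-free spec: W equals X."""
        return cls()

    @property
    def is_nondifferential(self) -> bool:
        return (
            self.psi0 == self.psi1
            and self.theta0 == self.theta1
            and self.err_var0 == self.err_var1
        )


def classify_spec(spec: MeasurementSpec) -> str:
    """Classify a spec as ``"random"``, ``"systematic"`` or ``"differential"``.

    Differential if any parameter differs between cases and noncases; else
    systematic if psi != 0 or theta != 1; else random (classical).
    """
    if not spec.is_nondifferential:
        return "differential"
    if spec.psi0 != 0.0 or spec.theta0 != 1.0:
        return "systematic"
    return "random"


def apply_measurement(
    X: np.ndarray,
    y: np.ndarray,
    specs: Sequence[MeasurementSpec] | MeasurementSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Transform exact measurements X into pragmatic measurements W.

    Each column j of X is transformed under its own spec:
    ``w_ij = psi_{y_i, j} + theta_{y_i, j} * x_ij + eps_ij`` with
    ``eps_ij ~ N(0, err_var_{y_i, j})``, independent across cells.
    X itself is left unmodified.

    Parameters
    ----------
    X
        (n, P) matrix of exact measurements (a 1-d vector is treated as one
        column).
    y
        Binary outcome vector of length n, used for class-specific
        parameters.
    specs
        One :class:`MeasurementSpec` per column, or a single spec applied to
        every column.
    """
    X = np.asarray(X, dtype=float)
    squeeze = X.ndim == 1
    X = np.atleast_2d(X.T).T  # (n, P)
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("y length must equal the number of rows of X")
    if isinstance(specs, MeasurementSpec):
        specs = [specs] * X.shape[1]
    if len(specs) != X.shape[1]:
        raise ValueError(
            f"got {len(specs)} measurement specs for {X.shape[1]} predictors"
        )
    case = y == 1
    W = np.empty_like(X)
    for j, spec in enumerate(specs):
        psi = np.where(case, spec.psi1, spec.psi0)
        theta = np.where(case, spec.theta1, spec.theta0)
        sd = np.where(case, np.sqrt(spec.err_var1), np.sqrt(spec.err_var0))
        W[:, j] = psi + theta * X[:, j] + rng.standard_normal(X.shape[0]) * sd
    return W[:, 0] if squeeze else W
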