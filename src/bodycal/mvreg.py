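"""Multivariate multiple regression for 2D body-composition outcomes.

The adjustment task yields a bivariate outcome per participant — estimated
fat mass and estimated muscle mass — and these outcomes are correlated, so
the analysis uses the multivariate linear model Y = XB + E: Y is n x r
(r = 2 outcomes), X is the n x p design (intercept, measured fat, measured
muscle, psychometric covariate), B is p x r, and the rows of E are i.i.d.
normal with covariance Sigma.  B is estimated by ordinary least squares,
which is the maximum-likelihood estimate regardless of Sigma.

Each predictor's overall (both-outcomes) effect is tested with Wilks'
lambda on a single-row contrast: Lambda = det(E) / det(E + H) with H the
hypothesis SSCP for that row of B.  For a one-row contrast Rao's F
transformation of Lambda is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class CollinearityError(ValueError):
    pass


@dataclass
class MultivariateFit:
    """OLS fit of Y = XB + E with per-coefficient inference."""

    X: np.ndarray  # (n, p), first column intercept by convention
    Y: np.ndarray  # (n, r)
    x_names: list[str]
    y_names: list[str]
    B_hat: np.ndarray  # (p, r)
    E_sscp: np.ndarray  # (r, r) residual SSCP
    sigma_hat: np.ndarray  # (r, r) = E_sscp / (n - p)
    xtx_inv: np.ndarray  # (p, p)
    se: np.ndarray  # (p, r)
    t: np.ndarray  # (p, r)
    p_values: np.ndarray  # (p, r), two-tailed

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def r(self) -> int:
        return self.Y.shape[1]

    def coef_table(self) -> pd.DataFrame:
        rows = []
        for j, yn in enumerate(self.y_names):
            for i, xn in enumerate(self.x_names):
                rows.append(
                    {
                        "outcome": yn,
                        "predictor": xn,
                        "estimate": self.B_hat[i, j],
                        "se": self.se[i, j],
                        "t": self.t[i, j],
                        "p": self.p_values[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class WilksTest:
    """Single-predictor MANOVA test across all outcomes."""

    predictor: str
    lam: float  # Wilks' lambda in (0, 1]
    f: float
    df1: int
    df2: int
    p: float


def fit_mvlm(
    X: np.ndarray,
    Y: np.ndarray,
    x_names: Sequence[str] | None = None,
    y_names: Sequence[str] | None = None,
) -> MultivariateFit:
    """Fit the multivariate linear model by ordinary least squares.

    Requires n > p and a full-column-rank design.  Per-coefficient standard
    errors come from the diagonal of (X'X)^-1 and the residual covariance
    Sigma_hat = E'E / (n - p); t tests use n - p degrees of freedom.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    r = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    x_names = list(x_names) if x_names else [f"x{i}" for i in range(p)]
    y_names = list(y_names) if y_names else [f"y{j}" for j in range(r)]
    if np.linalg.matrix_rank(X) < p:
        # name columns whose removal restores full rank
        bad = [
            x_names[i]
            for i in range(p)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise CollinearityError(f"design is rank deficient (suspect columns: {bad})")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    B = xtx_inv @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid
    sigma = E / (n - p)
    se = np.sqrt(np.outer(np.diag(xtx_inv), np.diag(sigma)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, 0.0)
    p_values = 2 * stats.t.sf(np.abs(t), n - p)
    return MultivariateFit(
        X=X,
        Y=Y,
        x_names=x_names,
        y_names=y_names,
        B_hat=B,
        E_sscp=E,
        sigma_hat=sigma,
        xtx_inv=xtx_inv,
        se=se,
        t=t,
        p_values=p_values,
    )


def wilks_test(fit: MultivariateFit, predictor: str | int) -> WilksTest:
    """Wilks' lambda test that one predictor has no effect on any outcome.

    The hypothesis SSCP for the single-row contrast L selecting that
    predictor's coefficients is H = (LB)'(L (X'X)^-1 L')^-1 (LB); then
    Lambda = det(E)/det(E + H) and, the contrast having one row, the F
    approximation F = ((1 - Lambda)/Lambda) * (n - p - r + 1)/r on
    (r, n - p - r + 1) degrees of freedom is exact.
    """
    if isinstance(predictor, str):
        if predictor not in fit.x_names:
            raise KeyError(f"unknown predictor {predictor!r}")
        j = fit.x_names.index(predictor)
    else:
        j = int(predictor)
    name = fit.x_names[j]
    if j == 0 and name.lower() in ("intercept", "const", "(intercept)"):
        raise ValueError("Wilks test on the intercept is not supported")
    lb = fit.B_hat[j : j + 1, :]  # L B with L the j-th unit row vector
    h = (lb.T @ lb) / fit.xtx_inv[j, j]
    lam = float(np.linalg.det(fit.E_sscp) / np.linalg.det(fit.E_sscp + h))
    n, p, r = fit.n, fit.p, fit.r
    df1 = r
    df2 = n - p - r + 1
    if df2 < 1:
        raise ValueError("insufficient residual degrees of freedom for the F test")
    f = (1 - lam) / lam * df2 / df1
    p_val = float(stats.f.sf(f, df1, df2))
    return WilksTest(predictor=name, lam=lam, f=float(f), df1=df1, df2=df2, p=p_val)


def shift_vectors(fit: MultivariateFit, measured: np.ndarray | None = None) -> pd.DataFrame:
    """Arrows from measured composition to model-predicted outcomes.

    Each row joins an individual's measured (fat, muscle) pair (arrow
    start) to the fitted value of their 2D outcome (arrow end).  With
    standardized inputs the arrows are in z-score units.  ``measured``
    defaults to the design columns named 'fat' and 'muscle'.
    """
    if fit.r != 2:
        raise ValueError("shift vectors require exactly 2 outcomes")
    if measured is None:
        try:
            cols = [fit.x_names.index("fat"), fit.x_names.index("muscle")]
        except ValueError as exc:
            raise ValueError(
                "pass `measured` explicitly: design has no 'fat'/'muscle' columns"
            ) from exc
        measured = fit.X[:, cols]
    measured = np.asarray(measured, float)
    if measured.shape != (fit.n, 2):
        raise ValueError("measured must be (n, 2) (fat, muscle) pairs")
    ends = fit.X @ fit.B_hat
    return pd.DataFrame(
        {
            "start_fat": measured[:, 0],
            "start_muscle": measured[:, 1],
            "end_fat": ends[:, 0],
            "end_muscle": ends[:, 1],
        }
    )
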