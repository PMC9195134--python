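"""Exponential cross-metric regression and threshold translation.

The three relatedness metrics are linked by single-term exponential curves
y = a * exp(b * x), fitted by nonlinear least squares on the original
(untransformed) scale, seeded from ordinary least squares of ln(y) on x.
R-squared is computed on the original scale, 1 - RSS/TSS.  A fitted curve
can then be inverted (``invert_at``) to translate an accepted threshold on
one metric — e.g. 70% dDDH — into its equivalent on another.

The response is allowed to contain zeros (the MLSA distance is exactly 0
for indistinguishable strain pairs); only the log-linear initialization is
restricted to the positive observations.  Negative responses are a domain
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ExponentialFit",
    "FitDomainError",
    "FitConvergenceError",
    "fit_exponential",
    "predict_at",
    "invert_at",
    "fit_all_metric_pairs",
]


class FitDomainError(ValueError):
    """Input data outside the domain of the exponential model."""


class FitConvergenceError(RuntimeError):
    """The nonlinear least-squares iteration failed to converge."""


@dataclass(frozen=True)
class ExponentialFit:
    """Parameters and goodness of fit of y = a * exp(b * x)."""

    a: float
    b: float
    response: str
    predictor: str
    n: int
    r2: float
    rss: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise FitDomainError(f"need at least 3 points, got n={self.n}")
        if self.a <= 0:
            raise FitDomainError(f"scale parameter a={self.a} must be > 0")
        if self.r2 > 1 + 1e-12:
            raise FitDomainError(f"impossible r2={self.r2}")

    def predict(self, x0: float) -> float:
        return self.a * math.exp(self.b * x0)

    def invert(self, y0: float) -> float:
        if self.b == 0:
            raise FitDomainError("flat curve (b = 0): inversion undefined")
        if y0 <= 0:
            raise FitDomainError(f"response value {y0} must be > 0 to invert")
        return (math.log(y0) - math.log(self.a)) / self.b


def _model(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.exp(b * x)


def _log_linear_start(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pos = y > 0
    if pos.sum() < 2:
        raise FitDomainError(
            "need at least 2 positive response values for initialization"
        )
    b0, log_a0 = np.polyfit(x[pos], np.log(y[pos]), 1)
    return math.exp(log_a0), b0


def fit_exponential(
    x: Sequence[float],
    y: Sequence[float],
    response: str = "y",
    predictor: str = "x",
    max_iter: int = 200,
) -> ExponentialFit:
    """Least-squares fit of y = a * exp(b * x) on the original scale."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitDomainError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise FitDomainError(f"need at least 3 points, got {n}")
    if np.any(y < 0):
        raise FitDomainError("negative response values are outside the model")
    a0, b0 = _log_linear_start(x, y)
    # Constant response: the log-linear start is already exact.
    if np.allclose(y, y[0]) and y[0] > 0:
        a, b = float(y[0]), 0.0
    else:
        try:
            (a, b), _ = curve_fit(
                _model, x, y, p0=[a0, b0], maxfev=max_iter * (n + 2)
            )
        except RuntimeError as exc:
            raise FitConvergenceError(
                f"exponential fit did not converge from (a0={a0:.4g}, "
                f"b0={b0:.4g}): {exc}"
            ) from exc
    resid = y - _model(x, a, b)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss > 0:
        r2 = 1.0 - rss / tss
    else:
        r2 = 1.0 if rss <= 1e-24 * n else -math.inf
    return ExponentialFit(
        a=float(a), b=float(b), response=response, predictor=predictor,
        n=n, r2=r2, rss=rss,
    )


def predict_at(fit: ExponentialFit, x0: float) -> float:
    """Evaluate the fitted curve at a predictor value."""
    return fit.predict(x0)


def invert_at(fit: ExponentialFit, y0: float) -> float:
    """Predictor value at which the fitted curve attains response y0."""
    return fit.invert(y0)


def fit_all_metric_pairs(table) -> dict[tuple[str, str], ExponentialFit]:
    """The three cross-metric fits used for threshold calibration.

    Keys are (response, predictor): dDDH as response of ANIm (inverted at
    dDDH = 70 to place the ANIm species cut-off), and the MLSA distance as
    response of dDDH and of ANIm (evaluated forward at the dDDH = 70
    boundary to place the MLSA cut-off).
    """
    if len(table) == 0:
        raise FitDomainError("empty table")
    cols = {m: np.asarray(table.column(m)) for m in ("anim", "mlsa", "ddh")}
    directions = [("ddh", "anim"), ("mlsa", "ddh"), ("mlsa", "anim")]
    return {
        (resp, pred): fit_exponential(
            cols[pred], cols[resp], response=resp, predictor=pred
        )
        for resp, pred in directions
    }
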