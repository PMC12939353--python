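"""Marginal quantile estimation and quantile-curve tabulation.

For a fitted LNI regression the alpha-quantile of response k at covariate
vector x is

    yhat_{k,alpha} = exp( sum_j bhat_{jk} x_j + sqrt(psihat_kk) qhat_alpha ),

where ``qhat_alpha`` is the alpha-quantile of the standard univariate NI
law at the fitted mixing parameter.  The median (alpha = 1/2) depends on
the covariates alone, and a unit increase in x_j multiplies every quantile
of response k by ``exp(bhat_jk)`` — the same factor at every alpha, which
is what keeps fitted quantile curves from crossing.

Quantiles here are evaluated at posterior point summaries (medians); a
per-draw mode (``marginal_quantile`` on each retained draw) is available
for uncertainty bands but is not the default reporting path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .families import MixingFamily, Parameters, get_family, standard_ni_quantile

__all__ = [
    "QuantileRequest",
    "QuantileCurve",
    "DEFAULT_PERCENTILES",
    "marginal_quantile",
    "effect_factor",
    "quantile_curves",
]

#: Default percentile levels for growth-curve reporting: the 0.5th, 5th,
#: 25th, 50th, 75th, 95th and 99.5th percentiles.
DEFAULT_PERCENTILES = (0.005, 0.05, 0.25, 0.5, 0.75, 0.95, 0.995)


@dataclass(frozen=True)
class QuantileRequest:
    """A single marginal-quantile evaluation: response k, level alpha,
    covariate vector x (first entry 1)."""

    k: int
    alpha: float
    x: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.atleast_1d(np.asarray(self.x, float)))
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.x[0] != 1.0:
            raise ValueError("covariate vector must start with the intercept 1")


@dataclass
class QuantileCurve:
    """Fitted quantiles of one response over a covariate grid x alpha set."""

    k: int
    alphas: tuple
    grid: np.ndarray
    varying: int
    values: np.ndarray  # (len(grid), len(alphas))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, row in zip(self.grid, self.values):
            for a, v in zip(self.alphas, row):
                rows.append({"grid": g, "alpha": a, "quantile": v})
        return pd.DataFrame(rows)


def marginal_quantile(
    params: Parameters,
    family: MixingFamily | str,
    req: QuantileRequest,
) -> float:
    """Fitted alpha-quantile of response k at covariate vector x."""
    family = get_family(family)
    if not 0 <= req.k < params.p:
        raise IndexError(f"response index {req.k} out of range")
    if req.x.size != params.r:
        raise ValueError("covariate vector length must match B")
    eta = float(req.x @ params.B[:, req.k])
    scale = float(np.sqrt(params.Psi[req.k, req.k]))
    q = standard_ni_quantile(req.alpha, params.nu, family)
    return float(np.exp(eta + scale * q))


def effect_factor(params: Parameters, j: int, k: int):
    """Multiplicative quantile effect of a unit increase in covariate j.

    Returns ``(exp(b_jk), 100 * (exp(b_jk) - 1))`` — the factor by which
    every quantile of response k changes, and the same as a percent change.
    """
    b = float(params.B[j, k])
    factor = float(np.exp(b))
    return factor, 100.0 * (factor - 1.0)


def quantile_curves(
    params: Parameters,
    family: MixingFamily | str,
    k: int,
    varying: int,
    grid,
    fixed: np.ndarray,
    alphas=DEFAULT_PERCENTILES,
) -> QuantileCurve:
    """Tabulate fitted quantiles of response k over a covariate grid.

    ``fixed`` is a full covariate vector (first entry 1); entry ``varying``
    is swept over ``grid``.  Values are strictly increasing in alpha at
    every grid point by construction.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty covariate grid")
    alphas = tuple(sorted(alphas))
    fixed = np.atleast_1d(np.asarray(fixed, dtype=float)).copy()
    if varying == 0:
        raise ValueError("cannot sweep the intercept column")
    values = np.empty((grid.size, len(alphas)))
    family = get_family(family)
    scale = float(np.sqrt(params.Psi[k, k]))
    qs = np.array([standard_ni_quantile(a, params.nu, family) for a in alphas])
    for i, g in enumerate(grid):
        x = fixed.copy()
        x[varying] = g
        eta = float(x @ params.B[:, k])
        values[i] = np.exp(eta + scale * qs)
    return QuantileCurve(k=k, alphas=alphas, grid=grid, varying=varying, values=values)
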