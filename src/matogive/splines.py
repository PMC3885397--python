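"""Natural cubic spline bases with knots at equally spaced quantiles.

The maturity models express length, age, latitude and longitude effects as
cubic splines whose flexibility is indexed by degrees of freedom df = k - 1,
where k is the number of knots (boundary knots included) placed at equally
spaced quantiles of the observed covariate.  A natural (restricted) cubic
spline with k knots spans exactly k functions including the constant, so
dropping the constant leaves df columns — matching the df = k - 1 counting
and allowing df as small as 2.  df = 1 degenerates to a plain (centered)
linear term.

Beyond the boundary knots the basis extrapolates linearly, which keeps
out-of-sample predictions (flagged as extrapolation by the model layer)
well behaved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["SplineSpec", "SplineBasis", "spline_basis"]

_VALID_VARIABLES = ("length", "age", "latitude", "longitude")


@dataclass(frozen=True)
class SplineSpec:
    """A spline term: which variable, and how many degrees of freedom.

    ``df=1`` is a plain linear term; ``df>=2`` a natural cubic spline with
    ``df+1`` knots at equally spaced quantiles of the data (the extreme
    quantiles, i.e. the data range, serve as boundary knots).
    """

    variable: str
    df: int

    def __post_init__(self) -> None:
        if self.variable not in _VALID_VARIABLES:
            raise ValueError(
                f"unknown spline variable {self.variable!r}; "
                f"expected one of {_VALID_VARIABLES}"
            )
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")


@dataclass
class SplineBasis:
    """A fitted basis: knots (or centering constant) frozen at training time."""

    spec: SplineSpec
    knots: np.ndarray  # for df=1: single element, the training mean
    train_min: float
    train_max: float

    @property
    def df(self) -> int:
        return self.spec.df

    def transform(self, x: Sequence[float]) -> np.ndarray:
        """Evaluate the basis at ``x`` (any values; extrapolates linearly)."""
        x = np.asarray(x, dtype=float)
        if self.df == 1:
            return (x - self.knots[0])[:, None]
        return _natural_spline_columns(x, self.knots)

    def column_names(self) -> list[str]:
        v = self.spec.variable
        if self.df == 1:
            return [v]
        return [f"{v}_ns{j + 1}" for j in range(self.df)]


def _natural_spline_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis on the given knots, constant dropped.

    Uses the truncated-power representation: with knots xi_1 < ... < xi_K,
    the space is spanned by {1, x, N_1, ..., N_{K-2}} where

        N_j(x) = d_j(x) - d_{K-1}(x),
        d_j(x) = [(x - xi_j)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_j),

    each N_j having zero second and third derivative outside [xi_1, xi_K].
    Dropping the constant gives K - 1 = df columns.
    """
    K = len(knots)
    cols = np.empty((x.shape[0], K - 1), dtype=float)
    cols[:, 0] = x

    def d(j: int) -> np.ndarray:
        return (
            np.clip(x - knots[j], 0.0, None) ** 3
            - np.clip(x - knots[-1], 0.0, None) ** 3
        ) / (knots[-1] - knots[j])

    d_last = d(K - 2)
    for j in range(K - 2):
        cols[:, j + 1] = d(j) - d_last
    return cols


def spline_basis(x: Sequence[float], spec: SplineSpec) -> SplineBasis:
    """Fit a spline basis to training data ``x`` under ``spec``.

    Knots are placed at the quantiles i/df, i = 0..df, of ``x``.  Requires
    strictly more observations than df and enough distinct values for the
    knots to be distinct.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in {spec.variable}")
    if x.size <= spec.df:
        raise ValueError(
            f"need more than df={spec.df} observations, got {x.size}"
        )
    n_distinct = np.unique(x).size
    if n_distinct < spec.df + 1:
        raise ValueError(
            f"{spec.variable} has {n_distinct} distinct values; "
            f"df={spec.df} requires at least {spec.df + 1}"
        )
    if spec.df == 1:
        knots = np.array([float(np.mean(x))])
    else:
        quantiles = np.linspace(0.0, 1.0, spec.df + 1)
        knots = np.quantile(x, quantiles)
        if np.unique(knots).size != knots.size:
            raise ValueError(
                f"{spec.variable}: quantile knots are not distinct "
                f"(ties in the data); reduce df={spec.df}"
            )
    return SplineBasis(
        spec=spec,
        knots=knots,
        train_min=float(x.min()),
        train_max=float(x.max()),
    )
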