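"""Monotone phenotype-scale transformations.

A "scale" here is a strictly increasing map applied to a nonnegative
quantitative trait before model fitting.  Statistical interactions are not
invariant to such maps, so the same dataset can show strong G×E on one scale
and none on another.  This module provides the power (Box-Cox) family over a
λ grid, the log special case (λ=0), and the rank inverse normal
transformation (RINT), which depends on the trait only through its ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.special
from scipy.stats import rankdata

__all__ = [
    "TransformSpec",
    "box_cox",
    "lambda_grid",
    "rint",
    "DEFAULT_LAMBDA_GRID",
]

#: |λ| below this is treated as exactly 0 (log transform) to avoid
#: catastrophic cancellation in (y**λ - 1)/λ.
_LAMBDA_ZERO_TOL = 1e-12

#: Blom offset used in the rank inverse normal transformation.
_BLOM_C = 3.0 / 8.0


@dataclass(frozen=True)
class TransformSpec:
    """A named member of the transformation family.

    kind
        One of ``"box_cox"``, ``"rint"``, ``"identity"``.
    lam
        Power parameter λ; required (and finite) when ``kind="box_cox"``.
    """

    kind: str
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("box_cox", "rint", "identity"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "box_cox":
            if self.lam is None or not np.isfinite(self.lam):
                raise ValueError("box_cox requires a finite lambda")

    def apply(self, y: np.ndarray) -> np.ndarray:
        if self.kind == "box_cox":
            return box_cox(y, self.lam)
        if self.kind == "rint":
            return rint(y)
        return np.asarray(y, dtype=float)

    @property
    def label(self) -> str:
        if self.kind == "box_cox":
            return f"lambda={self.lam:g}"
        return self.kind


def box_cox(y, lam: float) -> np.ndarray:
    """Box-Cox power transform (y**λ - 1)/λ, with log(y) at λ=0.

    Defined for strictly positive ``y`` only; a non-positive entry raises
    ``ValueError`` naming the smallest offending value rather than silently
    shifting, because a shift would change the scale being tested.

    The map is strictly increasing in ``y`` for every λ, so ranks are
    preserved; λ=1 is the identity up to the constant -1.
    """
    y = np.asarray(y, dtype=float)
    if y.size and np.nanmin(y) <= 0:
        raise ValueError(
            "Box-Cox requires a strictly positive phenotype (Y > 0); "
            f"smallest value is {np.nanmin(y):g}"
        )
    if abs(lam) < _LAMBDA_ZERO_TOL:
        return np.log(y)
    return scipy.special.boxcox(y, lam)


def lambda_grid(lo: float = -1.0, hi: float = 2.0, n_points: int = 25) -> np.ndarray:
    """Evenly spaced λ grid including both endpoints.

    The default grid of 25 points from -1 to 2 has spacing 0.125 and contains
    both λ=0 (log) and λ=1 (no transformation) exactly.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    return np.linspace(lo, hi, int(n_points))


DEFAULT_LAMBDA_GRID = lambda_grid()


def rint(y) -> np.ndarray:
    """Rank inverse normal transformation with the Blom (3/8) offset.

    Maps the empirical quantiles of ``y`` onto standard normal quantiles:
    ``Phi^{-1}((rank - 3/8) / (n + 1/4))``, with ties receiving their mean
    rank.  The output depends on ``y`` only through its rank order, so it is
    invariant under any strictly increasing transformation of the input.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("rint requires at least 2 observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("rint requires finite input")
    ranks = rankdata(y, method="average")
    return scipy.special.ndtri((ranks - _BLOM_C) / (n - 2 * _BLOM_C + 1))
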