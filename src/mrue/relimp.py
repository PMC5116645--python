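"""LMG relative-importance decomposition of a regression R².

The LMG metric (Lindeman-Merenda-Gold) attributes the coefficient of
determination of a linear model to its predictors by averaging, over all
p! orderings in which the predictors could enter the model, the increase
in R² contributed by each predictor when it enters.  Shares are
non-negative and sum exactly to the full-model R², making them a natural
"percent of explained variance" decomposition even under collinearity.

Computation enumerates the 2^p subset R² values once and combines them
with the combinatorial weights s!(p-1-s)!/p!, which is exact and fast for
the small predictor counts used here (capped at p = 12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["RelimpResult", "lmg", "contribution_percentages"]

_MAX_PREDICTORS = 12


@dataclass
class RelimpResult:
    """Per-predictor LMG shares of a regression R²."""

    predictors: tuple[str, ...]
    lmg_share: dict[str, float]
    total_r2: float

    @property
    def normalized_pct(self) -> dict[str, float]:
        return contribution_percentages(self)

    def to_frame(self) -> pd.DataFrame:
        pct = self.normalized_pct
        return pd.DataFrame(
            {
                "predictor": list(self.predictors),
                "lmg_share": [self.lmg_share[p] for p in self.predictors],
                "pct_of_r2": [pct[p] for p in self.predictors],
            }
        )


def _subset_r2(X: np.ndarray, y: np.ndarray) -> dict[frozenset, float]:
    """R² of the OLS fit of y on every subset of the columns of X."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("response is constant; R² undefined")
    r2 = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            Xs = Xc[:, subset]
            beta, _, rank, _ = np.linalg.lstsq(Xs, yc, rcond=None)
            resid = yc - Xs @ beta
            r2[frozenset(subset)] = 1.0 - float(resid @ resid) / tss
    return r2


def lmg(predictors: pd.DataFrame | np.ndarray, response) -> RelimpResult:
    """LMG decomposition of the regression of ``response`` on ``predictors``.

    Parameters
    ----------
    predictors : (n, p) table
        Predictor columns; must have full column rank and p <= 12.
    response : length-n values

    Returns
    -------
    RelimpResult
        Shares summing to the full-model R².
    """
    if isinstance(predictors, pd.DataFrame):
        names = tuple(str(c) for c in predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    y = np.asarray(response, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("response length does not match predictor rows")
    if p < 1:
        raise ValueError("need at least one predictor")
    if p > _MAX_PREDICTORS:
        raise ValueError(
            f"exact LMG enumeration capped at {_MAX_PREDICTORS} predictors, got {p}"
        )
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise ValueError("predictor matrix is rank deficient (collinear columns)")

    r2 = _subset_r2(X, y)
    fact = math.factorial
    shares = {}
    for k in range(p):
        others = [i for i in range(p) if i != k]
        total = 0.0
        for size in range(p):
            w = fact(size) * fact(p - 1 - size) / fact(p)
            for subset in combinations(others, size):
                s = frozenset(subset)
                total += w * (r2[s | {k}] - r2[s])
        shares[names[k]] = total
    return RelimpResult(
        predictors=names, lmg_share=shares, total_r2=r2[frozenset(range(p))]
    )


def contribution_percentages(result: RelimpResult) -> dict[str, float]:
    """LMG shares normalised to percentages of the full-model R²."""
    if not result.total_r2 > 0:
        raise ValueError("total R² is zero; percentage contributions undefined")
    return {
        name: 100.0 * share / result.total_r2
        for name, share in result.lmg_share.items()
    }
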