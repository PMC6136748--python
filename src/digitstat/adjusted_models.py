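"""Covariate-adjusted linear models with Wald chi-square term tests.

``fit_linear`` is an ordinary least-squares fit whose per-term tests are
reported in SPSS GLM style: Wald chi-square = (B/SE)^2 against
chi-square(1), 95% CI as B +/- 1.95996 SE, plus a joint Wald chi-square
over all non-intercept terms.  ``ancova_scaling_check`` applies it to
the classic allometry question for digit ratios: regress the ratio on a
group indicator with the hand's mean finger length as covariate, so the
group coefficient estimates the ratio difference net of overall hand
size.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

#: two-sided 95% normal quantile used for the Wald confidence interval
_Z95 = 1.95996


@dataclasses.dataclass(frozen=True)
class TermFit:
    name: str
    B: float
    SE: float
    wald_chi2: float
    p: float
    ci95: tuple[float, float]


@dataclasses.dataclass(frozen=True)
class LinearModelFit:
    terms: tuple[TermFit, ...]
    model_chi2: float
    model_df: int
    model_p: float
    n_obs: int

    def term(self, name: str) -> TermFit:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def fit_linear(
    design: np.ndarray,
    y: Sequence[float],
    term_names: Sequence[str] | None = None,
    intercept_col: int | None = 0,
) -> LinearModelFit:
    """Least-squares fit with per-term and joint Wald chi-square tests.

    ``design`` must have full column rank and include its own intercept
    column (by default column 0, excluded from the joint model test; pass
    ``intercept_col=None`` for a no-intercept model).  A saturated fit
    (zero residual variance) is guarded: SEs collapse to 0 and the Wald
    statistics to infinity with p = 0.
    """
    X = np.asarray(design, dtype=float)
    yv = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be a 2-d matrix")
    n, p = X.shape
    if yv.shape != (n,):
        raise ValueError(f"y must have length {n}, got {yv.shape}")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than terms ({p})")
    names = list(term_names) if term_names is not None else [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("term_names length must match the number of columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        dependent = _collinear_columns(X)
        raise ValueError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(names[j] for j in dependent)
        )
    ols = sm.OLS(yv, X).fit()
    beta = np.asarray(ols.params, dtype=float)
    sigma2 = float(ols.mse_resid)
    cov = np.asarray(ols.cov_params(), dtype=float)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    terms = []
    for j in range(p):
        if se[j] > 0.0:
            w = (beta[j] / se[j]) ** 2
            pj = float(stats.chi2.sf(w, 1))
        else:
            w = math.inf if beta[j] != 0.0 else 0.0
            pj = 0.0 if beta[j] != 0.0 else 1.0
        terms.append(
            TermFit(
                name=names[j],
                B=float(beta[j]),
                SE=float(se[j]),
                wald_chi2=float(w),
                p=pj,
                ci95=(float(beta[j] - _Z95 * se[j]), float(beta[j] + _Z95 * se[j])),
            )
        )

    test_idx = [j for j in range(p) if j != intercept_col]
    model_df = len(test_idx)
    if model_df == 0:
        model_chi2, model_p = 0.0, 1.0
    elif sigma2 > 0.0:
        b = beta[test_idx]
        C = cov[np.ix_(test_idx, test_idx)]
        model_chi2 = float(b @ np.linalg.solve(C, b))
        model_p = float(stats.chi2.sf(model_chi2, model_df))
    else:
        model_chi2, model_p = math.inf, 0.0
    return LinearModelFit(
        terms=tuple(terms),
        model_chi2=model_chi2,
        model_df=model_df,
        model_p=model_p,
        n_obs=n,
    )


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Columns rejected by a greedy rank-building pass (the redundant ones)."""
    kept: list[int] = []
    dependent: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            dependent.append(j)
    return dependent


def ancova_scaling_check(
    ratio: Sequence[float],
    group: Sequence[int],
    mean_finger_length: Sequence[float],
) -> LinearModelFit:
    """Is a digit-ratio group difference an artifact of overall hand size?

    Fits ratio ~ intercept + group + mean finger length.  The group
    term's B is the covariate-adjusted ratio difference; if the raw
    difference were pure allometric scaling, adjusting for finger length
    shrinks B toward zero.
    """
    r = np.asarray(ratio, dtype=float)
    g = np.asarray(group, dtype=float)
    c = np.asarray(mean_finger_length, dtype=float)
    if not (r.shape == g.shape == c.shape) or r.ndim != 1:
        raise ValueError("ratio, group, and covariate must be equal-length vectors")
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"group must be binary with both levels present, got {levels}")
    design = np.column_stack([np.ones_like(r), g, c])
    return fit_linear(
        design, r, term_names=["intercept", "group", "mean_finger_length"]
    )
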