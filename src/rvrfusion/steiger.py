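"""Steiger's test for two dependent correlations sharing one variable.

When two prediction models are scored on the same sample by correlating their
predictions with the same observed variable, the two accuracy correlations
r12 = corr(y, yhat_A) and r13 = corr(y, yhat_B) are themselves dependent
through r23 = corr(yhat_A, yhat_B).  Williams' modification of the
dependent-correlation t test (the form endorsed by Steiger) accounts for
this:

    det R = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23
    rbar  = (r12 + r13) / 2
    t2    = (r12 - r13) sqrt( (n-1)(1+r23) /
              ( 2 (n-1)/(n-3) det R + rbar^2 (1-r23)^3 ) )

with df = n - 3.  ``p_one_sided`` is the upper tail at t2; the upper tail at
|t2| (``p_abs``) and the lower tail are also exposed, since with a signed
statistic the direction being tested must be the caller's choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SteigerInput",
    "SteigerResult",
    "steiger_t",
    "steiger_from_predictions",
    "t_tail_p",
]


@dataclass
class SteigerInput:
    r12: float  # corr(y, prediction A)
    r13: float  # corr(y, prediction B)
    r23: float  # corr(prediction A, prediction B)
    n: int

    def __post_init__(self):
        for name in ("r12", "r13", "r23"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if self.n < 4:
            raise ValueError("need n >= 4 (df = n - 3 >= 1)")

    @property
    def det_r(self) -> float:
        r12, r13, r23 = self.r12, self.r13, self.r23
        return 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23


@dataclass
class SteigerResult:
    t2: float
    df: int
    p_one_sided: float   # P(T_df > t2)

    @property
    def p_lower(self) -> float:
        return 1.0 - self.p_one_sided

    @property
    def p_abs(self) -> float:
        """Upper tail at |t2| — the tail in the direction of the observed sign."""
        return float(stats.t.sf(abs(self.t2), self.df))


def t_tail_p(t: float, df: float) -> float:
    """One-sided upper tail P(T_df > t); monotone decreasing in t."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.sf(t, df))


def steiger_t(inp: SteigerInput) -> SteigerResult:
    """Williams/Steiger t statistic for r12 vs r13 with df = n - 3."""
    n = inp.n
    det = inp.det_r
    if inp.r23 == 1.0 and inp.r12 == inp.r13:
        warnings.warn(
            "predictions perfectly correlated with equal accuracies: "
            "degenerate comparison, t2 = 0",
            RuntimeWarning,
        )
        return SteigerResult(t2=0.0, df=n - 3, p_one_sided=0.5)
    if det <= 0.0 and inp.r12 != inp.r13:
        raise ValueError(
            f"correlation matrix not positive definite (det R = {det:.3g}); "
            "the three correlations are mutually inconsistent"
        )
    rbar = (inp.r12 + inp.r13) / 2.0
    denom = 2.0 * ((n - 1.0) / (n - 3.0)) * max(det, 0.0) + rbar**2 * (1.0 - inp.r23) ** 3
    t2 = (inp.r12 - inp.r13) * np.sqrt((n - 1.0) * (1.0 + inp.r23) / denom)
    return SteigerResult(t2=float(t2), df=n - 3, p_one_sided=t_tail_p(t2, n - 3))


def steiger_from_predictions(y, pred_a, pred_b) -> SteigerResult:
    """Compare two models' accuracy correlations directly from raw vectors.

    Computes r12 = corr(y, pred_a), r13 = corr(y, pred_b),
    r23 = corr(pred_a, pred_b) and applies :func:`steiger_t`, so callers
    cannot mismatch the correlation ordering.
    """
    y = np.asarray(y, dtype=float).ravel()
    a = np.asarray(pred_a, dtype=float).ravel()
    b = np.asarray(pred_b, dtype=float).ravel()
    if not (y.size == a.size == b.size):
        raise ValueError("all three vectors must share one length")
    C = np.corrcoef(np.vstack([y, a, b]))
    return steiger_t(SteigerInput(r12=C[0, 1], r13=C[0, 2], r23=C[1, 2], n=y.size))
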