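"""Nonparametric two-group comparison of per-sample dCt values.

The Mann-Whitney U statistic is reported in the case-over-control
orientation — U counts case–control pairs where the case value is larger,
with half credit for ties — so that U/(n_case·n_control) is exactly the
empirical AUC of the "higher in cases" classification polarity.  Small
tie-free samples (n1+n2 <= 20) get an exact two-sided p-value from the
full permutation null; otherwise a normal approximation with continuity
correction and tie-corrected variance is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError

EXACT_MAX_N = 20


@dataclass
class UTestResult:
    marker: str
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    n_case: int
    n_control: int
    q_value: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def u_statistic(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Case-over-control pair count with half credit for ties."""
    case = np.asarray(case_values, dtype=float)[:, None]
    control = np.asarray(control_values, dtype=float)[None, :]
    return float(np.sum(case > control) + 0.5 * np.sum(case == control))


def mann_whitney_u(
    case_values: Sequence[float],
    control_values: Sequence[float],
    alternative: str = "two-sided",
    marker: str = "",
) -> UTestResult:
    """Two-sided Mann-Whitney U test in the case-over-control orientation."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    n1, n2 = len(case), len(control)
    u = u_statistic(case, control)

    pooled = np.concatenate([case, control])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        warnings.warn("constant pooled data: the test is uninformative, p = 1")
        return UTestResult(marker, u, 1.0, "normal_approx", n1, n2)

    if not has_ties and n1 + n2 <= EXACT_MAX_N:
        res = stats.mannwhitneyu(case, control, alternative=alternative, method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            case, control, alternative=alternative,
            method="asymptotic", use_continuity=True,
        )
        method = "normal_approx"
    p = float(min(res.pvalue, 1.0))
    return UTestResult(marker, u, p, method, n1, n2)


def adjust_pvalues(
    results: Sequence[UTestResult], method: str = "none"
) -> list[UTestResult]:
    """Attach q-values: identity (``none``) or Benjamini-Hochberg step-up."""
    if len(results) == 0:
        raise InsufficientDataError("no results to adjust")
    pvals = [r.p_value for r in results]
    if method == "none":
        qvals = pvals
    elif method == "benjamini_hochberg":
        qvals = multipletests(pvals, method="fdr_bh")[1].tolist()
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return [replace(r, q_value=float(q)) for r, q in zip(results, qvals)]
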