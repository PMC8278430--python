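"""ROC diagnostics and multi-marker logistic panels.

Per-marker empirical ROC curves with trapezoidal AUC (identically
U/(n1·n2) of the Mann-Whitney statistic in the same orientation), DeLong
placement-component variance, logit-scale Wald confidence intervals, and
Youden-optimal operating points.  Markers are combined into a panel by a
maximum-likelihood logistic score — the standard linear construction for a
combined ROC curve — with complete/quasi-separation detection and a mildly
ridge-penalized fallback.  Panel membership is chosen by exhaustive subset
search with a parsimony rule: among subsets whose in-sample AUC is within a
tolerance of the best, the smallest wins.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InsufficientDataError
from .simulate import GROUP_CASE

MAX_EXHAUSTIVE_MARKERS = 16


@dataclass
class RocCurve:
    """Empirical ROC curve: matched FPR/TPR/threshold arrays.

    ``thresholds`` are on the original score scale; the classification rule
    is "score on the case side of the threshold ⇒ positive", where the case
    side is determined by ``polarity``.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    polarity: str  # "higher_is_case" | "lower_is_case"
    n_case: int
    n_control: int


@dataclass
class RocSummary:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    polarity: str
    n_case: int
    n_control: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _as_arrays(scores_case, scores_control) -> tuple[np.ndarray, np.ndarray]:
    case = np.asarray(scores_case, dtype=float)
    control = np.asarray(scores_control, dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    return case, control


def _pairwise_auc(case: np.ndarray, control: np.ndarray) -> float:
    """P(case > control) + ½P(tie) — the Mann-Whitney AUC, higher-is-case."""
    gt = np.sum(case[:, None] > control[None, :])
    eq = np.sum(case[:, None] == control[None, :])
    return float((gt + 0.5 * eq) / (len(case) * len(control)))


def empirical_roc(
    scores_case, scores_control, polarity: str = "auto"
) -> RocCurve:
    """ROC curve over the unique observed thresholds (plus a sentinel).

    ``polarity="auto"`` picks the orientation with AUC >= 0.5 and records
    the choice on the returned curve.
    """
    case, control = _as_arrays(scores_case, scores_control)
    if polarity == "auto":
        polarity = (
            "higher_is_case" if _pairwise_auc(case, control) >= 0.5 else "lower_is_case"
        )
    if polarity not in ("higher_is_case", "lower_is_case"):
        raise ValueError(f"unknown polarity {polarity!r}")
    sign = 1.0 if polarity == "higher_is_case" else -1.0
    y = np.concatenate([np.ones(len(case)), np.zeros(len(control))])
    s = sign * np.concatenate([case, control])
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        thresholds=sign * thr,  # back to the original scale
        polarity=polarity,
        n_case=len(case),
        n_control=len(control),
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the curve (ties get half credit)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def _placements(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components (higher-is-case orientation)."""
    psi = (case[:, None] > control[None, :]).astype(float)
    psi += 0.5 * (case[:, None] == control[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)  # V10 (per case), V01 (per control)


def delong_se(scores_case, scores_control) -> float:
    """DeLong standard error of a single empirical AUC."""
    case, control = _as_arrays(scores_case, scores_control)
    if len(case) < 2 or len(control) < 2:
        raise InsufficientDataError("DeLong variance needs >= 2 samples per group")
    v10, v01 = _placements(case, control)
    var = v10.var(ddof=1) / len(case) + v01.var(ddof=1) / len(control)
    return float(np.sqrt(max(var, 0.0)))


def delong_paired_test(
    scores_a, scores_b, labels
) -> tuple[float, float, float]:
    """Paired DeLong z-test for the AUC difference of two scores measured on
    the same samples.  ``labels`` marks cases (``"case"`` or truthy).

    Returns (delta_auc, z, p); for identical scores the difference and z are
    exactly 0 and p = 1.
    """
    labels = np.asarray(labels)
    is_case = (labels == GROUP_CASE) if labels.dtype.kind in "OSU" else labels.astype(bool)
    a, b = np.asarray(scores_a, dtype=float), np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != is_case.shape:
        raise ValueError("paired test requires both scores on identical samples")
    case_a, ctrl_a = a[is_case], a[~is_case]
    case_b, ctrl_b = b[is_case], b[~is_case]
    if len(case_a) < 2 or len(ctrl_a) < 2:
        raise InsufficientDataError("DeLong variance needs >= 2 samples per group")
    v10a, v01a = _placements(case_a, ctrl_a)
    v10b, v01b = _placements(case_b, ctrl_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(case_a), len(ctrl_a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        z = 0.0 if delta == 0 else np.inf * np.sign(delta)
    else:
        z = delta / np.sqrt(var)
    p = float(min(2 * norm.sf(abs(z)), 1.0)) if np.isfinite(z) else 0.0
    return float(delta), float(z), p


def auc_confidence_interval(
    auc_value: float, se: float, level: float = 0.95, transform: str = "logit_wald"
) -> tuple[float, float]:
    """Wald interval on the logit scale, back-transformed and clipped.

    Asymmetric around the AUC for AUC != 0.5, which matches the shape of
    intervals reported for high-AUC biomarker panels.
    """
    if transform != "logit_wald":
        raise ValueError(f"unknown transform {transform!r}")
    if not 0.0 <= auc_value <= 1.0 or se < 0:
        raise ValueError("need 0 <= auc <= 1 and se >= 0")
    if auc_value in (0.0, 1.0):
        warnings.warn("degenerate AUC at the boundary: returning a zero-width interval")
        return auc_value, auc_value
    if se == 0.0:
        return auc_value, auc_value
    z = norm.ppf(0.5 + level / 2.0)
    center = logit(auc_value)
    spread = z * se / (auc_value * (1.0 - auc_value))  # delta method
    low, high = expit(center - spread), expit(center + spread)
    return float(np.clip(low, 0, 1)), float(np.clip(high, 0, 1))


def youden_cutoff(curve: RocCurve) -> tuple[float, float, float, float]:
    """Operating point maximizing J = sensitivity + specificity − 1.

    Ties are broken in favor of higher sensitivity, then the lower cutoff
    (on the original score scale).

    Returns (cutoff, sensitivity, specificity, j).
    """
    j = curve.tpr - curve.fpr
    best_j = j.max()
    cand = np.flatnonzero(j >= best_j - 1e-12)
    cand = cand[curve.tpr[cand] >= curve.tpr[cand].max() - 1e-12]
    idx = cand[np.argmin(curve.thresholds[cand])]
    return (
        float(curve.thresholds[idx]),
        float(curve.tpr[idx]),
        float(1.0 - curve.fpr[idx]),
        float(j[idx]),
    )


def roc_summary(scores_case, scores_control, polarity: str = "auto") -> RocSummary:
    """One-stop per-score summary: AUC, DeLong SE, logit-Wald CI, Youden
    operating point."""
    curve = empirical_roc(scores_case, scores_control, polarity=polarity)
    a = auc(curve)
    se = delong_se(scores_case, scores_control)
    if a in (0.0, 1.0):
        ci_low = ci_high = a
    else:
        ci_low, ci_high = auc_confidence_interval(a, se)
    cutoff, sens, spec, j = youden_cutoff(curve)
    return RocSummary(
        auc=a, se=se, ci_low=ci_low, ci_high=ci_high,
        cutoff=cutoff, sensitivity=sens, specificity=spec, youden_j=j,
        polarity=curve.polarity, n_case=curve.n_case, n_control=curve.n_control,
    )


# ---------------------------------------------------------------------------
# logistic panel combination


class PanelLogisticClassifier(BaseEstimator, ClassifierMixin):
    """Maximum-likelihood logistic score for a marker panel.

    Fitted by iteratively reweighted least squares (Newton-Raphson).
    Complete or quasi-separation — any |standardized coefficient| > 15, or
    every fitted probability within 1e-6 of its label — sets
    ``separation_`` and triggers a refit with a small ridge penalty on the
    slopes (the intercept stays unpenalized), which keeps the score finite
    while preserving its ranking.

    Parameters
    ----------
    tol : convergence tolerance on the max coefficient update.
    max_iter : Newton iteration cap.
    ridge : slope penalty used in the separation fallback.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100, ridge: float = 1e-4):
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge

    @staticmethod
    def _irls(X: np.ndarray, y: np.ndarray, ridge: float, tol: float, max_iter: int):
        n, p = X.shape
        pen = np.full(p, ridge)
        pen[0] = 0.0  # never penalize the intercept
        beta = np.zeros(p)
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            eta = X @ beta
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            grad = X.T @ (y - mu) - pen * beta
            hess = (X * w[:, None]).T @ X + np.diag(pen)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.pinv(hess) @ grad
            beta = beta + step
            trace.append(float(np.max(np.abs(step))))
            if trace[-1] < tol:
                converged = True
                break
        return beta, converged, trace

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if y.dtype.kind in "OSU":
            y = (y == GROUP_CASE).astype(float)
        else:
            y = y.astype(float)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; drop incomplete samples first")
        Xd = np.column_stack([np.ones(len(y)), X])
        beta, converged, trace = self._irls(Xd, y, 0.0, self.tol, self.max_iter)

        mu = expit(Xd @ beta)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        std_coef = beta[1:] * np.where(sd > 0, sd, 1.0)
        separated = bool(
            np.any(np.abs(std_coef) > 15.0) or np.all(np.abs(mu - y) < 1e-6)
        )
        if separated:
            beta, converged, trace = self._irls(Xd, y, self.ridge, self.tol, self.max_iter)
        elif not converged:
            raise RuntimeError(
                "IRLS failed to converge without separation; "
                f"max-step trace: {np.array2string(np.asarray(trace), precision=3)}"
            )
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.converged_ = bool(converged)
        self.separation_ = separated
        self.n_iter_ = len(trace)
        self.classes_ = np.array([0.0, 1.0])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0.0).astype(float)


@dataclass
class PanelModel:
    """A fitted logistic marker panel and the ROC of its score."""

    markers: list[str]
    intercept: float
    coefficients: dict[str, float]
    converged: bool
    separation: bool
    score: np.ndarray
    labels: np.ndarray
    roc: RocSummary
    n_dropped: int = 0

    def as_dict(self) -> dict:
        d = {
            "markers": list(self.markers),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "converged": self.converged,
            "separation": self.separation,
            "n_dropped": self.n_dropped,
            "roc": self.roc.as_dict(),
        }
        return d


def _panel_matrix(
    marker_matrix: pd.DataFrame, labels, markers: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    X = marker_matrix.loc[:, list(markers)].to_numpy(dtype=float)
    labels = np.asarray(labels)
    is_case = (labels == GROUP_CASE) if labels.dtype.kind in "OSU" else labels.astype(bool)
    complete = ~np.isnan(X).any(axis=1)
    n_dropped = int((~complete).sum())
    return X[complete], is_case[complete].astype(float), n_dropped


def fit_logistic_panel(
    marker_matrix: pd.DataFrame,
    labels,
    markers: Sequence[str] | None = None,
    polarity: str = "auto",
) -> PanelModel:
    """Fit a logistic score on the given markers and summarize its ROC.

    ``marker_matrix`` is samples × markers (dCt values); samples with any
    missing marker are dropped (their count is recorded).
    """
    if markers is None:
        markers = list(marker_matrix.columns)
    markers = list(markers)
    if len(markers) == 0:
        raise InsufficientDataError("panel needs at least one marker")
    X, y, n_dropped = _panel_matrix(marker_matrix, labels, markers)
    clf = PanelLogisticClassifier().fit(X, y)
    score = clf.decision_function(X)
    summary = roc_summary(score[y == 1], score[y == 0], polarity=polarity)
    return PanelModel(
        markers=markers,
        intercept=clf.intercept_,
        coefficients={m: float(c) for m, c in zip(markers, clf.coef_)},
        converged=clf.converged_,
        separation=clf.separation_,
        score=score,
        labels=y,
        roc=summary,
        n_dropped=n_dropped,
    )


def select_panel(
    marker_matrix: pd.DataFrame,
    labels,
    tolerance: float = 0.01,
    mode: str = "exhaustive",
) -> tuple[PanelModel, dict]:
    """Choose the marker subset with the best in-sample panel AUC.

    Every non-empty subset is fitted; among subsets within ``tolerance`` of
    the maximum AUC the smallest subset wins (ties broken by lexicographic
    marker order) — markers that do not improve the combined ROC are
    excluded.  The returned trace records every subset's AUC and, for each
    excluded marker, the AUC change from adding it to the winning panel.

    Selection is in-sample (no cross-validation), so the winning AUC is
    optimistically biased; see the package docs.
    """
    markers = list(marker_matrix.columns)
    if mode != "exhaustive":
        raise ValueError("only exhaustive search is implemented; reduce the marker set")
    if len(markers) == 0:
        raise InsufficientDataError("no markers supplied")
    if len(markers) > MAX_EXHAUSTIVE_MARKERS:
        raise ValueError(
            f"{len(markers)} markers exceed the exhaustive-search cap "
            f"({MAX_EXHAUSTIVE_MARKERS}); pre-filter the panel"
        )

    fits: dict[tuple[str, ...], PanelModel] = {}
    for size in range(1, len(markers) + 1):
        for subset in itertools.combinations(markers, size):
            fits[subset] = fit_logistic_panel(marker_matrix, labels, subset)

    best_auc = max(m.roc.auc for m in fits.values())
    eligible = [s for s, m in fits.items() if m.roc.auc >= best_auc - tolerance]
    chosen = min(eligible, key=lambda s: (len(s), s))
    winner = fits[chosen]

    exclusions = {}
    for m in markers:
        if m in chosen:
            continue
        with_m = tuple(sorted(chosen + (m,), key=markers.index))
        delta = fits[with_m].roc.auc - winner.roc.auc
        exclusions[m] = {
            "delta_auc_vs_selected": float(delta),
            "rationale": (
                f"adding {m} changes the panel AUC by {delta:+.4f}, "
                f"below the {tolerance:g} improvement tolerance"
            ),
        }
    trace = {
        "tolerance": tolerance,
        "subsets": [
            {"markers": list(s), "auc": float(m.roc.auc)} for s, m in fits.items()
        ],
        "best_auc": float(best_auc),
        "selected": list(chosen),
        "excluded": exclusions,
    }
    return winner, trace
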