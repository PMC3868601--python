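"""Quadratic age trends: least-squares mean fits and check-loss quantile fits.

Both models regress subject-level normalized brain volume y on the coded
age band x ∈ {1..5}, with design (1, x, x²) (or (1, x) for degree 1),
unweighted across subjects:

* mean trend — minimizes Σ (y_i − c − b1·x_i − b2·x_i²)², the ordinary
  least-squares conditional-mean model;
* percentile-rank trend — minimizes the check (pinball) loss
  Σ ρ_τ(y_i − c − b1·x_i − b2·x_i²), ρ_τ(u) = u(τ − 1{u<0}), whose
  minimizer estimates the conditional τ-quantile.

The quantile fit is solved as an exact linear program. Because the
covariate takes few distinct values, the check loss separates into one
piecewise-linear convex function per distinct x, and the LP is posed in
epigraph form over those functions: one epigraph variable per distinct
covariate value plus the polynomial coefficients, with one supporting
line per order statistic. This is equivalent to the classical
split-residual primal LP but orders of magnitude smaller in columns,
and the optimum is certified a posteriori by the quantile subgradient
condition.

Residual diagnostics flag the linearity assumption when any age band
shows a significant imbalance of positive versus negative residuals
(two-sided binomial sign test), the assertable analogue of judging
residual plots by eye.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.optimize import linprog

from .cohort_io import GroupedCohort

__all__ = [
    "QuadraticTrend",
    "ResidualGroupSummary",
    "ResidualSummary",
    "QuantileFitError",
    "check_loss",
    "fit_mean_trend",
    "fit_quantile_trend",
    "evaluate_trend",
    "residual_diagnostics",
    "trends_to_frame",
    "frame_to_trends",
    "read_coefficients",
    "write_coefficients",
]


@dataclass(frozen=True)
class QuadraticTrend:
    """y = c + b1·x + b2·x² over the age-group code x.

    ``kind`` is "mean" for a least-squares fit and "rank" for a
    check-loss fit, in which case ``tau`` holds the quantile fraction.
    """

    c: float
    b1: float
    b2: float
    kind: str = "mean"
    tau: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("mean", "rank"):
            raise ValueError(f"kind must be 'mean' or 'rank', got {self.kind!r}")
        if self.kind == "rank":
            if self.tau is None or not 0.0 < self.tau < 1.0:
                raise ValueError("rank trends need tau strictly in (0, 1)")
        elif self.tau is not None:
            raise ValueError("mean trends carry no tau")

    def evaluate(self, code: float) -> float:
        return self.c + self.b1 * code + self.b2 * code * code


def evaluate_trend(trend: QuadraticTrend, code: float) -> float:
    """Trend prediction c + b1·code + b2·code² at an age-group code."""
    return trend.evaluate(code)


class QuantileFitError(RuntimeError):
    """Quantile LP failed to converge or certify optimality.

    Carries the achieved check loss and the subgradient counts so the
    failure is diagnosable.
    """

    def __init__(self, message: str, loss: float | None = None,
                 n_negative: int | None = None, n_nonpositive: int | None = None):
        super().__init__(message)
        self.loss = loss
        self.n_negative = n_negative
        self.n_nonpositive = n_nonpositive


def check_loss(residuals: np.ndarray, tau: float) -> float:
    """Σ ρ_τ(u) with ρ_τ(u) = u·(τ − 1{u<0})."""
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _design(x: np.ndarray, degree: int) -> np.ndarray:
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree}")
    cols = [np.ones_like(x), x]
    if degree == 2:
        cols.append(x * x)
    return np.column_stack(cols)


def _check_identifiable(x: np.ndarray, degree: int) -> None:
    distinct = np.unique(x).size
    if distinct < degree + 1:
        raise ValueError(
            f"degree-{degree} trend needs at least {degree + 1} distinct "
            f"age-group codes; got {distinct}"
        )


def _as_trend(beta: np.ndarray, degree: int, kind: str, tau: Optional[float]) -> QuadraticTrend:
    b2 = float(beta[2]) if degree == 2 else 0.0
    return QuadraticTrend(c=float(beta[0]), b1=float(beta[1]), b2=b2, kind=kind, tau=tau)


def fit_mean_trend(cohort: GroupedCohort, degree: int = 2) -> QuadraticTrend:
    """Unweighted least-squares fit of volume on age-group code.

    One row per subject, so bands contribute proportionally to their
    size. Degree 1 drops the quadratic column (b2 = 0).
    """
    x, y = cohort.design()
    _check_identifiable(x, degree)
    X = _design(x, degree)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return _as_trend(beta, degree, "mean", None)


def fit_quantile_trend(cohort: GroupedCohort, tau: float, degree: int = 2) -> QuadraticTrend:
    """Exact check-loss minimizing fit of the conditional τ-quantile.

    Solved as a condensed epigraph LP (see module docstring) with the
    HiGHS solver. Optimality is certified by the subgradient condition:
    at a minimizer, #{residuals < 0} ≤ τ·n ≤ #{residuals ≤ 0}, with
    slack for the p basic observations that can sit exactly on the fit.
    Raises :class:`QuantileFitError` if the solver fails or the
    certificate does not hold.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau={tau!r} must lie strictly in (0, 1)")
    x, y = cohort.design()
    _check_identifiable(x, degree)
    p = degree + 1

    values = np.unique(x)
    G = len(values)
    n_total = y.size

    # Variables: beta (p, free) then one epigraph level t_g per distinct
    # covariate value (free). Objective: sum of t_g.
    blocks = []
    rhs = []
    for gi, v in enumerate(values):
        ys = np.sort(y[x == v])
        n_g = ys.size
        prefix = np.concatenate([[0.0], np.cumsum(ys)])
        total = prefix[-1]
        k = np.arange(0, n_g + 1, dtype=float)
        # Anchor of segment k: the k-th order statistic (the smallest
        # value for the unbounded left segment k = 0).
        anchor = np.concatenate([[ys[0]], ys])
        ki = np.minimum(np.arange(0, n_g + 1), n_g)
        # Check loss of group g evaluated at each anchor point.
        loss_at_anchor = (1.0 - tau) * (k * anchor - prefix[ki]) + tau * (
            (total - prefix[ki]) - (n_g - k) * anchor
        )
        slope = k - tau * n_g
        # Supporting line: t_g >= loss_at_anchor + slope * (f_g - anchor)
        # with f_g = beta @ (1, v, v^2); as A_ub rows:
        #   slope * f_g - t_g <= slope * anchor - loss_at_anchor
        m = n_g + 1
        A = np.zeros((m, p + G))
        A[:, 0] = slope
        A[:, 1] = slope * v
        if degree == 2:
            A[:, 2] = slope * v * v
        A[:, p + gi] = -1.0
        blocks.append(A)
        rhs.append(slope * anchor - loss_at_anchor)

    A_ub = sp.csr_matrix(np.vstack(blocks))
    b_ub = np.concatenate(rhs)
    c_obj = np.concatenate([np.zeros(p), np.ones(G)])
    res = linprog(
        c_obj,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * (p + G),
        method="highs",
    )
    if res.status != 0:
        raise QuantileFitError(
            f"quantile LP did not converge (tau={tau}, status={res.status}: {res.message})",
            loss=float(res.fun) if res.fun is not None else None,
        )
    beta = res.x[:p]
    trend = _as_trend(beta, degree, "rank", tau)

    # Subgradient certificate.
    fitted = np.array([trend.evaluate(v) for v in x])
    resid = y - fitted
    tol = 1e-8 * max(1.0, float(np.max(np.abs(y))))
    n_neg = int(np.sum(resid < -tol))
    n_nonpos = int(np.sum(resid <= tol))
    target = tau * n_total
    if not (n_neg - p <= target <= n_nonpos + p):
        raise QuantileFitError(
            f"subgradient optimality condition violated at tau={tau}: "
            f"#neg={n_neg}, tau*n={target:.3f}, #nonpos={n_nonpos}",
            loss=check_loss(resid, tau),
            n_negative=n_neg,
            n_nonpositive=n_nonpos,
        )
    return trend


@dataclass(frozen=True)
class ResidualGroupSummary:
    """Residual behaviour of one age band under a fitted trend."""

    code: int
    n: int
    count_positive: int
    count_negative: int
    count_zero: int
    mean_residual: float
    skewness: float
    sign_test_p: float


@dataclass
class ResidualSummary:
    """Per-band residual diagnostics plus the linearity verdict."""

    groups: Dict[int, ResidualGroupSummary]
    linearity_questioned: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(g) for g in (self.groups[c] for c in sorted(self.groups))]
        )


def residual_diagnostics(
    trend: QuadraticTrend,
    cohort: GroupedCohort,
    alpha: float = 0.05,
    zero_tol: float = 1e-12,
) -> ResidualSummary:
    """Actual-minus-predicted residuals summarized per age band.

    For each band: signed counts, mean residual and adjusted
    Fisher–Pearson skewness. The linearity assumption is flagged as
    questioned when any band's positive/negative residual split is
    significant under a two-sided binomial sign test at level ``alpha``
    — the assertable counterpart of spotting systematically skewed
    residual plots.
    """
    groups: Dict[int, ResidualGroupSummary] = {}
    flagged = False
    for code in cohort.codes:
        y = cohort.groups[code]
        resid = y - trend.evaluate(code)
        pos = int(np.sum(resid > zero_tol))
        neg = int(np.sum(resid < -zero_tol))
        zero = int(resid.size - pos - neg)
        # skewness undefined for n < 3 or (near-)constant residuals
        if resid.size >= 3 and np.std(resid) > 1e-14:
            skew = float(stats.skew(resid, bias=False))
        else:
            skew = float("nan")
        if pos + neg > 0:
            p_val = float(stats.binomtest(pos, pos + neg, 0.5).pvalue)
        else:
            p_val = 1.0
        flagged = flagged or p_val < alpha
        groups[code] = ResidualGroupSummary(
            code=code,
            n=int(resid.size),
            count_positive=pos,
            count_negative=neg,
            count_zero=zero,
            mean_residual=float(np.mean(resid)),
            skewness=skew,
            sign_test_p=p_val,
        )
    return ResidualSummary(groups=groups, linearity_questioned=flagged)


# ---------------------------------------------------------------------------
# Coefficient-table serialization (rank, c, beta_x, beta_x2)


def trends_to_frame(
    mean_trend: QuadraticTrend,
    rank_trends: Mapping[float, QuadraticTrend],
) -> pd.DataFrame:
    """Coefficient table with one row for the mean and one per rank."""
    rows = [{"rank": "mean", "c": mean_trend.c, "beta_x": mean_trend.b1,
             "beta_x2": mean_trend.b2}]
    for tau in sorted(rank_trends):
        t = rank_trends[tau]
        rows.append({"rank": f"{tau * 100:g}", "c": t.c, "beta_x": t.b1,
                     "beta_x2": t.b2})
    return pd.DataFrame(rows)


def frame_to_trends(
    frame: pd.DataFrame,
) -> Tuple[QuadraticTrend, Dict[float, QuadraticTrend]]:
    """Inverse of :func:`trends_to_frame`; 'rank' is 'mean' or a percent."""
    mean_trend = None
    rank_trends: Dict[float, QuadraticTrend] = {}
    for _, row in frame.iterrows():
        c, b1, b2 = float(row["c"]), float(row["beta_x"]), float(row["beta_x2"])
        rank = str(row["rank"]).strip().lower()
        if rank == "mean":
            mean_trend = QuadraticTrend(c=c, b1=b1, b2=b2, kind="mean")
        else:
            tau = float(rank) / 100.0
            rank_trends[tau] = QuadraticTrend(c=c, b1=b1, b2=b2, kind="rank", tau=tau)
    if mean_trend is None:
        raise ValueError("coefficient table has no 'mean' row")
    return mean_trend, rank_trends


def read_coefficients(path: str | Path) -> Tuple[QuadraticTrend, Dict[float, QuadraticTrend]]:
    return frame_to_trends(pd.read_csv(path))


def write_coefficients(
    mean_trend: QuadraticTrend,
    rank_trends: Mapping[float, QuadraticTrend],
    path: str | Path,
) -> Path:
    path = Path(path)
    trends_to_frame(mean_trend, rank_trends).to_csv(path, index=False,
                                                    float_format="%.17g")
    return path
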