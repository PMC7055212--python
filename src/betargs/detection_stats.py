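"""Poisson discrimination statistics for probe counts.

With the probe dwelling for ``t_probe`` seconds on a spot, the observed
counts are Poisson with mean mu_T = R_T * t_probe over tumor and
mu_H = R_H * t_probe over healthy tissue. A spot is declared positive
when the counts reach an integer threshold mu_th. The operating
characteristics are the two Poisson tails

    FP = 1 - sum_{N=0}^{mu_th - 1} P_muH(N)      (background flagged)
    FN =     sum_{N=0}^{mu_th - 1} P_muT(N)      (tumor missed)

Raising mu_th at fixed means lowers FP and raises FN. The minimum
probing time is the smallest grid time at which a threshold exists with
FP <= 1% and FN < 5%; the discriminating power at a fixed dwell time is
summarized by the ROC curve over integer thresholds and its AUC, with
patients labeled Good when AUC exceeds 0.95.

Tail sums are evaluated through the regularized incomplete-gamma
relation (scipy's Poisson distribution), stable at large means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .probe_mc import RatePrediction

DEFAULT_FN_MAX = 0.05
DEFAULT_FP_MAX = 0.01
DEFAULT_ROC_T_PROBE = 3.0
DEFAULT_AUC_THRESHOLD = 0.95


def default_time_grid() -> np.ndarray:
    """Probing-time grid: 0.1 s to 60 s in 0.1 s steps."""
    return np.round(np.arange(1, 601) * 0.1, 10)


@dataclass(frozen=True)
class CountModel:
    """Expected Poisson counts for one dwell of the probe."""

    mu_tumor: float
    mu_healthy: float
    t_probe: float

    @classmethod
    def from_rates(cls, rates: RatePrediction, t_probe: float) -> "CountModel":
        return cls(mu_tumor=rates.rate_tumor * t_probe,
                   mu_healthy=rates.rate_healthy * t_probe,
                   t_probe=t_probe)


@dataclass(frozen=True)
class DetectionPlan:
    """Operating point from the minimum-probing-time search."""

    t_min: float  # seconds; nan when infeasible
    mu_th: int
    fn: float
    fp: float
    feasible: bool


@dataclass(frozen=True)
class RocCurve:
    """Discrete ROC over integer count thresholds, with trapezoidal AUC."""

    points: tuple[tuple[float, float], ...]  # (FPR, TPR), th ascending
    auc: float
    t_probe: float
    label: str = field(default="")

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValueError("AUC must be in [0, 1]")


def _check_threshold(mu_th) -> int:
    if mu_th < 0 or int(mu_th) != mu_th:
        raise ValueError(f"threshold must be a non-negative integer, got {mu_th}")
    return int(mu_th)


def fp_rate(mu_healthy: float, mu_th: int) -> float:
    """Probability that background counts reach the threshold (upper tail).

    The empty sum at mu_th = 0 gives FP = 1 (everything flagged positive).
    """
    mu_th = _check_threshold(mu_th)
    if mu_healthy < 0:
        raise ValueError("mean must be non-negative")
    if mu_th == 0:
        return 1.0
    return float(stats.poisson.sf(mu_th - 1, mu_healthy))


def fn_rate(mu_tumor: float, mu_th: int) -> float:
    """Probability that tumor counts fall below the threshold (lower tail)."""
    mu_th = _check_threshold(mu_th)
    if mu_tumor < 0:
        raise ValueError("mean must be non-negative")
    if mu_th == 0:
        return 0.0
    return float(stats.poisson.cdf(mu_th - 1, mu_tumor))


def _smallest_threshold_for_fp(mu_healthy: float, fp_max: float) -> int:
    """Smallest integer mu_th >= 1 with fp_rate(mu_healthy, mu_th) <= fp_max."""
    # ppf gives the right neighborhood; verify locally because of edge ties
    guess = int(stats.poisson.ppf(1.0 - fp_max, mu_healthy)) if mu_healthy > 0 else 0
    k = max(guess, 1)
    while fp_rate(mu_healthy, k) > fp_max:
        k += 1
    while k > 1 and fp_rate(mu_healthy, k - 1) <= fp_max:
        k -= 1
    return k


def min_probing_time(rates: RatePrediction,
                     fn_max: float = DEFAULT_FN_MAX,
                     fp_max: float = DEFAULT_FP_MAX,
                     grid: np.ndarray | None = None) -> DetectionPlan:
    """Grid search for the minimum probing time.

    Scans the time grid in ascending order; at each time the count threshold
    is the smallest integer keeping FP <= ``fp_max``, and the first time at
    which additionally FN < ``fn_max`` is returned with its achieved
    operating point. The approximate false-positive criterion is read as an
    upper bound, which makes the search deterministic.
    """
    if grid is None:
        grid = default_time_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty probing-time grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("probing-time grid must be strictly ascending")

    for t in grid:
        mu_t = rates.rate_tumor * t
        mu_h = rates.rate_healthy * t
        mu_th = _smallest_threshold_for_fp(mu_h, fp_max)
        fn = fn_rate(mu_t, mu_th)
        if fn < fn_max:
            return DetectionPlan(t_min=float(t), mu_th=mu_th, fn=fn,
                                 fp=fp_rate(mu_h, mu_th), feasible=True)
    return DetectionPlan(t_min=float("nan"), mu_th=0, fn=1.0, fp=1.0,
                         feasible=False)


def _tail_cutoff(mu: float) -> int:
    """Threshold beyond which both Poisson tails are < 1e-9."""
    return int(np.ceil(mu + 10.0 * np.sqrt(mu) + 20.0))


def roc_curve(rates: RatePrediction,
              t_probe: float = DEFAULT_ROC_T_PROBE,
              auc_threshold: float = DEFAULT_AUC_THRESHOLD) -> RocCurve:
    """ROC of tumor-vs-healthy discrimination at a fixed probing time.

    For integer thresholds th = 0 ... N_max, a spot is positive when counts
    >= th, giving TPR(th) = P(X >= th | mu_T) and FPR(th) = P(X >= th | mu_H).
    The points run from (1, 1) at th = 0 down to (0, 0); AUC is the
    trapezoidal area over the ordered points. The curve is labeled per
    :func:`classify_patient`.
    """
    if t_probe <= 0:
        raise ValueError("probing time must be positive")
    mu_t = rates.rate_tumor * t_probe
    mu_h = rates.rate_healthy * t_probe
    n_max = max(_tail_cutoff(mu_t), _tail_cutoff(mu_h))
    th = np.arange(0, n_max + 1)
    tpr = stats.poisson.sf(th - 1, mu_t)
    fpr = stats.poisson.sf(th - 1, mu_h)
    # ensure closed endpoints (0,0) and (1,1)
    fpr = np.concatenate([[1.0], fpr, [0.0]])
    tpr = np.concatenate([[1.0], tpr, [0.0]])
    order = np.argsort(fpr)
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    points = tuple(zip(fpr[1:-1].tolist(), tpr[1:-1].tolist()))
    curve = RocCurve(points=points, auc=auc, t_probe=t_probe)
    return RocCurve(points=points, auc=auc, t_probe=t_probe,
                    label=classify_patient(curve, auc_threshold))


def classify_patient(roc: RocCurve,
                     auc_threshold: float = DEFAULT_AUC_THRESHOLD) -> str:
    """'Good' iff AUC strictly exceeds the threshold, else 'Bad'."""
    return "Good" if roc.auc > auc_threshold else "Bad"


def auc_mann_whitney(mu_tumor: float, mu_healthy: float) -> float:
    """Exact AUC as P(X > Y) + P(X = Y)/2 for independent Poisson X, Y.

    Direct double summation over the probability mass; intended for
    moderate means (<= ~50) where the sums are short. Serves as the
    independent cross-check of the trapezoidal ROC area.
    """
    nx = _tail_cutoff(mu_tumor)
    ny = _tail_cutoff(mu_healthy)
    px = stats.poisson.pmf(np.arange(nx + 1), mu_tumor)
    py = stats.poisson.pmf(np.arange(ny + 1), mu_healthy)
    cum_y = np.cumsum(py)
    # P(X > Y) = sum_x px[x] * P(Y <= x - 1)
    idx = np.minimum(np.arange(0, nx), ny)
    p_greater = float(np.sum(px[1:] * cum_y[idx]))
    m = min(nx, ny)
    p_equal = float(np.sum(px[: m + 1] * py[: m + 1]))
    return float(p_greater + 0.5 * p_equal)
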