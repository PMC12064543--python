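"""Survival and discrimination metrics for DM risk models.

Implements the full evaluation battery used on distant-metastasis-free
survival (DMFS, months from surgery): rank-based ROC AUC with the DeLong
test for correlated AUCs, Harrell's concordance index, the
inverse-probability-of-censoring-weighted (IPCW) Brier score and its
time integral, cumulative/dynamic time-dependent AUC, equal-frequency
calibration points, decision-curve net benefit, an outcome-driven
optimal risk cutoff (log-rank maximizing, X-tile style), and
Kaplan-Meier curves with log-rank tests (via lifelines).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "roc_auc",
    "delong_compare",
    "harrell_c",
    "censoring_survival",
    "integrated_brier",
    "time_dependent_auc",
    "decision_curve",
    "calibration_points",
    "optimal_cutoff",
    "km_logrank",
    "EvaluationReport",
    "evaluate_model",
]


def _check_binary(labels: np.ndarray) -> None:
    u = set(np.unique(labels))
    if not u <= {0, 1} or len(u) != 2:
        raise ValueError("labels must contain both classes coded 0/1")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie correction."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_binary(y)
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (cases) and V01 (controls) for one marker."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def delong_compare(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """DeLong test for two correlated AUCs on paired subjects.

    Returns (AUC_A - AUC_B, standard error, two-sided p).  Identical score
    vectors give a difference of 0 with p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(a) != len(b) or len(a) != len(y):
        raise ValueError("scores_a, scores_b and labels must have equal length")
    _check_binary(y)
    auc_a, v10a, v01a = _delong_components(a, y)
    auc_b, v10b, v01b = _delong_components(b, y)
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / len(v10a)
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / len(v01a)
    )
    diff = auc_a - auc_b
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = 2.0 * stats.norm.sf(abs(diff) / se)
    return float(diff), se, float(p)


# ---------------------------------------------------------------------------
# concordance


def harrell_c(
    time: Sequence[float], event: Sequence[int], risk: Sequence[float]
) -> float:
    """Harrell's C under right censoring.

    A pair is comparable when the earlier of the two times is an observed
    event; it is concordant when the higher risk belongs to the earlier
    failure, and risk ties count one half.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    r = np.asarray(risk, dtype=float)
    conc = 0.0
    comp = 0
    n = len(t)
    for i in range(n):
        if e[i] != 1:
            continue
        later = t > t[i]
        comp += int(later.sum())
        conc += float((r[later] < r[i]).sum()) + 0.5 * float((r[later] == r[i]).sum())
    if comp == 0:
        raise ValueError("no comparable pairs")
    return float(conc / comp)


# ---------------------------------------------------------------------------
# IPCW machinery


def censoring_survival(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier estimate G(t) of the censoring distribution.

    Returns a step function evaluator; ``G(t-)`` is available via
    ``left=True``.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - event)
    times = kmf.survival_function_.index.to_numpy()
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()

    def g(at: np.ndarray, left: bool = False) -> np.ndarray:
        at = np.atleast_1d(np.asarray(at, dtype=float))
        if left:
            idx = np.searchsorted(times, at, side="left") - 1
        else:
            idx = np.searchsorted(times, at, side="right") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
        return out

    return g


def brier_score(
    time: np.ndarray,
    event: np.ndarray,
    surv_prob: np.ndarray,
    t: float,
) -> float:
    """IPCW Brier score of predicted survival probabilities at time t."""
    t_arr = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    s = np.asarray(surv_prob, dtype=float)
    g = censoring_survival(t_arr, e)
    died = (t_arr <= t) & (e == 1)
    alive = t_arr > t
    w_died = np.where(died, 1.0 / np.maximum(g(t_arr, left=True), 1e-12), 0.0)
    w_alive = np.where(alive, 1.0 / np.maximum(g(np.full_like(t_arr, t)), 1e-12), 0.0)
    contrib = died * (s**2) * w_died + alive * ((1.0 - s) ** 2) * w_alive
    return float(contrib.mean())


def integrated_brier(
    time: Sequence[float],
    event: Sequence[int],
    surv_matrix: np.ndarray,
    t_grid: Sequence[float],
) -> float:
    """Integrated Brier score over [0, t_max], normalized by t_max.

    ``surv_matrix`` holds each subject's predicted survival function
    evaluated on ``t_grid`` (subjects x grid).  Brier(t) uses IPCW weights
    from the censoring Kaplan-Meier; the integral is trapezoidal from 0
    (where Brier is 0 by convention) through the grid.
    """
    t_arr = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    grid = np.asarray(t_grid, dtype=float)
    S = np.asarray(surv_matrix, dtype=float)
    if S.shape != (len(t_arr), len(grid)):
        raise ValueError("surv_matrix must be (subjects x len(t_grid))")
    if grid.max() > t_arr.max():
        raise ValueError("t_grid extends beyond the last observed time")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("t_grid must be positive and strictly increasing")
    bs = np.array([
        brier_score(t_arr, e, S[:, j], grid[j]) for j in range(len(grid))
    ])
    # extend left-constant to t=0 so the normalization covers [0, t_max]
    full_grid = np.concatenate([[0.0], grid])
    full_bs = np.concatenate([[bs[0]], bs])
    return float(np.trapezoid(full_bs, full_grid) / grid.max())


def time_dependent_auc(
    time: Sequence[float],
    event: Sequence[int],
    scores: Sequence[float],
    t: float,
) -> float:
    """Cumulative/dynamic AUC(t) with IPCW case weights.

    Cases are subjects with an observed event by ``t``; controls are those
    still at risk after ``t``.  Case weights are 1/G(T_i-); the shared
    control weight cancels.
    """
    t_arr = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    s = np.asarray(scores, dtype=float)
    cases = (t_arr <= t) & (e == 1)
    controls = t_arr > t
    if not cases.any() or not controls.any():
        raise ValueError(f"need at least one case and one control at t={t}")
    g = censoring_survival(t_arr, e)
    w = 1.0 / np.maximum(g(t_arr[cases], left=True), 1e-12)
    sc, sn = s[cases], s[controls]
    # weighted Mann-Whitney with midrank ties
    wins = (sc[:, None] > sn[None, :]).astype(float)
    ties = (sc[:, None] == sn[None, :]).astype(float)
    num = float((w[:, None] * (wins + 0.5 * ties)).sum())
    den = float(w.sum() * len(sn))
    return num / den


# ---------------------------------------------------------------------------
# decision curves, calibration


def decision_curve(
    probabilities: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Net benefit of acting on the model at each risk threshold.

    ``NB(p) = TP/N - (FP/N) * p/(1-p)``; reference curves for treat-all
    and treat-none are returned alongside.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    th = np.asarray(thresholds, dtype=float)
    if np.any((th <= 0) | (th >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for t in th:
        treat = p >= t
        tp = int((treat & (y == 1)).sum())
        fp = int((treat & (y == 0)).sum())
        odds = t / (1.0 - t)
        rows.append({
            "threshold": t,
            "net_benefit": tp / n - fp / n * odds,
            "treat_all": prev - (1.0 - prev) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def calibration_points(
    probabilities: Sequence[float], labels: Sequence[int], n_bins: int = 10
) -> pd.DataFrame:
    """Equal-frequency calibration: mean prediction vs event rate per bin.

    The effective bin count is ``min(n_bins, number of distinct
    probabilities)`` so bins are never empty.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    n_eff = min(n_bins, len(np.unique(p)))
    order = np.argsort(p, kind="stable")
    chunks = np.array_split(order, n_eff)
    rows = [
        {"mean_predicted": float(p[c].mean()),
         "observed_fraction": float(y[c].mean()),
         "n": len(c)}
        for c in chunks if len(c)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cutoff and Kaplan-Meier


def _logrank_chi2(time, event, groups) -> tuple[float, float]:
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


def optimal_cutoff(
    risk: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    min_group_frac: float = 0.1,
) -> float:
    """Outcome-driven risk cutoff: maximize the two-group log-rank statistic.

    Candidate cutoffs are the observed score values; a candidate is
    admissible when both resulting groups hold at least ``min_group_frac``
    of the subjects.  Ties in the statistic break toward the lowest
    cutoff.  Subjects with ``risk > cutoff`` form the high-risk group.
    """
    r = np.asarray(risk, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    n = len(r)
    candidates = np.unique(r)
    best_c, best_stat = None, -np.inf
    for c in candidates:
        high = r > c
        k = int(high.sum())
        if k < min_group_frac * n or (n - k) < min_group_frac * n:
            continue
        stat, _ = _logrank_chi2(t, e, high.astype(int))
        if stat > best_stat + 1e-12:
            best_c, best_stat = float(c), stat
    if best_c is None:
        raise ValueError(
            "no admissible cutoff: scores too concentrated for "
            f"min_group_frac={min_group_frac}"
        )
    return best_c


@dataclasses.dataclass
class KMLogrankResult:
    curves: dict[object, pd.DataFrame]   # group -> KM step function table
    chi2: float
    p_value: float


def km_logrank(
    time: Sequence[float], event: Sequence[int], groups: Sequence
) -> KMLogrankResult:
    """Kaplan-Meier curves per group plus the log-rank test across groups."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    g = np.asarray(groups)
    uniq = pd.unique(g)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    curves: dict[object, pd.DataFrame] = {}
    for lev in uniq:
        sel = g == lev
        if not sel.any():
            raise ValueError(f"group {lev!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], event_observed=e[sel])
        df = kmf.survival_function_.rename(columns={kmf._label: "survival"})
        df["at_risk"] = [
            int((t[sel] >= u).sum()) for u in df.index.to_numpy()
        ]
        curves[lev] = df
    chi2, p = _logrank_chi2(t, e, g)
    return KMLogrankResult(curves=curves, chi2=chi2, p_value=p)


# ---------------------------------------------------------------------------
# report


@dataclasses.dataclass
class EvaluationReport:
    """Table-3-style summary of one model on one cohort split."""

    split: str
    auc: float
    c_index: float
    ibs: float
    auc_t: dict[float, float]
    calibration: pd.DataFrame
    decision: pd.DataFrame
    cutoff: float | None
    logrank_chi2: float | None
    logrank_p: float | None

    def to_dict(self) -> dict:
        return {
            "split": self.split,
            "auc": self.auc,
            "c_index": self.c_index,
            "ibs": self.ibs,
            "auc_t": {str(k): v for k, v in self.auc_t.items()},
            "cutoff": self.cutoff,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
        }


def evaluate_model(
    risk: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    timepoints: Sequence[float] = (12.0, 24.0, 36.0),
    split: str = "validation",
    cutoff: float | None = None,
    dca_thresholds: Sequence[float] | None = None,
) -> EvaluationReport:
    """One-call evaluation of a risk score against DMFS outcomes.

    The binary AUC treats observed events as cases.  Predicted survival
    for the Brier integral maps the risk score through an exponential
    forecast calibrated to the cohort event rate, which keeps the report
    self-contained when the model emits only a scalar risk.  A cutoff may
    be supplied (for example, learned on the training split); otherwise it
    is searched here.
    """
    r = np.asarray(risk, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    auc = roc_auc(r, e)
    c = harrell_c(t, e, r)
    horizon = float(np.quantile(t, 0.8))
    grid_all = np.unique(t[(e == 1) & (t <= horizon)])
    grid = grid_all if len(grid_all) else np.array([np.median(t)])
    # scalar risk -> exponential survival forecast, rate proportional to
    # risk and calibrated to the cohort's crude event rate
    lam0 = max(e.sum(), 1) / t.sum()
    clip = np.clip(r, 1e-6, 1 - 1e-6)
    lam = lam0 * clip / clip.mean()
    S = np.exp(-np.outer(lam, grid))
    ibs = integrated_brier(t, e, S, grid)
    auc_t = {}
    for tp in timepoints:
        try:
            auc_t[float(tp)] = time_dependent_auc(t, e, r, float(tp))
        except ValueError:
            auc_t[float(tp)] = float("nan")
    calib = calibration_points(clip, e, n_bins=min(10, len(r) // 5 or 2))
    if dca_thresholds is None:
        dca_thresholds = np.arange(0.2, 0.91, 0.05)
    dca = decision_curve(clip, e, dca_thresholds)
    chi2 = p = None
    if cutoff is None:
        try:
            cutoff = optimal_cutoff(r, t, e)
        except ValueError:
            cutoff = None
    if cutoff is not None:
        high = (r > cutoff).astype(int)
        if len(np.unique(high)) == 2:
            res = km_logrank(t, e, high)
            chi2, p = res.chi2, res.p_value
    return EvaluationReport(
        split=split, auc=auc, c_index=c, ibs=ibs, auc_t=auc_t,
        calibration=calib, decision=dca, cutoff=cutoff,
        logrank_chi2=chi2, logrank_p=p,
    )
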