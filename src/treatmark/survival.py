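"""Kaplan-Meier estimation and single-covariate Cox proportional hazards.

The Cox model here is deliberately minimal: one binary (or real) covariate,
Efron handling of tied event times, Newton iteration with step-halving,
two-sided Wald p-value, and a score-test (log-rank) fallback when the
partial likelihood is monotone (e.g. complete separation of event times).
Censored observations remain at risk at their own time (standard
convention: censoring at an event time happens "just after" the event).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_MAX_ITER = 50
_TOL = 1e-9
_BETA_DIVERGED = 20.0


@dataclass(frozen=True)
class SurvivalObservation:
    case_id: str
    time: float  # positive, years
    event: int   # 1 death observed, 0 censored
    group: int   # binary covariate

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class KMCurve:
    event_times: np.ndarray     # distinct event times, increasing
    survival_prob: np.ndarray   # S(t) after each event time, non-increasing
    at_risk: np.ndarray         # number at risk just before each event time


@dataclass
class CoxResult:
    coefficient: float
    se: float
    p_value: float
    converged: bool
    valid: bool = True


def _unpack(observations):
    obs = list(observations)
    t = np.array([o.time for o in obs], dtype=float)
    e = np.array([o.event for o in obs], dtype=int)
    g = np.array([o.group for o in obs], dtype=float)
    return t, e, g


def km_estimate(observations) -> KMCurve:
    """Product-limit estimator over the distinct event times."""
    obs = list(observations)
    if not obs:
        raise ValueError("km_estimate needs at least one observation")
    t, e, _ = _unpack(obs)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv, at_risk = [], []
    s = 1.0
    for et in event_times:
        n_i = int(np.sum(t >= et))
        d_i = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
    return KMCurve(event_times=event_times,
                   survival_prob=np.array(surv),
                   at_risk=np.array(at_risk, dtype=int))


def km_table(curve: KMCurve, group: int | None = None) -> pd.DataFrame:
    """Exportable TSV form of a KM curve (time, survival, at_risk[, group])."""
    df = pd.DataFrame({"time": curve.event_times,
                       "survival": curve.survival_prob,
                       "at_risk": curve.at_risk})
    if group is not None:
        df["group"] = group
    return df


def _efron_derivatives(beta: float, t: np.ndarray, e: np.ndarray, x: np.ndarray):
    """Efron partial log-likelihood, score and information at ``beta``.

    Observations are processed by distinct event time; within a tied death
    set of size d the death-set averages are removed in d graded steps.
    Risk-set sums are suffix cumulative sums over the time-sorted arrays.
    """
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    w = np.exp(beta * x)
    wx = w * x
    wx2 = w * x * x
    # suffix sums: risk set at time t[i] = observations i..n-1
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1])[::-1]
    s2 = np.cumsum(wx2[::-1])[::-1]

    et = t[e == 1]
    if et.size == 0:
        return 0.0, 0.0, 0.0
    uniq, first_any = np.unique(et, return_index=True)
    # index of the first observation with time >= each unique event time
    i0 = np.searchsorted(t, uniq, side="left")
    r0, r1, r2 = s0[i0], s1[i0], s2[i0]
    # per-unique-event-time sums over the tied deaths
    ev = np.flatnonzero(e == 1)
    grp = np.searchsorted(uniq, t[ev])
    d = np.bincount(grp, minlength=uniq.size).astype(float)
    d0 = np.bincount(grp, weights=w[ev], minlength=uniq.size)
    d1 = np.bincount(grp, weights=wx[ev], minlength=uniq.size)
    d2 = np.bincount(grp, weights=wx2[ev], minlength=uniq.size)
    s = np.bincount(grp, weights=x[ev], minlength=uniq.size)

    ll = beta * s.sum()
    score = s.sum()
    info = 0.0
    single = d == 1
    if np.any(single):
        phi0, phi1, phi2 = r0[single], r1[single], r2[single]
        m = phi1 / phi0
        ll -= np.log(phi0).sum()
        score -= m.sum()
        info += (phi2 / phi0 - m * m).sum()
    for k in np.flatnonzero(~single):
        dk = d[k]
        for l in range(int(dk)):
            f = l / dk
            phi0 = r0[k] - f * d0[k]
            phi1 = r1[k] - f * d1[k]
            phi2 = r2[k] - f * d2[k]
            ll -= np.log(phi0)
            m = phi1 / phi0
            score -= m
            info += phi2 / phi0 - m * m
    return float(ll), float(score), float(info)


def cox_group_p(observations) -> CoxResult:
    """Fit the one-covariate Cox model and test the group coefficient.

    Returns the two-sided Wald p-value; when the Newton iteration fails to
    converge (monotone likelihood) the coefficient is reported as fit but
    the p-value comes from the score statistic at beta = 0, which for a
    binary covariate is the log-rank test.
    """
    obs = list(observations)
    t, e, x = _unpack(obs)
    groups = np.unique(x)
    if len(groups) < 2:
        return CoxResult(np.nan, np.nan, np.nan, converged=False, valid=False)
    if e.sum() == 0:
        return CoxResult(np.nan, np.nan, np.nan, converged=False, valid=False)

    beta = 0.0
    ll, score, info = _efron_derivatives(beta, t, e, x)
    score0, info0 = score, info
    converged = False
    for _ in range(_MAX_ITER):
        if info <= 0:
            break
        step = score / info
        # step-halving on likelihood decrease
        new_beta = beta + step
        new_ll, new_score, new_info = _efron_derivatives(new_beta, t, e, x)
        n_half = 0
        while new_ll < ll - 1e-12 and n_half < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _efron_derivatives(new_beta, t, e, x)
            n_half += 1
        delta = abs(new_beta - beta)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > _BETA_DIVERGED:
            break
        if delta < _TOL:
            converged = True
            break

    if converged and info > 0:
        se = 1.0 / np.sqrt(info)
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        return CoxResult(float(beta), float(se), float(p), converged=True)
    # score (log-rank) fallback
    if info0 > 0:
        chi2 = score0 * score0 / info0
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        p = 1.0
    return CoxResult(float(beta), np.nan, p, converged=False)


def cox_score_test(observations) -> tuple[float, float]:
    """Score statistic and p-value at beta = 0 (the log-rank test for a
    binary covariate without ties)."""
    t, e, x = _unpack(list(observations))
    _, score0, info0 = _efron_derivatives(0.0, t, e, x)
    if info0 <= 0:
        return 0.0, 1.0
    chi2 = score0 * score0 / info0
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def make_observations(patients, ids, group_of: dict[str, int]) -> list[SurvivalObservation]:
    """Build observations for the given case ids.

    ``patients`` maps case_id -> PatientRecord; alive patients are censored
    at years-to-last-followup, dead patients are events at survival time.
    Non-positive times cannot enter the risk sets and are dropped with a
    warning.
    """
    obs = []
    n_dropped = 0
    for cid in ids:
        p = patients[cid]
        if p.time_years <= 0:
            n_dropped += 1
            continue
        obs.append(SurvivalObservation(
            case_id=cid, time=p.time_years,
            event=1 if p.vital_status == "dead" else 0,
            group=group_of[cid]))
    if n_dropped:
        logger.warning("dropped %d observations with non-positive time", n_dropped)
    return obs
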