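"""Censored-survival numerics.

The training objective is the Cox negative log partial likelihood over bag
risk scores O_i,

    L = -sum_i delta_i * ( O_i - log sum_{j : t_j >= t_i} exp(O_j) ),

with Breslow handling of tied event times (the risk set for subject i is
every subject with observed time >= t_i, including i).  Evaluation uses
Harrell's concordance index, median-threshold risk stratification, the
Kaplan-Meier product-limit estimator and the two-group log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RiskScore",
    "KMCurve",
    "cox_loss",
    "cox_loss_gradient",
    "concordance_index",
    "stratify_by_median",
    "kaplan_meier",
    "logrank_test",
]


@dataclass
class RiskScore:
    """Predicted risk O_i for one bag; higher risk = shorter predicted survival."""

    bag_id: str
    risk: float

    def __post_init__(self) -> None:
        self.risk = float(self.risk)
        if not np.isfinite(self.risk):
            raise ValueError(f"bag {self.bag_id!r}: non-finite risk")


@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.survival_probs = np.asarray(self.survival_probs, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=int)


def _as_arrays(risks, times, events):
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if risks.size == 0:
        raise ValueError("empty input")
    if not (risks.shape == times.shape == events.shape):
        raise ValueError("risks, times, events must have equal length")
    return risks, times, events


def cox_loss(risks, times, events, normalize: bool = False) -> float:
    """Cox negative log partial likelihood of the risk scores.

    With ``normalize=True`` the sum is divided by the number of events,
    which keeps magnitudes comparable across batch sizes during training;
    the default is the plain (unnormalized) likelihood.

    All-censored input carries no likelihood terms; it returns exactly 0.0
    with a warning.  Stabilized with a max-shifted log-sum-exp so scores up
    to |O| ~ 1e3 do not overflow.
    """
    risks, times, events = _as_arrays(risks, times, events)
    n_events = int(events.sum())
    if n_events == 0:
        warnings.warn("cox_loss: all subjects censored; loss is 0", stacklevel=2)
        return 0.0
    # sort descending by time so risk sets are prefixes of the sorted order
    order = np.argsort(-times, kind="stable")
    r, t, e = risks[order], times[order], events[order]
    shift = r.max()
    cum = np.logaddexp.accumulate(r - shift) + shift  # log sum exp over {t_j >= t_i}
    # ties: every subject with equal time belongs to the same (Breslow) risk set
    _, inv = np.unique(-t, return_inverse=True)
    last_of_group = np.searchsorted(inv, inv, side="right") - 1
    log_risk_set = cum[last_of_group]
    loss = -float(np.sum(e * (r - log_risk_set)))
    return loss / n_events if normalize else loss


def cox_loss_gradient(risks, times, events, normalize: bool = False) -> np.ndarray:
    """Analytic gradient of :func:`cox_loss` with respect to each risk score.

    d L / d O_i = -delta_i + exp(O_i) * sum_{k : t_i >= t_k, delta_k = 1}
    1 / (sum_{l : t_l >= t_k} exp(O_l)).
    """
    risks, times, events = _as_arrays(risks, times, events)
    n_events = int(events.sum())
    if n_events == 0:
        return np.zeros_like(risks)
    order = np.argsort(-times, kind="stable")
    r, t, e = risks[order], times[order], events[order]
    shift = r.max()
    exp_r = np.exp(r - shift)
    cum = np.cumsum(exp_r)
    _, inv = np.unique(-t, return_inverse=True)
    last_of_group = np.searchsorted(inv, inv, side="right") - 1
    denom = cum[last_of_group]  # risk-set sums, shifted scale
    # each event k contributes exp(O_i)/denom_k to every i in its risk set,
    # i.e. to every i with position <= last position of k's time group
    contrib = e / denom
    # subject at sorted position p is in risk set of event k iff p <= last_of_group[k]
    # reverse-cumulative sum of contrib over positions gives per-position factor
    w = np.zeros_like(r)
    np.add.at(w, last_of_group, contrib)  # place each event's weight at group end
    factor = np.cumsum(w[::-1])[::-1]
    grad_sorted = -e + exp_r * factor
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return grad / n_events if normalize else grad


def concordance_index(risks, times, events) -> float:
    """Harrell's concordance index.

    Comparable pairs are (i, j) with t_i < t_j and delta_i = 1 (pairs with
    tied times are not comparable).  A pair is concordant when the
    earlier-event subject has the higher risk; tied risks count 0.5.
    Raises ``ValueError`` when no comparable pair exists.
    """
    risks, times, events = _as_arrays(risks, times, events)
    ti = times[:, None]
    comparable = (ti < times[None, :]) & (events[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pair: concordance index undefined")
    ri = risks[:, None]
    conc = np.sum(comparable & (ri > risks[None, :]))
    ties = np.sum(comparable & (ri == risks[None, :]))
    return float((conc + 0.5 * ties) / n_pairs)


def stratify_by_median(train_risks, eval_risks) -> np.ndarray:
    """Label evaluation bags high-risk (1) / low-risk (0) at the training median.

    The threshold is the median of the *training* risks (midpoint of the two
    central order statistics for even counts); an evaluation risk >= the
    threshold is high-risk.  Accepts sequences of floats or RiskScore.
    """

    def _values(xs):
        return np.asarray(
            [x.risk if isinstance(x, RiskScore) else float(x) for x in xs], dtype=float
        )

    train = _values(train_risks)
    if train.size == 0:
        raise ValueError("empty training risks")
    threshold = float(np.median(train))
    return (_values(eval_risks) >= threshold).astype(int)


def kaplan_meier(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Survival drops only at observed event times; censored subjects leave the
    risk set after their time (at tied times, events are processed before
    censorings, the standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    uniq = np.unique(times[events == 1])
    ev_times, probs, at_risk = [], [], []
    s = 1.0
    for t in uniq:
        n_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_risk
        ev_times.append(t)
        probs.append(s)
        at_risk.append(n_risk)
    return KMCurve(np.array(ev_times), np.array(probs), np.array(at_risk))


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Observed-minus-expected events are accumulated over the pooled distinct
    event times; the statistic is chi-square with 1 degree of freedom and is
    invariant to swapping the group labels.  Raises ``ValueError`` when the
    pooled sample has no events.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled_t = np.concatenate([ta, tb])
    pooled_e = np.concatenate([ea, eb])
    if pooled_e.sum() == 0:
        raise ValueError("no events: log-rank test undefined")
    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(pooled_t[pooled_e == 1]):
        n1 = np.sum(ta >= t)
        n2 = np.sum(tb >= t)
        n = n1 + n2
        d1 = np.sum((ta == t) & (ea == 1))
        d = d1 + np.sum((tb == t) & (eb == 1))
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = float(obs_minus_exp**2 / var)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p
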