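"""Survival statistics: Kaplan-Meier, restricted mean, log-rank, 2x2 chi-square.

The restricted-mean convention follows the reporting software used for
the clinical cohort (SPSS): the mean is the area under the product-limit
curve up to the largest observed time of the group — event or censored —
with a Greenwood-based standard error and a normal-approximation 95% CI.
All p-values in this module are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance per step."""

    event_times: np.ndarray      # distinct times with >= 1 event
    survival: np.ndarray         # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray    # Var{S(t)} per step
    n: int
    t_max: float                 # largest observed time, event or censored

    def survival_at(self, t: float) -> float:
        k = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if k == 0 else float(self.survival[k - 1])


@dataclass
class RmstEstimate:
    mean: float
    se: float
    ci95: tuple[float, float]
    tau: float


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass
class Chi2Result:
    statistic: float
    p: float
    table: np.ndarray


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` is True/1 for a death, False/0 for censoring.  Censoring
    tied with a death is conventionally counted as occurring after it
    (the censored subject is still at risk at that time).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be equal-length vectors")
    if len(t) == 0:
        raise ValueError("empty survival data")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    uniq = np.unique(t[e])
    surv, risk, dths, gvar = [], [], [], []
    S = 1.0
    gw = 0.0
    for u in uniq:
        n_i = int(np.sum(t >= u))
        d_i = int(np.sum((t == u) & e))
        S *= (n_i - d_i) / n_i
        if n_i - d_i > 0:
            gw += d_i / (n_i * (n_i - d_i))
            var = S * S * gw
        else:
            var = 0.0  # S hit zero; Greenwood variance degenerates
        surv.append(S)
        risk.append(n_i)
        dths.append(d_i)
        gvar.append(var)
    return KMCurve(
        event_times=uniq,
        survival=np.array(surv),
        at_risk=np.array(risk),
        n_events=np.array(dths),
        greenwood_var=np.array(gvar),
        n=len(t),
        t_max=float(t.max()),
    )


def rmst(curve: KMCurve, tau: float | None = None) -> RmstEstimate:
    """Restricted mean survival: area under the KM curve on [0, tau].

    Default tau is the group's largest observed time.  The variance is
    the Greenwood-based restricted-mean form
    sum_i A_i^2 d_i / (n_i (n_i - d_i)) with A_i the area under the
    curve from t_i to tau.
    """
    if curve.n == 0:
        raise ValueError("empty curve")
    if tau is None:
        tau = curve.t_max
    if tau > curve.t_max + 1e-9:
        raise ValueError(f"tau {tau} exceeds largest observed time {curve.t_max}")
    ts = curve.event_times
    keep = ts <= tau
    ts = ts[keep]
    surv = curve.survival[keep]
    # area under the step function
    grid = np.concatenate(([0.0], ts, [tau]))
    s_vals = np.concatenate(([1.0], surv))
    widths = np.diff(grid)
    area = float(np.sum(s_vals * widths))
    # tail areas A_i from each event time to tau
    var = 0.0
    for i in range(len(ts)):
        a = float(np.sum(s_vals[i + 1:] * widths[i + 1:]))
        n_i = curve.at_risk[keep][i]
        d_i = curve.n_events[keep][i]
        if n_i - d_i > 0:
            var += a * a * d_i / (n_i * (n_i - d_i))
    se = float(np.sqrt(var))
    return RmstEstimate(
        mean=area, se=se,
        ci95=(area - 1.96 * se, area + 1.96 * se),
        tau=float(tau),
    )


def logrank(times, events, group_labels) -> LogRankResult:
    """Mantel-Cox log-rank test for two groups.

    At each distinct event time the observed minus hypergeometric-
    expected events in group 1 are accumulated; the squared sum over the
    hypergeometric variance is chi-square with 1 df.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group_labels)
    names = np.unique(g)
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(names)}")
    for name in names:
        if np.sum(g == name) == 0:
            raise ValueError(f"group {name!r} has no subjects")
    g1 = g == names[0]
    o_minus_e = 0.0
    v = 0.0
    for u in np.unique(t[e]):
        at = t >= u
        n_i = at.sum()
        n1 = (at & g1).sum()
        d_i = ((t == u) & e).sum()
        d1 = ((t == u) & e & g1).sum()
        o_minus_e += d1 - d_i * n1 / n_i
        if n_i > 1:
            v += d_i * (n1 / n_i) * (1 - n1 / n_i) * (n_i - d_i) / (n_i - 1)
    if v <= 0:
        return LogRankResult(statistic=0.0, df=1, p=1.0)
    chi2 = o_minus_e**2 / v
    return LogRankResult(statistic=float(chi2), df=1, p=float(stats.chi2.sf(chi2, 1)))


def plot_km(curves: dict[str, KMCurve], path, title: str = "Overall survival") -> None:
    """Write a Kaplan-Meier step plot for one or more groups."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        t = np.concatenate(([0.0], np.repeat(curve.event_times, 2), [curve.t_max]))
        s = np.concatenate(([1.0, 1.0], np.repeat(curve.survival, 2)))
        ax.plot(t, s[: len(t)], label=f"{label} (n={curve.n})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pearson_chi2_2x2(table) -> Chi2Result:
    """Pearson chi-square for a 2x2 table, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("table has a zero margin")
    n = tab.sum()
    det = tab[0, 0] * tab[1, 1] - tab[0, 1] * tab[1, 0]
    chi2 = n * det**2 / (rows[0] * rows[1] * cols[0] * cols[1])
    return Chi2Result(statistic=float(chi2), p=float(stats.chi2.sf(chi2, 1)),
                      table=tab.astype(int))
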