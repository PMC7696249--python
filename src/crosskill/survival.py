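"""Kaplan–Meier estimation, log-rank testing, and expression-cutoff scanning.

The cutoff scan reproduces the 'scan' modus of Kaplan–Meier-by-expression
tools: every admissible midpoint between consecutive distinct expression
values is tested with a two-group log-rank test and the cutoff minimizing
the p-value is reported.  The minimum p over many data-driven cutoffs is
anti-conservative, so the number of cutoffs scanned is always reported
alongside for a Bonferroni-style correction by the user; no correction is
applied here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["km_estimate", "logrank", "scan_cutoff", "ScanResult"]


def km_estimate(times, events=None):
    """Product-limit (Kaplan–Meier) survival estimate for one group.

    ``times`` may be a DataFrame with columns time/event or an array with a
    separate ``events`` array (1 observed, 0 censored).  Returns a step
    table (one row per distinct event time) with columns time, n_at_risk,
    n_events, survival; survival starts at 1 and is non-increasing.
    """
    if isinstance(times, pd.DataFrame):
        t = times["time"].to_numpy(float)
        e = times["event"].to_numpy(int)
    else:
        t = np.asarray(times, dtype=float)
        e = np.ones(len(t), dtype=int) if events is None else np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("need at least 1 subject")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    rows, s = [], 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / n_risk
        rows.append((et, n_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def _logrank_terms(t, e, grp):
    """O-E and hypergeometric variance contribution of group 1, per event time."""
    event_times = np.unique(t[e == 1])
    O = E = V = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & grp).sum()
        dead = (t == et) & (e == 1)
        d = dead.sum()
        d1 = (dead & grp).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O, E, V


def logrank(time_low, event_low, time_high=None, event_high=None):
    """Two-group log-rank test.

    Either pass two (time, event) pairs, or two DataFrames with columns
    time/event as the first and third arguments.  The statistic is
    (ΣO - ΣE)²/ΣV with the hypergeometric variance at each distinct event
    time; p comes from the chi-square distribution with 1 df.
    """
    if isinstance(time_low, pd.DataFrame):
        g1, g2 = time_low, event_low
        t1, e1 = g1["time"].to_numpy(float), g1["event"].to_numpy(int)
        t2, e2 = g2["time"].to_numpy(float), g2["event"].to_numpy(int)
    else:
        t1, e1 = np.asarray(time_low, float), np.asarray(event_low, int)
        t2, e2 = np.asarray(time_high, float), np.asarray(event_high, int)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    if e.sum() < 1:
        raise ValueError("need at least 1 observed event")
    grp = np.zeros(len(t), dtype=bool)
    grp[: len(t1)] = True
    O, E, V = _logrank_terms(t, e, grp)
    if V == 0:
        return 0.0, 1.0
    stat = (O - E) ** 2 / V
    return float(stat), float(stats.chi2.sf(stat, 1))


@dataclass
class ScanResult:
    table: pd.DataFrame      # cutoff, n_low, n_high, statistic, p
    best_cutoff: float
    min_p: float
    n_cutoffs_scanned: int   # multiplicity note: min-p over this many tests

    def to_dict(self):
        return {"best_cutoff": self.best_cutoff, "min_p": self.min_p,
                "n_cutoffs_scanned": self.n_cutoffs_scanned,
                "multiplicity_note": (f"min p over {self.n_cutoffs_scanned} scanned "
                                      "cutoffs; uncorrected and anti-conservative")}


def scan_cutoff(cohort, min_group_frac=0.1):
    """Exhaustive expression-cutoff scan minimizing the log-rank p-value.

    ``cohort`` needs columns expression, time, event.  Candidate cutoffs are
    midpoints between consecutive sorted distinct expression values; a
    cutoff is admissible when both groups hold at least
    ``min_group_frac * n`` subjects.  Ties in p are broken toward the cutoff
    nearest the median expression.
    """
    expr = cohort["expression"].to_numpy(float)
    t = cohort["time"].to_numpy(float)
    e = cohort["event"].to_numpy(int)
    n = len(cohort)
    distinct = np.unique(expr)
    if len(distinct) < 2:
        raise ValueError("need at least 2 distinct expression values")
    min_n = min_group_frac * n
    rows = []
    for cut in (distinct[:-1] + distinct[1:]) / 2.0:
        high = expr > cut
        n_high = int(high.sum())
        n_low = n - n_high
        if n_low < min_n or n_high < min_n:
            continue
        stat, p = logrank(t[~high], e[~high], t[high], e[high])
        rows.append((float(cut), n_low, n_high, stat, p))
    if not rows:
        raise ValueError("no admissible cutoff under min_group_frac")
    table = pd.DataFrame(rows, columns=["cutoff", "n_low", "n_high", "statistic", "p"])
    med = float(np.median(expr))
    order = table.sort_values(["p", "cutoff"],
                              key=lambda s: np.abs(s - med) if s.name == "cutoff" else s,
                              kind="mergesort")
    best = order.iloc[0]
    return ScanResult(table, float(best["cutoff"]), float(best["p"]), len(table))
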