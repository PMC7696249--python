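"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the ANOM oracle builds
its decision rule from first principles with scipy's t quantile, and the
permutation log-rank oracle evaluates the statistic for thousands of label
permutations with its own vectorized risk-set bookkeeping.
"""

import numpy as np
from scipy import stats


def anom_flags_oracle(groups, alpha):
    """Exhaustive per-group Bonferroni-t ANOM decisions.

    groups: list of 1-D arrays (replicates per group).  Returns a list of
    'above'/'below'/'within' per group, computed independently of the
    package implementation.
    """
    k = len(groups)
    ns = [len(g) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    sp2 = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups) / (sum(ns) - k)
    crit = stats.t.ppf(1 - alpha / (2 * k), sum(ns) - k)
    out = []
    for g, n in zip(groups, ns):
        margin = crit * np.sqrt(sp2) * np.sqrt((k - 1) / (k * n))
        m = np.mean(g)
        out.append("above" if m > grand + margin
                   else "below" if m < grand - margin else "within")
    return out


def logrank_statistic_permutations(time, event, group, n_perm, seed):
    """Log-rank chi-square statistic for the observed labels and n_perm shuffles.

    Fully vectorized over permutations: sorts by time once, then for every
    permutation computes group-1 risk sets by reverse cumulative sums and the
    (O-E)^2/V statistic with hypergeometric variance at each distinct event
    time.  Returns (observed_stat, permuted_stats).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, bool)
    order = np.argsort(time, kind="mergesort")
    t, e = time[order], event[order]
    g0 = group[order]
    n = len(t)

    rng = np.random.default_rng(seed)
    labels = np.empty((n, n_perm + 1), dtype=bool)
    labels[:, 0] = g0
    for j in range(1, n_perm + 1):
        labels[:, j] = g0[rng.permutation(n)]

    # distinct event times -> row slices of the sorted arrays
    ev_times = np.unique(t[e == 1])
    first_idx = np.searchsorted(t, ev_times, side="left")

    at_risk_counts = n - first_idx                       # subjects with t >= ev time
    # group-1 at risk: reverse cumulative sum of labels over subjects
    rev_cum = np.cumsum(labels[::-1, :], axis=0)[::-1, :]
    n1 = rev_cum[first_idx, :]                           # (n_events, n_perm+1)
    # events (and group-1 events) at each distinct event time
    d = np.array([np.sum((t == et) & (e == 1)) for et in ev_times])
    d1 = np.vstack([labels[(t == et) & (e == 1), :].sum(axis=0) for et in ev_times])

    nn = at_risk_counts[:, None].astype(float)
    dd = d[:, None].astype(float)
    E = dd * n1 / nn
    with np.errstate(divide="ignore", invalid="ignore"):
        V = dd * (n1 / nn) * (1 - n1 / nn) * (nn - dd) / (nn - 1)
    V = np.where(nn > 1, V, 0.0)
    O_minus_E = (d1 - E).sum(axis=0)
    Vsum = V.sum(axis=0)
    stat = np.where(Vsum > 0, O_minus_E**2 / np.where(Vsum > 0, Vsum, 1.0), 0.0)
    return float(stat[0]), stat[1:]


def logrank_permutation_p(time, event, group, n_perm=10_000, seed=0):
    """Permutation p-value for the log-rank statistic (label shuffling)."""
    obs, perm = logrank_statistic_permutations(time, event, group, n_perm, seed)
    return float(np.mean(perm >= obs - 1e-12))


def balanced_anova_ss_oracle(y, a, b):
    """Two-way sums of squares by explicit cell-mean algebra (balanced design)."""
    import pandas as pd
    df = pd.DataFrame({"y": y, "a": a, "b": b})
    grand = df["y"].mean()
    ss_total = ((df["y"] - grand) ** 2).sum()
    mean_a = df.groupby("a")["y"].transform("mean")
    mean_b = df.groupby("b")["y"].transform("mean")
    mean_ab = df.groupby(["a", "b"])["y"].transform("mean")
    ss_a = ((mean_a - grand) ** 2).sum()
    ss_b = ((mean_b - grand) ** 2).sum()
    ss_ab = ((mean_ab - mean_a - mean_b + grand) ** 2).sum()
    ss_res = ((df["y"] - mean_ab) ** 2).sum()
    return float(ss_a), float(ss_b), float(ss_ab), float(ss_res), float(ss_total)
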