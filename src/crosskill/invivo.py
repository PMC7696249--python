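"""Xenograft growth-curve bookkeeping and two-way ANOVA.

Tumor volume uses the ellipsoid caliper approximation (L × W²)/2 with W the
smaller caliper reading (auto-swapped).  Study rules re-zero each mouse at
the first measurement reaching the randomization volume and drop records
after the endpoint (volume crossing or study day), keeping an explicit
exclusion ledger.  Group differences over time are tested with a
fixed-effects two-way (group × day) ANOVA: balanced designs by direct sums
of squares, unbalanced designs by Type-II SS via statsmodels (noted in the
output).  Repeated measures within mouse are deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["tumor_volume", "apply_study_rules", "two_way_anova", "shared_days",
           "TumorStudy", "StudyRules"]


def tumor_volume(length_mm, width_mm):
    """Ellipsoid tumor volume (L × W²)/2 in mm³; caliper order is irrelevant."""
    a = np.asarray(length_mm, dtype=float)
    b = np.asarray(width_mm, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("caliper dimensions must be positive")
    L = np.maximum(a, b)
    W = np.minimum(a, b)
    out = L * W**2 / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass
class StudyRules:
    randomization_volume: float = 100.0   # mm³; mouse day-0 = first crossing
    endpoint_volume: float = 1500.0       # mm³; later records excluded
    endpoint_day: float = 18.0            # days post-randomization


@dataclass
class TumorStudy:
    measurements: pd.DataFrame            # mouse_id, group, day, length_mm, width_mm, volume_mm3
    exclusions: pd.DataFrame              # mouse_id, reason, detail
    rules: StudyRules
    group_sizes: pd.Series = field(default=None)

    def __post_init__(self):
        if self.group_sizes is None:
            self.group_sizes = (self.measurements.drop_duplicates("mouse_id")
                                .groupby("group").size())

    def write(self, volumes_csv, exclusions_tsv=None):
        self.measurements.to_csv(volumes_csv, index=False)
        if exclusions_tsv is not None:
            self.exclusions.to_csv(exclusions_tsv, sep="\t", index=False)


def apply_study_rules(measurements, rules=None, **kwargs):
    """Apply randomization and endpoint rules to a raw caliper table.

    Expects columns mouse_id, group, day, length_mm, width_mm.  Per mouse,
    day 0 becomes the first measurement day with volume >= the randomization
    volume (mice never reaching it are excluded and listed); records after
    the first crossing of the endpoint volume (the crossing record itself is
    kept) or after the endpoint day are excluded.  The operation is
    idempotent on its own output.
    """
    rules = rules or StudyRules(**kwargs)
    df = measurements.copy()
    if (df["day"] < 0).any():
        raise ValueError("day values must be non-negative")
    df["volume_mm3"] = tumor_volume(df["length_mm"].to_numpy(),
                                    df["width_mm"].to_numpy())
    swapped = df["width_mm"] > df["length_mm"]
    if swapped.any():
        L = df[["length_mm", "width_mm"]].max(axis=1)
        W = df[["length_mm", "width_mm"]].min(axis=1)
        df["length_mm"], df["width_mm"] = L, W

    kept, excl = [], []
    for mouse, g in df.sort_values("day").groupby("mouse_id", sort=True):
        reached = g[g["volume_mm3"] >= rules.randomization_volume]
        if reached.empty:
            excl.append((mouse, "never_randomized",
                         f"max volume {g['volume_mm3'].max():.1f} mm3 "
                         f"< {rules.randomization_volume:g}"))
            continue
        day0 = reached["day"].iloc[0]
        g = g[g["day"] >= day0].copy()
        g["day"] = g["day"] - day0
        over_day = g["day"] > rules.endpoint_day
        if over_day.any():
            excl.append((mouse, "endpoint_day",
                         f"{int(over_day.sum())} record(s) after day {rules.endpoint_day:g}"))
            g = g[~over_day]
        crossing = g.index[g["volume_mm3"] >= rules.endpoint_volume]
        if len(crossing):
            first = g.index.get_loc(crossing[0])
            dropped = len(g) - (first + 1)
            if dropped > 0:
                excl.append((mouse, "endpoint_volume",
                             f"{dropped} record(s) after crossing "
                             f"{rules.endpoint_volume:g} mm3"))
            g = g.iloc[: first + 1]
        kept.append(g)
    meas = (pd.concat(kept, ignore_index=True) if kept
            else df.iloc[0:0].assign(volume_mm3=[]))
    cols = ["mouse_id", "group", "day", "length_mm", "width_mm", "volume_mm3"]
    exclusions = pd.DataFrame(excl, columns=["mouse_id", "reason", "detail"])
    return TumorStudy(meas[cols].reset_index(drop=True), exclusions, rules)


def shared_days(study):
    """Restrict a study to the (re-zeroed) days every mouse was measured on.

    Per-mouse randomization and endpoint rules can leave mice on staggered
    day grids; the two-way ANOVA needs every group × day cell populated, so
    analysis is aligned to the intersection of the mice's day sets (no
    interpolation).  Returns a measurements DataFrame.
    """
    df = study.measurements if isinstance(study, TumorStudy) else pd.DataFrame(study)
    day_sets = df.groupby("mouse_id")["day"].agg(set)
    common = set.intersection(*day_sets) if len(day_sets) else set()
    if not common:
        raise ValueError("no measurement day shared by all mice")
    return df[df["day"].isin(common)].reset_index(drop=True)


def _balanced_anova(df):
    """Direct sums-of-squares two-way ANOVA for a balanced group × day design."""
    y = df["volume_mm3"].to_numpy(float)
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    ga = df.groupby("group")["volume_mm3"]
    gb = df.groupby("day")["volume_mm3"]
    gc = df.groupby(["group", "day"])["volume_mm3"]
    ss_a = float((ga.size() * (ga.mean() - grand) ** 2).sum())
    ss_b = float((gb.size() * (gb.mean() - grand) ** 2).sum())
    ss_cells = float((gc.size() * (gc.mean() - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_res = float(ss_total - ss_cells)
    k_a = df["group"].nunique()
    k_b = df["day"].nunique()
    n = len(df)
    df_a, df_b = k_a - 1, k_b - 1
    df_ab = df_a * df_b
    df_res = n - k_a * k_b
    return ss_a, ss_b, ss_ab, ss_res, df_a, df_b, df_ab, df_res


def two_way_anova(study):
    """Two-way fixed-effects ANOVA (group × day) on tumor volumes.

    Accepts a :class:`TumorStudy` or a DataFrame with columns group, day,
    volume_mm3.  Balanced designs use the classical sums-of-squares
    decomposition; unbalanced designs fall back to Type-II SS (statsmodels
    OLS), recorded in the table attribute ``ss_type``.  With a single
    observation per cell the interaction is pooled into the residual.

    Returns a DataFrame indexed by effect (group, day, group:day, residual)
    with columns sum_sq, df, mean_sq, F, p.
    """
    df = study.measurements if isinstance(study, TumorStudy) else pd.DataFrame(study)
    df = df[["group", "day", "volume_mm3"]].copy()
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 treatment groups")
    if df["day"].nunique() < 2:
        raise ValueError("need at least 2 shared measurement days")
    cell_n = df.groupby(["group", "day"]).size().unstack()
    empty = cell_n.isna()
    if empty.to_numpy().any():
        g, d = next((g, d) for g in cell_n.index for d in cell_n.columns
                    if empty.at[g, d])
        raise ValueError(f"empty design cell: group={g!r}, day={d!r}")

    balanced = cell_n.to_numpy().std() == 0
    if balanced:
        ss_a, ss_b, ss_ab, ss_res, df_a, df_b, df_ab, df_res = _balanced_anova(df)
        ss_type = "balanced"
        if df_res == 0:  # one observation per cell: interaction becomes the error term
            ss_res, df_res, ss_ab, df_ab = ss_ab, df_ab, 0.0, 0
            ss_type = "balanced (interaction pooled into residual; n=1 per cell)"
    else:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        model = smf.ols("volume_mm3 ~ C(group) * C(day)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        ss_a, ss_b, ss_ab = tab["sum_sq"].iloc[0:3]
        ss_res = tab["sum_sq"].iloc[3]
        df_a, df_b, df_ab = (int(x) for x in tab["df"].iloc[0:3])
        df_res = int(tab["df"].iloc[3])
        ss_type = "Type II (unbalanced design)"

    rows = []
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    for name, ss, d in (("group", ss_a, df_a), ("day", ss_b, df_b),
                        ("group:day", ss_ab, df_ab)):
        if d == 0:
            continue
        ms = ss / d
        F = ms / ms_res if ms_res > 0 else np.inf
        p = float(stats.f.sf(F, d, df_res)) if np.isfinite(F) else 0.0
        rows.append((name, ss, d, ms, F, max(p, np.finfo(float).tiny)))
    rows.append(("residual", ss_res, df_res, ms_res, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["effect", "sum_sq", "df", "mean_sq", "F", "p"])
    out = out.set_index("effect")
    out.attrs["ss_type"] = ss_type
    out.attrs["note"] = ("repeated measures within mouse are not modeled; "
                         "observations are treated as independent")
    return out
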