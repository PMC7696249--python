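"""Hit calling and Analysis-of-Means selection of top drugs.

A hit is a (cell line, compound) pair whose percent killing reaches the
threshold (default 50% at the screening dose).  Analysis of Means (ANOM)
flags compounds whose mean killing falls outside decision limits around the
grand mean; the two-sided critical value is the Bonferroni t quantile, a
conservative, fully specified stand-in for the exact multivariate-t ANOM
constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["call_hits", "anom_top_drugs", "summarize_screen",
           "HitTable", "AnomResult", "ScreenSummary"]


@dataclass
class HitTable:
    """Per-(line, compound) hit calls plus per-line and per-compound summaries."""

    long: pd.DataFrame           # cell_line, compound_id, percent_killing, is_hit
    per_line: pd.Series          # hit fraction per cell line
    per_compound: pd.DataFrame   # n_lines_hit, mean_killing
    threshold: float
    strict: bool

    def killing_wide(self):
        return self.long.pivot(index="cell_line", columns="compound_id",
                               values="percent_killing")

    def write(self, path):
        self.long.to_csv(path, sep="\t", index=False)


def call_hits(matrix, threshold=50.0, strict=False):
    """Call hits on a :class:`~crosskill.normalize.KillingMatrix`.

    ``strict=False`` uses killing >= threshold (the boundary value counts);
    ``strict=True`` uses a strict inequality.
    """
    values = matrix.values
    if values.empty:
        raise ValueError("empty killing matrix")
    is_hit = values.gt(threshold) if strict else values.ge(threshold)
    long = pd.DataFrame({
        "cell_line": np.repeat(values.index.to_numpy(), values.shape[1]),
        "compound_id": np.tile(values.columns.to_numpy(), values.shape[0]),
        "percent_killing": values.to_numpy().ravel(),
        "is_hit": is_hit.to_numpy().ravel(),
    })
    per_line = is_hit.mean(axis=1)
    per_compound = pd.DataFrame({
        "n_lines_hit": is_hit.sum(axis=0).astype(int),
        "mean_killing": values.mean(axis=0),
    })
    return HitTable(long, per_line, per_compound, float(threshold), bool(strict))


@dataclass
class AnomResult:
    """Analysis-of-Means decision chart data.

    ``table`` has one row per group (compound) with columns mean, n, lower,
    upper, exceeds ('above' | 'below' | 'within').  Groups above the upper
    decision limit are the top candidates.
    """

    table: pd.DataFrame
    grand_mean: float
    pooled_sd: float
    alpha: float
    k: int
    df_resid: int
    critical_value: float
    balanced: bool

    @property
    def top_candidates(self):
        return list(self.table.index[self.table["exceeds"] == "above"])

    def write(self, tsv_path):
        self.table.to_csv(tsv_path, sep="\t")

    def to_dict(self):
        return {"grand_mean": self.grand_mean, "pooled_sd": self.pooled_sd,
                "alpha": self.alpha, "k": self.k, "df_resid": self.df_resid,
                "critical_value": self.critical_value, "balanced": self.balanced,
                "top_candidates": self.top_candidates}


def anom_top_drugs(replicate_killing, alpha=0.05):
    """Analysis of Means over compounds with replicate killing observations.

    ``replicate_killing`` is a long DataFrame with columns ``compound_id``
    and ``percent_killing`` (one row per replicate observation), or a mapping
    compound -> sequence of values.  Decision limits are

        grand_mean +/- t(1 - alpha/(2k); df) * s_p * sqrt((k-1)/(k*n_i))

    with s_p the pooled within-group standard deviation (df = sum(n_i - 1));
    for unbalanced designs the per-group n_i enters the limit and a warning
    notes the departure from classical ANOM.
    """
    if isinstance(replicate_killing, pd.DataFrame):
        groups = {cid: g["percent_killing"].to_numpy(float)
                  for cid, g in replicate_killing.groupby("compound_id", sort=True)}
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in replicate_killing.items()}
    k = len(groups)
    if k < 2:
        raise ValueError("ANOM needs at least 2 groups")
    ns = np.array([len(v) for v in groups.values()])
    if np.any(ns < 2):
        raise ValueError("every group needs at least 2 replicates")
    means = np.array([v.mean() for v in groups.values()])
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_resid = int(ns.sum() - k)
    pooled_var = ss_within / df_resid
    pooled_sd = float(np.sqrt(pooled_var))
    grand_mean = float(np.average(means, weights=ns))

    balanced = bool(np.all(ns == ns[0]))
    if not balanced:
        warnings.warn("unbalanced design: per-group n used in ANOM decision limits")
    h = float(stats.t.ppf(1.0 - alpha / (2.0 * k), df_resid))
    half_width = h * pooled_sd * np.sqrt((k - 1.0) / (k * ns))
    lower = grand_mean - half_width
    upper = grand_mean + half_width
    if pooled_sd == 0.0:
        warnings.warn("zero within-group variance: decision limits collapse to the grand mean")
    exceeds = np.where(means > upper, "above", np.where(means < lower, "below", "within"))
    table = pd.DataFrame({"mean": means, "n": ns, "lower": lower, "upper": upper,
                          "exceeds": exceeds}, index=pd.Index(groups.keys(), name="compound_id"))
    return AnomResult(table, grand_mean, pooled_sd, float(alpha), k, df_resid, h, balanced)


@dataclass
class ScreenSummary:
    per_line_hit_fraction: pd.Series
    per_compound_mean_killing: pd.Series
    high_mean_compounds: list
    mean_bar: float


def summarize_screen(matrix, hits, mean_bar=95.0):
    """Screen-level summary: per-line hit fractions and cross-line mean killing.

    Compounds whose mean killing over all lines exceeds ``mean_bar`` (strict,
    default 95%) are flagged as broadly efficacious.
    """
    mean_killing = matrix.values.mean(axis=0)
    flagged = sorted(mean_killing.index[mean_killing > mean_bar])
    return ScreenSummary(hits.per_line.copy(), mean_killing, flagged, float(mean_bar))
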