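"""Target- and pathway-level roll-up of screen hits.

Single-compound hits are noisy and most inhibitors are promiscuous, so the
high-confidence selection aggregates by annotated target: a target passes
when at least ``min_drugs`` of its annotated compounds kill more than the
threshold in the required cell lines.  The default follows the selection
that surfaces the proteasome (9 of 11 inhibitors) and CRM1 nuclear export
(3 of 4) targets: strict >50% killing in *all* lines, at least 3 drugs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["rollup", "compare_rollups", "TargetRollup", "read_annotation",
           "write_annotation"]


@dataclass
class TargetRollup:
    """Ranked target (or pathway) roll-up with the parameters that produced it."""

    table: pd.DataFrame          # target, pathway, n_drugs_total, n_drugs_hit, hit_fraction, passes_filter
    level: str
    min_drugs: int
    threshold: float
    strict: bool
    require_lines: object
    n_unannotated: int
    n_missing_pathway: int = 0

    @property
    def passing(self):
        key = self.table.columns[0]
        return list(self.table.loc[self.table["passes_filter"], key])

    def to_dict(self):
        return {"level": self.level, "min_drugs": self.min_drugs,
                "threshold": self.threshold, "strict": self.strict,
                "require_lines": (list(self.require_lines)
                                  if isinstance(self.require_lines, (list, tuple))
                                  else self.require_lines),
                "n_unannotated": self.n_unannotated,
                "n_missing_pathway": self.n_missing_pathway,
                "passing": self.passing}

    def write(self, csv_path):
        self.table.to_csv(csv_path, index=False)


def _compound_hit(killing_wide, threshold, strict, require_lines):
    """Boolean per-compound hit under the line requirement."""
    if isinstance(require_lines, str) and require_lines in ("all", "any"):
        sub = killing_wide
        mode = require_lines
    else:
        missing = set(require_lines) - set(killing_wide.index)
        if missing:
            raise ValueError(f"required cell lines absent from hit table: {sorted(missing)}")
        sub = killing_wide.loc[list(require_lines)]
        mode = "all"
    per_line = sub.gt(threshold) if strict else sub.ge(threshold)
    return per_line.all(axis=0) if mode == "all" else per_line.any(axis=0)


def rollup(hits, annotation, level="target", min_drugs=3, threshold=50.0,
           require_lines="all", strict=True):
    """Aggregate compound hits to targets (or pathways) and apply the filter.

    A compound counts toward every one of its annotated targets (no
    fractional weighting) when its killing exceeds ``threshold`` (strict by
    default) in the required cell lines ('all', 'any', or an explicit list of
    line names).  Ranked by (n_drugs_hit, hit_fraction) descending with a
    deterministic name tie-break.  Unannotated compounds are counted and
    reported, not fatal.
    """
    if level not in ("target", "pathway"):
        raise ValueError("level must be 'target' or 'pathway'")
    if annotation is None or len(annotation) == 0:
        raise ValueError("empty compound annotation")
    killing = hits.killing_wide()
    is_hit = _compound_hit(killing, threshold, strict, require_lines)

    ann = annotation.set_index("compound_id")
    screened = pd.Index(killing.columns)
    unannotated = screened.difference(ann.index)
    ann = ann.loc[ann.index.intersection(screened)]

    n_missing_pathway = 0
    if level == "target":
        long = pd.DataFrame({
            "key": ann["targets"].map(sorted).to_numpy(),
            "pathway": ann["pathway"].to_numpy(),
            "compound_id": ann.index,
        }).explode("key")
    else:
        valid = ann["pathway"].map(lambda p: isinstance(p, str) and p != "")
        n_missing_pathway = int((~valid).sum())
        long = pd.DataFrame({
            "key": ann.loc[valid, "pathway"].to_numpy(),
            "pathway": ann.loc[valid, "pathway"].to_numpy(),
            "compound_id": ann.index[valid],
        })
    if long.empty:
        raise ValueError("no annotated, screened compounds to roll up")
    long["hit"] = long["compound_id"].map(is_hit).fillna(False).astype(bool)

    grouped = long.groupby("key", sort=True).agg(
        pathway=("pathway", "first"),
        n_drugs_total=("compound_id", "nunique"),
        n_drugs_hit=("hit", "sum"),
    ).reset_index()
    if level == "pathway":
        grouped = grouped.drop(columns="pathway")
    grouped = grouped.rename(columns={"key": level})
    grouped["n_drugs_hit"] = grouped["n_drugs_hit"].astype(int)
    grouped["hit_fraction"] = grouped["n_drugs_hit"] / grouped["n_drugs_total"]
    grouped["passes_filter"] = grouped["n_drugs_hit"] >= min_drugs
    grouped = grouped.sort_values(
        ["n_drugs_hit", "hit_fraction", level],
        ascending=[False, False, True], kind="mergesort").reset_index(drop=True)
    return TargetRollup(grouped, level, int(min_drugs), float(threshold), bool(strict),
                        require_lines, int(len(unannotated)), n_missing_pathway)


def compare_rollups(rollup_a, rollup_b):
    """Set algebra on the passing targets of two roll-ups (same annotation)."""
    a = set(rollup_a.passing)
    b = set(rollup_b.passing)
    return {
        "both": sorted(a & b),
        "either": sorted(a | b),
        "only_a": sorted(a - b),
        "only_b": sorted(b - a),
    }


def write_annotation(annotation, path):
    """CSV writer; the targets set is serialized as a ';'-joined field."""
    out = annotation.copy()
    out["targets"] = out["targets"].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, index=False)


def read_annotation(path):
    ann = pd.read_csv(path)
    ann["targets"] = ann["targets"].map(lambda s: frozenset(str(s).split(";")))
    if ann["compound_id"].duplicated().any():
        raise ValueError("duplicate compound_id in annotation")
    if (ann["targets"].map(len) == 0).any():
        raise ValueError("compound with empty target set")
    return ann
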