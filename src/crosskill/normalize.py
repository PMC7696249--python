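"""Raw plate luminescence -> percent-killing matrix.

Percent killing is defined against the plate's own vehicle (DMSO) controls:
``100 * (1 - treated / control_center)``, with the control center the median
(robust to the odd dead control well) or mean of the plate's vehicle wells.
Values below 0 (growth stimulation) or above 100 are retained unless clipping
is requested; downstream thresholds operate on the raw scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["percent_killing", "normalize_plates", "aggregate_replicates", "KillingMatrix"]


def percent_killing(treated_rlu, control_center):
    """Percent killing of a treated well relative to the plate control center."""
    control_center = np.asarray(control_center, dtype=float)
    if np.any(control_center <= 0):
        raise ValueError("control_center must be positive (unusable plate)")
    treated_rlu = np.asarray(treated_rlu, dtype=float)
    return 100.0 * (control_center - treated_rlu) / control_center


def normalize_plates(measurements, control_stat="median"):
    """Per-well percent killing, each plate normalized to its own controls.

    Plates with fewer than two vehicle-control wells are excluded with a
    warning; blank wells are dropped.  Returns a long DataFrame with columns
    plate_id, well, cell_line, species, compound_id, replicate,
    luminescence_rlu, percent_killing.
    """
    if control_stat not in ("median", "mean"):
        raise ValueError("control_stat must be 'median' or 'mean'")
    df = measurements
    controls = df[df["role"] == "vehicle_control"]
    stat = controls.groupby("plate_id")["luminescence_rlu"].agg(control_stat)
    counts = controls.groupby("plate_id").size()

    treated = df[df["role"] == "treated"].copy()
    usable = counts[counts >= 2].index
    bad = sorted(set(treated["plate_id"].unique()) - set(usable))
    if bad:
        warnings.warn(f"{len(bad)} plate(s) without >=2 vehicle controls excluded: {bad}")
        treated = treated[treated["plate_id"].isin(usable)]
    center = treated["plate_id"].map(stat).to_numpy(float)
    treated["percent_killing"] = percent_killing(treated["luminescence_rlu"].to_numpy(float),
                                                 center)
    cols = ["plate_id", "well", "cell_line", "species", "compound_id", "replicate",
            "luminescence_rlu", "percent_killing"]
    return treated[[c for c in cols if c in treated.columns]].reset_index(drop=True)


@dataclass
class KillingMatrix:
    """Cell lines x compounds percent-killing matrix with species labels.

    ``values`` rows are cell lines, columns compounds; ``species`` maps line
    name -> species; ``qc_flags`` holds per-entry flag strings ('' = clean),
    ``n_replicates`` the replicate count behind each entry.
    """

    values: pd.DataFrame
    species: pd.Series
    qc_flags: pd.DataFrame | None = None
    n_replicates: pd.DataFrame | None = None
    clipped: bool = field(default=False)

    def __post_init__(self):
        if not self.values.index.equals(pd.Index(self.species.index)):
            self.species = self.species.reindex(self.values.index)
        if self.species.isna().any():
            raise ValueError("every cell line needs a species label")
        if self.qc_flags is None:
            self.qc_flags = pd.DataFrame("", index=self.values.index,
                                         columns=self.values.columns)
        unflagged = self.qc_flags == ""
        if self.values.isna().to_numpy()[unflagged.to_numpy()].any():
            raise ValueError("NaN killing value in an unflagged entry")

    @property
    def cell_lines(self):
        return list(self.values.index)

    @property
    def compounds(self):
        return list(self.values.columns)

    def clip(self, lower=0.0, upper=100.0):
        """Copy with killing clipped into [lower, upper] (off by default everywhere)."""
        return KillingMatrix(self.values.clip(lower, upper), self.species.copy(),
                             self.qc_flags.copy(),
                             None if self.n_replicates is None else self.n_replicates.copy(),
                             clipped=True)

    def to_long(self):
        long = self.values.stack(future_stack=True).rename("percent_killing").reset_index()
        long.columns = ["cell_line", "compound_id", "percent_killing"]
        long["species"] = long["cell_line"].map(self.species)
        long["qc_flag"] = [self.qc_flags.at[l, c]
                           for l, c in zip(long["cell_line"], long["compound_id"])]
        return long

    def write(self, wide_csv, long_tsv=None):
        wide = self.values.copy()
        wide.insert(0, "species", self.species)
        wide.rename_axis("cell_line").to_csv(wide_csv)
        if long_tsv is not None:
            self.to_long().to_csv(long_tsv, sep="\t", index=False)


def aggregate_replicates(per_well, cv_threshold=20.0):
    """Collapse per-well killing to a :class:`KillingMatrix` of replicate means.

    The QC flag records a replicate luminescence coefficient of variation
    above ``cv_threshold`` percent ('cv>...') and single-replicate entries
    ('n=1'); flagged entries are kept, not dropped.
    """
    g = per_well.groupby(["cell_line", "compound_id"], sort=True)
    agg = g.agg(percent_killing=("percent_killing", "mean"),
                lum_mean=("luminescence_rlu", "mean"),
                lum_sd=("luminescence_rlu", "std"),
                n=("percent_killing", "size"))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * agg["lum_sd"] / agg["lum_mean"]
    flags = np.where(agg["n"] == 1, "n=1",
                     np.where(cv.fillna(0.0) > cv_threshold, f"cv>{cv_threshold:g}", ""))
    agg = agg.assign(qc_flag=flags).reset_index()

    values = agg.pivot(index="cell_line", columns="compound_id", values="percent_killing")
    qc = agg.pivot(index="cell_line", columns="compound_id", values="qc_flag")
    qc = qc.fillna("missing").where(~values.isna() | (qc != ""), "missing")
    nrep = agg.pivot(index="cell_line", columns="compound_id", values="n").fillna(0).astype(int)
    species = per_well.drop_duplicates("cell_line").set_index("cell_line")["species"]
    species = species.reindex(values.index)
    qc = qc.where(~values.isna(), "missing")
    return KillingMatrix(values, species, qc, nrep)
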