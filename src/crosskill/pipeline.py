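"""End-to-end orchestration of the synthetic cross-species screen analysis.

``run_pipeline`` drives every stage from a single config: simulate the
compound libraries and screens, normalize plates, call hits, run Analysis of
Means, cluster cell lines and measure species concordance, roll hits up to
targets, fit dose-response curves, score Bliss synergy, apply xenograft
study rules with a two-way ANOVA, and scan a survival cohort for an
expression cutoff.  Every output file is recorded with a content hash in a
run manifest; identical config + seed reruns are bit-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from . import concordance, curves, hits, invivo, normalize, simulate, survival
from .rollup import rollup as rollup_targets, write_annotation

__all__ = ["DEFAULT_CONFIG", "RunConfig", "ConfigError", "StageError",
           "run_pipeline", "load_config"]

PANEL_LINES = [
    ("143B", "human"), ("MG63", "human"), ("SAOS", "human"),
    ("U2OS", "human"), ("17-3X", "human"),
    ("Abrams", "dog"), ("Moresco", "dog"), ("D17", "dog"), ("D418", "dog"),
]

#: Defaults mirror the study design: 1 µM single-dose triplicate 384-well
#: screens, hit threshold 50% killing, >=3-drug target filter, 20 µM/4-fold
#: dilution series, 100 mm³ randomization / 1500 mm³ or day-18 endpoint,
#: n=5 mice per arm.
DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "crosskill_run",
    "screen_panel": {
        "n_compounds": 119, "n_targets": 40,
        "driver_spec": [["proteasome", 2, 2]],
        "sensitive_range": [96.0, 99.5],
        "noise_sd": 4.0, "species_sd": 8.0, "line_sd": 2.0,
        "n_replicates": 3, "plate_size": 384, "control_wells_per_plate": 32,
    },
    "screen_library": {
        "n_compounds": 2100, "n_targets": 200,
        "driver_spec": [["proteasome", 11, 9], ["CRM1", 4, 3]],
        "sensitive_range": [65.0, 95.0],
        "noise_sd": 8.0, "species_sd": 6.0, "line_sd": 4.0,
        "n_replicates": 3, "plate_size": 384, "control_wells_per_plate": 32,
        "cell_lines": [["D418", "dog"], ["17-3X", "human"]],
    },
    "normalization": {"control_stat": "median", "cv_threshold": 20.0},
    "hits": {"threshold": 50.0, "strict": False},
    "anom": {"alpha": 0.05},
    "clustering": {"metric": "euclidean", "linkage": "average"},
    "rollup": {"level": "target", "min_drugs": 3, "threshold": 50.0,
               "require_lines": "all", "strict": True},
    "dose_response": {
        "start_uM": 20.0, "fold": 4.0, "n_points": 8, "n_reps": 3, "noise_sd": 3.0,
        "drugs": [
            {"name": "bortezomib", "top": 100.0, "bottom": 0.0,
             "ic50_uM": 0.05, "hill": 1.2},
            {"name": "verdinexor", "top": 100.0, "bottom": 5.0,
             "ic50_uM": 1.25, "hill": 1.0},
        ],
    },
    "synergy": {
        "effect_a": [0.15, 0.25, 0.4, 0.55, 0.7],
        "effect_b": [0.1, 0.2, 0.35, 0.5, 0.65],
        "planted_excess": 0.1, "noise_sd": 0.05,
    },
    "tumor": {
        "groups": [["control", 5, 0.16], ["verdinexor", 5, 0.05],
                   ["bortezomib", 5, 0.10]],
        "v0": 100.0, "noise_sd": 12.0,
        "randomization_volume": 100.0, "endpoint_volume": 1500.0, "endpoint_day": 18.0,
    },
    "survival": {
        "n": 80, "cutoff": 5.0, "hazard_low": 0.05, "hazard_high": 0.25,
        "censor_rate": 0.1, "min_group_frac": 0.1,
    },
}


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(dict):
    """Validated pipeline configuration (plain nested mapping)."""

    @classmethod
    def from_dict(cls, overrides=None):
        cfg = copy.deepcopy(DEFAULT_CONFIG)
        for section, val in (overrides or {}).items():
            if section not in cfg:
                raise ConfigError(f"unknown config section: {section!r}")
            if isinstance(cfg[section], dict):
                if not isinstance(val, dict):
                    raise ConfigError(f"section {section!r} must be a mapping")
                for k, v in val.items():
                    if k not in cfg[section]:
                        raise ConfigError(f"unknown config field: {section}.{k}")
                    cfg[section][k] = v
            else:
                cfg[section] = val
        obj = cls(cfg)
        obj.validate()
        return obj

    def validate(self):
        checks = [
            ("hits.threshold", self["hits"]["threshold"], lambda v: -100 <= v <= 200),
            ("anom.alpha", self["anom"]["alpha"], lambda v: 0 < v < 1),
            ("rollup.min_drugs", self["rollup"]["min_drugs"], lambda v: v >= 1),
            ("dose_response.fold", self["dose_response"]["fold"], lambda v: v > 1),
            ("tumor.v0", self["tumor"]["v0"], lambda v: v > 0),
            ("survival.min_group_frac", self["survival"]["min_group_frac"],
             lambda v: 0 <= v < 0.5),
            ("seed", self["seed"], lambda v: isinstance(v, int)),
        ]
        for name, value, ok in checks:
            if not ok(value):
                raise ConfigError(f"config field {name} out of range: {value!r}")


def load_config(path):
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must hold a mapping")
    return RunConfig.from_dict(raw)


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _screen_stage(cfg, seed, cell_lines, out, tag, norm_cfg, hit_cfg):
    ann, truth = simulate.generate_compound_library(
        n_targets=cfg["n_targets"], driver_spec=[tuple(d) for d in cfg["driver_spec"]],
        seed=seed, n_compounds=cfg["n_compounds"],
        sensitive_range=tuple(cfg["sensitive_range"]),
        noise_sd=cfg["noise_sd"], species_sd=cfg["species_sd"], line_sd=cfg["line_sd"])
    wells = simulate.generate_screen(
        truth, cell_lines, n_replicates=cfg["n_replicates"],
        control_wells_per_plate=cfg["control_wells_per_plate"],
        plate_size=cfg["plate_size"], seed=seed + 1)
    wells.to_csv(out / f"{tag}_wells.csv", index=False)
    write_annotation(ann, out / f"{tag}_annotation.csv")
    truth.compound_effects.rename_axis("compound_id").to_csv(out / f"{tag}_truth.csv")
    per_well = normalize.normalize_plates(wells, control_stat=norm_cfg["control_stat"])
    matrix = normalize.aggregate_replicates(per_well, cv_threshold=norm_cfg["cv_threshold"])
    matrix.write(out / f"{tag}_killing.csv", out / f"{tag}_killing_long.tsv")
    table = hits.call_hits(matrix, threshold=hit_cfg["threshold"], strict=hit_cfg["strict"])
    table.write(out / f"{tag}_hits.tsv")
    return ann, truth, per_well, matrix, table


def run_pipeline(config=None, out_dir=None):
    """Run every stage from a :class:`RunConfig`; returns the run manifest."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    seed = cfg["seed"]
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    stage = "setup"
    try:
        # --- approved-oncology panel screen: 9 lines --------------------------------
        stage = "screen_panel"
        _, _, per_well, matrix, hit_table = _screen_stage(
            cfg["screen_panel"], seed, PANEL_LINES, out, "panel",
            cfg["normalization"], cfg["hits"])
        screen_summary = hits.summarize_screen(matrix, hit_table)
        summary["panel_high_mean_compounds"] = screen_summary.high_mean_compounds
        summary["panel_hit_fraction_per_line"] = {
            k: float(v) for k, v in screen_summary.per_line_hit_fraction.items()}

        stage = "anom"
        per_line_killing = hit_table.long.rename(columns={})[["compound_id", "percent_killing"]]
        anom = hits.anom_top_drugs(per_line_killing, alpha=cfg["anom"]["alpha"])
        anom.write(out / "panel_anom.tsv")
        summary["anom_top_candidates"] = anom.top_candidates
        summary["anom_n_top"] = len(anom.top_candidates)

        stage = "clustering"
        clust = concordance.cluster_cell_lines(
            matrix, metric=cfg["clustering"]["metric"], linkage=cfg["clustering"]["linkage"])
        clust.linkage_table().to_csv(out / "panel_linkage.tsv", sep="\t", index=False)
        (out / "panel_dendrogram.nwk").write_text(clust.newick() + "\n")
        summary["species_purity"] = clust.species_purity

        stage = "concordance_panel"
        conc_panel = concordance.species_concordance(matrix, "dog", "human")
        conc_panel.table.to_csv(out / "panel_concordance.csv")
        summary["panel_concordance"] = conc_panel.to_dict()

        # --- 2100-compound bioactives screen: 2 matched lines -----------------------
        stage = "screen_library"
        lib_lines = [tuple(x) for x in cfg["screen_library"]["cell_lines"]]
        ann2, truth2, _, matrix2, hit_table2 = _screen_stage(
            cfg["screen_library"], seed + 100, lib_lines, out, "library",
            cfg["normalization"], cfg["hits"])
        summary["library_hit_fraction_per_line"] = {
            k: float(v) for k, v in hit_table2.per_line.items()}

        stage = "concordance_library"
        conc_lib = concordance.species_concordance(matrix2)
        summary["library_concordance"] = conc_lib.to_dict()

        stage = "rollup"
        rl = rollup_targets(hit_table2, ann2, **{k: v for k, v in cfg["rollup"].items()})
        rl.write(out / "library_rollup.csv")
        (out / "library_rollup.json").write_text(json.dumps(rl.to_dict(), indent=2,
                                                            sort_keys=True) + "\n")
        summary["rollup_passing_targets"] = rl.passing
        summary["rollup_recovered_drivers"] = sorted(
            set(rl.passing) & set(truth2.driver_targets))

        stage = "dose_response"
        dr = cfg["dose_response"]
        conc = curves.dilution_series(dr["start_uM"], dr["fold"], dr["n_points"])
        fits = {}
        for i, drug in enumerate(dr["drugs"]):
            data = simulate.generate_dose_response(
                drug["top"], drug["bottom"], drug["ic50_uM"], drug["hill"],
                conc, noise_sd=dr["noise_sd"], n_reps=dr["n_reps"], seed=seed + 200 + i)
            fit = curves.fit_4pl(data["concentration_uM"], data["viability_pct"])
            fits[drug["name"]] = fit.to_dict()
        (out / "dose_response_fits.json").write_text(
            json.dumps(fits, indent=2, sort_keys=True) + "\n")
        summary["ic50_uM"] = {name: f["ic50"] for name, f in fits.items()}

        stage = "synergy"
        sy = cfg["synergy"]
        import numpy as np
        excess = np.full((len(sy["effect_a"]), len(sy["effect_b"])),
                         float(sy["planted_excess"]))
        grid = simulate.generate_combination_grid(
            sy["effect_a"], sy["effect_b"], excess, noise_sd=sy["noise_sd"],
            seed=seed + 300)
        combo = curves.bliss_excess(grid)
        combo.excess.to_csv(out / "bliss_excess.csv")
        summary["bliss_summary_excess"] = combo.summary_excess

        stage = "invivo"
        tm = cfg["tumor"]
        caliper = simulate.generate_tumor_study(
            [tuple(g) for g in tm["groups"]], v0=tm["v0"], noise_sd=tm["noise_sd"],
            seed=seed + 400)
        caliper.to_csv(out / "tumor_caliper.csv", index=False)
        study = invivo.apply_study_rules(
            caliper, randomization_volume=tm["randomization_volume"],
            endpoint_volume=tm["endpoint_volume"], endpoint_day=tm["endpoint_day"])
        study.write(out / "tumor_volumes.csv", out / "tumor_exclusions.tsv")
        anova = invivo.two_way_anova(invivo.shared_days(study))
        anova.to_csv(out / "tumor_anova.tsv", sep="\t")
        summary["tumor_anova_group_p"] = float(anova.loc["group", "p"])

        stage = "kmscan"
        sv = cfg["survival"]
        cohort = simulate.generate_survival_cohort(
            sv["n"], sv["cutoff"], sv["hazard_low"], sv["hazard_high"],
            censor_rate=sv["censor_rate"], seed=seed + 500)
        cohort.to_csv(out / "survival_cohort.csv", index=False)
        scan = survival.scan_cutoff(cohort, min_group_frac=sv["min_group_frac"])
        scan.table.to_csv(out / "survival_scan.tsv", sep="\t", index=False)
        summary["survival_scan"] = scan.to_dict()
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # halt with the stage name, never silently
        raise StageError(stage, exc) from exc

    manifest = {
        "config": json.loads(json.dumps(dict(cfg))),
        "seed": seed,
        "summary": summary,
        "outputs": {p.name: {"path": str(p), "sha256": _sha256(p)}
                    for p in sorted(out.iterdir()) if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
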