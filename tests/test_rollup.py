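"""Target roll-up: the >=m-drugs-above-threshold filter and its algebra."""

import pandas as pd
import pytest

import crosskill as ck
from crosskill import KillingMatrix


def _hits_from(values_by_line, compounds):
    values = pd.DataFrame(values_by_line, columns=compounds)
    values.index = ["D418", "17-3X"][: len(values)]
    species = pd.Series({"D418": "dog", "17-3X": "human"}).reindex(values.index)
    return ck.call_hits(KillingMatrix(values, species))


def _annotation(mapping):
    rows = [(cid, cid.lower(), frozenset({tgt}), f"{tgt} pathway")
            for cid, tgt in mapping.items()]
    return pd.DataFrame(rows, columns=["compound_id", "name", "targets", "pathway"])


class TestRollup:
    def test_three_of_four_pattern_passes(self):
        compounds = ["a", "b", "c", "d"]
        hits = _hits_from([[90.0, 80.0, 70.0, 40.0], [85.0, 75.0, 60.0, 45.0]],
                          compounds)
        ann = _annotation({c: "CRM1" for c in compounds})
        rl = ck.rollup(hits, ann)
        row = rl.table.iloc[0]
        assert (row["n_drugs_hit"], row["n_drugs_total"]) == (3, 4)
        assert rl.passing == ["CRM1"]

    def test_nine_of_eleven_pattern_passes(self):
        compounds = [f"p{i}" for i in range(11)]
        killing = [[80.0] * 9 + [30.0] * 2] * 2
        rl = ck.rollup(_hits_from(killing, compounds),
                       _annotation({c: "proteasome" for c in compounds}))
        assert rl.table.iloc[0]["n_drugs_hit"] == 9
        assert rl.passing == ["proteasome"]

    def test_two_hits_fail_min_three(self):
        compounds = ["a", "b", "c"]
        rl = ck.rollup(_hits_from([[90.0, 80.0, 10.0]] * 2, compounds),
                       _annotation({c: "t" for c in compounds}))
        assert rl.passing == []

    def test_threshold_is_strict_by_default(self):
        compounds = ["a", "b", "c"]
        rl = ck.rollup(_hits_from([[50.0, 50.0, 50.0]] * 2, compounds),
                       _annotation({c: "t" for c in compounds}))
        assert rl.table.iloc[0]["n_drugs_hit"] == 0
        rl2 = ck.rollup(_hits_from([[50.0, 50.0, 50.0]] * 2, compounds),
                        _annotation({c: "t" for c in compounds}), strict=False)
        assert rl2.table.iloc[0]["n_drugs_hit"] == 3

    def test_all_lines_requirement_vs_any(self):
        compounds = ["a", "b", "c"]
        killing = [[90.0, 90.0, 90.0], [90.0, 90.0, 10.0]]  # c misses line 2
        ann = _annotation({c: "t" for c in compounds})
        assert ck.rollup(_hits_from(killing, compounds), ann,
                         require_lines="all").table.iloc[0]["n_drugs_hit"] == 2
        assert ck.rollup(_hits_from(killing, compounds), ann,
                         require_lines="any").table.iloc[0]["n_drugs_hit"] == 3

    def test_multi_target_drug_counts_toward_each_target(self):
        ann = pd.DataFrame([
            ("a", "a", frozenset({"t1", "t2"}), "p"),
            ("b", "b", frozenset({"t1"}), "p"),
        ], columns=["compound_id", "name", "targets", "pathway"])
        hits = _hits_from([[90.0, 90.0]] * 2, ["a", "b"])
        rl = ck.rollup(hits, ann, min_drugs=1)
        counts = rl.table.set_index("target")["n_drugs_hit"]
        assert counts["t1"] == 2 and counts["t2"] == 1

    def test_unannotated_compounds_counted_not_fatal(self):
        ann = _annotation({"a": "t"})
        rl = ck.rollup(_hits_from([[90.0, 90.0]] * 2, ["a", "zz"]), ann, min_drugs=1)
        assert rl.n_unannotated == 1

    def test_empty_annotation_rejected(self):
        hits = _hits_from([[90.0]] * 2, ["a"])
        with pytest.raises(ValueError, match="empty"):
            ck.rollup(hits, ann := _annotation({}))

    def test_lowering_threshold_or_min_drugs_is_monotone(self):
        compounds = [f"c{i}" for i in range(6)]
        killing = [[80.0, 70.0, 55.0, 45.0, 30.0, 20.0]] * 2
        ann = _annotation({c: "t" for c in compounds})
        hits = _hits_from(killing, compounds)
        strict_pass = set(ck.rollup(hits, ann, threshold=60, min_drugs=3).passing)
        loose_pass = set(ck.rollup(hits, ann, threshold=40, min_drugs=2).passing)
        assert strict_pass <= loose_pass

    def test_pathway_level_rollup(self):
        ann = _annotation({"a": "t1", "b": "t2"})
        hits = _hits_from([[90.0, 90.0]] * 2, ["a", "b"])
        rl = ck.rollup(hits, ann, level="pathway", min_drugs=1)
        assert set(rl.table["pathway"]) == {"t1 pathway", "t2 pathway"}


class TestCompareRollups:
    def test_identical_inputs_intersection_equals_union(self):
        ann = _annotation({"a": "t", "b": "t", "c": "t"})
        hits = _hits_from([[90.0, 80.0, 70.0]] * 2, ["a", "b", "c"])
        rl = ck.rollup(hits, ann)
        cmp = ck.compare_rollups(rl, rl)
        assert cmp["both"] == cmp["either"] == ["t"]

    def test_disjoint_passing_sets(self):
        ann = _annotation({"a": "t1", "b": "t2"})
        h1 = _hits_from([[90.0, 10.0]] * 2, ["a", "b"])
        h2 = _hits_from([[10.0, 90.0]] * 2, ["a", "b"])
        r1 = ck.rollup(h1, ann, min_drugs=1)
        r2 = ck.rollup(h2, ann, min_drugs=1)
        cmp = ck.compare_rollups(r1, r2)
        assert cmp["both"] == [] and cmp["either"] == ["t1", "t2"]

    def test_planted_drivers_intersection_on_split_screens(self):
        ann, truth = ck.generate_compound_library(
            30, driver_spec=[("proteasome", 5, 4), ("CRM1", 4, 3)],
            seed=9, n_compounds=150, noise_sd=0.0)
        lines = [("D418", "dog"), ("17-3X", "human")]
        wells = ck.generate_screen(truth, lines, seed=10)
        m = ck.aggregate_replicates(ck.normalize_plates(wells))
        hits = ck.call_hits(m)
        r_dog = ck.rollup(hits, ann, require_lines=["D418"])
        r_hum = ck.rollup(hits, ann, require_lines=["17-3X"])
        cmp = ck.compare_rollups(r_dog, r_hum)
        assert cmp["both"] == ["CRM1", "proteasome"]


def test_annotation_round_trip(tmp_path):
    ann, _ = ck.generate_compound_library(5, driver_spec=[("x", 2, 1)],
                                          seed=0, n_compounds=20)
    path = tmp_path / "ann.csv"
    ck.write_annotation(ann, path)
    back = ck.read_annotation(path)
    assert back["targets"].map(frozenset).tolist() == ann["targets"].tolist()
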