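"""Cohort database: import, filters, sample algebra, scenarios, logging."""

import numpy as np
import pandas as pd
import pytest

from braincohort.cohortdb import CohortDB, parse_log
from braincohort.errors import NotFoundError, ValidationError


@pytest.fixture
def db():
    return CohortDB()


@pytest.fixture
def clinical_csv(tmp_path, rng):
    """12-subject table: one nominal-coded column, two numerics, one text
    nominal, with two planted blanks."""
    subjects = [f"S{i:02d}" for i in range(1, 13)]
    frame = pd.DataFrame({
        "subject": subjects,
        "group_code": [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3],
        "ventricle_volume": np.round(rng.uniform(10, 40, 12), 3),
        "white_matter": np.round(rng.uniform(300, 500, 12), 3),
        "status": ["normal", "abnormal"] * 6,
    })
    frame.loc[4, "ventricle_volume"] = np.nan
    frame.loc[7, "white_matter"] = np.nan
    path = tmp_path / "clinical.csv"
    frame.to_csv(path, index=False)
    return str(path), frame


class TestImport:
    def test_counts(self, db, clinical_csv):
        path, frame = clinical_csv
        variables = db.import_table(path)
        assert len(variables) == 4
        assert len(db.list_subjects()) == 12
        values = db.get_values([v.name for v in variables])
        assert values.shape == (12, 4)

    def test_nominal_hint_with_labels(self, db, clinical_csv):
        path, _ = clinical_csv
        db.import_table(path, type_hints={
            "group_code": {"type": "nominal",
                           "labels": {1: "term", 2: "incubator", 3: "kmc"}}})
        var = db.get_variable("group_code")
        assert var.var_type == "nominal"
        assert var.levels == {1: "term", 2: "incubator", 3: "kmc"}

    def test_text_column_becomes_nominal_with_inferred_levels(
            self, db, clinical_csv):
        path, _ = clinical_csv
        db.import_table(path)
        var = db.get_variable("status")
        assert var.var_type == "nominal"
        assert sorted(var.levels.values()) == ["abnormal", "normal"]

    def test_blank_cell_is_missing_not_zero(self, db, clinical_csv):
        path, _ = clinical_csv
        db.import_table(path)
        values = db.get_values("ventricle_volume")
        assert values["ventricle_volume"].isna().sum() == 1
        assert (values["ventricle_volume"] == 0).sum() == 0

    def test_reimport_updates_in_place(self, db, clinical_csv, tmp_path):
        path, frame = clinical_csv
        db.import_table(path)
        frame2 = frame.copy()
        frame2.loc[0, "white_matter"] = 999.0
        p2 = tmp_path / "v2.csv"
        frame2.to_csv(p2, index=False)
        db.import_table(str(p2))
        assert db.get_values("white_matter").loc["S01", "white_matter"] == 999.0

    def test_type_conflict_on_reimport_lists_columns(self, db, clinical_csv,
                                                     tmp_path):
        path, frame = clinical_csv
        db.import_table(path)
        frame2 = frame.copy()
        frame2["ventricle_volume"] = ["a"] * 12  # numeric -> nominal conflict
        p2 = tmp_path / "bad.csv"
        frame2.to_csv(p2, index=False)
        with pytest.raises(ValidationError, match="ventricle_volume"):
            db.import_table(str(p2))


class TestFilters:
    def test_vacuous_filter_keeps_everyone(self, db, clinical_csv):
        path, _ = clinical_csv
        db.import_table(path)
        s = db.create_sample_filter("all", [("white_matter", ">=", -1e9)],
                                    missing_policy="include")
        assert len(s.subjects) == 12

    def test_quantile_screen_matches_row_scan_oracle(self, db, clinical_csv):
        """High-ventricle / low-white-matter screen == a hand loop."""
        path, frame = clinical_csv
        db.import_table(path)
        q75 = frame["ventricle_volume"].quantile(0.75)
        q25 = frame["white_matter"].quantile(0.25)
        s = db.create_sample_filter(
            "pvl_screen",
            [("ventricle_volume", ">=", q75), ("white_matter", "<=", q25)],
            missing_policy="exclude")
        expected = set()
        for _, row in frame.iterrows():
            if pd.isna(row.ventricle_volume) or pd.isna(row.white_matter):
                continue
            if row.ventricle_volume >= q75 and row.white_matter <= q25:
                expected.add(row.subject)
        assert set(s.subjects) == expected

    def test_missing_policy_differs_by_exactly_the_missing_subject(
            self, db, clinical_csv):
        path, frame = clinical_csv
        db.import_table(path)
        missing_subject = frame.loc[
            frame.ventricle_volume.isna(), "subject"].item()
        incl = db.create_sample_filter(
            "incl", [("ventricle_volume", ">=", -1e9)], "include")
        excl = db.create_sample_filter(
            "excl", [("ventricle_volume", ">=", -1e9)], "exclude")
        assert set(incl.subjects) - set(excl.subjects) == {missing_subject}

    def test_ordering_relation_on_nominal_rejected(self, db, clinical_csv):
        path, _ = clinical_csv
        db.import_table(path)
        with pytest.raises(ValidationError):
            db.create_sample_filter("x", [("status", ">=", 1)])

    def test_unknown_variable_rejected(self, db):
        with pytest.raises(NotFoundError):
            db.create_sample_filter("x", [("ghost", ">=", 0)])


class TestSampleAlgebra:
    @pytest.fixture
    def populated(self, db, clinical_csv):
        path, _ = clinical_csv
        db.import_table(path)
        return db

    def test_union_idempotent(self, populated):
        a = populated.create_sample("a", ["S01", "S02", "S03"])
        out = populated.sample_setop("aua", a, a, "union")
        assert out.subjects == a.subjects

    def test_disjoint_union_additivity(self, populated):
        a = populated.create_sample("a", ["S01", "S02"])
        b = populated.create_sample("b", ["S05", "S06", "S07"])
        out = populated.sample_setop("ab", a, b, "union")
        assert len(out.subjects) == 5

    def test_partition_identity(self, populated, rng):
        """(A \\ B) | (A & B) == A on random samples."""
        everyone = populated.list_subjects()
        for k in range(5):
            a_ids = rng.choice(everyone, size=6, replace=False)
            b_ids = rng.choice(everyone, size=5, replace=False)
            a = populated.create_sample(f"a{k}", a_ids)
            b = populated.create_sample(f"b{k}", b_ids)
            diff = populated.sample_setop(f"d{k}", a, b, "difference")
            inter = populated.sample_setop(f"i{k}", a, b, "intersection")
            back = populated.sample_setop(f"u{k}", diff, inter, "union")
            assert back.subjects == a.subjects

    def test_subsample_reproducible_and_bounded(self, populated):
        parent = populated.create_sample("p", populated.list_subjects())
        s1 = populated.random_subsample("s1", parent, 5, seed=42)
        s2 = populated.random_subsample("s2", parent, 5, seed=42)
        assert s1.subjects == s2.subjects
        assert set(s1.subjects) <= set(parent.subjects)
        full = populated.random_subsample("full", parent, len(parent.subjects),
                                          seed=0)
        assert full.subjects == parent.subjects
        with pytest.raises(ValidationError):
            populated.random_subsample("big", parent, 13, seed=0)

    def test_subsample_inclusion_frequencies_binomial(self, populated):
        """2000 draws of 5-of-10: every subject's inclusion frequency within
        3 sigma of 0.5."""
        parent = populated.create_sample("p10", populated.list_subjects()[:10])
        counts = {s: 0 for s in parent.subjects}
        for seed in range(2000):
            picked = parent  # reuse storage; only membership matters
            sub = populated.random_subsample("tmp", picked, 5, seed=seed)
            for s in sub.subjects:
                counts[s] += 1
        sigma = np.sqrt(0.5 * 0.5 / 2000)
        for s, c in counts.items():
            assert abs(c / 2000 - 0.5) < 3 * sigma + 1e-12, (s, c)

    def test_reevaluation_reproduces_membership(self, populated):
        q = populated.get_values("white_matter")["white_matter"].median()
        f = populated.create_sample_filter(
            "heavy", [("white_matter", ">=", q)], "exclude")
        a = populated.create_sample("a", ["S01", "S02", "S05"])
        u = populated.sample_setop("u", f, a, "union")
        r = populated.random_subsample("r", u, 3, seed=9)
        for name in ["heavy", "a", "u", "r"]:
            assert populated.reevaluate_sample(name) == \
                populated.get_sample(name).subjects

    def test_unknown_subject_rejected(self, populated):
        with pytest.raises(ValidationError):
            populated.create_sample("bad", ["NOBODY"])


class TestScenariosAnnotationsLog:
    def test_scenario_round_trip(self, db):
        state = {"expression": "(A | B) & ~C", "space": "reference",
                 "sample": ["S01", "S02"]}
        sid = db.save_scenario("callosal bundle", state,
                               application="bundle", description="demo")
        loaded = db.load_scenario(sid)
        assert loaded["state"] == state
        assert loaded["description"] == "demo"

    def test_unknown_scenario_not_found(self, db):
        with pytest.raises(NotFoundError):
            db.load_scenario(999)

    def test_subject_annotation_round_trip(self, db):
        db.annotate("subject", "S07", "possible segmentation artifact")
        db.annotate("subject", "S07", "re-checked: genuine finding")
        notes = db.get_annotations("subject", "S07")
        assert notes == ["possible segmentation artifact",
                         "re-checked: genuine finding"]

    def test_log_ordering_and_query(self, db):
        db.log_event("roi", {"action": "create"}, subject_id="S01")
        db.log_event("stats", {"action": "anova"})
        db.log_event("roi", {"action": "propagate"}, subject_id="S02")
        assert [e["event"]["action"] for e in db.query_log()] == \
            ["create", "anova", "propagate"]
        assert len(db.query_log(module="roi")) == 2
        assert db.query_log(subject_id="S01")[0]["event"]["action"] == "create"

    def test_log_links_scenarios(self, db):
        sid = db.save_scenario("s", {"x": 1})
        db.log_event("bundle", {"action": "save"}, scenario_id=sid)
        assert db.query_log()[0]["scenario_id"] == sid

    def test_log_export_parses_back(self, db):
        db.log_event("roi", {"action": "create", "r": 5.0}, subject_id="S01")
        db.log_event("sample", {"action": "filter"})
        text = db.export_log()
        entries = parse_log(text)
        assert entries == db.query_log()


class TestSingleDataModel:
    def test_captured_variable_indistinguishable_from_imported(
            self, db, clinical_csv):
        """A descriptor-written variable feeds the stats layer exactly like
        an imported one."""
        path, _ = clinical_csv
        db.import_table(path)
        db.add_variable("captured_volume", "numeric",
                        provenance='{"module": "descriptors"}')
        db.set_values("captured_volume",
                      {s: float(i) for i, s in enumerate(db.list_subjects())})
        frame = db.get_values(["white_matter", "captured_volume"])
        assert frame["captured_volume"].notna().all()
        assert frame.dtypes.nunique() == 1
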