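"""Family-state engine: timelines, classifier, covariates, panel."""

import numpy as np
import pandas as pd
import pytest

from famstates.engine import (
    InputIntegrityError,
    build_child_year_panel,
    build_marriage_timeline,
    classify_parent_state,
    count_same_year_death_dissolution,
    encode_covariates,
    summarize_panel,
)
from famstates.records import (
    EXTERNAL,
    ChildRecord,
    MarriageSpell,
    ParentState,
    ParentVital,
    Sex,
    ValidationError,
)


def _vit(*ids, dead=(), unknown=()):
    out = []
    for i in ids:
        out.append(
            ParentVital(i, dict(dead).get(i), known=i not in unknown)
        )
    return out


def _child(**kw):
    base = dict(
        child_id="c1", sex=Sex.FEMALE, birth_year=2000, twin=False,
        birth_order=1, mother_id="m", father_id="f", death_year=None,
        last_observed_year=2014,
    )
    base.update(kw)
    return ChildRecord(**base)


class TestTimeline:
    def test_single_interval_membership(self):
        tl = build_marriage_timeline(
            [MarriageSpell("f", "m", 2000, 2005)], _vit("f", "m")
        )
        assert tl.spouse_set("f", 2003) == frozenset({"m"})
        assert tl.spouse_set("f", 2006) == frozenset()
        assert tl.spouse_set("m", 2000) == frozenset({"f"})

    def test_overlapping_spells_define_polygyny(self):
        tl = build_marriage_timeline(
            [MarriageSpell("f", "a", 2000, 2010), MarriageSpell("f", "b", 2004, 2006)],
            _vit("f", "a", "b"),
        )
        assert tl.spouse_set("f", 2005) == frozenset({"a", "b"})
        assert tl.spouse_set("f", 2008) == frozenset({"a"})

    def test_deceased_have_empty_spouse_sets(self):
        tl = build_marriage_timeline(
            [MarriageSpell("f", "m", 2000, None)], _vit("f", "m", dead=[("f", 2005)])
        )
        assert tl.spouse_set("f", 2004) == frozenset({"m"})
        assert tl.spouse_set("f", 2006) == frozenset()
        assert not tl.alive("f", 2005)

    def test_unknown_parent_rejected(self):
        with pytest.raises(InputIntegrityError):
            build_marriage_timeline([MarriageSpell("f", "m", 2000, None)], _vit("f"))

    def test_end_before_start_rejected(self):
        with pytest.raises(ValidationError):
            MarriageSpell("f", "m", 2005, 2000)

    def test_matches_bruteforce_interval_scan(self, rng):
        """Per-year spouse sets equal an exhaustive scan of 100 random spells."""
        people = [f"p{i}" for i in range(12)]
        spells = []
        for _ in range(100):
            a, b = rng.choice(people, size=2, replace=False)
            start = int(rng.integers(1990, 2010))
            end = None if rng.uniform() < 0.3 else int(start + rng.integers(0, 10))
            spells.append(MarriageSpell(a, b, start, end))
        tl = build_marriage_timeline(spells, _vit(*people))
        for year in range(1988, 2015):
            for p in people:
                expected = set()
                for s in spells:
                    active = s.start_year <= year and (
                        s.end_year is None or year <= s.end_year
                    )
                    if active and s.parent_id == p:
                        expected.add(s.spouse_id)
                    if active and s.spouse_id == p:
                        expected.add(s.parent_id)
                assert tl.spouse_set(p, year) == frozenset(expected), (p, year)


class TestClassifier:
    def test_sole_biological_spouse_is_bio_mono(self):
        tl = build_marriage_timeline(
            [MarriageSpell("f", "m", 1999, None)], _vit("f", "m")
        )
        assert classify_parent_state(_child(), "mother", 2005, tl) == ParentState.BIO_MONO
        assert classify_parent_state(_child(), "father", 2005, tl) == ParentState.BIO_MONO

    def test_vital_status_dominates_spells(self):
        tl = build_marriage_timeline(
            [MarriageSpell("f", "m", 1999, None)], _vit("f", "m", dead=[("m", 2003)])
        )
        assert classify_parent_state(_child(), "mother", 2004, tl) == ParentState.DECEASED
        assert classify_parent_state(_child(), "mother", 2003, tl) == ParentState.DECEASED

    def test_unknown_vital_status_is_external(self):
        tl = build_marriage_timeline([], _vit("m", "f", unknown={"f"}))
        assert classify_parent_state(_child(), "father", 2005, tl) == ParentState.EXTERNAL

    @pytest.mark.parametrize(
        "known,alive,married,bio,nwives,expected",
        [
            (False, True, True, True, 1, ParentState.EXTERNAL),
            (True, False, True, True, 1, ParentState.DECEASED),
            (True, True, False, False, 0, ParentState.UNMARRIED),
            (True, True, True, True, 1, ParentState.BIO_MONO),
            (True, True, True, True, 2, ParentState.BIO_POLY),
            (True, True, True, False, 1, ParentState.STEP_MONO),
            (True, True, True, False, 2, ParentState.STEP_POLY),
        ],
    )
    def test_truth_table_father(self, known, alive, married, bio, nwives, expected):
        """Exhaustive branching combinations match the hand-written table."""
        spells = []
        if married:
            spouse = "m" if bio else "s1"
            spells.append(MarriageSpell("f", spouse, 2000, None))
            if nwives == 2:
                spells.append(MarriageSpell("f", "s2", 2000, None))
        dead = [("f", 2002)] if not alive else []
        tl = build_marriage_timeline(
            spells, _vit("f", "m", "s1", "s2", dead=dead, unknown=set() if known else {"f"})
        )
        assert classify_parent_state(_child(), "father", 2005, tl) == expected

    @pytest.mark.parametrize(
        "known,alive,married,bio,husband_wives,expected",
        [
            (False, True, True, True, 1, ParentState.EXTERNAL),
            (True, False, True, True, 1, ParentState.DECEASED),
            (True, True, False, False, 0, ParentState.UNMARRIED),
            (True, True, True, True, 1, ParentState.BIO_MONO),
            (True, True, True, True, 2, ParentState.BIO_POLY),
            (True, True, True, False, 1, ParentState.STEP_MONO),
            (True, True, True, False, 2, ParentState.STEP_POLY),
        ],
    )
    def test_truth_table_mother(self, known, alive, married, bio, husband_wives, expected):
        """Mother polygyny is the current husband's concurrent wife count."""
        spells = []
        if married:
            husband = "f" if bio else "h"
            spells.append(MarriageSpell(husband, "m", 2000, None))
            if husband_wives == 2:
                spells.append(MarriageSpell(husband, "w2", 2000, None))
        dead = [("m", 2002)] if not alive else []
        tl = build_marriage_timeline(
            spells, _vit("m", "f", "h", "w2", dead=dead, unknown=set() if known else {"m"})
        )
        assert classify_parent_state(_child(), "mother", 2005, tl) == expected


class TestCovariates:
    def test_base_case_all_zero(self):
        ind = encode_covariates(ParentState.BIO_MONO, ParentState.BIO_MONO, _child())
        assert all(v == 0 for v in ind.values())

    def test_step_polygyny_sets_both_z_and_p(self):
        ind = encode_covariates(ParentState.STEP_POLY, ParentState.BIO_MONO, _child())
        assert ind["Z"] == 1 and ind["P"] == 1

    def test_external_father_sets_u_only(self):
        ind = encode_covariates(ParentState.BIO_MONO, ParentState.EXTERNAL, _child())
        assert ind["U"] == 1
        assert all(ind[k] == 0 for k in ("V", "SM", "PB", "PN", "F"))

    def test_mother_deceased_excludes_marital_flags(self):
        ind = encode_covariates(ParentState.DECEASED, ParentState.BIO_MONO, _child())
        assert ind["X"] == 1 and ind["W"] == ind["Z"] == ind["P"] == 0

    def test_encoding_separates_all_leaves(self):
        """No two distinct leaves share an indicator vector (per perspective)."""
        child = _child()
        mother_vecs = {}
        father_vecs = {}
        for leaf in ParentState:
            mi = encode_covariates(leaf, ParentState.BIO_MONO, child)
            fi = encode_covariates(ParentState.BIO_MONO, leaf, child)
            mother_vecs[leaf] = tuple(mi[k] for k in ("X", "W", "Z", "P", "U"))
            father_vecs[leaf] = tuple(fi[k] for k in ("F", "V", "SM", "PB", "PN", "U"))
        assert len(set(mother_vecs.values())) == len(mother_vecs)
        assert len(set(father_vecs.values())) == len(father_vecs)


class TestPanel:
    def test_censoring_at_data_end(self, fixture_data, fixture_panel):
        """A 2009 birth observed through 2014 yields rows for ages 0-5 only."""
        rows = fixture_panel[fixture_panel.child_id == "c02"]
        assert list(rows.age) == [0, 1, 2, 3, 4, 5]
        assert (rows.survived == 1).all()

    def test_early_death_truncates_and_flags(self, fixture_panel):
        """Born 1975, died 1977: ages 0-2 with survived=0 on the final row."""
        rows = fixture_panel[fixture_panel.child_id == "c03"].sort_values("age")
        assert list(rows.age) == [0, 1, 2]
        assert list(rows.survived) == [1, 1, 0]

    def test_full_observation_base_case(self, fixture_panel):
        rows = fixture_panel[fixture_panel.child_id == "c01"]
        assert len(rows) == 19
        assert (rows.mother_state == "bio_mono").all()
        assert (rows.father_state == "bio_mono").all()

    def test_row_count_rule(self, small_population):
        """Rows per child = min(19, death age + 1, last observed age + 1)."""
        panel = small_population["panel"]
        counts = panel.groupby("child_id").size()
        for rec in small_population["records"]:
            expect = min(
                19,
                rec.last_observed_year - rec.birth_year + 1,
                (rec.death_year - rec.birth_year + 1) if rec.death_year else 99,
            )
            assert counts[rec.child_id] == expect

    def test_external_flag_consistency(self, small_population):
        panel = small_population["panel"]
        ext = (panel.mother_state == "external") | (panel.father_state == "external")
        assert (panel.U.to_numpy() == ext.to_numpy().astype(int)).all()

    def test_measurements_only_in_survey_years(self, fixture_data, fixture_panel):
        got = fixture_panel[fixture_panel.height_cm.notna()]
        assert set(got.year).issubset(set(fixture_data.survey_years))
        assert len(got) == len(fixture_data.measurements)

    def test_invalid_child_rejected(self):
        with pytest.raises(ValidationError):
            _child(last_observed_year=1999)

    def test_summary_counts(self, fixture_data, fixture_panel):
        s = summarize_panel(fixture_panel, fixture_data.records)
        assert s.n_children == 12
        assert s.n_rows == len(fixture_panel)
        assert s.n_deaths == 2  # c03 and c11


class TestSameYearDeathDissolution:
    def test_empty(self):
        tl = build_marriage_timeline([], _vit("m", "f"))
        assert count_same_year_death_dissolution([_child()], tl) == (0, 0)

    def test_single_overlap(self):
        tl = build_marriage_timeline(
            [MarriageSpell("f", "m", 2000, 2003)], _vit("f", "m")
        )
        rec = _child(death_year=2003, last_observed_year=2003, birth_year=2001)
        assert count_same_year_death_dissolution([rec], tl) == (1, 1)

    def test_matches_bruteforce_scan(self, small_population):
        records = small_population["records"]
        tl = build_marriage_timeline(
            small_population["spells"], small_population["vitals"]
        )
        overlap, total = count_same_year_death_dissolution(records, tl)
        ends = {}
        for s in small_population["spells"]:
            if s.end_year is not None:
                ends.setdefault(s.parent_id, set()).add(s.end_year)
                ends.setdefault(s.spouse_id, set()).add(s.end_year)
        exp_total = exp_overlap = 0
        for r in records:
            if r.death_year is None or r.death_year - r.birth_year > 18:
                continue
            exp_total += 1
            years = ends.get(r.mother_id, set()) | ends.get(r.father_id, set())
            if r.death_year in years:
                exp_overlap += 1
        assert (overlap, total) == (exp_overlap, exp_total)
        assert total > 0
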