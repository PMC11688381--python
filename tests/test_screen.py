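"""Tests for ranking, class-level screening and the descriptive reports."""

import filecmp

import pytest

from pvsignal.dedup import CaseRecord
from pvsignal.screen import (
    ScreenConfig,
    annual_trend,
    demographic_summary,
    percent,
    rank_top_drugs,
    results_to_frame,
    run_screen,
    screen_cases,
    screen_groups,
    screen_single_drugs,
)


def case(caseid, fda_dt="20200101", **kw):
    return CaseRecord(primaryid=caseid, caseid=caseid, fda_dt=fda_dt, **kw)


@pytest.fixture(scope="module")
def screened(small_cases, small_config):
    cases, _ = small_cases
    atc = {d.name: d.atc_class for d in small_config.drug_catalog}
    cfg = ScreenConfig(top_n=30, atc_map=atc, n_draws=20_000, seed=3)
    return screen_cases(cases, cfg), cfg


class TestRanking:
    def test_top_n_by_event_count(self):
        cfg = ScreenConfig(top_n=2, exclusion_list={})
        drug_cases = {"A": {"1", "2", "3", "4", "5"}, "B": {"1", "2", "3"}, "C": {"9"}}
        events = {"1", "2", "3", "4", "5"}
        assert rank_top_drugs(events, drug_cases, cfg) == ["A", "B"]

    def test_exclusion_precedes_truncation(self):
        cfg = ScreenConfig(top_n=1, exclusion_list={"A": "excluded"})
        drug_cases = {"A": {"1", "2", "3"}, "B": {"1"}}
        assert rank_top_drugs({"1", "2", "3"}, drug_cases, cfg) == ["B"]

    def test_fewer_entities_than_top_n(self):
        cfg = ScreenConfig(top_n=10, exclusion_list={})
        assert rank_top_drugs({"1"}, {"A": {"1"}}, cfg) == ["A"]

    def test_synthetic_ranking_matches_manifest_counts(self, screened, small_sim):
        out, _ = screened
        m = small_sim.manifest_cases
        truth = (
            m[m["is_event"] == 1].groupby("ps_drug").size()
            .reindex([r.entity for r in out.signals]).fillna(0)
        )
        observed = [r.table.a for r in out.signals]
        assert observed == truth.astype(int).tolist()
        assert observed == sorted(observed, reverse=True)


class TestSignals:
    def test_universe_shared_across_entities(self, screened):
        out, _ = screened
        totals = {r.table.a + r.table.c for r in out.signals}
        assert len(totals) == 1
        assert totals.pop() == len(out.event_cases)

    def test_planted_drugs_positive_by_all_three(self, screened):
        out, _ = screened
        by = {r.entity: r for r in out.signals}
        for name in ("STUDY DRUG 00", "STUDY DRUG 01", "STUDY DRUG 02"):
            r = by[name]
            assert r.flag_ror and r.flag_prr and r.flag_bcpnn and r.positive

    def test_row_count_is_min_top_n_entities(self, screened):
        out, cfg = screened
        assert len(out.signals) == min(cfg.top_n, len(out.ranked))

    def test_error_recorded_not_raised(self):
        # an entity covering the whole universe has zero margins for PRR
        cases = {"E": {"1", "2"}}
        res = screen_single_drugs(["E"], {"1", "2"}, cases, {"1", "2"},
                                  ScreenConfig(n_draws=10_000))
        assert res[0].error is not None


class TestGroups:
    def test_single_member_class_equals_drug(self, screened):
        out, cfg = screened
        drug_cases, events = out.drug_cases, out.event_cases
        universe = {c.caseid for c in out.cases}
        single = screen_single_drugs(["STUDY DRUG 00"], events, drug_cases, universe, cfg)[0]
        group = screen_groups({"solo": ["STUDY DRUG 00"]}, events, drug_cases, universe, cfg)[0]
        assert group.table == single.table
        assert group.ror == pytest.approx(single.ror)

    def test_union_counts_overlapping_case_once(self, screened):
        out, cfg = screened
        drug_cases = {"X": {"1", "2"}, "Y": {"2", "3"}}
        events = {"1", "2", "3"}
        universe = {str(i) for i in range(1, 60)}
        res = screen_groups({"g": ["X", "Y"]}, events, drug_cases, universe, cfg)
        assert res[0].table.a == 3  # not 4

    def test_disjoint_members_sum(self, screened):
        out, cfg = screened
        by = {r.entity: r for r in out.signals}
        grp = {r.entity: r for r in out.group_signals}
        member_a = sum(by[f"STUDY DRUG {i:02d}"].table.a for i in range(3))
        assert grp["planted class"].table.a == member_a

    def test_groups_ranked_by_ror(self, screened):
        out, _ = screened
        rors = [r.ror for r in out.group_signals]
        assert rors == sorted(rors, reverse=True)


class TestDemographics:
    def test_percent_rounding_examples(self):
        assert percent(18734, 40545) == 46.2
        assert percent(13183, 40545) == 32.5
        assert percent(14951, 40545) == 36.9

    def test_strata_partition_each_dimension(self, screened):
        out, _ = screened
        total = len(out.event_cases)
        df = out.demographics
        for dim in ("sex", "age_band", "country"):
            assert df.loc[df["dimension"] == dim, "count"].sum() == total

    def test_multi_outcome_case_counts_once_per_outcome(self):
        cases = [case("1", outcomes={"DE", "HO"}), case("2", outcomes=set())]
        df = demographic_summary(cases).set_index(["dimension", "category"])
        assert df.loc[("outcome", "Death"), "count"] == 1
        assert df.loc[("outcome", "Hospitalization or prolongation of hospitalization"), "count"] == 1
        assert df.loc[("outcome", "Others or unknown"), "count"] == 1

    def test_zero_cases_empty(self):
        assert demographic_summary([]).empty


class TestTrend:
    def test_zero_fill(self):
        cases = [case("1", "20040401"), case("2", "20060101")]
        df = annual_trend(cases).set_index("year")
        assert list(df.index) == [2004, 2005, 2006]
        assert df.loc[2005, "count"] == 0

    def test_counts_conserved(self, screened):
        out, _ = screened
        assert out.trend["count"].sum() == len(out.event_cases)

    def test_uniform_quarters_give_uniform_years(self, small_cases, small_sim):
        # all quarters fall in one year here, so the trend is a single bin
        cases, _ = small_cases
        event_ids = set(
            small_sim.manifest_cases.loc[small_sim.manifest_cases["is_event"] == 1, "caseid"]
        )
        df = annual_trend([c for c in cases if c.caseid in event_ids])
        assert df["count"].sum() == len(event_ids)


class TestEndToEnd:
    def test_repeated_runs_byte_identical(self, small_db, tmp_path, small_config):
        atc = {d.name: d.atc_class for d in small_config.drug_catalog}
        outs = []
        for name in ("r1", "r2"):
            cfg = ScreenConfig(top_n=10, atc_map=atc, n_draws=10_000, seed=5)
            run_screen(small_db, tmp_path / name, cfg)
            outs.append(tmp_path / name)
        for f in ("signals.csv", "groups.csv", "demographics.csv",
                  "pt_distribution.csv", "trend.csv"):
            assert filecmp.cmp(outs[0] / f, outs[1] / f, shallow=False), f

    def test_report_frame_schema(self, screened):
        out, _ = screened
        df = results_to_frame(out.signals)
        expected = ["entity", "a", "b", "c", "d", "ROR", "ROR_lo", "ROR_hi",
                    "PRR", "chi2", "IC", "IC025", "IC975",
                    "flag_ror", "flag_prr", "flag_bcpnn", "positive", "corrected"]
        assert list(df.columns)[: len(expected)] == expected
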