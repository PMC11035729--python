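"""Screening pipeline, SOC aggregation, ranking and the model interface."""

from __future__ import annotations

import pytest

from pvsignal import (
    DispropResult,
    DisproportionalityAnalysis,
    ExclusionPolicy,
    SignalCriteria,
    VocabularyMap,
    aggregate_by_soc,
    annotate_label_status,
    generate_vocabulary,
    run_screen,
    subgroup,
    top_n,
    write_reports,
)
from pvsignal.screen import screen_counts, write_results_csv


@pytest.fixture(scope="module")
def screened(small_synthetic, small_cases):
    cfg, _, _ = small_synthetic
    vocab = VocabularyMap(generate_vocabulary(cfg))
    return run_screen(small_cases, "ticagrelor", vocab=vocab)


class TestRunScreen:
    def test_planted_signals_found_and_exclusions_marked(self, small_synthetic,
                                                         small_cases):
        cfg, _, manifest = small_synthetic
        planted_pts = [pt for _, pt in manifest.planted]
        excl = ExclusionPolicy.from_pts(planted_pts[:2])
        results = run_screen(small_cases, "ticagrelor", exclusions=excl)
        by_pt = {r.pt: r for r in results}
        detected = {pt for pt in planted_pts if by_pt[pt].combined_signal}
        signal_set = {r.pt for r in results if r.is_signal}
        assert detected - set(planted_pts[:2]) <= signal_set
        for pt in planted_pts[:2]:
            assert by_pt[pt].excluded
            assert pt not in signal_set

    def test_empty_exclusions_equal_raw_triple_positive_set(self, screened,
                                                            small_cases):
        raw = {r.pt for r in screened if r.combined_signal}
        assert {r.pt for r in screened if r.is_signal} == raw

    def test_unreachable_min_a_yields_no_signals(self, small_cases):
        crit = SignalCriteria(min_a=10**9)
        results = run_screen(small_cases, "ticagrelor", criteria=crit)
        assert not any(r.combined_signal for r in results)
        assert results  # PTs still enumerated, never silently dropped

    def test_exclusion_changes_no_statistic(self, small_synthetic, small_cases):
        cfg, _, manifest = small_synthetic
        pt = manifest.planted[0][1]
        plain = {r.pt: r for r in run_screen(small_cases, "ticagrelor")}
        excl = {r.pt: r for r in run_screen(
            small_cases, "ticagrelor",
            exclusions=ExclusionPolicy.from_pts([pt]))}
        assert (plain[pt].ror, plain[pt].prr, plain[pt].chi2,
                plain[pt].ic_minus_2sd) == \
               (excl[pt].ror, excl[pt].prr, excl[pt].chi2,
                excl[pt].ic_minus_2sd)
        assert excl[pt].excluded and not plain[pt].excluded

    def test_stage_counts_are_consistent(self, screened):
        log = screen_counts(screened)
        assert log["final_signals"] == (log["triple_positive"]
                                        - log["excluded_positive"])
        assert log["tables_built"] == len(screened)

    def test_pipeline_deterministic_output(self, tmp_path, small_cases):
        paths = []
        for i in (1, 2):
            p = tmp_path / f"out{i}.csv"
            write_results_csv(run_screen(small_cases, "ticagrelor"), p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestAggregateBySoc:
    def test_hand_count_on_toy_results(self, toy_vocab):
        results = [
            DispropResult("X", "E", a=10, combined_signal=True),
            DispropResult("X", "F", a=5, combined_signal=True),
            DispropResult("X", "Dyspnoea", a=7, combined_signal=True),
            DispropResult("X", "E2", a=99, combined_signal=False),
        ]
        summaries = aggregate_by_soc(results, toy_vocab)
        by_soc = {s.soc: s for s in summaries}
        resp = by_soc["Respiratory, thoracic and mediastinal disorders"]
        assert (resp.n_reports, resp.n_signals) == (12, 2)
        card = by_soc["Cardiac disorders"]
        assert (card.n_reports, card.n_signals) == (10, 1)
        assert summaries[0] is resp  # sorted by report sum descending

    def test_all_signals_in_one_soc(self, toy_vocab):
        results = [DispropResult("X", "E", a=k, combined_signal=True)
                   for k in (3, 4)]
        (s,) = aggregate_by_soc(results, toy_vocab)
        assert s.n_signals == 2 and s.n_reports == 7

    def test_unmapped_bucket(self):
        results = [DispropResult("X", "Oddity", a=2, combined_signal=True)]
        (s,) = aggregate_by_soc(results, None)
        assert s.soc == "Unmapped"

    def test_signal_total_matches_fixture_truth(self, small_synthetic, screened):
        cfg, _, manifest = small_synthetic
        summaries = aggregate_by_soc(screened)
        n_signals = sum(r.is_signal for r in screened)
        assert sum(s.n_signals for s in summaries) == n_signals


class TestRankingAndViews:
    def make(self, pt, a, ror):
        return DispropResult("X", pt, a=a, ror=ror)

    def test_top_by_reports_with_tiebreak(self):
        rs = [self.make("p", 5, 9.0), self.make("q", 5, 4.0), self.make("r", 2, 7.0)]
        assert [r.pt for r in top_n(rs, "reports", 3)] == ["p", "q", "r"]

    def test_top_by_strength(self):
        rs = [self.make("p", 5, 9.0), self.make("q", 5, 4.0), self.make("r", 2, 7.0)]
        assert [r.ror for r in top_n(rs, "strength", 3)] == [9.0, 7.0, 4.0]

    def test_n_larger_than_list(self):
        rs = [self.make("p", 1, 1.0)]
        assert len(top_n(rs, "reports", 10)) == 1

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            top_n([], "alphabetical")

    def test_subgroup_filters_and_preserves_order(self):
        rs = [self.make(p, 1, 1.0) for p in ("p", "q", "r")]
        assert [r.pt for r in subgroup(rs, ["R", "p"])] == ["p", "r"]
        assert subgroup(rs, []) == []

    def test_label_annotation(self):
        rs = [self.make("p", 1, 1.0), self.make("q", 1, 1.0)]
        out = annotate_label_status(rs, {"P"})
        assert [r.labelled for r in out] == [True, False]
        assert all(r.labelled is False for r in annotate_label_status(rs, set()))


class TestModelInterface:
    def test_fit_matches_functional_pipeline(self, small_synthetic, small_cases,
                                             screened):
        cfg, _, _ = small_synthetic
        vocab = VocabularyMap(generate_vocabulary(cfg))
        res = DisproportionalityAnalysis(small_cases, "ticagrelor",
                                         vocab=vocab).fit()
        assert [(r.pt, r.a, r.is_signal) for r in res.results] == \
               [(r.pt, r.a, r.is_signal) for r in screened]

    def test_from_csv_roundtrip(self, tmp_path, small_synthetic):
        _, reports, manifest = small_synthetic
        p = tmp_path / "reports.csv"
        write_reports(reports, p)
        model = DisproportionalityAnalysis.from_csv(p, drug="ticagrelor")
        assert model.n_cases == manifest.n_cases
        assert model.n_exposed == manifest.ps_case_counts["ticagrelor"]

    def test_summary_and_frame_agree_with_run_log(self, small_synthetic,
                                                  small_cases):
        cfg, _, _ = small_synthetic
        res = DisproportionalityAnalysis(small_cases, "ticagrelor").fit()
        df = res.to_frame()
        assert len(df) == res.run_log["tables_built"]
        assert int(df["signal"].sum()) == res.run_log["final_signals"]
        text = res.summary()
        assert f"final signals:        {res.run_log['final_signals']:,}" in text

    def test_save_writes_report_files(self, tmp_path, small_cases):
        res = DisproportionalityAnalysis(small_cases, "ticagrelor").fit()
        res.save(tmp_path / "out")
        for name in ("results.csv", "soc_summary.csv", "top_by_reports.csv",
                     "top_by_strength.csv", "run_log.json"):
            assert (tmp_path / "out" / name).exists()
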