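"""Pair enumeration, the per-participant battery and matrix assembly."""

import numpy as np
import pytest

from sensorbench.benchmark_pipeline import (PipelineConfig, PairSpec,
                                            PipelineError, assemble_matrix,
                                            default_roster, enumerate_pairs,
                                            run_participant)
from sensorbench.benchmark_pipeline import FULL_BATTERY, CORRELATION_BATTERY
from sensorbench.signal_prep import ChannelName
from conftest import make_series


def _raw_same(pairs):
    return [p for p in pairs if p.pair_type == "same_parameter"
            and not p.a.mvavg and not p.a.filtered]


class TestEnumeratePairs:
    def test_single_parameter_two_sources(self):
        pairs = enumerate_pairs([ChannelName("HR", "VP"), ChannelName("HR", "BH")],
                                {"gsr_filter": False})
        same = _raw_same(pairs)
        assert len(same) == 1
        assert same[0].a.platform == "VP"  # reference leads
        # raw and mv-avg variants are paired separately
        assert sum(p.pair_type == "same_parameter" for p in pairs) == 2

    def test_five_ibi_sources_give_ten_pairs(self):
        roster = [ChannelName("IBI", "VP"), ChannelName("IBI", "BH"),
                  ChannelName("IBI", "E4"),
                  ChannelName("IBI", "VP", derived_from="ECG"),
                  ChannelName("IBI", "BH", derived_from="ECG")]
        pairs = enumerate_pairs(roster, {"gsr_filter": False})
        assert len(_raw_same(pairs)) == 10

    def test_default_roster_counts_logged_and_consistent(self):
        pairs = enumerate_pairs(default_roster())
        same = [p for p in pairs if p.pair_type == "same_parameter"]
        cross = [p for p in pairs if p.pair_type == "cross_parameter"]
        # 15 base same-parameter pairings per variant + filtered GSR pair
        assert len(_raw_same(pairs)) == 15
        assert len(same) == 32
        # 17 mv-avg channels, all unordered cross-parameter combinations
        assert len(cross) == 116
        assert all(p.battery == FULL_BATTERY for p in same)
        assert all(p.battery == CORRELATION_BATTERY for p in cross)

    def test_capability_violation_rejected(self):
        with pytest.raises(PipelineError):
            enumerate_pairs([ChannelName("GSR", "BH")])

    def test_deterministic_order(self):
        a = enumerate_pairs(default_roster())
        b = enumerate_pairs(list(reversed(default_roster())))
        assert [p.key for p in a] == [p.key for p in b]


def _channels_for(names_values, resolution_ms=1000):
    return {name.render(): make_series(v, resolution_ms=resolution_ms,
                                       parameter=name.parameter,
                                       platform=name.platform)
            for name, v in names_values}


class TestRunParticipant:
    def test_self_pair_identity_battery(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=400).cumsum() + 100
        a, b = ChannelName("HR", "VP"), ChannelName("HR", "BH")
        channels = _channels_for([(a, v), (b, v.copy())])
        pair = PairSpec(a, b, "same_parameter", FULL_BATTERY)
        res = run_participant(channels, [pair])
        m = res[pair.key]
        assert m.r2 == pytest.approx(1.0)
        assert m.mic == pytest.approx(1.0)
        assert m.dtw == 0.0
        assert m.frechet_global == 0.0
        assert m.ccf.best_lag == 0.0

    def test_missing_channel_isolated(self):
        rng = np.random.default_rng(1)
        a, b = ChannelName("HR", "VP"), ChannelName("HR", "BH")
        c = ChannelName("GSR", "VP")
        channels = _channels_for([(a, rng.normal(size=300) + 70),
                                  (b, rng.normal(size=300) + 75)])
        good = PairSpec(a, b, "same_parameter", CORRELATION_BATTERY)
        bad = PairSpec(a, c, "cross_parameter", CORRELATION_BATTERY)
        res = run_participant(channels, [good, bad])
        assert res[good.key] is not None
        assert res[bad.key] is None

    def test_all_pairs_failing_raises(self):
        a, b = ChannelName("HR", "VP"), ChannelName("HR", "BH")
        pair = PairSpec(a, b, "same_parameter", CORRELATION_BATTERY)
        with pytest.raises(PipelineError, match="all pairs failed"):
            run_participant({}, [pair])

    def test_configured_lag_recovered_end_to_end(self, clean_channels):
        a = ChannelName("GSR", "VP")
        b = ChannelName("GSR", "E4")
        pair = PairSpec(a, b, "same_parameter", CORRELATION_BATTERY)
        res = run_participant(clean_channels, [pair])
        assert res[pair.key].ccf.best_lag == pytest.approx(2.0, abs=1.0)


def _metrics_cell(pair, r2):
    from sensorbench.benchmark_pipeline import PairMetrics
    m = PairMetrics(pair=pair)
    m.r2 = r2
    return m


class TestAssembleMatrix:
    def _pairs(self):
        return [PairSpec(ChannelName("HR", "VP"), ChannelName("HR", "BH"),
                         "same_parameter", ("r2",)),
                PairSpec(ChannelName("GSR", "VP"), ChannelName("GSR", "E4"),
                         "same_parameter", ("r2",))]

    def test_two_by_two_hand_sorted(self):
        p_hr, p_gsr = self._pairs()
        results = {
            "q1": {p_hr.key: _metrics_cell(p_hr, 0.9), p_gsr.key: _metrics_cell(p_gsr, 0.2)},
            "q2": {p_hr.key: _metrics_cell(p_hr, 0.95), p_gsr.key: _metrics_cell(p_gsr, 0.8)},
        }
        m = assemble_matrix(results, "r2", pairs=[p_hr, p_gsr])
        # q2 has the larger participant mean -> first column
        assert list(m.data.columns) == ["q2", "q1"]
        assert list(m.data.index) == [p_hr.key, p_gsr.key]
        assert m.row_avgs[p_hr.key] == pytest.approx(0.925)
        assert m.col_avgs.loc["HR", "q2"] == pytest.approx(0.95)

    def test_ties_keep_enumeration_order(self):
        p_hr, p_gsr = self._pairs()
        results = {"q1": {p_hr.key: _metrics_cell(p_hr, 0.5),
                          p_gsr.key: _metrics_cell(p_gsr, 0.5)}}
        m = assemble_matrix(results, "r2", pairs=[p_hr, p_gsr])
        assert list(m.data.index) == [p_hr.key, p_gsr.key]

    def test_missing_cells_excluded_from_averages(self):
        p_hr, p_gsr = self._pairs()
        results = {
            "q1": {p_hr.key: _metrics_cell(p_hr, 0.9), p_gsr.key: None},
            "q2": {p_hr.key: _metrics_cell(p_hr, 0.7), p_gsr.key: _metrics_cell(p_gsr, 0.4)},
        }
        m = assemble_matrix(results, "r2", pairs=[p_hr, p_gsr])
        assert m.row_avgs[p_gsr.key] == pytest.approx(0.4)  # not imputed as 0
        assert np.isnan(m.data.loc[p_gsr.key, "q1"])

    def test_distance_statistic_sorted_ascending(self):
        p_hr, p_gsr = self._pairs()
        from sensorbench.benchmark_pipeline import PairMetrics
        def cell(pair, d):
            m = PairMetrics(pair=pair)
            m.dtw = d
            return m
        results = {"q1": {p_hr.key: cell(p_hr, 5.0), p_gsr.key: cell(p_gsr, 1.0)},
                   "q2": {p_hr.key: cell(p_hr, 6.0), p_gsr.key: cell(p_gsr, 2.0)}}
        m = assemble_matrix(results, "dtw", pairs=self._pairs())
        assert m.ascending
        assert list(m.data.columns) == ["q1", "q2"]  # smaller mean first

    def test_unknown_statistic_rejected(self):
        p_hr, _ = self._pairs()
        results = {"q1": {p_hr.key: _metrics_cell(p_hr, 0.5)}}
        with pytest.raises(KeyError):
            assemble_matrix(results, "nope", pairs=[p_hr])

    def test_display_frame_has_average_rows_and_column(self):
        p_hr, p_gsr = self._pairs()
        results = {"q1": {p_hr.key: _metrics_cell(p_hr, 0.9),
                          p_gsr.key: _metrics_cell(p_gsr, 0.2)}}
        m = assemble_matrix(results, "r2", pairs=[p_hr, p_gsr])
        disp = m.to_display_frame()
        assert "avg" in disp.columns
        assert "[HR] participant avg" in disp.index
        assert "[GSR] participant avg" in disp.index

    def test_order_invariant_to_participant_processing(self):
        p_hr, p_gsr = self._pairs()
        res1 = {"q1": {p_hr.key: _metrics_cell(p_hr, 0.9), p_gsr.key: _metrics_cell(p_gsr, 0.2)},
                "q2": {p_hr.key: _metrics_cell(p_hr, 0.8), p_gsr.key: _metrics_cell(p_gsr, 0.3)}}
        res2 = {k: res1[k] for k in ["q2", "q1"]}
        m1 = assemble_matrix(res1, "r2", pairs=[p_hr, p_gsr])
        m2 = assemble_matrix(res2, "r2", pairs=[p_hr, p_gsr])
        assert m1.data.equals(m2.data)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("metric_resolution_ms: 2000\nepsilon: 0.2\n")
        cfg = PipelineConfig.from_yaml(path)
        assert cfg.metric_resolution_ms == 2000
        assert cfg.epsilon == 0.2

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("nope: 1\n")
        with pytest.raises(PipelineError, match="unknown config"):
            PipelineConfig.from_yaml(path)
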