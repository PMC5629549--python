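"""HMM emissions, Viterbi decoding, segmentation, validation, calibration."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seqcnv.hmm import (
    COPY_NUMBER,
    STATES,
    STATE_INDEX,
    CNVCall,
    HMMError,
    HMMParams,
    baf_loglik,
    calibrate_lrr_params,
    call_sample,
    emission_matrix,
    lrr_loglik,
    merge_calls,
    read_hmm_config,
    segment,
    validate_region,
    viterbi,
    write_hmm_config,
)
from seqcnv.signal import SignalTrack, center_lrr
from seqcnv.simulate import TruthCNV, simulate_signal

from helpers import draw_state_emissions, emissions_frame, exhaustive_decode


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


class TestHMMParams:
    def test_transition_rows_sum_to_one(self):
        A = HMMParams().transition_matrix()
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_diploid_state_is_sticky(self):
        A = HMMParams().transition_matrix()
        i2 = STATE_INDEX["CN2"]
        assert A[i2, i2] == pytest.approx(0.999)
        # off-diagonal mass from CNV states mostly reverts to diploid
        i1 = STATE_INDEX["CN1"]
        assert A[i1, i2] == pytest.approx(0.9 * (1 - 0.89))

    @pytest.mark.parametrize(
        "kw",
        [
            {"lrr_sd": {**HMMParams().lrr_sd, "CN1": 0.0}},
            {"lrr_mean": {**HMMParams().lrr_mean, "CN3": -2.0}},
            {"lrr_mean": {**HMMParams().lrr_mean, "LOH": 0.3}},
            {"self_prob": {**HMMParams().self_prob, "CN0": 1.5}},
        ],
    )
    def test_invalid_parameters_raise(self, kw):
        with pytest.raises(HMMError):
            HMMParams(**kw)

    def test_config_round_trip(self):
        params = HMMParams()
        params.lrr_mean["CN1"] = -0.9
        params.self_prob["CN4"] = 0.95
        buf = io.StringIO()
        write_hmm_config(params, buf)
        buf.seek(0)
        back = read_hmm_config(buf)
        assert back.lrr_mean == params.lrr_mean
        assert back.self_prob == params.self_prob
        assert back.baf_het_sd == params.baf_het_sd


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------


class TestLrrLoglik:
    def test_matches_gaussian_closed_form_at_diploid_mean(self):
        params = HMMParams(outlier_frac=0.0)
        expected = -math.log(0.16 * math.sqrt(2 * math.pi))  # ~0.914
        assert lrr_loglik("CN2", 0.0, params) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.914, abs=5e-4)

    def test_unimodal_at_state_mean(self):
        assert lrr_loglik("CN2", 0.0) > lrr_loglik("CN2", -1.0)

    def test_deletion_mean_best_explained_by_zero_copy_state(self):
        x = HMMParams().lrr_mean["CN0"]
        scores = {s: lrr_loglik(s, x) for s in STATES}
        assert max(scores, key=scores.get) == "CN0"

    def test_unknown_state_raises(self):
        with pytest.raises(HMMError):
            lrr_loglik("CN9", 0.0)

    @given(x=st.floats(-50, 50), state=st.sampled_from(STATES))
    @settings(max_examples=100, deadline=None)
    def test_finite_for_all_finite_lrr(self, x, state):
        assert math.isfinite(lrr_loglik(state, x))


class TestBafLoglik:
    @pytest.mark.parametrize("state", STATES)
    def test_sentinel_contributes_nothing(self, state):
        assert baf_loglik(state, 2.0, 0.5) == 0.0

    def test_diploid_het_cluster_beats_loh_at_half(self):
        assert baf_loglik("CN2", 0.5, 0.5) > baf_loglik("LOH", 0.5, 0.5)

    def test_one_third_favors_three_copies_over_diploid(self):
        assert baf_loglik("CN3", 1 / 3, 0.5) > baf_loglik("CN2", 1 / 3, 0.5)

    def test_out_of_domain_raises(self):
        with pytest.raises(HMMError):
            baf_loglik("CN2", 1.5, 0.5)

    def test_depth_widens_het_clusters(self):
        # at depth 20 the binomial spread exceeds the array floor, so a
        # mildly off-center het BAF is less surprising than without depth
        assert baf_loglik("CN2", 0.38, 0.5, depth=20) > baf_loglik("CN2", 0.38, 0.5)

    @given(
        x=st.floats(0, 1),
        pf=st.one_of(st.none(), st.floats(0, 1)),
        state=st.sampled_from(STATES),
    )
    @settings(max_examples=150, deadline=None)
    def test_finite_even_at_degenerate_frequencies(self, x, pf, state):
        assert math.isfinite(baf_loglik(state, x, pf))
        assert math.isfinite(baf_loglik(state, x, pf, depth=20.0))


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------


class TestViterbi:
    def test_flat_diploid_signal_decodes_to_diploid(self):
        path = viterbi(emissions_frame(np.zeros(10)))
        assert path.labels == ["CN2"] * 10
        assert math.isfinite(path.loglik)

    def test_matches_exhaustive_enumeration_on_short_instances(self):
        rng = np.random.default_rng(42)
        params = HMMParams()
        for _ in range(40):
            n = int(rng.integers(2, 9))
            E = rng.normal(0.0, 3.0, size=(n, len(STATES)))
            got = viterbi_from_E(E, params)
            want_path, want_ll = exhaustive_decode(E, params)
            assert np.array_equal(got.states, want_path)
            assert got.loglik == pytest.approx(want_ll, abs=1e-9)

    def test_planted_deletion_run_recovered(self):
        rng = np.random.default_rng(7)
        params = HMMParams()
        parts = [
            draw_state_emissions("CN2", 75, rng, params),
            draw_state_emissions("CN1", 50, rng, params),
            draw_state_emissions("CN2", 75, rng, params),
        ]
        lrr = np.concatenate([p[0] for p in parts])
        baf = np.concatenate([p[1] for p in parts])
        pf = np.concatenate([p[2] for p in parts])
        path = viterbi(emissions_frame(lrr, baf, pf), params)
        planted = np.asarray(path.states[75:125])
        assert (planted == STATE_INDEX["CN1"]).mean() >= 0.8

    def test_empty_markers_raise(self):
        with pytest.raises(HMMError):
            viterbi(emissions_frame([]))


def viterbi_from_E(E, params):
    from seqcnv.hmm import _viterbi_from_emissions

    return _viterbi_from_emissions(E, params)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


class TestSegment:
    def test_all_diploid_yields_no_calls(self):
        df = emissions_frame(np.zeros(12))
        assert segment(viterbi(df), df) == []

    def test_single_embedded_run_becomes_one_call(self):
        df = emissions_frame(np.zeros(12))
        path = viterbi(df)
        path.states[5:8] = STATE_INDEX["CN1"]
        calls = segment(path, df)
        assert len(calls) == 1
        c = calls[0]
        assert (c.state, c.n_markers) == ("CN1", 3)
        assert c.start == df["start"].iloc[5] and c.end == df["end"].iloc[7]

    def test_path_reconstructed_from_calls_and_diploid_gaps(self):
        rng = np.random.default_rng(3)
        df = emissions_frame(np.zeros(60))
        path = viterbi(df)
        path.states[:] = rng.choice(len(STATES), size=60)
        calls = segment(path, df)
        rebuilt = np.full(60, STATE_INDEX["CN2"])
        starts = df["start"].to_numpy()
        for c in calls:
            i = np.searchsorted(starts, c.start)
            rebuilt[i : i + c.n_markers] = STATE_INDEX[c.state]
        assert np.array_equal(rebuilt, path.states)

    def test_length_mismatch_raises(self):
        df = emissions_frame(np.zeros(5))
        path = viterbi(df)
        with pytest.raises(HMMError):
            segment(path, df.iloc[:4])

    def test_confidence_is_margin_over_diploid(self):
        params = HMMParams()
        df = emissions_frame(np.full(6, -1.0))
        path = viterbi(df, params)
        calls = segment(path, df, params)
        assert len(calls) == 1
        E = emission_matrix(df, params)
        i0, i1 = STATE_INDEX[calls[0].state], STATE_INDEX["CN2"]
        assert calls[0].confidence == pytest.approx(float(E[:, i0].sum() - E[:, i1].sum()))


class TestMergeCalls:
    def _call(self, start, end, state="CN1", chrom="chr1"):
        return CNVCall(chrom, start, end, state, COPY_NUMBER[state], 5, 1.0)

    def test_merges_same_state_across_small_gap(self):
        merged = merge_calls([self._call(1, 10_000), self._call(10_501, 20_000)], 0.2)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (1, 20_000)
        assert merged[0].n_markers == 10

    def test_keeps_distinct_states_and_large_gaps(self):
        calls = [
            self._call(1, 10_000),
            self._call(50_001, 60_000),  # gap 67% of span
            self._call(60_501, 70_000, state="CN3"),
        ]
        assert len(merge_calls(calls, 0.2)) == 3


# ---------------------------------------------------------------------------
# region validation
# ---------------------------------------------------------------------------


class TestValidateRegion:
    def test_flat_diploid_region_validates_as_two_copies(self):
        df = emissions_frame(np.zeros(20))
        res = validate_region(df, "chr1", 1, 10_000)
        assert res.best == 2
        assert set(res.loglik) == {0, 1, 2, 3, 4}
        assert res.loglik[res.best] == max(res.loglik.values())

    @pytest.mark.parametrize("state,cn", [("CN0", 0), ("CN3", 3)])
    def test_state_drawn_regions_validate_correctly(self, state, cn):
        rng = np.random.default_rng(17)
        params = HMMParams()
        lrr, baf, pf = draw_state_emissions(state, 40, rng, params, snv_frac=0.6)
        df = emissions_frame(lrr, baf, pf)
        res = validate_region(df, "chr1", 1, int(df["end"].max()), params)
        assert res.best == cn

    def test_empty_region_raises(self):
        df = emissions_frame(np.zeros(5))
        with pytest.raises(HMMError, match="no signal"):
            validate_region(df, "chr1", 10_000_000, 10_000_100)


# ---------------------------------------------------------------------------
# whole-sample calling on simulated tracks
# ---------------------------------------------------------------------------


class TestCallSample:
    def test_diploid_only_track_yields_no_calls(self, small_cfg):
        # calibrate on a CNV-bearing sample, call a CNV-free one
        cfg_cnv = small_cfg(seed=21)
        track_cnv, truth = simulate_signal(cfg_cnv)
        params = calibrate_lrr_params(center_lrr(track_cnv), truth)
        cfg0 = small_cfg(seed=22, cnv_counts={})
        track0, truth0 = simulate_signal(cfg0)
        assert truth0 == []
        calls = call_sample(center_lrr(track0), params, min_markers=3)
        assert calls == []

    def test_planted_deletion_found_with_reciprocal_overlap(self, small_cfg):
        cfg = small_cfg(seed=23, cnv_counts={})
        truth = [TruthCNV("chrA", 1_500_001, 1_600_000, 0)]
        track, _ = simulate_signal(cfg, truth=truth)
        params = calibrate_lrr_params(center_lrr(track), truth)
        calls = [c for c in call_sample(center_lrr(track), params) if c.copy_number == 0]
        assert len(calls) == 1
        c = calls[0]
        ov = min(c.end, 1_600_000) - max(c.start, 1_500_001) + 1
        assert ov / 100_000 >= 0.7 and ov / c.length >= 0.7

    def test_empty_chromosome_raises(self):
        df = emissions_frame(np.zeros(3))
        track = SignalTrack("s", df, {"chr1": 20.0, "chr2": 20.0})
        with pytest.raises(HMMError, match="chr2"):
            call_sample(track)

    def test_stickier_diploid_state_cannot_increase_call_count(self, small_cfg):
        cfg = small_cfg(seed=24)
        track, truth = simulate_signal(cfg)
        track = center_lrr(track)
        base = calibrate_lrr_params(track, truth)
        counts = []
        for sp in (0.99, 0.999, 0.99999):
            p = calibrate_lrr_params(track, truth)
            p.self_prob["CN2"] = sp
            counts.append(len(call_sample(track, p, min_markers=1)))
        assert counts[0] >= counts[1] >= counts[2]


class TestCalibration:
    def test_recovers_class_ordering_and_ties_loh_to_diploid(self, small_cfg):
        cfg = small_cfg(seed=25)
        track, truth = simulate_signal(cfg)
        params = calibrate_lrr_params(center_lrr(track), truth)
        m = params.lrr_mean
        assert m["CN0"] < m["CN1"] < m["CN2"] < m["CN3"] < m["CN4"]
        assert m["LOH"] == m["CN2"] and params.lrr_sd["LOH"] == params.lrr_sd["CN2"]
        assert all(sd >= 0.05 for sd in params.lrr_sd.values())
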