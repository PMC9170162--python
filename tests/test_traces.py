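"""Trace processing: F/F0, binarization, activation, responder selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endonet.traces import (CalciumRecording, EventRaster, baseline_correct,
                            binarize, detect_activation,
                            exclude_initial_window, select_first_responders)


def make_rec(values, fs=10.0, onset=2.0):
    values = np.asarray(values, dtype=float)
    return CalciumRecording(values=values, fs=fs, onset=onset,
                           cell_ids=np.arange(values.shape[0]))


class TestCalciumRecording:
    def test_validation(self):
        with pytest.raises(ValueError):
            CalciumRecording(np.ones((2, 1)), 10.0, 0.0, np.arange(2))
        with pytest.raises(ValueError):
            CalciumRecording(np.array([[1.0, np.nan]]), 10.0, 0.0,
                             np.arange(1))
        with pytest.raises(ValueError):
            CalciumRecording(np.ones((2, 5)), 0.0, 0.0, np.arange(2))
        with pytest.raises(ValueError):
            CalciumRecording(np.ones((2, 5)), 10.0, 0.0, np.arange(3))


class TestBaselineCorrect:
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_baseline_mean_is_one(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(0.5, 3.0, size=(4, 100))
        rec = baseline_correct(raw, fs=10.0, baseline_window=(0.0, 5.0))
        assert np.allclose(rec.values[:, :50].mean(axis=1), 1.0, atol=1e-12)

    def test_nonpositive_baseline_names_cells(self):
        raw = np.ones((3, 100))
        raw[1] = 0.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            baseline_correct(raw, fs=10.0, baseline_window=(0.0, 5.0))

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="at least 1 s"):
            baseline_correct(np.ones((1, 100)), 10.0, (0.0, 0.5))

    def test_window_outside_recording_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(np.ones((1, 20)), 10.0, (0.0, 10.0))


class TestBinarize:
    def test_known_step_detected_at_right_sample(self):
        rng = np.random.default_rng(0)
        vals = 1.0 + rng.normal(0, 0.01, size=(1, 100))
        vals[0, 50:] += 1.0  # step between samples 49 and 50
        rec = make_rec(vals, onset=3.0)
        raster = binarize(rec, threshold_sd_mult=5)
        col = np.flatnonzero(raster.events[0])
        assert 49 in col  # derivative column 49 covers samples 49->50
        assert raster.times[49] == pytest.approx(5.0)

    def test_threshold_is_strict_and_monotone(self):
        rng = np.random.default_rng(1)
        vals = 1.0 + rng.normal(0, 0.02, size=(5, 400))
        vals[:, 200] += 0.5
        rec = make_rec(vals, onset=10.0)
        n5 = binarize(rec, 5).events.sum()
        n8 = binarize(rec, 8).events.sum()
        assert n8 <= n5

    def test_zero_sd_with_activity_warns(self):
        vals = np.ones((1, 100))
        vals[0, 60:] = 2.0
        rec = make_rec(vals, onset=3.0)
        with pytest.warns(UserWarning, match="zero baseline-derivative SD"):
            raster = binarize(rec)
        assert raster.events[0].any()

    def test_empty_baseline_rejected(self):
        rec = make_rec(np.ones((1, 100)), onset=0.0)
        with pytest.raises(ValueError, match="baseline window"):
            binarize(rec)


class TestDetectActivation:
    def test_all_zero_raster(self):
        rec = make_rec(np.ones((3, 100)) +
                       np.random.default_rng(0).normal(0, 0.01, (3, 100)))
        raster = binarize(rec, threshold_sd_mult=50)
        table = detect_activation(rec, raster)
        assert not table["active"].any()
        assert table["activation_time"].isna().all()

    def test_single_event_time(self):
        rng = np.random.default_rng(0)
        vals = 1.0 + rng.normal(0, 0.005, size=(1, 100))
        vals[0, 70:] += 1.0
        rec = make_rec(vals, onset=2.0)
        raster = binarize(rec)
        table = detect_activation(rec, raster)
        assert table.loc[0, "active"]
        assert table.loc[0, "activation_time"] == pytest.approx(7.0)

    def test_chain_activation_order_matches_hop_order(self):
        from endonet.simulate import SimulationParams, simulate_recording
        from endonet.tissue import SensitivityMap, build_hex_lattice

        tissue = build_hex_lattice(3, 6, seed=0)
        n = tissue.n_cells
        init = np.zeros(n, dtype=bool)
        init[7] = True
        sens = SensitivityMap(np.ones(n, dtype=bool), np.full(n, -1),
                              is_initiator=init)
        params = SimulationParams(duration=90, onset=10, noise_sd=0.0,
                                  propagation_prob=1.0, event_rate=0.02,
                                  seed=4, terminal_latency_s=0.0)
        rec, log = simulate_recording(tissue, sens, params)
        raster = binarize(rec, baseline_window=(0.0, 10.0))
        table = detect_activation(rec, raster)
        first = log.groupby("target_id")["time_s"].min()
        got = table.set_index("cell_id")["activation_time"]
        # activation order equals the simulator's hop order
        cells = first.index.to_numpy()
        assert np.array_equal(np.argsort(first.to_numpy(), kind="stable"),
                              np.argsort(got[cells].to_numpy(),
                                         kind="stable"))


class TestSelectFirstResponders:
    def make_table(self, n_cells, responders):
        act = np.zeros(n_cells, dtype=bool)
        t = np.full(n_cells, np.nan)
        for cid, when in responders.items():
            act[cid] = True
            t[cid] = when
        return pd.DataFrame({"cell_id": np.arange(n_cells), "active": act,
                             "activation_time": t,
                             "peak": np.ones(n_cells)})

    def test_quota_from_total_cells(self):
        resp = {i: float(i) for i in range(40)}
        table = self.make_table(100, resp)
        out = select_first_responders(table, 0.25)
        assert sorted(out) == list(range(25))

    def test_fewer_responders_returns_all(self):
        table = self.make_table(100, {i: float(i) for i in range(10)})
        out = select_first_responders(table, 0.25)
        assert sorted(out) == list(range(10))

    def test_tie_break_deterministic_under_permutation(self):
        rng = np.random.default_rng(0)
        resp = {i: float(min(i, 24)) for i in range(40)}  # ties at rank 25
        table = self.make_table(100, resp)
        ref = select_first_responders(table, 0.25)
        assert len(ref) == 25
        for _ in range(10):
            shuffled = table.sample(frac=1, random_state=rng.integers(2**31))
            out = select_first_responders(shuffled, 0.25)
            assert np.array_equal(np.sort(out), np.sort(ref))

    def test_bad_fraction(self):
        table = self.make_table(10, {0: 1.0})
        with pytest.raises(ValueError):
            select_first_responders(table, 0.0)


class TestExcludeInitialWindow:
    def make_raster(self, events_at, fs=10.0, onset=60.0, n=1, T=4200):
        ev = np.zeros((n, T - 1), dtype=bool)
        for t in events_at:
            ev[0, int(t * fs) - 1] = True
        return EventRaster(events=ev, fs=fs, onset=onset,
                           cell_ids=np.arange(n))

    def test_skip_zero_identity(self):
        r = self.make_raster([100.0])
        assert exclude_initial_window(r, 0.0) is r

    def test_boundary_semantics(self):
        r = self.make_raster([60 + 299.0, 60 + 301.0])
        out = exclude_initial_window(r, 300.0)
        times = out.times[out.events[0]]
        assert 359.0 not in times
        assert 361.0 in times

    def test_conservation_and_idempotence(self):
        r = self.make_raster([30.0, 100.0, 200.0, 380.0])
        out = exclude_initial_window(r, 300.0)
        removed = ((r.times >= 60) & (r.times < 360) & r.events[0]).sum()
        assert out.events.sum() == r.events.sum() - removed
        again = exclude_initial_window(out, 300.0)
        assert np.array_equal(again.events, out.events)

    def test_pre_onset_events_untouched(self):
        r = self.make_raster([30.0])
        out = exclude_initial_window(r, 300.0)
        assert out.events[0, int(30 * 10) - 1]

    def test_whole_record_warning(self):
        r = self.make_raster([10.0], onset=0.0, T=500)
        with pytest.warns(UserWarning, match="whole post-onset"):
            exclude_initial_window(r, 300.0)

    def test_negative_skip_rejected(self):
        r = self.make_raster([100.0])
        with pytest.raises(ValueError):
            exclude_initial_window(r, -1.0)
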