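"""Modulation-index algebra, state rates, significance, bursts, regressions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cortexstate as cs
from cortexstate import modulation, simulate
from cortexstate.config import anesthetized
from cortexstate.datatypes import DESYNCHRONIZED, SYNCHRONIZED, StimWindows
from conftest import seg_from_labels

rates = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


class TestModulationIndex:
    @pytest.mark.parametrize("fd,fs,expected", [
        (6.0, 2.0, 0.5), (3.0, 3.0, 0.0), (5.0, 0.0, 1.0), (0.0, 5.0, -1.0),
    ])
    def test_arithmetic(self, fd, fs, expected):
        assert cs.modulation_index(fd, fs) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        assert math.isnan(cs.modulation_index(0.0, 0.0))

    def test_negative_rate_invalid(self):
        with pytest.raises(ValueError):
            cs.modulation_index(-1.0, 2.0)

    @given(fd=rates, fs=rates)
    @settings(derandomize=True, max_examples=200)
    def test_bounds_and_sign(self, fd, fs):
        mi = cs.modulation_index(fd, fs)
        if fd + fs == 0:
            assert math.isnan(mi)
        else:
            assert -1.0 <= mi <= 1.0
            assert np.sign(mi) == np.sign(fd - fs)

    @given(fd=rates, fs=rates,
           scale=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    @settings(derandomize=True, max_examples=200)
    def test_scale_invariance(self, fd, fs, scale):
        if fd + fs > 0:
            a = cs.modulation_index(fd, fs)
            b = cs.modulation_index(fd * scale, fs * scale)
            assert a == pytest.approx(b, abs=1e-9)


class TestStateRates:
    def test_spontaneous_counting(self):
        labels = [SYNCHRONIZED] * 10 + [DESYNCHRONIZED] * 10
        seg = seg_from_labels(labels)
        spikes = np.arange(10) + 0.5          # one spike per synchronized bin
        r = cs.rate_by_state_spontaneous(spikes, seg, min_bins=5)
        assert r.fr_sync == pytest.approx(1.0)
        assert r.fr_desync == pytest.approx(0.0)

    def test_empty_train_undefined_mi(self):
        seg = seg_from_labels([SYNCHRONIZED] * 40 + [DESYNCHRONIZED] * 40)
        r = cs.rate_by_state_spontaneous(np.empty(0), seg)
        assert r.fr_sync == 0.0 and r.fr_desync == 0.0
        assert math.isnan(cs.modulation_index(r.fr_desync, r.fr_sync))

    def test_missing_state_flagged(self):
        seg = seg_from_labels([SYNCHRONIZED] * 50)
        r = cs.rate_by_state_spontaneous(np.arange(5.0), seg)
        assert math.isnan(r.fr_desync)
        assert any("absent" in f for f in r.flags)

    def test_generator_design_rate_recovered(self, dataset, segmented):
        # gain-1 units: FR_s ~= FR_d ~= design rate within 3 SE
        _, seg = segmented
        units = dataset.unit_table.units
        for uid in units.index[:8]:
            row = units.loc[uid]
            t = dataset.unit_table.spike_times(uid)
            r = cs.rate_by_state_spontaneous(t, seg)
            for fr, design, n in ((r.fr_sync, row["fr_sync_hz"], r.sync_counts.size),
                                  (r.fr_desync, row["fr_desync_hz"],
                                   r.desync_counts.size)):
                se = math.sqrt(max(design, 0.1) / n)
                assert abs(fr - design) < 4 * se

    def test_evoked_counting(self):
        ev = pd.DataFrame([{"stim_time_s": 100.0, "pre_start_s": 98.0,
                            "pre_end_s": 100.0, "post_start_s": 101.0,
                            "post_end_s": 103.0, "effective": True}])
        spikes = np.array([98.2, 98.5, 99.0, 99.9, 101.5])
        r = cs.rate_by_state_evoked(spikes, StimWindows(events=ev), min_events=1)
        assert r.fr_sync == pytest.approx(2.0)    # 4 spikes / 2 s
        assert r.fr_desync == pytest.approx(0.5)  # 1 spike / 2 s

    def test_all_events_ineffective_skips_unit(self):
        ev = pd.DataFrame([{"stim_time_s": 100.0, "pre_start_s": 98.0,
                            "pre_end_s": 100.0, "post_start_s": 101.0,
                            "post_end_s": 103.0, "effective": False}])
        r = cs.rate_by_state_evoked(np.arange(10.0), StimWindows(events=ev))
        assert math.isnan(r.fr_sync)
        assert any("skipped" in f for f in r.flags)


class TestSignificance:
    def test_zero_variance_is_ns(self):
        seg = seg_from_labels([SYNCHRONIZED] * 40 + [DESYNCHRONIZED] * 40)
        spikes = np.arange(80) + 0.5           # exactly one spike per bin
        r = cs.rate_by_state_spontaneous(spikes, seg)
        p, sig = modulation.per_cell_significance(r)
        assert math.isnan(p) and sig == modulation.NS

    def test_strong_suppression_detected(self, rng):
        labels = ([SYNCHRONIZED] * 300 + [DESYNCHRONIZED] * 300) * 2
        seg = seg_from_labels(labels)
        hits = 0
        for i in range(50):
            t = []
            for st_, s, e in seg.epochs:
                lam = 3.0 if st_ == SYNCHRONIZED else 0.6
                t.append(simulate._poisson_times(rng, lam, s, e))
            r = cs.rate_by_state_spontaneous(np.sort(np.concatenate(t)), seg)
            _, sig = modulation.per_cell_significance(r)
            hits += sig == modulation.SUPPRESSED
        assert hits >= 48     # >= 95% power at gain 0.2, 600 bins/state

    def test_evoked_paired_test_detects_doubling(self, rng):
        n_ev = 50
        rows, spikes = [], []
        for i in range(n_ev):
            t0 = 10.0 + 10.0 * i
            rows.append({"stim_time_s": t0, "pre_start_s": t0 - 2, "pre_end_s": t0,
                         "post_start_s": t0 + 1, "post_end_s": t0 + 3,
                         "effective": True})
            spikes.append(simulate._poisson_times(rng, 4.0, t0 - 2, t0))
            spikes.append(simulate._poisson_times(rng, 8.0, t0 + 1, t0 + 3))
        r = cs.rate_by_state_evoked(np.sort(np.concatenate(spikes)),
                                    StimWindows(events=pd.DataFrame(rows)))
        assert abs(r.fr_desync - 8.0) < 3 * math.sqrt(8.0 / (2 * n_ev))
        p, sig = modulation.per_cell_significance(r)
        assert sig == modulation.ENHANCED and p < 0.05


class TestSignedRank:
    def test_exact_small_sample(self):
        # all-positive n=5: p = 2/2^5 by enumeration of sign patterns
        med, p = modulation.population_signed_rank([0.1, 0.2, 0.3, 0.4, 0.5])
        assert med == pytest.approx(0.3)
        assert p == pytest.approx(0.0625)

    def test_symmetric_sample_not_significant(self):
        _, p = modulation.population_signed_rank([-0.4, 0.4, -0.2, 0.2, -0.1, 0.1])
        assert p > 0.5

    def test_all_zero_mi(self):
        med, p = modulation.population_signed_rank([0.0] * 6)
        assert (med, p) == (0.0, 1.0)

    def test_too_few_defined(self):
        with pytest.raises(ValueError):
            modulation.population_signed_rank([0.1, np.nan, 0.2])


class TestBurstFraction:
    def test_poisson_closed_form_within_state(self, rng):
        lam = 5.0
        labels = [SYNCHRONIZED] * 2000
        seg = seg_from_labels(labels)
        t = np.sort(simulate._poisson_times(rng, lam, 0.0, 2000.0))
        for w_ms in (10.0, 15.0, 20.0, 25.0):
            bf = cs.burst_fraction(t, seg, window_ms=w_ms)
            expected = 1.0 - math.exp(-lam * w_ms / 1000.0)
            se = math.sqrt(expected * (1 - expected) / t.size)
            assert abs(bf["frac_sync"] - expected) < 4 * se

    def test_regular_train_has_zero_fraction(self):
        seg = seg_from_labels([SYNCHRONIZED] * 100)
        t = np.arange(0.0, 100.0, 0.1)
        bf = cs.burst_fraction(t, seg, window_ms=20.0)
        assert bf["frac_sync"] == 0.0

    def test_boundary_spanning_isis_discarded(self):
        seg = seg_from_labels([SYNCHRONIZED] * 10 + [DESYNCHRONIZED] * 10
                              + [SYNCHRONIZED] * 10)
        # one spike near each side of the state boundary: the short ISI
        # spans epochs and must not count
        t = np.array([9.999, 10.001, 20.0005, 25.0, 25.005])
        bf = cs.burst_fraction(t, seg, window_ms=20.0)
        # sync ISIs: (20.0005, 25.0) long + (25.0, 25.005) short; the short
        # (9.999, 10.001) pair spans the boundary and is discarded
        assert bf["frac_sync"] == pytest.approx(0.5)
        assert math.isnan(bf["frac_desync"])

    def test_under_two_spikes_undefined(self):
        seg = seg_from_labels([SYNCHRONIZED] * 10 + [DESYNCHRONIZED] * 10)
        bf = cs.burst_fraction(np.array([3.0]), seg)
        assert math.isnan(bf["frac_sync"]) and math.isnan(bf["frac_desync"])

    def test_doublet_generator_hits_analytic_target(self, rng):
        cfg = anesthetized(seed=55, duration_s=5000.0, n_channels=1, lfp_fs=100.0)
        cfg.state_mean_durations["desynchronized"] = math.inf
        for cp in cfg.class_params.values():
            cp.n_units = 0
        cp = cfg.class_params["dPC"]
        cp.n_units = 5
        cp.baseline_rate_hz = 4.0
        cp.burst_prob = simulate.solve_burst_prob(0.25, 4.0, 0.02, 0.5, 0.5, 0.004)
        _, epochs = simulate.generate_state_sequence(cfg)
        ud = simulate.generate_updown_phases(cfg, epochs)
        spikes, _ = simulate.generate_spike_trains(cfg, epochs, ud)
        seg = seg_from_labels([SYNCHRONIZED] * int(cfg.duration_s))
        fracs = [cs.burst_fraction(
            np.sort(spikes.loc[spikes.unit_id == u, "timestamp_s"].to_numpy()),
            seg, 20.0)["frac_sync"] for u in range(5)]
        assert np.mean(fracs) == pytest.approx(0.25, abs=0.01)


class TestBurstComparison:
    def test_identical_groups_rank_sum_p_one(self):
        df = pd.DataFrame({"cell_class": ["dPC"] * 6,
                           "frac_sync": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
                           "frac_desync": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]})
        out = modulation.burst_state_comparison(df)
        assert out["posthoc_p"]["dPC"] == 1.0

    def test_null_kruskal_p_uniform(self, rng):
        ps = []
        for _ in range(300):
            df = pd.DataFrame({
                "cell_class": np.repeat(["sPC", "dPC", "sFS", "dFS"], 8),
                "frac_sync": rng.random(32) * 0.3,
                "frac_desync": rng.random(32) * 0.3})
            ps.append(modulation.burst_state_comparison(df)["kruskal_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_class_detected_with_power(self, rng):
        hits = 0
        for _ in range(50):
            base = rng.normal(0.20, 0.03, 30)
            df = pd.DataFrame({
                "cell_class": ["dPC"] * 30,
                "frac_sync": base,
                "frac_desync": rng.normal(0.15, 0.03, 30)})
            out = modulation.burst_state_comparison(df)
            hits += out["posthoc_p"]["dPC"] < 0.05
        assert hits >= 40      # >= 80% power for a -0.05 shift at n=30

    def test_empty_group_dropped_with_warning(self):
        df = pd.DataFrame({"cell_class": ["sPC"] * 5 + ["dPC"] * 5,
                           "frac_sync": [0.1] * 5 + [np.nan] * 5,
                           "frac_desync": [0.2, 0.3, 0.1, 0.15, 0.2] + [np.nan] * 5})
        out = modulation.burst_state_comparison(df)
        assert any("dPC" in w for w in out["warnings"])
        assert "dPC" not in out["posthoc_p"]


class TestRateModulationCorrelation:
    def test_perfect_semilog_fit(self):
        fr = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        mi = 0.2 * np.log10(fr)
        out = modulation.rate_modulation_correlation(fr, mi)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(0.2)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_rate_units_excluded(self):
        fr = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0])
        mi = np.array([0.9, 0.1, 0.1, 0.1, 0.1, 0.1])
        out = modulation.rate_modulation_correlation(fr, mi)
        assert out["n"] == 5

    def test_null_r_distribution(self, rng):
        n = 20
        rs = []
        for _ in range(500):
            fr = rng.lognormal(0.5, 0.8, n)
            mi = rng.uniform(-0.5, 0.5, n)
            rs.append(modulation.rate_modulation_correlation(fr, mi)["r"])
        rs = np.asarray(rs)
        assert abs(rs.mean()) < 0.05
        # |r|^2 under the null is Beta(1/2, (n-2)/2)
        q95 = math.sqrt(stats.beta.ppf(0.95, 0.5, (n - 2) / 2))
        emp = np.quantile(np.abs(rs), 0.95)
        assert emp == pytest.approx(q95, abs=0.06)

    def test_gain_increasing_with_rate_gives_positive_r(self, rng):
        # constructed positive-dependence cohort of deep PCs
        fr = rng.lognormal(1.0, 0.6, 40)
        gain = (fr / 3.0) ** 0.5
        mi = (gain - 1) / (gain + 1) + rng.normal(0, 0.05, 40)
        out = modulation.rate_modulation_correlation(fr, mi)
        assert out["r"] > 0 and out["p"] < 0.05


class TestMuaAndSummary:
    def _cohort(self, gains, n_each=6, seed=0, duration=400.0):
        """Spike-train-only dataset with ground-truth segmentation."""
        cfg = anesthetized(seed=seed, duration_s=duration, n_channels=1,
                           lfp_fs=100.0)
        cfg.state_mean_durations = {"synchronized": 60.0, "desynchronized": 60.0}
        for cls, cp in cfg.class_params.items():
            cp.n_units = n_each
            cp.desync_gain = gains.get(cls, 1.0)
            cp.burst_prob = 0.0
        labels, epochs = simulate.generate_state_sequence(cfg)
        ud = simulate.generate_updown_phases(cfg, epochs)
        spikes, units = simulate.generate_spike_trains(cfg, epochs, ud)
        from cortexstate.datatypes import UnitTable
        ut = UnitTable(spikes=spikes, units=units)
        return ut, seg_from_labels(labels)

    def test_mua_modulation_direction(self):
        tables, segs = [], []
        for seed in range(12):
            ut, seg = self._cohort({"sPC": 0.3, "sFS": 0.3,
                                    "dPC": 1.6, "dFS": 1.6}, seed=seed)
            tables.append(ut)
            segs.append(seg)
        out = cs.modulation.mua_modulation(tables, segs)
        sup = out.set_index("window").loc["superficial"]
        deep = out.set_index("window").loc["deep"]
        assert sup["mean_mi"] < 0 and sup["p"] < 0.05
        assert deep["mean_mi"] > 0 and deep["p"] < 0.05

    def test_mua_single_recording_has_na_p(self):
        ut, seg = self._cohort({}, seed=3)
        out = cs.modulation.mua_modulation(ut, seg)
        assert math.isnan(out["p"].iloc[0])

    def test_gain_recovered_from_mi(self):
        # configured gains recovered via gain = (1+MI)/(1-MI)
        gains = {"sPC": 0.4, "dPC": 1.0, "sFS": 0.6, "dFS": 1.5}
        ut, seg = self._cohort(gains, n_each=10, seed=9, duration=1500.0)
        res = cs.analyze_units(ut, seg)
        res = res.join(ut.units["cell_class"])
        for cls, g in gains.items():
            mis = res.loc[res["cell_class"] == cls, "mi"].dropna().to_numpy()
            est = (1 + mis) / (1 - mis)
            se = est.std(ddof=1) / math.sqrt(est.size)
            assert abs(est.mean() - g) < max(3 * se, 0.05)

    def test_summary_suppressed_cohort_row(self):
        ut, seg = self._cohort({"sPC": 0.2}, n_each=10, seed=4, duration=1200.0)
        res = cs.analyze_units(ut, seg)
        res = res.join(ut.units["cell_class"])
        summ = cs.summarize_population(res)
        row = summ.loc["sPC"]
        assert row["n_units"] == 10
        assert row["n_enhanced"] == 0
        assert row["n_suppressed"] == 10
        assert row["enhanced_suppressed"] == "0:10"

    def test_summary_counts_are_consistent(self, dataset, segmented):
        _, seg = segmented
        labels = cs.label_units(dataset.unit_table)
        res = cs.analyze_units(dataset.unit_table, seg, labels=labels)
        summ = cs.summarize_population(res)
        grouped = res.copy()
        grouped["group"] = grouped.apply(cs.modulation.group_key, axis=1)
        for cls, row in summ.iterrows():
            sub = grouped[grouped["group"] == cls]
            n_ns = int((sub["sig_class"] == cs.modulation.NS).sum())
            assert row["n_enhanced"] + row["n_suppressed"] + n_ns == row["n_units"]

    def test_summary_empty_class_blank_ratio(self):
        res = pd.DataFrame({"cell_class": ["dPC"] * 6, "mi": [0.1] * 6,
                            "sig_class": ["ns"] * 6,
                            "fr_sync_hz": [1.0] * 6, "fr_desync_hz": [1.2] * 6})
        summ = cs.summarize_population(res)
        assert summ.loc["sFS", "n_units"] == 0
        assert summ.loc["sFS", "enhanced_suppressed"] == ""
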