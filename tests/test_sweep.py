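"""Threshold bookkeeping, montage enumeration, pareto selection, sweep."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tidose.errors import ConfigurationError
from tidose.phantom import electrode_positions, make_roi_set
from tidose.sweep import (argmax_depth_mm, enumerate_montages,
                          exposure_metrics, homolog_pairs,
                          iso_percentile_threshold, pareto_front, run_sweep)


class TestThreshold:
    def test_order_statistic_interpolation(self):
        """100 voxels valued 1..100: the 98th percentile interpolates to
        98.02 and exactly 2 voxels lie strictly above."""
        vals = np.arange(1.0, 101.0).reshape(10, 10, 1)
        mask = np.ones_like(vals, dtype=bool)
        thr = iso_percentile_threshold(vals, mask, 98.0)
        assert thr == pytest.approx(98.02)
        assert int((vals > thr).sum()) == 2

    def test_constant_map(self):
        vals = np.full((4, 4, 4), 0.7)
        mask = np.ones_like(vals, dtype=bool)
        thr = iso_percentile_threshold(vals, mask, 98.0)
        assert thr == 0.7
        assert not (vals > thr).any()

    def test_median(self):
        vals = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        assert iso_percentile_threshold(vals, np.ones_like(vals, bool),
                                        50.0) == 2.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ConfigurationError):
            iso_percentile_threshold(np.ones((2, 2, 2)),
                                     np.zeros((2, 2, 2), bool))

    def test_suprathreshold_fraction_close_to_nominal(self, rng):
        vals = rng.random((30, 30, 30))
        mask = np.ones_like(vals, dtype=bool)
        thr = iso_percentile_threshold(vals, mask, 98.0)
        frac = (vals > thr).mean()
        assert abs(frac - 0.02) <= 1.0 / vals.size + 1e-12


class TestExposureMetrics:
    def _toy(self, rng):
        vals = rng.random((10, 10, 10))
        brain = np.zeros_like(vals, dtype=bool)
        brain[1:-1, 1:-1, 1:-1] = True
        target = np.zeros_like(brain)
        target[3:6, 3:6, 3:6] = True
        return vals, target, brain

    def test_bruteforce_recount(self, rng):
        """Focality/activation equal an exhaustive voxel-loop recount."""
        vals, target, brain = self._toy(rng)
        met = exposure_metrics(vals, target, brain, p=90.0)
        thr = np.percentile(vals[brain], 90.0)
        n_supra = n_hit = n_target = n_target_hit = 0
        for idx in np.ndindex(vals.shape):
            if not brain[idx]:
                continue
            supra = vals[idx] > thr
            n_supra += supra
            if target[idx]:
                n_target += 1
                n_target_hit += supra
            n_hit += supra and target[idx]
        assert met.suprathreshold_brain_voxels == n_supra
        assert met.focality_pct == pytest.approx(100.0 * n_hit / n_supra)
        assert met.activation_pct == pytest.approx(
            100.0 * n_target_hit / n_target)
        tv = vals[target]
        assert met.target_mean == pytest.approx(tv.mean())
        assert met.target_sd == pytest.approx(tv.std(ddof=1))
        assert met.target_median == pytest.approx(np.median(tv))

    def test_all_suprathreshold_inside_target_gives_full_focality(self):
        vals = np.zeros((6, 6, 6))
        brain = np.ones_like(vals, dtype=bool)
        target = np.zeros_like(brain)
        target[2:4, 2:4, 2:4] = True
        vals[target] = np.linspace(1.0, 2.0, int(target.sum()))
        met = exposure_metrics(vals, target, brain, p=95.0)
        assert met.focality_pct == 100.0
        assert met.suprathreshold_brain_voxels > 0

    def test_disjoint_target_gives_zero(self, rng):
        vals = np.zeros((6, 6, 6))
        brain = np.ones_like(vals, dtype=bool)
        vals[0, 0, 0] = vals[5, 5, 5] = 1.0
        target = np.zeros_like(brain)
        target[2:4, 2:4, 2:4] = True
        met = exposure_metrics(vals, target, brain, p=98.0)
        assert met.activation_pct == 0.0
        assert met.focality_pct == 0.0

    def test_constant_map_has_undefined_focality(self):
        vals = np.ones((4, 4, 4))
        brain = np.ones_like(vals, dtype=bool)
        target = np.zeros_like(brain)
        target[1:3, 1:3, 1:3] = True
        met = exposure_metrics(vals, target, brain, p=98.0)
        assert np.isnan(met.focality_pct)
        assert met.activation_pct == 0.0

    def test_activation_monotone_in_percentile(self, rng):
        vals, target, brain = self._toy(rng)
        acts = [exposure_metrics(vals, target, brain, p=p).activation_pct
                for p in (50.0, 80.0, 95.0, 99.0)]
        assert all(a >= b - 1e-12 for a, b in zip(acts, acts[1:]))


class TestEnumeration:
    def test_four_electrode_listing(self, coarse_phantom):
        els = electrode_positions(["F3", "F4", "TP7", "TP8"], coarse_phantom)
        montages = enumerate_montages(els)
        assert len(montages) == 3
        by_class = {m.geometry_class: m for m in montages}
        assert set(by_class) == {"parallel-sagittal", "parallel-coronal",
                                 "crossing"}
        sag = by_class["parallel-sagittal"]
        assert {frozenset((sag.pair1.anode.label, sag.pair1.cathode.label)),
                frozenset((sag.pair2.anode.label, sag.pair2.cathode.label))} \
            == {frozenset(("F3", "TP7")), frozenset(("F4", "TP8"))}
        cor = by_class["parallel-coronal"]
        assert {frozenset((cor.pair1.anode.label, cor.pair1.cathode.label)),
                frozenset((cor.pair2.anode.label, cor.pair2.cathode.label))} \
            == {frozenset(("F3", "F4")), frozenset(("TP7", "TP8"))}
        cro = by_class["crossing"]
        assert {frozenset((cro.pair1.anode.label, cro.pair1.cathode.label)),
                frozenset((cro.pair2.anode.label, cro.pair2.cathode.label))} \
            == {frozenset(("F3", "TP8")), frozenset(("F4", "TP7"))}

    def test_too_few_electrodes_rejected(self, coarse_phantom):
        els = electrode_positions(["F3", "F4", "TP7"], coarse_phantom)
        with pytest.raises(ConfigurationError):
            enumerate_montages(els)

    def test_count_matches_bruteforce_for_three_pairs(self, coarse_phantom):
        """6 electrodes (3 homolog pairs): count equals an independent
        brute-force enumeration of pairings up to the stated symmetries."""
        labels = ["F3", "F4", "TP7", "TP8", "AF3", "AF4"]
        els = electrode_positions(labels, coarse_phantom)
        montages = enumerate_montages(els)
        pairs = homolog_pairs(els)
        k = len(pairs)
        assert len(montages) == 3 * k * (k - 1) // 2  # closed form

        # brute force: all ways to partition 2 homolog pairs into two
        # channels, deduplicated under channel swap and polarity swap
        seen = set()
        for (l1, r1), (l2, r2) in itertools.combinations(pairs, 2):
            quad = [l1.label, r1.label, l2.label, r2.label]
            for perm in itertools.permutations(quad):
                c1 = frozenset(perm[:2])
                c2 = frozenset(perm[2:])
                if len(c1) == 2 and len(c2) == 2:
                    seen.add(frozenset((c1, c2)))
        assert len(montages) == len(seen)

    def test_montage_pairings_unique(self, coarse_phantom):
        els = electrode_positions(["F3", "F4", "TP7", "TP8", "AF3", "AF4"],
                                  coarse_phantom)
        montages = enumerate_montages(els)
        keys = {frozenset((frozenset((m.pair1.anode.label,
                                      m.pair1.cathode.label)),
                           frozenset((m.pair2.anode.label,
                                      m.pair2.cathode.label))))
                for m in montages}
        assert len(keys) == len(montages)


class TestPareto:
    def test_dominated_row_unflagged(self):
        flags = pareto_front(np.array([[1.0, 1, 1], [2.0, 2, 2]]))
        assert flags.tolist() == [False, True]

    def test_incomparable_rows_both_flagged(self):
        flags = pareto_front(np.array([[2.0, 1, 1], [1.0, 2, 1]]))
        assert flags.tolist() == [True, True]

    def test_equal_rows_all_flagged(self):
        flags = pareto_front(np.array([[1.0, 1, 1], [1.0, 1, 1]]))
        assert flags.tolist() == [True, True]

    def test_random_rows_match_quadratic_scan(self, rng):
        obj = rng.random((50, 3))
        flags = pareto_front(obj)
        for i in range(50):
            dominated = any(
                np.all(obj[j] >= obj[i]) and np.any(obj[j] > obj[i])
                for j in range(50) if j != i)
            assert flags[i] == (not dominated)


@pytest.fixture(scope="module")
def sweep_result(coarse_phantom):
    els = electrode_positions(["F3", "F4", "TP7", "TP8", "AF3", "AF4"],
                              coarse_phantom)
    rois = make_roi_set(coarse_phantom)
    return run_sweep(coarse_phantom, rois, els, currents_mA=(1.0, 1.0),
                     p=98.0, tol=1e-7)


class TestRunSweep:
    def test_front_nonempty_and_nondominated(self, sweep_result):
        t = sweep_result.table
        assert t["pareto"].any()
        obj = t[["target_median", "focality_pct", "activation_pct"]].to_numpy()
        obj = np.where(np.isnan(obj), -np.inf, obj)
        for i in range(len(t)):
            dominated = any(
                np.all(obj[j] >= obj[i]) and np.any(obj[j] > obj[i])
                for j in range(len(t)) if j != i)
            if t["pareto"].iloc[i]:
                assert not dominated
            else:
                assert dominated

    def test_no_failures_on_default_phantom(self, sweep_result):
        assert not sweep_result.table["failed"].any()

    def test_current_scaling_leaves_ranking_invariant(self, coarse_phantom):
        els = electrode_positions(["F3", "F4", "TP7", "TP8"], coarse_phantom)
        rois = make_roi_set(coarse_phantom)
        s1 = run_sweep(coarse_phantom, rois, els, currents_mA=(1.0, 1.0),
                       tol=1e-7)
        s2 = run_sweep(coarse_phantom, rois, els, currents_mA=(2.0, 2.0),
                       tol=1e-7)
        t1, t2 = s1.table, s2.table
        assert np.allclose(t2["threshold_V_per_m"],
                           2.0 * t1["threshold_V_per_m"], rtol=1e-9)
        assert np.allclose(t2["focality_pct"], t1["focality_pct"],
                           rtol=1e-12, equal_nan=True)
        assert np.allclose(t2["activation_pct"], t1["activation_pct"],
                           rtol=1e-12)
        assert t2["pareto"].tolist() == t1["pareto"].tolist()

    def test_single_montage_is_pareto(self, coarse_phantom):
        els = electrode_positions(["F3", "F4", "TP7", "TP8"], coarse_phantom)
        rois = make_roi_set(coarse_phantom)
        res = run_sweep(coarse_phantom, rois, els, tol=1e-7)
        sub = res.table.iloc[[0]]
        flags = pareto_front(sub[["target_median", "focality_pct",
                                  "activation_pct"]].to_numpy())
        assert flags.all()

    def test_determinism(self, coarse_phantom):
        els = electrode_positions(["F3", "F4", "TP7", "TP8"], coarse_phantom)
        rois = make_roi_set(coarse_phantom)
        a = run_sweep(coarse_phantom, rois, els, tol=1e-7).table
        b = run_sweep(coarse_phantom, rois, els, tol=1e-7).table
        pd.testing.assert_frame_equal(a, b)
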