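"""Exclusion bookkeeping, nuisance machinery, ALFF, and mask thresholds."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rvrfusion as rf
from rvrfusion.synthetic import Roster


def _roster_from_flags(flag_sets):
    return [
        Roster(subject_id=f"s{i}", flags=frozenset(fl))
        for i, fl in enumerate(flag_sets)
    ]


class TestApplyExclusions:
    def test_printed_roster_yields_547_included(self):
        roster = rf.generate_roster(
            625,
            dict(head_motion=69, missing_volumes=4, normalization_failure=1,
                 dwi_artifact=8),
            {("dwi_artifact", "head_motion"): 4},
            seed=0,
        )
        report = rf.apply_exclusions(roster)
        assert report.n_included == 547
        assert report.counts_per_reason["head_motion"] == 69
        assert report.n_overlap == 4

    def test_no_flags_keeps_everyone(self):
        report = rf.apply_exclusions(_roster_from_flags([set()] * 9))
        assert report.n_included == 9

    def test_union_counted_once_matches_set_oracle(self, rng):
        flags = ["a", "b", "c"]
        flag_sets = [
            {f for f in flags if rng.random() < 0.2} for _ in range(200)
        ]
        report = rf.apply_exclusions(_roster_from_flags(flag_sets))
        assert report.n_included == sum(1 for fl in flag_sets if not fl)

    def test_duplicate_ids_rejected(self):
        roster = [Roster("x", frozenset()), Roster("x", frozenset({"a"}))]
        with pytest.raises(ValueError, match="duplicate"):
            rf.apply_exclusions(roster)

    def test_idempotent_on_filtered_roster(self):
        roster = _roster_from_flags([{"a"}, set(), {"b"}, set()])
        first = rf.apply_exclusions(roster)
        survivors = [r for r in roster if r.subject_id in first.included_ids]
        second = rf.apply_exclusions(survivors)
        assert second.n_included == first.n_included


class TestFriston24:
    def test_zero_motion_zero_expansion(self):
        out = rf.friston24(np.zeros((5, 6)))
        assert out.shape == (5, 24) and np.all(out == 0)

    def test_single_column_expansion_by_definition(self):
        motion = np.zeros((3, 6))
        motion[:, 0] = [1, 2, 3]
        out = rf.friston24(motion)
        np.testing.assert_array_equal(out[:, 0], [1, 2, 3])
        np.testing.assert_array_equal(out[:, 6], [1, 4, 9])
        np.testing.assert_array_equal(out[:, 12], [0, 1, 2])
        np.testing.assert_array_equal(out[:, 18], [0, 1, 4])

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(2, 30), st.integers(0, 10_000))
    def test_matches_elementwise_loop_oracle(self, T, seed):
        motion = np.random.default_rng(seed).standard_normal((T, 6))
        out = rf.friston24(motion)
        for t in range(T):
            for j in range(6):
                lag = motion[t - 1, j] if t > 0 else 0.0
                assert out[t, j] == motion[t, j]
                assert out[t, 6 + j] == motion[t, j] ** 2
                assert out[t, 12 + j] == lag
                assert out[t, 18 + j] == lag**2

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="6"):
            rf.friston24(np.zeros((5, 5)))


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero(self):
        fd = rf.framewise_displacement(np.ones((6, 6)))
        assert np.all(fd == 0)

    def test_single_translation_step(self):
        motion = np.zeros((5, 6))
        motion[3:, 0] = 1.0  # 1 mm x-translation from frame 3 on
        fd = rf.framewise_displacement(motion)
        np.testing.assert_array_equal(fd, [0, 0, 0, 1, 0])

    def test_matches_finite_difference_oracle(self, rng):
        motion = np.cumsum(rng.standard_normal((20, 6)) * 0.1, axis=0)
        fd = rf.framewise_displacement(motion, head_radius_mm=50.0)
        for t in range(1, 20):
            d = np.abs(motion[t] - motion[t - 1])
            assert fd[t] == pytest.approx(d[:3].sum() + 50.0 * d[3:].sum())

    def test_non_finite_motion_rejected(self):
        motion = np.zeros((4, 6))
        motion[1, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            rf.framewise_displacement(motion)


class TestNuisanceDesign:
    @staticmethod
    def _inputs(T=80, seed=0):
        rng = np.random.default_rng(seed)
        motion = np.cumsum(rng.standard_normal((T, 6)) * 0.01, axis=0)
        tissue = {k: rng.standard_normal(T) for k in ("csf", "wm", "global")}
        return motion, tissue

    def test_gsr_toggle_changes_exactly_one_column(self):
        motion, tissue = self._inputs()
        with_g = rf.build_nuisance_design(motion, tissue, include_gsr=True)
        without = rf.build_nuisance_design(motion, tissue, include_gsr=False)
        assert with_g.matrix.shape[1] == without.matrix.shape[1] + 1
        assert "global" in with_g.column_names
        assert "global" not in without.column_names

    def test_fd_below_threshold_adds_no_spikes(self):
        motion, tissue = self._inputs()
        design = rf.build_nuisance_design(
            motion, tissue, fd=np.full(80, 0.1), fd_threshold=0.5
        )
        assert not any(n.startswith("spike") for n in design.column_names)

    def test_three_suprathreshold_frames_make_three_onehot_columns(self):
        motion, tissue = self._inputs()
        fd = np.full(80, 0.1)
        hot = [4, 11, 23]
        fd[hot] = 0.7
        design = rf.build_nuisance_design(motion, tissue, fd=fd, fd_threshold=0.5)
        spikes = [n for n in design.column_names if n.startswith("spike")]
        assert len(spikes) == len(hot)
        for t in hot:
            col = design.matrix[:, design.column_names.index(f"spike_{t}")]
            assert col[t] == 1.0 and col.sum() == 1.0

    def test_rank_deficient_design_rejected(self):
        motion, tissue = self._inputs()
        tissue["csf"] = 2.0 * tissue["wm"]  # dependent but not an exact duplicate
        with pytest.raises(ValueError, match="rank"):
            rf.build_nuisance_design(motion, tissue)


class TestRegressNuisance:
    def test_residuals_orthogonal_to_design(self, rng):
        motion, tissue = TestNuisanceDesign._inputs(T=60, seed=3)
        design = rf.build_nuisance_design(motion, tissue)
        series = rng.standard_normal((60, 15))
        resid = rf.regress_nuisance(series, design)
        X = design.matrix
        proj = np.abs(X.T @ resid)
        scale = np.linalg.norm(X, axis=0)[:, None] * np.linalg.norm(resid, axis=0)
        assert np.all(proj / np.maximum(scale, 1e-300) < 1e-8)

    def test_design_column_regresses_to_zero(self):
        motion, tissue = TestNuisanceDesign._inputs(T=40, seed=1)
        design = rf.build_nuisance_design(motion, tissue)
        resid = rf.regress_nuisance(design.matrix[:, [5]], design)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_series_returned_unchanged(self):
        T = 50
        design = np.ones((T, 1))  # intercept only
        series = np.sin(np.linspace(0, 4 * np.pi, T))[:, None]
        series -= series.mean()
        resid = rf.regress_nuisance(series, design)
        np.testing.assert_allclose(resid, series, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((40, 5))
        S = rng.standard_normal((40, 7))
        resid = rf.regress_nuisance(S, X)
        beta = np.linalg.solve(X.T @ X, X.T @ S)
        np.testing.assert_allclose(resid, S - X @ beta, atol=1e-10)


class TestComputeALFF:
    def test_constant_series_zero(self):
        alff = rf.compute_alff(np.full((200, 3), 7.0), tr_seconds=2.0)
        np.testing.assert_allclose(alff.values, 0.0, atol=1e-12)

    def test_single_in_band_sinusoid_matches_dft_oracle(self):
        # unit sinusoid at 0.05 Hz, TR=2 s, 200 points: exactly one in-band
        # bin carries amplitude 1; ALFF = 1 / (number of in-band bins)
        T, tr = 200, 2.0
        t = np.arange(T) * tr
        x = np.sin(2 * np.pi * 0.05 * t)
        alff = rf.compute_alff(x[:, None], tr)
        n = np.arange(T)
        amps = np.array(
            [2.0 * abs(np.sum(x * np.exp(-2j * np.pi * k * n / T))) / T
             for k in range(T // 2 + 1)]
        )
        freqs = np.fft.rfftfreq(T, tr)
        in_band = (freqs >= 0.01) & (freqs <= 0.1) & (freqs > 0)
        assert alff.values[0] == pytest.approx(amps[in_band].mean(), rel=1e-10)
        assert alff.values[0] == pytest.approx(1.0 / in_band.sum(), rel=1e-10)

    def test_out_of_band_sinusoid_contributes_nothing(self):
        T, tr = 200, 2.0
        t = np.arange(T) * tr
        x = np.sin(2 * np.pi * 0.2 * t)  # 0.2 Hz: exact bin, out of band
        alff = rf.compute_alff(x[:, None], tr)
        assert alff.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_homogeneity_under_scaling(self, rng):
        x = rng.standard_normal((128, 4))
        x -= x.mean(axis=0)
        a1 = rf.compute_alff(x, 2.0).values
        a3 = rf.compute_alff(3 * x, 2.0).values
        np.testing.assert_allclose(a3, 3 * a1, rtol=1e-10)

    def test_band_without_bins_errors_naming_minimal_length(self):
        # 20 points at TR=2 s give a 0.025 Hz grid: only one bin inside
        # a 0.01-0.03 Hz band
        with pytest.raises(ValueError) as err:
            rf.compute_alff(np.zeros((20, 1)), tr_seconds=2.0, band=(0.01, 0.03))
        assert re.search(r"\d+ timepoints", str(err.value))

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            rf.compute_alff(np.zeros((100, 1)), tr_seconds=2.0, band=(0.01, 0.3))


class TestMakeMask:
    def test_strict_threshold_boundary(self):
        mask = rf.make_mask(np.array([0.1, 0.25, 0.2]), threshold=0.2)
        np.testing.assert_array_equal(mask, [False, True, False])

    def test_all_ones_included(self):
        assert rf.make_mask(np.ones(5)).all()

    def test_matches_elementwise_oracle(self, rng):
        p = rng.uniform(0, 1, size=50)
        mask = rf.make_mask(p, threshold=0.3)
        np.testing.assert_array_equal(mask, np.array([v > 0.3 for v in p]))

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            rf.make_mask(np.array([0.5, 1.2]))
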