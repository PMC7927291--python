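"""Generator contracts: determinism, planted-truth identities, fixtures."""

import numpy as np
import pytest

import rvrfusion as rf


def _tiny_config(**kw):
    base = dict(
        n_subjects=50,
        voxels_per_modality={"a": 60, "b": 80},
        n_true_voxels={"a": 10, "b": 5},
        seed=3,
    )
    base.update(kw)
    return rf.SyntheticConfig(**base)


class TestGenerateDataset:
    def test_noise_free_scores_match_planted_linear_model(self):
        ds = rf.generate_dataset(
            _tiny_config(noise_sd=0.0, planted_r2=None, score_noise_sd=0.0)
        )
        expected = ds.truth.noise_free_scores(ds.features)
        np.testing.assert_allclose(ds.scores, expected, rtol=1e-12)

    def test_same_seed_bit_identical(self):
        a = rf.generate_dataset(_tiny_config())
        b = rf.generate_dataset(_tiny_config())
        assert np.array_equal(a.scores, b.scores)
        for m in a.modalities:
            assert np.array_equal(a.features[m], b.features[m])

    def test_different_seed_differs(self):
        a = rf.generate_dataset(_tiny_config())
        b = rf.generate_dataset(_tiny_config(seed=4))
        assert not np.array_equal(a.scores, b.scores)

    def test_shapes_and_score_range(self):
        cfg = _tiny_config()
        ds = rf.generate_dataset(cfg)
        for m, V in cfg.voxels_per_modality.items():
            assert ds.features[m].shape == (cfg.n_subjects, V)
            assert (ds.truth.weight_maps[m] != 0).sum() == cfg.n_true_voxels[m]
        lo, hi = cfg.score_range
        assert ds.scores.min() >= lo - 1e-12 and ds.scores.max() <= hi + 1e-12

    def test_shared_signal_fraction_recovered_from_components(self):
        # noise-free features make the planted component correlation exactly
        # the shared fraction in expectation; oracle = direct covariance of
        # the components recomputed from the returned truth
        cfg = rf.SyntheticConfig(
            n_subjects=2000,
            voxels_per_modality={"a": 50, "b": 50},
            n_true_voxels={"a": 5, "b": 5},
            cluster_width=5,
            noise_sd=0.0,
            shared_signal_fraction=0.5,
            seed=21,
        )
        ds = rf.generate_dataset(cfg)
        comp = {m: ds.features[m] @ ds.truth.weight_maps[m] for m in ds.modalities}
        for m in ds.modalities:
            np.testing.assert_allclose(comp[m], ds.truth.modality_components[m])
        r = abs(np.corrcoef(comp["a"], comp["b"])[0, 1])
        # Monte-Carlo tolerance: 3 sd of a sample correlation at n=2000
        assert abs(r - 0.5) < 3 * (1 - 0.25) / np.sqrt(2000)

    def test_cluster_width_exceeding_voxels_is_configuration_error(self):
        with pytest.raises(ValueError, match="cluster_width"):
            rf.generate_dataset(
                rf.SyntheticConfig(
                    n_subjects=20,
                    voxels_per_modality={"a": 8},
                    n_true_voxels={"a": 4},
                    cluster_width=10,
                    seed=0,
                )
            )

    def test_ols_on_true_support_recovers_weights(self):
        # recoverability ceiling: at planted R^2 ~ 0.5 and n=200, least squares
        # restricted to the true support correlates > 0.9 with the truth
        corrs = []
        for seed in range(10):
            cfg = rf.SyntheticConfig(
                n_subjects=200,
                voxels_per_modality={"a": 500, "b": 500, "c": 500},
                n_true_voxels={"a": 5, "b": 5, "c": 5},
                cluster_width=1,
                noise_sd=1.0,
                shared_signal_fraction=0.0,
                seed=seed,
            )
            ds = rf.generate_dataset(cfg)
            sup = {m: np.flatnonzero(ds.truth.weight_maps[m]) for m in ds.modalities}
            X = np.hstack([ds.features[m][:, sup[m]] for m in ds.modalities])
            w_true = np.concatenate(
                [ds.truth.weight_maps[m][sup[m]] for m in ds.modalities]
            )
            design = np.column_stack([X, np.ones(len(X))])
            beta = np.linalg.lstsq(design, ds.scores, rcond=None)[0][:-1]
            corrs.append(np.corrcoef(beta, w_true)[0, 1])
        assert np.mean(corrs) > 0.9


class TestGenerateTimeseries:
    def test_no_components_no_noise_is_zero(self):
        ts = rf.generate_timeseries(2, 16, 3, 2.0, [], seed=0)
        for s in ts.series:
            assert np.all(s == 0.0)

    def test_single_sinusoid_energy_in_one_dft_bin(self):
        # 0.05 Hz at TR=2 s, 200 points: exact bin k=20 on a 0.0025 Hz grid;
        # oracle: explicit DFT summation
        ts = rf.generate_timeseries(1, 200, 4, 2.0, [(0.05, 1.0)], seed=5)
        x = ts.series[0][:, 2]
        t = np.arange(200)
        dft = np.array(
            [np.sum(x * np.exp(-2j * np.pi * k * t / 200)) for k in range(101)]
        )
        power = np.abs(dft) ** 2
        k = int(round(0.05 * 200 * 2.0))
        assert power[k] / power[1:].sum() > 1 - 1e-9

    def test_seeded_reproducibility(self):
        a = rf.generate_timeseries(2, 32, 3, 2.0, [(0.05, 1.0)], seed=9, noise_sd=0.5)
        b = rf.generate_timeseries(2, 32, 3, 2.0, [(0.05, 1.0)], seed=9, noise_sd=0.5)
        for sa, sb in zip(a.series, b.series):
            assert np.array_equal(sa, sb)
        for ma, mb in zip(a.motion, b.motion):
            assert np.array_equal(ma, mb)

    def test_frequency_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            rf.generate_timeseries(1, 32, 2, 2.0, [(0.25, 1.0)], seed=0)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="timepoints"):
            rf.generate_timeseries(1, 4, 2, 2.0, [], seed=0)


class TestGenerateRoster:
    PRINTED = dict(
        head_motion=69, missing_volumes=4, normalization_failure=1, dwi_artifact=8
    )

    def test_printed_roster_gives_78_distinct_flagged(self):
        roster = rf.generate_roster(
            625, self.PRINTED, {("dwi_artifact", "head_motion"): 4}, seed=1
        )
        flagged = {r.subject_id for r in roster if r.flags}
        assert len(flagged) == 78
        for flag, count in self.PRINTED.items():
            assert sum(flag in r.flags for r in roster) == count

    def test_zero_counts_no_flags(self):
        roster = rf.generate_roster(10, {f: 0 for f in self.PRINTED}, seed=0)
        assert all(not r.flags for r in roster)

    def test_no_overlap_distinct_count_equals_sum(self, rng):
        counts = {"a": int(rng.integers(1, 8)), "b": int(rng.integers(1, 8)),
                  "c": int(rng.integers(1, 8))}
        roster = rf.generate_roster(100, counts, seed=2)
        union = set()
        for r in roster:
            if r.flags:
                union.add(r.subject_id)
        assert len(union) == sum(counts.values())

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            rf.generate_roster(50, {"a": 3, "b": 5}, {("a", "b"): 4}, seed=0)


class TestGenerateAtlas:
    def test_identity_partition(self):
        atlas = rf.generate_atlas(12, 12, 3, seed=0)
        assert np.array_equal(np.sort(atlas.voxel_to_node), np.arange(12))

    def test_node_sizes_sum_to_voxel_count(self):
        atlas = rf.generate_atlas(100, 10, 4, seed=1)
        sizes = np.bincount(atlas.voxel_to_node, minlength=10)
        assert sizes.sum() == 100 and (sizes >= 1).all()
        net_sizes = np.bincount(atlas.node_to_network, minlength=4)
        assert net_sizes.sum() == 10 and (net_sizes >= 1).all()

    def test_seeded_reproducibility(self):
        a = rf.generate_atlas(50, 7, 3, seed=4)
        b = rf.generate_atlas(50, 7, 3, seed=4)
        assert np.array_equal(a.voxel_to_node, b.voxel_to_node)
        assert np.array_equal(a.node_to_network, b.node_to_network)

    def test_impossible_partition_rejected(self):
        with pytest.raises(ValueError):
            rf.generate_atlas(5, 10, 2, seed=0)
        with pytest.raises(ValueError):
            rf.generate_atlas(10, 4, 6, seed=0)
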