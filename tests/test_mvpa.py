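import logging

import numpy as np
import pandas as pd
import pytest

from fmripattern import mvpa, synth
from fmripattern.group import SharedROI
from fmripattern.synth import VolumeSeries


def _vols(rng, shape=(5, 5, 4), n_volumes=20, n_runs=2, tr=2.0):
    return [
        VolumeSeries(rng.normal(100, 1, shape + (n_volumes,)), tr, np.eye(4), r)
        for r in range(n_runs)
    ]


def _two_block_events():
    """One NA and one NV block per run, 15 s epochs."""
    rows = [
        (0, 0.0, 15.0, "NA", 0),
        (0, 20.0, 15.0, "NV", 1),
    ]
    return [pd.DataFrame(rows, columns=["run_id", "onset", "duration", "trial_type", "block_id"])]


class TestExtractRoiTimeseries:
    def test_single_voxel_equals_its_series(self):
        rng = np.random.default_rng(0)
        vols = _vols(rng, n_runs=1)
        roi = SharedROI("r", [[2, 3, 1]], 1)
        mat = mvpa.extract_roi_timeseries(vols, roi)
        assert np.array_equal(mat.values[0], vols[0].data[2, 3, 1, :])

    def test_paper_defaults_column_count(self, paper_design, small_atlas, quiet_noise):
        design, events = paper_design
        runs, _ = synth.simulate_subject(
            design, events, small_atlas, synth.EffectSpec(), quiet_noise, seed=0
        )
        roi = SharedROI("r", small_atlas.region_voxels("LSMA"), 1)
        mat = mvpa.extract_roi_timeseries(runs, roi)
        assert mat.values.shape[1] == 324

    def test_values_match_direct_indexing(self):
        rng = np.random.default_rng(1)
        vols = _vols(rng)
        vox = np.array([[0, 0, 0], [4, 4, 3], [2, 1, 2]])
        mat = mvpa.extract_roi_timeseries(vols, SharedROI("r", vox, 1))
        for row, (i, j, k) in enumerate(vox):
            expected = np.concatenate([v.data[i, j, k, :] for v in vols])
            assert np.array_equal(mat.values[row], expected)

    def test_out_of_grid_rejected(self):
        vols = _vols(np.random.default_rng(2))
        with pytest.raises(ValueError):
            mvpa.extract_roi_timeseries(vols, SharedROI("r", [[9, 9, 9]], 1))


def _matrix(values):
    values = np.asarray(values, dtype=float)
    tp = pd.DataFrame({"run_id": [0] * values.shape[1],
                       "volume": range(values.shape[1])})
    vox = np.array([[i, 0, 0] for i in range(values.shape[0])])
    return mvpa.RoiMatrix(values, vox, tp)


class TestNormalizeTwoStep:
    def test_columns_normalized(self):
        rng = np.random.default_rng(3)
        norm = mvpa.normalize_two_step(_matrix(rng.normal(10, 3, (8, 30))))
        assert np.allclose(norm.values.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(norm.values.std(axis=0), 1.0, atol=1e-10)

    def test_matches_independent_two_pass_oracle(self):
        vals = np.array([[1.0, 2, 3, 6], [4, 0, 2, 2], [5, 5, 1, 1]])
        norm = mvpa.normalize_two_step(_matrix(vals))
        # hand-rolled oracle, written independently of the implementation
        z = np.empty_like(vals)
        for j in range(vals.shape[0]):
            z[j] = (vals[j] - vals[j].mean()) / vals[j].std()
        b = np.empty_like(z)
        for i in range(vals.shape[1]):
            col = z[:, i]
            b[:, i] = (col - col.mean()) / col.std()
        assert np.allclose(norm.values, b, atol=1e-12)

    def test_fixed_point_unchanged(self):
        # rows and columns both already mean-0 sd-1: balanced sign matrix
        vals = np.array([
            [1.0, -1.0, 1.0, -1.0],
            [-1.0, 1.0, -1.0, 1.0],
        ])
        norm = mvpa.normalize_two_step(_matrix(vals))
        assert np.allclose(norm.values, vals, atol=1e-10)

    def test_constant_voxel_dropped_with_warning(self, caplog):
        vals = np.vstack([np.random.default_rng(4).normal(size=(3, 12)),
                          np.full(12, 9.0)])
        with caplog.at_level(logging.WARNING, logger="fmripattern.mvpa"):
            norm = mvpa.normalize_two_step(_matrix(vals))
        assert norm.values.shape[0] == 3
        assert "constant" in caplog.text

    def test_single_voxel_roi_rejected(self):
        with pytest.raises(ValueError, match="spatial"):
            mvpa.normalize_two_step(_matrix(np.random.default_rng(5).normal(size=(1, 10))))

    def test_invariant_to_voxelwise_affine_rescaling(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(6, 40))
        gains = rng.uniform(0.5, 3.0, size=6)
        offsets = rng.normal(0, 10, size=6)
        a = mvpa.normalize_two_step(_matrix(vals))
        b = mvpa.normalize_two_step(_matrix(vals * gains[:, None] + offsets[:, None]))
        assert np.allclose(a.values, b.values, atol=1e-10)


class TestAssembleSamples:
    def test_midpoint_enumeration(self):
        # shift 0, NA block [0, 15), TR 2 -> midpoints 1,3,...,13 s
        # -> volumes 0..6 (7 samples)
        rng = np.random.default_rng(7)
        norm = mvpa.normalize_two_step(_matrix(rng.normal(size=(4, 20))))
        ss = mvpa.assemble_samples(norm, _two_block_events(), tr=2.0,
                                   hemodynamic_shift_s=0.0)
        na_cols = [i for i, lab in enumerate(ss.labels) if lab == "NA"]
        assert np.sum(ss.labels == "NA") == 7
        assert np.array_equal(ss.features[na_cols[0]], norm.values[:, 0])
        assert np.array_equal(ss.features[na_cols[-1]], norm.values[:, 6])

    def test_disjoint_conditions_disjoint_samples(self):
        rng = np.random.default_rng(8)
        norm = mvpa.normalize_two_step(_matrix(rng.normal(size=(4, 20))))
        ss = mvpa.assemble_samples(norm, _two_block_events(), 2.0, 0.0)
        groups_na = set(ss.groups[ss.labels == "NA"].tolist())
        groups_nv = set(ss.groups[ss.labels == "NV"].tolist())
        assert groups_na.isdisjoint(groups_nv)

    def test_paper_defaults_near_balanced(self, paper_design, small_atlas, quiet_noise):
        # block onsets alternate parity against the TR grid, so midpoint
        # labeling yields 60 vs 61 samples; asserted within one sample
        design, events = paper_design
        runs, _ = synth.simulate_subject(
            design, events, small_atlas,
            synth.EffectSpec({("LSMA", "NA"): 1.0}, {("LSMA", "NA"): 0.1}, {"LSMA": 0}),
            synth.NoiseSpec(white_sd=0.01, drift_amplitude=0, n_drift_components=0),
            seed=0,
        )
        roi = SharedROI("r", small_atlas.region_voxels("LSMA"), 1)
        norm = mvpa.normalize_two_step(mvpa.extract_roi_timeseries(runs, roi))
        ss = mvpa.assemble_samples(norm, events, design.tr_seconds)
        n_na = int(np.sum(ss.labels == "NA"))
        n_nv = int(np.sum(ss.labels == "NV"))
        assert abs(n_na - n_nv) <= 1
        assert n_na + n_nv > 100

    def test_rest_and_cue_excluded(self, paper_design):
        design, events = paper_design
        rng = np.random.default_rng(9)
        norm = mvpa.normalize_two_step(_matrix(rng.normal(size=(4, 162))))
        ss = mvpa.assemble_samples(norm, events[:1], design.tr_seconds)
        assert set(ss.labels.tolist()) == {"NA", "NV"}

    def test_no_samples_for_condition_rejected(self):
        rng = np.random.default_rng(10)
        norm = mvpa.normalize_two_step(_matrix(rng.normal(size=(4, 20))))
        with pytest.raises(ValueError, match="NV"):
            mvpa.assemble_samples(norm, _two_block_events(), 2.0, 30.0)

    def test_negative_shift_rejected(self):
        rng = np.random.default_rng(11)
        norm = mvpa.normalize_two_step(_matrix(rng.normal(size=(4, 20))))
        with pytest.raises(ValueError):
            mvpa.assemble_samples(norm, _two_block_events(), 2.0, -1.0)


def _cloud_samples(rng, separation, n_blocks=8, per_block=7, n_vox=10):
    feats, labels, groups = [], [], []
    centers = {"NA": rng.normal(0, 1, n_vox), "NV": rng.normal(0, 1, n_vox)}
    centers["NV"] = centers["NA"] + separation * rng.normal(0, 1, n_vox)
    for cond in ("NA", "NV"):
        for b in range(n_blocks):
            for _ in range(per_block):
                feats.append(centers[cond] + rng.normal(0, 1, n_vox))
                labels.append(cond)
                groups.append(b if cond == "NA" else 100 + b)
    return mvpa.SampleSet(np.array(feats), np.array(labels), np.array(groups))


class TestCrossvalClassify:
    def test_separable_clouds_perfect_accuracy(self):
        ss = _cloud_samples(np.random.default_rng(0), separation=50.0)
        accs = mvpa.crossval_classify(ss, n_folds=8, seed=0)
        assert np.all(accs == 1.0)
        assert len(accs) == 8

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        ss = _cloud_samples(rng, separation=0.0)
        means = []
        for _ in range(100):
            labels = ss.labels.copy()
            # permute condition assignment at block level (labels follow blocks)
            blocks = sorted(set(ss.groups.tolist()))
            flip = dict(zip(blocks, rng.permutation([b < 100 for b in blocks])))
            labels = np.array(["NA" if flip[g] else "NV" for g in ss.groups])
            ss2 = mvpa.SampleSet(ss.features, labels, ss.groups)
            try:
                means.append(np.mean(mvpa.crossval_classify(ss2, 8, seed=0)))
            except ValueError:
                continue  # a fold drew a single class; skip that reshuffle
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_fold_sizes_one_eighth(self):
        ss = _cloud_samples(np.random.default_rng(2), separation=1.0)
        n = len(ss.labels)
        folds = mvpa._block_pair_folds(ss, 8, seed=0)
        for test in folds:
            assert abs(int(test.sum()) - n / 8) <= 2

    def test_no_block_leakage(self):
        ss = _cloud_samples(np.random.default_rng(3), separation=1.0)
        folds = mvpa._block_pair_folds(ss, 8, seed=4)
        for test in folds:
            train_groups = set(ss.groups[~test].tolist())
            test_groups = set(ss.groups[test].tolist())
            assert train_groups.isdisjoint(test_groups)

    def test_too_many_folds_rejected(self):
        ss = _cloud_samples(np.random.default_rng(4), separation=1.0, n_blocks=4)
        with pytest.raises(ValueError, match="block pairs"):
            mvpa.crossval_classify(ss, n_folds=8)

    def test_bit_stable_given_seed(self):
        ss = _cloud_samples(np.random.default_rng(5), separation=0.5)
        a = mvpa.crossval_classify(ss, 8, seed=7)
        b = mvpa.crossval_classify(ss, 8, seed=7)
        assert np.array_equal(a, b)


class TestGroupAccuracyTest:
    def test_all_at_chance_t_zero(self):
        t, dof, p = mvpa.group_accuracy_test([0.5, 0.5, 0.5])
        assert t == 0.0

    def test_paper_scale_t_statistic(self):
        # mean 65.21%, SE ~2.1%, n=21 -> t near the printed 7.35
        rng = np.random.default_rng(6)
        accs = rng.normal(0, 1, 21)
        accs = (accs - accs.mean()) / accs.std(ddof=1)  # mean 0, sd 1
        accs = 0.6521 + accs * (0.021 * np.sqrt(21))
        t, dof, p = mvpa.group_accuracy_test(accs, 0.5)
        assert dof == 20
        assert t == pytest.approx((0.6521 - 0.5) / 0.021, abs=1e-6)
        assert abs(t - 7.35) < 0.4
        assert p < 0.001

    def test_matches_closed_form(self):
        t, dof, p = mvpa.group_accuracy_test([0.6, 0.55, 0.65], 0.5)
        assert t == pytest.approx(3.4641016151377544, abs=1e-12)
        assert dof == 2

    def test_one_sided_p(self):
        t, _, p_hi = mvpa.group_accuracy_test([0.6, 0.7, 0.65, 0.62], 0.5)
        assert p_hi < 0.05
        t2, _, p_lo = mvpa.group_accuracy_test([0.4, 0.3, 0.35, 0.38], 0.5)
        assert p_lo > 0.95

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mvpa.group_accuracy_test([0.7, 0.7, 0.7])


class TestGroupDecode:
    def test_aggregation(self):
        folds = [np.array([0.5, 0.75]), np.array([0.625, 0.625]), np.array([0.5, 0.5])]
        res = mvpa.group_decode(folds, "shared-X")
        assert res.group_mean == pytest.approx(np.mean([0.625, 0.625, 0.5]))
        assert res.dof == 2
        assert res.roi_name == "shared-X"
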