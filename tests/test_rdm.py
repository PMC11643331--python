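"""RDM construction: neural, behavioral, gaze, semantic, and feature RDMs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from actionrsa.rdm import (
    RDM,
    ArrangementTrial,
    GazeTrajectory,
    aggregate_arrangements,
    annotator_agreement,
    arrangement_distances,
    build_gaze_rdm,
    feature_rdm,
    gaze_trial_distance,
    preprocess_gaze,
    semantic_rdm,
    split_data_rdm,
    zscore_profiles,
)

from conftest import random_rdm


class TestRDMType:
    def test_symmetrization_and_invariants(self):
        rng = np.random.default_rng(0)
        r = random_rdm(rng, 6)
        assert np.allclose(r.matrix, r.matrix.T)
        assert np.all(np.isfinite(r.matrix))

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            RDM(["a", "b"], m)

    def test_vector_roundtrip(self):
        rng = np.random.default_rng(1)
        r = random_rdm(rng, 7)
        back = RDM.from_vector(r.stimulus_ids, r.vector)
        assert np.allclose(back.matrix, r.matrix)

    def test_vector_order_is_row_major_upper_triangle(self):
        mat = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        r = RDM(["a", "b", "c"], mat)
        assert list(r.vector) == [1, 2, 3]

    def test_reorder_permutes_consistently(self):
        rng = np.random.default_rng(2)
        r = random_rdm(rng, 5)
        perm = ["s3", "s1", "s4", "s0", "s2"]
        r2 = r.reorder(perm)
        for i, a in enumerate(perm):
            for j, b in enumerate(perm):
                ia, ib = r.stimulus_ids.index(a), r.stimulus_ids.index(b)
                assert r2.matrix[i, j] == r.matrix[ia, ib]


class TestZscoreProfiles:
    def test_closed_form_column(self):
        df = pd.DataFrame({"u": [1.0, 2.0, 3.0]})
        out = zscore_profiles(df)
        assert np.allclose(out["u"], [-1.22474487, 0.0, 1.22474487])

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(20, 4)))
        once = zscore_profiles(df)
        twice = zscore_profiles(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)

    def test_random_table_recompute_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(90, 50)))
        out = zscore_profiles(df).to_numpy()
        assert np.allclose(out.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(out.std(axis=0), 1, atol=1e-9)

    def test_constant_column_zeroed_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_profiles(df)
        assert np.all(out["b"] == 0)


class TestSplitDataRDM:
    def test_orthogonal_patterns_identity_sessions(self):
        p = pd.DataFrame([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]],
                         index=["a", "b"])
        rdm = split_data_rdm(p, p)
        assert rdm.matrix[0, 1] == pytest.approx(1.0)
        assert np.diag(rdm.matrix) == pytest.approx([0.0, 0.0])

    def test_anticorrelated_pattern_bound(self):
        p1 = pd.DataFrame([[1.0, 2.0, 3.0], [0.5, 0.1, 0.9]], index=["a", "b"])
        p2 = p1.copy()
        p2.loc["b"] = -p1.loc["a"]  # session-2 pattern of b anti-matches a
        rdm = split_data_rdm(p1, p2)
        # c_ab component (-1) pushes the symmetrized dissimilarity toward 2
        assert rdm.matrix[0, 1] > 1.0

    def test_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        ids = [f"s{i}" for i in range(10)]
        p1 = pd.DataFrame(rng.normal(size=(10, 30)), index=ids)
        p2 = pd.DataFrame(rng.normal(size=(10, 30)), index=ids)
        rdm = split_data_rdm(p1, p2)
        for i in range(10):
            for j in range(10):
                cij = pearsonr(p1.iloc[i], p2.iloc[j]).statistic
                cji = pearsonr(p1.iloc[j], p2.iloc[i]).statistic
                assert rdm.matrix[i, j] == pytest.approx(1 - (cij + cji) / 2, abs=1e-12)

    def test_unit_permutation_invariance(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(8)]
        p1 = pd.DataFrame(rng.normal(size=(8, 20)), index=ids)
        p2 = pd.DataFrame(rng.normal(size=(8, 20)), index=ids)
        perm = rng.permutation(20)
        r1 = split_data_rdm(p1, p2)
        r2 = split_data_rdm(p1.iloc[:, perm], p2.iloc[:, perm])
        assert np.allclose(r1.matrix, r2.matrix, atol=1e-12)

    def test_zero_variance_pattern_named_in_error(self):
        p = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            split_data_rdm(p, p)


class TestArrangements:
    def test_345_triangle(self):
        t = ArrangementTrial("task", ["a", "b"], [[0.0, 0.0], [3.0, 4.0]])
        assert arrangement_distances(t)[("a", "b")] == pytest.approx(5.0)

    def test_pair_count_for_30_stimuli(self):
        rng = np.random.default_rng(7)
        ids = [f"s{i}" for i in range(30)]
        t = ArrangementTrial("task", ids, rng.random((30, 2)) * 100)
        assert len(arrangement_distances(t)) == 435

    def test_single_full_trial_equals_distance_matrix(self):
        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(6)]
        coords = rng.random((6, 2)) * 100
        t = ArrangementTrial("task", ids, coords)
        rdm = aggregate_arrangements([t], ids)
        from scipy.spatial.distance import squareform, pdist

        assert np.allclose(rdm.matrix, squareform(pdist(coords)), atol=1e-12)

    def test_pair_mean_over_trials(self):
        a = ArrangementTrial("task", ["x", "y"], [[0.0, 0.0], [100.0, 0.0]])
        b = ArrangementTrial("task", ["x", "y"], [[0.0, 0.0], [200.0, 0.0]])
        rdm = aggregate_arrangements([a, b], ["x", "y"])
        assert rdm.matrix[0, 1] == pytest.approx(150.0)

    def test_multi_trial_accumulation_oracle(self):
        rng = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(8)]
        trials = [ArrangementTrial("t", ids, rng.random((8, 2)) * 50)]
        for k in range(12):
            sub = [ids[i] for i in rng.permutation(8)[:4]]
            trials.append(ArrangementTrial("t", sub, rng.random((4, 2)) * 50))
        rdm = aggregate_arrangements(trials, ids)
        # brute-force per-pair mean
        for i in range(8):
            for j in range(i + 1, 8):
                vals = []
                for t in trials:
                    if ids[i] in t.subset and ids[j] in t.subset:
                        ci = t.coords[t.subset.index(ids[i])]
                        cj = t.coords[t.subset.index(ids[j])]
                        vals.append(np.linalg.norm(ci - cj))
                assert rdm.matrix[i, j] == pytest.approx(np.mean(vals), abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(10)
        ids = [f"s{i}" for i in range(5)]
        coords = rng.random((5, 2)) * 100
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = coords @ rot.T * np.array([1, 1]) + np.array([13.0, -7.0])
        r1 = aggregate_arrangements([ArrangementTrial("t", ids, coords)], ids)
        r2 = aggregate_arrangements([ArrangementTrial("t", ids, moved)], ids)
        assert np.allclose(r1.matrix, r2.matrix, atol=1e-9)

    def test_unmeasured_pair_is_error(self):
        a = ArrangementTrial("t", ["x", "y"], [[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="never measured"):
            aggregate_arrangements([a], ["x", "y", "z"])


def make_traj(xy, valid=None, stimulus="s", participant="p", block=0):
    n = len(xy)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return GazeTrajectory(
        t_ms=np.arange(n, dtype=float) + 1,
        x=np.asarray(xy)[:, 0], y=np.asarray(xy)[:, 1],
        valid=np.asarray(valid, dtype=bool),
        stimulus_id=stimulus, participant_id=participant, block=block,
    )


class TestGazePreprocessing:
    def test_2500_samples_decimate_to_60(self):
        rng = np.random.default_rng(11)
        traj = make_traj(rng.random((2500, 2)) * 100)
        out = preprocess_gaze(traj)
        assert out.shape == (60, 2)

    def test_constant_trajectory_with_gap_stays_constant(self):
        xy = np.full((2500, 2), 42.0)
        valid = np.ones(2500, dtype=bool)
        valid[1000:1400] = False
        out = preprocess_gaze(make_traj(xy, valid))
        assert np.allclose(out, 42.0, atol=1e-9)

    def test_single_sample_spike_removed_by_median(self):
        xy = np.full((2500, 2), 10.0)
        spiked = xy.copy()
        spiked[1200] = [500.0, 500.0]
        clean = preprocess_gaze(make_traj(xy))
        despiked = preprocess_gaze(make_traj(spiked))
        assert np.allclose(despiked, clean, atol=1e-9)

    def test_fully_invalid_trial_excluded(self):
        xy = np.zeros((2500, 2))
        assert preprocess_gaze(make_traj(xy, np.zeros(2500, dtype=bool))) is None


class TestGazeDistance:
    def test_identical_trajectories_zero(self):
        a = np.random.default_rng(12).random((60, 2))
        assert gaze_trial_distance(a, a) == 0.0

    def test_constant_offset(self):
        a = np.zeros((60, 2))
        b = a + np.array([3.0, 4.0])
        assert gaze_trial_distance(a, b) == pytest.approx(300.0)

    def test_loop_oracle(self):
        rng = np.random.default_rng(13)
        a, b = rng.random((60, 2)), rng.random((60, 2))
        expect = sum(np.linalg.norm(a[t] - b[t]) for t in range(60))
        assert gaze_trial_distance(a, b) == pytest.approx(expect, abs=1e-9)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            gaze_trial_distance(np.zeros((60, 2)), np.zeros((59, 2)))


class TestGazeRDM:
    def _trajs(self, rng, n_stim=5, participants=("pA",), blocks=2,
               shuffle_for=(), n=250):
        out = []
        protos = {f"s{i}": rng.random((n, 2)) * 200 for i in range(n_stim)}
        for pid in participants:
            for b in range(blocks):
                items = list(protos.items())
                if pid in shuffle_for:
                    rng.shuffle(items)
                    # decouple blocks: random paths instead of prototypes
                    items = [(k, rng.random((n, 2)) * 200) for k, _ in items]
                for sid, p in items:
                    out.append(make_traj(p + rng.normal(size=(n, 2)),
                                         stimulus=sid, participant=pid, block=b))
        return out

    def test_identical_blocks_retained_with_r_1(self):
        rng = np.random.default_rng(14)
        protos = {f"s{i}": rng.random((250, 2)) * 200 for i in range(5)}
        trajs = [
            make_traj(p, stimulus=sid, participant="pA", block=b)
            for b in range(2) for sid, p in protos.items()
        ]
        rdm, report = build_gaze_rdm(trajs, duration_s=2.5, out_rate_hz=24)
        assert report.loc[0, "retained"]
        assert report.loc[0, "mean_interblock_r"] == pytest.approx(1.0)

    def test_unreliable_participant_excluded(self):
        rng = np.random.default_rng(15)
        trajs = self._trajs(rng, participants=("good", "noisy"),
                            shuffle_for=("noisy",))
        rdm, report = build_gaze_rdm(trajs, min_interblock_r=0.1)
        rep = report.set_index("participant")
        assert rep.loc["good", "retained"]
        assert not rep.loc["noisy", "retained"]

    def test_filter_off_limit_retains_everyone(self):
        rng = np.random.default_rng(16)
        trajs = self._trajs(rng, participants=("a", "b"), shuffle_for=("b",))
        _, report = build_gaze_rdm(trajs, min_interblock_r=-1.0)
        assert report["retained"].all()

    def test_reliability_increases_after_exclusion(self):
        rng = np.random.default_rng(17)
        trajs = self._trajs(rng, participants=("good1", "good2", "bad"),
                            shuffle_for=("bad",))
        _, report = build_gaze_rdm(trajs, min_interblock_r=0.1)
        before = report["mean_interblock_r"].mean()
        after = report.loc[report["retained"], "mean_interblock_r"].mean()
        assert after > before


class TestSemanticRDM:
    def test_shared_identical_token_gives_zero(self):
        table = pd.DataFrame({"v0": [1.0], "v1": [2.0]}, index=["tok"])
        ann = {"a": ["tok"], "b": ["tok"]}
        rdm = semantic_rdm(ann, table)
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_cosine_bounds(self):
        table = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]], index=["e1", "e2", "e3"]
        )
        rdm = semantic_rdm({"a": ["e1"], "b": ["e2"], "c": ["e3"]}, table)
        pos = {s: i for i, s in enumerate(rdm.stimulus_ids)}
        assert rdm.matrix[pos["a"], pos["b"]] == pytest.approx(1.0)
        assert rdm.matrix[pos["a"], pos["c"]] == pytest.approx(2.0)

    def test_dot_product_oracle(self):
        rng = np.random.default_rng(18)
        tokens = [f"t{i}" for i in range(30)]
        table = pd.DataFrame(rng.normal(size=(30, 12)), index=tokens)
        ann = {
            f"s{i}": [tokens[j] for j in rng.choice(30, 3, replace=False)]
            for i in range(10)
        }
        rdm = semantic_rdm(ann, table)
        for i, si in enumerate(rdm.stimulus_ids):
            for j, sj in enumerate(rdm.stimulus_ids):
                vi = table.loc[ann[si]].mean(axis=0).to_numpy()
                vj = table.loc[ann[sj]].mean(axis=0).to_numpy()
                cos = vi @ vj / (np.linalg.norm(vi) * np.linalg.norm(vj))
                if i != j:
                    assert rdm.matrix[i, j] == pytest.approx(1 - cos, abs=1e-12)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(19)
        tokens = [f"t{i}" for i in range(10)]
        table = pd.DataFrame(rng.normal(size=(10, 8)), index=tokens)
        ann = {f"s{i}": [tokens[i]] for i in range(10)}
        r1 = semantic_rdm(ann, table)
        r2 = semantic_rdm(ann, table * 7.5)
        assert np.allclose(r1.matrix, r2.matrix, atol=1e-12)

    def test_unresolvable_stimulus_named(self):
        table = pd.DataFrame({"v0": [1.0]}, index=["known"])
        with pytest.raises(ValueError, match="ghost"):
            semantic_rdm({"ghost": ["unknown"]}, table)


class TestAnnotatorAgreement:
    def test_identical_annotations_r_1(self):
        rng = np.random.default_rng(20)
        tokens = [f"t{i}" for i in range(12)]
        table = pd.DataFrame(rng.normal(size=(12, 20)), index=tokens)
        ann = {f"s{i}": [tokens[i], tokens[i + 1]] for i in range(5)}
        out = annotator_agreement(ann, ann, table)
        assert np.allclose(out["r"], 1.0)

    def test_negated_vectors_r_minus_1(self):
        table = pd.DataFrame(
            [[1.0, 2.0, -1.0], [-1.0, -2.0, 1.0]], index=["pos", "neg"]
        )
        out = annotator_agreement({"s": ["pos"]}, {"s": ["neg"]}, table)
        assert out.loc["s", "r"] == pytest.approx(-1.0)

    def test_agreement_decreases_with_noise(self):
        rng = np.random.default_rng(21)
        base = rng.normal(size=(10, 50))
        means = []
        for noise in [0.0, 0.5, 1.0, 2.0, 4.0]:
            tok_a = [f"a{i}" for i in range(10)]
            tok_b = [f"b{i}" for i in range(10)]
            table = pd.DataFrame(
                np.vstack([base, base + rng.normal(size=(10, 50)) * noise]),
                index=tok_a + tok_b,
            )
            ann_a = {f"s{i}": [tok_a[i]] for i in range(10)}
            ann_b = {f"s{i}": [tok_b[i]] for i in range(10)}
            means.append(annotator_agreement(ann_a, ann_b, table)["r"].mean())
        assert all(x > y for x, y in zip(means, means[1:]))


class TestFeatureRDM:
    def test_identical_rows_zero_under_all_metrics(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        for metric in ["correlation", "euclidean", "cosine"]:
            assert feature_rdm(df, metric).matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_euclidean_345(self):
        df = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        assert feature_rdm(df, "euclidean").matrix[0, 1] == pytest.approx(5.0)

    def test_per_pair_metric_oracle(self):
        rng = np.random.default_rng(22)
        df = pd.DataFrame(rng.normal(size=(8, 15)), index=[f"s{i}" for i in range(8)])
        rdm = feature_rdm(df, "correlation")
        for i in range(8):
            for j in range(i + 1, 8):
                r = pearsonr(df.iloc[i], df.iloc[j]).statistic
                assert rdm.matrix[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_zero_variance_row_rejected_under_correlation(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            feature_rdm(df, "correlation")
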