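"""Condition decoding: binning, dataset assembly, resampled SVM evaluation."""

import numpy as np
import pytest

from cortexscope.decode import (
    DecodeConfig,
    ablation_sweep,
    assemble_dataset,
    bin_traces,
    compare_phases,
    region_ablation,
    train_eval,
)
from cortexscope.preprocess import RegionTraces
from cortexscope.regions import REGIONS


def traces_from(values, fps=11.7):
    return RegionTraces(values=values, region_names=REGIONS, fps=fps, units="dff")


def make_separable(rng, n_per_class=60, gap=10.0, n_features=12, labels=("a", "b", "c")):
    xs, ys = [], []
    for i, lab in enumerate(labels):
        xs.append(rng.normal(size=(n_per_class, n_features)) + i * gap)
        ys.extend([lab] * n_per_class)
    return np.vstack(xs), np.asarray(ys)


class TestBinTraces:
    def test_paper_geometry_7016_frames_to_60_bins(self):
        values = np.zeros((12, 7016))
        bins = bin_traces(traces_from(values), bin_s=10.0)
        assert bins.shape == (60, 12)

    def test_constant_trace_bins_constant(self):
        values = np.full((12, 702), 3.3)
        assert np.allclose(bin_traces(traces_from(values)), 3.3)

    def test_matches_slicing_oracle(self, rng):
        values = rng.normal(size=(12, 700))
        bins = bin_traces(traces_from(values))
        block = 117  # round(10 * 11.7)
        for b in range(bins.shape[0]):
            assert np.allclose(bins[b], values[:, b * block : (b + 1) * block].mean(axis=1))

    def test_empty_traces_rejected(self):
        with pytest.raises(ValueError):
            bin_traces(traces_from(np.empty((12, 0))))


class TestAssembleDataset:
    def _sessions(self, rng, n_frames=7016):
        return [
            (traces_from(rng.normal(size=(12, n_frames))), cond, day)
            for day, cond in enumerate(["saline", "thioperamide", "pitolisant"])
        ]

    def test_three_conditions_give_180_balanced_rows(self, rng):
        X, y = assemble_dataset(self._sessions(rng))
        assert X.shape == (180, 12)
        assert all(np.sum(y == c) == 60 for c in np.unique(y))

    def test_two_label_subset_gives_120_rows(self, rng):
        X, y = assemble_dataset(self._sessions(rng), labels_subset=("saline", "pitolisant"))
        assert X.shape == (120, 12)
        assert set(y) == {"saline", "pitolisant"}

    def test_session_order_is_canonicalized(self, rng):
        sessions = self._sessions(rng)
        X1, y1 = assemble_dataset(sessions)
        X2, y2 = assemble_dataset(sessions[::-1])
        assert np.array_equal(X1, X2)
        assert np.array_equal(y1, y2)

    def test_missing_session_is_an_error(self, rng):
        with pytest.raises(ValueError, match="thioperamide"):
            assemble_dataset(self._sessions(rng)[:1], labels_subset=("saline", "thioperamide"))


class TestTrainEval:
    def test_separable_classes_reach_perfect_accuracy(self, rng):
        X, y = make_separable(rng)
        res = train_eval(X, y, DecodeConfig(n_resamples=20), seed=0)
        assert res.accuracy_mean == 1.0

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(90, 12))
        y = np.repeat(["a", "b", "c"], 30)
        r1 = train_eval(X, y, DecodeConfig(n_resamples=25), seed=7)
        r2 = train_eval(X, y, DecodeConfig(n_resamples=25), seed=7)
        assert r1.accuracy_mean == r2.accuracy_mean
        assert np.array_equal(r1.accuracies, r2.accuracies)

    def test_shuffled_labels_decode_at_chance(self, rng):
        X = rng.normal(size=(180, 12))
        y = rng.permutation(np.repeat(["a", "b", "c"], 60))
        res = train_eval(X, y, DecodeConfig(n_resamples=300), seed=1)
        assert res.accuracy_mean == pytest.approx(1 / 3, abs=0.05)

    def test_feature_permutation_invariance(self, rng):
        X, y = make_separable(rng, gap=1.0)
        perm = rng.permutation(12)
        r1 = train_eval(X, y, DecodeConfig(n_resamples=50), seed=3)
        r2 = train_eval(X[:, perm], y, DecodeConfig(n_resamples=50), seed=3)
        assert r1.accuracy_mean == pytest.approx(r2.accuracy_mean)

    def test_small_classes_rejected(self, rng):
        X = rng.normal(size=(7, 3))
        y = np.array(["a"] * 4 + ["b"] * 3)
        with pytest.raises(ValueError):
            train_eval(X, y, DecodeConfig(n_resamples=5))


class TestRegionAblation:
    def test_leave_one_out_sweep_yields_12_decoders(self, rng):
        X, y = make_separable(rng, gap=1.0)
        sweep = ablation_sweep(X, y, REGIONS, mode="leave_one_out",
                               config=DecodeConfig(n_resamples=10), n_resamples=10)
        assert len(sweep) == 12
        assert list(sweep["region"]) == list(REGIONS)

    def test_single_informative_region_beats_chance(self, rng):
        X = rng.normal(size=(120, 12))
        y = np.repeat(["a", "b"], 60)
        X[y == "b", 4] += 8.0  # only one informative column
        informative = region_ablation(X, y, REGIONS, "single", REGIONS[4],
                                      DecodeConfig(n_resamples=60), seed=2)
        blank = region_ablation(X, y, REGIONS, "single", REGIONS[0],
                                DecodeConfig(n_resamples=60), seed=2)
        assert informative.accuracy_mean > 0.95
        assert blank.accuracy_mean == pytest.approx(0.5, abs=0.1)

    def test_dropping_a_noise_column_changes_little(self, rng):
        X, y = make_separable(rng, gap=0.7)
        X = np.hstack([X[:, :11], rng.normal(size=(180, 1))])  # column 11 pure noise
        full = train_eval(X, y, DecodeConfig(n_resamples=150), seed=4)
        dropped = region_ablation(X, y, REGIONS, "leave_one_out", REGIONS[11],
                                  DecodeConfig(n_resamples=150), seed=4)
        assert dropped.accuracy_mean == pytest.approx(full.accuracy_mean, abs=0.05)

    def test_unknown_region_rejected(self, rng):
        X, y = make_separable(rng)
        with pytest.raises(ValueError):
            region_ablation(X, y, REGIONS, "single", "L_X")


class TestComparePhases:
    def test_identical_accuracies_give_null_t(self):
        acc = np.array([0.5, 0.6, 0.7, 0.4, 0.5, 0.6, 0.7])
        t, p = compare_phases(acc, acc)
        assert (t, p) == (0.0, 1.0)

    def test_constant_improvement_is_degenerate_significant(self):
        pre = np.array([0.4, 0.5, 0.45, 0.55, 0.5, 0.6, 0.42])
        t, p = compare_phases(pre, pre + 0.1)
        assert np.isinf(t) and t > 0
        assert p == 0.0


class TestPostBeatsPreOnSyntheticStudies:
    def test_planted_post_effects_raise_decodability(self):
        # drug effects exist only post: mean post accuracy should exceed pre
        # for most subjects of a small replicate set
        from cortexscope.synth import SynthConfig, generate_study

        wins = 0
        n_rep = 3
        for rep in range(n_rep):
            cfg = SynthConfig(n_subjects=3, seed=500 + rep)
            manifest, sessions = generate_study(cfg)
            means = {}
            for phase in ["pre", "post"]:
                accs = []
                for subject in range(cfg.n_subjects):
                    sess = [
                        (sessions[(r.subject, r.day, r.phase)][0], r.condition, r.day)
                        for r in manifest.itertuples()
                        if r.subject == subject and r.phase == phase
                    ]
                    X, y = assemble_dataset(sess)
                    res = train_eval(X, y, DecodeConfig(n_resamples=60), seed=rep)
                    accs.append(res.accuracy_mean)
                means[phase] = np.mean(accs)
            wins += means["post"] > means["pre"]
        assert wins >= n_rep - 1
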