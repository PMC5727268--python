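import numpy as np
import pytest

import cmaplin as cml
from cmaplin import (
    DecisionBoundary,
    LinearNerveModel,
    ModelPoint,
    SplitConfig,
    classify,
    evaluate,
    label_points,
    split_data,
    train_svm,
)


def make_points(n_subjects=16, rng_seed=0, spread=0.05):
    """Well-separated synthetic parameter cloud: healthy a~1, injured a~0.2."""
    rng = np.random.default_rng(rng_seed)
    pts = []
    for s in range(n_subjects):
        for cond in range(4):
            a_center = 1.0 if cond in (0, 1) else 0.2
            pts.append(
                ModelPoint(
                    a=a_center + rng.normal(0, spread),
                    b=rng.normal(0, spread),
                    condition_index=cond,
                    label="healthy" if cond in (0, 1) else "injured",
                    subject_id=f"S{s}",
                )
            )
    return pts


class TestLabelPoints:
    def test_cohort_split_32_32(self):
        models = [
            LinearNerveModel(a=1.0, b=0.0, condition_index=c, subject_id=f"S{s}")
            for s in range(16)
            for c in range(4)
        ]
        pts = label_points(models)
        assert sum(p.label == "healthy" for p in pts) == 32
        assert sum(p.label == "injured" for p in pts) == 32

    @pytest.mark.parametrize("cond,expected", [(0, "healthy"), (1, "healthy"), (2, "injured"), (3, "injured")])
    def test_condition_map(self, cond, expected):
        pts = label_points([LinearNerveModel(a=0, b=0, condition_index=cond)])
        assert pts[0].label == expected

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            label_points([LinearNerveModel(a=0, b=0, condition_index=7)])


class TestSplitData:
    def test_sizes_70_30(self):
        train, test = split_data(make_points(), SplitConfig(seed=3))
        assert (len(train), len(test)) == (44, 20)

    def test_deterministic(self):
        pts = make_points()
        s1 = split_data(pts, SplitConfig(seed=9))
        s2 = split_data(pts, SplitConfig(seed=9))
        assert s1 == s2

    def test_half_split(self):
        pts = make_points(n_subjects=2) + make_points(n_subjects=1, rng_seed=5)[:2]
        pts = pts[:10]
        train, test = split_data(pts, SplitConfig(train_fraction=0.5, seed=0))
        assert (len(train), len(test)) == (5, 5)

    def test_partition_exhaustive_and_disjoint(self):
        pts = make_points()
        train, test = split_data(pts, SplitConfig(seed=1))
        assert sorted(map(id, train + test)) == sorted(map(id, pts))

    def test_stratification_preserves_proportions(self):
        train, test = split_data(make_points(), SplitConfig(seed=2))
        assert sum(p.label == "healthy" for p in train) == 22
        assert sum(p.label == "healthy" for p in test) == 10

    def test_single_class_stratification_fails(self):
        pts = [p for p in make_points() if p.label == "healthy"][:4] + [
            p for p in make_points() if p.label == "injured"
        ][:1]
        with pytest.raises(ValueError, match="stratify"):
            split_data(pts, SplitConfig(seed=0))


class TestTrainSvm:
    def test_separable_perfect_training_accuracy(self):
        pts = make_points()
        boundary = train_svm(pts)
        assert evaluate(classify(boundary, pts), pts).accuracy == 100.0

    def test_xor_soft_margin_absorbs(self):
        pts = [
            ModelPoint(a=x, b=y, condition_index=c, label=lab)
            for x, y, c, lab in [
                (0.0, 0.0, 0, "healthy"),
                (1.1, 0.9, 1, "healthy"),
                (0.0, 1.0, 2, "injured"),
                (1.0, 0.0, 3, "injured"),
            ]
        ]
        boundary = train_svm(pts)  # no error
        acc = evaluate(classify(boundary, pts), pts).accuracy
        assert acc < 100.0

    def test_two_point_maximum_margin_geometry(self):
        pts = [
            ModelPoint(a=1.0, b=0.0, condition_index=0, label="healthy"),
            ModelPoint(a=0.0, b=0.0, condition_index=3, label="injured"),
        ]
        boundary = train_svm(pts)
        # separating line is the perpendicular bisector a = 0.5
        assert boundary.weights[1] == pytest.approx(0.0, abs=1e-9)
        assert -boundary.bias / boundary.weights[0] == pytest.approx(0.5, abs=1e-6)

    def test_single_class_errors(self):
        pts = [p for p in make_points() if p.label == "healthy"]
        with pytest.raises(ValueError, match="single class"):
            train_svm(pts)


class TestClassify:
    boundary = DecisionBoundary(weights=(-1.0, 0.0), bias=0.5)  # injured iff a < 0.5

    def test_point_on_boundary_is_healthy(self):
        pt = ModelPoint(a=0.5, b=3.0, condition_index=0, label="healthy")
        assert classify(self.boundary, [pt]) == ["healthy"]

    def test_mirrored_point_flips(self):
        lo = ModelPoint(a=0.2, b=0.0, condition_index=3, label="injured")
        hi = ModelPoint(a=0.8, b=0.0, condition_index=0, label="healthy")
        assert classify(self.boundary, [lo, hi]) == ["injured", "healthy"]


class TestEvaluate:
    def test_all_correct(self):
        pts = make_points(n_subjects=2)
        assert evaluate([p.label for p in pts], pts).accuracy == 100.0

    def test_fifteen_of_sixteen(self):
        pts = make_points(n_subjects=4)[:16]
        preds = [p.label for p in pts]
        preds[0] = "injured" if preds[0] == "healthy" else "healthy"
        res = evaluate(preds, pts)
        assert res.accuracy == pytest.approx(93.75)
        assert res.rounded().accuracy == 93.8

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            evaluate([], [])

    def test_length_mismatch(self):
        pts = make_points(n_subjects=1)
        with pytest.raises(ValueError, match="mismatch"):
            evaluate(["healthy"], pts)

    def test_order_invariance(self):
        pts = make_points(n_subjects=3)
        preds = ["healthy"] * len(pts)
        acc1 = evaluate(preds, pts).accuracy
        order = np.random.default_rng(0).permutation(len(pts))
        acc2 = evaluate([preds[i] for i in order], [pts[i] for i in order]).accuracy
        assert acc1 == acc2

    def test_per_condition_breakdown(self):
        pts = make_points(n_subjects=4)
        preds = ["healthy"] * len(pts)  # everything called healthy
        res = evaluate(preds, pts)
        assert res.per_condition[0] == 100.0
        assert res.per_condition[2] == 0.0


class TestCrossNormalization:
    def test_consistency_when_modes_coincide(self, cohort_seed1):
        # duplicate the baseline row everywhere: Eq-3 and Eq-5 curves differ
        # only by the fixed denominator, and all conditions collapse onto the
        # initial-condition curve, so both normalizations agree exactly
        mats = []
        for m in cohort_seed1:
            vpp = np.vstack([m.vpp[0]] * 4)
            mats.append(cml.CmapMatrix(vpp=vpp, schedule=m.schedule, subject_id=m.subject_id))
        base = cml.points_from_matrices(mats, "baseline")
        trial = cml.points_from_matrices(mats, "per_trial")
        np.testing.assert_allclose(
            [p.a for p in base], [p.a for p in trial], rtol=1e-12
        )

    def test_default_cohort_transfer_pattern(self, cohort_seed1):
        report = cml.cross_normalization_eval(cohort_seed1, SplitConfig(seed=1))
        per_cond = report["transfer_per_condition"]
        assert set(per_cond) == {0, 1, 2, 3}
        # the paper's pattern: the mild-injury boundary condition (damage2)
        # is the hardest to transfer
        assert per_cond[0] >= per_cond[2]
        assert report["n_train"] == 44 and report["n_test"] == 20

    def test_single_condition_report(self):
        pts = make_points()
        boundary = train_svm(pts)
        only_initial = [p for p in pts if p.condition_index == 0]
        res = evaluate(classify(boundary, only_initial), only_initial)
        assert list(res.per_condition) == [0]
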