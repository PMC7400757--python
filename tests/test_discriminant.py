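"""1-D discriminant: boundary placement, published-score form, LOOCV."""

import numpy as np
import pytest

from eloreta_npv import (
    DiscriminantModel, fit_discriminant, loocv, predict_score,
)
from eloreta_npv.discriminant import DegenerateDataError


def labels_of(y):
    return ["responder" if v else "nonresponder" for v in y]


class TestFit:
    def test_boundary_at_midpoint_of_means(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(1.0, 0.2, 20), rng.normal(-1.0, 0.2, 20)])
        y = np.array([True] * 20 + [False] * 20)
        model = fit_discriminant(x, labels_of(y))
        mid = 0.5 * (x[:20].mean() + x[20:].mean())
        assert model.weight == 1.0
        assert model.intercept == pytest.approx(-mid, abs=1e-12)
        assert abs(model.intercept) < 0.2

    def test_translation_equivariance(self):
        x = np.array([1.0, 1.2, -0.9, -1.1])
        y = [True, True, False, False]
        m0 = fit_discriminant(x, labels_of(y))
        m1 = fit_discriminant(x + 3.5, labels_of(y))
        assert m1.intercept == pytest.approx(m0.intercept - 3.5, abs=1e-12)

    def test_label_swap_flips_decision(self):
        x = np.array([1.0, 1.2, -0.9, -1.1])
        y = [True, True, False, False]
        m = fit_discriminant(x, labels_of(y))
        m_sw = fit_discriminant(x, labels_of([not v for v in y]))
        assert m_sw.weight == -m.weight
        assert m_sw.intercept == pytest.approx(-m.intercept, abs=1e-12)

    def test_matches_sklearn_lda_boundary(self):
        """Cross-check: equal-prior sklearn LDA predicts identically."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0.8, 0.5, 13), rng.normal(-0.4, 0.5, 17)])
        y = np.array([1] * 13 + [0] * 17)
        model = fit_discriminant(x, labels_of(y == 1))
        lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(x[:, None], y)
        ours = np.array([
            predict_score(model, float(np.exp(v))) > 0 for v in x
        ])
        assert np.array_equal(ours, lda.predict(x[:, None]).astype(bool))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_discriminant(np.array([1.0, 2.0]), ["responder", "responder"])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError, match="variance"):
            fit_discriminant(
                np.array([1.0, 1.0, 2.0, 2.0]),
                ["responder", "responder", "nonresponder", "nonresponder"],
            )


class TestPredictScore:
    def test_published_form_at_npv_one(self):
        """score = ln(NPV) + 1.49 evaluates to 1.49 at NPV = 1 (responder)."""
        model = DiscriminantModel(voxel_id=0, band="beta", weight=1.0, intercept=1.49)
        score = predict_score(model, 1.0)
        assert score == pytest.approx(1.49, abs=1e-12)
        assert score > 0  # predicted responder

    def test_decision_boundary(self):
        model = DiscriminantModel(voxel_id=0, band="beta", weight=1.0, intercept=1.49)
        assert predict_score(model, float(np.exp(-1.49))) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_npv_rejected(self):
        model = DiscriminantModel(voxel_id=0, band="beta", weight=1.0, intercept=1.49)
        for bad in (0.0, -1.0):
            with pytest.raises(ValueError, match="positive"):
                predict_score(model, bad)

    def test_strictly_increasing_in_npv(self):
        model = DiscriminantModel(voxel_id=0, band="beta", weight=1.0, intercept=0.3)
        vals = [predict_score(model, v) for v in (0.1, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(vals) > 0)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            DiscriminantModel(voxel_id=0, band="beta", weight=0.0, intercept=1.0)


class TestLOOCV:
    def test_perfectly_separated_cohort(self):
        x = np.array([-1.2, -1.0, -0.8, 0.8, 1.0, 1.2])
        y = [False, False, False, True, True, True]
        report = loocv(x, labels_of(y))
        assert report.accuracy == 1.0
        assert (report.tp, report.tn, report.fp, report.fn) == (3, 3, 0, 0)

    def test_metrics_consistent_with_counts(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=16)
        y = [True] * 8 + [False] * 8
        r = loocv(x, labels_of(y))
        assert r.total == 16
        assert r.accuracy == (r.tp + r.tn) / 16

    def test_duplicated_cohort_preserves_metrics(self):
        x = np.array([-1.0, -0.7, -0.4, 0.5, 0.9, 1.3])
        y = [False, False, False, True, True, True]
        base = loocv(x, labels_of(y))
        dup = loocv(np.tile(x, 2), labels_of(y * 2))
        assert dup.accuracy == base.accuracy
        assert dup.ppv == base.ppv

    def test_permuted_labels_hit_chance(self):
        """Label shuffles on separable data: mean LOOCV accuracy near 0.5."""
        rng = np.random.default_rng(3)
        x = np.concatenate([np.linspace(-2, -1, 10), np.linspace(1, 2, 10)])
        y = np.array([False] * 10 + [True] * 10)
        accs = []
        for _ in range(100):
            perm = rng.permutation(20)
            try:
                accs.append(loocv(x, labels_of(y[perm])).accuracy)
            except DegenerateDataError:
                pass
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_deterministic(self):
        x = np.array([-1.0, -0.5, 0.2, 0.7, 1.1, -0.2])
        y = [False, False, True, True, True, False]
        assert loocv(x, labels_of(y)) == loocv(x, labels_of(y))

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            loocv(np.array([1.0, 2, 3]), ["responder", "nonresponder", "responder"])
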