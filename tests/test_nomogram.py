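"""Nomogram point geometry, feature mapping, cutoffs and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nomostack.exceptions import ValidationError
from nomostack.nomogram import (
    Nomogram,
    RiskCutoffs,
    analytic_clinic_beta,
    build_nomogram,
    classify,
    derive_cutoffs,
    fma_convert,
)
from nomostack.ordinal import OLRFit


def _fit(beta, theta=(-1.0, 1.0), names=None):
    beta = np.asarray(beta, dtype=float)
    names = names or [f"x{j}" for j in range(len(beta))]
    k = len(theta) + 1
    return OLRFit(
        beta=beta,
        theta=np.asarray(theta, dtype=float),
        cov=np.eye(len(beta) + len(theta)),
        loglik=0.0,
        covariate_names=list(names),
        n=100,
        n_classes=k,
    )


class TestBuildNomogram:
    def test_single_unit_covariate_spans_100_points(self):
        nomo = build_nomogram(_fit([1.0]), ranges=np.array([[0.0, 1.0]]))
        x = np.array([[0.0], [0.5], [1.0]])
        assert np.allclose(nomo.axis_points(x)[:, 0], [0.0, 50.0, 100.0])
        assert nomo.points_to_eta(100.0) == pytest.approx(1.0)
        assert nomo.points_to_eta(0.0) == pytest.approx(0.0)

    def test_negative_coefficient_axis_is_zero_at_upper_end(self):
        nomo = build_nomogram(_fit([-2.0]), ranges=np.array([[0.0, 1.0]]))
        pts = nomo.axis_points(np.array([[0.0], [1.0]]))[:, 0]
        assert pts[0] == pytest.approx(200.0 / 2.0)  # widest axis still spans 100
        assert pts[1] == pytest.approx(0.0)
        assert (np.diff(nomo.axis_points(np.linspace(0, 1, 5)[:, None])[:, 0]) < 0).all()

    def test_two_axes_scale_by_effect_width(self):
        nomo = build_nomogram(_fit([2.0, 1.0]), ranges=np.array([[0.0, 1.0], [0.0, 1.0]]))
        assert np.allclose(nomo.max_axis_points, [100.0, 50.0])

    def test_round_trip_eta_through_points(self):
        rng = np.random.default_rng(0)
        nomo = build_nomogram(
            _fit([2.0, 1.0]), ranges=np.array([[0.0, 1.0], [0.0, 1.0]])
        )
        V = rng.uniform(size=(1000, 2))
        eta_direct = V @ nomo.beta
        eta_via_points = nomo.points_to_eta(nomo.total_points(V))
        assert np.abs(eta_direct - eta_via_points).max() < 1e-9

    def test_exactly_one_axis_attains_100(self):
        rng = np.random.default_rng(1)
        beta = rng.normal(size=4)
        ranges = np.sort(rng.uniform(0, 2, size=(4, 2)), axis=1)
        ranges[:, 1] += 0.1
        nomo = build_nomogram(_fit(beta), ranges=ranges)
        mx = nomo.max_axis_points
        assert np.isclose(mx.max(), 100.0)
        assert (mx <= 100.0 + 1e-9).all()

    def test_zero_width_range_rejected(self):
        with pytest.raises(ValidationError, match="zero-width"):
            build_nomogram(_fit([1.0]), ranges=np.array([[2.0, 2.0]]))

    def test_prob_table_rows_sum_to_one_and_risk_is_monotone(self):
        nomo = build_nomogram(_fit([1.5, -0.5]), ranges=np.array([[0, 1], [0, 1]]))
        tab = nomo.prob_table()
        total = tab[["p_low", "p_intermediate", "p_high"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)
        assert (np.diff(tab["p_high"]) >= -1e-12).all()
        assert (np.diff(tab["p_low"]) <= 1e-12).all()


class TestScore:
    def test_score_at_axis_extremes(self):
        nomo = build_nomogram(_fit([2.0, -1.0]), ranges=np.array([[0, 1], [0, 1]]))
        # 0-point corner: x0 at lo (beta>0), x1 at hi (beta<0)
        eta, pts = nomo.score(np.array([0.0, 1.0]))
        assert pts[0] == pytest.approx(0.0)
        assert eta[0] == pytest.approx(nomo.eta_min)
        eta, pts = nomo.score(np.array([1.0, 0.0]))
        assert pts[0] == pytest.approx(nomo.max_axis_points.sum())

    def test_mid_range_score_equals_linear_predictor(self):
        rng = np.random.default_rng(2)
        nomo = build_nomogram(_fit([2.0, 1.0]), ranges=np.array([[0, 1], [0, 1]]))
        V = rng.uniform(size=(50, 2))
        eta, _ = nomo.score(V)
        assert np.allclose(eta, V @ np.array([2.0, 1.0]), atol=1e-9)

    def test_out_of_range_values_clip_with_warning(self):
        nomo = build_nomogram(_fit([1.0]), ranges=np.array([[0.0, 1.0]]))
        with pytest.warns(UserWarning, match="clipped"):
            _, pts = nomo.score(np.array([2.0]))
        assert pts[0] == pytest.approx(100.0)

    def test_missing_axis_value_rejected(self):
        nomo = build_nomogram(_fit([1.0, 1.0]), ranges=np.array([[0, 1], [0, 1]]))
        with pytest.raises(ValidationError, match="missing"):
            nomo.score({"x0": 0.5})


class TestSerialization:
    def test_save_load_round_trip_is_exact(self, tmp_path):
        nomo = build_nomogram(
            _fit([1.37, -0.229], theta=(-0.73, 1.19)),
            ranges=np.array([[0.11, 0.93], [0.05, 0.87]]),
        )
        nomo.save(tmp_path / "bundle")
        back = Nomogram.load(tmp_path / "bundle")
        assert np.array_equal(back.beta, nomo.beta)
        assert np.array_equal(back.theta, nomo.theta)
        assert np.array_equal(back.ranges, nomo.ranges)
        V = np.random.default_rng(3).uniform(0.1, 0.8, size=(20, 2))
        assert np.array_equal(nomo.total_points(V), back.total_points(V))


class TestFMA:
    def test_single_model_identity_mapping(self):
        FI = pd.DataFrame({"m1": [1.0, 0.0, 0.0]}, index=["a", "b", "c"])
        MV = pd.DataFrame({"m1": [1.3, 2.7]}, index=["p1", "p2"])
        res = fma_convert(FI=FI, MV=MV)
        assert np.allclose(res.CF["a"], [1.3, 2.7])
        assert np.allclose(res.CF[["b", "c"]], 0.0)

    def test_conservation_of_total(self):
        rng = np.random.default_rng(4)
        M, N, n = 9, 4, 30
        FI = pd.DataFrame(rng.dirichlet(np.ones(M), size=N).T,
                          index=[f"f{i}" for i in range(M)],
                          columns=[f"m{j}" for j in range(N)])
        MV = pd.DataFrame(rng.uniform(1, 3, size=(n, N)), columns=FI.columns)
        res = fma_convert(FI=FI, MV=MV)
        assert np.allclose(
            res.CF.sum(axis=1), MV.sum(axis=1), atol=1e-12
        )

    def test_equal_model_values_distribute_by_row_sums(self):
        rng = np.random.default_rng(5)
        M, N = 5, 3
        FI = pd.DataFrame(rng.dirichlet(np.ones(M), size=N).T,
                          index=[f"f{i}" for i in range(M)],
                          columns=[f"m{j}" for j in range(N)])
        c = 2.2
        MV = pd.DataFrame(np.full((4, N), c), columns=FI.columns)
        res = fma_convert(FI=FI, MV=MV)
        expected = c * FI.sum(axis=1)
        assert np.allclose(res.CF.iloc[0], expected, atol=1e-12)

    def test_off_simplex_importances_rejected(self):
        FI = pd.DataFrame({"m1": [0.8, 0.8]}, index=["a", "b"])
        MV = pd.DataFrame({"m1": [1.0]})
        with pytest.raises(ValidationError, match="simplex"):
            fma_convert(FI=FI, MV=MV)

    def test_analytic_clinic_coefficients(self):
        FI = pd.DataFrame(
            {"m1": [0.5, 0.5], "m2": [0.2, 0.8]}, index=["a", "b"]
        )
        beta_ml = np.array([2.0, 1.0])
        out = analytic_clinic_beta(FI, beta_ml)
        assert np.allclose(out, [0.5 * 2 + 0.2 * 1, 0.5 * 2 + 0.8 * 1])


class TestClassify:
    def test_published_cutoff_convention(self):
        cuts = RiskCutoffs(2.24, 6.00)
        assert classify(np.array([2.24]), cuts)[0] == 1  # boundary closed on the left
        assert classify(np.array([7.1]), cuts)[0] == 3
        assert np.array_equal(classify(np.array([1.0, 3.0, 9.0]), cuts), [1, 2, 3])

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValidationError):
            RiskCutoffs(6.0, 2.24)

    @given(
        scores=st.lists(st.floats(-10, 10), min_size=2, max_size=30),
        c1=st.floats(-5, 0),
        width=st.floats(0.1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_classification_is_monotone_in_score(self, scores, c1, width):
        cuts = RiskCutoffs(c1, c1 + width)
        s = np.sort(np.asarray(scores))
        labels = classify(s, cuts)
        assert (np.diff(labels) >= 0).all()


class TestDeriveCutoffs:
    def test_perfect_separation_returns_gap_midpoints(self):
        scores = np.array([1.0, 2.0, 5.0, 6.0, 10.0, 11.0])
        labels = np.array([1, 1, 2, 2, 3, 3])
        cuts, acc = derive_cutoffs(scores, labels)
        assert acc == pytest.approx(1.0)
        assert cuts.c1 == pytest.approx(3.5)
        assert cuts.c2 == pytest.approx(8.0)

    def test_shuffled_labels_report_near_chance_recall(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(size=600)
        labels = rng.permutation(np.repeat([1, 2, 3], 200))
        _, acc = derive_cutoffs(scores, labels)
        assert acc < 0.45  # macro recall close to the 1/3 chance level

    def test_monotone_group_means_on_ordinal_signal(self):
        rng = np.random.default_rng(7)
        labels = np.repeat([1, 2, 3], 150)
        scores = labels + rng.normal(0, 0.8, 450)
        cuts, _ = derive_cutoffs(scores, labels)
        induced = classify(scores, cuts)
        means = [scores[induced == k].mean() for k in (1, 2, 3)]
        assert means[0] < means[1] < means[2]

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValidationError):
            derive_cutoffs(np.ones(30), np.repeat([1, 2, 3], 10))

    def test_missing_class_rejected(self):
        with pytest.raises(ValidationError):
            derive_cutoffs(np.arange(20.0), np.repeat([1, 3], 10))
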