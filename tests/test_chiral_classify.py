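import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enantiopore import (
    BaselineStats,
    EventTable,
    FEATURES,
    GaussianBand,
    estimate_mixture_ratio,
    evaluate_confusion,
    expected_mc_recall,
    fit_pc2_band,
    fit_pca_model,
    label_single,
    labeled_from_pc2,
    logistic_baseline,
    monte_carlo_classify,
    project_events,
    simulate_pc2_samples,
)

BAND_D = GaussianBand(-0.039, 0.043, "D")
BAND_L = GaussianBand(0.047, 0.035, "L")


def feature_table(n=500, seed=0, correlated=True):
    rng = np.random.default_rng(seed)
    if correlated:
        dwell = rng.exponential(800.0, n) + 200.0
        di_b = rng.normal(100.0, 6.0, n)
        di_bmin = di_b - np.abs(rng.normal(8.0, 2.0, n))
        di_bmax = di_b + np.abs(rng.normal(8.0, 2.0, n))
        sigma = np.abs(rng.normal(3.0, 0.5, n)) + 1.0
    else:
        dwell, di_b, di_bmin, di_bmax, sigma = (rng.normal(0, 1, n) for _ in range(5))
    df = pd.DataFrame(
        {
            "start_index": np.arange(n) * 1000,
            "end_index": np.arange(n) * 1000 + 100,
            "t_t_us": dwell,
            "di_bmin_pA": di_bmin,
            "di_bmax_pA": di_bmax,
            "di_b_pA": di_b,
            "i_bs_pA": sigma,
            "norm_di_b": np.clip(np.asarray(di_b) / 250.0, 0.0, 1.0),
        }
    )
    return EventTable(df, BaselineStats(250.0, 2.0), 250_000.0)


class TestPCAModel:
    def test_orthonormal_components_and_descending_eigenvalues(self):
        model = fit_pca_model(feature_table(800, seed=1))
        np.testing.assert_allclose(model.components @ model.components.T, np.eye(2), atol=1e-10)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert np.all(model.eigenvalues >= -1e-12)
        np.testing.assert_allclose(np.diag(model.correlation), 1.0, atol=1e-12)
        np.testing.assert_allclose(model.correlation, model.correlation.T, atol=1e-12)

    def test_matches_sklearn_pca_on_standardized_features(self):
        table = feature_table(800, seed=2)
        model = fit_pca_model(table)
        from sklearn.decomposition import PCA

        X = table.events[FEATURES].to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        sk = PCA(n_components=2).fit(Z)
        np.testing.assert_allclose(sk.explained_variance_, model.eigenvalues[:2], rtol=1e-6)
        for ours, theirs in zip(model.components, sk.components_):
            assert np.allclose(ours, theirs, atol=1e-8) or np.allclose(ours, -theirs, atol=1e-8)

    def test_sign_convention(self):
        table = feature_table(800, seed=3)
        model = fit_pca_model(table)
        assert model.components[0, FEATURES.index("di_b_pA")] >= 0
        proj = project_events(table, model)
        assert np.median(proj.data.pc2) <= 1e-12

    def test_sign_convention_invariant_to_row_order(self):
        table = feature_table(800, seed=4)
        shuffled = EventTable(
            table.events.sample(frac=1.0, random_state=9).reset_index(drop=True),
            table.baseline,
            table.sampling_rate,
        )
        m1, m2 = fit_pca_model(table), fit_pca_model(shuffled)
        np.testing.assert_allclose(m1.components, m2.components, atol=1e-8)

    def test_isotropic_features_preserve_total_variance(self):
        table = feature_table(5000, seed=5, correlated=False)
        model = fit_pca_model(table)
        assert model.eigenvalues == pytest.approx(np.ones(5), abs=0.15)
        assert model.eigenvalues.sum() == pytest.approx(5.0, abs=1e-8)

    def test_duplicated_feature_dominates(self):
        table = feature_table(500, seed=6)
        df = table.events.copy()
        df["di_bmax_pA"] = 2.0 * df["di_b_pA"]  # perfectly correlated pair
        model = fit_pca_model(EventTable(df, table.baseline, table.sampling_rate))
        assert model.eigenvalues[0] >= 2.0 - 1e-9

    def test_zero_variance_feature_named(self):
        table = feature_table(500, seed=7)
        df = table.events.copy()
        df["i_bs_pA"] = 3.0
        with pytest.raises(ValueError, match="i_bs_pA"):
            fit_pca_model(EventTable(df, table.baseline, table.sampling_rate))

    def test_too_few_events(self):
        with pytest.raises(ValueError, match="100"):
            fit_pca_model(feature_table(50))

    def test_json_round_trip(self, tmp_path):
        model = fit_pca_model(feature_table(300, seed=8))
        path = tmp_path / "model.json"
        model.to_json(path)
        from enantiopore import PCAModel

        back = PCAModel.from_json(path)
        np.testing.assert_allclose(back.components, model.components)
        np.testing.assert_allclose(back.center, model.center)


class TestProjection:
    def test_reference_projection_is_centered(self):
        table = feature_table(1000, seed=10)
        model = fit_pca_model(table)
        proj = project_events(table, model)
        assert abs(proj.data.pc1.mean()) < 1e-10
        assert abs(proj.data.pc2.mean()) < 1e-10

    def test_deterministic(self):
        table = feature_table(200, seed=11)
        model = fit_pca_model(table)
        p1, p2 = project_events(table, model), project_events(table, model)
        pd.testing.assert_frame_equal(p1.data, p2.data)

    def test_projection_is_affine(self):
        table = feature_table(200, seed=12)
        model = fit_pca_model(table)
        a = table.events[FEATURES].iloc[0].to_numpy()
        b = table.events[FEATURES].iloc[1].to_numpy()
        lam = 0.3

        def project_row(row):
            z = (row - model.center) / model.scale
            return z @ model.components.T

        combo = project_row(lam * a + (1 - lam) * b)
        parts = lam * project_row(a) + (1 - lam) * project_row(b)
        np.testing.assert_allclose(combo, parts, atol=1e-10)

    def test_uses_reference_normalization_not_own(self):
        ref = feature_table(500, seed=13)
        model = fit_pca_model(ref)
        shifted = ref.events.copy()
        shifted[FEATURES] = shifted[FEATURES] + 5.0
        proj = project_events(EventTable(shifted, ref.baseline, ref.sampling_rate), model)
        # a uniformly shifted dataset must NOT project to zero mean
        assert abs(proj.data.pc1.mean()) > 0.1

    def test_missing_feature_column(self):
        table = feature_table(200, seed=14)
        model = fit_pca_model(table)
        df = table.events.drop(columns=["i_bs_pA"])
        with pytest.raises(ValueError, match="i_bs_pA"):
            project_events(EventTable(df, table.baseline, table.sampling_rate), model)


class TestBands:
    def test_band_fit_recovers_printed_parameters(self):
        x = simulate_pc2_samples(BAND_D, 10_000, seed=20)
        band = fit_pc2_band(x, "D")
        assert band.mean == pytest.approx(-0.039, abs=0.005)
        assert band.sd == pytest.approx(0.043, abs=0.005)
        assert band.upper - band.lower == pytest.approx(6 * band.sd)

    def test_own_sample_retention_is_three_sigma_mass(self):
        x = simulate_pc2_samples(BAND_D, 50_000, seed=21)
        band = fit_pc2_band(x, "D")
        inside = band.contains(x).mean()
        assert inside == pytest.approx(0.9973, abs=0.004)

    def test_bimodal_distribution_rejected(self):
        rng = np.random.default_rng(22)
        x = np.concatenate([rng.normal(-1.0, 0.1, 2000), rng.normal(1.0, 0.1, 2000)])
        with pytest.raises(ValueError, match="bimodal"):
            fit_pc2_band(x, "D")

    def test_label_single_boundaries(self):
        band = GaussianBand(0.0, 1.0, "L")
        events = labeled_from_pc2(np.array([0.0, 3.0, 3.01, -3.0, -3.2]))
        out = label_single(events, band).data.label.tolist()
        assert out == ["L", "L", "unlabeled", "L", "unlabeled"]


class TestMonteCarlo:
    def test_identical_bands_split_evenly(self):
        band = GaussianBand(0.0, 1.0, "D")
        band_l = GaussianBand(0.0, 1.0, "L")
        x = simulate_pc2_samples(band, 10_000, seed=30)
        pred = monte_carlo_classify(labeled_from_pc2(x), band, band_l, seed=31)
        counts = pred.counts()
        n_labeled = counts["D"] + counts["L"]
        assert counts["D"] / n_labeled == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n_labeled))

    def test_separated_bands_near_perfect(self):
        bd = GaussianBand(0.0, 1.0, "D")
        bl = GaussianBand(10.0, 1.0, "L")
        xd = simulate_pc2_samples(bd, 5000, seed=32)
        xl = simulate_pc2_samples(bl, 5000, seed=33)
        pred = monte_carlo_classify(labeled_from_pc2(np.concatenate([xd, xl])), bd, bl, 34)
        truth = np.array(["D"] * 5000 + ["L"] * 5000, dtype=object)
        cm = evaluate_confusion(pred, truth)
        assert cm.per_class_success["D"] == pytest.approx(0.997, abs=0.005)
        assert cm.per_class_success["L"] == pytest.approx(0.997, abs=0.005)
        assert cm.false_positive_rate["D"] <= 0.001

    def test_label_conservation_and_reproducibility(self):
        x = np.concatenate(
            [simulate_pc2_samples(BAND_D, 2000, 35), simulate_pc2_samples(BAND_L, 2000, 36)]
        )
        p1 = monte_carlo_classify(labeled_from_pc2(x), BAND_D, BAND_L, seed=37)
        p2 = monte_carlo_classify(labeled_from_pc2(x), BAND_D, BAND_L, seed=37)
        pd.testing.assert_frame_equal(p1.data, p2.data)
        counts = p1.counts()
        assert sum(counts.values()) == 4000

    @pytest.mark.parametrize(
        "band_pair",
        [
            (BAND_D, BAND_L),
            (GaussianBand(-0.5, 0.3, "D"), GaussianBand(0.2, 0.5, "L")),
            (GaussianBand(0.0, 1.0, "D"), GaussianBand(0.5, 1.0, "L")),
        ],
    )
    def test_recall_matches_integration_oracle(self, band_pair):
        bd, bl = band_pair
        n = 30_000
        xd = simulate_pc2_samples(bd, n, seed=38)
        pred = monte_carlo_classify(labeled_from_pc2(xd), bd, bl, seed=39)
        recall = np.mean(pred.data.label == "D")
        expected = expected_mc_recall(bd, bl)
        se = np.sqrt(expected * (1 - expected) / n)
        assert recall == pytest.approx(expected, abs=4 * se)


class TestEvaluation:
    def test_perfect_predictions(self):
        x = np.array([-1.0, -1.0, 1.0])
        ev = labeled_from_pc2(x)
        ev.data["label"] = ["D", "D", "L"]
        cm = evaluate_confusion(ev, np.array(["D", "D", "L"], dtype=object))
        assert cm.per_class_success == {"D": 1.0, "L": 1.0}
        assert cm.overall_success == 1.0
        assert cm.false_positive_rate == {"D": 0.0, "L": 0.0}

    def test_all_unlabeled(self):
        ev = labeled_from_pc2(np.zeros(4))
        cm = evaluate_confusion(ev, np.array(["D", "D", "L", "L"], dtype=object))
        assert cm.overall_success == 0.0
        assert cm.false_positive_rate == {"D": 0.0, "L": 0.0}

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_confusion(labeled_from_pc2(np.zeros(3)), np.array(["D"], dtype=object))


class TestMixtureRatio:
    @staticmethod
    def classify_mix(n_l, n_d, seed):
        bd = GaussianBand(0.0, 1.0, "D")
        bl = GaussianBand(12.0, 1.0, "L")  # well separated
        x = np.concatenate(
            [simulate_pc2_samples(bl, n_l, seed), simulate_pc2_samples(bd, n_d, seed + 1)]
        )
        return monte_carlo_classify(labeled_from_pc2(x), bd, bl, seed + 2)

    def test_equal_counts_give_unit_ratio(self):
        r = estimate_mixture_ratio(self.classify_mix(2000, 2000, seed=40))
        assert r.ci_low <= 1.0 <= r.ci_high
        assert r.ratio == pytest.approx(1.0, abs=0.1)

    def test_three_to_one(self):
        r = estimate_mixture_ratio(self.classify_mix(3000, 1000, seed=41))
        assert r.ci_low <= 3.0 <= r.ci_high

    def test_reciprocal_symmetry(self):
        r31 = estimate_mixture_ratio(self.classify_mix(3000, 1000, seed=42))
        r13 = estimate_mixture_ratio(self.classify_mix(1000, 3000, seed=43))
        assert r31.ratio == pytest.approx(1.0 / r13.ratio, rel=0.15)

    def test_zero_d_flagged(self):
        ev = labeled_from_pc2(np.zeros(10))
        ev.data["label"] = "L"
        r = estimate_mixture_ratio(ev)
        assert not r.defined


class TestLogisticBaseline:
    def test_separated_classes_near_perfect(self):
        xd = simulate_pc2_samples(GaussianBand(-5.0, 0.5, "D"), 1000, 50)
        xl = simulate_pc2_samples(GaussianBand(5.0, 0.5, "L"), 1000, 51)
        ev = labeled_from_pc2(np.concatenate([xd, xl]))
        truth = np.array(["D"] * 1000 + ["L"] * 1000, dtype=object)
        rep = logistic_baseline(ev, truth, seed=52)
        assert rep["accuracy"] >= 0.99
        assert rep["n_train"] == pytest.approx(0.2 * 2000, abs=1)

    def test_identical_classes_at_chance(self):
        band = GaussianBand(0.0, 1.0, "D")
        ev = labeled_from_pc2(
            np.concatenate([simulate_pc2_samples(band, 2000, 53),
                            simulate_pc2_samples(band, 2000, 54)])
        )
        truth = np.array(["D"] * 2000 + ["L"] * 2000, dtype=object)
        rep = logistic_baseline(ev, truth, seed=55)
        assert rep["accuracy"] == pytest.approx(0.5, abs=0.05)

    def test_hard_decisions_beat_soft_assignment(self):
        # MAP decisions within the bands dominate the stochastic soft rule
        n = 20_000
        xd = simulate_pc2_samples(BAND_D, n, 56)
        xl = simulate_pc2_samples(BAND_L, n, 57)
        ev = labeled_from_pc2(np.concatenate([xd, xl]))
        truth = np.array(["D"] * n + ["L"] * n, dtype=object)
        rep = logistic_baseline(ev, truth, seed=58)
        soft = 0.5 * (expected_mc_recall(BAND_D, BAND_L) + expected_mc_recall(BAND_L, BAND_D))
        assert rep["accuracy"] >= soft - 0.01
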