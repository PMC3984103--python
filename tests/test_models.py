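import numpy as np
import pytest

from splitimpute import (
    Cohort,
    GeneratorConfig,
    RunnerRecord,
    choose_svd_rank,
    fit_anova,
    fit_lm_models,
    fit_svd,
    fit_two_way_log_anova,
    generate_cohort,
    generate_fixture,
    load_model_bundle,
    predict_anova,
    predict_lm,
    predict_svd,
    save_model_bundle,
)
from splitimpute.models import reconstruct_svd_row


@pytest.fixture(scope="module")
def eq1_fixture():
    return generate_fixture("eq1", seed=2, n=120)


@pytest.fixture(scope="module")
def anova_cohort():
    # large enough that all 32 pacing subgroups are populated
    return generate_cohort(GeneratorConfig(n=4000, seed=11))


class TestLinearRegression:
    def test_noiseless_coefficients_recovered(self, eq1_fixture):
        models = fit_lm_models(eq1_fixture.cohort)
        coef = models.models[35.0]
        assert abs(coef[0] - eq1_fixture.params["intercept"]) < 1e-8
        np.testing.assert_allclose(coef[1:8], eq1_fixture.params["coef"], atol=1e-8)

    def test_noisy_fit_matches_normal_equations(self):
        fx = generate_fixture("eq1", seed=8, n=150, noise_sd=30.0)
        models = fit_lm_models(fx.cohort)
        X = np.array([r.section_times for r in fx.cohort])
        design = np.column_stack([np.ones(len(X)), X[:, :7]])
        target = X[:, 7:].sum(axis=1)
        beta = np.linalg.solve(design.T @ design, design.T @ target)
        np.testing.assert_allclose(models.models[35.0], beta, atol=1e-8)

    def test_underdetermined_errors(self):
        recs = [RunnerRecord(f"r{i}", 2013, "M", 40, [1800.0 + i] * 9) for i in range(3)]
        with pytest.raises(ValueError):
            fit_lm_models(Cohort(recs))

    def test_predict_exact_on_noiseless_model(self, eq1_fixture):
        models = fit_lm_models(eq1_fixture.cohort)
        rec = eq1_fixture.cohort.records[0]
        true_remaining = sum(rec.section_times[7:])
        pred = predict_lm(rec.truncated(7), models)
        assert pred.remaining_s == pytest.approx(true_remaining, abs=1e-6)

    def test_predict_at_mean_gives_mean_response(self, small_cohort):
        models = fit_lm_models(small_cohort)
        X = np.array([r.section_times for r in small_cohort])
        mean_rec = RunnerRecord("mean", 2013, "M", 40, list(X[:, :7].mean(axis=0)))
        pred = predict_lm(mean_rec, models)
        assert pred.remaining_s == pytest.approx(X[:, 7:].sum(axis=1).mean(), rel=1e-10)

    def test_fader_cohort_has_negative_early_coefficients(self):
        # on a fading population, slower early splits predict a relatively
        # faster (smaller) remaining time: negative early-section weights
        cohort = generate_cohort(
            GeneratorConfig(n=3000, seed=6, fade_mix=(0.2, 0.8, 0.0))
        )
        models = fit_lm_models(cohort)
        coef = models.models[40.0]
        assert coef[1] < 0 and coef[2] < 0

    def test_demographic_variant_fits(self, small_cohort):
        models = fit_lm_models(small_cohort, include_demographics=True)
        rec = small_cohort.records[0].truncated(7)
        assert predict_lm(rec, models).remaining_s > 0


class TestAnova:
    def test_two_way_closed_form(self, rng):
        y = rng.lognormal(np.log(1800), 0.1, (40, 9))
        mu, beta = fit_two_way_log_anova(y)
        logs = np.log(y)
        assert mu == pytest.approx(logs.mean())
        np.testing.assert_allclose(beta, logs.mean(axis=0) - logs.mean(), atol=1e-12)
        assert abs(beta.sum()) < 1e-9

    def test_noiseless_effects_recovered(self):
        fx = generate_fixture("anova", seed=3, n=60)
        times = np.array([r.section_times for r in fx.cohort])
        mu, beta = fit_two_way_log_anova(times)
        # the fitted grand mean absorbs the mean runner effect
        assert mu == pytest.approx(fx.params["mu"] + fx.params["alpha"].mean(), abs=1e-8)
        np.testing.assert_allclose(beta, fx.params["beta"], atol=1e-8)

    def test_32_subgroups_with_zero_sum_effects(self, anova_cohort):
        model = fit_anova(anova_cohort)
        assert len(model.subgroups) == 32
        for mu, beta in model.subgroups.values():
            assert abs(beta.sum()) < 1e-9

    def test_subgroup_assignment_is_partition(self, anova_cohort):
        from splitimpute.models import _assign_subgroup

        model = fit_anova(anova_cohort)
        counts = {}
        for rec in anova_cohort:
            key = _assign_subgroup(rec, model, __import__("splitimpute").DEFAULT_LAYOUT)
            counts[key] = counts.get(key, 0) + 1
        assert sum(counts.values()) == len(anova_cohort)
        assert set(counts) <= set(model.subgroups)

    def test_small_cohort_rejected(self):
        cohort = generate_cohort(GeneratorConfig(n=100, seed=1))
        with pytest.raises(ValueError):
            fit_anova(cohort)

    def test_imputation_scale_equivariance_within_subgroup(self, anova_cohort):
        # multiplicative model: with the subgroup effects held fixed, scaling
        # the observed sections by c shifts alpha by log c and scales every
        # imputed section by c (subgroup *membership* is pace-dependent, so
        # it is pinned here)
        from splitimpute.models import _assign_subgroup

        model = fit_anova(anova_cohort)
        rec = anova_cohort.records[5].truncated(6)
        key = _assign_subgroup(rec, model, __import__("splitimpute").DEFAULT_LAYOUT)
        mu, beta = model.subgroups[key]

        def impute(sections):
            alpha = np.mean(np.log(sections) - mu - beta[: len(sections)])
            return np.exp(mu + alpha + beta[len(sections):]).sum()

        base = impute(np.asarray(rec.section_times))
        scaled = impute(1.1 * np.asarray(rec.section_times))
        assert scaled == pytest.approx(1.1 * base, rel=1e-10)

    def test_imputation_matches_hand_formula(self, anova_cohort):
        from splitimpute.models import _assign_subgroup

        model = fit_anova(anova_cohort)
        rec = anova_cohort.records[7].truncated(7)
        key = _assign_subgroup(rec, model, __import__("splitimpute").DEFAULT_LAYOUT)
        mu, beta = model.subgroups[key]
        alpha = np.mean(np.log(rec.section_times) - mu - beta[:7])
        expected = np.exp(mu + alpha + beta[7:]).sum()
        assert predict_anova(rec, model).remaining_s == pytest.approx(expected, rel=1e-12)

    def test_noiseless_single_subgroup_recovery(self):
        # runners generated from the multiplicative model with identical
        # pacing land in one subgroup; their tails are recovered exactly
        fx = generate_fixture("anova", seed=4, n=50, params={"alpha_sd": 0.0})
        times = np.array([r.section_times for r in fx.cohort])
        mu, beta = fit_two_way_log_anova(times)
        rec = fx.cohort.records[0]
        obs = np.log(rec.section_times[:6])
        alpha = np.mean(obs - mu - beta[:6])
        imputed = np.exp(mu + alpha + beta[6:])
        np.testing.assert_allclose(imputed, rec.section_times[6:], rtol=1e-10)


class TestSvd:
    def test_exact_rank_k_reconstruction(self):
        fx = generate_fixture("lowrank", {"rank": 3}, seed=4, n=200)
        model = fit_svd(fx.cohort, 3)
        X = np.array([r.section_times for r in fx.cohort])
        recon = np.vstack([reconstruct_svd_row(r, model) for r in fx.cohort])
        assert np.linalg.norm(recon - X) / np.linalg.norm(X) < 1e-8

    def test_singular_values_match_gram_eigendecomposition(self, rng):
        times = rng.lognormal(np.log(1800), 0.1, (6, 9))
        recs = [
            RunnerRecord(f"t{i}", 2011, "M", 40, list(times[i])) for i in range(6)
        ]
        model = fit_svd(Cohort(recs), 6)
        eig = np.sort(np.linalg.eigvalsh(times @ times.T))[::-1]
        np.testing.assert_allclose(model.singular_values, np.sqrt(eig[:6]), rtol=1e-10)

    def test_singular_values_non_increasing(self, small_cohort):
        model = fit_svd(small_cohort, 5)
        assert np.all(np.diff(model.singular_values) <= 0)

    def test_invalid_rank_rejected(self, small_cohort):
        for k in (0, 10):
            with pytest.raises(ValueError):
                fit_svd(small_cohort, k)

    def test_completion_exact_for_model_consistent_record(self):
        fx = generate_fixture("lowrank", {"rank": 3}, seed=4, n=200)
        model = fit_svd(fx.cohort, 3)
        for rec in fx.cohort.records[:5]:
            true_remaining = sum(rec.section_times[5:])
            pred = predict_svd(rec.truncated(5), model)
            assert pred.remaining_s == pytest.approx(true_remaining, rel=1e-6)

    def test_minimum_norm_solution_matches_pinv_oracle(self, small_cohort):
        model = fit_svd(small_cohort, 4)
        rec = small_cohort.records[3].truncated(4)
        x = np.asarray(rec.section_times)
        Vd = model.section_vectors * model.singular_values
        A = Vd[:4]
        # explicit min-norm least squares: u = A^T (A A^T)^{-1} x
        u = A.T @ np.linalg.solve(A @ A.T, x)
        expected = float((Vd[4:] @ u).sum())
        assert predict_svd(rec, model).remaining_s == pytest.approx(expected, rel=1e-9)


class TestChooseRank:
    def test_recovers_true_rank(self):
        fx = generate_fixture("lowrank", {"rank": 3}, seed=7, n=300, noise_sd=0.004)
        assert choose_svd_rank(fx.cohort, range(1, 7), seed=1) == 3

    def test_single_candidate_returned(self, small_cohort):
        assert choose_svd_rank(small_cohort, [4], seed=0) == 4

    def test_deterministic_given_seed(self, small_cohort):
        a = choose_svd_rank(small_cohort, range(1, 5), seed=5)
        b = choose_svd_rank(small_cohort, range(1, 5), seed=5)
        assert a == b


class TestModelBundle:
    def test_round_trip(self, tmp_path, small_cohort, anova_cohort):
        bundle = {
            "lm": fit_lm_models(small_cohort),
            "svd": fit_svd(small_cohort, 3),
            "anova": fit_anova(anova_cohort),
        }
        path = tmp_path / "bundle.json"
        save_model_bundle(bundle, path)
        loaded = load_model_bundle(path)
        rec = small_cohort.records[0].truncated(7)
        assert predict_lm(rec, loaded["lm"]).remaining_s == pytest.approx(
            predict_lm(rec, bundle["lm"]).remaining_s
        )
        assert predict_svd(rec, loaded["svd"]).remaining_s == pytest.approx(
            predict_svd(rec, bundle["svd"]).remaining_s
        )
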