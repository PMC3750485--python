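"""Estimator correctness: degenerate identifiability, likelihood oracle,
censoring handling, model comparison and mixture behavior."""

import numpy as np
import pytest

import anakinra_pkpd as ap
from anakinra_pkpd import cohort
from anakinra_pkpd.fit import SaemSettings


@pytest.fixture(scope="module")
def toy_pk_truth():
    return ap.PopPKParams(
        tv_cl=6.24, beta_cl=0.47, tv_v=65.2, beta_v=0.76, ka=0.38,
        omega_cl=0.05, gamma_v=0.05, sigma_add=0.05, loq=0.001,
    )


class TestPKFit:
    def test_noise_free_structural_recovery(self, pk_ref):
        """With no noise and variabilities held at truth, the structural
        parameters are recovered to well under 1%."""
        truth = ap.PopPKParams(
            **{**vars(pk_ref), "omega_cl": 0.0, "gamma_v": 0.0, "sigma_add": 0.0, "loq": 1e-6}
        )
        design = cohort.study_pk_design(n_subjects=40, pk_samples_per_subject=4, seed=51)
        subs = cohort.simulate_pk_dataset(design, truth)
        fit = ap.fit_pk(
            subs,
            ap.default_pk_init(subs),
            SaemSettings(
                seed=61,
                fix={"omega_cl": 0.0, "gamma_v": 0.0, "sigma_add": 0.005},
                compute_se=False, n_burnin=200, n_smooth=80,
            ),
        )
        for name in ("tv_cl", "tv_v", "ka"):
            assert getattr(fit.params, name) == pytest.approx(getattr(truth, name), rel=0.01)
        for name in ("beta_cl", "beta_v"):
            assert getattr(fit.params, name) == pytest.approx(getattr(truth, name), abs=0.01)

    def test_matches_grid_search_likelihood_oracle(self, toy_pk_truth):
        """On a 2-subject toy with everything but clearance fixed, the
        SAEM-maximized likelihood matches a dense grid search within the
        likelihood resolution of the grid."""
        design = cohort.study_pk_design(
            n_subjects=2, pk_samples_per_subject=3, n_occasions=1, occasion_days=(2,), seed=71
        )
        subs = cohort.simulate_pk_dataset(design, toy_pk_truth)
        fix = {k: getattr(toy_pk_truth, k)
               for k in ("tv_v", "beta_cl", "beta_v", "ka", "omega_cl", "gamma_v", "sigma_add")}
        fit = ap.fit_pk(
            subs, toy_pk_truth,
            SaemSettings(seed=81, fix=fix, compute_se=False, n_burnin=300, n_smooth=150),
        )

        def oracle(tv_cl):
            p = ap.PopPKParams(**{**vars(toy_pk_truth), "tv_cl": tv_cl})
            return ap.pk_marginal_loglik(subs, p, n_mc=2000, seed=99)

        grid = np.arange(5.0, 8.01, 0.15)
        lls = np.array([oracle(c) for c in grid])
        i_max = int(np.argmax(lls))
        # LL drop over one grid step near the optimum = the grid's resolution
        tol = max(lls[i_max] - lls[max(i_max - 1, 0)], lls[i_max] - lls[min(i_max + 1, grid.size - 1)])
        assert oracle(fit.params.tv_cl) >= lls[i_max] - max(tol, 1e-3)

    def test_all_censored_flagged_not_raised(self, pk_ref):
        design = cohort.study_pk_design(n_subjects=5, seed=57)
        subs = cohort.simulate_pk_dataset(design, pk_ref)
        for s in subs:
            s.obs_cens[:] = True
            s.obs_lloq[:] = 10.0
            s.obs_values[:] = 10.0
        fit = ap.fit_pk(subs, pk_ref, SaemSettings(seed=3, n_burnin=5, n_smooth=5))
        assert not fit.converged
        assert any("censored" in f for f in fit.flags)

    def test_no_dosing_is_input_error(self, pk_ref):
        design = cohort.study_pk_design(n_subjects=3, seed=59)
        subs = cohort.simulate_pk_dataset(design, pk_ref)
        for s in subs:
            s.dose_times = np.array([])
            s.dose_amounts = np.array([])
        with pytest.raises(ValueError, match="dosing"):
            ap.fit_pk(subs, pk_ref, SaemSettings(seed=3, n_burnin=5, n_smooth=5))

    def test_censoring_consistent_with_uncensored_fit(self, pk_ref):
        """Lightly censored data give estimates close to the same fit with
        censoring ignored (values kept at their simulated magnitudes)."""
        design = cohort.study_pk_design(n_subjects=120, pk_samples_per_subject=3, seed=63)
        subs = cohort.simulate_pk_dataset(design, pk_ref)
        frac = np.mean(np.concatenate([s.obs_cens for s in subs]))
        assert frac <= 0.08
        fit = ap.fit_pk(subs, ap.default_pk_init(subs),
                        SaemSettings(seed=65, compute_se=False))
        assert fit.params.tv_cl == pytest.approx(pk_ref.tv_cl, rel=0.15)
        assert fit.params.sigma_add == pytest.approx(pk_ref.sigma_add, rel=0.35)

    def test_unit_invariance_of_marginal_likelihood(self, toy_pk_truth):
        """Rescaling the time unit with matched rate conversion leaves the
        marginal likelihood unchanged."""
        design = cohort.study_pk_design(n_subjects=4, pk_samples_per_subject=2, seed=67)
        subs = cohort.simulate_pk_dataset(design, toy_pk_truth)
        ll_hours = ap.pk_marginal_loglik(subs, toy_pk_truth, n_mc=500, seed=7)
        scaled = []
        for s in subs:
            import copy

            s2 = copy.deepcopy(s)
            s2.dose_times = s.dose_times * 60.0
            s2.obs_times = s.obs_times * 60.0
            scaled.append(s2)
        params_min = ap.PopPKParams(
            **{
                **vars(toy_pk_truth),
                "tv_cl": toy_pk_truth.tv_cl / 60.0,  # L/min
                "ka": toy_pk_truth.ka / 60.0,        # 1/min
            }
        )
        ll_minutes = ap.pk_marginal_loglik(scaled, params_min, n_mc=500, seed=7)
        assert ll_minutes == pytest.approx(ll_hours, abs=1e-8)

    def test_same_seed_same_fit(self, pk_ref):
        design = cohort.study_pk_design(n_subjects=15, seed=69)
        subs = cohort.simulate_pk_dataset(design, pk_ref)
        s = SaemSettings(seed=42, n_burnin=40, n_smooth=20, compute_se=False)
        a = ap.fit_pk(subs, ap.default_pk_init(subs), s)
        b = ap.fit_pk(subs, ap.default_pk_init(subs), s)
        assert vars(a.params) == vars(b.params)
        assert a.minus2ll == b.minus2ll


class TestModelComparison:
    def test_identical_fits_have_zero_deltas(self, allometric_comparison):
        full, _ = allometric_comparison
        cmp = ap.compare_models(full, full)
        assert cmp.delta_aic == 0.0
        assert cmp.delta_bic == 0.0

    def test_lrt_is_difference_of_minus2ll(self, allometric_comparison):
        full, null = allometric_comparison
        cmp = ap.compare_models(full, null, nested=True)
        assert cmp.lrt_stat == pytest.approx(abs(null.minus2ll - full.minus2ll))
        assert cmp.lrt_df == 2
        assert cmp.lrt_pvalue < 0.001

    def test_allometric_covariate_improves_fit(self, allometric_comparison):
        """Adding the bodyweight covariate to data generated with it drops
        AIC/BIC substantially and shrinks the CL variability."""
        full, null = allometric_comparison
        cmp = ap.compare_models(full, null)
        assert cmp.delta_aic < -15.0
        assert cmp.delta_bic < -15.0
        assert full.params.omega_cl < null.params.omega_cl

    def test_different_datasets_rejected(self, allometric_comparison, pk_ref):
        full, _ = allometric_comparison
        other = cohort.simulate_pk_dataset(cohort.study_pk_design(n_subjects=10, seed=99), pk_ref)
        other_fit = ap.fit_pk(other, pk_ref, SaemSettings(seed=1, n_burnin=10, n_smooth=5,
                                                          compute_se=False))
        with pytest.raises(ValueError, match="different datasets"):
            ap.compare_models(full, other_fit)


class TestPDFit:
    def test_single_class_limit(self, pk_ref, pd_ref):
        """With the responder proportion fixed at 1, the resistance
        parameters drop out and turnover/baseline are recovered."""
        pdp = ap.PopPDParams(**{**vars(pd_ref), "p_resp": 1.0})
        design = cohort.study_pd_design(n_subjects=60, seed=73)
        subs = cohort.simulate_pd_dataset(design, pk_ref, pdp)
        fit = ap.fit_pd(
            subs, pk_ref, ap.default_pd_init(subs),
            SaemSettings(seed=75, fix={"p_resp": 1.0}, compute_se=False),
        )
        assert fit.n_params == 5
        assert fit.params.k_tr == pytest.approx(pd_ref.k_tr, rel=0.2)
        assert fit.params.r0_resp == pytest.approx(pd_ref.r0_resp, rel=0.1)
        assert np.all(fit.posterior_resp.to_numpy() == 1.0)

    def test_classification_accuracy(self, pd_recovery):
        """Posterior-mode class assignment recovers the generating class for
        the large majority of subjects."""
        for subs, fit in pd_recovery[:1]:
            truth = np.array([s.truth["group"] == "RESP" for s in subs])
            assigned = fit.posterior_resp.to_numpy() >= 0.5
            assert (assigned == truth).mean() > 0.8

    def test_mixture_proportion_recovered(self, pd_recovery):
        estimates = [fit.params.p_resp for _, fit in pd_recovery]
        assert abs(float(np.median(estimates)) - 0.37) < 0.10

    def test_degenerate_mixture_warns(self, pk_ref, pd_ref):
        pdp = ap.PopPDParams(**{**vars(pd_ref), "p_resp": 1.0})
        design = cohort.study_pd_design(n_subjects=8, seed=79)
        subs = cohort.simulate_pd_dataset(design, pk_ref, pdp)
        with pytest.warns(UserWarning, match="degenerate mixture"):
            ap.fit_pd(
                subs, pk_ref,
                ap.PopPDParams(**{**vars(pd_ref), "r0_resp": 5000.0}),
                SaemSettings(seed=2, n_burnin=10, n_smooth=5, compute_se=False),
            )

    def test_aic_bic_definitions(self, pd_recovery):
        _, fit = pd_recovery[0]
        assert fit.aic == pytest.approx(fit.minus2ll + 2 * fit.n_params)
        assert fit.bic == pytest.approx(fit.minus2ll + fit.n_params * np.log(fit.n_subjects))
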