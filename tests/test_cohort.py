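"""Generator faithfulness: covariate distributions, noise structure,
censoring rates, mixture fractions and determinism."""

import numpy as np
import pytest

import anakinra_pkpd as ap
from anakinra_pkpd import cohort, io


class TestCovariates:
    def test_range_and_median(self):
        design = cohort.CohortDesign(n_subjects=1000, bw_range=(4.3, 83.0), seed=9)
        table = cohort.draw_covariates(design)
        assert table.bw.between(4.3, 83.0).all()
        # log-uniform reproduces the right-skewed observed median (~21 kg)
        assert 15.0 <= table.bw.median() <= 30.0
        assert table.age.between(*design.age_range).all()

    def test_reproducible_from_seed(self):
        design = cohort.CohortDesign(n_subjects=50, seed=3)
        a = cohort.draw_covariates(design)
        b = cohort.draw_covariates(design)
        assert a.equals(b)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            cohort.CohortDesign(n_subjects=0)
        with pytest.raises(ValueError):
            cohort.CohortDesign(bw_range=(10.0, 5.0))


class TestPKSimulation:
    def test_noise_free_matches_closed_form(self):
        pk = ap.PopPKParams(
            tv_cl=6.24, beta_cl=0.47, tv_v=65.2, beta_v=0.76, ka=0.38,
            omega_cl=0.0, gamma_v=0.0, sigma_add=0.0, loq=0.0001,
        )
        design = cohort.study_pk_design(n_subjects=20, seed=5)
        subs = cohort.simulate_pk_dataset(design, pk)
        for s in subs:
            assert s.obs_values == pytest.approx(np.asarray(s.truth["pred"]), rel=1e-12)
            # with no random effects the truth equals the typical profile
            assert s.truth["cl"] == pytest.approx(pk.cl_at(s.bw))

    def test_blq_fraction_plausible(self, pk_ref):
        design = cohort.study_pk_design(n_subjects=300, seed=13)
        subs = cohort.simulate_pk_dataset(design, pk_ref)
        cens = np.concatenate([s.obs_cens for s in subs])
        frac = cens.mean()
        assert 0.0 <= frac <= 0.10  # the study observed ~3% below LOQ
        censored_values = np.concatenate([s.obs_values[s.obs_cens] for s in subs])
        assert np.all(censored_values == pk_ref.loq)  # DV carries the LOQ

    def test_random_effect_moments(self, pk_ref):
        design = cohort.study_pk_design(n_subjects=5000, pk_samples_per_subject=1, seed=17)
        subs = cohort.simulate_pk_dataset(design, pk_ref)
        eta = np.array([s.truth["eta_cl"] for s in subs])
        assert eta.std() == pytest.approx(0.28, abs=0.02)
        assert eta.mean() == pytest.approx(0.0, abs=0.02)

    def test_dose_capping(self, pk_ref):
        design = cohort.study_pk_design(n_subjects=200, seed=19)
        subs = cohort.simulate_pk_dataset(design, pk_ref)
        for s in subs:
            expected = min(2.0 * s.bw, 100.0)
            assert s.dose_amounts[0] == pytest.approx(expected)

    def test_determinism(self, pk_ref):
        design = cohort.study_pk_design(n_subjects=30, seed=23)
        a = cohort.simulate_pk_dataset(design, pk_ref)
        b = cohort.simulate_pk_dataset(design, pk_ref)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.obs_values, sb.obs_values)
            assert np.array_equal(sa.obs_times, sb.obs_times)
            assert sa.truth == sb.truth


class TestPDSimulation:
    def test_pure_responders(self, pk_ref, pd_ref):
        pdp = ap.PopPDParams(**{**vars(pd_ref), "p_resp": 1.0})
        design = cohort.study_pd_design(n_subjects=40, seed=29)
        subs = cohort.simulate_pd_dataset(design, pk_ref, pdp)
        assert all(s.truth["group"] == "RESP" for s in subs)
        # responder trajectories decline monotonically to a plateau (noise aside)
        noise_free = cohort.study_pd_design(n_subjects=10, seed=29, pd_noise_log10=0.0)
        subs_nf = cohort.simulate_pd_dataset(noise_free, pk_ref, pdp)
        for s in subs_nf:
            assert np.all(np.diff(s.obs_values) <= 1e-9)

    def test_mixture_fraction(self, pk_ref, pd_ref):
        design = cohort.study_pd_design(n_subjects=5000, seed=31)
        subs = cohort.simulate_pd_dataset(design, pk_ref, pd_ref)
        frac = np.mean([s.truth["group"] == "RESP" for s in subs])
        se = np.sqrt(0.37 * 0.63 / 5000)
        assert abs(frac - 0.37) < 2 * se + 1e-12

    def test_noise_free_matches_closed_form_oracle(self, pk_ref):
        # a responder at constant exposure follows the analytic trajectory
        pdp = ap.PopPDParams(
            r0_resp=141.0, r0_resi=37.9, k_tr=0.042, c50=0.03, k_resi=0.0048,
            p_resp=1.0, omega_r0_resi=0.0, omega_ktr=0.0, sigma_pd=0.17,
        )
        pk0 = ap.PopPKParams(**{**vars(pk_ref), "omega_cl": 0.0})
        design = cohort.study_pd_design(n_subjects=5, seed=37, pd_noise_log10=0.0)
        subs = cohort.simulate_pd_dataset(design, pk0, pdp)
        for s in subs:
            oracle = ap.crp_closed_form(s.obs_times, s.truth["css"], pdp, "RESP").values
            assert s.obs_values == pytest.approx(oracle, rel=1e-9)

    def test_css_consistent_with_clearance(self, pk_ref, pd_ref):
        design = cohort.study_pd_design(n_subjects=50, seed=41)
        subs = cohort.simulate_pd_dataset(design, pk_ref, pd_ref)
        for s in subs:
            assert s.truth["css"] == pytest.approx(
                s.daily_dose / (24.0 * s.truth["cl"])
                if "cl" in s.truth
                else s.truth["css"]
            )
            assert s.truth["css"] == pytest.approx(
                ap.css_mean(s.daily_dose, pk_ref.cl_at(s.bw) * np.exp(s.truth["eta_cl"]))
            )


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, pk_ref, pd_ref):
        pk_subs = cohort.simulate_pk_dataset(cohort.study_pk_design(n_subjects=12, seed=43), pk_ref)
        pd_subs = cohort.simulate_pd_dataset(
            cohort.study_pd_design(n_subjects=6, seed=47), pk_ref, pd_ref
        )
        for subs, name in ((pk_subs, "pk.csv"), (pd_subs, "pd.csv")):
            path = tmp_path / name
            io.write_dataset(subs, path)
            back = io.read_dataset(path)
            assert len(back) == len(subs)
            for sa, sb in zip(subs, back):
                assert sa.subject_id == sb.subject_id
                assert sa.bw == pytest.approx(sb.bw)
                assert np.allclose(sa.obs_times, sb.obs_times)
                assert np.allclose(sa.obs_values, sb.obs_values)
                assert np.array_equal(sa.obs_cens, sb.obs_cens)
                assert np.array_equal(sa.obs_occ, sb.obs_occ)
                assert np.allclose(sa.dose_times, sb.dose_times)
                assert np.allclose(sa.dose_amounts, sb.dose_amounts)
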