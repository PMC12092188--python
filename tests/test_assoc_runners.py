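"""Model runners: joint r-XCI, stratified e-XCI, female genotypic s-XCI,
proxy correction, scale conversion and sex comparison."""
import numpy as np
import pytest
from scipy import stats

from xwas import (
    StudySimConfig,
    XCIState,
    apply_proxy_correction,
    compare_sex_effects,
    run_exci,
    run_rxci,
    run_sxci_female,
    simulate_study,
    to_real_scale,
)
from xwas.assoc import DominanceInestimableError

from conftest import make_samples
from oracles import newton_logistic


class TestRunRxci:
    def test_requires_both_sexes(self, small_study):
        males_only = small_study.samples[small_study.samples["sex"] == "male"]
        dose = small_study.dosages.row(0)[small_study.male]
        with pytest.raises(ValueError):
            run_rxci("v0", dose, males_only.reset_index(drop=True))

    def test_male_only_coding_halves_beta(self, small_study):
        # {0,2} coding vs {0,1} coding of the same male data: beta and SE
        # exactly halved, p identical
        male = small_study.male
        dose = small_study.dosages.row(0)[male]
        samples = small_study.samples[male].reset_index(drop=True)
        r = run_rxci("v0", dose, samples, variance_mode="plain", require_both_sexes=False)
        e = run_exci("v0", dose, samples, mode="stratified").male
        assert r.beta == pytest.approx(e.beta / 2, rel=1e-9)
        assert r.se == pytest.approx(e.se / 2, rel=1e-9)
        assert r.p == pytest.approx(e.p, rel=1e-9)

    def test_matches_direct_maximization(self, tiny_fixture):
        dose, male, y = tiny_fixture
        samples = make_samples(y, male)
        r = run_rxci("v0", dose, samples, variance_mode="plain")
        X = np.column_stack([np.ones(40), np.where(male, 2 * dose, dose)])
        b, cov = newton_logistic(X, y)
        assert r.beta == pytest.approx(b[1], abs=1e-6)
        assert r.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-6)

    def test_robust_and_model_se_agree_under_correct_model(self):
        # correctly specified model at n = 20,000: sandwich within 10%
        s = simulate_study(StudySimConfig(n_female=10_000, n_male=10_000, maf=0.3,
                                          real_or=1.2, seed=13))
        dose = s.dosages.row(0)
        robust = run_rxci("v0", dose, s.samples, variance_mode="robust")
        plain = run_rxci("v0", dose, s.samples, variance_mode="plain")
        assert robust.beta == pytest.approx(plain.beta, rel=1e-9)
        assert abs(robust.se / plain.se - 1) < 0.10

    def test_allele_frequencies_on_copies_scale(self, small_study):
        r = run_rxci("v1", small_study.dosages.row(1), small_study.samples)
        male = small_study.male
        d = small_study.dosages.row(1)
        expected = d.sum() / (2 * (~male).sum() + male.sum())
        assert r.eaf_overall == pytest.approx(expected)
        assert r.eaf_male == pytest.approx(d[male].mean())
        assert r.eaf_female == pytest.approx(d[~male].mean() / 2)


class TestRunExci:
    def test_no_males_flags_stratum(self, small_study):
        fem = ~small_study.male
        samples = small_study.samples[fem].reset_index(drop=True)
        res = run_exci("v0", small_study.dosages.row(0)[fem], samples)
        assert res.female is not None
        assert res.male is None
        assert "male_stratum_skipped" in res.flags

    def test_escape_effect_recovery_mean(self):
        # escape-inactivation data analysed on the identity coding recovers
        # the real-scale log odds ratio on average
        betas = []
        for rep in range(60):
            s = simulate_study(
                StudySimConfig(n_female=4000, n_male=4000, maf=0.3, real_or=1.3,
                               xci=XCIState("escape"), seed=9000 + rep)
            )
            r = run_exci("v0", s.dosages.row(0), s.samples, mode="sex_adjusted_combined")
            betas.append(r.beta)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - np.log(1.3)) < 3 * mc_se


class TestRunSxciFemale:
    def test_no_heterozygotes_is_inestimable(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        dose = np.r_[np.full(20, 2.0), np.zeros(20)]
        samples = make_samples(y, np.zeros(40, bool))
        with pytest.raises(DominanceInestimableError):
            run_sxci_female("v0", dose, samples)

    def test_null_dominance_z2_is_chi2_1(self):
        # random inactivation has no dominance: z^2 has mean 1 across reps
        z2 = []
        for rep in range(300):
            s = simulate_study(StudySimConfig(n_female=1500, n_male=50, maf=0.3,
                                              real_or=1.0, seed=4000 + rep))
            r = run_sxci_female("v0", s.dosages.row(0), s.samples)
            z2.append((r.dominance_beta / r.dominance_se) ** 2)
        band = 3 * np.sqrt(2 / len(z2))  # chi2_1 variance is 2
        assert abs(np.mean(z2) - 1.0) < band

    def test_matches_direct_maximization(self):
        rng = np.random.default_rng(17)
        dose = rng.binomial(2, 0.4, 120).astype(float)
        y = rng.binomial(1, 0.3 + 0.1 * (dose == 1), 120).astype(float)
        samples = make_samples(y, np.zeros(120, bool))
        r = run_sxci_female("v0", dose, samples)
        X = np.column_stack([np.ones(120), dose, (dose == 1).astype(float)])
        b, cov = newton_logistic(X, y)
        assert r.beta == pytest.approx(b[1], abs=1e-6)
        assert r.dominance_beta == pytest.approx(b[2], abs=1e-6)
        assert r.dominance_se == pytest.approx(np.sqrt(cov[2, 2]), abs=1e-6)


class TestProxyCorrection:
    def test_doubles_beta_and_se(self, small_study):
        r = run_rxci("v0", small_study.dosages.row(0), small_study.samples)
        c = apply_proxy_correction(r)
        assert c.beta == 2 * r.beta and c.se == 2 * r.se
        assert c.z == pytest.approx(r.z) and c.p == pytest.approx(r.p)
        assert c.proxy_corrected

    def test_zero_effect_preserved(self, small_study):
        r = run_rxci("v0", small_study.dosages.row(0), small_study.samples)
        r0 = r.replace(beta=0.0, se=0.01)
        c = apply_proxy_correction(r0)
        assert c.beta == 0.0 and c.se == 0.02

    def test_double_application_rejected(self, small_study):
        r = run_rxci("v0", small_study.dosages.row(0), small_study.samples)
        with pytest.raises(ValueError):
            apply_proxy_correction(apply_proxy_correction(r))


class TestRealScale:
    def test_null_is_symmetric_about_one(self, small_study):
        r = run_rxci("v0", small_study.dosages.row(0), small_study.samples)
        est = to_real_scale(r.replace(beta=0.0, se=0.05))
        assert est.odds_ratio == 1.0
        assert est.ci_low * est.ci_high == pytest.approx(1.0)

    def test_rxci_doubling(self, small_study):
        r = run_rxci("v0", small_study.dosages.row(0), small_study.samples)
        est = to_real_scale(r.replace(beta=0.1, se=0.05))
        assert est.odds_ratio == pytest.approx(np.exp(0.2), rel=1e-9)
        assert est.ci_low == pytest.approx(np.exp(0.2 - 2 * 1.959964 * 0.05), rel=1e-6)
        assert est.ci_high == pytest.approx(np.exp(0.2 + 2 * 1.959964 * 0.05), rel=1e-6)

    def test_exci_identity(self, small_study):
        res = run_exci("v0", small_study.dosages.row(0), small_study.samples)
        est = to_real_scale(res.female.replace(beta=0.1))
        assert est.odds_ratio == pytest.approx(np.exp(0.1), rel=1e-9)


class TestCompareSexEffects:
    def _pair(self, small_study, bm, sm, bf, sf):
        res = run_exci("v0", small_study.dosages.row(0), small_study.samples)
        return res.male.replace(beta=bm, se=sm), res.female.replace(beta=bf, se=sf)

    def test_identical_effects(self, small_study):
        m, f = self._pair(small_study, 0.2, 0.1, 0.2, 0.1)
        z, p = compare_sex_effects(m, f)
        assert z == 0.0 and p == 1.0

    def test_hand_computed_wald(self, small_study):
        m, f = self._pair(small_study, 0.3, 0.1, 0.0, 0.1)
        z, p = compare_sex_effects(m, f)
        assert z == pytest.approx(0.3 / np.sqrt(0.02), abs=1e-4)
        assert p == pytest.approx(2 * stats.norm.sf(2.1213), abs=1e-4)

    def test_antisymmetry(self, small_study):
        m, f = self._pair(small_study, 0.3, 0.1, 0.1, 0.2)
        z1, p1 = compare_sex_effects(m, f)
        z2, p2 = compare_sex_effects(f.replace(stratum="male"), m.replace(stratum="female"))
        assert z2 == pytest.approx(-z1) and p2 == pytest.approx(p1)

    def test_mismatched_coding_scales_rejected(self, small_study):
        r = run_rxci("v0", small_study.dosages.row(0), small_study.samples)
        e = run_exci("v0", small_study.dosages.row(0), small_study.samples).female
        with pytest.raises(ValueError):
            compare_sex_effects(r, e)
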