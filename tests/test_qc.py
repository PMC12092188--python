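"""QC filter cascade: effective allele count, pre-/post-meta rules,
effective case counts, and the one-drop-per-reason panel."""
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from xwas import (
    AssocResult,
    MetaResult,
    StudyMeta,
    effective_allele_count,
    effective_case_count,
    in_par,
    post_meta_filter,
    pre_meta_filter,
)


def res(vid="v0", beta=0.1, se=0.05, p=None, eaf=0.2, info=0.9):
    if p is None:
        p = float(2 * stats.norm.sf(abs(beta / se))) if np.isfinite(beta) else np.nan
    return AssocResult(variant_id=vid, model="r_xci", stratum="combined",
                       variance_mode="robust", beta=beta, se=se, p=p, n=4000,
                       n_cases=1000, eaf_overall=eaf, info=info)


def meta(vid="v0", coverage=0.9, p_het=0.5, eaf_min=0.2, eaf_max=0.25):
    return MetaResult(variant_id=vid, beta=0.1, se=0.05, z=2.0, p=0.045, k=3,
                      q=1.0, i2=0.0, p_het=p_het, eaf_weighted=(eaf_min + eaf_max) / 2,
                      eaf_min=eaf_min, eaf_max=eaf_max, case_coverage=coverage)


STUDY = StudyMeta("s1", n_cases_female=100, n_cases_male=0,
                  n_controls_female=40, n_controls_male=0)


class TestEffectiveAlleleCount:
    def test_product_of_info_and_min_group_mac(self):
        # cases: 200 copies * 0.1 = 20; controls: 80 * 0.1 = 8; info 0.5 -> 4
        assert effective_allele_count(0.5, 0.1, STUDY) == pytest.approx(4.0)

    def test_full_info_equal_groups(self):
        sm = StudyMeta("s", 50, 20, 50, 20)
        mac = 0.05 * (2 * 50 + 20)
        assert effective_allele_count(1.0, 0.05, sm) == pytest.approx(mac)

    def test_enumeration_oracle(self):
        sm = StudyMeta("s", 100, 50, 200, 100)
        maf = 0.01
        # brute-force expected minor-allele copies per group
        mac_cases = maf * (2 * 100 + 50)
        mac_controls = maf * (2 * 200 + 100)
        expected = 0.7 * min(mac_cases, mac_controls)
        assert effective_allele_count(0.7, maf, sm) == pytest.approx(expected)

    def test_major_allele_folded(self):
        assert effective_allele_count(1.0, 0.9, STUDY) == pytest.approx(
            effective_allele_count(1.0, 0.1, STUDY)
        )


class TestPreMetaFilter:
    def test_missing_statistic(self):
        d = pre_meta_filter(res(beta=np.nan), STUDY)
        assert not d.keep and d.reason == "missing_stat"

    def test_large_effect(self):
        d = pre_meta_filter(res(beta=5.2, se=1.0), STUDY)
        assert d.reason == "beta_magnitude"

    def test_low_info(self):
        d = pre_meta_filter(res(info=0.2), STUDY)
        assert d.reason == "low_info"

    def test_ref_freq_difference(self):
        d = pre_meta_filter(res(eaf=0.9), STUDY, ref_freq=0.3)
        assert d.reason == "ref_freq_diff"

    def test_liftover_flag(self):
        d = pre_meta_filter(res(), STUDY, liftover_failed=True)
        assert d.reason == "liftover_fail"

    @pytest.mark.parametrize(
        "kw,extra",
        [
            (dict(beta=5.0, se=1.0), {}),                      # |beta| = 5 kept
            (dict(info=0.3, eaf=0.3), {}),                     # info = 0.3 kept
            (dict(eaf=0.8), {"ref_freq": 0.3}),                # diff = 0.5 kept
        ],
    )
    def test_boundaries_kept(self, kw, extra):
        assert pre_meta_filter(res(**kw), STUDY, **extra).keep

    def test_eac_boundary_kept(self):
        # EAC exactly at the threshold is kept (strict inequality)
        sm = StudyMeta("s", 100, 0, 40, 0)  # control copies 80
        r = res(eaf=0.125, info=0.5)        # EAC = 0.5 * 0.125 * 80 = 5.0
        assert pre_meta_filter(r, sm).keep

    def test_priority_order(self):
        # violating both the effect-size and info rules reports the first
        d = pre_meta_filter(res(beta=6.0, se=1.0, info=0.1), STUDY)
        assert d.reason == "beta_magnitude"

    def test_clean_variant_kept(self):
        d = pre_meta_filter(res(), STUDY, ref_freq=0.25)
        assert d.keep and d.reason == "ok"


class TestEffectiveCases:
    def test_proxy_divided_by_four(self):
        sm = StudyMeta("ukb", 10_000, 0, 20_000, 0, proxy_female_based=True)
        assert effective_case_count(sm) == 2500.0

    def test_clinical_raw(self):
        sm = StudyMeta("eadb", 3000, 2000, 4000, 3000)
        assert effective_case_count(sm) == 5000.0

    def test_portfolio_additivity(self):
        studies = [
            StudyMeta("a", 1000, 500, 100, 100),
            StudyMeta("b", 4000, 0, 100, 100, proxy_female_based=True),
        ]
        assert sum(effective_case_count(s) for s in studies) == 1500 + 1000


class TestPostMetaFilter:
    def test_low_coverage(self):
        d = post_meta_filter(meta(coverage=0.39))
        assert d.reason == "low_case_coverage"

    def test_extreme_heterogeneity(self):
        d = post_meta_filter(meta(p_het=1e-9))
        assert d.reason == "het_extreme"

    def test_frequency_spread(self):
        d = post_meta_filter(meta(eaf_min=0.05, eaf_max=0.50))
        assert d.reason == "freq_spread"

    def test_boundaries_kept(self):
        assert post_meta_filter(meta(coverage=0.40)).keep
        assert post_meta_filter(meta(p_het=5e-8)).keep
        assert post_meta_filter(meta(eaf_min=0.1, eaf_max=0.5)).keep  # spread 0.4


class TestCascadePanel:
    def test_one_drop_per_reason(self):
        """Crafted panel: each rule fires exactly once; one clean variant."""
        pre_cases = [
            (res("v1", beta=np.nan), {}),
            (res("v2", beta=5.5, se=1.0), {}),
            (res("v3", info=0.1), {}),
            (res("v4", eaf=0.001), {}),                # EAC = 0.9*0.001*80 << 5
            (res("v5"), {"liftover_failed": True}),
            (res("v6", eaf=0.9), {"ref_freq": 0.2}),
            (res("v7"), {"ref_freq": 0.25}),           # clean
        ]
        post_cases = [
            meta("v8", coverage=0.2),
            meta("v9", p_het=1e-12),
            meta("v10", eaf_min=0.01, eaf_max=0.6),
        ]
        decisions = [pre_meta_filter(r, STUDY, **kw) for r, kw in pre_cases]
        decisions += [post_meta_filter(m) for m in post_cases]
        reasons = Counter(d.reason for d in decisions)
        assert reasons == Counter(
            {
                "missing_stat": 1, "beta_magnitude": 1, "low_info": 1, "low_eac": 1,
                "liftover_fail": 1, "ref_freq_diff": 1, "low_case_coverage": 1,
                "het_extreme": 1, "freq_spread": 1, "ok": 1,
            }
        )
        assert sum(d.keep for d in decisions) == 1

    def test_kept_variant_passes_rules_in_isolation(self):
        r = res("v7")
        assert pre_meta_filter(r, STUDY).keep
        assert pre_meta_filter(r, STUDY, ref_freq=r.eaf_overall).keep
        assert pre_meta_filter(r, STUDY, liftover_failed=False).keep


class TestPar:
    @pytest.mark.parametrize("pos,expected", [
        (1_000_000, True),      # PAR1
        (2_781_479, True),      # PAR1 right edge
        (2_781_480, False),
        (100_000_000, False),
        (155_701_383, True),    # PAR2 left edge
        (156_030_895, True),
        (10_000, False),
    ])
    def test_par_boundaries(self, pos, expected):
        assert in_par(pos) is expected
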