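"""Variant filter cascade: per-study (pre-meta) and post-meta rules.

All thresholds follow strict inequalities, so boundary values are kept.
Each decision carries a machine-readable reason code; rules are applied in
a fixed priority order and the first failing rule is reported.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .types import AssocResult, FilterDecision, MetaResult, StudyMeta

__all__ = [
    "PAR1",
    "PAR2",
    "in_par",
    "effective_allele_count",
    "pre_meta_filter",
    "effective_case_count",
    "post_meta_filter",
]

# GRCh38 pseudoautosomal regions, 1-based inclusive
PAR1 = (10_001, 2_781_479)
PAR2 = (155_701_383, 156_030_895)


def in_par(pos: int) -> bool:
    """True if a 1-based chrX position falls in PAR1 or PAR2 (GRCh38).

    Only the non-pseudoautosomal region is analysed; PAR variants are
    excluded at ingest.
    """
    return PAR1[0] <= pos <= PAR1[1] or PAR2[0] <= pos <= PAR2[1]


def effective_allele_count(info: float, eaf: float, study: StudyMeta) -> float:
    """Imputation quality times the expected minor-allele count in the
    smaller of the case and control groups.

    Allele copies are counted on the X: 2 per female, 1 per male.  A NaN
    imputation quality is treated as 1 (hard genotypes).
    """
    if np.isfinite(info) and not (0.0 <= info <= 1.0):
        raise ValueError("info must lie in [0, 1]")
    if not (0.0 <= eaf <= 1.0):
        raise ValueError("eaf must lie in [0, 1]")
    maf = min(eaf, 1.0 - eaf)
    copies_cases = 2 * study.n_cases_female + study.n_cases_male
    copies_controls = 2 * study.n_controls_female + study.n_controls_male
    q = 1.0 if not np.isfinite(info) else info
    return q * min(maf * copies_cases, maf * copies_controls)


def _missing(x: Optional[float]) -> bool:
    return x is None or not np.isfinite(x)


def pre_meta_filter(
    result: AssocResult,
    study: StudyMeta,
    ref_freq: Optional[float] = None,
    liftover_failed: bool = False,
    beta_max: float = 5.0,
    info_min: float = 0.3,
    ref_freq_diff_max: float = 0.5,
) -> FilterDecision:
    """Per-study filter, first failing rule wins:

    1. missing effect, SE, or p-value;
    2. absolute effect size greater than 5 (analysis scale);
    3. imputation quality less than 0.3;
    4. effective allele count below the study threshold (5, or 10 for
       family-based designs with inflated rare-variant counts);
    5. build conversion (liftover) failure, supplied as an input flag;
    6. frequency differing from the reference panel by more than 0.5.

    Boundary values (|beta| = 5, info = 0.3, EAC = threshold, diff = 0.5)
    are kept: every comparison is strict.
    """
    vid = result.variant_id

    def drop(reason):
        return FilterDecision(vid, "pre_meta", False, reason)

    if _missing(result.beta) or _missing(result.se) or _missing(result.p):
        return drop("missing_stat")
    if abs(result.beta) > beta_max:
        return drop("beta_magnitude")
    if np.isfinite(result.info) and result.info < info_min:
        return drop("low_info")
    eac = effective_allele_count(result.info, result.eaf_overall, study)
    if eac < study.eac_threshold:
        return drop("low_eac")
    if liftover_failed:
        return drop("liftover_fail")
    if ref_freq is not None and abs(result.eaf_overall - ref_freq) > ref_freq_diff_max:
        return drop("ref_freq_diff")
    return FilterDecision(vid, "pre_meta", True, "ok")


def effective_case_count(study: StudyMeta) -> float:
    """Effective number of cases a study contributes to the meta-analysis.

    Female-based proxy designs observe the phenotype through parental
    history, which costs roughly a factor four in effective sample size, so
    their female proxy cases enter divided by four; all other case counts
    enter raw.
    """
    if study.proxy_female_based:
        return study.n_cases_female / 4.0 + study.n_cases_male
    return float(study.n_cases_female + study.n_cases_male)


def post_meta_filter(
    meta: MetaResult,
    total_effective_cases: Optional[float] = None,
    case_coverage_min: float = 0.40,
    p_het_min: float = 5e-8,
    freq_spread_max: float = 0.4,
) -> FilterDecision:
    """Post-meta filter, first failing rule wins:

    1. analysed in less than 40% of effective cases;
    2. extreme heterogeneity (p_het < 5e-8);
    3. cross-study frequency spread (max - min) higher than 0.4.

    Boundaries kept (strict comparisons).  ``case_coverage`` is taken from
    the meta result; rules with missing inputs are skipped.
    """
    vid = meta.variant_id

    def drop(reason):
        return FilterDecision(vid, "post_meta", False, reason)

    cov = meta.case_coverage
    if np.isfinite(cov) and cov < case_coverage_min:
        return drop("low_case_coverage")
    if np.isfinite(meta.p_het) and meta.p_het < p_het_min:
        return drop("het_extreme")
    if (
        np.isfinite(meta.eaf_max)
        and np.isfinite(meta.eaf_min)
        and (meta.eaf_max - meta.eaf_min) > freq_spread_max
    ):
        return drop("freq_spread")
    return FilterDecision(vid, "post_meta", True, "ok")
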