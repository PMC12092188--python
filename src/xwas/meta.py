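"""Fixed-effect inverse-variance-weighted meta-analysis across studies.

Pools per-study (optionally per-sex) association results for one variant,
reports Cochran's Q / I-squared heterogeneity and the per-study frequency
envelope, harmonizes effect alleles across studies, and assembles the
2-degree-of-freedom additive + dominance statistic of the skewed-
inactivation analysis.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import AssocResult, MetaResult, TwoDfResult

__all__ = [
    "AlleleHarmonizationError",
    "harmonize_alleles",
    "ivw_meta",
    "combine_exci",
    "sxci_2df",
    "sxci_2df_study_sum",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class AlleleHarmonizationError(ValueError):
    """Effect alleles cannot be reconciled across studies."""

    def __init__(self, variant_id: str, reason: str):
        self.variant_id = variant_id
        self.reason = reason
        super().__init__(f"{variant_id}: {reason}")


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_alleles(results: Sequence[AssocResult]) -> list[AssocResult]:
    """Align every result to the first study's effect allele.

    Swapped effect/other alleles are flipped (beta negated, eaf -> 1 - eaf).
    Palindromic (A/T, C/G) variants with any study eaf in [0.4, 0.6] are
    ambiguous under unknown strand and are rejected; other mismatches are
    rejected outright.  Results without allele labels pass through.
    """
    ref = results[0]
    if ref.effect_allele is None or ref.other_allele is None:
        return list(results)
    ea, oa = ref.effect_allele.upper(), ref.other_allele.upper()
    if _is_palindromic(ea, oa):
        for r in results:
            if np.isfinite(r.eaf_overall) and 0.4 <= r.eaf_overall <= 0.6:
                raise AlleleHarmonizationError(ref.variant_id, "palindromic_ambiguous")
    out = []
    for r in results:
        if r.effect_allele is None:
            out.append(r)
            continue
        rea, roa = r.effect_allele.upper(), r.other_allele.upper()
        if (rea, roa) == (ea, oa):
            out.append(r)
        elif (rea, roa) == (oa, ea):
            out.append(
                r.replace(
                    beta=-r.beta,
                    effect_allele=ea,
                    other_allele=oa,
                    eaf_overall=1 - r.eaf_overall,
                    eaf_male=1 - r.eaf_male,
                    eaf_female=1 - r.eaf_female,
                )
            )
        elif (_COMPLEMENT.get(rea), _COMPLEMENT.get(roa)) in ((ea, oa),):
            out.append(r.replace(effect_allele=ea, other_allele=oa))
        elif (_COMPLEMENT.get(rea), _COMPLEMENT.get(roa)) == (oa, ea):
            out.append(
                r.replace(
                    beta=-r.beta,
                    effect_allele=ea,
                    other_allele=oa,
                    eaf_overall=1 - r.eaf_overall,
                    eaf_male=1 - r.eaf_male,
                    eaf_female=1 - r.eaf_female,
                )
            )
        else:
            raise AlleleHarmonizationError(ref.variant_id, "allele_mismatch")
    return out


def ivw_meta(
    results: Sequence[AssocResult],
    effective_cases: Optional[Sequence[float]] = None,
    total_effective_cases: Optional[float] = None,
) -> MetaResult:
    """Inverse-variance-weighted fixed-effect pool of one variant's results.

    Weights are 1/SE^2; heterogeneity is Cochran's Q against chi-square with
    k - 1 df and I^2 = max(0, (Q - (k - 1)) / Q) * 100.  The effect-allele
    frequency envelope (min/max) and the sample-size-weighted mean frequency
    are carried along for the post-meta filters.  With ``effective_cases``
    (aligned with ``results``) and ``total_effective_cases``, the fraction
    of effective cases covered is recorded.
    """
    if len(results) == 0:
        raise ValueError("no results to pool")
    results = harmonize_alleles(results)
    beta = np.array([r.beta for r in results])
    se = np.array([r.se for r in results])
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("all standard errors must be finite and positive")
    w = 1.0 / se**2
    b = float(np.sum(w * beta) / np.sum(w))
    s = float(1.0 / math.sqrt(np.sum(w)))
    z = b / s
    p = float(2.0 * stats.norm.sf(abs(z)))
    k = len(results)
    q = float(np.sum(w * (beta - b) ** 2))
    p_het = float(stats.chi2.sf(q, k - 1)) if k > 1 else np.nan
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0

    eaf = np.array([r.eaf_overall for r in results], dtype=float)
    n = np.array([r.n for r in results], dtype=float)
    ok = np.isfinite(eaf) & np.isfinite(n)
    eaf_weighted = float(np.sum(eaf[ok] * n[ok]) / np.sum(n[ok])) if ok.any() else np.nan
    eaf_min = float(np.min(eaf[ok])) if ok.any() else np.nan
    eaf_max = float(np.max(eaf[ok])) if ok.any() else np.nan

    coverage = np.nan
    if effective_cases is not None and total_effective_cases:
        coverage = float(np.sum(effective_cases) / total_effective_cases)

    first = results[0]
    return MetaResult(
        variant_id=first.variant_id,
        beta=b,
        se=s,
        z=float(z),
        p=p,
        k=k,
        q=q,
        i2=i2,
        p_het=p_het,
        eaf_weighted=eaf_weighted,
        eaf_min=eaf_min,
        eaf_max=eaf_max,
        case_coverage=coverage,
        model=first.model,
        effect_allele=first.effect_allele,
        other_allele=first.other_allele,
    )


def combine_exci(
    male_results: Sequence[AssocResult],
    female_results: Sequence[AssocResult],
    **kw,
) -> MetaResult:
    """Pool escape-model results across studies *and* sexes in one
    fixed-effect IVW meta-analysis.

    Study/sex selection (e.g. keeping only female results from family
    studies where related males would violate independence) is done by the
    caller through the input lists.
    """
    flat = list(male_results) + list(female_results)
    for r in flat:
        if r.model != "e_xci":
            raise ValueError(f"{r.variant_id}: expected e_xci coding, got {r.model}")
    return ivw_meta(flat, **kw)


def sxci_2df(meta_additive: MetaResult, meta_dominance: MetaResult) -> TwoDfResult:
    """Joint 2-df test for association allowing skewed inactivation.

    Adds the chi-square of the pooled female dominance effect to the
    chi-square of the pooled additive effect; the 2-df survival function
    has the closed form p = exp(-chi2 / 2).
    """
    if meta_dominance is None:
        raise ValueError("dominance pool is required for the 2-df statistic")
    chi2_add = meta_additive.z**2
    chi2_dom = meta_dominance.z**2
    total = chi2_add + chi2_dom
    return TwoDfResult(
        chi2_add=float(chi2_add),
        chi2_dom=float(chi2_dom),
        chi2_total=float(total),
        p=float(np.exp(-total / 2.0)),
    )


def sxci_2df_study_sum(
    additive: Sequence[AssocResult], dominance: Sequence[AssocResult]
) -> TwoDfResult:
    """Alternative 2-df assembly: sum per-study chi-squares instead of
    pooling betas first (kept behind this separate entry point; the pooled
    form is the default and matches the fixed-effect treatment of the
    additive part)."""
    chi2_add = float(sum((r.beta / r.se) ** 2 for r in additive))
    chi2_dom = float(sum((r.beta / r.se) ** 2 for r in dominance))
    k = len(additive) + len(dominance)
    total = chi2_add + chi2_dom
    return TwoDfResult(chi2_add, chi2_dom, total, float(stats.chi2.sf(total, k)))
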