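"""Genomic-control inflation and multiple-testing thresholds.

The inflation factor lambda is the median of the association chi-square
statistics over common, LD-pruned variants divided by the median of the
1-df chi-square distribution.  The X-chromosome-wide significance
threshold scales the conventional one-test-per-million genome-wide level
by R, the number of X tests relative to autosomal tests.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .types import LambdaReport, ThresholdReport

__all__ = [
    "CHI2_1DF_MEDIAN",
    "ld_prune",
    "genomic_lambda",
    "xwide_threshold",
    "bonferroni",
    "format_sig",
]

#: median of the chi-square distribution with 1 df, fixed to 10 digits so
#: lambda is bit-stable across platforms
CHI2_1DF_MEDIAN = 0.4549364231


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    return float(np.corrcoef(xs, ys)[0, 1] ** 2)


def ld_prune(
    dosages: np.ndarray,
    positions: Optional[np.ndarray] = None,
    maf: Optional[np.ndarray] = None,
    r2_threshold: float = 0.2,
    window: int = 500,
) -> list[int]:
    """Greedy LD pruning; returns indices of kept variants.

    Variants are scanned in position order; within a sliding window of
    ``window`` variants, whenever a pair has squared Pearson correlation at
    or above ``r2_threshold`` the lower-MAF variant is dropped (ties keep
    the smaller position).  Zero-variance variants never enter the r^2
    computation and are always kept.
    """
    d = np.asarray(dosages, dtype=float)
    m = d.shape[0]
    if m == 0:
        raise ValueError("at least one variant is required")
    positions = np.arange(m) if positions is None else np.asarray(positions)
    if maf is None:
        freq = np.nanmean(d, axis=1) / 2.0
        maf = np.minimum(freq, 1 - freq)
    order = np.argsort(positions, kind="stable")
    kept: list[int] = []
    for i in order:
        if np.nanstd(d[i]) == 0:
            kept.append(i)
            continue
        conflicts = []
        for j in kept[-window:]:
            if np.nanstd(d[j]) == 0:
                continue
            if _pairwise_r2(d[i], d[j]) >= r2_threshold:
                conflicts.append(j)
        if not conflicts:
            kept.append(i)
            continue
        # keep the higher-MAF member of each conflicting pair; the candidate
        # survives only if it strictly beats every conflict (ties favour the
        # earlier position, i.e. the already-kept variant)
        if all(maf[i] > maf[j] for j in conflicts):
            kept = [j for j in kept if j not in conflicts]
            kept.append(i)
    return sorted(kept, key=lambda j: (positions[j], j))


def genomic_lambda(
    values: np.ndarray,
    maf: Optional[np.ndarray] = None,
    kept: Optional[Sequence[int]] = None,
    maf_floor: float = 0.01,
    kind: str = "p",
    prune_r2: float = 0.2,
) -> LambdaReport:
    """Genomic inflation factor via the median approach.

    ``values`` are two-sided p-values (``kind='p'``) or 1-df chi-square
    statistics (``kind='chi2'``); eligibility is restricted to the LD-pruned
    index set ``kept`` (if given) and to common variants with MAF above
    ``maf_floor`` (if ``maf`` is given).  lambda = median(chi2) / 0.4549364231.
    """
    values = np.asarray(values, dtype=float)
    idx = np.arange(values.size) if kept is None else np.asarray(list(kept), dtype=int)
    mask = np.isfinite(values[idx])
    if maf is not None:
        maf = np.asarray(maf, dtype=float)
        mask &= maf[idx] > maf_floor
    eligible = values[idx][mask]
    if eligible.size == 0:
        raise ValueError("no eligible variants for lambda computation")
    if eligible.size < 10:
        warnings.warn(f"lambda computed from only {eligible.size} variants", stacklevel=2)
    if kind == "p":
        chi2 = stats.chi2.isf(eligible, 1)
    elif kind == "chi2":
        chi2 = eligible
    else:
        raise ValueError(f"unknown kind: {kind!r}")
    lam = float(np.median(chi2) / CHI2_1DF_MEDIAN)
    return LambdaReport(
        lambda_gc=lam,
        n_variants_used=int(eligible.size),
        maf_floor=maf_floor,
        prune_r2=prune_r2,
    )


def format_sig(x: float, sig: int) -> str:
    """Scientific notation rounded to ``sig`` significant figures, with a
    bare exponent (e.g. 1.6e-6)."""
    if x == 0 or not np.isfinite(x):
        return str(x)
    s = f"{x:.{sig - 1}e}"
    mant, exp = s.split("e")
    mant = mant.rstrip("0").rstrip(".") if "." in mant else mant
    return f"{mant}e{int(exp)}"


def xwide_threshold(
    r_fraction: Optional[float] = None,
    n_x_tests: Optional[int] = None,
    n_auto_tests: Optional[int] = None,
) -> ThresholdReport:
    """X-chromosome-wide significance threshold 0.05 / (R * 1e6).

    R is the number of tests on the X relative to the autosomes, given
    directly or derived as ``n_x_tests / n_auto_tests``.  The genome-wide
    5e-8 level corresponds to a Bonferroni correction for one million
    tests; the X-wide level rescales it by R.
    """
    if r_fraction is None:
        if not (n_x_tests and n_auto_tests):
            raise ValueError("provide r_fraction or both test counts")
        r_fraction = n_x_tests / n_auto_tests
    if not (0.0 < r_fraction < 1.0):
        raise ValueError("r_fraction must lie in (0, 1)")
    thr = 0.05 / (r_fraction * 1_000_000)
    return ThresholdReport(
        r_fraction=float(r_fraction),
        threshold=float(thr),
        display=format_sig(thr, 2),
        n_x_tests=n_x_tests,
        n_auto_tests=n_auto_tests,
    )


def bonferroni(m: int, alpha: float = 0.05) -> tuple[float, str]:
    """Bonferroni-corrected per-test level alpha / m, with its
    3-significant-figure display form."""
    if m < 1:
        raise ValueError("m must be >= 1")
    thr = alpha / m
    return float(thr), format_sig(thr, 3)
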