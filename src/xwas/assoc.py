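"""Per-study association testing under X-inactivation-aware genotype codings.

Three codings are supported for a biallelic X variant with dosages on the
copies scale (females 0-2, males 0-1):

* random inactivation (``r_xci``): males are treated as homozygous females,
  i.e. male dosages are doubled to {0, 2} while females stay {0, 1, 2};
  a single logistic model is fitted jointly in both sexes, by default with
  a Huber-White (HC0) sandwich variance because the coded genotypic
  variance differs between sexes;
* escape (``e_xci``): identity coding (males {0, 1}, females {0, 1, 2});
  effects are estimated separately per sex, or jointly with a sex
  adjustment;
* skewed (``s_xci``): the female-only genotypic model adds a dominance
  indicator (1 for heterozygous females) to the additive term, capturing
  non-random inactivation.

Fitted effects live on the *analysis* coding scale; `to_real_scale`
converts to the biologically interpretable scale (males {0, 1}, females
{0, 0.5, 1} under random/skewed inactivation), which doubles the log-odds
for the r/s codings.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import (
    AssocResult,
    FitResult,
    RealScaleEstimate,
    case_vector,
    male_mask,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SeparationError",
    "RankDeficiencyError",
    "NonConvergenceError",
    "DominanceInestimableError",
    "code_genotypes",
    "fit_logistic",
    "run_rxci",
    "run_exci",
    "run_sxci_female",
    "run_quantitative",
    "apply_proxy_correction",
    "to_real_scale",
    "compare_sex_effects",
    "allele_frequencies",
    "rank_inverse_normal",
    "SexStratifiedResults",
]


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class NonConvergenceError(RuntimeError):
    pass


class RankDeficiencyError(ValueError):
    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class DominanceInestimableError(RuntimeError):
    """No heterozygous females: the dominance effect cannot be estimated."""


def code_genotypes(
    dosages: np.ndarray,
    male: np.ndarray,
    model: str,
    het_window: tuple[float, float] = (0.5, 1.5),
    hard_call: bool = False,
):
    """Transform copies-scale dosages into the model's analysis coding.

    ``r_xci`` / ``s_xci``: male dosages doubled, females unchanged.
    ``e_xci``: identity.  ``s_xci`` additionally returns a dominance column,
    1 for females whose dosage falls in ``het_window`` (or rounds to exactly
    one copy when ``hard_call``), 0 otherwise and for all males.
    """
    d = np.asarray(dosages, dtype=float)
    male = np.asarray(male, dtype=bool)
    if model in ("r_xci", "s_xci"):
        coded = np.where(male, 2.0 * d, d)
    elif model == "e_xci":
        coded = d.copy()
    else:
        raise ValueError(f"unknown model: {model!r}")
    if model != "s_xci":
        return coded
    if hard_call:
        het = (~male) & (np.round(d) == 1)
    else:
        lo, hi = het_window
        het = (~male) & (d >= lo) & (d <= hi)
    return coded, het.astype(float)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: Optional[Sequence[str]] = None,
    maxiter: int = 25,
    tol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood logistic fit (IRLS) with model-based and HC0
    sandwich covariances.

    Raises on rank deficiency (naming the collinear columns), separation,
    or non-convergence; no statistics are emitted in those cases.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns from the pivoted QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = diag < 1e-8 * diag.max()
        raise RankDeficiencyError([names[j] for j in np.where(bad)[0]] or names)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=maxiter, tol=tol)
    except Exception as exc:  # statsmodels raises on perfect separation
        if "separation" in str(exc).lower():
            raise SeparationError(str(exc)) from exc
        raise
    mu = np.asarray(res.fittedvalues)
    eta = X @ res.params
    if y.min() == 0 and y.max() == 1:
        if mu[y == 1].min() > mu[y == 0].max() and np.abs(eta).max() > 15:
            raise SeparationError("outcome perfectly separated by the linear predictor")
    if not res.converged:
        raise NonConvergenceError("IRLS did not converge")
    bread = np.asarray(res.cov_params())
    resid2 = (y - mu) ** 2
    meat = (X * resid2[:, None]).T @ X
    cov_robust = bread @ meat @ bread
    n_iter = len(res.fit_history.get("deviance", [])) - 1 if hasattr(res, "fit_history") else -1
    return FitResult(
        params=np.asarray(res.params),
        cov_model=bread,
        cov_robust=cov_robust,
        converged=bool(res.converged),
        n_iter=max(n_iter, 0),
        names=names,
    )


def allele_frequencies(dose: np.ndarray, male: np.ndarray) -> tuple[float, float, float]:
    """(overall, male, female) effect-allele frequencies on the copies scale.

    Allele copies per sample: 2 for females, 1 for males (non-PAR X).
    """
    d = np.asarray(dose, float)
    male = np.asarray(male, bool)
    ok = np.isfinite(d)
    dm, df = d[ok & male], d[ok & ~male]
    copies = 2 * df.size + dm.size
    overall = (df.sum() + dm.sum()) / copies if copies else np.nan
    return (
        float(overall),
        float(dm.mean()) if dm.size else np.nan,
        float(df.mean() / 2) if df.size else np.nan,
    )


def _complete_rows(
    dose: np.ndarray, samples: pd.DataFrame, covariates: Sequence[str]
) -> np.ndarray:
    ok = np.isfinite(np.asarray(dose, float))
    for c in covariates:
        ok &= np.isfinite(samples[c].to_numpy(dtype=float))
    return ok


def _wald(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _fit_binary(
    variant_id: str,
    dose: np.ndarray,
    samples: pd.DataFrame,
    covariates: Sequence[str],
    model: str,
    stratum: str,
    variance_mode: str,
    info: float = np.nan,
    study_id: Optional[str] = None,
    effect_allele: Optional[str] = None,
    other_allele: Optional[str] = None,
) -> AssocResult:
    male = male_mask(samples)
    y = case_vector(samples)
    coding = "e_xci" if model == "e_xci" else ("s_xci" if model == "s_xci_female" else "r_xci")
    if model == "s_xci_female":
        add, dom = code_genotypes(dose, male, "s_xci")
        cols = [add, dom]
        colnames = ["genotype", "dominance"]
        if dom.sum() == 0:
            raise DominanceInestimableError(variant_id)
    else:
        cols = [code_genotypes(dose, male, coding)]
        colnames = ["genotype"]
    for c in covariates:
        cols.append(samples[c].to_numpy(dtype=float))
        colnames.append(c)
    if variance_mode == "sex_adjusted":
        cols.append(male.astype(float))
        colnames.append("sex")
    X = np.column_stack([np.ones(len(y))] + cols)
    fit = fit_logistic(X, y, names=["intercept"] + colnames)
    cov = fit.cov_robust if variance_mode == "robust" else fit.cov_model
    beta = float(fit.params[1])
    se = float(np.sqrt(cov[1, 1]))
    eaf, eaf_m, eaf_f = allele_frequencies(dose, male)
    kw = {}
    if model == "s_xci_female":
        kw = dict(dominance_beta=float(fit.params[2]), dominance_se=float(np.sqrt(cov[2, 2])))
    return AssocResult(
        variant_id=variant_id,
        model=model,  # type: ignore[arg-type]
        stratum=stratum,  # type: ignore[arg-type]
        variance_mode=variance_mode,  # type: ignore[arg-type]
        beta=beta,
        se=se,
        p=_wald(beta, se),
        n=len(y),
        n_cases=int(y.sum()),
        eaf_overall=eaf,
        eaf_male=eaf_m,
        eaf_female=eaf_f,
        info=info,
        study_id=study_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        **kw,
    )


def run_rxci(
    variant_id: str,
    dose: np.ndarray,
    samples: pd.DataFrame,
    covariates: Sequence[str] = (),
    variance_mode: str = "robust",
    info: float = np.nan,
    study_id: Optional[str] = None,
    require_both_sexes: bool = True,
) -> AssocResult:
    """Joint-sex additive logistic model with males coded as homozygous
    females ({0, 2}); robust (sandwich) variance by default, or a sex
    adjustment instead (``variance_mode='sex_adjusted'``), or naive
    model-based variance (``'plain'``, for calibration studies).
    """
    if variance_mode not in ("robust", "sex_adjusted", "plain"):
        raise ValueError(f"unknown variance_mode: {variance_mode!r}")
    ok = _complete_rows(dose, samples, covariates)
    sub = samples.loc[ok]
    male = male_mask(sub)
    if require_both_sexes and (male.all() or (~male).all()):
        raise ValueError("combined-stratum analysis requires both sexes present")
    return _fit_binary(
        variant_id, np.asarray(dose, float)[ok], sub, covariates,
        "r_xci", "combined", variance_mode, info=info, study_id=study_id,
    )


class SexStratifiedResults:
    """Container for per-sex escape-model results; empty strata are None
    with the reason recorded in ``flags``."""

    def __init__(self, female: Optional[AssocResult], male: Optional[AssocResult], flags: list[str]):
        self.female = female
        self.male = male
        self.flags = flags

    def __iter__(self):
        return iter([r for r in (self.female, self.male) if r is not None])


def run_exci(
    variant_id: str,
    dose: np.ndarray,
    samples: pd.DataFrame,
    covariates: Sequence[str] = (),
    mode: str = "stratified",
    info: float = np.nan,
    study_id: Optional[str] = None,
):
    """Escape-inactivation analysis: identity coding (males {0, 1}).

    ``stratified`` fits males and females separately (model-based variance;
    an empty or case/control-degenerate stratum is skipped with a flag);
    ``sex_adjusted_combined`` fits one joint sex-adjusted model.
    """
    ok = _complete_rows(dose, samples, covariates)
    d = np.asarray(dose, float)[ok]
    sub = samples.loc[ok]
    if mode == "sex_adjusted_combined":
        return _fit_binary(variant_id, d, sub, covariates, "e_xci", "combined",
                           "sex_adjusted", info=info, study_id=study_id)
    if mode != "stratified":
        raise ValueError(f"unknown mode: {mode!r}")
    male = male_mask(sub)
    out: dict[str, Optional[AssocResult]] = {}
    flags: list[str] = []
    for label, mask in (("female", ~male), ("male", male)):
        strat = sub.loc[mask]
        y = case_vector(strat) if len(strat) else np.array([])
        if len(strat) == 0 or y.sum() == 0 or y.sum() == len(y):
            out[label] = None
            flags.append(f"{label}_stratum_skipped")
            logger.warning("%s: %s stratum skipped (empty or no case/control contrast)",
                           variant_id, label)
            continue
        out[label] = _fit_binary(variant_id, d[mask], strat, covariates, "e_xci",
                                 label, "plain", info=info, study_id=study_id)
    return SexStratifiedResults(out["female"], out["male"], flags)


def run_sxci_female(
    variant_id: str,
    dose: np.ndarray,
    samples: pd.DataFrame,
    covariates: Sequence[str] = (),
    info: float = np.nan,
    study_id: Optional[str] = None,
    hard_call: bool = False,
) -> AssocResult:
    """Female-only genotypic model: additive term plus a dominance
    indicator equal to 1 in heterozygous females, capturing skewed
    inactivation.  Requires at least one heterozygous female."""
    fem = ~male_mask(samples)
    ok = _complete_rows(dose, samples, covariates) & fem
    sub = samples.loc[ok]
    d = np.asarray(dose, float)[ok]
    if len(sub) == 0:
        raise ValueError("no female samples")
    # hard_call plumbed through by re-deriving the het window
    if hard_call:
        het = np.round(d) == 1
        if het.sum() == 0:
            raise DominanceInestimableError(variant_id)
    return _fit_binary(variant_id, d, sub, covariates, "s_xci_female", "female",
                       "plain", info=info, study_id=study_id)


def rank_inverse_normal(x: np.ndarray, offset: float = 0.375) -> np.ndarray:
    """Blom rank-based inverse-normal transform."""
    x = np.asarray(x, float)
    r = stats.rankdata(x)
    return stats.norm.ppf((r - offset) / (x.size - 2 * offset + 1))


def run_quantitative(
    variant_id: str,
    dose: np.ndarray,
    trait: np.ndarray,
    samples: pd.DataFrame,
    covariates: Sequence[str] = (),
    coding: str = "r_xci",
    maf_floor: Optional[float] = None,
    normalize: bool = True,
    study_id: Optional[str] = None,
) -> Optional[AssocResult]:
    """Linear (quantitative-trait) association of a coded genotype.

    The trait is rank-inverse-normal transformed before fitting (matching
    the treatment of skewed biomarker levels).  Variants below the minor
    allele frequency floor are not fitted and ``None`` is returned: the
    floor is 1%, raised to 5% for batches of fewer than 250 samples, unless
    overridden explicitly.
    """
    if coding not in ("r_xci", "e_xci"):
        raise ValueError(f"unknown coding: {coding!r}")
    trait = np.asarray(trait, float)
    ok = _complete_rows(dose, samples, covariates) & np.isfinite(trait)
    sub = samples.loc[ok]
    d = np.asarray(dose, float)[ok]
    t = trait[ok]
    n = len(sub)
    male = male_mask(sub)
    eaf, eaf_m, eaf_f = allele_frequencies(d, male)
    maf = min(eaf, 1 - eaf)
    floor = maf_floor if maf_floor is not None else (0.01 if n >= 250 else 0.05)
    if maf < floor:
        logger.info("%s filtered: MAF %.4g below floor %.4g (n=%d)", variant_id, maf, floor, n)
        return None
    if normalize:
        t = rank_inverse_normal(t)
    coded = code_genotypes(d, male, coding)
    X = np.column_stack(
        [np.ones(n), coded] + [sub[c].to_numpy(dtype=float) for c in covariates]
    )
    res = sm.OLS(t, X).fit()
    beta, se = float(res.params[1]), float(res.bse[1])
    flags = []
    p = float(res.pvalues[1])
    if res.ssr <= 1e-12 * max(res.centered_tss, 1.0):  # numerically perfect fit
        p = np.nextafter(0.0, 1.0)
        flags.append("perfect_fit")
    return AssocResult(
        variant_id=variant_id,
        model="quantitative",
        stratum="combined",
        variance_mode="plain",
        beta=beta,
        se=se,
        p=p,
        n=n,
        n_cases=0,
        eaf_overall=eaf,
        eaf_male=eaf_m,
        eaf_female=eaf_f,
        study_id=study_id,
        flags=flags,
    )


def apply_proxy_correction(result: AssocResult) -> AssocResult:
    """Double beta and SE of a female-based proxy-phenotype analysis.

    A proxy phenotype observed through one transmitted maternal X dilutes
    the genotype-phenotype association by half, so effect size and standard
    error are both multiplied by 2, leaving z and p unchanged.  Applying
    the correction twice is an error.
    """
    if result.proxy_corrected:
        raise ValueError(f"{result.variant_id}: proxy correction already applied")
    return result.replace(beta=2.0 * result.beta, se=2.0 * result.se, proxy_corrected=True)


def to_real_scale(result: AssocResult, ci: float = 0.95) -> RealScaleEstimate:
    """Odds ratio with confidence interval on the real XCI scale.

    Under the r/s codings (males {0, 2}) one real-scale expressed copy
    corresponds to two coded units, so OR = exp(2 * beta); the escape
    coding is already on the real scale.
    """
    if result.model in ("r_xci", "s_xci_female"):
        f = 2.0
    elif result.model == "e_xci":
        f = 1.0
    else:
        raise ValueError(f"no odds-ratio scale for model {result.model!r}")
    zq = stats.norm.ppf(0.5 + ci / 2)
    lo, hi = f * (result.beta - zq * result.se), f * (result.beta + zq * result.se)
    return RealScaleEstimate(
        odds_ratio=float(np.exp(f * result.beta)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        log_or=f * result.beta,
        log_or_se=f * result.se,
    )


def compare_sex_effects(male: AssocResult, female: AssocResult) -> tuple[float, float]:
    """Wald comparison of male vs female effect sizes on a shared coding
    scale: z = (b_m - b_f) / sqrt(se_m^2 + se_f^2), two-sided normal p."""
    if male.model != female.model:
        raise ValueError(
            f"coding scales differ: {male.model} vs {female.model}; effects not comparable"
        )
    z = (male.beta - female.beta) / np.hypot(male.se, female.se)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
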