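"""Synthetic multi-study X-linked case-control data with known ground truth.

The generator emulates the statistical structure of a sex-aware X-chromosome
association study of a late-onset disease: X-linked genotypes under
Hardy-Weinberg sampling with sex-specific ploidy, phenotypes from a logistic
liability on the biologically *expressed* allele dose (which depends on the
inactivation state of the variant), optional proxy phenotypes derived from
explicitly simulated parents and one meiosis, per-study allele-frequency
drift (Balding-Nichols), and imputation-quality attenuation of dosages.

Everything is a pure function of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import DosageMatrix, XCIState

__all__ = [
    "StudySimConfig",
    "SimTruth",
    "SimulatedStudy",
    "drift_frequency",
    "effective_dose",
    "simulate_study",
    "apply_imputation_noise",
]


@dataclass
class StudySimConfig:
    """Parameters of one simulated study.

    Defaults describe a mid-sized case-control study of a disease with ~27%
    baseline prevalence in the sampled (enriched) cohort, one causal variant
    with no effect (null), random inactivation, no frequency drift and clean
    (info = 1) genotypes.
    """

    n_female: int = 2000
    n_male: int = 2000
    n_variants: int = 1
    maf: Union[float, np.ndarray] = 0.2
    fst: float = 0.0
    causal_index: Optional[int] = 0
    real_or: float = 1.0
    xci: XCIState = field(default_factory=lambda: XCIState("random"))
    baseline_logit: float = -1.0
    sex_effect: float = 0.0          # extra log-odds of disease in males
    covariate_effects: dict[str, float] = field(default_factory=dict)
    proxy_mode: bool = False
    nonad_contamination: float = 0.0  # P(parent labelled demented | unaffected)
    info_target: float = 1.0
    seed: int = 0
    # optional sex-specific allele-frequency overrides (post-drift)
    maf_male: Optional[float] = None
    maf_female: Optional[float] = None
    # nuisance covariates
    n_pcs: int = 2
    pc_shift: float = 0.0
    age_range: tuple[float, float] = (65.0, 90.0)
    apoe_e4_freq: float = 0.15
    apoe_e2_freq: float = 0.08
    study_id: str = "sim"

    def __post_init__(self) -> None:
        if self.n_female <= 0 or self.n_male <= 0 or self.n_variants <= 0:
            raise ValueError("sample and variant counts must be positive")
        maf = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if np.any((maf <= 0) | (maf > 0.5)):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.real_or <= 0:
            raise ValueError("real_or must be positive")
        if not (0.0 < self.info_target <= 1.0):
            raise ValueError("info_target must lie in (0, 1]")
        if self.fst < 0:
            raise ValueError("fst must be >= 0")
        if not (0.0 <= self.nonad_contamination <= 1.0):
            raise ValueError("nonad_contamination must lie in [0, 1]")

    @property
    def maf_vector(self) -> np.ndarray:
        maf = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if maf.size == 1:
            maf = np.full(self.n_variants, maf[0])
        if maf.size != self.n_variants:
            raise ValueError("maf vector length must equal n_variants")
        return maf


@dataclass
class SimTruth:
    """Ground truth of a simulated study."""

    causal_index: Optional[int]
    real_log_or: float
    xci: XCIState
    maf_study: np.ndarray
    info_estimated: np.ndarray


@dataclass
class SimulatedStudy:
    dosages: DosageMatrix          # true genotypes, copies scale
    noisy_dosages: DosageMatrix    # after imputation-noise injection
    samples: pd.DataFrame
    truth: SimTruth
    config: StudySimConfig

    @property
    def male(self) -> np.ndarray:
        return (self.samples["sex"] == "male").to_numpy()


def drift_frequency(
    base_maf: float, fst: float, rng: Union[int, np.random.Generator]
) -> float:
    """Study-specific allele frequency under the Balding-Nichols model.

    Draws from a Beta distribution with mean ``base_maf`` and variance
    ``fst * base_maf * (1 - base_maf)``; ``fst = 0`` is the identity.
    """
    if not (0.0 < base_maf < 1.0):
        raise ValueError("base_maf must lie in (0, 1)")
    if fst < 0:
        raise ValueError("fst must be >= 0")
    if fst == 0:
        return float(base_maf)
    if fst >= 1:
        raise ValueError("fst must be < 1 for a proper Beta distribution")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    scale = (1.0 - fst) / fst  # a + b; gives Var = fst * p * (1 - p)
    return float(rng.beta(base_maf * scale, (1.0 - base_maf) * scale))


def effective_dose(
    genotype: Union[float, np.ndarray],
    male: Union[bool, np.ndarray],
    xci: XCIState,
) -> np.ndarray:
    """Expressed risk-allele dose on the copies scale.

    Males express their single copy: dose = genotype.  Females under
    random/skewed inactivation express one copy, so homozygotes contribute
    genotype / 2 and heterozygotes the probability that the risk copy is
    active (0.5 under random inactivation, ``skew`` under skewed).  Under
    escape both copies are expressed and dose = genotype.  A male carrier
    and a female expressing one active risk copy thus have equal dose.
    """
    g = np.atleast_1d(np.asarray(genotype, dtype=float))
    m = np.broadcast_to(np.atleast_1d(np.asarray(male, dtype=bool)), g.shape)
    if np.any((g[m] < 0) | (g[m] > 1)):
        raise ValueError("male genotypes must lie in {0, 1}")
    if np.any((g[~m] < 0) | (g[~m] > 2)):
        raise ValueError("female genotypes must lie in {0, 1, 2}")
    dose = g.copy()
    if xci.kind != "escape":  # under escape both copies are expressed as-is
        skew = xci.effective_skew
        fem = ~m
        het = fem & np.isclose(g, 1.0)
        hom = fem & ~het
        dose[hom] = g[hom] / 2.0
        dose[het] = skew
    if np.ndim(genotype) == 0:
        return float(dose[0])
    return dose


def _simulate_covariates(cfg: StudySimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    cols["age"] = rng.uniform(*cfg.age_range, size=n)
    for k in range(cfg.n_pcs):
        cols[f"PC{k + 1}"] = rng.standard_normal(n) + cfg.pc_shift
    cols["apoe_e4"] = rng.binomial(2, cfg.apoe_e4_freq, size=n).astype(float)
    cols["apoe_e2"] = rng.binomial(2, cfg.apoe_e2_freq, size=n).astype(float)
    return pd.DataFrame(cols)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _linear_predictor(
    cfg: StudySimConfig,
    causal_geno: np.ndarray,
    male: np.ndarray,
    covs: Optional[pd.DataFrame],
) -> np.ndarray:
    eta = np.full(causal_geno.shape, cfg.baseline_logit)
    eta += cfg.sex_effect * male
    if cfg.causal_index is not None and cfg.real_or != 1.0:
        eta += np.log(cfg.real_or) * effective_dose(causal_geno, male, cfg.xci)
    if covs is not None:
        for name, coef in cfg.covariate_effects.items():
            eta += coef * covs[name].to_numpy()
    return eta


def _draw_genotypes(
    cfg: StudySimConfig, maf_study: np.ndarray, n_f: int, n_m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(variants x females diploid counts, variants x males haploid counts)."""
    maf_f = np.full_like(maf_study, cfg.maf_female) if cfg.maf_female is not None else maf_study
    maf_m = np.full_like(maf_study, cfg.maf_male) if cfg.maf_male is not None else maf_study
    gf = rng.binomial(2, maf_f[:, None], size=(cfg.n_variants, n_f)).astype(float)
    gm = rng.binomial(1, maf_m[:, None], size=(cfg.n_variants, n_m)).astype(float)
    return gf, gm


def simulate_study(config: StudySimConfig) -> SimulatedStudy:
    """Simulate one study: genotypes, covariates, phenotypes, ground truth.

    In ``proxy_mode`` each sample's parents are simulated explicitly (mother
    diploid, father haploid), the child's X genotype is produced by one
    meiosis (sons receive one maternal allele, daughters one maternal plus
    the paternal allele), parental disease statuses follow the same logistic
    model, and the proxy label of a daughter is "at least one parent
    affected" while a son's uses the mother's status only.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_f, n_m = cfg.n_female, cfg.n_male
    n = n_f + n_m
    maf_study = np.array(
        [drift_frequency(m, cfg.fst, rng) for m in cfg.maf_vector], dtype=float
    )

    male = np.r_[np.zeros(n_f, dtype=bool), np.ones(n_m, dtype=bool)]
    covs = _simulate_covariates(cfg, n, rng)
    ci = cfg.causal_index

    if not cfg.proxy_mode:
        gf, gm = _draw_genotypes(cfg, maf_study, n_f, n_m, rng)
        geno = np.hstack([gf, gm])
        causal = geno[ci] if ci is not None else np.zeros(n)
        p = _logistic(_linear_predictor(cfg, causal, male, covs))
        y = rng.random(n) < p
        status = np.where(y, "case", "control")
        extra = {}
    else:
        # parents: mothers diploid, fathers haploid, for every child
        gm_mother = rng.binomial(2, maf_study[:, None], size=(cfg.n_variants, n)).astype(float)
        g_father = rng.binomial(1, maf_study[:, None], size=(cfg.n_variants, n)).astype(float)
        # one meiosis: transmitted maternal allele ~ Bernoulli(g_mother / 2)
        maternal = (rng.random((cfg.n_variants, n)) < gm_mother / 2.0).astype(float)
        geno = np.where(male[None, :], maternal, maternal + g_father)
        c_mother = gm_mother[ci] if ci is not None else np.zeros(n)
        c_father = g_father[ci] if ci is not None else np.zeros(n)
        p_mother = _logistic(_linear_predictor(cfg, c_mother, np.zeros(n, bool), None))
        p_father = _logistic(_linear_predictor(cfg, c_father, np.ones(n, bool), None))
        mother_aff = rng.random(n) < p_mother
        father_aff = rng.random(n) < p_father
        if cfg.nonad_contamination > 0:
            # unaffected parents mislabelled demented for non-disease reasons
            mother_aff |= rng.random(n) < cfg.nonad_contamination
            father_aff |= rng.random(n) < cfg.nonad_contamination
        proxy = np.where(male, mother_aff, mother_aff | father_aff)
        status = np.where(proxy, "proxy_case", "control")
        extra = {
            "mother_status": mother_aff.astype(int),
            "father_status": father_aff.astype(int),
        }

    sample_ids = [f"{cfg.study_id}_s{i}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": np.where(male, "male", "female"),
            "status": status,
            **{c: covs[c].to_numpy() for c in covs.columns},
            **extra,
        }
    )

    dm = DosageMatrix(
        dosages=geno,
        variant_ids=[f"v{i}" for i in range(cfg.n_variants)],
        positions=np.arange(cfg.n_variants) * 10_000 + 3_000_000,
        ref=["A"] * cfg.n_variants,
        alt=["G"] * cfg.n_variants,
        sample_ids=sample_ids,
    )
    noisy, info_est = apply_imputation_noise(dm, male, cfg.info_target, rng)
    truth = SimTruth(
        causal_index=ci,
        real_log_or=float(np.log(cfg.real_or)),
        xci=cfg.xci,
        maf_study=maf_study,
        info_estimated=info_est,
    )
    return SimulatedStudy(dosages=dm, noisy_dosages=noisy, samples=samples, truth=truth, config=cfg)


def apply_imputation_noise(
    dosages: DosageMatrix,
    male: np.ndarray,
    info_target: float,
    rng: Union[int, np.random.Generator],
) -> tuple[DosageMatrix, np.ndarray]:
    """Attenuate dosages to a target imputation quality (r-squared).

    Each variant's standardized dosage z is replaced by
    ``sqrt(info) * z + sqrt(1 - info) * eps`` and rescaled to the original
    mean and variance, then clipped to the sex-valid range (females [0, 2],
    males [0, 1]).  The realized squared correlation with the true dosage is
    re-estimated empirically and returned per variant.  ``info_target = 1``
    returns the input unchanged; zero-variance variants are returned
    unchanged with info recorded as NaN.
    """
    if not (0.0 < info_target <= 1.0):
        raise ValueError("info_target must lie in (0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    male = np.asarray(male, dtype=bool)
    d = dosages.dosages
    out = d.copy()
    info_est = np.full(dosages.n_variants, np.nan)
    if info_target == 1.0:
        info_est[:] = [np.nan if np.nanstd(row) == 0 else 1.0 for row in d]
        return (
            DosageMatrix(out, dosages.variant_ids, dosages.positions, dosages.ref,
                         dosages.alt, dosages.sample_ids, dosages.chrom),
            info_est,
        )
    for i in range(dosages.n_variants):
        row = d[i]
        ok = np.isfinite(row)
        mu, sd = np.nanmean(row), np.nanstd(row)
        if sd == 0:
            continue  # monomorphic: unchanged, info stays NaN
        z = (row[ok] - mu) / sd
        eps = rng.standard_normal(ok.sum())
        hi = np.where(male[ok], 1.0, 2.0)

        def realized(t: float) -> tuple[np.ndarray, float]:
            mix = mu + sd * (np.sqrt(t) * z + np.sqrt(1.0 - t) * eps)
            mix = np.clip(mix, 0.0, hi)
            if np.std(mix) == 0:
                return mix, 0.0
            return mix, float(np.corrcoef(row[ok], mix)[0, 1] ** 2)

        # clipping truncates the noise and inflates the realized r^2, so the
        # mixing weight is calibrated by bisection against the post-clip r^2
        lo_t, hi_t = 1e-6, info_target
        noisy, r2 = realized(info_target)
        for _ in range(20):
            if abs(r2 - info_target) < 2e-3:
                break
            t_mid = 0.5 * (lo_t + hi_t)
            noisy, r2 = realized(t_mid)
            if r2 > info_target:
                hi_t = t_mid
            else:
                lo_t = t_mid
        # quantize to float32: dosages round-trip exactly through VCF DS fields
        out[i, ok] = noisy.astype(np.float32).astype(np.float64)
        if np.std(out[i, ok]) > 0:
            info_est[i] = float(np.corrcoef(row[ok], out[i, ok])[0, 1] ** 2)
    return (
        DosageMatrix(out, dosages.variant_ids, dosages.positions, dosages.ref,
                     dosages.alt, dosages.sample_ids, dosages.chrom),
        info_est,
    )
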