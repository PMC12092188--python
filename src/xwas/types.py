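"""Core data containers shared across the association pipeline.

Dosages are always carried on the *copies* scale (females in [0, 2], males
in [0, 1] on the non-pseudoautosomal X).  Model-specific genotype codings
(e.g. doubling male dosages under the random-inactivation model) are applied
transiently at fit time and never stored.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

ModelName = Literal["r_xci", "e_xci", "s_xci_female", "quantitative"]
Stratum = Literal["combined", "male", "female"]
VarianceMode = Literal["robust", "sex_adjusted", "plain"]

#: phenotype labels counting as "case" in a binary analysis
CASE_STATUSES = frozenset({"case", "proxy_case"})


@dataclass(frozen=True)
class XCIState:
    """X-inactivation state of a variant.

    kind
        ``random``: each female X is silenced with probability one half;
        ``skewed``: the risk-allele copy is active with probability ``skew``
        in heterozygous females; ``escape``: both copies stay expressed.
    """

    kind: Literal["random", "skewed", "escape"]
    skew: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("random", "skewed", "escape"):
            raise ValueError(f"unknown XCI kind: {self.kind!r}")
        if self.kind == "skewed":
            if self.skew is None or not (0.0 <= self.skew <= 1.0):
                raise ValueError("skewed XCI requires skew in [0, 1]")
        elif self.skew is not None:
            raise ValueError("skew is only defined for skewed XCI")

    @property
    def effective_skew(self) -> float:
        """Probability that the risk copy is the active one in a het female."""
        if self.kind == "escape":
            raise ValueError("escape XCI has no skew")
        return 0.5 if self.kind == "random" else float(self.skew)  # type: ignore[arg-type]


@dataclass
class DosageMatrix:
    """Variants x samples dosage matrix on the copies scale.

    Missing genotypes are NaN.  ``positions`` are 1-based GRCh38 coordinates.
    """

    dosages: np.ndarray
    variant_ids: list[str]
    positions: np.ndarray
    ref: list[str]
    alt: list[str]
    sample_ids: list[str]
    chrom: str = "X"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (variants x samples)")
        if self.dosages.shape[0] != len(self.variant_ids):
            raise ValueError("variant_ids length mismatch")
        if self.dosages.shape[1] != len(self.sample_ids):
            raise ValueError("sample_ids length mismatch")

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def row(self, i: int) -> np.ndarray:
        return self.dosages[i]

    def index_of(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)


def male_mask(samples: pd.DataFrame) -> np.ndarray:
    """Boolean mask of male samples from a sample table (``sex`` column)."""
    sex = samples["sex"].to_numpy()
    bad = ~np.isin(sex, ("male", "female"))
    if bad.any():
        raise ValueError(f"unrecognized sex labels: {set(sex[bad])}")
    return sex == "male"


def case_vector(samples: pd.DataFrame) -> np.ndarray:
    """Binary outcome vector: 1 for case / proxy-case, 0 for control."""
    status = samples["status"].to_numpy()
    known = CASE_STATUSES | {"control"}
    bad = ~np.isin(status, sorted(known))
    if bad.any():
        raise ValueError(f"unrecognized status labels: {set(status[bad])}")
    return np.isin(status, sorted(CASE_STATUSES)).astype(float)


@dataclass
class FitResult:
    """Raw regression fit: coefficients plus model-based and robust covariance."""

    params: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    converged: bool
    n_iter: int
    names: list[str] = field(default_factory=list)


@dataclass
class AssocResult:
    """One variant's association statistics on the analysis coding scale."""

    variant_id: str
    model: ModelName
    stratum: Stratum
    variance_mode: VarianceMode
    beta: float
    se: float
    p: float
    n: int
    n_cases: int
    eaf_overall: float
    eaf_male: float = np.nan
    eaf_female: float = np.nan
    info: float = np.nan
    dominance_beta: Optional[float] = None
    dominance_se: Optional[float] = None
    proxy_corrected: bool = False
    study_id: Optional[str] = None
    effect_allele: Optional[str] = None
    other_allele: Optional[str] = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.se) and self.se <= 0:
            raise ValueError("se must be positive")
        if (self.dominance_beta is not None) != (self.model == "s_xci_female"):
            raise ValueError("dominance fields present iff model is s_xci_female")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def replace(self, **kw) -> "AssocResult":
        return replace(self, **kw)


@dataclass
class RealScaleEstimate:
    """Odds ratio and 95% CI on the real XCI scale (males {0,1}, females {0,0.5,1}
    under random/skewed inactivation, {0,1,2} under escape)."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    log_or_se: float


@dataclass
class MetaResult:
    """Inverse-variance-weighted fixed-effect pooled result for one variant."""

    variant_id: str
    beta: float
    se: float
    z: float
    p: float
    k: int
    q: float
    i2: float
    p_het: float
    eaf_weighted: float
    eaf_min: float
    eaf_max: float
    case_coverage: float = np.nan
    model: Optional[str] = None
    effect_allele: Optional[str] = None
    other_allele: Optional[str] = None


@dataclass
class TwoDfResult:
    """Joint additive + dominance chi-square (2 df) for skewed inactivation."""

    chi2_add: float
    chi2_dom: float
    chi2_total: float
    p: float


FilterReason = Literal[
    "missing_stat",
    "beta_magnitude",
    "low_info",
    "low_eac",
    "ref_freq_diff",
    "liftover_fail",
    "low_case_coverage",
    "het_extreme",
    "freq_spread",
    "ok",
]


@dataclass(frozen=True)
class FilterDecision:
    """Per-variant keep/drop verdict with a machine-readable reason code."""

    variant_id: str
    stage: Literal["pre_meta", "post_meta"]
    keep: bool
    reason: FilterReason

    def __post_init__(self) -> None:
        if self.keep != (self.reason == "ok"):
            raise ValueError("keep must be True iff reason is 'ok'")


@dataclass
class StudyMeta:
    """Per-study sample bookkeeping used by the QC filters."""

    study_id: str
    n_cases_female: int
    n_cases_male: int
    n_controls_female: int
    n_controls_male: int
    proxy_female_based: bool = False
    eac_threshold: float = 5.0

    def __post_init__(self) -> None:
        for f in ("n_cases_female", "n_cases_male", "n_controls_female", "n_controls_male"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass
class LambdaReport:
    """Genomic-control inflation factor (median approach)."""

    lambda_gc: float
    n_variants_used: int
    maf_floor: float
    prune_r2: float


@dataclass
class ThresholdReport:
    """X-chromosome-wide significance threshold derived from the relative
    number of X vs autosomal tests."""

    r_fraction: float
    threshold: float
    display: str
    n_x_tests: Optional[int] = None
    n_auto_tests: Optional[int] = None
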