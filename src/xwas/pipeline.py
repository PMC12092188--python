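"""Orchestration: per-study association -> proxy correction -> pre-meta QC ->
IVW meta-analysis (with 2-df assembly for the skewed-inactivation track) ->
post-meta QC -> inflation and significance-threshold reports.

Sensitivity subsets (excluding proxy studies, excluding biobanks, stricter
imputation-quality floor) are realized by roster selection on the same
per-study statistics, without refitting.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import assoc, inflation, meta as meta_mod, qc
from .types import (
    AssocResult,
    DosageMatrix,
    FilterDecision,
    LambdaReport,
    MetaResult,
    StudyMeta,
    ThresholdReport,
    TwoDfResult,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StudyInput", "PipelineResult", "run_pipeline", "study_meta_from_samples"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the main-analysis conventions.

    ``model`` selects the analysis track; every QC threshold is
    overridable; ``info_floor`` supports the stricter imputation-quality
    sensitivity analysis (e.g. 0.8).
    """

    model: str = "r_xci"                 # r_xci | e_xci | s_xci
    variance_mode: str = "robust"        # robust | sex_adjusted (r_xci track)
    covariates: list[str] = field(default_factory=list)
    exclude_proxy: bool = False
    exclude_biobanks: bool = False
    info_floor: Optional[float] = None
    beta_max: float = 5.0
    info_min: float = 0.3
    ref_freq_diff_max: float = 0.5
    case_coverage_min: float = 0.40
    p_het_min: float = 5e-8
    freq_spread_max: float = 0.4
    r_fraction: float = 0.0312
    lambda_maf_floor: float = 0.01
    prune_r2: float = 0.2
    prune_window: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class StudyInput:
    """One study's data plus design metadata for roster selection."""

    study_id: str
    dosages: DosageMatrix
    samples: pd.DataFrame
    study_meta: Optional[StudyMeta] = None
    info: Optional[np.ndarray] = None          # per-variant imputation quality
    is_biobank: bool = False
    family_female_only: bool = False           # related males excluded from e-XCI
    exci_combined: bool = False                # sex-adjusted combined e-XCI fit
    variance_mode: Optional[str] = None        # per-study override (r-XCI track)
    ref_freq: Optional[np.ndarray] = None      # reference-panel frequencies
    liftover_failed: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.study_meta is None:
            self.study_meta = study_meta_from_samples(self.study_id, self.samples)

    @property
    def proxy(self) -> bool:
        return self.study_meta.proxy_female_based

    def variant_info(self, i: int) -> float:
        return float(self.info[i]) if self.info is not None else np.nan


def study_meta_from_samples(study_id: str, samples: pd.DataFrame) -> StudyMeta:
    """Derive QC bookkeeping counts from a sample table."""
    sex = samples["sex"]
    status = samples["status"]
    case = status.isin(("case", "proxy_case"))
    return StudyMeta(
        study_id=study_id,
        n_cases_female=int((case & (sex == "female")).sum()),
        n_cases_male=int((case & (sex == "male")).sum()),
        n_controls_female=int((~case & (sex == "female")).sum()),
        n_controls_male=int((~case & (sex == "male")).sum()),
        proxy_female_based=bool((status == "proxy_case").any()),
    )


@dataclass
class PipelineResult:
    per_study: list[AssocResult]
    meta_results: dict[str, MetaResult]
    two_df: dict[str, TwoDfResult]
    filter_log: list[FilterDecision]
    lambda_report: Optional[LambdaReport]
    threshold_report: ThresholdReport
    config: RunConfig

    def per_study_frame(self, variants: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        from .io import summary_frame

        return summary_frame(self.per_study, variants)

    def meta_frame(self) -> pd.DataFrame:
        rows = []
        dec = {d.variant_id: d for d in self.filter_log if d.stage == "post_meta"}
        for vid, m in self.meta_results.items():
            row = dataclasses.asdict(m)
            d = dec.get(vid)
            row["keep"] = d.keep if d else True
            row["reason"] = d.reason if d else "ok"
            if vid in self.two_df:
                t = self.two_df[vid]
                row["chi2_2df"] = t.chi2_total
                row["p_2df"] = t.p
            rows.append(row)
        return pd.DataFrame(rows)

    def filter_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(d) for d in self.filter_log])


def _roster(studies: Sequence[StudyInput], config: RunConfig) -> list[StudyInput]:
    out = []
    for s in studies:
        if config.exclude_proxy and s.proxy:
            logger.info("sensitivity subset: excluding proxy study %s", s.study_id)
            continue
        if config.exclude_biobanks and s.is_biobank:
            logger.info("sensitivity subset: excluding biobank %s", s.study_id)
            continue
        out.append(s)
    return out


def _study_results_for_variant(
    s: StudyInput, i: int, config: RunConfig
) -> tuple[list[AssocResult], list[AssocResult]]:
    """(additive-track results, dominance results) for one study/variant."""
    vid = s.dosages.variant_ids[i]
    dose = s.dosages.row(i)
    info = s.variant_info(i)
    covs = [c for c in config.covariates if c in s.samples.columns]
    results: list[AssocResult] = []
    dominance: list[AssocResult] = []
    try:
        if config.model in ("r_xci", "s_xci"):
            if s.proxy:
                # sex-stratified proxy analysis; x2 correction on females only
                fem = s.samples[s.samples["sex"] == "female"]
                mal = s.samples[s.samples["sex"] == "male"]
                fmask = (s.samples["sex"] == "female").to_numpy()
                rf = assoc.run_rxci(vid, dose[fmask], fem.reset_index(drop=True), covs,
                                    variance_mode="plain", info=info, study_id=s.study_id,
                                    require_both_sexes=False)
                results.append(assoc.apply_proxy_correction(rf.replace(stratum="female")))
                rm = assoc.run_rxci(vid, dose[~fmask], mal.reset_index(drop=True), covs,
                                    variance_mode="plain", info=info, study_id=s.study_id,
                                    require_both_sexes=False)
                results.append(rm.replace(stratum="male"))
            else:
                vm = s.variance_mode or ("sex_adjusted" if s.is_biobank else config.variance_mode)
                results.append(
                    assoc.run_rxci(vid, dose, s.samples, covs, variance_mode=vm,
                                   info=info, study_id=s.study_id)
                )
            if config.model == "s_xci" and not s.proxy and not s.is_biobank:
                sx = assoc.run_sxci_female(vid, dose, s.samples, covs,
                                           info=info, study_id=s.study_id)
                # carry the dominance estimate as its own poolable result
                dominance.append(
                    sx.replace(model="r_xci", beta=sx.dominance_beta, se=sx.dominance_se,
                               dominance_beta=None, dominance_se=None)
                )
        elif config.model == "e_xci":
            if s.proxy:
                logger.info("proxy study %s excluded from the e-XCI track", s.study_id)
                return [], []
            if s.exci_combined:
                results.append(
                    assoc.run_exci(vid, dose, s.samples, covs, mode="sex_adjusted_combined",
                                   info=info, study_id=s.study_id)
                )
            else:
                strat = assoc.run_exci(vid, dose, s.samples, covs, mode="stratified",
                                       info=info, study_id=s.study_id)
                for r in strat:
                    if s.family_female_only and r.stratum == "male":
                        continue
                    results.append(r)
        else:
            raise ValueError(f"unknown model: {config.model!r}")
    except (assoc.SeparationError, assoc.NonConvergenceError,
            assoc.DominanceInestimableError, assoc.RankDeficiencyError, ValueError) as exc:
        logger.warning("study %s variant %s: %s; skipped", s.study_id, vid, exc)
    return results, dominance


def run_pipeline(config: RunConfig, studies: Sequence[StudyInput]) -> PipelineResult:
    """Execute the full analysis over a study portfolio.

    Deterministic given the inputs and config; per-variant errors are
    logged with study/variant context and the run continues.
    """
    roster = _roster(studies, config)
    if not roster:
        raise ValueError("no studies left after roster selection")
    eff_cases = {s.study_id: qc.effective_case_count(s.study_meta) for s in roster}
    total_eff = sum(eff_cases.values())

    variant_ids = roster[0].dosages.variant_ids
    per_study: list[AssocResult] = []
    metas: dict[str, MetaResult] = {}
    two_df: dict[str, TwoDfResult] = {}
    filter_log: list[FilterDecision] = []

    for i, vid in enumerate(variant_ids):
        pooled: list[AssocResult] = []
        dom_pooled: list[AssocResult] = []
        contributing: list[str] = []
        for s in roster:
            try:
                j = s.dosages.index_of(vid)
            except ValueError:
                continue
            res, dom = _study_results_for_variant(s, j, config)
            per_study.extend(res)
            kept_any = False
            for r in res:
                if config.info_floor is not None and np.isfinite(r.info) and r.info <= config.info_floor:
                    filter_log.append(FilterDecision(vid, "pre_meta", False, "low_info"))
                    continue
                ref = float(s.ref_freq[j]) if s.ref_freq is not None else None
                lift = bool(s.liftover_failed[j]) if s.liftover_failed is not None else False
                d = qc.pre_meta_filter(
                    r, s.study_meta, ref_freq=ref, liftover_failed=lift,
                    beta_max=config.beta_max, info_min=config.info_min,
                    ref_freq_diff_max=config.ref_freq_diff_max,
                )
                filter_log.append(d)
                if d.keep:
                    pooled.append(r)
                    kept_any = True
            if kept_any:
                contributing.append(s.study_id)
                dom_pooled.extend(dom)
        if not pooled:
            logger.warning("variant %s: no study-level results survived pre-meta QC", vid)
            continue
        try:
            m = meta_mod.ivw_meta(
                pooled,
                effective_cases=[eff_cases[sid] for sid in contributing],
                total_effective_cases=total_eff,
            )
        except meta_mod.AlleleHarmonizationError as exc:
            logger.warning("variant %s excluded from meta: %s", vid, exc.reason)
            continue
        metas[vid] = m
        filter_log.append(
            qc.post_meta_filter(
                m,
                case_coverage_min=config.case_coverage_min,
                p_het_min=config.p_het_min,
                freq_spread_max=config.freq_spread_max,
            )
        )
        if config.model == "s_xci" and dom_pooled:
            two_df[vid] = meta_mod.sxci_2df(m, meta_mod.ivw_meta(dom_pooled))

    lam = None
    if metas:
        first = roster[0]
        keep_ids = [v for v in variant_ids if v in metas]
        idx = [first.dosages.index_of(v) for v in keep_ids]
        sub = first.dosages.dosages[idx]
        kept_local = inflation.ld_prune(
            sub, positions=first.dosages.positions[idx],
            r2_threshold=config.prune_r2, window=config.prune_window,
        )
        pvals = np.array([metas[keep_ids[j]].p for j in range(len(keep_ids))])
        mafs = np.array(
            [min(metas[v].eaf_weighted, 1 - metas[v].eaf_weighted) for v in keep_ids]
        )
        try:
            lam = inflation.genomic_lambda(
                pvals, maf=mafs, kept=kept_local,
                maf_floor=config.lambda_maf_floor, prune_r2=config.prune_r2,
            )
        except ValueError as exc:
            logger.warning("lambda not computed: %s", exc)

    thr = inflation.xwide_threshold(r_fraction=config.r_fraction)
    return PipelineResult(
        per_study=per_study,
        meta_results=metas,
        two_df=two_df,
        filter_log=filter_log,
        lambda_report=lam,
        threshold_report=thr,
        config=config,
    )
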