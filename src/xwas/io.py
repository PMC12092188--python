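"""File formats: VCF genotypes, sample tables, summary statistics, truth files.

VCF is read with cyvcf2 and written by a minimal in-package writer (VCF 4.2,
GT:DS per genotype, haploid GT for males, diploid for females).  All tabular
formats are tab-delimited text with fixed, documented column orders.
Coordinates are 1-based inclusive in every user-facing file.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .qc import in_par
from .types import AssocResult, DosageMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "write_vcf",
    "read_genotypes",
    "write_sample_table",
    "read_sample_table",
    "write_truth",
    "SUMMARY_COLUMNS",
    "summary_frame",
    "write_summary_stats",
    "read_summary_stats",
]

#: canonical summary-statistics column order
SUMMARY_COLUMNS = [
    "study_id", "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf_overall", "eaf_male", "eaf_female", "model", "stratum", "beta", "se",
    "p", "log10_p", "n", "n_cases", "info", "proxy_corrected",
]

#: header synonyms accepted on import from external tools
_HEADER_SYNONYMS = {
    "EA": "effect_allele", "NEA": "other_allele",
    "A1": "effect_allele", "A2": "other_allele",
    "BETA": "beta", "SE": "se", "P": "p", "PVAL": "p", "P_VALUE": "p",
    "CHR": "chrom", "BP": "pos", "POS": "pos", "SNP": "variant_id",
    "EAF": "eaf_overall", "N": "n", "INFO": "info", "RSID": "variant_id",
}


# ---------------------------------------------------------------- VCF

def write_vcf(
    dm: DosageMatrix,
    male: np.ndarray,
    path: Union[str, Path],
    hard_genotypes: Optional[np.ndarray] = None,
) -> None:
    """Write a VCF 4.2 with GT:DS fields; males haploid, females diploid.

    GT is taken from ``hard_genotypes`` (integer copies) when given, else
    from rounded dosages; missing dosages become './.' (or '.' haploid).
    """
    male = np.asarray(male, dtype=bool)
    hard = hard_genotypes if hard_genotypes is not None else np.round(dm.dosages)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={dm.chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(dm.sample_ids),
    ]
    for i in range(dm.n_variants):
        fields = [dm.chrom, str(dm.positions[i]), dm.variant_ids[i],
                  dm.ref[i], dm.alt[i], ".", "PASS", ".", "GT:DS"]
        for j in range(dm.n_samples):
            d = dm.dosages[i, j]
            g = hard[i, j]
            if not np.isfinite(d) or not np.isfinite(g):
                fields.append("." if male[j] else "./.")
                continue
            gi = int(round(g))
            if male[j]:
                gt = str(min(max(gi, 0), 1))
            else:
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(gi, 0), 2)]
            ds = np.format_float_positional(np.float32(d), unique=True, trim="0")
            fields.append(f"{gt}:{ds}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes(
    vcf_path: Union[str, Path],
    sample_table_path: Union[str, Path],
) -> tuple[DosageMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a VCF plus sample table into (DosageMatrix, samples, variants).

    Dosages come from the DS field when present, else from GT.  Male
    records may be haploid GT, diploid-homozygous GT, or a dosage in
    [0, 1]; a diploid-coded male dosage in (1, 2] is halved with a logged
    warning, and a heterozygous male hard call is set missing and counted.
    Variants inside the pseudoautosomal regions are excluded with a log
    record; samples with unresolvable sex are dropped with a warning.
    """
    from cyvcf2 import VCF

    samples = read_sample_table(sample_table_path)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    samples = samples.set_index("sample_id").reindex(vcf_samples).reset_index()
    missing_sex = ~samples["sex"].isin(["male", "female"])
    if missing_sex.any():
        logger.warning("dropping %d samples with missing sex", int(missing_sex.sum()))
    keep_idx = np.where(~missing_sex.to_numpy())[0]
    samples = samples.iloc[keep_idx].reset_index(drop=True)
    male = (samples["sex"] == "male").to_numpy()

    rows, vids, positions, refs, alts = [], [], [], [], []
    n_par_excluded = 0
    n_male_het = 0
    n_male_halved = 0
    for v in vcf:
        if in_par(v.POS):
            n_par_excluded += 1
            logger.info("excluding PAR variant %s at %s:%d", v.ID, v.CHROM, v.POS)
            continue
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.array(ds, dtype=np.float32).astype(float).reshape(-1)[keep_idx]
            dose = np.where(dose < 0, np.nan, dose)  # cyvcf2 missing sentinel
        else:
            dose = np.full(len(keep_idx), np.nan)
            for out_j, j in enumerate(keep_idx):
                g = v.genotypes[j]
                alleles = [a for a in g[:-1] if a >= 0]
                if not alleles:
                    continue
                if male[out_j] and len(alleles) == 2 and alleles[0] != alleles[1]:
                    n_male_het += 1  # heterozygous male hard call: missing
                    continue
                if male[out_j]:
                    dose[out_j] = float(alleles[0])
                else:
                    dose[out_j] = float(sum(alleles)) if len(alleles) == 2 else float(alleles[0]) * 2
        high_male = male & (dose > 1)
        if high_male.any():
            n_male_halved += int(high_male.sum())
            dose = np.where(high_male, dose / 2.0, dose)
        rows.append(dose)
        vids.append(v.ID or f"{v.CHROM}:{v.POS}")
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0] if v.ALT else ".")
    if n_par_excluded:
        logger.warning("excluded %d PAR variants", n_par_excluded)
    if n_male_het:
        logger.warning("set %d heterozygous male hard calls to missing", n_male_het)
    if n_male_halved:
        logger.warning("halved %d diploid-coded male dosages", n_male_halved)
    dm = DosageMatrix(
        dosages=np.array(rows) if rows else np.empty((0, len(keep_idx))),
        variant_ids=vids,
        positions=np.array(positions, dtype=np.int64),
        ref=refs,
        alt=alts,
        sample_ids=samples["sample_id"].tolist(),
        chrom="X",
    )
    variants = pd.DataFrame(
        {"variant_id": vids, "chrom": "X", "pos": positions, "ref": refs, "alt": alts}
    )
    return dm, samples, variants


# ---------------------------------------------------------------- tables

def write_sample_table(samples: pd.DataFrame, path: Union[str, Path]) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_truth(study, path: Union[str, Path]) -> None:
    """Tab-delimited ground-truth record of a simulated study."""
    t = study.truth
    rows = []
    for i, vid in enumerate(study.dosages.variant_ids):
        rows.append(
            {
                "variant_id": vid,
                "causal": int(i == t.causal_index),
                "real_log_or": t.real_log_or if i == t.causal_index else 0.0,
                "xci_kind": t.xci.kind,
                "xci_skew": t.xci.skew if t.xci.skew is not None else "",
                "maf_study": t.maf_study[i],
                "info_estimated": t.info_estimated[i],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- summary stats

def _sci(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    return np.format_float_scientific(p, unique=True, min_digits=6)


def summary_frame(
    results: list[AssocResult],
    variants: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Assemble AssocResults into the canonical summary-statistics frame."""
    pos_map = {}
    allele_map = {}
    if variants is not None:
        for _, r in variants.iterrows():
            pos_map[r["variant_id"]] = int(r["pos"])
            allele_map[r["variant_id"]] = (str(r.get("alt", "")), str(r.get("ref", "")))
    rows = []
    for r in results:
        ea, oa = r.effect_allele, r.other_allele
        if ea is None and r.variant_id in allele_map:
            ea, oa = allele_map[r.variant_id]
        with np.errstate(divide="ignore"):
            from scipy import stats as _st
            log10_p = float((_st.norm.logsf(abs(r.beta / r.se)) + np.log(2)) / np.log(10))
        rows.append(
            {
                "study_id": r.study_id or "NA",
                "variant_id": r.variant_id,
                "chrom": "X",
                "pos": pos_map.get(r.variant_id, -1),
                "effect_allele": (ea or "NA").upper(),
                "other_allele": (oa or "NA").upper(),
                "eaf_overall": r.eaf_overall,
                "eaf_male": r.eaf_male,
                "eaf_female": r.eaf_female,
                "model": r.model,
                "stratum": r.stratum,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "log10_p": log10_p,
                "n": r.n,
                "n_cases": r.n_cases,
                "info": r.info,
                "proxy_corrected": int(r.proxy_corrected),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary_stats(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write summary statistics; p in scientific notation with >= 6
    significant digits (shortest round-trip representation)."""
    out = frame.copy()
    out["p"] = [_sci(p) for p in out["p"]]
    out.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={c: _HEADER_SYNONYMS.get(c, c) for c in df.columns})
    for c in ("effect_allele", "other_allele"):
        if c in df.columns:
            df[c] = df[c].astype(str).str.upper()
    return df
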