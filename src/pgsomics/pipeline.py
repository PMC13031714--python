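"""End-to-end study orchestration: per-tissue, per-sex OREML + MOA.

Mirrors the sex-stratified design of the emulated study: each (tissue,
sex) pair is an independent analysis sharing only the per-sex weight
files; tissues enter the two-sex analysis set only when both sexes have
at least ``min_samples_per_sex`` samples (sex-specific tissues are routed
to a single-sex list).  OREML p-values are FDR-adjusted across tissues
within (trait x sex); MOA uses a per-tissue Bonferroni cutoff and a
nominal p < 1e-3 screen for cross-tissue summaries.  Outputs are sorted
deterministically and per-tissue failures are isolated, not fatal.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .association import MoaModel, SignificanceThresholds, summarize_hits
from .relationship import ExpressionMatrix, build_orm
from .scoring import PgsVector, align_alleles, compute_pgs
from .variance import CovariateTable, OremlModel, fdr_adjust

__all__ = [
    "TissueSexDataset",
    "StudyConfig",
    "StudyResult",
    "filter_tissues",
    "run_study",
    "qq_manhattan_tables",
]

logger = logging.getLogger(__name__)


@dataclass
class TissueSexDataset:
    """One (tissue, sex) analysis unit."""

    tissue: str
    sex: str
    expression: ExpressionMatrix
    covariates: CovariateTable
    outcome: PgsVector | None = None

    def __post_init__(self) -> None:
        have = set(self.covariates.table["sample_id"])
        missing = [s for s in self.expression.sample_ids if s not in have]
        if missing:
            raise ValueError(f"{self.tissue}/{self.sex}: samples without "
                             f"covariates: {missing[:5]} ...")

    @property
    def n(self) -> int:
        return self.expression.n_samples


@dataclass
class StudyConfig:
    """Paths and thresholds for a full study run (YAML-loadable)."""

    bundle_dir: str
    out_dir: str
    trait: str = "PGS_T"
    weights: dict = field(default_factory=dict)  # sex -> path
    genotypes: dict = field(default_factory=dict)  # sex -> path
    pgs_dir: str | None = None  # per-tissue-sex score files override scoring
    covariates_path: str | None = None
    min_samples_per_sex: int = 30
    nominal_threshold: float = 1e-3
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nominal_threshold < 1 or not 0 < self.alpha < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        if self.min_samples_per_sex < 2:
            raise ValueError("min_samples_per_sex must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def filter_tissues(datasets: list[TissueSexDataset], min_per_sex: int = 30,
                   ) -> tuple[list[TissueSexDataset], list[TissueSexDataset], list[dict]]:
    """Split datasets into two-sex-eligible and single-sex lists.

    A tissue is retained for the two-sex set only when *both* sexes reach
    ``min_per_sex`` samples (boundary inclusive).  Tissues present in one
    sex only, or where exactly one sex meets the floor, go to the
    single-sex list; tissues where no sex qualifies are dropped.  The log
    records every exclusion.
    """
    by_tissue: dict[str, dict[str, TissueSexDataset]] = {}
    for d in datasets:
        by_tissue.setdefault(d.tissue, {})[d.sex] = d

    retained, single, log = [], [], []
    for tissue in sorted(by_tissue):
        group = by_tissue[tissue]
        ok = {sex: d for sex, d in group.items() if d.n >= min_per_sex}
        for sex, d in sorted(group.items()):
            if sex not in ok:
                log.append({"tissue": tissue, "sex": sex, "n": d.n,
                            "reason": f"fewer than {min_per_sex} samples"})
        if len(ok) == 2:
            retained.extend(ok[s] for s in sorted(ok))
        elif len(ok) == 1:
            ((sex, d),) = ok.items()
            single.append(d)
            if len(group) == 2:
                log.append({"tissue": tissue, "sex": sex, "n": d.n,
                            "reason": "other sex below minimum; routed single-sex"})
    return retained, single, log


def qq_manhattan_tables(moa_frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plotting-ready QQ and Manhattan tables from a MOA result frame.

    QQ: observed ``-log10 p`` against expected quantiles
    ``-log10((rank - 0.5) / m)``.  Manhattan: results in genome order by
    (chrom, pos) with a cumulative x coordinate; empty when the frame has
    no positional annotation.
    """
    if moa_frame.empty:
        raise ValueError("no MOA results")
    df = moa_frame.sort_values(["p", "transcript"]).reset_index(drop=True)
    m = len(df)
    qq = pd.DataFrame({
        "transcript": df["transcript"],
        "p": df["p"],
        "expected_neglog10": -np.log10((np.arange(1, m + 1) - 0.5) / m),
        "observed_neglog10": -np.log10(df["p"].clip(lower=1e-300)),
    })

    if {"chrom", "pos"}.issubset(moa_frame.columns):
        man = moa_frame.dropna(subset=["chrom", "pos"]).copy()
        man["_ck"] = man["chrom"].astype(str).map(
            lambda c: (0, int(c)) if c.isdigit() else (1, 0))
        man = man.sort_values(["_ck", "pos", "transcript"]).reset_index(drop=True)
        offset, offsets = 0, {}
        for ck, sub in man.groupby("_ck", sort=True):
            offsets[ck] = offset
            offset += int(sub["pos"].max()) + 1
        man["genome_pos"] = [offsets[c] + p for c, p in zip(man["_ck"], man["pos"])]
        man["neglog10_p"] = -np.log10(man["p"].clip(lower=1e-300))
        man = man.drop(columns=["_ck"])
    else:
        man = pd.DataFrame()
    return qq, man


@dataclass
class StudyResult:
    """Assembled outputs of :func:`run_study`."""

    oreml_table: pd.DataFrame
    moa_tables: dict  # (tissue, sex) -> DataFrame
    hits_nominal: pd.DataFrame
    hits_bonferroni: pd.DataFrame
    per_transcript_tissues: pd.DataFrame
    qq_tables: dict
    failures: list = field(default_factory=list)
    exclusion_log: list = field(default_factory=list)


def _load_datasets(cfg: StudyConfig, failures: list) -> list[TissueSexDataset]:
    bundle = Path(cfg.bundle_dir)
    covar_path = cfg.covariates_path or bundle / "covariates.tsv"
    covar_all = pio.read_covariates(covar_path)

    score_cache: dict[str, PgsVector] = {}

    def sexwide_scores(sex: str) -> PgsVector:
        if sex not in score_cache:
            wpath = cfg.weights.get(sex, bundle / f"weights_{sex}.tsv")
            gpath = cfg.genotypes.get(sex, bundle / f"genotypes_{sex}.tsv")
            w = pio.read_weights(wpath)
            g = (pio.read_vcf(gpath) if str(gpath).endswith(".vcf")
                 else pio.read_dosage_tsv(gpath))
            aligned, _ = align_alleles(w, g)
            score_cache[sex] = compute_pgs(w, aligned, sex=sex)
        return score_cache[sex]

    datasets = []
    tissue_root = bundle / "tissues"
    for tdir in sorted(p for p in tissue_root.iterdir() if p.is_dir()):
        tissue = tdir.name
        for sex in ("female", "male"):
            epath = tdir / f"expression_{sex}.tsv"
            if not epath.exists():
                continue
            try:
                expr = pio.read_expression(epath)
                if not np.all(np.isfinite(expr.values)):
                    raise ValueError(f"non-numeric or non-finite values in {epath}")
                pgs_dir = Path(cfg.pgs_dir) if cfg.pgs_dir else bundle / "pgs"
                ppath = pgs_dir / f"{tissue}_{sex}.tsv"
                outcome = (pio.read_pgs(ppath) if ppath.exists()
                           else sexwide_scores(sex))
                sub = covar_all.table[covar_all.table["sample_id"]
                                      .isin(expr.sample_ids)]
                datasets.append(TissueSexDataset(
                    tissue=tissue, sex=sex, expression=expr,
                    covariates=CovariateTable(sub.reset_index(drop=True)),
                    outcome=outcome))
            except Exception as exc:  # corrupt unit must not sink the batch
                logger.error("failed to load %s/%s: %s", tissue, sex, exc)
                failures.append({"tissue": tissue, "sex": sex,
                                 "error": str(exc),
                                 "traceback": traceback.format_exc()})
    return datasets


def _analyse_one(d: TissueSexDataset, cfg: StudyConfig):
    orm = build_orm(d.expression)
    null_fit = OremlModel(d.outcome, orm, d.covariates).fit()
    moa = MoaModel(d.outcome, d.expression, orm, d.covariates).fit(
        null_fit=null_fit, tissue=d.tissue, sex=d.sex, trait=cfg.trait)
    oreml_row = {
        "tissue": d.tissue, "sex": d.sex, "trait": cfg.trait,
        "n": null_fit.n, "m": orm.m_used,
        "sigma2_o": null_fit.sigma2_o, "sigma2_e": null_fit.sigma2_e,
        "r2": null_fit.r2, "se_r2": null_fit.se_r2, "p": null_fit.p_value,
        "converged": null_fit.converged, "boundary": null_fit.boundary,
    }
    return oreml_row, moa


def run_study(config: StudyConfig | str) -> StudyResult:
    """Run the full sex-stratified study and write result tables.

    Deterministic given inputs; per-(tissue, sex) failures are caught,
    logged to ``failures.json`` and do not abort the remaining units.
    """
    cfg = StudyConfig.from_yaml(config) if isinstance(config, (str, Path)) else config
    out = Path(cfg.out_dir)
    (out / "moa").mkdir(parents=True, exist_ok=True)
    (out / "qq").mkdir(exist_ok=True)

    failures: list = []
    datasets = _load_datasets(cfg, failures)
    two_sex, single_sex, excl_log = filter_tissues(datasets, cfg.min_samples_per_sex)

    oreml_rows, moa_results, moa_tables, qq_tables = [], [], {}, {}
    for d in two_sex + single_sex:
        try:
            row, moa = _analyse_one(d, cfg)
        except Exception as exc:
            logger.error("analysis failed for %s/%s: %s", d.tissue, d.sex, exc)
            failures.append({"tissue": d.tissue, "sex": d.sex, "error": str(exc),
                             "traceback": traceback.format_exc()})
            continue
        oreml_rows.append(row)
        frame = (moa.frame.sort_values(["p", "transcript"])
                 .reset_index(drop=True))
        moa_results.append(moa)
        moa_tables[(d.tissue, d.sex)] = frame
        qq, man = qq_manhattan_tables(frame)
        qq_tables[(d.tissue, d.sex)] = qq
        logger.info("%s/%s: n=%d m=%d r2=%.3f converged=%s",
                    d.tissue, d.sex, row["n"], row["m"], row["r2"],
                    row["converged"])

    oreml = pd.DataFrame(oreml_rows)
    if not oreml.empty:
        # FDR across tissues within (trait x sex), the study's convention
        oreml["fdr"] = np.nan
        for (_, _), idx in oreml.groupby(["trait", "sex"]).groups.items():
            oreml.loc[idx, "fdr"] = fdr_adjust(oreml.loc[idx, "p"].to_numpy())
        oreml = oreml.sort_values(["tissue", "sex"]).reset_index(drop=True)

    if moa_results:
        summary = summarize_hits(moa_results)
        hits_nominal = summary.per_tissue_nominal
        hits_bonf = summary.bonferroni_hits
        per_transcript = summary.per_transcript_tissues
    else:
        hits_nominal = hits_bonf = per_transcript = pd.DataFrame()

    # -- write deterministic outputs ------------------------------------
    ff = "%.10g"
    oreml.to_csv(out / "oreml_summary.tsv", sep="\t", index=False, float_format=ff)
    for (tissue, sex), frame in sorted(moa_tables.items()):
        frame.to_csv(out / "moa" / f"{tissue}_{sex}.tsv", sep="\t",
                     index=False, float_format=ff)
        qq_tables[(tissue, sex)].to_csv(out / "qq" / f"{tissue}_{sex}.tsv",
                                        sep="\t", index=False, float_format=ff)
    hits_nominal.to_csv(out / "hits_nominal.tsv", sep="\t", index=False,
                        float_format=ff)
    hits_bonf.to_csv(out / "hits_bonferroni.tsv", sep="\t", index=False,
                     float_format=ff)
    per_transcript.to_csv(out / "hits_per_transcript.tsv", sep="\t",
                          index=False, float_format=ff)
    (out / "failures.json").write_text(json.dumps(failures, indent=1) + "\n")
    (out / "exclusions.json").write_text(json.dumps(excl_log, indent=1) + "\n")

    return StudyResult(oreml_table=oreml, moa_tables=moa_tables,
                       hits_nominal=hits_nominal, hits_bonferroni=hits_bonf,
                       per_transcript_tissues=per_transcript,
                       qq_tables=qq_tables, failures=failures,
                       exclusion_log=excl_log)
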