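"""Readers and writers for the plain-text formats used by the pipeline.

Formats: weights TSV (PLINK/SBayesR-like), a samples-x-SNPs dosage TSV
dialect with a ``.variants.tsv`` sidecar for allele metadata, VCF with DS
(or GT) via cyvcf2, expression TSV with an ``.annot.tsv`` sidecar,
covariate and score TSVs, dense ORM TSV, and a ground-truth JSON.
All writers use a fixed float format so outputs are byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .relationship import ExpressionMatrix, OmicsRelationshipMatrix
from .scoring import GenotypeDosageMatrix, PgsVector, VariantWeightSet
from .variance import CovariateTable

__all__ = [
    "read_weights", "write_weights",
    "read_dosage_tsv", "write_dosage_tsv",
    "read_vcf", "write_vcf",
    "read_expression", "write_expression",
    "read_covariates", "write_covariates",
    "read_pgs", "write_pgs",
    "read_orm", "write_orm",
    "read_truth", "write_truth",
    "write_study_bundle",
]

_FLOAT = "%.10g"


def read_weights(path) -> VariantWeightSet:
    """Weights TSV; SBayesR-style headers (Name/A1/A2/A1Effect) accepted."""
    return VariantWeightSet.from_dataframe(pd.read_csv(path, sep="\t"))


def write_weights(weights: VariantWeightSet, path) -> None:
    weights.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def _variants_sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix("").with_suffix(".variants.tsv") if p.suffix else p


def write_dosage_tsv(gm: GenotypeDosageMatrix, path, variants_path=None) -> None:
    """Dosage dialect: sample_id + one column per SNP (NA = missing),
    plus a variants sidecar carrying snp_id/chrom/pos/a1/a2."""
    path = Path(path)
    if variants_path is None:
        variants_path = _variants_sidecar(path)
    df = pd.DataFrame(gm.dosages, columns=gm.variants["snp_id"])
    df.insert(0, "sample_id", gm.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT, na_rep="NA")
    gm.variants.to_csv(variants_path, sep="\t", index=False)


def read_dosage_tsv(path, variants_path=None) -> GenotypeDosageMatrix:
    path = Path(path)
    if variants_path is None:
        variants_path = _variants_sidecar(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    variants = pd.read_csv(Path(variants_path), sep="\t",
                           dtype={"chrom": str, "a1": str, "a2": str})
    sample_ids = df["sample_id"].astype(str).tolist()
    snp_cols = [c for c in df.columns if c != "sample_id"]
    if list(variants["snp_id"]) != snp_cols:
        variants = variants.set_index("snp_id").loc[snp_cols].reset_index()
    return GenotypeDosageMatrix(sample_ids, variants,
                                df[snp_cols].to_numpy(dtype=float))


def write_vcf(gm: GenotypeDosageMatrix, path) -> None:
    """Minimal uncompressed VCF with a DS FORMAT field (missing = '.')."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Dosage of the ALT (coded) allele">\n')
        for c in sorted({str(c) for c in gm.variants["chrom"]},
                        key=lambda s: (len(s), s)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, row in gm.variants.iterrows():
            # a1 is the coded (dosage-counted) allele -> ALT by convention
            vals = ["." if np.isnan(d) else (_FLOAT % d)
                    for d in gm.dosages[:, j]]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                     f"{row['a2']}\t{row['a1']}\t.\t.\t.\tDS\t" + "\t".join(vals) + "\n")


def read_vcf(path) -> GenotypeDosageMatrix:
    """Read dosages from VCF: DS where present, else the GT allele count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    meta, cols = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        meta.append({"snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                     "chrom": str(var.CHROM), "pos": int(var.POS),
                     "a1": alt, "a2": var.REF})
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where(col < 0, np.nan, col)
        else:
            gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
            col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        cols.append(col)
    vcf.close()
    if not cols:
        raise ValueError(f"no variants in {path}")
    return GenotypeDosageMatrix(sample_ids, pd.DataFrame(meta),
                                np.column_stack(cols))


def _annot_sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(".annot.tsv") if p.suffix else p


def write_expression(expr: ExpressionMatrix, path, annot_path=None) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format=_FLOAT)
    if expr.annotation is not None:
        if annot_path is None:
            annot_path = _annot_sidecar(path)
        expr.annotation.to_csv(annot_path, sep="\t", index=False)


def read_expression(path, annot_path=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if annot_path is None:
        cand = _annot_sidecar(path)
        annot_path = cand if cand.exists() else None
    ann = (pd.read_csv(annot_path, sep="\t", dtype={"chrom": str})
           if annot_path else None)
    return ExpressionMatrix.from_frame(df, annotation=ann)


def write_covariates(covar: CovariateTable, path) -> None:
    covar.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_covariates(path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_pgs(pgs: PgsVector, path) -> None:
    pgs.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_pgs(path) -> PgsVector:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    sex = None
    if "sex" in df.columns:
        vals = df["sex"].dropna().astype(str).unique()
        sex = vals[0] if len(vals) == 1 and vals[0] else None
    n_used = (df["n_used"].to_numpy(dtype=int) if "n_used" in df.columns
              else np.ones(len(df), dtype=int))
    return PgsVector(df["sample_id"].tolist(), df["score"].to_numpy(dtype=float),
                     n_used, sex=sex)


def write_orm(orm: OmicsRelationshipMatrix, path, exclusions_path=None) -> None:
    df = pd.DataFrame(orm.values, index=pd.Index(orm.sample_ids, name="sample_id"),
                      columns=orm.sample_ids)
    with open(path, "w") as fh:
        fh.write(f"# m_used={orm.m_used}\n")
        df.to_csv(fh, sep="\t", float_format="%.12g")
    if exclusions_path is not None:
        Path(exclusions_path).write_text("\n".join(orm.excluded_ids) + "\n"
                                         if orm.excluded_ids else "")


def read_orm(path) -> OmicsRelationshipMatrix:
    with open(path) as fh:
        first = fh.readline()
        m_used = 0
        if first.startswith("#"):
            m_used = int(first.strip().split("m_used=")[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    vals = df.to_numpy(dtype=float)
    return OmicsRelationshipMatrix(list(df.index), (vals + vals.T) / 2.0,
                                   m_used or vals.shape[0])


def write_truth(truth_map: dict, path) -> None:
    """truth_map: {(tissue, sex) or str: SyntheticTruth-like}."""
    out = {}
    for key, tr in truth_map.items():
        name = key if isinstance(key, str) else "/".join(key)
        out[name] = tr.to_dict() if hasattr(tr, "to_dict") else tr
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True) + "\n")


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_study_bundle(bundle, out_dir) -> Path:
    """Write a StudyBundle as the on-disk layout run_study consumes.

    out_dir/
      weights_<sex>.tsv            genotypes_<sex>.tsv (+ .variants.tsv)
      covariates.tsv               truth.json
      tissues/<tissue>/expression_<sex>.tsv (+ .annot.tsv)
      pgs/<tissue>_<sex>.tsv       (the proxy outcome per tissue-sex)
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sex, w in bundle.weights.items():
        write_weights(w, out / f"weights_{sex}.tsv")
    for sex, g in bundle.genotypes.items():
        write_dosage_tsv(g, out / f"genotypes_{sex}.tsv")
    allc = pd.concat([c.table for c in bundle.covariates.values()],
                     ignore_index=True)
    write_covariates(CovariateTable(allc), out / "covariates.tsv")

    (out / "pgs").mkdir(exist_ok=True)
    truth_map = {}
    for (tissue, sex), parts in sorted(bundle.tissues.items()):
        tdir = out / "tissues" / tissue
        tdir.mkdir(parents=True, exist_ok=True)
        write_expression(parts["expression"], tdir / f"expression_{sex}.tsv",
                         tdir / f"expression_{sex}.annot.tsv")
        write_pgs(parts["outcome"], out / "pgs" / f"{tissue}_{sex}.tsv")
        truth_map[(tissue, sex)] = parts["truth"]
    write_truth(truth_map, out / "truth.json")
    return out
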