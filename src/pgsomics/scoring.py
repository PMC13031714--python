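"""Polygenic score (PGS) computation from SNP weights and genotype dosages.

A polygenic score summarizes an individual's genetic liability for a trait
as a weighted sum of allele dosages,

    PGS_j = sum_i S_i * G_ij / (2 * M_j),

where ``S_i`` is the per-effect-allele weight of SNP ``i``, ``G_ij`` the
dosage of the effect allele carried by sample ``j`` (0..2), and ``M_j`` the
number of SNPs with a non-missing dosage in sample ``j``.  The divisor
``2*M_j`` gives the average score per non-missing allele, the convention of
PLINK ``--score``; a plain weighted sum is available via ``average=False``.

Because weights and genotypes typically come from different cohorts, the
genotype file's coded allele need not be the weight file's effect allele.
:func:`align_alleles` re-codes dosages onto the effect allele (``g -> 2-g``
when the coding is swapped), drops strand-ambiguous palindromic variants
(A/T, C/G) whose orientation cannot be verified from the files alone, and
drops variants whose allele pairs disagree outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantWeightSet",
    "GenotypeDosageMatrix",
    "PgsVector",
    "AlignmentReport",
    "CorrelationSummary",
    "align_alleles",
    "compute_pgs",
    "correlate_scores",
    "fisher_ci",
]

WEIGHT_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "weight"]

#: palindromic allele pairs whose strand cannot be resolved between cohorts
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass
class VariantWeightSet:
    """Per-SNP effect-allele weights (the ``S_i`` of the score formula).

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``snp_id, chrom, pos, effect_allele, other_allele, weight``.
        ``snp_id`` must be unique, alleles distinct, weights finite.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in WEIGHT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"weight table missing columns: {missing}")
        t = self.table.reset_index(drop=True)
        if t["snp_id"].duplicated().any():
            dups = t.loc[t["snp_id"].duplicated(), "snp_id"].tolist()[:5]
            raise ValueError(f"duplicate snp_id in weight table: {dups} ...")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise ValueError("effect_allele must differ from other_allele")
        if not np.all(np.isfinite(t["weight"].to_numpy(dtype=float))):
            raise ValueError("weights must be finite")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.table["snp_id"])

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "VariantWeightSet":
        """Build from a data frame, accepting SBayesR-style column names
        (``Name/Chrom/Position/A1/A2/A1Effect``) as synonyms."""
        synonyms = {
            "Name": "snp_id", "Chrom": "chrom", "Position": "pos",
            "A1": "effect_allele", "A2": "other_allele", "A1Effect": "weight",
        }
        df = df.rename(columns={k: v for k, v in synonyms.items() if k in df.columns})
        df = df[WEIGHT_COLUMNS].copy()
        df["chrom"] = df["chrom"].astype(str)
        return cls(df)


@dataclass
class GenotypeDosageMatrix:
    """Samples x variants allele-dosage matrix with missingness.

    ``dosages`` holds the dosage of the *coded* allele (``variants['a1']``)
    per sample, in ``[0, 2]``; missing entries are NaN.
    """

    sample_ids: list[str]
    variants: pd.DataFrame  # columns: snp_id, chrom, pos, a1 (coded), a2
    dosages: np.ndarray  # shape (n_samples, n_variants), float, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n != len(self.sample_ids) or p != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages must lie in [0, 2] where present")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class AlignmentReport:
    """Bookkeeping from :func:`align_alleles`."""

    n_weights: int = 0
    n_genotyped: int = 0
    n_matched: int = 0
    n_flipped: int = 0
    ambiguous: int = 0
    mismatched: int = 0
    n_retained: int = 0
    dropped_ids: list = field(default_factory=list)


@dataclass
class PgsVector:
    """Per-sample polygenic scores with the non-missing SNP count used."""

    sample_ids: list[str]
    score: np.ndarray
    n_used: np.ndarray
    sex: str | None = None
    trait: str | None = None

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        self.n_used = np.asarray(self.n_used, dtype=int)
        if len(self.sample_ids) != self.score.size or self.score.size != self.n_used.size:
            raise ValueError("sample_ids, score and n_used must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "score": self.score, "n_used": self.n_used,
             "sex": self.sex if self.sex is not None else ""}
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.score, index=pd.Index(self.sample_ids, name="sample_id"),
                         name="score")


@dataclass
class CorrelationSummary:
    """Pearson correlation with a Fisher-z confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"r = {self.r:.2f}, 95% CI [{self.ci_low:.2f}, {self.ci_high:.2f}], "
                f"p = {self.p_value:.3g}, n = {self.n}")


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in _AMBIGUOUS_PAIRS


def align_alleles(
    weights: VariantWeightSet, genotypes: GenotypeDosageMatrix
) -> tuple[GenotypeDosageMatrix, AlignmentReport]:
    """Re-code genotype dosages onto the weight file's effect allele.

    For each variant present in both inputs: if the genotype coded allele
    equals the effect allele the dosage is kept; if it equals the other
    allele the dosage is flipped ``g -> 2 - g``; strand-ambiguous (A/T, C/G)
    weight variants and allele-pair mismatches are dropped and counted.

    Returns the re-coded matrix restricted to retained variants (in weight
    order) together with an :class:`AlignmentReport`.

    Raises
    ------
    ValueError
        If no variant survives the intersection and filtering.
    """
    report = AlignmentReport(n_weights=len(weights), n_genotyped=genotypes.n_variants)

    gvar = genotypes.variants.set_index("snp_id")
    wt = weights.table
    keep_cols = []
    new_meta = []
    for _, row in wt.iterrows():
        sid = row["snp_id"]
        if sid not in gvar.index:
            continue
        report.n_matched += 1
        ea, oa = row["effect_allele"], row["other_allele"]
        if _is_ambiguous(ea, oa):
            report.ambiguous += 1
            report.dropped_ids.append(sid)
            continue
        g = gvar.loc[sid]
        if g["a1"] == ea and g["a2"] == oa:
            flip = False
        elif g["a1"] == oa and g["a2"] == ea:
            flip = True
        else:
            report.mismatched += 1
            report.dropped_ids.append(sid)
            continue
        j = gvar.index.get_loc(sid)
        keep_cols.append((j, flip))
        new_meta.append(
            {"snp_id": sid, "chrom": row["chrom"], "pos": row["pos"], "a1": ea, "a2": oa}
        )

    if not keep_cols:
        raise ValueError("no variants shared between weights and genotypes after filtering")

    idx = np.array([j for j, _ in keep_cols])
    flips = np.array([f for _, f in keep_cols])
    dos = genotypes.dosages[:, idx].copy()
    dos[:, flips] = 2.0 - dos[:, flips]
    report.n_flipped = int(flips.sum())
    report.n_retained = len(keep_cols)

    aligned = GenotypeDosageMatrix(
        sample_ids=list(genotypes.sample_ids),
        variants=pd.DataFrame(new_meta),
        dosages=dos,
    )
    return aligned, report


def compute_pgs(
    weights: VariantWeightSet,
    genotypes: GenotypeDosageMatrix,
    *,
    average: bool = True,
    mean_impute: bool = False,
    sex: str | None = None,
    trait: str | None = None,
) -> PgsVector:
    """Compute per-sample polygenic scores from aligned dosages.

    Assumes ``genotypes`` is already coded to the effect allele (see
    :func:`align_alleles`).  With ``average=True`` (default) scores are
    ``sum(S_i G_ij) / (2 M_j)`` over non-missing SNPs; with ``average=False``
    the raw weighted sum is returned.  ``mean_impute=True`` replaces missing
    dosages with the per-SNP mean dosage instead of adjusting ``M_j``.

    Samples with no non-missing SNP get a NaN score and ``n_used = 0``.
    """
    wt = weights.table.set_index("snp_id")
    ids = genotypes.variants["snp_id"]
    if not ids.isin(wt.index).all():
        missing = ids[~ids.isin(wt.index)].tolist()[:5]
        raise ValueError(f"genotype variants without weights: {missing} ...")
    s = wt.loc[ids, "weight"].to_numpy(dtype=float)

    dos = genotypes.dosages
    miss = np.isnan(dos)
    if mean_impute and miss.any():
        col_mean = np.nanmean(dos, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # all-missing SNP
        dos = np.where(miss, col_mean[None, :], dos)
        miss = np.zeros_like(miss)

    m_used = (~miss).sum(axis=1)
    total = np.nansum(dos * s[None, :], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = total / (2.0 * m_used) if average else total
    score = np.where(m_used == 0, np.nan, score)
    return PgsVector(list(genotypes.sample_ids), score, m_used, sex=sex, trait=trait)


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation.

    Uses ``z = atanh(r)`` with standard error ``1/sqrt(n-3)``; the interval
    is mapped back with ``tanh``.  Degenerates to ``(r, r)`` when |r| = 1.
    """
    if n < 4:
        raise ValueError("Fisher interval requires n >= 4")
    if abs(r) >= 1.0:
        return float(np.sign(r)), float(np.sign(r))
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlate_scores(a: PgsVector, b: PgsVector) -> CorrelationSummary:
    """Pearson correlation between two score vectors matched on sample id.

    The 95% CI comes from the Fisher z-transform (SE ``1/sqrt(n-3)``); the
    two-sided p-value from ``t = r sqrt(n-2) / sqrt(1-r^2)`` on ``n-2``
    degrees of freedom.  At |r| = 1 the CI collapses to a point and p = 0.
    """
    sa, sb = a.to_series(), b.to_series()
    common = sa.index.intersection(sb.index)
    x = sa.loc[common].to_numpy()
    y = sb.loc[common].to_numpy()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("correlate_scores requires at least 4 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a score vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    lo, hi = fisher_ci(r, n)
    if abs(r) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationSummary(r=r, ci_low=lo, ci_high=hi, p_value=p, n=n)
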