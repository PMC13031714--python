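"""Synthetic GTEx-like study generator with known ground truth.

The real study couples UK Biobank testosterone SNP weights with GTEx
multi-tissue expression; neither input is redistributable, so this module
produces seeded bundles with the same statistical skeleton:

* two sexes with weakly correlated SNP weight sets (the study observed a
  cross-sex polygenic-score correlation of about 0.17),
* a donor pool per sex whose tissues sample 30+ donors each,
* per-tissue expression panels whose columns are rank-inverse-normal
  marginals (unit variance), a subset of which carry true effects,
* a polygenic-score proxy outcome
      y = beta_age z(age) + beta_bmi z(bmi) + W u + e
  in which ``e`` is the standardized genotype-derived polygenic score and
  the expression term is rescaled so the realized in-sample variance
  fraction var(Wu) / (var(Wu) + var(e)) equals ``r2_target`` *exactly* —
  parameter-recovery tests then have a sharp truth, free of simulation
  noise.

Genotypes are drawn in linkage equilibrium under Hardy–Weinberg
proportions; LD structure, realistic frequency spectra and batch effects
are deliberately out of scope (they live upstream of what this package
models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .relationship import ExpressionMatrix
from .scoring import GenotypeDosageMatrix, PgsVector, VariantWeightSet, compute_pgs
from .variance import CovariateTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "rank_inverse_normal",
    "simulate_genotypes",
    "simulate_weight_pair",
    "simulate_expression_and_score",
    "simulate_study",
    "StudyBundle",
]

# non-palindromic allele pairs only, so generated weights always align
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

SEXES = ("male", "female")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults give a desk-scale bundle.

    ``n_samples_per_sex`` is the donor-pool size per sex; individual
    tissues subsample at least ``min_tissue_samples`` donors from it,
    mirroring the 30-sample-per-sex floor of the emulated study design.
    ``r2_target`` is the true proportion of outcome variance carried by
    expression; ``r2_by_tissue`` overrides it per tissue.
    """

    n_samples_per_sex: int = 150
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_transcripts: int = 1000
    n_causal_transcripts: int = 100
    r2_target: float = 0.3
    covariate_effect_sizes: tuple[float, float] = (0.2, 0.2)  # age, BMI (per SD)
    cross_sex_weight_correlation: float = 0.17
    n_tissues: int = 6
    seed: int = 0
    prop_causal_snps: float = 0.1
    min_tissue_samples: int = 30
    r2_by_tissue: list[float] | None = None

    def __post_init__(self) -> None:
        for name in ("n_samples_per_sex", "n_snps", "n_transcripts", "n_tissues"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.n_causal_transcripts <= self.n_transcripts):
            raise ValueError("n_causal_transcripts must lie in [0, n_transcripts]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.r2_target <= 1:
            raise ValueError("r2_target must lie in [0, 1]")
        if abs(self.cross_sex_weight_correlation) > 1:
            raise ValueError("cross_sex_weight_correlation must lie in [-1, 1]")
        if self.n_causal_transcripts == 0 and self.r2_target > 0:
            raise ValueError("r2_target > 0 requires causal transcripts")
        if self.r2_by_tissue is not None and len(self.r2_by_tissue) != self.n_tissues:
            raise ValueError("r2_by_tissue must have one entry per tissue")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for recovery tests."""

    true_r2: float
    causal_transcript_ids: list[str]
    effects: np.ndarray  # per-transcript, exactly zero off the causal set
    seed: int

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)

    def to_dict(self) -> dict:
        return {"true_r2": self.true_r2,
                "causal_transcript_ids": list(self.causal_transcript_ids),
                "effects": self.effects.tolist(), "seed": int(self.seed)}


def rank_inverse_normal(values, offset: str = "half") -> np.ndarray:
    """Rank-based inverse normal transform across samples.

    Maps values to standard-normal quantiles of their (adjusted) ranks:
    ``Phi^-1((rank - 0.5) / n)`` by default, or the Blom variant
    ``Phi^-1((rank - 3/8) / (n + 1/4))`` with ``offset='blom'``.  Ties get
    average ranks; NaNs are propagated and excluded from n.

    Raises
    ------
    ValueError
        Fewer than 2 finite values, or all finite values identical.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n < 2:
        raise ValueError("need at least 2 finite values")
    xf = x[finite]
    if np.all(xf == xf[0]):
        raise ValueError("all values identical; ranks undefined")
    ranks = stats.rankdata(xf, method="average")
    if offset == "half":
        q = (ranks - 0.5) / n
    elif offset == "blom":
        q = (ranks - 0.375) / (n + 0.25)
    else:
        raise ValueError(f"unknown offset {offset!r}")
    out[finite] = stats.norm.ppf(q)
    return out


def _variant_frame(n_snps: int, rng: np.random.Generator) -> pd.DataFrame:
    pairs = [_ALLELE_PAIRS[k] for k in rng.integers(len(_ALLELE_PAIRS), size=n_snps)]
    return pd.DataFrame({
        "snp_id": [f"snp_{i + 1:06d}" for i in range(n_snps)],
        "chrom": [str(1 + i % 22) for i in range(n_snps)],
        "pos": np.arange(1, n_snps + 1) * 1000,
        "a1": [p[0] for p in pairs],
        "a2": [p[1] for p in pairs],
    })


def simulate_genotypes(n_samples: int, n_snps: int,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       seed: int = 0, *, missing_rate: float = 0.0,
                       sample_prefix: str = "S") -> GenotypeDosageMatrix:
    """Hardy–Weinberg dosages: per-SNP MAF uniform in ``maf_range``,
    dosage ~ Binomial(2, maf); SNPs are in linkage equilibrium."""
    if n_samples < 1 or n_snps < 1:
        raise ValueError("n_samples and n_snps must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    variants = _variant_frame(n_snps, rng)
    maf = rng.uniform(lo, hi, size=n_snps)
    dos = rng.binomial(2, maf[None, :], size=(n_samples, n_snps)).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    ids = [f"{sample_prefix}{i + 1:05d}" for i in range(n_samples)]
    return GenotypeDosageMatrix(ids, variants, dos)


def simulate_weight_pair(
    n_snps: int, prop_causal: float = 0.1,
    cross_sex_weight_correlation: float = 0.17, seed: int = 0,
    *, variants: pd.DataFrame | None = None,
) -> tuple[VariantWeightSet, VariantWeightSet]:
    """Male/female SNP weight sets with controlled cross-sex correlation.

    A shared causal SNP subset gets bivariate-normal weights with the
    requested correlation (rho = 1 gives identical sets); non-causal
    weights are exactly zero in both sexes.  Pass the genotype matrix's
    ``variants`` frame so alleles match; otherwise compatible metadata is
    synthesized from the same seed convention.
    """
    if not 0 < prop_causal <= 1:
        raise ValueError("prop_causal must lie in (0, 1]")
    rho = cross_sex_weight_correlation
    if abs(rho) > 1:
        raise ValueError("cross_sex_weight_correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    if variants is None:
        variants = _variant_frame(n_snps, np.random.default_rng(seed))
    if len(variants) != n_snps:
        raise ValueError("variants frame does not match n_snps")

    n_causal = max(1, int(round(prop_causal * n_snps)))
    causal = np.sort(rng.choice(n_snps, size=n_causal, replace=False))
    sd = 1.0 / np.sqrt(n_causal)
    z1 = rng.standard_normal(n_causal)
    z2 = rng.standard_normal(n_causal)
    wm = np.zeros(n_snps)
    wf = np.zeros(n_snps)
    wm[causal] = sd * z1
    wf[causal] = sd * (rho * z1 + np.sqrt(max(0.0, 1 - rho * rho)) * z2)

    def _pack(w: np.ndarray) -> VariantWeightSet:
        t = variants.rename(columns={"a1": "effect_allele", "a2": "other_allele"}).copy()
        t["weight"] = w
        return VariantWeightSet(t[["snp_id", "chrom", "pos",
                                   "effect_allele", "other_allele", "weight"]])

    return _pack(wm), _pack(wf)


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / s


def simulate_expression_and_score(
    genotypes: GenotypeDosageMatrix,
    weights: VariantWeightSet,
    config: SimulationConfig,
    seed: int,
    *,
    sex: str | None = None,
    covariates: CovariateTable | None = None,
    transcript_prefix: str = "ENSG",
) -> tuple[ExpressionMatrix, CovariateTable, PgsVector, SyntheticTruth]:
    """Draw an expression panel and a PGS-proxy outcome with known truth.

    The outcome is ``covariates + W u + e`` where ``e`` is the
    standardized genotype polygenic score (so the 'unexplained' part of
    the proxy really is genetic) and the expression term is rescaled so
    its realized in-sample variance fraction equals ``config.r2_target``
    exactly.  Covariate effects apply to standardized age and BMI and sit
    in the fixed-effect span, so they do not perturb the target fraction.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    m = config.n_transcripts
    nc = config.n_causal_transcripts
    r2 = config.r2_target
    if nc == 0 and r2 > 0:
        raise ValueError("r2_target > 0 requires causal transcripts")

    tids = [f"{transcript_prefix}{i + 1:08d}" for i in range(m)]
    raw = rng.standard_normal((n, m))
    x = np.column_stack([rank_inverse_normal(raw[:, j]) for j in range(m)])
    annotation = pd.DataFrame({
        "transcript_id": tids,
        "chrom": [str(1 + j % 22) for j in range(m)],
        "pos": np.arange(1, m + 1) * 5000,
        "symbol": [f"GENE{j + 1}" for j in range(m)],
    })
    expr = ExpressionMatrix(list(genotypes.sample_ids), tids, x, annotation)

    if covariates is None:
        age = rng.integers(20, 71, size=n).astype(float)
        bmi = rng.normal(27.0, 4.0, size=n)
        covar = CovariateTable(pd.DataFrame({
            "sample_id": genotypes.sample_ids,
            "sex": sex if sex is not None else "",
            "age": age, "bmi": bmi,
        }))
    else:
        covar = covariates.subset(list(genotypes.sample_ids))
        age = covar.table["age"].to_numpy(dtype=float)
        bmi = covar.table["bmi"].to_numpy(dtype=float)

    pgs_raw = compute_pgs(weights, genotypes, sex=sex)
    e = _standardize(pgs_raw.score)

    effects = np.zeros(m)
    if nc > 0 and r2 > 0:
        causal = np.sort(rng.choice(m, size=nc, replace=False))
        u = rng.standard_normal(nc) / np.sqrt(nc)
        g = x[:, causal] @ u
        g = g - g.mean()
        if r2 >= 1.0:
            e_term = np.zeros(n)
            g_term = g
            scale = 1.0
        else:
            scale = np.sqrt(r2 / (1.0 - r2) * e.var() / g.var())
            g_term = scale * g
            e_term = e
        effects[causal] = scale * u
        causal_ids = [tids[j] for j in causal]
    else:
        g_term = np.zeros(n)
        e_term = e
        causal_ids = []

    b_age, b_bmi = config.covariate_effect_sizes
    y = b_age * _standardize(age) + b_bmi * _standardize(bmi) + g_term + e_term

    outcome = PgsVector(list(genotypes.sample_ids), y, pgs_raw.n_used, sex=sex)
    truth = SyntheticTruth(true_r2=float(r2), causal_transcript_ids=causal_ids,
                           effects=effects, seed=int(seed))
    return expr, covar, outcome, truth


@dataclass
class StudyBundle:
    """In-memory multi-tissue, two-sex synthetic study."""

    config: SimulationConfig
    weights: dict  # sex -> VariantWeightSet
    genotypes: dict  # sex -> GenotypeDosageMatrix (donor pool)
    covariates: dict  # sex -> CovariateTable (donor pool)
    tissues: dict = field(default_factory=dict)
    # tissues[(tissue, sex)] = {"expression": ..., "outcome": ..., "truth": ...}

    @property
    def tissue_names(self) -> list[str]:
        return sorted({t for t, _ in self.tissues})


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Generate the full two-sex, multi-tissue bundle.

    Per sex: one donor pool of genotypes and covariates and one weight
    set (the male/female sets share causal SNPs with correlation
    ``cross_sex_weight_correlation``).  Each tissue subsamples a random
    number of donors (at least ``min_tissue_samples``) and draws its own
    expression panel and proxy outcome.  Fully deterministic given
    ``config.seed``.
    """
    root = np.random.default_rng(config.seed)
    child = lambda: int(root.integers(2**31))  # noqa: E731

    geno_seed = {s: child() for s in SEXES}
    genotypes = {
        s: simulate_genotypes(config.n_samples_per_sex, config.n_snps,
                              config.maf_range, geno_seed[s],
                              sample_prefix={"male": "M", "female": "F"}[s])
        for s in SEXES
    }
    wm, wf = simulate_weight_pair(
        config.n_snps, config.prop_causal_snps,
        config.cross_sex_weight_correlation, child(),
        variants=genotypes["male"].variants,
    )
    weights = {"male": wm, "female": wf}

    # donor-level covariates are fixed across tissues, as in a real cohort
    pool_covar = {}
    for sex in SEXES:
        rng_c = np.random.default_rng(child())
        age = rng_c.integers(20, 71, size=config.n_samples_per_sex).astype(float)
        bmi = rng_c.normal(27.0, 4.0, size=config.n_samples_per_sex)
        pool_covar[sex] = CovariateTable(pd.DataFrame({
            "sample_id": genotypes[sex].sample_ids,
            "sex": sex, "age": age, "bmi": bmi,
        }))

    bundle = StudyBundle(config=config, weights=weights, genotypes=genotypes,
                         covariates=pool_covar)
    r2s = (config.r2_by_tissue if config.r2_by_tissue is not None
           else [config.r2_target] * config.n_tissues)

    pool = config.n_samples_per_sex
    n_min = min(config.min_tissue_samples, pool)
    for ti in range(config.n_tissues):
        tissue = f"tissue_{ti + 1:02d}"
        for sex in SEXES:
            n_t = int(root.integers(n_min, pool + 1))
            idx = np.sort(root.choice(pool, size=n_t, replace=False))
            g = genotypes[sex]
            sub = GenotypeDosageMatrix(
                [g.sample_ids[i] for i in idx],
                g.variants.copy(), g.dosages[idx],
            )
            cfg_t = SimulationConfig(**{**config.__dict__,
                                        "r2_target": r2s[ti],
                                        "r2_by_tissue": None})
            expr, covar, outcome, truth = simulate_expression_and_score(
                sub, weights[sex], cfg_t, child(), sex=sex,
                covariates=pool_covar[sex])
            bundle.tissues[(tissue, sex)] = {
                "expression": expr, "covariates": covar,
                "outcome": outcome, "truth": truth,
            }
    return bundle
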