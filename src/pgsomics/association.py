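"""Mixed-linear-model omic association (MOA): per-transcript TWAS.

Each transcript ``w_i`` is tested as a fixed effect while all transcripts
jointly enter as a random polygenic-like background term,

    y = w_i b_i + C beta + W u + e,

which guards against inflation from unobserved confounders shared across
the transcriptome.  The variance components (sigma_o^2, sigma_e^2) are
estimated once under the covariates-only null model and then held fixed,
giving for each transcript

    b_i   = w_i' P y / (w_i' P w_i),
    var(b_i) = 1 / (w_i' P w_i),
    chi2_i   = b_i^2 * (w_i' P w_i)   ~  chi2_1 under H0,

with ``P`` the REML projection under the fitted V.  This fixed-V scan is
the standard mixed-model association shortcut; an exact mode that refits
the variance components per transcript (as a fixed-effect GLS under each
refit) is available for small panels via ``fit(exact=True)``.

The tested transcript is *not* removed from the background relationship
matrix, which makes the scan slightly conservative for strong single
transcripts (proximal contamination); see the package methods note.

Multiplicity follows the study design: a per-tissue Bonferroni cutoff
``alpha/m`` over the m transcripts tested, plus a nominal ``p < 1e-3``
screen used for cross-tissue summaries and enrichment exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .relationship import ExpressionMatrix, OmicsRelationshipMatrix, build_orm
from .variance import CovariateTable, OremlModel, OremlResults

__all__ = [
    "SignificanceThresholds",
    "MoaModel",
    "MoaResults",
    "fit_moa",
    "bonferroni_threshold",
    "summarize_hits",
    "HitSummary",
]


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-tissue Bonferroni significance cutoff ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


@dataclass(frozen=True)
class SignificanceThresholds:
    """Bonferroni (``alpha/m``) and nominal cutoffs for m tested transcripts."""

    m: int
    alpha: float = 0.05
    nominal: float = 1e-3

    @property
    def bonferroni(self) -> float:
        return bonferroni_threshold(self.m, self.alpha)


class MoaModel:
    """Per-transcript mixed-model association scan.

    Parameters
    ----------
    y : PgsVector, Series or array
        Outcome (polygenic score).
    expression : ExpressionMatrix
        Samples x transcripts panel; every column is tested.
    orm : OmicsRelationshipMatrix, optional
        Background relationship matrix.  Built from ``expression`` when
        omitted; if given it must come from the same expression panel for
        the model to match its description.
    covariates : CovariateTable, DataFrame or array, optional
    """

    def __init__(self, y, expression: ExpressionMatrix, orm=None, covariates=None):
        if orm is None:
            orm = build_orm(expression)
        self.null_model = OremlModel(y, orm, covariates)
        ids = self.null_model.sample_ids
        if ids is not None:
            expression = expression.subset_samples(ids)
        if expression.n_samples != self.null_model.n:
            raise ValueError("expression rows do not match outcome length")
        self.expression = expression

    def fit(self, *, fix_sigma2_o: float | None = None, exact: bool = False,
            null_fit: OremlResults | None = None, tissue: str | None = None,
            sex: str | None = None, trait: str | None = None) -> "MoaResults":
        """Run the scan.

        ``fix_sigma2_o=0`` pins the background variance to zero (the scan
        then reduces to covariate-adjusted regression with the null-model
        residual variance).  ``exact=True`` refits REML per transcript —
        quadratic cost, intended for small m.
        """
        nm = self.null_model
        if null_fit is None:
            null_fit = nm.fit(fix_sigma2_o=fix_sigma2_o)
        w_all = self.expression.values
        var = w_all.var(axis=0, ddof=1)
        tested = var > 0
        skipped = [t for t, ok in zip(self.expression.transcript_ids, tested) if not ok]

        if exact:
            rows = self._fit_exact(w_all, tested)
        else:
            rows = self._fit_fixed_v(null_fit, w_all, tested)

        frame = pd.DataFrame(rows)
        ann = self.expression.annotation
        if ann is not None and not frame.empty:
            frame = frame.merge(
                ann[["transcript_id", "chrom", "pos", "symbol"]].rename(
                    columns={"transcript_id": "transcript", "symbol": "gene"}),
                on="transcript", how="left")
        if tissue is not None:
            frame["tissue"] = tissue
        if sex is not None:
            frame["sex"] = sex
        if trait is not None:
            frame["trait"] = trait
        return MoaResults(frame=frame, null_fit=null_fit, skipped_ids=skipped,
                          thresholds=SignificanceThresholds(m=max(int(tested.sum()), 1)))

    def _fit_fixed_v(self, null_fit: OremlResults, w_all, tested) -> list[dict]:
        nm = self.null_model
        # rotated projection under the fitted V, mapped back to sample space
        pt = nm._projection(null_fit.sigma2_o, null_fit.sigma2_e)
        p_mat = nm._U @ pt @ nm._U.T
        py = p_mat @ nm.y
        w = w_all[:, tested]
        pw = p_mat @ w
        den = np.einsum("ij,ij->j", w, pw)
        num = w.T @ py
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = num / den
            se = np.sqrt(1.0 / den)
            chi2 = num * num / den
        pvals = stats.chi2.sf(chi2, 1)
        ids = [t for t, ok in zip(self.expression.transcript_ids, tested) if ok]
        return [
            {"transcript": t, "beta": float(b), "se": float(s),
             "chi2": float(c), "p": float(p), "n": nm.n}
            for t, b, s, c, p in zip(ids, beta, se, chi2, pvals)
        ]

    def _fit_exact(self, w_all, tested) -> list[dict]:
        nm = self.null_model
        rows = []
        base_c = nm.C[:, 1:]  # model re-adds the intercept
        for j, tid in enumerate(self.expression.transcript_ids):
            if not tested[j]:
                continue
            wj = w_all[:, j]
            m = OremlModel(nm.y, nm.A, np.column_stack([base_c, wj]),
                           sample_ids=nm.sample_ids)
            r = m.fit()
            # GLS fixed effects under the refitted V
            v = r.sigma2_o * m._d + r.sigma2_e
            wts = 1.0 / v
            cr, yr = m._Cr, m._yr
            xtvx = cr.T @ (wts[:, None] * cr)
            xtvy = cr.T @ (wts * yr)
            cov = np.linalg.inv(xtvx)
            beta = cov @ xtvy
            b, s = float(beta[-1]), float(np.sqrt(cov[-1, -1]))
            chi2 = (b / s) ** 2
            rows.append({"transcript": tid, "beta": b, "se": s, "chi2": chi2,
                         "p": float(stats.chi2.sf(chi2, 1)), "n": nm.n})
        return rows


@dataclass
class MoaResults:
    """Per-transcript association results plus the null variance fit."""

    frame: pd.DataFrame  # transcript, beta, se, chi2, p, n [, chrom, pos, gene, ...]
    null_fit: OremlResults
    skipped_ids: list[str] = field(default_factory=list)
    thresholds: SignificanceThresholds | None = None

    @property
    def m(self) -> int:
        return len(self.frame)

    def significant(self, threshold: float | None = None) -> pd.DataFrame:
        """Rows with ``p`` strictly below ``threshold`` (default Bonferroni)."""
        if threshold is None:
            threshold = SignificanceThresholds(m=self.m).bonferroni
        return self.frame[self.frame["p"] < threshold]

    def summary(self, top: int = 10) -> str:
        th = SignificanceThresholds(m=max(self.m, 1))
        n_bonf = int((self.frame["p"] < th.bonferroni).sum())
        n_nom = int((self.frame["p"] < th.nominal).sum())
        lines = [
            "MOA transcriptome-wide association",
            "==================================",
            f"transcripts tested    {self.m}",
            f"skipped (zero var)    {len(self.skipped_ids)}",
            f"background R2 (null)  {self.null_fit.r2:.4f}",
            f"Bonferroni 0.05/m     {th.bonferroni:.3g}  ->  {n_bonf} hit(s)",
            f"nominal p < {th.nominal:g}     ->  {n_nom} hit(s)",
            "",
            self.frame.nsmallest(min(top, self.m), "p").to_string(index=False),
        ]
        return "\n".join(lines)


def fit_moa(y, expression: ExpressionMatrix, orm=None, covariates=None,
            **fit_kwargs) -> MoaResults:
    """One-call MOA scan; see :class:`MoaModel`."""
    return MoaModel(y, expression, orm, covariates).fit(**fit_kwargs)


@dataclass
class HitSummary:
    """Cross-tissue tallies of nominal and Bonferroni-significant results."""

    per_tissue_nominal: pd.DataFrame  # tissue [, sex], n_nominal (desc)
    per_transcript_tissues: pd.DataFrame  # transcript, n_tissues_nominal (desc)
    bonferroni_hits: pd.DataFrame  # rows passing the per-tissue 0.05/m cutoff


def summarize_hits(results: pd.DataFrame | list[MoaResults],
                   thresholds: SignificanceThresholds | dict | None = None,
                   ) -> HitSummary:
    """Tally nominal (p < 1e-3) and Bonferroni hits across tissues.

    ``results`` is a concatenated MOA table (columns ``transcript, p,
    tissue`` and optionally ``sex``) or a list of :class:`MoaResults`.
    ``thresholds`` may be a single :class:`SignificanceThresholds`, a dict
    keyed by tissue, or None (per-tissue m inferred from row counts).
    Counting uses strict inequality, matching 'p < cutoff'.
    """
    if isinstance(results, list):
        frames = []
        th_map: dict = {}
        for r in results:
            frames.append(r.frame)
            if "tissue" in r.frame.columns and len(r.frame):
                th_map[r.frame["tissue"].iloc[0]] = r.thresholds
        results = pd.concat(frames, ignore_index=True)
        if thresholds is None:
            thresholds = th_map
    if results.empty:
        raise ValueError("no MOA results to summarize")

    df = results.copy()
    if "tissue" not in df.columns:
        df["tissue"] = "all"
    group_cols = ["tissue"] + (["sex"] if "sex" in df.columns else [])

    def _thresh(tissue: str, m: int) -> SignificanceThresholds:
        if isinstance(thresholds, SignificanceThresholds):
            return thresholds
        if isinstance(thresholds, dict) and tissue in thresholds:
            return thresholds[tissue]
        return SignificanceThresholds(m=m)

    nom_rows, bonf_rows = [], []
    for keys, sub in df.groupby(group_cols, sort=True):
        keys = (keys,) if not isinstance(keys, tuple) else keys
        th = _thresh(keys[0], len(sub))
        nom_rows.append(dict(zip(group_cols, keys))
                        | {"n_nominal": int((sub["p"] < th.nominal).sum())})
        bonf_rows.append(sub[sub["p"] < th.bonferroni])

    per_tissue = (pd.DataFrame(nom_rows)
                  .sort_values(["n_nominal"] + group_cols, ascending=[False] + [True] * len(group_cols))
                  .reset_index(drop=True))

    nominal_mask = pd.Series(False, index=df.index)
    for keys, sub in df.groupby(group_cols, sort=False):
        keys = (keys,) if not isinstance(keys, tuple) else keys
        th = _thresh(keys[0], len(sub))
        nominal_mask.loc[sub.index] = sub["p"] < th.nominal
    per_transcript = (df[nominal_mask]
                      .groupby("transcript")["tissue"].nunique()
                      .rename("n_tissues_nominal").reset_index()
                      .sort_values(["n_tissues_nominal", "transcript"],
                                   ascending=[False, True])
                      .reset_index(drop=True))

    bonf = (pd.concat(bonf_rows, ignore_index=True) if bonf_rows
            else df.iloc[0:0].copy())
    if len(bonf):
        bonf = bonf.sort_values(["p", "transcript"]).reset_index(drop=True)
    return HitSummary(per_tissue, per_transcript, bonf)
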