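"""Omics relationship matrix (ORM) construction.

The ORM is the expression-space analog of a genomic relationship matrix:
for samples j, k and m retained transcripts,

    A_jk = (1/m) * sum_i (x_ij - mu_i)(x_ik - mu_i) / sigma_i^2,

i.e. ``A = Z Z' / m`` for the column-standardized expression matrix ``Z``.
Transcript means and variances use the n-1 (sample) denominator, so the
mean of diag(A) is exactly 1.  Zero-variance transcripts (e.g. transcripts
not detected in any sample) carry no relationship information and are
excluded rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "OmicsRelationshipMatrix", "build_orm"]

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["transcript_id", "chrom", "pos", "symbol"]


@dataclass
class ExpressionMatrix:
    """Samples x transcripts expression values with optional annotation."""

    sample_ids: list[str]
    transcript_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_transcripts)
    annotation: pd.DataFrame | None = None  # transcript_id, chrom, pos, symbol

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.transcript_ids):
            raise ValueError("expression shape inconsistent with id lists")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.transcript_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   annotation: pd.DataFrame | None = None) -> "ExpressionMatrix":
        return cls(sample_ids=[str(s) for s in df.index],
                   transcript_ids=[str(t) for t in df.columns],
                   values=df.to_numpy(dtype=float),
                   annotation=annotation)

    def subset_samples(self, ids: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return ExpressionMatrix(list(ids), list(self.transcript_ids),
                                self.values[idx], self.annotation)


@dataclass
class OmicsRelationshipMatrix:
    """n x n sample-similarity matrix built from standardized transcripts."""

    sample_ids: list[str]
    values: np.ndarray
    m_used: int
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("ORM must be square and match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("ORM must be symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, ids: list[str]) -> "OmicsRelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in ids])
        return OmicsRelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)],
                                       self.m_used, list(self.excluded_ids))


def build_orm(expr: ExpressionMatrix, *, ddof: int = 1) -> OmicsRelationshipMatrix:
    """Build the ORM ``A = Z Z' / m`` from an expression matrix.

    Standardizes each transcript to mean 0, variance 1 (variance with the
    ``ddof`` denominator, default n-1) and averages the outer products.
    Zero-variance transcripts are excluded and recorded in
    ``excluded_ids``; non-finite values raise.

    Raises
    ------
    ValueError
        On fewer than 2 samples, non-finite input, or no transcript
        retained.
    """
    x = expr.values
    if expr.n_samples < 2:
        raise ValueError("ORM requires at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("expression matrix contains non-finite values")

    var = x.var(axis=0, ddof=ddof)
    keep = var > 0
    excluded = [t for t, k in zip(expr.transcript_ids, keep) if not k]
    if excluded:
        logger.warning("build_orm: excluding %d zero-variance transcript(s)", len(excluded))
    m_used = int(keep.sum())
    if m_used < 1:
        raise ValueError("no transcript with non-zero variance")

    z = (x[:, keep] - x[:, keep].mean(axis=0)) / np.sqrt(var[keep])
    a = z @ z.T / m_used
    a = (a + a.T) / 2.0  # enforce exact symmetry against round-off
    return OmicsRelationshipMatrix(list(expr.sample_ids), a, m_used, excluded)
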