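"""Restricted maximum likelihood variance partitioning on an ORM (OREML).

Model
-----
For a phenotype-like outcome ``y`` (here a polygenic score) on n samples,

    y = C beta + W u + e,      u ~ N(0, I sigma_u^2),  e ~ N(0, I sigma_e^2),

where ``W`` is the column-standardized n x m expression matrix and ``C``
the fixed-effect design (intercept plus quantitative covariates such as
age and BMI).  Marginally,

    var(y) = V = A sigma_o^2 + I sigma_e^2,

with ``A = W W'/m`` the omics relationship matrix and
``sigma_o^2 = m sigma_u^2`` the variance captured jointly by all
transcripts.  The quantity of interest is

    R^2 = sigma_o^2 / (sigma_o^2 + sigma_e^2),

the proportion of outcome variance associated with genome-wide expression.

Estimation
----------
The restricted log-likelihood (up to an additive constant) is

    l(sigma_o^2, sigma_e^2) = -1/2 [ log|V| + log|C' V^-1 C| + y' P y ],
    P = V^-1 - V^-1 C (C' V^-1 C)^-1 C' V^-1.

With a single relationship matrix the problem is one-dimensional: after
eigendecomposing ``A = U diag(d) U'`` once, for any variance ratio
``lambda = sigma_o^2 / sigma_e^2`` the residual variance profiles out in
closed form, and the profile likelihood is maximized by Brent search on
``log lambda``.  This avoids the boundary fragility of iterative
(AI-)REML updates.  Estimates at the ``sigma_o^2 = 0`` boundary are
reported as ``r2 = 0`` with ``boundary=True``.

Standard errors come from the inverse expected (Fisher) information,
``I_ij = tr(P A_i P A_j)/2`` with ``A_1 = A`` and ``A_2 = I``; the SE of
R^2 follows by the delta method.  The null hypothesis ``sigma_o^2 = 0``
sits on the boundary of the parameter space, so the likelihood-ratio
p-value uses the 50:50 mixture ``chi2_0 : chi2_1`` by default
(``null_dist='chi2'`` switches to a plain one-degree chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

from .relationship import OmicsRelationshipMatrix
from .scoring import PgsVector

__all__ = [
    "CovariateTable",
    "OremlModel",
    "OremlResults",
    "reml_loglik",
    "fit_oreml",
    "fdr_adjust",
]


@dataclass
class CovariateTable:
    """Quantitative covariates (age in years, BMI in kg/m^2) keyed by sample."""

    table: pd.DataFrame  # columns: sample_id, sex, age, bmi (extra columns kept)

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns:
            raise ValueError("covariate table needs a sample_id column")
        self.table = self.table.reset_index(drop=True)

    @property
    def numeric_columns(self) -> list[str]:
        return [c for c in self.table.columns
                if c not in ("sample_id", "sex")
                and pd.api.types.is_numeric_dtype(self.table[c])]

    def design(self, sample_ids: list[str]) -> np.ndarray:
        """Covariate values (no intercept) aligned to ``sample_ids``."""
        t = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise ValueError(f"samples without covariates: {missing[:5]} ...")
        x = t.loc[sample_ids, self.numeric_columns].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("covariates must be finite")
        return x

    def subset(self, sample_ids: list[str]) -> "CovariateTable":
        t = self.table.set_index("sample_id").loc[sample_ids].reset_index()
        return CovariateTable(t)


def _as_outcome(y) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(y, PgsVector):
        return np.asarray(y.score, dtype=float), list(y.sample_ids)
    if isinstance(y, pd.Series):
        return y.to_numpy(dtype=float), [str(i) for i in y.index]
    return np.asarray(y, dtype=float), None


class OremlModel:
    """Single-variance-component REML model ``var(y) = A s2o + I s2e``.

    Parameters
    ----------
    y : array-like, pandas.Series or PgsVector
        Outcome vector (a polygenic score in the intended application).
    orm : OmicsRelationshipMatrix or ndarray
        The n x n relationship matrix ``A``.
    covariates : CovariateTable, DataFrame, ndarray or None
        Quantitative fixed-effect covariates; an intercept is always
        appended (the mean model is required for REML to be well posed).

    When both ``y`` and ``orm`` carry sample ids the inputs are aligned on
    their id intersection; bare arrays are assumed pre-aligned.
    """

    def __init__(self, y, orm, covariates=None, *, sample_ids=None):
        yv, y_ids = _as_outcome(y)

        if isinstance(orm, OmicsRelationshipMatrix):
            a_ids = list(orm.sample_ids)
            a = orm.values
        else:
            a_ids = None
            a = np.asarray(orm, dtype=float)

        ids = sample_ids
        if ids is None and y_ids is not None and a_ids is not None:
            ids = [s for s in y_ids if s in set(a_ids)]
        elif ids is None:
            ids = y_ids if y_ids is not None else a_ids

        if ids is not None and y_ids is not None:
            pos = {s: i for i, s in enumerate(y_ids)}
            yv = yv[[pos[s] for s in ids]]
        if ids is not None and a_ids is not None:
            pos = {s: i for i, s in enumerate(a_ids)}
            idx = np.array([pos[s] for s in ids])
            a = a[np.ix_(idx, idx)]

        ok = np.isfinite(yv)
        if not ok.all():
            if ids is not None:
                ids = [s for s, o in zip(ids, ok) if o]
            a = a[np.ix_(np.where(ok)[0], np.where(ok)[0])]
            yv = yv[ok]

        n = yv.size
        if a.shape != (n, n):
            raise ValueError(f"ORM shape {a.shape} does not match n={n} outcomes")

        if covariates is None:
            c = np.empty((n, 0))
        elif isinstance(covariates, CovariateTable):
            if ids is None:
                raise ValueError("CovariateTable requires sample ids on y or orm")
            c = covariates.design(ids)
        elif isinstance(covariates, pd.DataFrame):
            c = covariates.to_numpy(dtype=float)
        else:
            c = np.asarray(covariates, dtype=float)
            if c.ndim == 1:
                c = c[:, None]
        if c.shape[0] != n:
            raise ValueError("covariate rows do not match outcome length")
        c = np.column_stack([np.ones(n), c])  # intercept always included
        if np.linalg.matrix_rank(c) < c.shape[1]:
            raise ValueError("covariate design (with intercept) is rank deficient")

        self.sample_ids = ids
        self.y = yv
        self.A = (a + a.T) / 2.0
        self.C = c
        self.n, self.p = n, c.shape[1]

        # one-off eigendecomposition; the whole profile search reuses it
        d, u = linalg.eigh(self.A)
        tiny = -1e-8 * max(np.trace(self.A) / n, 1.0)
        if d.min() < tiny:
            raise ValueError(f"ORM is not positive semi-definite (min eigenvalue {d.min():.3g})")
        self._d = np.clip(d, 0.0, None)
        self._U = u
        self._yr = u.T @ yv
        self._Cr = u.T @ c

    # -- likelihood -----------------------------------------------------

    def loglik(self, sigma2_o: float, sigma2_e: float, *, method: str = "eigen") -> float:
        """Restricted log-likelihood at ``(sigma2_o, sigma2_e)``.

        Up to an additive constant that is fixed across calls.  The
        ``method='dense'`` path evaluates the textbook matrix formula and
        exists as an internal cross-check of the rotated evaluation.
        """
        if sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")
        if sigma2_o < 0:
            raise ValueError("sigma2_o must be non-negative")
        if method == "eigen":
            v = sigma2_o * self._d + sigma2_e
            w = 1.0 / v
            m = self._Cr.T @ (w[:, None] * self._Cr)
            sign, logdet_m = np.linalg.slogdet(m)
            if sign <= 0:
                raise ValueError("singular C' V^-1 C")
            b = self._Cr.T @ (w * self._yr)
            ypy = float(self._yr @ (w * self._yr) - b @ np.linalg.solve(m, b))
            return -0.5 * (float(np.sum(np.log(v))) + logdet_m + ypy)
        if method == "dense":
            v = sigma2_o * self.A + sigma2_e * np.eye(self.n)
            sign_v, logdet_v = np.linalg.slogdet(v)
            vinv_c = np.linalg.solve(v, self.C)
            m = self.C.T @ vinv_c
            sign_m, logdet_m = np.linalg.slogdet(m)
            if sign_v <= 0 or sign_m <= 0:
                raise ValueError("singular V or C' V^-1 C")
            vinv_y = np.linalg.solve(v, self.y)
            ypy = float(self.y @ vinv_y
                        - (self.C.T @ vinv_y) @ np.linalg.solve(m, self.C.T @ vinv_y))
            return -0.5 * (logdet_v + logdet_m + ypy)
        raise ValueError(f"unknown method {method!r}")

    def _profile(self, lam: float) -> tuple[float, float]:
        """Profile restricted log-likelihood at variance ratio ``lam``.

        Returns ``(loglik, sigma2_e_hat)`` with sigma2_e profiled out in
        closed form (``s2e = y'P_lam y / (n-p)``).  At the profiled
        optimum this equals :meth:`loglik` evaluated there, same additive
        constant.
        """
        u = 1.0 + lam * self._d
        w = 1.0 / u
        m = self._Cr.T @ (w[:, None] * self._Cr)
        sign, logdet_m = np.linalg.slogdet(m)
        if sign <= 0:
            raise ValueError("singular C' V^-1 C in profile")
        b = self._Cr.T @ (w * self._yr)
        q = float(self._yr @ (w * self._yr) - b @ np.linalg.solve(m, b))
        df = self.n - self.p
        s2e = q / df
        ll = -0.5 * (df * np.log(s2e) + float(np.sum(np.log(u))) + logdet_m + df)
        return ll, s2e

    # -- fitting --------------------------------------------------------

    def fit(
        self,
        *,
        log_lambda_bounds: tuple[float, float] = (-18.0, 18.0),
        xatol: float = 1e-10,
        null_dist: str = "mixture",
        fix_sigma2_o: float | None = None,
    ) -> "OremlResults":
        """Maximize the restricted likelihood over ``(sigma2_o, sigma2_e)``.

        The search is a bounded Brent minimization on the natural-log
        variance ratio; the boundary ``sigma2_o = 0`` is always evaluated
        and wins ties.  ``fix_sigma2_o=0`` skips the search and fits the
        covariates-only model (used by the association scan to pin the
        variance structure).
        """
        ll0, s2e0 = self._profile(0.0)

        if fix_sigma2_o is not None:
            if fix_sigma2_o != 0.0:
                raise NotImplementedError("only fix_sigma2_o=0 is supported")
            return self._results(0.0, s2e0, ll0, ll0, 0, True, True, null_dist)

        res = optimize.minimize_scalar(
            lambda t: -self._profile(np.exp(t))[0],
            bounds=log_lambda_bounds, method="bounded",
            options={"xatol": xatol},
        )
        lam = float(np.exp(res.x))
        ll_hat, s2e_hat = self._profile(lam)

        if ll_hat <= ll0 + 1e-12:
            # interior candidate no better than the boundary
            return self._results(0.0, s2e0, ll0, ll0, int(res.nfev), bool(res.success),
                                 True, null_dist)
        s2o = lam * s2e_hat
        at_upper = res.x >= log_lambda_bounds[1] - 1e-6
        converged = bool(res.success) and not at_upper
        return self._results(s2o, s2e_hat, ll_hat, ll0, int(res.nfev), converged,
                             False, null_dist)

    def _projection(self, s2o: float, s2e: float) -> np.ndarray:
        """Rotated projection matrix P~ = U' P U (dense n x n)."""
        v = s2o * self._d + s2e
        w = 1.0 / v
        wc = w[:, None] * self._Cr
        m = self._Cr.T @ wc
        return np.diag(w) - wc @ np.linalg.solve(m, wc.T)

    def _results(self, s2o, s2e, ll_full, ll_null, n_iter, converged, boundary,
                 null_dist) -> "OremlResults":
        # Fisher information in the rotated basis: A is diag(d) there, so
        # the traces reduce to weighted sums of squared entries of P~.
        pt = self._projection(s2o, s2e)
        b = pt * pt
        d = self._d
        info = 0.5 * np.array([
            [d @ b @ d, d @ b.sum(axis=1)],
            [d @ b.sum(axis=1), b.sum()],
        ], dtype=float)
        try:
            cov = np.linalg.inv(info)
            se_s2o = float(np.sqrt(max(cov[0, 0], 0.0)))
            se_s2e = float(np.sqrt(max(cov[1, 1], 0.0)))
            tot = s2o + s2e
            grad = np.array([s2e, -s2o]) / tot**2
            se_r2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
            se_s2o = se_s2e = se_r2 = float("nan")

        lr = max(0.0, 2.0 * (ll_full - ll_null))
        if null_dist == "mixture":
            p = 1.0 if lr <= 0 else min(1.0, 0.5 * float(stats.chi2.sf(lr, 1)))
        elif null_dist == "chi2":
            p = float(stats.chi2.sf(lr, 1)) if lr > 0 else 1.0
        else:
            raise ValueError(f"unknown null_dist {null_dist!r}")

        return OremlResults(
            model=self,
            sigma2_o=float(s2o), sigma2_e=float(s2e),
            r2=float(s2o / (s2o + s2e)),
            se_sigma2_o=se_s2o, se_sigma2_e=se_s2e, se_r2=se_r2,
            loglik_full=float(ll_full), loglik_null=float(ll_null),
            p_value=p, n_iter=n_iter, converged=converged, boundary=boundary,
            cov_params=cov,
        )


@dataclass
class OremlResults:
    """OREML estimates with Fisher-information standard errors."""

    model: OremlModel
    sigma2_o: float
    sigma2_e: float
    r2: float
    se_sigma2_o: float
    se_sigma2_e: float
    se_r2: float
    loglik_full: float
    loglik_null: float
    p_value: float
    n_iter: int
    converged: bool
    boundary: bool
    cov_params: np.ndarray

    @property
    def n(self) -> int:
        return self.model.n

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "sigma2_o": self.sigma2_o, "sigma2_e": self.sigma2_e, "r2": self.r2,
            "se_sigma2_o": self.se_sigma2_o, "se_sigma2_e": self.se_sigma2_e,
            "se_r2": self.se_r2,
            "loglik_full": self.loglik_full, "loglik_null": self.loglik_null,
            "p_value": self.p_value, "n_iter": self.n_iter,
            "converged": self.converged, "boundary": self.boundary,
        }

    def summary(self) -> str:
        lines = [
            "OREML variance partitioning",
            "===========================",
            f"n samples            {self.n:>10d}",
            f"sigma2_o (omics)     {self.sigma2_o:>10.4f}  (SE {self.se_sigma2_o:.4f})",
            f"sigma2_e (residual)  {self.sigma2_e:>10.4f}  (SE {self.se_sigma2_e:.4f})",
            f"R2 = s2o/(s2o+s2e)   {self.r2:>10.4f}  (SE {self.se_r2:.4f})",
            f"LRT p (boundary mix) {self.p_value:>10.3g}",
            f"restricted loglik    {self.loglik_full:>10.4f}  (null {self.loglik_null:.4f})",
            f"converged            {str(self.converged):>10s}  boundary={self.boundary}",
        ]
        return "\n".join(lines)


def reml_loglik(y, orm, covariates, sigma2_o: float, sigma2_e: float,
                *, method: str = "eigen") -> float:
    """Restricted log-likelihood of ``y`` under ``V = A s2o + I s2e``.

    Convenience wrapper over :meth:`OremlModel.loglik`; see the class for
    the exact expression and the additive-constant convention.
    """
    return OremlModel(y, orm, covariates).loglik(sigma2_o, sigma2_e, method=method)


def fit_oreml(y, orm, covariates=None, **fit_kwargs) -> OremlResults:
    """One-call OREML fit; see :class:`OremlModel` for input handling."""
    return OremlModel(y, orm, covariates).fit(**fit_kwargs)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Input values must lie in (0, 1]; the output is the usual monotone
    step-up adjustment (``min`` over the tail of ``p * n / rank``).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
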