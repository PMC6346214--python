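"""CV2-mean trend fitting and highly-variable-gene (HVG) detection.

Inter-individual expression noise decreases with expression level: across
genes, CV2 (variance over squared mean, computed across individuals at one
time-point) follows a trend

    CV2(mu) = a1 / mu + a0

with ``a0`` the asymptotic CV2 at high expression. The trend is fitted per
time-point by a gamma-family GLM with identity link of CV2 on 1/mu, over a
fit subset of well-expressed genes. Each gene then gets

* a corrected CV2, ``log2(CV2 / trend(mu))`` — its variability relative to
  genes of the same expression level (0 = on trend); and
* a chi-square overdispersion test asking whether its CV2 significantly
  exceeds the trend plus a minimum biological CV of 10%. With m individuals,
  ``minBiolDisp = min_biol_cv**2``, ``cv2th = a0 + minBiolDisp +
  a0*minBiolDisp``, ``denom = (mu*a1 + mu^2*cv2th) / (1 + cv2th/m)`` and the
  statistic ``(m-1) * mu^2 * CV2 / denom`` is referred to the upper tail of a
  chi-square with m-1 degrees of freedom.

Genes with a Benjamini-Hochberg adjusted p below the FDR (10% by default) are
called highly variable. The lowly variable set (LVG) is the bottom-n genes by
corrected CV2, and size-matched random gene sets provide an empirical null
envelope for downstream comparisons.

The same machinery is exposed as :class:`HVGDetector`, a scikit-learn feature
selector (individuals as samples, genes as features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data
from statsmodels.stats.multitest import multipletests

from .quantify import ExpressionMatrix, cv2_table

__all__ = [
    "TrendFit",
    "fit_cv2_trend",
    "corrected_cv2",
    "test_hvg",
    "bh_adjust",
    "variability_table",
    "select_hvg",
    "select_lvg",
    "sample_random_sets",
    "HVGDetector",
]

MIN_FIT_GENES = 50


@dataclass
class TrendFit:
    """Fitted CV2 = a1/mu + a0 relation for one time-point."""

    a0: float
    a1: float
    fit_gene_ids: pd.Index | None = None
    min_mean_for_fit: float = 0.0
    method: str = "glmgam"
    converged: bool = True

    def trend(self, mu) -> np.ndarray:
        return self.a1 / np.asarray(mu, dtype=float) + self.a0

    def to_dict(self) -> dict:
        return {
            "a0": float(self.a0),
            "a1": float(self.a1),
            "min_mean_for_fit": float(self.min_mean_for_fit),
            "n_fit_genes": None if self.fit_gene_ids is None else int(len(self.fit_gene_ids)),
            "method": self.method,
            "converged": bool(self.converged),
        }


def _gamma_glm(y: np.ndarray, inv_mu: np.ndarray, max_iter: int, tol: float):
    X = np.column_stack([np.ones_like(inv_mu), inv_mu])
    # OLS start; nudged if it predicts non-positive CV2 anywhere
    start, *_ = np.linalg.lstsq(X, y, rcond=None)
    if np.any(X @ start <= 0):
        start = np.array([max(float(np.mean(y)) / 2.0, 1e-6), 1e-6])
    with warnings.catch_warnings():
        # identity link on the Gamma family is the standard CV2-trend choice;
        # statsmodels warns about the domain (and about an exact fit) anyway
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Identity()))
        res = model.fit(start_params=start, maxiter=max_iter, tol=tol)
    # an exact interpolating fit reports converged=False with zero deviance
    converged = bool(res.converged) or float(res.deviance) < tol * max(len(y), 1)
    return float(res.params[0]), float(res.params[1]), converged


def fit_cv2_trend(
    means,
    cv2s,
    *,
    min_mean_for_fit: float | None = None,
    fit_quantile: float = 0.4,
    cv2_floor: float = 0.05,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> TrendFit:
    """Fit the CV2-mean trend by a gamma GLM with identity link.

    The fit subset is genes with mean >= ``min_mean_for_fit``; when the
    threshold is not given it defaults to the ``fit_quantile`` quantile of
    means among genes whose CV2 exceeds ``cv2_floor`` (lowly expressed and
    near-deterministic genes would otherwise drag the trend down). Falls back
    to ordinary least squares on (CV2, 1/mu), with a warning, if the IRLS
    fit fails to converge.
    """
    means = pd.Series(np.asarray(means, dtype=float)) if not isinstance(means, pd.Series) else means.astype(float)
    cv2s = pd.Series(np.asarray(cv2s, dtype=float), index=means.index) if not isinstance(cv2s, pd.Series) else cv2s.astype(float)
    cv2s = cv2s.reindex(means.index)
    ok = means.notna() & cv2s.notna() & (means > 0) & (cv2s > 0)
    means, cv2s = means[ok], cv2s[ok]

    if min_mean_for_fit is None:
        candidates = means[cv2s > cv2_floor]
        if candidates.empty:
            candidates = means
        min_mean_for_fit = float(np.quantile(candidates, fit_quantile))
    subset = means >= min_mean_for_fit
    mu = means[subset].to_numpy()
    y = cv2s[subset].to_numpy()

    if mu.size < MIN_FIT_GENES:
        raise ValueError(
            f"only {mu.size} genes in the trend fit subset (need >= {MIN_FIT_GENES})"
        )
    if np.unique(mu).size < 2:
        raise ValueError("all fit-subset means are equal: trend is unidentifiable")

    inv_mu = 1.0 / mu
    method, converged = "glmgam", True
    try:
        a0, a1, converged = _gamma_glm(y, inv_mu, max_iter, tol)
        if not converged or not np.isfinite(a0) or not np.isfinite(a1):
            raise RuntimeError("gamma GLM did not converge")
    except Exception as err:  # pragma: no cover - exercised via fallback test
        warnings.warn(f"gamma GLM failed ({err}); falling back to OLS on (CV2, 1/mu)")
        X = np.column_stack([np.ones_like(inv_mu), inv_mu])
        (a0, a1), *_ = np.linalg.lstsq(X, y, rcond=None)
        method, converged = "ols", True

    return TrendFit(
        a0=float(a0),
        a1=float(a1),
        fit_gene_ids=means.index[subset],
        min_mean_for_fit=float(min_mean_for_fit),
        method=method,
        converged=converged,
    )


def corrected_cv2(cv2, mu, fit: TrendFit):
    """log2(CV2 / trend(mu)): variability relative to the expression trend.

    Positive = more variable than same-expression genes. Non-positive CV2
    yields NaN with a warning (never -inf).
    """
    cv2 = np.asarray(cv2, dtype=float)
    mu = np.asarray(mu, dtype=float)
    t = fit.trend(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(cv2 / t)
    bad = ~(cv2 > 0) | ~(t > 0)
    n_bad = int(np.sum(bad & np.isfinite(np.broadcast_to(mu, out.shape))))
    if np.any(bad):
        warnings.warn(f"{int(np.sum(bad))} value(s) with non-positive CV2 or trend: NaN returned")
        out = np.where(bad, np.nan, out)
    return out if out.ndim else float(out)


def test_hvg(mu, cv2, m: int, fit: TrendFit, min_biol_cv: float = 0.10):
    """Upper-tail chi-square p-value for CV2 exceeding the trend.

    Tests whether a gene's biological CV significantly exceeds
    ``min_biol_cv`` (10% by default) on top of the fitted trend, with m
    individuals. A non-positive test denominator signals a pathological fit;
    those genes get NaN and a warning.
    """
    if m < 2:
        raise ValueError("need at least 2 individuals")
    mu = np.asarray(mu, dtype=float)
    cv2 = np.asarray(cv2, dtype=float)
    min_biol_disp = min_biol_cv**2
    cv2th = fit.a0 + min_biol_disp + fit.a0 * min_biol_disp
    denom = (mu * fit.a1 + mu**2 * cv2th) / (1.0 + cv2th / m)
    bad = ~(denom > 0)
    if np.any(bad):
        warnings.warn(f"{int(np.sum(bad))} gene(s) with non-positive test denominator: excluded")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (m - 1) * mu**2 * cv2 / denom
    p = stats.chi2.sf(stat, df=m - 1)
    p = np.where(bad | ~np.isfinite(stat), np.nan, p)
    return p if p.ndim else float(p)


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values (NaNs preserved)."""
    arr = np.asarray(pvalues, dtype=float)
    flat = arr.ravel()
    mask = np.isfinite(flat)
    if np.any((flat[mask] < 0) | (flat[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(flat.shape, np.nan)
    if mask.any():
        out[mask] = multipletests(flat[mask], method="fdr_bh")[1]
    out = out.reshape(arr.shape)
    if isinstance(pvalues, pd.Series):
        return pd.Series(out, index=pvalues.index)
    return out


def variability_table(
    matrix: ExpressionMatrix,
    genes=None,
    fit: TrendFit | None = None,
    *,
    min_biol_cv: float = 0.10,
    fdr: float = 0.10,
    fit_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, TrendFit]:
    """Full per-gene variability table for one time-point.

    Computes mean and CV2 per gene (restricted to ``genes`` when given —
    typically the filter-passing set), fits the trend unless one is supplied,
    and derives corrected CV2, test p, BH-adjusted p and the HVG flag.
    """
    if matrix.unit != "tpm":
        raise ValueError("variability_table expects a TPM matrix")
    base = cv2_table(matrix, genes)
    if fit is None:
        fit = fit_cv2_trend(base["mean_tpm"], base["cv2"], **(fit_kwargs or {}))
    m = matrix.n_samples
    trend = fit.trend(base["mean_tpm"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ccv2 = corrected_cv2(base["cv2"].to_numpy(), base["mean_tpm"].to_numpy(), fit)
        p = test_hvg(base["mean_tpm"].to_numpy(), base["cv2"].to_numpy(), m, fit, min_biol_cv)
    table = base.copy()
    table["trend"] = trend
    table["corrected_cv2"] = ccv2
    table["p"] = p
    table["p_adj"] = bh_adjust(table["p"])
    table["is_hvg"] = table["p_adj"] < fdr
    table.attrs.update(
        timepoint=matrix.timepoint, m=m, min_biol_cv=min_biol_cv, fdr=fdr, trend_fit=fit.to_dict()
    )
    return table, fit


def select_hvg(table: pd.DataFrame, fdr: float = 0.10) -> list[str]:
    """Genes whose BH-adjusted p is strictly below the FDR threshold."""
    hits = table.index[table["p_adj"] < fdr]
    return sorted(hits)


def select_lvg(table: pd.DataFrame, n: int = 1000) -> list[str]:
    """The n genes with the smallest corrected CV2 (ties broken by gene ID)."""
    ranked = (
        table.dropna(subset=["corrected_cv2"])
        .rename_axis("gene_id")
        .reset_index()
        .sort_values(["corrected_cv2", "gene_id"], kind="mergesort")
    )
    return list(ranked["gene_id"].iloc[:n])


def sample_random_sets(universe, size: int, n_sets: int = 1000, seed=None) -> list[list[str]]:
    """n_sets simple random gene samples (without replacement within a set).

    Size-matched random sets provide the empirical null envelope against
    which HVG feature distributions are compared.
    """
    universe = np.asarray(sorted(universe))
    if size > universe.size:
        raise ValueError(f"requested set size {size} exceeds universe of {universe.size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [list(rng.choice(universe, size=size, replace=False)) for _ in range(n_sets)]


class HVGDetector(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector flagging highly variable genes.

    Samples are individuals, features are genes (TPM). ``fit`` computes
    per-gene mean and CV2, fits the CV2-mean trend and runs the chi-square
    overdispersion test; the support mask marks genes called highly variable
    at the configured FDR. ``transform`` therefore restricts a matrix to its
    HVGs, composing with sklearn pipelines.

    Attributes (after fit): ``a0_``, ``a1_``, ``trend_fit_``, ``means_``,
    ``cv2_``, ``corrected_cv2_``, ``pvalues_``, ``pvalues_adj_``,
    ``support_``.
    """

    def __init__(
        self,
        fdr: float = 0.10,
        min_biol_cv: float = 0.10,
        fit_quantile: float = 0.4,
        cv2_floor: float = 0.05,
        min_mean_for_fit: float | None = None,
    ):
        self.fdr = fdr
        self.min_biol_cv = min_biol_cv
        self.fit_quantile = fit_quantile
        self.cv2_floor = cv2_floor
        self.min_mean_for_fit = min_mean_for_fit

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=2, dtype=float)
        if np.any(X < 0):
            raise ValueError("expression values must be non-negative")
        m = X.shape[0]
        means = X.mean(axis=0)
        var = X.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv2 = var / means**2
        cv2 = np.where(means > 0, cv2, np.nan)
        self.trend_fit_ = fit_cv2_trend(
            means,
            cv2,
            min_mean_for_fit=self.min_mean_for_fit,
            fit_quantile=self.fit_quantile,
            cv2_floor=self.cv2_floor,
        )
        self.a0_ = self.trend_fit_.a0
        self.a1_ = self.trend_fit_.a1
        self.means_ = means
        self.cv2_ = cv2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.corrected_cv2_ = corrected_cv2(cv2, means, self.trend_fit_)
            self.pvalues_ = test_hvg(means, cv2, m, self.trend_fit_, self.min_biol_cv)
        self.pvalues_adj_ = bh_adjust(self.pvalues_)
        with np.errstate(invalid="ignore"):
            self.support_ = np.nan_to_num(self.pvalues_adj_, nan=np.inf) < self.fdr
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
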