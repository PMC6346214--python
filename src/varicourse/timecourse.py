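"""Time-course assembly: HVG sharing, variability-profile clustering,
expression-variability coupling and seedling-subsampling saturation.

Per-time-point variability tables are assembled into genes x time-points
matrices of corrected CV2 and boolean HVG/LVG membership. On top of these:

* the distribution of the number of time-points at which a gene is called
  highly variable;
* the percentage of HVGs shared between any two time-points, summarised as
  within-day / within-night / day-night block averages (ZT12, harvested
  minutes before dusk, behaves like a night time-point and is excluded from
  the day/night blocks by default);
* hierarchical clustering of corrected-CV2 profiles with distance
  1 - Pearson correlation (complete linkage, four clusters by default),
  separating day-variable, night-variable and always-variable genes;
* per-gene correlation between the mean-normalised expression profile and
  the corrected-CV2 profile, partitioned at p <= 0.05;
* subsampling saturation: how well corrected CV2 from k of M individuals
  reproduces the full-M ranking (the analysis that justifies using 14
  seedlings per time-point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import hvg as hvgmod
from .quantify import ExpressionMatrix, filter_genes

__all__ = [
    "TimeCourseVariability",
    "assemble",
    "default_phases",
    "timepoint_count_distribution",
    "pairwise_sharing",
    "day_night_summary",
    "cluster_profiles",
    "profile_correlation",
    "subsample_stability",
]


def default_phases(timepoints: Sequence[str]) -> tuple[pd.Series, str | None]:
    """Day/night tags (first half day, second half night) and the dusk label.

    The last day time-point (ZT12 analogue) is tagged as dusk: it is still a
    light sample but shares most of its HVGs with the night.
    """
    n = len(timepoints)
    half = n // 2
    tags = ["day" if i < half else "night" for i in range(n)]
    dusk = timepoints[half - 1] if half >= 1 and n >= 4 else None
    return pd.Series(tags, index=list(timepoints)), dusk


@dataclass
class TimeCourseVariability:
    """Gene x time-point variability structures for one time course."""

    corrected_cv2: pd.DataFrame
    hvg: pd.DataFrame  # bool
    lvg: pd.DataFrame  # bool
    phases: pd.Series
    dusk: str | None = None

    def __post_init__(self) -> None:
        for name in ("hvg", "lvg"):
            mat = getattr(self, name)
            if mat.shape != self.corrected_cv2.shape:
                raise ValueError(f"{name} membership shape mismatch")

    @property
    def timepoints(self) -> list[str]:
        return list(self.corrected_cv2.columns)

    def union_hvgs(self) -> list[str]:
        return sorted(self.hvg.index[self.hvg.any(axis=1)])

    def union_lvgs(self) -> list[str]:
        return sorted(self.lvg.index[self.lvg.any(axis=1)])


def assemble(
    tables: Mapping[str, pd.DataFrame],
    n_lvg: int = 1000,
    phases: pd.Series | None = None,
    dusk: str | None = None,
) -> TimeCourseVariability:
    """Build the time-course structures from per-time-point tables."""
    timepoints = list(tables)
    ccv2 = pd.concat({tp: t["corrected_cv2"] for tp, t in tables.items()}, axis=1)
    ccv2.columns = timepoints
    hvg = pd.concat({tp: t["is_hvg"] for tp, t in tables.items()}, axis=1)
    hvg.columns = timepoints
    hvg = hvg.astype("boolean").fillna(False).astype(bool)
    lvg = pd.DataFrame(False, index=ccv2.index, columns=timepoints)
    for tp, t in tables.items():
        lvg.loc[hvgmod.select_lvg(t, n=n_lvg), tp] = True
    if phases is None:
        phases, default_dusk = default_phases(timepoints)
        dusk = dusk if dusk is not None else default_dusk
    return TimeCourseVariability(ccv2, hvg, lvg, phases, dusk)


def timepoint_count_distribution(membership: pd.DataFrame) -> pd.Series:
    """Histogram of the number of time-points at which each member gene appears.

    Indexed 1..n_timepoints; sums to the union-set size.
    """
    counts = membership.sum(axis=1)
    counts = counts[counts > 0]
    n = membership.shape[1]
    hist = counts.value_counts().reindex(range(1, n + 1), fill_value=0)
    hist.index.name = "n_timepoints"
    return hist.astype(int)


def pairwise_sharing(membership: pd.DataFrame, method: str = "conditional") -> pd.DataFrame:
    """Time-point x time-point percentage of shared member genes.

    ``conditional`` (default): cell (i, j) = 100 * |S_i & S_j| / |S_i|, an
    asymmetric, row-conditioned sharing; ``jaccard`` uses the union in the
    denominator. Diagonal is 100. Time-points with an empty set get a NaN
    row with a warning.
    """
    if membership.shape[1] < 2:
        raise ValueError("need at least 2 time-points")
    sets = {tp: set(membership.index[membership[tp]]) for tp in membership.columns}
    tps = list(membership.columns)
    out = pd.DataFrame(np.nan, index=tps, columns=tps)
    empty = [tp for tp, s in sets.items() if not s]
    if empty:
        warnings.warn(f"time-point(s) with no member genes: {empty}")
    for i in tps:
        if not sets[i]:
            continue
        for j in tps:
            inter = len(sets[i] & sets[j])
            if method == "conditional":
                out.loc[i, j] = 100.0 * inter / len(sets[i])
            elif method == "jaccard":
                union = len(sets[i] | sets[j])
                out.loc[i, j] = 100.0 * inter / union if union else np.nan
            else:
                raise ValueError(f"unknown sharing method {method!r}")
    return out


def day_night_summary(
    sharing: pd.DataFrame,
    phases: pd.Series,
    exclude: Sequence[str] = (),
) -> dict[str, float]:
    """Mean off-diagonal sharing within day, within night and between phases.

    ``exclude`` drops time-points (typically the dusk ZT12 analogue) before
    averaging. Averages run over ordered pairs, so the asymmetric
    conditional sharing is effectively symmetrised.
    """
    keep = [tp for tp in sharing.index if tp not in set(exclude)]
    day = [tp for tp in keep if phases.get(tp) == "day"]
    night = [tp for tp in keep if phases.get(tp) == "night"]
    if len(day) < 2 or len(night) < 2:
        raise ValueError("need at least 2 day and 2 night time-points")

    def block_mean(rows, cols, off_diagonal: bool) -> float:
        vals = []
        for i in rows:
            for j in cols:
                if off_diagonal and i == j:
                    continue
                vals.append(sharing.loc[i, j])
        return float(np.nanmean(vals))

    return {
        "within_day": block_mean(day, day, True),
        "within_night": block_mean(night, night, True),
        "between": block_mean(day, night, False),
    }


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = 4,
    linkage_method: str = "complete",
) -> tuple[pd.Series, np.ndarray]:
    """Hierarchical clustering of variability profiles.

    Distance is 1 - Pearson correlation between corrected-CV2 profiles,
    agglomerated with the requested linkage (complete by default) and cut
    into k clusters. Constant or incomplete profiles cannot be correlated;
    they get a missing label and a warning.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    valid = profiles.dropna(axis=0)
    valid = valid[valid.std(axis=1) > 0]
    dropped = profiles.index.difference(valid.index)
    if len(dropped):
        warnings.warn(f"{len(dropped)} constant/incomplete profile(s) left unlabelled")
    if k > len(valid):
        raise ValueError(f"k={k} exceeds the {len(valid)} clusterable profiles")

    corr = np.corrcoef(valid.to_numpy())
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = hierarchy.linkage(squareform(np.clip(dist, 0.0, None), checks=False), method=linkage_method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(np.nan, index=profiles.index, dtype="float")
    labels.loc[valid.index] = flat
    return labels, Z


def profile_correlation(
    expression: pd.DataFrame,
    variability: pd.DataFrame,
    method: str = "spearman",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene correlation of expression and variability profiles.

    Both inputs are genes x time-points (mean-normalised expression and
    corrected CV2). Genes are partitioned into significant-positive /
    significant-negative / non-significant at ``alpha`` (p <= alpha);
    constant or incomplete profiles give an undefined correlation.
    """
    genes = expression.index.intersection(variability.index)
    cols = expression.columns.intersection(variability.columns)
    if len(cols) < 3:
        raise ValueError("need at least 3 shared time-points")
    rows = []
    for g in genes:
        x = expression.loc[g, cols].to_numpy(dtype=float)
        y = variability.loc[g, cols].to_numpy(dtype=float)
        if (
            np.any(~np.isfinite(x))
            or np.any(~np.isfinite(y))
            or np.std(x) == 0
            or np.std(y) == 0
        ):
            rows.append((g, np.nan, np.nan, "undefined"))
            continue
        if method == "spearman":
            r, p = stats.spearmanr(x, y)
        elif method == "pearson":
            r, p = stats.pearsonr(x, y)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        if p <= alpha:
            cat = "positive" if r > 0 else "negative"
        else:
            cat = "ns"
        rows.append((g, float(r), float(p), cat))
    return pd.DataFrame(rows, columns=["gene_id", "r", "p", "category"]).set_index("gene_id")


def _corrected_profile(
    matrix: ExpressionMatrix,
    *,
    fit_kwargs: dict | None = None,
    filter_kwargs: dict | None = None,
) -> pd.Series:
    """Filter -> trend fit -> corrected CV2 for one (possibly subset) matrix."""
    report = filter_genes({matrix.timepoint: matrix}, matrix.timepoint, **(filter_kwargs or {}))
    table, _ = hvgmod.variability_table(matrix, genes=report.retained, fit_kwargs=fit_kwargs)
    return table["corrected_cv2"].dropna()


def subsample_stability(
    matrix: ExpressionMatrix,
    subset_sizes: Sequence[int],
    n_draws: int = 20,
    seed: int | None = None,
    *,
    method: str = "spearman",
    fit_kwargs: dict | None = None,
    filter_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Corrected-CV2 stability under individual subsampling.

    For each subset size k, draws ``n_draws`` random k-individual subsets,
    reruns the filter -> trend -> corrected CV2 pipeline on each, and reports
    the mean rank correlation with the full-matrix corrected CV2 over the
    genes retained in both runs. A subset equal to the full matrix gives
    correlation 1 by construction.
    """
    if matrix.unit != "tpm":
        raise ValueError("subsample_stability expects a TPM matrix")
    M = matrix.n_samples
    if any(k < 2 for k in subset_sizes):
        raise ValueError("subset sizes must be at least 2")
    if any(k > M for k in subset_sizes):
        raise ValueError("subset size exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    full = _corrected_profile(matrix, fit_kwargs=fit_kwargs, filter_kwargs=filter_kwargs)

    rows = []
    for k in subset_sizes:
        corrs = []
        for _ in range(n_draws):
            cols = rng.choice(M, size=k, replace=False)
            sub = matrix.subset_samples(matrix.sample_ids[np.sort(cols)])
            part = _corrected_profile(sub, fit_kwargs=fit_kwargs, filter_kwargs=filter_kwargs)
            shared = full.index.intersection(part.index)
            if len(shared) < 3:
                corrs.append(np.nan)
                continue
            if method == "spearman":
                r, _ = stats.spearmanr(full.loc[shared], part.loc[shared])
            else:
                r, _ = stats.pearsonr(full.loc[shared], part.loc[shared])
            corrs.append(float(r))
        rows.append((k, float(np.nanmean(corrs)), len(corrs)))
    return pd.DataFrame(rows, columns=["subset_size", "mean_correlation", "n_draws"]).set_index(
        "subset_size"
    )
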