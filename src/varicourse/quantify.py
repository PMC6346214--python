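"""Expression quantification, gene filtering and normalisation.

The unit of analysis is an :class:`ExpressionMatrix`: one genes x individuals
table for a single time-point, carrying either raw counts or TPM
(transcripts per million, which corrects for gene length and library size).
All downstream variability statistics are computed on TPM.

Gene filtering applies four rules before any variability statistic is
computed, so that lowly expressed and very short genes — whose apparent
variability is dominated by technical noise — never enter the trend fit or
the overdispersion test:

(i)   mean TPM across *all* loaded samples (every time-point) >= 5;
(ii)  gene length >= 150 bp;
(iii) TPM of 0 in fewer than 5 individuals at the analysed time-point;
(iv)  mean TPM at the analysed time-point >= 5.

Rule (i) is computed over whatever samples are loaded, so partial runs are
explicit rather than silently different.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FilterReport",
    "compute_tpm",
    "filter_genes",
    "mean_normalize",
    "compute_cv2",
    "cv2_table",
]

_VALID_UNITS = ("counts", "tpm")


@dataclass
class ExpressionMatrix:
    """Genes x individuals expression table for one time-point.

    Parameters
    ----------
    values
        DataFrame with gene IDs as index and sample IDs as columns.
        Non-negative; counts may be fractional (multi-mapped reads).
    unit
        ``"counts"`` or ``"tpm"``.
    timepoint
        Time-point label, e.g. ``"ZT2"``.
    gene_lengths
        Per-gene length in bp; required to convert counts to TPM.
    """

    values: pd.DataFrame
    unit: str
    timepoint: str | None = None
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unit must be one of {_VALID_UNITS}, got {self.unit!r}")
        if not self.values.index.is_unique:
            raise ValueError("gene IDs are not unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample IDs are not unique")
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError("expression values must be non-negative")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        lengths = None if self.gene_lengths is None else self.gene_lengths.loc[genes]
        return ExpressionMatrix(self.values.loc[genes], self.unit, self.timepoint, lengths)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(samples)], self.unit, self.timepoint, self.gene_lengths
        )


RULE_NAMES = (
    "min_global_mean",
    "min_length",
    "max_zero_individuals",
    "min_timepoint_mean",
)


@dataclass
class FilterReport:
    """Per-gene pass/fail for each of the four filtering rules."""

    table: pd.DataFrame  # boolean columns RULE_NAMES + "pass_all"
    timepoint: str | None = None
    thresholds: dict = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["pass_all"]])

    @property
    def counts(self) -> pd.Series:
        """Number of genes removed by each rule (a gene may fail several)."""
        removed = {rule: int((~self.table[rule]).sum()) for rule in RULE_NAMES}
        removed["retained"] = int(self.table["pass_all"].sum())
        removed["total"] = int(len(self.table))
        return pd.Series(removed)


def compute_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a count matrix to TPM.

    ``rate_g = counts_g / length_g``; ``TPM_g = 1e6 * rate_g / sum_g rate_g``
    per sample. Every sample column sums to 1e6 (all-zero columns stay zero,
    with a warning).
    """
    if matrix.unit != "counts":
        raise ValueError("compute_tpm expects a matrix in counts")
    if matrix.gene_lengths is None:
        raise ValueError("gene lengths are required to compute TPM")
    lengths = matrix.gene_lengths
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene length for {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be strictly positive")

    rate = matrix.values.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} sample(s) have zero total counts; TPM left at 0"
        )
        colsum = colsum.replace(0, np.nan)
    tpm = rate.div(colsum, axis=1).fillna(0.0) * 1e6
    return ExpressionMatrix(tpm, "tpm", matrix.timepoint, matrix.gene_lengths)


def filter_genes(
    matrices: Mapping[str, ExpressionMatrix] | Sequence[ExpressionMatrix],
    timepoint: str,
    gene_lengths: pd.Series | None = None,
    *,
    min_mean_tpm: float = 5.0,
    min_length_bp: float = 150.0,
    max_zero_individuals: int = 5,
    min_timepoint_mean_tpm: float = 5.0,
) -> FilterReport:
    """Apply the four-rule gene filter for one time-point.

    ``matrices`` holds the TPM matrices of the full time course (used for the
    global-mean rule); ``timepoint`` selects the analysed one. Thresholds are
    inclusive for the means (">= 5 TPM") and the length (">= 150 bp"), and the
    zero-count rule is strict ("fewer than 5 individuals at 0").
    """
    if not isinstance(matrices, Mapping):
        matrices = {m.timepoint: m for m in matrices}
    if timepoint not in matrices:
        raise KeyError(f"time-point {timepoint!r} not among loaded matrices")
    for tp, m in matrices.items():
        if m.unit != "tpm":
            raise ValueError(f"matrix for {tp!r} is not in TPM")

    target = matrices[timepoint]
    if gene_lengths is None:
        gene_lengths = target.gene_lengths
    if gene_lengths is None:
        raise ValueError("gene lengths are required for the length rule")
    gene_lengths = gene_lengths.reindex(target.gene_ids)

    all_values = pd.concat([m.values.reindex(target.gene_ids) for m in matrices.values()], axis=1)
    global_mean = all_values.mean(axis=1)
    tp_values = target.values
    tp_mean = tp_values.mean(axis=1)
    n_zero = (tp_values == 0).sum(axis=1)

    table = pd.DataFrame(
        {
            "min_global_mean": global_mean >= min_mean_tpm,
            "min_length": gene_lengths.fillna(0) >= min_length_bp,
            "max_zero_individuals": n_zero < max_zero_individuals,
            "min_timepoint_mean": tp_mean >= min_timepoint_mean_tpm,
        },
        index=target.gene_ids,
    )
    table["pass_all"] = table[list(RULE_NAMES)].all(axis=1)
    return FilterReport(
        table,
        timepoint=timepoint,
        thresholds={
            "min_mean_tpm": min_mean_tpm,
            "min_length_bp": min_length_bp,
            "max_zero_individuals": max_zero_individuals,
            "min_timepoint_mean_tpm": min_timepoint_mean_tpm,
        },
    )


def mean_normalize(profiles: pd.DataFrame | pd.Series):
    """Divide each gene's time-course profile by its mean across time-points.

    The normalised profile has mean 1. Genes with a zero (or all-missing)
    time-course average yield an all-NaN profile with a warning, not an
    exception.
    """
    if isinstance(profiles, pd.Series):
        out = mean_normalize(profiles.to_frame().T)
        return out.iloc[0]
    avg = profiles.mean(axis=1)
    bad = ~(avg > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) have zero time-course average; profile set to NaN"
        )
    safe = avg.where(~bad)
    return profiles.div(safe, axis=0)


def compute_cv2(values: Iterable[float]) -> tuple[float, float]:
    """Mean and squared coefficient of variation of one gene at one time-point.

    CV2 = s^2 / mu^2 with the unbiased (n-1) sample variance; invariant to
    rescaling all values by a common positive factor.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector of per-individual values")
    if arr.size < 2:
        raise ValueError("at least 2 individuals are required to compute CV2")
    mu = arr.mean()
    if mu <= 0:
        raise ValueError("CV2 undefined for non-positive mean expression")
    var = arr.var(ddof=1)
    return float(mu), float(var / mu**2)


def cv2_table(matrix: ExpressionMatrix, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene mean and CV2 for one time-point matrix.

    Genes with non-positive mean get NaN CV2 (recorded, not raised), so a
    filtered matrix never aborts on a degenerate row.
    """
    values = matrix.values if genes is None else matrix.values.loc[list(genes)]
    if values.shape[1] < 2:
        raise ValueError("at least 2 individuals are required to compute CV2")
    mu = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = var / mu**2
    cv2 = cv2.where(mu > 0)
    n_bad = int((~(mu > 0)).sum())
    if n_bad:
        warnings.warn(f"{n_bad} gene(s) with non-positive mean: CV2 set to NaN")
    return pd.DataFrame({"mean_tpm": mu, "cv2": cv2})
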