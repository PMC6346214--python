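"""Feature and annotation-set enrichment for HVG/LVG/random gene sets.

Compares gene sets (highly variable, lowly variable, size-matched random)
on quantitative features (gene length, intron count, number of targeting
TFs, tissue-specificity entropy) and on set memberships (per-TF target
lists, chromatin-mark gene lists, functional categories):

* Wilcoxon rank-sum for feature shifts, with an empirical envelope from the
  random sets;
* one-sided hypergeometric overrepresentation with BH across a batch of
  sets (the TF-target and functional-category test);
* Fisher's exact test for TF-family composition of the enriched-TF list;
* chi-square (Yates-corrected 2x2, mirroring R's chisq.test default) for
  chromatin-mark presence proportions, with the random-set 95% interval;
* Shannon entropy of relative expression across tissues (bits; low =
  tissue-restricted);
* the in-silico fragmentation control: splitting long genes into ~250-300 bp
  fragments with multinomial count reallocation and re-testing, to check
  that gene length does not artifactually drive HVG calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import hvg as hvgmod
from .quantify import ExpressionMatrix, compute_tpm, filter_genes

__all__ = [
    "compare_feature",
    "count_tf_per_gene",
    "set_overrepresentation",
    "family_enrichment",
    "presence_enrichment",
    "shannon_entropy",
    "tissue_specificity_entropy",
    "matched_size_subset",
    "fragment_gene",
    "fragmentation_control",
]


@dataclass
class FeatureComparison:
    statistic: float
    p: float
    median_a: float
    median_b: float
    envelope: tuple[float, float] | None = None  # 95% interval of random-set medians


def compare_feature(
    feature: pd.Series,
    set_a: Iterable[str],
    set_b: Iterable[str],
    random_sets: Sequence[Iterable[str]] | None = None,
) -> FeatureComparison:
    """Two-sided Wilcoxon rank-sum comparison of a feature between two sets.

    Exact p for small samples (scipy's exact Mann-Whitney path), normal
    approximation otherwise. When random sets are given, their medians form
    a percentile 95% envelope for the feature.
    """
    a = feature.reindex(list(set_a)).dropna().to_numpy()
    b = feature.reindex(list(set_b)).dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("both sets need at least one gene with a feature value")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    envelope = None
    if random_sets is not None:
        medians = [float(feature.reindex(list(s)).dropna().median()) for s in random_sets]
        envelope = (float(np.percentile(medians, 2.5)), float(np.percentile(medians, 97.5)))
    return FeatureComparison(
        float(stat), float(p), float(np.median(a)), float(np.median(b)), envelope
    )


def count_tf_per_gene(tf_targets: Mapping[str, Iterable[str]], universe: Iterable[str]) -> pd.Series:
    """Number of TFs whose target list contains each universe gene."""
    universe = list(universe)
    uni = set(universe)
    counts = pd.Series(0, index=pd.Index(universe, name="gene_id"), dtype=int)
    outside = set()
    for tf, targets in tf_targets.items():
        targets = set(targets)
        outside |= targets - uni
        hits = sorted(targets & uni)
        counts.loc[hits] += 1
    if outside:
        warnings.warn(f"{len(outside)} target gene(s) outside the universe ignored")
    return counts


def set_overrepresentation(
    query: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of each set in the query.

    p = P(overlap >= observed) drawing |query| genes from the universe;
    BH-adjusted across the batch. Fold is observed/expected overlap.
    """
    universe = set(universe)
    query = set(query) & universe
    if not universe or not query:
        raise ValueError("universe and query must be non-empty")
    N, n = len(universe), len(query)
    rows = []
    for name, s in sets.items():
        s = set(s) & universe
        K = len(s)
        k = len(s & query)
        expected = n * K / N
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        fold = k / expected if expected > 0 else np.nan
        rows.append((name, k, expected, fold, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "expected", "fold", "p"]).set_index(
        "set_name"
    )
    out["p_adj"] = hvgmod.bh_adjust(out["p"])
    return out


def family_enrichment(
    hit_tfs: Iterable[str],
    tf_families: Mapping[str, str],
) -> pd.DataFrame:
    """Fisher's exact test for TF-family composition of a hit list.

    For each family the 2x2 table is [in-family hits, in-family non-hits;
    out-family hits, out-family non-hits] against all catalogued TFs.
    """
    hits = set(hit_tfs)
    unlabeled = hits - set(tf_families)
    if unlabeled:
        raise ValueError(f"TF(s) without a family label: {sorted(unlabeled)[:5]}")
    all_tfs = set(tf_families)
    rows = []
    for family in sorted(set(tf_families.values())):
        fam = {tf for tf, f in tf_families.items() if f == family}
        a = len(fam & hits)
        b = len(fam - hits)
        c = len(hits - fam)
        d = len(all_tfs - fam - hits)
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((family, len(fam), a, float(odds), float(p)))
    return pd.DataFrame(
        rows, columns=["family", "n_tfs", "n_hits", "odds_ratio", "p"]
    ).set_index("family")


@dataclass
class PresenceEnrichment:
    prop_query: float
    prop_universe: float
    statistic: float
    p: float
    test: str  # "chi2" or "fisher"
    ci_low: float
    ci_high: float


def presence_enrichment(
    query: Iterable[str],
    mark_set: Iterable[str],
    universe: Iterable[str],
    random_sets: Sequence[Iterable[str]],
    *,
    yates: bool = True,
) -> PresenceEnrichment:
    """Proportion of marked genes in a query set vs the gene universe.

    Chi-square test (Yates continuity correction by default) of the 2x2
    query/non-query x marked/unmarked table; falls back to Fisher's exact
    test when an expected cell drops below 1. The 2.5-97.5 percentile
    interval of the marked proportion across the random sets gives the
    empirical null band.
    """
    universe = set(universe)
    query = set(query) & universe
    marked = set(mark_set) & universe
    if not query or not random_sets:
        raise ValueError("query and random_sets must be non-empty")
    rest = universe - query
    a = len(query & marked)
    b = len(query - marked)
    c = len(rest & marked)
    d = len(rest - marked)
    prop_query = a / len(query)
    prop_universe = len(marked) / len(universe)
    table = np.array([[a, b], [c, d]], dtype=float)
    if rest:
        expected = stats.contingency.expected_freq(table)
        if expected.min() < 1:
            stat, p = stats.fisher_exact(table.astype(int))
            test = "fisher"
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
            test = "chi2"
    else:
        stat, p, test = np.nan, 1.0, "degenerate"
    props = [len(set(s) & marked) / max(len(set(s)), 1) for s in random_sets]
    return PresenceEnrichment(
        float(prop_query),
        float(prop_universe),
        float(stat),
        float(p),
        test,
        float(np.percentile(props, 2.5)),
        float(np.percentile(props, 97.5)),
    )


def shannon_entropy(tissue_expression: Iterable[float]) -> float:
    """Shannon entropy (bits) of a gene's relative expression over tissues.

    H = -sum p_t log2 p_t with p_t the tissue share of total expression;
    zero-expression tissues contribute 0 via the p log p -> 0 limit. Bounded
    by log2(n_tissues) (uniform) with 0 = single-tissue. All-zero genes are
    filtered out of the analysis: NaN with a warning.
    """
    x = np.asarray(list(tissue_expression), dtype=float)
    if np.any(x < 0):
        raise ValueError("tissue expression must be non-negative")
    total = x.sum()
    if total <= 0:
        warnings.warn("gene with no expression in any tissue: entropy undefined")
        return float("nan")
    p = x / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def tissue_specificity_entropy(table: pd.DataFrame) -> pd.Series:
    """Per-gene Shannon entropy for a tissues x genes expression table."""
    totals = table.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = table.div(totals, axis=1)
        logp = np.log2(p.where(p > 0))
    H = -(p * logp).sum(axis=0, min_count=1)
    H = H.where(totals > 0)
    n_bad = int((~(totals > 0)).sum())
    if n_bad:
        warnings.warn(f"{n_bad} gene(s) with no expression in any tissue: entropy NaN")
    H.name = "entropy_bits"
    return H


def matched_size_subset(
    sets: Mapping[str, Iterable[str]],
    lengths: pd.Series,
    window: tuple[float, float] = (1100.0, 1400.0),
) -> dict[str, list[str]]:
    """Restrict each gene set to genes within a length window.

    Size-matched subsets decouple length from the other features when
    comparing HVGs, LVGs and random genes (default window 1100-1400 bp).
    """
    lo, hi = window
    out = {}
    for name, s in sets.items():
        sub = [g for g in s if g in lengths.index and lo <= lengths.loc[g] <= hi]
        if not sub:
            warnings.warn(f"size-matched subset of {name!r} is empty")
        out[name] = sorted(sub)
    return out


def fragment_gene(
    length: int,
    rng: np.random.Generator,
    frag_range: tuple[int, int] = (250, 300),
) -> list[int]:
    """Partition a gene into contiguous fragments with in-range lengths.

    Fragment lengths are drawn uniformly in ``frag_range``; the final
    fragment absorbs any remainder shorter than the minimum, so every
    fragment is at least ``frag_range[0]`` bp.
    """
    lo, hi = frag_range
    if length < 2 * lo:
        raise ValueError(f"gene of {length} bp too short to fragment at >= {lo} bp")
    frags: list[int] = []
    rem = int(length)
    while rem > hi:
        step = int(rng.integers(lo, hi + 1))
        if rem - step < lo:
            frags.append(rem)
            rem = 0
            break
        frags.append(step)
        rem -= step
    if rem:
        frags.append(rem)
    return frags


@dataclass
class FragmentationResult:
    table: pd.DataFrame  # per-fragment statistics and concordance
    concordance: float  # fraction of fragments matching the parent HVG status


def fragmentation_control(
    counts: ExpressionMatrix,
    genes: Sequence[str],
    *,
    frag_range: tuple[int, int] = (250, 300),
    seed: int | None = None,
    fdr: float = 0.10,
    min_biol_cv: float = 0.10,
    fit_kwargs: dict | None = None,
    filter_kwargs: dict | None = None,
) -> FragmentationResult:
    """In-silico fragmentation robustness control.

    Each selected gene is partitioned into ~250-300 bp fragments and every
    individual's count is split multinomially across fragments with
    probabilities proportional to fragment length (so counts are conserved
    exactly). The fragmented matrix is pushed through the full TPM ->
    filter -> trend -> HVG pipeline and each fragment's HVG status is
    compared with its parent's from the unfragmented run.
    """
    if counts.unit != "counts":
        raise ValueError("fragmentation operates on a counts matrix")
    if counts.gene_lengths is None:
        raise ValueError("gene lengths required")
    rng = np.random.default_rng(seed)

    def analyze(mat: ExpressionMatrix) -> pd.DataFrame:
        tpm = compute_tpm(mat)
        report = filter_genes({tpm.timepoint: tpm}, tpm.timepoint, **(filter_kwargs or {}))
        table, _ = hvgmod.variability_table(
            tpm, genes=report.retained, fdr=fdr, min_biol_cv=min_biol_cv, fit_kwargs=fit_kwargs
        )
        return table

    parent_table = analyze(counts)

    new_rows = {}
    new_lengths = {}
    parents = {}
    for g in genes:
        if g not in counts.gene_ids:
            raise KeyError(f"gene {g!r} not in matrix")
        L = int(counts.gene_lengths.loc[g])
        frag_lens = fragment_gene(L, rng, frag_range)
        probs = np.array(frag_lens, dtype=float) / sum(frag_lens)
        gene_counts = counts.values.loc[g].to_numpy()
        split = np.stack([rng.multinomial(int(c), probs) for c in gene_counts], axis=1)
        for fi, fl in enumerate(frag_lens):
            fid = f"{g}:frag{fi + 1}"
            new_rows[fid] = split[fi]
            new_lengths[fid] = fl
            parents[fid] = g

    keep = [g for g in counts.gene_ids if g not in set(genes)]
    frag_values = pd.DataFrame(new_rows, index=counts.sample_ids).T
    values = pd.concat([counts.values.loc[keep], frag_values])
    lengths = pd.concat([counts.gene_lengths.loc[keep], pd.Series(new_lengths)])
    frag_matrix = ExpressionMatrix(values, "counts", counts.timepoint, lengths)
    frag_table = analyze(frag_matrix)

    rows = []
    for fid, parent in parents.items():
        in_run = fid in frag_table.index
        parent_in = parent in parent_table.index
        frag_hvg = bool(frag_table.loc[fid, "is_hvg"]) if in_run else np.nan
        parent_hvg = bool(parent_table.loc[parent, "is_hvg"]) if parent_in else np.nan
        ccv2 = float(frag_table.loc[fid, "corrected_cv2"]) if in_run else np.nan
        concordant = (
            frag_hvg == parent_hvg if in_run and parent_in else np.nan
        )
        rows.append(
            (fid, parent, new_lengths[fid], ccv2, frag_hvg, parent_hvg, concordant)
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "fragment_id",
            "parent",
            "length_bp",
            "corrected_cv2",
            "fragment_is_hvg",
            "parent_is_hvg",
            "concordant",
        ],
    ).set_index("fragment_id")
    conc = table["concordant"].dropna()
    concordance = float(conc.mean()) if len(conc) else float("nan")
    return FragmentationResult(table, concordance)
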