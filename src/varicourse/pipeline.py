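"""End-to-end orchestration of the variability analysis.

``run_pipeline`` drives quantification -> filtering -> trend/HVG calling ->
time-course assembly -> enrichment over a directory of per-time-point count
(or TPM) matrices, writing one sub-directory of stable TSV/YAML outputs per
stage so stages are resumable and diffable. Every numeric convention (5 TPM,
150 bp, <5 zero individuals, 10% minimum biological CV, 10% FDR, 1,000 LVGs,
1,000 random sets, 4 clusters, 1100-1400 bp size window) lives in
:class:`RunConfig` as a default, never hard-coded in a stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enrich
from . import hvg as hvgmod
from . import io as vio
from . import timecourse as tc
from .quantify import ExpressionMatrix, compute_tpm, filter_genes, mean_normalize

logger = logging.getLogger("varicourse")

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """Serialisable configuration of a full pipeline run."""

    input_dir: str = "."
    out_dir: str = "out"
    unit: str = "counts"
    # filtering
    min_mean_tpm: float = 5.0
    min_length_bp: float = 150.0
    max_zero_individuals: int = 5
    # HVG test
    min_biol_cv: float = 0.10
    fdr: float = 0.10
    fit_quantile: float = 0.4
    cv2_floor: float = 0.05
    # reference sets and time-course structure
    n_lvg: int = 1000
    n_random_sets: int = 1000
    k_clusters: int = 4
    size_window: tuple[float, float] = (1100.0, 1400.0)
    correlation: str = "spearman"
    sharing_method: str = "conditional"
    seed: int = 0
    stages: tuple[str, ...] = ("quantify", "hvg", "timecourse", "enrich")

    def validate(self) -> None:
        if self.fdr <= 0 or self.min_biol_cv <= 0 or self.min_mean_tpm < 0:
            raise ValueError("thresholds must be positive")
        if self.unit not in ("counts", "tpm"):
            raise ValueError("unit must be 'counts' or 'tpm'")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["size_window"] = list(self.size_window)
        d["stages"] = list(self.stages)
        vio.write_yaml(d, path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = vio.read_yaml(path) or {}
        if "size_window" in d:
            d["size_window"] = tuple(d["size_window"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


@dataclass
class RunReport:
    """Per-stage gene counts, trend parameters and warnings of one run."""

    timepoints: list[str] = field(default_factory=list)
    filter_counts: dict = field(default_factory=dict)
    trend_fits: dict = field(default_factory=dict)
    hvg_counts: dict = field(default_factory=dict)
    union_hvgs: int = 0
    warnings: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        vio.write_yaml(dataclasses.asdict(self), path)


def _load_matrices(config: RunConfig) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame | None]:
    root = Path(config.input_dir)
    models = None
    flat = root / "gene_models.tsv"
    gff = root / "genes.gff3"
    if flat.exists():
        models = vio.read_gene_models_tsv(flat)
    elif gff.exists():
        models = vio.gene_models_from_gff3(gff)
    lengths = None if models is None else models["length_bp"].astype(float)

    prefix = "counts_" if config.unit == "counts" else "tpm_"
    paths = sorted(root.glob(f"{prefix}*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no {prefix}*.tsv matrices under {root}")
    matrices = {}
    for p in paths:
        tp = p.stem.removeprefix(prefix)
        matrices[tp] = vio.read_matrix_tsv(p, config.unit, timepoint=tp, gene_lengths=lengths)
    return matrices, models


def _order_timepoints(labels) -> list[str]:
    def key(lab: str):
        digits = "".join(ch for ch in lab if ch.isdigit())
        return (0, int(digits)) if digits else (1, lab)

    return sorted(labels, key=key)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run all configured stages; deterministic under fixed config and seed."""
    config.validate()
    report = RunReport(config=dataclasses.asdict(config))
    out = vio.ensure_dir(config.out_dir)
    config.to_yaml(out / "config.yaml")

    matrices, models = _load_matrices(config)
    order = _order_timepoints(matrices)
    report.timepoints = order

    # ---- quantify ---------------------------------------------------------
    qdir = vio.ensure_dir(out / "quantify")
    tpm: dict[str, ExpressionMatrix] = {}
    for tp in order:
        mat = matrices[tp]
        mat = compute_tpm(mat) if mat.unit == "counts" else mat
        tpm[tp] = mat
        if "quantify" in config.stages:
            vio.write_matrix_tsv(mat, qdir / f"tpm_{tp}.tsv")
    if "hvg" not in config.stages:
        report.to_yaml(out / "report.yaml")
        return report

    # ---- per-time-point filtering + HVG calling ---------------------------
    hdir = vio.ensure_dir(out / "hvg")
    tables: dict[str, pd.DataFrame] = {}
    fit_kwargs = {"fit_quantile": config.fit_quantile, "cv2_floor": config.cv2_floor}
    for tp in order:
        rep = filter_genes(
            tpm,
            tp,
            min_mean_tpm=config.min_mean_tpm,
            min_length_bp=config.min_length_bp,
            max_zero_individuals=config.max_zero_individuals,
            min_timepoint_mean_tpm=config.min_mean_tpm,
        )
        report.filter_counts[tp] = {k: int(v) for k, v in rep.counts.items()}
        table, fit = hvgmod.variability_table(
            tpm[tp],
            genes=rep.retained,
            min_biol_cv=config.min_biol_cv,
            fdr=config.fdr,
            fit_kwargs=fit_kwargs,
        )
        tables[tp] = table
        report.trend_fits[tp] = fit.to_dict()
        report.hvg_counts[tp] = int(table["is_hvg"].sum())
        table.rename_axis("gene_id").to_csv(hdir / f"table_{tp}.tsv", sep="\t")
        pd.Series(hvgmod.select_hvg(table, config.fdr), name="gene_id").to_csv(
            hdir / f"hvg_{tp}.tsv", sep="\t", index=False
        )
        pd.Series(hvgmod.select_lvg(table, config.n_lvg), name="gene_id").to_csv(
            hdir / f"lvg_{tp}.tsv", sep="\t", index=False
        )
        logger.info("time-point %s: %d HVGs of %d tested", tp, report.hvg_counts[tp], len(table))
    vio.write_yaml(report.trend_fits, hdir / "trend.yaml")

    # ---- time-course assembly ---------------------------------------------
    course = tc.assemble({tp: tables[tp] for tp in order}, n_lvg=config.n_lvg)
    report.union_hvgs = len(course.union_hvgs())
    if "timecourse" in config.stages and len(order) >= 2:
        tdir = vio.ensure_dir(out / "timecourse")
        course.corrected_cv2.rename_axis("gene_id").to_csv(tdir / "corrected_cv2.tsv", sep="\t")
        course.hvg.astype(int).rename_axis("gene_id").to_csv(tdir / "hvg_membership.tsv", sep="\t")
        course.lvg.astype(int).rename_axis("gene_id").to_csv(tdir / "lvg_membership.tsv", sep="\t")
        hist = tc.timepoint_count_distribution(course.hvg)
        hist.rename("n_genes").to_csv(tdir / "hvg_timepoint_histogram.tsv", sep="\t")
        sharing = tc.pairwise_sharing(course.hvg, method=config.sharing_method)
        sharing.rename_axis("timepoint").to_csv(tdir / "sharing.tsv", sep="\t")
        exclude = [course.dusk] if course.dusk else []
        keep = [tp for tp in order if tp not in exclude]
        n_day = sum(course.phases.get(tp) == "day" for tp in keep)
        n_night = sum(course.phases.get(tp) == "night" for tp in keep)
        if n_day < 2 or n_night < 2:
            exclude, keep = [], order  # too short a course to drop dusk
            n_day = sum(course.phases.get(tp) == "day" for tp in keep)
            n_night = sum(course.phases.get(tp) == "night" for tp in keep)
        if n_day >= 2 and n_night >= 2:
            summary = tc.day_night_summary(sharing, course.phases, exclude=exclude)
            vio.write_yaml({k: float(v) for k, v in summary.items()}, tdir / "day_night.yaml")
        else:
            report.warnings.append("day/night summary skipped: too few time-points per phase")
        union = course.union_hvgs()
        if len(union) >= config.k_clusters:
            labels, _ = tc.cluster_profiles(
                course.corrected_cv2.loc[union], k=config.k_clusters
            )
            labels.rename("cluster").rename_axis("gene_id").to_csv(
                tdir / "clusters.tsv", sep="\t"
            )
        mean_tpm = pd.concat({tp: tpm[tp].values.mean(axis=1) for tp in order}, axis=1)
        norm = mean_normalize(mean_tpm)
        if union:
            corr = tc.profile_correlation(
                norm.loc[union], course.corrected_cv2.loc[union], method=config.correlation
            )
            corr.to_csv(tdir / "profile_correlation.tsv", sep="\t")

    # ---- enrichment -------------------------------------------------------
    root = Path(config.input_dir)
    features_path = root / "features.tsv"
    if "enrich" in config.stages and features_path.exists():
        edir = vio.ensure_dir(out / "enrich")
        features = pd.read_csv(features_path, sep="\t", index_col=0)
        universe = sorted(set(course.corrected_cv2.index))
        hvgs = course.union_hvgs()
        lvgs = course.union_lvgs()
        rng = np.random.default_rng(config.seed)
        random_sets = (
            hvgmod.sample_random_sets(universe, len(hvgs), config.n_random_sets, rng)
            if hvgs
            else []
        )
        rows = []
        for feat in ("length_bp", "n_introns"):
            if feat in features.columns and hvgs and lvgs:
                cmp = enrich.compare_feature(features[feat], hvgs, lvgs, random_sets)
                rows.append((feat, cmp.statistic, cmp.p, cmp.median_a, cmp.median_b))
        if rows:
            pd.DataFrame(
                rows, columns=["feature", "statistic", "p", "median_hvg", "median_lvg"]
            ).to_csv(edir / "feature_comparisons.tsv", sep="\t", index=False)

        tf_path = root / "tf_targets.gmt"
        if tf_path.exists() and hvgs:
            tf_targets = vio.read_gmt(tf_path)
            tf_targets = {k: set(v) & set(universe) for k, v in tf_targets.items()}
            counts_per_gene = enrich.count_tf_per_gene(tf_targets, universe)
            counts_per_gene.rename("n_tfs").to_csv(edir / "tf_counts.tsv", sep="\t")
            over = enrich.set_overrepresentation(hvgs, tf_targets, universe)
            over.to_csv(edir / "tf_enrichment.tsv", sep="\t")
            fam_path = root / "tf_families.tsv"
            if fam_path.exists():
                fams = pd.read_csv(fam_path, sep="\t", index_col=0)["family"].to_dict()
                hits = list(over.index[over["p_adj"] < config.fdr])
                enrich.family_enrichment(hits, fams).to_csv(
                    edir / "tf_family_enrichment.tsv", sep="\t"
                )

        marks_path = root / "marks.gmt"
        if marks_path.exists() and hvgs and random_sets:
            marks = vio.read_gmt(marks_path)
            rows = []
            for mark, members in marks.items():
                res = enrich.presence_enrichment(hvgs, members, universe, random_sets)
                rows.append(
                    (mark, res.prop_query, res.prop_universe, res.p, res.test, res.ci_low, res.ci_high)
                )
            pd.DataFrame(
                rows,
                columns=["mark", "prop_hvg", "prop_all", "p", "test", "ci_low", "ci_high"],
            ).to_csv(edir / "mark_presence.tsv", sep="\t", index=False)

        tissue_path = root / "tissue_table.tsv"
        if tissue_path.exists():
            table = vio.read_tissue_table(tissue_path)
            H = enrich.tissue_specificity_entropy(table[ [c for c in table.columns if c in set(universe)] ])
            H.rename_axis("gene_id").to_csv(edir / "tissue_entropy.tsv", sep="\t")

    report.to_yaml(out / "report.yaml")
    return report
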