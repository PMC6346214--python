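"""Synthetic diurnal time-course generator with known ground truth.

Emulates the study design the pipeline was built for: 12 time-points
(ZT2..ZT24, seedlings harvested every 2 h; ZT2-ZT12 in the light, ZT14-ZT24
in the dark) x 14 individuals — 168 transcriptomes in total — with
per-individual negative-binomial count noise whose TPM-scale CV2 follows the
trend CV2 = a1/mu + a0 for null genes, scattered around it by a per-gene
log-normal biological heterogeneity factor (mean 1, so the binned trend is
preserved; set ``biological_cv2_sigma = 0`` for an exactly on-trend null).
A configurable fraction of genes is planted as highly variable: their CV2 is
further inflated by a multiplier at the time-points where their variability
cluster (day-variable, night-variable, always-variable) is active.

Mechanics, per time-point:

1. every gene gets a diurnal mean profile (flat, day-peaking or
   night-peaking sinusoid); the per-time-point mean vector is rescaled so
   TPM sums to 1e6, making the configured means the realized TPM scale;
2. expected counts are ``library_size * tpm * length / sum(tpm * length)``
   with a mild log-normal library-size spread across individuals;
3. per-gene NB dispersion is chosen by inverting
   ``CV2_target = 1/mean_count + 1/size`` (Poisson when the target is below
   the shot-noise floor), so that the TPM-scale CV2 of the derived matrix
   matches the target up to the TPM-renormalisation approximation.

A companion feature generator plants genomic/epigenomic associations
(HVGs shorter, fewer introns, preferentially targeted by a subset of TFs,
shifted chromatin-mark prevalence), and a tissue-table generator plants
higher tissue specificity (lower Shannon entropy) for HVGs. Zero effect
sizes make HVG and null genes exchangeable, which is what the calibration
tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "FeatureEffects",
    "AnnotationSets",
    "default_cluster_scheme",
    "generate_dataset",
    "generate_gene_features",
    "generate_tissue_table",
]

TF_FAMILIES = ("NAC", "bZIP", "MYB", "WRKY", "ZF-HD", "bHLH", "AP2", "GATA")
DEFAULT_MARK_FOLDS = {
    "H3K27me3": 2.0,
    "H3K27me1": 1.6,
    "H2AZ_body": 1.6,
    "H3K4me3": 0.5,
    "H3K36me3": 0.6,
    "DNA_methylation": 0.7,
}


def default_cluster_scheme(n_timepoints: int) -> dict[str, np.ndarray]:
    """Day/night/always activity masks.

    The first half of the time-points is "day" (ZT2-ZT12 analogue), the
    second half "night" (ZT14-ZT24); always-variable genes are active
    throughout. With a single time-point only "always" is meaningful.
    """
    t = np.arange(n_timepoints)
    if n_timepoints < 2:
        return {"always": np.ones(n_timepoints, dtype=bool)}
    half = n_timepoints // 2
    return {
        "day": t < half,
        "night": t >= half,
        "always": np.ones(n_timepoints, dtype=bool),
    }


def timepoint_labels(n_timepoints: int) -> list[str]:
    if n_timepoints == 12:
        return [f"ZT{2 * (i + 1)}" for i in range(12)]
    return [f"T{i + 1:02d}" for i in range(n_timepoints)]


@dataclass
class SimConfig:
    """Parameters of the synthetic diurnal design.

    Defaults reproduce the study layout: 12 time-points x 14 individuals,
    negative-binomial noise on a CV2 = 1/mu + 0.02 trend, 10% planted HVGs
    at 4-fold trend CV2 split across day/night/always clusters.
    """

    n_timepoints: int = 12
    n_individuals: int = 14
    n_genes: int = 2000
    trend_a1: float = 1.0
    trend_a0: float = 0.02
    hvg_fraction: float = 0.10
    hvg_cv2_multiplier: float = 4.0
    cluster_scheme: Mapping[str, Sequence[bool]] | None = None
    cluster_multipliers: Mapping[str, float] | None = None
    flat_fraction: float = 0.4
    day_peak_fraction: float = 0.3
    diurnal_amplitude: float = 0.5
    mean_range: tuple[float, float] = (2.0, 2000.0)
    biological_cv2_sigma: float = 0.5
    library_size: float = 5e6
    library_size_cv: float = 0.10
    length_range: tuple[float, float] = (1000.0, 3000.0)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_timepoints, self.n_individuals, self.n_genes) <= 0:
            raise ValueError("dimensions must be positive")
        if not 0.0 <= self.hvg_fraction <= 1.0:
            raise ValueError("hvg_fraction must lie in [0, 1]")
        if self.hvg_cv2_multiplier <= 1.0:
            raise ValueError("hvg_cv2_multiplier must exceed 1")
        if self.trend_a1 <= 0 or self.trend_a0 < 0:
            raise ValueError("trend parameters must be positive (a1) / non-negative (a0)")
        if self.biological_cv2_sigma < 0:
            raise ValueError("biological_cv2_sigma must be non-negative")
        if not 0.0 <= self.diurnal_amplitude < 1.0:
            raise ValueError("diurnal_amplitude must lie in [0, 1)")
        if self.mean_range[0] <= 0 or self.mean_range[1] < self.mean_range[0]:
            raise ValueError("mean_range must be positive and ordered")
        if self.flat_fraction + self.day_peak_fraction > 1.0:
            raise ValueError("profile fractions must sum to <= 1")
        scheme = self.masks()
        for name, mask in scheme.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.n_timepoints,):
                raise ValueError(f"cluster mask {name!r} does not match n_timepoints")

    def masks(self) -> dict[str, np.ndarray]:
        if self.cluster_scheme is None:
            return default_cluster_scheme(self.n_timepoints)
        return {k: np.asarray(v, dtype=bool) for k, v in self.cluster_scheme.items()}

    def multiplier_for(self, cluster: str) -> float:
        if self.cluster_multipliers and cluster in self.cluster_multipliers:
            return float(self.cluster_multipliers[cluster])
        return float(self.hvg_cv2_multiplier)

    def labels(self) -> list[str]:
        return timepoint_labels(self.n_timepoints)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``cv2`` holds the target TPM-scale CV2 per gene and time-point: the
    gene's baseline dispersion (trend times its biological jitter factor)
    times the cluster multiplier wherever the gene's cluster is active.
    With ``biological_cv2_sigma = 0`` this reduces to ``multiplier *
    trend(mu)`` at active time-points and ``trend(mu)`` elsewhere.
    """

    gene_ids: pd.Index
    timepoints: list[str]
    is_planted_hvg: pd.Series  # bool per gene
    cluster: pd.Series  # cluster name, "" for null genes
    active: pd.DataFrame  # genes x timepoints bool
    mean_tpm: pd.DataFrame  # genes x timepoints
    cv2: pd.DataFrame  # genes x timepoints
    gene_lengths: pd.Series
    config: SimConfig

    @property
    def planted(self) -> list[str]:
        return list(self.gene_ids[self.is_planted_hvg])

    @property
    def null_genes(self) -> list[str]:
        return list(self.gene_ids[~self.is_planted_hvg])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "is_planted_hvg": self.is_planted_hvg,
                "cluster": self.cluster,
                "length_bp": self.gene_lengths,
            }
        )


def _profile_matrix(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene diurnal multiplier profiles (genes x timepoints)."""
    G, T = config.n_genes, config.n_timepoints
    classes = rng.choice(
        3,
        size=G,
        p=[
            config.flat_fraction,
            config.day_peak_fraction,
            1.0 - config.flat_fraction - config.day_peak_fraction,
        ],
    )
    t = np.arange(T)
    # peak mid-day for class 1, mid-night for class 2
    peak_day = (T / 2 - 1) / 2.0
    peak_night = peak_day + T / 2.0
    prof = np.ones((G, T))
    day_curve = 1.0 + config.diurnal_amplitude * np.cos(2 * np.pi * (t - peak_day) / T)
    night_curve = 1.0 + config.diurnal_amplitude * np.cos(2 * np.pi * (t - peak_night) / T)
    prof[classes == 1] = day_curve
    prof[classes == 2] = night_curve
    return prof, classes


def generate_dataset(config: SimConfig) -> tuple[list[ExpressionMatrix], SyntheticTruth]:
    """Simulate one full time course of per-individual count matrices.

    Returns one counts :class:`ExpressionMatrix` per time-point (with gene
    lengths attached, so ``compute_tpm`` applies directly) and the
    :class:`SyntheticTruth`. Bit-identical under identical config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, T, m = config.n_genes, config.n_timepoints, config.n_individuals
    gene_ids = pd.Index([f"G{i + 1:05d}" for i in range(G)], name="gene_id")
    labels = config.labels()

    base = np.exp(rng.uniform(np.log(config.mean_range[0]), np.log(config.mean_range[1]), G))
    prof, _ = _profile_matrix(config, rng)
    mu = base[:, None] * prof
    mu *= 1e6 / mu.sum(axis=0, keepdims=True)  # configured means are the TPM scale

    lengths = np.exp(
        rng.uniform(np.log(config.length_range[0]), np.log(config.length_range[1]), G)
    ).round()

    n_hvg = int(round(config.hvg_fraction * G))
    planted_idx = rng.choice(G, size=n_hvg, replace=False) if n_hvg else np.array([], dtype=int)
    is_planted = np.zeros(G, dtype=bool)
    is_planted[planted_idx] = True
    scheme = config.masks()
    names = list(scheme)
    cluster = np.full(G, "", dtype=object)
    active = np.zeros((G, T), dtype=bool)
    mult = np.ones((G, T))
    for j, gi in enumerate(planted_idx):
        name = names[j % len(names)]
        cluster[gi] = name
        active[gi] = scheme[name]
        mult[gi, scheme[name]] = config.multiplier_for(name)

    trend = config.trend_a1 / mu + config.trend_a0
    # per-gene biological dispersion heterogeneity: real CV2 clouds scatter
    # severalfold around the trend; log-normal with mean 1 keeps the binned
    # trend intact (set sigma to 0 for an exactly on-trend null)
    sigma_b = config.biological_cv2_sigma
    jitter = np.exp(rng.normal(-sigma_b**2 / 2.0, sigma_b, G)) if sigma_b > 0 else np.ones(G)
    cv2_true = trend * mult * jitter[:, None]

    sigma = np.sqrt(np.log1p(config.library_size_cv**2))
    matrices: list[ExpressionMatrix] = []
    for ti, label in enumerate(labels):
        w = mu[:, ti] * lengths
        p = w / w.sum()
        libs = config.library_size * np.exp(rng.normal(-sigma**2 / 2.0, sigma, m))
        mean_counts = np.outer(p, libs)  # genes x individuals
        expected = config.library_size * p  # dispersion targeted at nominal depth
        inv_size = cv2_true[:, ti] - 1.0 / expected
        counts = np.empty((G, m), dtype=np.int64)
        nb = inv_size > 0
        if np.any(nb):
            size = 1.0 / inv_size[nb]
            p_nb = size[:, None] / (size[:, None] + mean_counts[nb])
            counts[nb] = rng.negative_binomial(size[:, None], p_nb)
        if np.any(~nb):
            counts[~nb] = rng.poisson(mean_counts[~nb])
        values = pd.DataFrame(
            counts,
            index=gene_ids,
            columns=[f"{label}_s{j + 1:02d}" for j in range(m)],
        )
        matrices.append(
            ExpressionMatrix(
                values,
                "counts",
                timepoint=label,
                gene_lengths=pd.Series(lengths, index=gene_ids, name="length_bp"),
            )
        )

    truth = SyntheticTruth(
        gene_ids=gene_ids,
        timepoints=labels,
        is_planted_hvg=pd.Series(is_planted, index=gene_ids),
        cluster=pd.Series(cluster, index=gene_ids),
        active=pd.DataFrame(active, index=gene_ids, columns=labels),
        mean_tpm=pd.DataFrame(mu, index=gene_ids, columns=labels),
        cv2=pd.DataFrame(cv2_true, index=gene_ids, columns=labels),
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length_bp"),
        config=config,
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# gene features and annotation sets


@dataclass
class FeatureEffects:
    """Planted HVG-vs-null effect sizes for the feature generator.

    Folds are multiplicative (1.0 = no effect, i.e. HVG and null genes
    exchangeable). Defaults plant the association directions the enrichment
    stage is meant to detect: HVGs ~30% shorter, with proportionally fewer
    introns, twice as likely to be targeted by the HVG-preferring TF subset,
    and with shifted chromatin-mark prevalence.
    """

    length_fold: float = 0.7
    intron_fold: float = 0.7
    tf_fold: float = 2.0
    mark_folds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MARK_FOLDS))
    n_tfs: int = 60
    tf_hvg_fraction: float = 0.25
    base_mark_prevalence: float = 0.25
    length_median: float = 1800.0
    length_sigma: float = 0.45
    introns_per_bp: float = 1.0 / 450.0

    @classmethod
    def neutral(cls) -> "FeatureEffects":
        return cls(length_fold=1.0, intron_fold=1.0, tf_fold=1.0,
                   mark_folds={k: 1.0 for k in DEFAULT_MARK_FOLDS})

    def validate(self) -> None:
        folds = [self.length_fold, self.intron_fold, self.tf_fold, *self.mark_folds.values()]
        if any(f <= 0 for f in folds):
            raise ValueError("effect folds must be strictly positive")


@dataclass
class AnnotationSets:
    """Named gene sets over a common universe."""

    universe: list[str]
    sets: dict[str, frozenset]  # chromatin marks etc.
    tf_targets: dict[str, frozenset]
    tf_families: dict[str, str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for name, s in {**self.sets, **self.tf_targets}.items():
            if not set(s) <= uni:
                raise ValueError(f"annotation set {name!r} contains genes outside the universe")


def generate_gene_features(
    truth: SyntheticTruth,
    effects: FeatureEffects | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, AnnotationSets]:
    """Sample per-gene features and annotation sets with planted associations.

    Lengths are log-normal; intron counts Poisson with rate proportional to
    length (so the two are positively correlated, as in real annotations);
    TF target lists are Bernoulli with a higher hit probability for planted
    HVGs in the HVG-preferring TF subset; chromatin marks are Bernoulli with
    per-mark prevalence folds. These feature lengths are an annotation layer
    for the enrichment stage and are drawn independently of the lengths used
    for read-depth bookkeeping inside the count simulator.
    """
    effects = effects or FeatureEffects()
    effects.validate()
    rng = np.random.default_rng(truth.config.seed + 1 if seed is None else seed)
    genes = truth.gene_ids
    G = len(genes)
    hvg = truth.is_planted_hvg.to_numpy()

    length = np.exp(rng.normal(np.log(effects.length_median), effects.length_sigma, G))
    length = np.where(hvg, length * effects.length_fold, length)
    length = np.maximum(length.round(), 200.0)

    lam = length * effects.introns_per_bp * np.where(hvg, effects.intron_fold, 1.0)
    introns = rng.poisson(lam)

    features = pd.DataFrame({"length_bp": length, "n_introns": introns}, index=genes)

    tf_ids = [f"TF{i + 1:03d}" for i in range(effects.n_tfs)]
    families = {tf: TF_FAMILIES[i % len(TF_FAMILIES)] for i, tf in enumerate(tf_ids)}
    n_pref = int(np.ceil(effects.tf_hvg_fraction * effects.n_tfs))
    preferring = set(rng.permutation(tf_ids)[:n_pref])
    tf_targets: dict[str, frozenset] = {}
    for tf in tf_ids:
        p0 = rng.uniform(0.02, 0.12)
        p = np.full(G, p0)
        if tf in preferring:
            p = np.where(hvg, np.minimum(p0 * effects.tf_fold, 0.9), p)
        tf_targets[tf] = frozenset(genes[rng.random(G) < p])

    sets: dict[str, frozenset] = {}
    for mark, fold in effects.mark_folds.items():
        p0 = effects.base_mark_prevalence
        p = np.where(hvg, np.clip(p0 * fold, 0.0, 0.95), p0)
        sets[mark] = frozenset(genes[rng.random(G) < p])

    ann = AnnotationSets(
        universe=list(genes), sets=sets, tf_targets=tf_targets, tf_families=families
    )
    return features, ann


def generate_tissue_table(
    truth: SyntheticTruth,
    n_tissues: int = 8,
    *,
    restricted_alpha: float = 0.3,
    null_alpha: float = 5.0,
    restriction: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tissues x genes expression table for the Shannon-entropy stage.

    Each gene's relative expression across tissues is Dirichlet: null genes
    use a near-uniform concentration (high entropy), planted HVGs a sparse
    one when ``restriction`` is on (tissue-restricted, low entropy).
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = np.random.default_rng(truth.config.seed + 2 if seed is None else seed)
    genes = truth.gene_ids
    hvg = truth.is_planted_hvg.to_numpy()
    alphas = np.where(hvg & restriction, restricted_alpha, null_alpha)
    rel = np.empty((len(genes), n_tissues))
    for i, a in enumerate(alphas):
        rel[i] = rng.dirichlet(np.full(n_tissues, a))
    totals = np.exp(rng.normal(np.log(50.0), 1.0, len(genes)))
    table = (rel * totals[:, None]).T
    return pd.DataFrame(
        table, index=[f"tissue{j + 1}" for j in range(n_tissues)], columns=genes
    )


def write_dataset(
    matrices: Sequence[ExpressionMatrix],
    truth: SyntheticTruth,
    outdir,
    features: pd.DataFrame | None = None,
    annotations: "AnnotationSets | None" = None,
    tissue_table: pd.DataFrame | None = None,
) -> None:
    """Write a simulated dataset in the pipeline's input layout.

    Produces per-time-point ``counts_<TP>.tsv`` matrices, ``gene_models.tsv``,
    the truth table with a YAML config sidecar, and (when given) the feature
    table, GMT annotation sets, TF family map and tissue table.
    """
    import dataclasses

    from . import io as vio

    out = vio.ensure_dir(outdir)
    for mat in matrices:
        vio.write_matrix_tsv(mat, out / f"counts_{mat.timepoint}.tsv")
    models = pd.DataFrame(
        {
            "length_bp": truth.gene_lengths.astype(int),
            "n_introns": 0 if features is None else features["n_introns"].astype(int),
        }
    )
    models.rename_axis("gene_id").to_csv(out / "gene_models.tsv", sep="\t")
    truth.to_frame().rename_axis("gene_id").to_csv(out / "truth.tsv", sep="\t")
    cfg = dataclasses.asdict(truth.config)
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in cfg.items()
        if not isinstance(v, (np.ndarray, dict)) or k == "cluster_multipliers"
    }
    cfg.pop("cluster_scheme", None)
    vio.write_yaml(cfg, out / "truth.yaml")
    if features is not None:
        features.rename_axis("gene_id").to_csv(out / "features.tsv", sep="\t")
    if annotations is not None:
        vio.write_gmt(annotations.sets, out / "marks.gmt")
        vio.write_gmt(annotations.tf_targets, out / "tf_targets.gmt")
        pd.Series(annotations.tf_families, name="family").rename_axis("tf_id").to_csv(
            out / "tf_families.tsv", sep="\t"
        )
    if tissue_table is not None:
        tissue_table.rename_axis("tissue").to_csv(out / "tissue_table.tsv", sep="\t")
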