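"""End-to-end benchmark: pretrain, embed, and run the evaluation battery.

Ties the pipeline together the way the study protocol does: scaffold-grouped
70/10/20 split, feature learning on train+valid pairs only, then unsupervised
(replicate / MoA kNN clustering) and supervised (multitask bioactivity)
evaluation of each feature type on the held-out test compounds under one
shared configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autoencoder import BAEConfig, embed_cp_bae, train_bae
from .bioactivity import (
    MultitaskConfig,
    compare_feature_types,
    filter_eval_tasks,
    filter_train_tasks,
    score_tasks,
    select_tx_strong_cp_weak,
    train_multitask,
)
from .clustering import moa_clustering_eval, replicate_clustering_eval
from .contrastive import CLConfig, embed_cp, train_contrastive
from .profiles import (
    BioactivityMatrix,
    ProfileMatrix,
    aggregate_replicates,
    build_pairs,
    scaffold_split,
)
from .simulate import ScreenConfig, generate_screen

logger = logging.getLogger(__name__)


def small_profile(seed: int = 0) -> tuple[ScreenConfig, CLConfig, BAEConfig, MultitaskConfig]:
    """CPU-scale configuration bundle used by the bundled evaluation runs.

    Screen conditions keep the full profile widths (800 CP features, 4000 TX
    genes, ~2000 compounds, 3 replicates, noisy CP replicates, TX-only
    latent factors); the network widths and epoch counts are reduced to
    desk scale.
    """
    screen = ScreenConfig(
        n_compounds=2000,
        replicate_count_range=(3, 3),
        seed=seed,
    )
    cl = CLConfig(
        cp_hidden_sizes=(256, 256),
        tx_hidden_sizes=(256, 256),
        encoder_output_dim=128,
        projection_dim=64,
        batch_size=256,
        epochs=40,
        learning_rate=1e-3,
        seed=seed,
    )
    bae = BAEConfig(
        encoder_hidden=(256, 128),
        embedding_dim=64,
        cp_decoder_hidden=(128, 256),
        tx_decoder_hidden=(256, 512),
        batch_size=256,
        epochs=20,
        learning_rate=1e-3,
        seed=seed,
    )
    mt = MultitaskConfig(hidden_size=128, n_layers=2, epochs=60,
                         learning_rate=1e-3, seed=seed)
    return screen, cl, bae, mt


def permute_task_labels(
    bio: BioactivityMatrix, task_ids: list[str], seed: int
) -> BioactivityMatrix:
    """Permute the label columns of the given tasks across compounds.

    Destroys any feature-label association while preserving each task's
    prevalence and missingness pattern size — the negative control for the
    supervised evaluation.
    """
    rng = np.random.default_rng(seed)
    labels = bio.labels.copy()
    tj = bio.task_index()
    for t in task_ids:
        labels[:, tj[t]] = rng.permutation(labels[:, tj[t]])
    return BioactivityMatrix(labels, list(bio.compound_ids), list(bio.task_ids),
                             dict(bio.family))


@dataclass
class BenchmarkResult:
    """All quantities computed by one benchmark run."""

    knn_replicates: dict[str, float]
    knn_moa: dict[str, float]
    mean_auroc_all: dict[str, float]
    mean_riptop_all: dict[str, float]
    subset_tasks: list[str]
    mean_auroc_subset: dict[str, float]
    mean_riptop_subset: dict[str, float]
    permuted_mean_auroc: float | None
    wilcoxon_cl_vs_cp_auroc_p: float | None
    n_eval_tasks: int
    n_scored_tasks: int
    n_permuted_scored: int
    n_test_compounds: int


def run_benchmark(
    screen_cfg: ScreenConfig,
    cl_cfg: CLConfig,
    bae_cfg: BAEConfig,
    mt_cfg: MultitaskConfig,
    n_permuted_tasks: int = 5,
    knn_k: int = 5,
    top_m_moa: int = 9,
) -> BenchmarkResult:
    """Run the full pipeline on a synthetic screen and score every stage."""
    screen = generate_screen(screen_cfg)
    split = scaffold_split(screen.compounds, seed=screen_cfg.seed)
    pairs = build_pairs(screen.cp, screen.tx)
    pretrain_compounds = set(split.compounds("train")) | set(split.compounds("valid"))
    pretrain_pairs = pairs.restrict_to(pretrain_compounds)

    logger.info("training contrastive model on %d pairs", len(pretrain_pairs))
    cl_model = train_contrastive(pretrain_pairs, screen.cp, screen.tx, split, cl_cfg)
    logger.info("training bimodal autoencoder on %d pairs", len(pretrain_pairs))
    bae_model = train_bae(pretrain_pairs, screen.cp, screen.tx, split, bae_cfg)

    # replicate-level feature spaces derived from CP only
    rep_features: dict[str, ProfileMatrix] = {
        "CP": screen.cp,
        "CL Emb": embed_cp(cl_model, screen.cp),
        "BAE Emb": embed_cp_bae(bae_model, screen.cp),
    }

    test_compounds = split.compounds("test")
    knn_replicates, knn_moa = {}, {}
    moa = screen.compounds.moa_labels()
    comp_features: dict[str, ProfileMatrix] = {}
    # leave-one-out voting: including the query point both inflates scores
    # uniformly and, under the nearest-neighbour tie-break, saturates the
    # replicate task, so the ordering comparison uses exclude_self=True
    for name, feats in rep_features.items():
        test_feats = feats.rows_for(test_compounds)
        knn_replicates[name] = replicate_clustering_eval(
            test_feats, k=knn_k, exclude_self=True, feature_type_name=name
        ).knn_accuracy
        agg = aggregate_replicates(feats, method="median")
        comp_features[name] = agg
        knn_moa[name] = moa_clustering_eval(
            agg.rows_for(test_compounds), moa, top_m=top_m_moa, k=knn_k,
            exclude_self=True, feature_type_name=name,
        ).knn_accuracy
    comp_features["TX"] = screen.tx

    # supervised multitask evaluation, optionally with permuted-label controls
    bio = screen.bioactivity
    permuted: list[str] = []
    if n_permuted_tasks > 0:
        permuted = bio.task_ids[-n_permuted_tasks:]
        bio = permute_task_labels(bio, permuted, seed=screen_cfg.seed + 1)

    train_tasks = filter_train_tasks(bio, split)
    eval_tasks = [t for t in filter_eval_tasks(bio, split) if t in train_tasks]
    if not eval_tasks:
        raise ValueError("no tasks survive both the training and test filters")

    metrics = {}
    for name, feats in comp_features.items():
        model = train_multitask(feats, bio, split, mt_cfg, task_ids=train_tasks)
        assert model.config == mt_cfg  # identical protocol across feature types
        metrics[name] = score_tasks(model, feats, bio, split, task_ids=eval_tasks)

    real = [t for t in eval_tasks if t not in permuted]
    def mean_over(name: str, tasks: list[str], attr: str) -> float:
        vals = [getattr(m, attr) for m in metrics[name] if m.task_id in set(tasks)]
        return float(np.mean(vals)) if vals else float("nan")

    mean_auroc_all = {n: mean_over(n, real, "auroc") for n in metrics}
    mean_riptop_all = {n: mean_over(n, real, "riptop_auprc") for n in metrics}

    subset = select_tx_strong_cp_weak(
        [m for m in metrics["TX"] if m.task_id in set(real)],
        [m for m in metrics["CP"] if m.task_id in set(real)],
    )
    mean_auroc_subset = {n: mean_over(n, subset, "auroc") for n in metrics}
    mean_riptop_subset = {n: mean_over(n, subset, "riptop_auprc") for n in metrics}

    permuted_scored = [t for t in permuted if t in set(eval_tasks)]
    permuted_mean = (
        mean_over("CP", permuted_scored, "auroc") if permuted_scored else None
    )

    wil = None
    if len(real) >= 6:
        cmp = compare_feature_types(
            {m.task_id: m.auroc for m in metrics["CL Emb"] if m.task_id in set(real)},
            {m.task_id: m.auroc for m in metrics["CP"] if m.task_id in set(real)},
            "CL Emb", "CP",
        )
        wil = cmp.p_value

    return BenchmarkResult(
        knn_replicates=knn_replicates,
        knn_moa=knn_moa,
        mean_auroc_all=mean_auroc_all,
        mean_riptop_all=mean_riptop_all,
        subset_tasks=subset,
        mean_auroc_subset=mean_auroc_subset,
        mean_riptop_subset=mean_riptop_subset,
        permuted_mean_auroc=permuted_mean,
        wilcoxon_cl_vs_cp_auroc_p=wil,
        n_eval_tasks=len(eval_tasks),
        n_scored_tasks=len(real),
        n_permuted_scored=len(permuted_scored),
        n_test_compounds=len(test_compounds),
    )
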