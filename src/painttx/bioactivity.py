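"""Supervised evaluation: multitask bioactivity classification and scoring.

One MLP with a sigmoid output per binarized assay task is trained per
feature type under an identical configuration, so the only experimental
variable is the feature space itself.  Missing labels are masked out of the
binary cross-entropy.  Per-task test performance is summarised by AUROC and
by RIPtoP-corrected AUPRC — average precision rescaled so the random
baseline maps to 0 and a perfect model to 1:

    RIPtoP(AUPRC) = (AUPRC - BASELINE) / (1 - BASELINE)

with BASELINE the positive prevalence among the scored test labels.
Feature types are compared per task with a one-sided Wilcoxon signed-rank
test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from ._nn import MLP, Adam, cosine_warm_restart_lr, minibatches
from .profiles import BioactivityMatrix, ProfileMatrix, SplitAssignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MultitaskConfig:
    """Hyperparameters of the multitask classifier (shared by feature types)."""

    hidden_size: int = 256
    n_layers: int = 3
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 128
    epochs: int = 100
    dropout: float = 0.3
    scheduler_period: int = 10  # cosine-annealing warm-restart period, epochs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hidden_size", "n_layers", "learning_rate", "batch_size",
                     "epochs", "scheduler_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class TaskMetrics:
    task_id: str
    auroc: float
    auprc: float
    baseline: float  # positive prevalence in the scored test labels
    riptop_auprc: float
    n_pos: int
    n_neg: int
    family: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComparisonResult:
    feature_type_a: str
    feature_type_b: str
    metric: str
    n_tasks: int
    p_value: float | None  # one-sided, H1: a > b; None when degenerate
    median_difference: float
    degenerate: bool = False


@dataclass
class MultitaskModel:
    net: MLP
    task_ids: list[str]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    config: MultitaskConfig
    history: list[dict] = field(default_factory=list)

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        """Sigmoid task scores for compound-level feature rows."""
        z = (features - self.feature_mean) / self.feature_sd
        logits = self.net.forward(z)
        return 1.0 / (1.0 + np.exp(-logits))


def _counts(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    obs = ~np.isnan(labels)
    pos = np.nansum(labels, axis=0)
    neg = obs.sum(axis=0) - pos
    return pos, neg, obs.sum(axis=0)


def filter_train_tasks(
    labels: BioactivityMatrix, split: SplitAssignment
) -> list[str]:
    """Tasks with >=25 positives, >=25 negatives and >=100 observed labels
    among train+valid compounds."""
    cids = [
        c for c in labels.compound_ids
        if split.assignment.get(c) in ("train", "valid")
    ]
    pos, neg, n_obs = _counts(labels.rows_for(cids))
    keep = [
        t for j, t in enumerate(labels.task_ids)
        if pos[j] >= 25 and neg[j] >= 25 and n_obs[j] >= 100
    ]
    if not keep:
        warnings.warn("no tasks pass the 25/25/100 training filter", stacklevel=2)
    return keep


def filter_eval_tasks(
    labels: BioactivityMatrix, split: SplitAssignment
) -> list[str]:
    """Tasks with >=25 positives and >=25 negatives among test compounds."""
    cids = [c for c in labels.compound_ids if split.assignment.get(c) == "test"]
    pos, neg, _ = _counts(labels.rows_for(cids))
    return [
        t for j, t in enumerate(labels.task_ids)
        if pos[j] >= 25 and neg[j] >= 25
    ]


def _masked_bce_and_grad(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """BCE averaged over observed labels; gradient wrt logits."""
    obs = ~np.isnan(y)
    n_obs = int(obs.sum())
    if n_obs == 0:
        return 0.0, np.zeros_like(logits)
    yv = np.where(obs, y, 0.0)
    # stable log(1 + exp(-|z|)) formulation
    z = logits
    loss_mat = np.maximum(z, 0.0) - z * yv + np.log1p(np.exp(-np.abs(z)))
    loss = float(loss_mat[obs].sum() / n_obs)
    p = 1.0 / (1.0 + np.exp(-z))
    grad = np.where(obs, p - yv, 0.0) / n_obs
    return loss, grad


def train_multitask(
    features: ProfileMatrix,
    labels: BioactivityMatrix,
    split: SplitAssignment,
    cfg: MultitaskConfig,
    task_ids: Sequence[str] | None = None,
) -> MultitaskModel:
    """Train one multitask MLP on train+valid compounds.

    ``features`` must be compound-level (one row per compound).  Tasks are
    expected to be pre-filtered (pass ``task_ids``; defaults to the
    25/25/100 training filter).  Inputs are standardised with training-set
    statistics.  Final-epoch weights are kept — the epoch budget is part of
    the protocol, not a tuning dial.
    """
    if task_ids is None:
        task_ids = filter_train_tasks(labels, split)
    if not task_ids:
        raise ValueError("no retained tasks to train on")
    tj = labels.task_index()
    cols = [tj[t] for t in task_ids]

    feat_index = features.compound_row_index()
    train_cids = [
        c for c in labels.compound_ids
        if split.assignment.get(c) in ("train", "valid") and c in feat_index
    ]
    if not train_cids:
        raise ValueError("no train+valid compounds with features and labels")
    X = features.values[[feat_index[c] for c in train_cids]]
    Y = labels.rows_for(train_cids)[:, cols]

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    Xz = (X - mean) / sd

    rng = np.random.default_rng(cfg.seed)
    net = MLP(
        [X.shape[1]] + [cfg.hidden_size] * cfg.n_layers + [len(cols)],
        rng,
        dropout=cfg.dropout,
    )
    opt = Adam(net.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    history: list[dict] = []
    for epoch in range(cfg.epochs):
        lr = cosine_warm_restart_lr(cfg.learning_rate, epoch, cfg.scheduler_period)
        losses = []
        for batch in minibatches(X.shape[0], cfg.batch_size, rng):
            logits = net.forward(Xz[batch], train=True, rng=rng)
            loss, g = _masked_bce_and_grad(logits, Y[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite BCE at epoch {epoch}")
            losses.append(loss)
            _, grads = net.backward(g)
            opt.step(grads, lr=lr)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "lr": lr})
    return MultitaskModel(net, list(task_ids), mean, sd, cfg, history)


def riptop(auprc: float, baseline: float) -> float:
    """Relative Improvement of Proximity to Perfection for AUPRC.

    Maps the random baseline (AUPRC == positive prevalence) to 0 and a
    perfect model to 1.
    """
    if not (0.0 < baseline < 1.0):
        raise ValueError("baseline must lie strictly in (0, 1)")
    return (auprc - baseline) / (1.0 - baseline)


def score_tasks(
    model: MultitaskModel,
    features: ProfileMatrix,
    labels: BioactivityMatrix,
    split: SplitAssignment,
    task_ids: Sequence[str] | None = None,
) -> list[TaskMetrics]:
    """Per-task AUROC / AUPRC / RIPtoP on the test split.

    AUROC is the rank statistic with ties averaged; AUPRC is average
    precision (step-wise, no interpolation).  Tasks with a single observed
    class in the test set are skipped with a warning.
    """
    if task_ids is None:
        task_ids = model.task_ids
    unknown = set(task_ids) - set(model.task_ids)
    if unknown:
        raise ValueError(f"tasks not in the trained model: {sorted(unknown)[:5]}")
    feat_index = features.compound_row_index()
    test_cids = [
        c for c in labels.compound_ids
        if split.assignment.get(c) == "test" and c in feat_index
    ]
    X = features.values[[feat_index[c] for c in test_cids]]
    scores = model.predict_scores(X)
    col_of = {t: j for j, t in enumerate(model.task_ids)}
    tj = labels.task_index()
    Y = labels.rows_for(test_cids)

    out: list[TaskMetrics] = []
    for t in task_ids:
        y = Y[:, tj[t]]
        s = scores[:, col_of[t]]
        obs = ~np.isnan(y)
        yt, st = y[obs], s[obs]
        n_pos = int(yt.sum())
        n_neg = int(obs.sum() - n_pos)
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"task {t}: single class in test set, skipped",
                          stacklevel=2)
            continue
        auroc = float(roc_auc_score(yt, st))
        auprc = float(average_precision_score(yt, st))
        base = n_pos / (n_pos + n_neg)
        out.append(
            TaskMetrics(
                t, auroc, auprc, base, riptop(auprc, base),
                n_pos, n_neg, labels.family.get(t),
            )
        )
    return out


def metrics_frame(metrics: Sequence[TaskMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.to_dict() for m in metrics])


def select_tx_strong_cp_weak(
    tx_metrics: Sequence[TaskMetrics],
    cp_metrics: Sequence[TaskMetrics],
    threshold: float = 0.7,
) -> list[str]:
    """Tasks where TX AUROC > threshold and CP AUROC < threshold (strict)."""
    tx = {m.task_id: m.auroc for m in tx_metrics}
    cp = {m.task_id: m.auroc for m in cp_metrics}
    if set(tx) != set(cp):
        raise ValueError("TX and CP metrics must cover identical task sets")
    return [t for t in tx if tx[t] > threshold and cp[t] < threshold]


def compare_feature_types(
    metrics_a: Mapping[str, float],
    metrics_b: Mapping[str, float],
    feature_type_a: str = "a",
    feature_type_b: str = "b",
    metric: str = "auroc",
) -> ComparisonResult:
    """One-sided Wilcoxon signed-rank test, H1: feature type a > b per task.

    Zero differences are dropped (standard Wilcoxon practice); the exact
    null distribution is used for fewer than 25 non-zero differences without
    ties, otherwise the normal approximation with continuity correction.
    """
    tasks = sorted(metrics_a)
    if set(tasks) != set(metrics_b):
        raise ValueError("metric dicts must be paired by task")
    d = np.array([metrics_a[t] - metrics_b[t] for t in tasks])
    nz = d[d != 0.0]
    median_diff = float(np.median(d)) if d.size else 0.0
    if nz.size == 0:
        return ComparisonResult(
            feature_type_a, feature_type_b, metric, len(tasks),
            None, median_diff, degenerate=True,
        )
    ties = len(np.unique(np.abs(nz))) < nz.size
    method = "exact" if (nz.size < 25 and not ties) else "approx"
    res = stats.wilcoxon(
        nz, alternative="greater", method=method, correction=(method == "approx")
    )
    return ComparisonResult(
        feature_type_a, feature_type_b, metric, len(tasks),
        float(res.pvalue), median_diff,
    )


def group_by_family(
    metrics_by_feature_type: Mapping[str, Sequence[TaskMetrics]],
    annotation: Mapping[str, str] | None = None,
    metric: str = "auroc",
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Per-family metric summaries and within-family feature-type comparisons.

    ``annotation`` maps task -> protein family; tasks without an annotation
    are summarised under the remainder group ``"(unannotated)"``.  Empty
    families are omitted with a warning.  Returns a summary frame with
    (family, feature_type, mean, sd, n_tasks) rows and all pairwise
    within-family one-sided comparisons.
    """
    ft_names = list(metrics_by_feature_type)
    if annotation is None:
        first = metrics_by_feature_type[ft_names[0]]
        annotation = {m.task_id: m.family for m in first if m.family}

    def fam_of(task: str) -> str:
        return annotation.get(task, "(unannotated)")

    rows = []
    comparisons: list[ComparisonResult] = []
    families = sorted(
        {fam_of(m.task_id) for m in metrics_by_feature_type[ft_names[0]]}
    )
    for fam in families:
        per_ft: dict[str, dict[str, float]] = {}
        for ft in ft_names:
            vals = {
                m.task_id: getattr(m, metric)
                for m in metrics_by_feature_type[ft]
                if fam_of(m.task_id) == fam
            }
            per_ft[ft] = vals
            if not vals:
                warnings.warn(f"family {fam!r} empty for {ft}", stacklevel=2)
                continue
            arr = np.array(list(vals.values()))
            rows.append(
                {
                    "family": fam, "feature_type": ft, "metric": metric,
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                    "n_tasks": arr.size,
                }
            )
        for i, a in enumerate(ft_names):
            for b in ft_names[i + 1:]:
                common = set(per_ft[a]) & set(per_ft[b])
                if len(common) < 2:
                    continue
                cmp = compare_feature_types(
                    {t: per_ft[a][t] for t in common},
                    {t: per_ft[b][t] for t in common},
                    f"{a}[{fam}]", f"{b}[{fam}]", metric,
                )
                comparisons.append(cmp)
    return pd.DataFrame(rows), comparisons
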