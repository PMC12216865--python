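"""CLIP-style contrastive pretraining on paired (CP, TX) profiles.

Two MLP encoders (one per modality) map masked profiles to a 512-d output;
linear projection heads map those to a shared 256-d contrastive space where
the symmetric InfoNCE objective pulls together the CP replicate and TX
profile of the same compound and pushes apart mismatched in-batch pairs.
At embedding time the projection head is discarded and only the CP encoder
is used, so embeddings exist for compounds without TX data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field


import numpy as np
from scipy.special import logsumexp

from ._nn import MLP, Adam, minibatches
from .profiles import PairSet, ProfileMatrix, SplitAssignment

logger = logging.getLogger(__name__)

_NORM_EPS = 1e-12  # guards row normalisation inside the training loop only


@dataclass(frozen=True)
class CLConfig:
    """Hyperparameters of the contrastive pretraining stage.

    Defaults follow the full-scale architecture (CP encoder [1024]*3, TX
    encoder [4096]*3, encoder output 512, projection 256).  The temperature
    divides similarities inside the softmax and controls how concentrated
    the representation space is; it is a fixed scalar, not learned.
    """

    cp_hidden_sizes: tuple[int, ...] = (1024, 1024, 1024)
    tx_hidden_sizes: tuple[int, ...] = (4096, 4096, 4096)
    encoder_output_dim: int = 512
    projection_dim: int = 256
    temperature: float = 0.07
    mask_rate: float = 0.10
    batch_size: int = 256
    epochs: int = 50
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not (0.0 <= self.mask_rate < 1.0):
            raise ValueError("mask_rate must lie in [0, 1)")
        for sizes in (self.cp_hidden_sizes, self.tx_hidden_sizes):
            if any(s <= 0 for s in sizes):
                raise ValueError("layer sizes must be positive")
        if self.encoder_output_dim <= 0 or self.projection_dim <= 0:
            raise ValueError("output/projection dims must be positive")


@dataclass
class EncodedBatch:
    """Projected outputs of a batch of matched (CP, TX) pairs."""

    x: np.ndarray  # (N, projection_dim) CP side
    z: np.ndarray  # (N, projection_dim) TX side

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.x.shape != self.z.shape:
            raise ValueError("x and z must have identical shapes")

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass
class CLModel:
    """Trained contrastive model: two encoders plus projection heads."""

    cp_encoder: MLP
    tx_encoder: MLP
    cp_projection: MLP  # single linear layer (512 -> 256)
    tx_projection: MLP
    config: CLConfig
    history: list[dict] = field(default_factory=list)
    cp_feature_names: list[str] = field(default_factory=list)


def mask_features(
    X: np.ndarray, rate: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Zero a fresh uniformly random ``floor(rate*d)`` features per row.

    Profiles are Z-scores, so zero is control-like; masking is the
    augmentation applied to both modalities before encoding.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("mask rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.array(X, dtype=np.float64)
    n, d = X.shape
    m = int(rate * d)
    if m == 0:
        return X
    # per-row random subset without replacement via argpartition of uniforms
    u = rng.random((n, d))
    idx = np.argpartition(u, m - 1, axis=1)[:, :m]
    np.put_along_axis(X, idx, 0.0, axis=1)
    return X


def cosine_similarity(x: np.ndarray, z: np.ndarray) -> float:
    """Cosine similarity x.z / (||x|| ||z||); undefined for zero vectors."""
    nx, nz = np.linalg.norm(x), np.linalg.norm(z)
    if nx == 0.0 or nz == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(x @ z / (nx * nz))


def _normalize_rows(a: np.ndarray) -> np.ndarray:
    return a / np.maximum(np.linalg.norm(a, axis=1, keepdims=True), _NORM_EPS)


def _infonce_from_sim(sim: np.ndarray, temperature: float) -> float:
    """Symmetric InfoNCE from a pairwise similarity matrix.

    Sum of the two directional cross-entropy terms (CP->TX retrieval over
    rows, TX->CP retrieval over columns), each averaged over the batch.
    """
    n = sim.shape[0]
    s = sim / temperature
    diag = np.diag(s)
    row = logsumexp(s, axis=1)
    col = logsumexp(s, axis=0)
    return float((row.sum() - diag.sum()) / n + (col.sum() - diag.sum()) / n)


def infonce_loss(batch: EncodedBatch, temperature: float) -> float:
    """Symmetric InfoNCE over a batch of matched projected pairs."""
    if batch.n < 2:
        raise ValueError("InfoNCE needs a batch of at least 2 pairs")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if not (np.isfinite(batch.x).all() and np.isfinite(batch.z).all()):
        raise ValueError("non-finite projections in batch")
    sim = _normalize_rows(batch.x) @ _normalize_rows(batch.z).T
    return _infonce_from_sim(sim, temperature)


def _infonce_loss_and_grads(
    x: np.ndarray, z: np.ndarray, temperature: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus analytic gradients wrt the unnormalised projections."""
    n = x.shape[0]
    xn = _normalize_rows(x)
    zn = _normalize_rows(z)
    sim = xn @ zn.T
    loss = _infonce_from_sim(sim, temperature)

    s = sim / temperature
    p_row = np.exp(s - logsumexp(s, axis=1, keepdims=True))
    p_col = np.exp(s - logsumexp(s, axis=0, keepdims=True))
    eye = np.eye(n)
    g_sim = (p_row - eye + p_col - eye) / (n * temperature)

    g_xn = g_sim @ zn
    g_zn = g_sim.T @ xn
    # through row normalisation: d(x/||x||) applied to upstream gradient
    def through_norm(a: np.ndarray, an: np.ndarray, g: np.ndarray) -> np.ndarray:
        norms = np.maximum(np.linalg.norm(a, axis=1, keepdims=True), _NORM_EPS)
        return (g - (g * an).sum(axis=1, keepdims=True) * an) / norms

    return loss, through_norm(x, xn, g_xn), through_norm(z, zn, g_zn)


def _check_pairs_in_split(pairs: PairSet, split: SplitAssignment) -> None:
    allowed = set(split.compounds("train")) | set(split.compounds("valid"))
    outside = set(pairs.compound_ids) - allowed
    if outside:
        raise ValueError(
            f"pretraining pairs include {len(outside)} compounds outside "
            "train+valid; restrict the PairSet first"
        )


def train_contrastive(
    pairs: PairSet,
    cp: ProfileMatrix,
    tx: ProfileMatrix,
    split: SplitAssignment,
    cfg: CLConfig,
) -> CLModel:
    """Train the two-encoder contrastive model on train pairs.

    Feature learning uses train and validation compounds only: gradient
    steps on the train portion, model selection by validation InfoNCE
    (computed unmasked for determinism); the parameters with the lowest
    validation loss are retained.
    """
    train_pairs = pairs.restrict_to(split.compounds("train"))
    valid_pairs = pairs.restrict_to(split.compounds("valid"))
    if len(train_pairs) == 0:
        raise ValueError("no training pairs after restricting to train split")
    _check_pairs_in_split(
        PairSet(
            train_pairs.cp_row_ids + valid_pairs.cp_row_ids,
            train_pairs.compound_ids + valid_pairs.compound_ids,
        ),
        split,
    )

    rng = np.random.default_rng(cfg.seed)
    cp_enc = MLP([cp.n_features, *cfg.cp_hidden_sizes, cfg.encoder_output_dim], rng)
    tx_enc = MLP([tx.n_features, *cfg.tx_hidden_sizes, cfg.encoder_output_dim], rng)
    cp_proj = MLP([cfg.encoder_output_dim, cfg.projection_dim], rng)
    tx_proj = MLP([cfg.encoder_output_dim, cfg.projection_dim], rng)
    modules = [cp_enc, tx_enc, cp_proj, tx_proj]
    opt = Adam([p for m in modules for p in m.params], lr=cfg.learning_rate)

    cp_idx = cp.row_index()
    tx_idx = tx.compound_row_index()

    def gather(ps: PairSet) -> tuple[np.ndarray, np.ndarray]:
        u = cp.values[[cp_idx[r] for r in ps.cp_row_ids]]
        v = tx.values[[tx_idx[c] for c in ps.compound_ids]]
        return u, v

    u_tr, v_tr = gather(train_pairs)
    u_va, v_va = gather(valid_pairs) if len(valid_pairs) >= 2 else (None, None)

    def valid_loss() -> float:
        if u_va is None:
            return float("nan")
        x = cp_proj.forward(cp_enc.forward(u_va))
        z = tx_proj.forward(tx_enc.forward(v_va))
        return infonce_loss(EncodedBatch(x, z), cfg.temperature)

    history: list[dict] = []
    best = (np.inf, [m.copy_params() for m in modules])
    for epoch in range(cfg.epochs):
        losses = []
        for batch in minibatches(len(train_pairs), cfg.batch_size, rng):
            if batch.size < 2:
                continue
            u = mask_features(u_tr[batch], cfg.mask_rate, rng)
            v = mask_features(v_tr[batch], cfg.mask_rate, rng)
            e_u = cp_enc.forward(u, train=True)
            e_v = tx_enc.forward(v, train=True)
            x = cp_proj.forward(e_u, train=True)
            z = tx_proj.forward(e_v, train=True)
            loss, gx, gz = _infonce_loss_and_grads(x, z, cfg.temperature)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite InfoNCE at epoch {epoch}: {loss}"
                )
            losses.append(loss)
            g_eu, g_proj_cp = cp_proj.backward(gx)
            g_ev, g_proj_tx = tx_proj.backward(gz)
            _, g_enc_cp = cp_enc.backward(g_eu)
            _, g_enc_tx = tx_enc.backward(g_ev)
            opt.step(g_enc_cp + g_enc_tx + g_proj_cp + g_proj_tx)
        vl = valid_loss()
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "valid_loss": vl}
        )
        score = vl if np.isfinite(vl) else history[-1]["train_loss"]
        if score < best[0]:
            best = (score, [m.copy_params() for m in modules])
    for m, params in zip(modules, best[1]):
        m.set_params(params)
    logger.info("contrastive training done: best selection loss %.4f", best[0])
    return CLModel(
        cp_enc, tx_enc, cp_proj, tx_proj, cfg, history, list(cp.feature_names)
    )


def embed_cp(model: CLModel, cp: ProfileMatrix) -> ProfileMatrix:
    """CP-only embeddings: encoder output (512-d), projection head discarded.

    No masking at inference; deterministic.  Returned as a CP-modality
    ProfileMatrix so replicate aggregation and downstream evaluation apply
    unchanged.
    """
    if cp.n_features != model.cp_encoder.d_in:
        raise ValueError(
            f"CP matrix has {cp.n_features} features; model expects "
            f"{model.cp_encoder.d_in}"
        )
    emb = model.cp_encoder.forward(cp.values)
    names = [f"emb_{j:03d}" for j in range(emb.shape[1])]
    return ProfileMatrix(emb, list(cp.row_ids), list(cp.compound_ids), names, "CP")
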