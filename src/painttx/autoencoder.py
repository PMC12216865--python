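"""Bimodal masked autoencoder: CP encoder, CP decoder, TX decoder.

The encoder consumes a masked CP profile; its output is the learned
embedding.  Two decoders reconstruct the (unmasked) CP profile and the
compound's TX profile from that embedding, so the embedding is forced to
carry transcriptome-predictive information while only ever needing CP data
at inference time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP, Adam, minibatches
from .contrastive import mask_features
from .profiles import PairSet, ProfileMatrix, SplitAssignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BAEConfig:
    """Hyperparameters of the bimodal autoencoder stage."""

    encoder_hidden: tuple[int, ...] = (1024, 512, 512)
    embedding_dim: int = 512
    cp_decoder_hidden: tuple[int, ...] = (512, 512, 1024)
    tx_decoder_hidden: tuple[int, ...] = (1024, 2048, 4096)
    mask_rate: float = 0.10
    batch_size: int = 256
    epochs: int = 50
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")
        if not (0.0 <= self.mask_rate < 1.0):
            raise ValueError("mask_rate must lie in [0, 1)")


@dataclass
class ReconBatch:
    """Originals and reconstructions for one batch of (CP, TX) pairs."""

    u: np.ndarray   # original CP rows
    v: np.ndarray   # original TX rows
    u_hat: np.ndarray  # CP reconstructions
    v_hat: np.ndarray  # TX reconstructions

    def __post_init__(self) -> None:
        if self.u.shape != self.u_hat.shape or self.v.shape != self.v_hat.shape:
            raise ValueError("originals and reconstructions must be shape-matched")
        if self.u.shape[0] != self.v.shape[0]:
            raise ValueError("u and v must cover the same batch rows")


@dataclass
class BAEModel:
    encoder: MLP
    cp_decoder: MLP
    tx_decoder: MLP
    config: BAEConfig
    history: list[dict] = field(default_factory=list)
    cp_feature_names: list[str] = field(default_factory=list)


def bae_loss(batch: ReconBatch, reduction: str = "mean") -> float:
    """Reconstruction loss: half CP error plus half TX error.

    ``reduction="mean"`` (default) averages squared residuals over rows and
    features per modality, keeping the magnitude invariant to batch size and
    feature dimension; ``reduction="sum"`` is the raw summed form.
    """
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    red = np.mean if reduction == "mean" else np.sum
    du = red((batch.u_hat - batch.u) ** 2)
    dv = red((batch.v_hat - batch.v) ** 2)
    return float(0.5 * du + 0.5 * dv)


def train_bae(
    pairs: PairSet,
    cp: ProfileMatrix,
    tx: ProfileMatrix,
    split: SplitAssignment,
    cfg: BAEConfig,
) -> BAEModel:
    """Train the masked bimodal autoencoder on train+valid compounds.

    The CP input is masked afresh each batch; reconstruction targets are the
    unmasked originals.  The parameter set with the lowest validation loss
    is retained.  Deterministic for a fixed seed.
    """
    train_pairs = pairs.restrict_to(split.compounds("train"))
    valid_pairs = pairs.restrict_to(split.compounds("valid"))
    if len(train_pairs) == 0:
        raise ValueError("no training pairs after restricting to train split")

    rng = np.random.default_rng(cfg.seed)
    enc = MLP([cp.n_features, *cfg.encoder_hidden, cfg.embedding_dim], rng)
    dec_cp = MLP([cfg.embedding_dim, *cfg.cp_decoder_hidden, cp.n_features], rng)
    dec_tx = MLP([cfg.embedding_dim, *cfg.tx_decoder_hidden, tx.n_features], rng)
    modules = [enc, dec_cp, dec_tx]
    opt = Adam([p for m in modules for p in m.params], lr=cfg.learning_rate)

    cp_idx = cp.row_index()
    tx_idx = tx.compound_row_index()

    def gather(ps: PairSet) -> tuple[np.ndarray, np.ndarray]:
        u = cp.values[[cp_idx[r] for r in ps.cp_row_ids]]
        v = tx.values[[tx_idx[c] for c in ps.compound_ids]]
        return u, v

    u_tr, v_tr = gather(train_pairs)
    u_va, v_va = gather(valid_pairs) if len(valid_pairs) else (None, None)

    def valid_loss() -> float:
        if u_va is None:
            return float("nan")
        emb = enc.forward(u_va)
        return bae_loss(ReconBatch(u_va, v_va, dec_cp.forward(emb), dec_tx.forward(emb)))

    history: list[dict] = []
    best = (np.inf, [m.copy_params() for m in modules])
    for epoch in range(cfg.epochs):
        losses = []
        for batch in minibatches(len(train_pairs), cfg.batch_size, rng):
            u, v = u_tr[batch], v_tr[batch]
            u_masked = mask_features(u, cfg.mask_rate, rng)
            emb = enc.forward(u_masked, train=True)
            u_hat = dec_cp.forward(emb, train=True)
            v_hat = dec_tx.forward(emb, train=True)
            loss = bae_loss(ReconBatch(u, v, u_hat, v_hat))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite BAE loss at epoch {epoch}")
            losses.append(loss)
            g_u = (u_hat - u) / u.size          # d/du_hat of 0.5*mean(.^2)
            g_v = (v_hat - v) / v.size
            g_emb_cp, g_dec_cp = dec_cp.backward(g_u)
            g_emb_tx, g_dec_tx = dec_tx.backward(g_v)
            _, g_enc = enc.backward(g_emb_cp + g_emb_tx)
            opt.step(g_enc + g_dec_cp + g_dec_tx)
        vl = valid_loss()
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "valid_loss": vl}
        )
        score = vl if np.isfinite(vl) else history[-1]["train_loss"]
        if score < best[0]:
            best = (score, [m.copy_params() for m in modules])
    for m, params in zip(modules, best[1]):
        m.set_params(params)
    logger.info("BAE training done: best selection loss %.4f", best[0])
    return BAEModel(enc, dec_cp, dec_tx, cfg, history, list(cp.feature_names))


def embed_cp_bae(model: BAEModel, cp: ProfileMatrix) -> ProfileMatrix:
    """Encoder output as embeddings; no masking at inference, decoders unused."""
    if cp.n_features != model.encoder.d_in:
        raise ValueError(
            f"CP matrix has {cp.n_features} features; model expects "
            f"{model.encoder.d_in}"
        )
    emb = model.encoder.forward(cp.values)
    names = [f"emb_{j:03d}" for j in range(emb.shape[1])]
    return ProfileMatrix(emb, list(cp.row_ids), list(cp.compound_ids), names, "CP")
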