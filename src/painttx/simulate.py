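"""Synthetic paired CP/TX screen with known latent structure.

The generator emulates the structure of a high-content compound screen with
paired readouts: each compound carries a latent state split into *shared*
dimensions (biology visible to both morphology and expression, carrying the
MoA cluster structure) and *TX-only* dimensions (biology visible only to the
transcriptome).  CP replicates are noisy linear images of the shared latent;
the single TX profile is a less noisy linear image of the full latent.
Bioactivity tasks are thresholded noisy linear scores of the latent, a
configurable fraction depending only on TX-only dimensions — tasks that
transcriptomics can solve but morphology cannot.

The model is linear-Gaussian: the simplest structure under which cross-modal
contrastive alignment is provably possible, so a failure downstream indicts
the implementation rather than the data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import (
    BioactivityMatrix,
    CompoundTable,
    ProfileMatrix,
)

DEFAULT_FAMILIES = (
    "GPCR Transmembrane Receptor",
    "Hydrolase",
    "Ion Channel",
    "Transferase (Kinase)",
    "Cell Proliferation",
)


@dataclass(frozen=True)
class ScreenConfig:
    """Knobs of the synthetic screen.

    Dimensions follow the real assays: ~800 morphological features per CP
    profile; TX profiles are gene-level and much wider.  Z-score marginals
    are centred on the DMSO control (zero) by construction.
    """

    n_compounds: int = 2000
    n_moa_classes: int = 12
    d_cp: int = 800
    d_tx: int = 4000
    d_latent_shared: int = 16
    d_latent_tx_only: int = 8
    replicate_count_range: tuple[int, int] = (2, 4)
    cp_noise_sd: float = 1.5
    cp_struct_noise_sd: float = 1.2
    cp_nuisance_sd: float = 0.0
    cp_noise_rank: int = 8
    frac_weak_cp_dims: float = 0.5
    cp_weak_gain: float = 0.4
    tx_noise_sd: float = 0.3
    moa_centroid_scale: float = 1.2
    moa_within_sd: float = 1.0
    n_tasks: int = 60
    frac_tx_only_tasks: float = 0.4
    task_noise_sd: float = 0.5
    label_density: float = 0.7
    scaffold_mean_size: float = 3.0
    families: tuple[str, ...] = DEFAULT_FAMILIES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_moa_classes", "d_cp", "d_tx",
                     "d_latent_shared", "n_tasks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_latent_tx_only < 0:
            raise ValueError("d_latent_tx_only must be >= 0")
        if min(self.cp_noise_sd, self.cp_struct_noise_sd, self.cp_nuisance_sd,
               self.tx_noise_sd) < 0:
            raise ValueError("noise sds must be >= 0")
        if self.cp_noise_rank < 1:
            raise ValueError("cp_noise_rank must be >= 1")
        if not (0.0 <= self.frac_weak_cp_dims <= 1.0):
            raise ValueError("frac_weak_cp_dims must lie in [0, 1]")
        if self.cp_weak_gain < 0:
            raise ValueError("cp_weak_gain must be >= 0")
        if not (0.0 <= self.frac_tx_only_tasks <= 1.0):
            raise ValueError("frac_tx_only_tasks must lie in [0, 1]")
        if not (0.0 < self.label_density <= 1.0):
            raise ValueError("label_density must lie in (0, 1]")
        lo, hi = self.replicate_count_range
        if lo < 1 or hi < lo:
            raise ValueError("replicate_count_range must be 1 <= lo <= hi")

    def with_(self, **kw) -> "ScreenConfig":
        return replace(self, **kw)


@dataclass
class SyntheticScreen:
    """Generated bundle: profiles, annotations, labels and ground truth."""

    cp: ProfileMatrix
    tx: ProfileMatrix
    compounds: CompoundTable
    bioactivity: BioactivityMatrix
    latents: np.ndarray  # (n_compounds, d_shared + d_tx_only); row order = compounds
    task_weights: np.ndarray  # (n_tasks, d_shared + d_tx_only)
    config: ScreenConfig

    @property
    def compound_ids(self) -> list[str]:
        return self.compounds.compound_ids


def _rng(cfg: ScreenConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((cfg.seed, salt))


def sample_compounds(cfg: ScreenConfig) -> tuple[CompoundTable, np.ndarray]:
    """Draw compounds with MoA classes, latents and scaffold groups.

    Latent = MoA centroid + within-class perturbation on the shared
    dimensions, plus independent standard-normal TX-only dimensions.
    Scaffold group sizes are geometric with the configured mean, independent
    of MoA, so the split is a pure generalization control.
    """
    if cfg.n_moa_classes > cfg.n_compounds:
        raise ValueError("n_moa_classes cannot exceed n_compounds")
    rng = _rng(cfg, 1)
    n, ds, dt = cfg.n_compounds, cfg.d_latent_shared, cfg.d_latent_tx_only

    centroids = rng.normal(0.0, cfg.moa_centroid_scale, size=(cfg.n_moa_classes, ds))
    # round-robin class assignment guarantees every class is populated
    moa = np.arange(n) % cfg.n_moa_classes
    rng.shuffle(moa)
    shared = centroids[moa] + rng.normal(0.0, cfg.moa_within_sd, size=(n, ds))
    tx_only = rng.normal(0.0, 1.0, size=(n, dt))
    latents = np.hstack([shared, tx_only])

    # geometric scaffold group sizes (mean = scaffold_mean_size)
    p = min(1.0, 1.0 / cfg.scaffold_mean_size)
    sizes: list[int] = []
    while sum(sizes) < n:
        sizes.append(int(rng.geometric(p)))
    sizes[-1] -= sum(sizes) - n
    scaffold_keys = np.repeat(
        [f"SCAF{i:05d}" for i in range(len(sizes))], sizes
    )
    rng.shuffle(scaffold_keys)

    frame = pd.DataFrame(
        {
            "compound_id": [f"CPD{i:05d}" for i in range(n)],
            "smiles": pd.NA,
            "scaffold_key": scaffold_keys,
            "moa": [f"MoA{m:02d}" for m in moa],
        }
    )
    return CompoundTable(frame), latents


def render_profiles(
    latents: np.ndarray, cfg: ScreenConfig, compound_ids: Sequence[str]
) -> tuple[ProfileMatrix, ProfileMatrix]:
    """Render CP replicates (shared latent only) and TX rows (full latent).

    CP noise has three parts mirroring how replicate variation behaves in
    high-content screens: i.i.d. per-feature noise (``cp_noise_sd``), a
    low-rank *structured* per-replicate component (``cp_struct_noise_sd``,
    rank ``cp_noise_rank``) standing in for plate/batch technical factors,
    and a low-rank per-compound *nuisance* shared by all replicates of a
    compound (``cp_nuisance_sd``, default off) standing in for
    compound-specific technical effects that do not average out under
    replicate aggregation.  Neither structured component appears in TX, so
    it is removable by cross-modal pretraining but pollutes raw CP
    distances.

    Shared latent dimensions carry heterogeneous CP gains: a
    ``frac_weak_cp_dims`` fraction (the trailing dimensions) is expressed in
    CP at gain ``cp_weak_gain`` while TX sees every dimension at full gain —
    biology that morphology reports only faintly.  Raw Euclidean CP
    distances are dominated by the strong dimensions plus noise, whereas a
    representation aligned to TX can re-amplify the weak ones.
    """
    rng = _rng(cfg, 2)
    n = latents.shape[0]
    ds = cfg.d_latent_shared
    shared, full = latents[:, :ds], latents
    n_weak = int(round(cfg.frac_weak_cp_dims * ds))
    gains = np.ones(ds)
    if n_weak:
        gains[ds - n_weak:] = cfg.cp_weak_gain

    # loading matrices with unit per-feature signal variance in expectation
    a_cp = rng.normal(0.0, 1.0 / np.sqrt(ds), size=(ds, cfg.d_cp))
    a_tx = rng.normal(0.0, 1.0 / np.sqrt(full.shape[1]), size=(full.shape[1], cfg.d_tx))
    q = cfg.cp_noise_rank
    b_struct = rng.normal(0.0, 1.0 / np.sqrt(q), size=(q, cfg.d_cp))
    b_nuis = rng.normal(0.0, 1.0 / np.sqrt(q), size=(q, cfg.d_cp))

    lo, hi = cfg.replicate_count_range
    rep_counts = rng.integers(lo, hi + 1, size=n)
    cp_rows, cp_row_ids, cp_cids = [], [], []
    for i, cid in enumerate(compound_ids):
        base = (shared[i] * gains) @ a_cp
        base = base + (rng.normal(0.0, cfg.cp_nuisance_sd, size=q) @ b_nuis)
        for r in range(rep_counts[i]):
            noise = rng.normal(0.0, cfg.cp_noise_sd, size=cfg.d_cp)
            noise += rng.normal(0.0, cfg.cp_struct_noise_sd, size=q) @ b_struct
            cp_rows.append(base + noise)
            cp_row_ids.append(f"{cid}_rep{r}")
            cp_cids.append(cid)
    cp = ProfileMatrix(
        np.vstack(cp_rows), cp_row_ids, cp_cids,
        [f"cp_f{j:04d}" for j in range(cfg.d_cp)], "CP",
    )

    tx_vals = full @ a_tx + rng.normal(0.0, cfg.tx_noise_sd, size=(n, cfg.d_tx))
    tx = ProfileMatrix(
        tx_vals, [f"{c}_tx" for c in compound_ids], list(compound_ids),
        [f"tx_g{j:05d}" for j in range(cfg.d_tx)], "TX",
    )
    return cp, tx


def sample_bioactivity(
    latents: np.ndarray, cfg: ScreenConfig, compound_ids: Sequence[str]
) -> tuple[BioactivityMatrix, np.ndarray]:
    """Threshold noisy linear scores of the latent into binary tasks.

    A ``frac_tx_only_tasks`` share of tasks weight only the TX-only latent
    dimensions; the remaining tasks weight the full latent with a random
    per-task emphasis (Dirichlet over strong-CP shared, weak-CP shared and
    TX-only dimension groups), emulating assay panels whose biology is
    variably visible to morphology.  Thresholding at the score median gives
    ~50% positive rate before subsampling by ``label_density``.  Task
    families are assigned round-robin from the configured list.
    """
    rng = _rng(cfg, 3)
    n, d = latents.shape
    ds = cfg.d_latent_shared
    dt = d - ds
    n_weak = int(round(cfg.frac_weak_cp_dims * ds))
    n_strong = ds - n_weak
    n_tx_only = int(round(cfg.frac_tx_only_tasks * cfg.n_tasks))

    weights = rng.normal(0.0, 1.0, size=(cfg.n_tasks, d))
    weights[:n_tx_only, :ds] = 0.0  # TX-only tasks ignore shared dims
    if dt == 0:
        weights[:n_tx_only] = rng.normal(0.0, 1.0, size=(n_tx_only, d))
    groups = [np.arange(n_strong), np.arange(n_strong, ds), np.arange(ds, d)]
    for j in range(n_tx_only, cfg.n_tasks):
        emphasis = rng.dirichlet(np.ones(3))
        for grp, e in zip(groups, emphasis):
            if grp.size:
                gn = np.linalg.norm(weights[j, grp])
                if gn > 0:
                    weights[j, grp] *= np.sqrt(e) / gn
    norms = np.linalg.norm(weights, axis=1, keepdims=True)
    weights = weights / np.where(norms == 0, 1.0, norms)

    scores = latents @ weights.T + rng.normal(0.0, cfg.task_noise_sd, size=(n, cfg.n_tasks))
    thresholds = np.median(scores, axis=0)
    labels = (scores > thresholds).astype(float)
    if cfg.label_density < 1.0:
        mask = rng.random(size=labels.shape) >= cfg.label_density
        labels[mask] = np.nan

    task_ids = [f"TASK{j:03d}" for j in range(cfg.n_tasks)]
    family = {t: cfg.families[j % len(cfg.families)] for j, t in enumerate(task_ids)}
    bio = BioactivityMatrix(labels, list(compound_ids), task_ids, family)
    return bio, weights


def generate_screen(cfg: ScreenConfig) -> SyntheticScreen:
    """Compose the samplers into a full screen; reproducible from (cfg, seed)."""
    compounds, latents = sample_compounds(cfg)
    cids = compounds.compound_ids
    cp, tx = render_profiles(latents, cfg, cids)
    bio, weights = sample_bioactivity(latents, cfg, cids)
    return SyntheticScreen(cp, tx, compounds, bio, latents, weights, cfg)
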