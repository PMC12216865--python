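# Methods

`painttx` implements cross-modality representation learning for paired
high-content screens: Cell Painting (CP) morphological profiles and bulk
transcriptomics (TX) expression profiles of the same compound library. The
goal is a representation that is *trained* on both modalities but *generated*
from CP alone, because new compounds typically have only the cheap imaging
readout. Two pretraining routes are provided, together with the full
evaluation battery and a synthetic-screen generator that makes every stage
testable end to end.

## Data model

Profiles are Z-scores against the DMSO vehicle control: a CP profile is a
vector of ~800 morphological features per replicate well, a TX profile one
vector of gene-level robust adjusted Z-scores per compound. Each compound has
one TX row and one or more CP replicate rows; every CP replicate row of a
compound forms one (CP, TX) pretraining pair with the compound's single TX
row. Compounds missing a modality are dropped from pairing.

Data are split 70/10/20 into train/validation/test at the *compound* level,
grouped by Murcko scaffold (RDKit canonical scaffold SMILES; all acyclic
molecules share the reserved `<acyclic>` key), so structurally related
compounds never straddle a split boundary. The assignment is greedy:
scaffold groups sorted by size descending, each assigned to the split with
the largest remaining deficit relative to its target count; the seed
shuffles equal-size groups. On 1,000 geometric-size groups the realised
proportions are within 2% of target. Feature learning uses train+validation
compounds only; all reported numbers come from the held-out test compounds.

## Contrastive pretraining (CL)

Two MLP encoders (CP: hidden [1024, 1024, 1024]; TX: hidden
[4096, 4096, 4096]; both output 512) feed linear projection heads into a
256-d space where the symmetric InfoNCE loss is minimised over batches of N
matched pairs:

    L = -(1/N) Σ_i ln[exp(sim(x_i,z_i)/τ) / Σ_j exp(sim(x_i,z_j)/τ)]
        -(1/N) Σ_i ln[exp(sim(x_i,z_i)/τ) / Σ_j exp(sim(x_j,z_i)/τ)]

with `sim` the cosine similarity and τ the temperature. The two directional
terms are summed, not averaged. Both inputs are augmented by masking a
fresh uniformly random 10% of features to zero each batch (profiles are
Z-scores, so zero is control-like); the mask count per row is ⌊rate·d⌋.
At embedding time the projection heads are discarded and only the CP
encoder runs, unmasked — embeddings therefore exist for compounds without
TX data and are deterministic.

Unstated training details are fixed as: ReLU activations, linear output
layers, no normalisation layers; Adam at a constant learning rate; the
parameter set with the lowest validation InfoNCE (computed unmasked, for
determinism) is retained. τ defaults to 0.07 and is a fixed scalar, not a
learned parameter. All of these are configurable.

## Bimodal autoencoder pretraining (BAE)

One CP encoder (hidden [1024, 512, 512], embedding 512) and two decoders
(CP: [512, 512, 1024]; TX: [1024, 2048, 4096]) reconstruct *both*
modalities from a masked CP input — a masked autoencoder whose latent must
carry transcriptome-predictive information. The loss is half the CP
reconstruction error plus half the TX reconstruction error. The default
normalisation averages squared residuals over rows *and* features per
modality, which keeps the two halves comparable regardless of the very
different feature counts (800 vs 4000) and makes magnitudes batch-size
invariant; the raw summed form is available via `reduction="sum"`.
Reconstruction targets are the unmasked originals (standard
masked-autoencoder practice). Embeddings are the encoder output, unmasked,
independent of the decoders.

## Evaluation battery

**kNN cluster accuracy.** A feature space is scored by the fraction of
points whose k = 5 nearest Euclidean neighbours vote for the true cluster
label — compound identity for CP replicate clustering (replicate rows of
test compounds), MoA class for mechanism clustering (compound-level
features, median-aggregated over replicates, restricted to the 9
most-populated annotated MoA classes in the test split). Majority ties are
broken by the tied class containing the closest neighbour, which is
deterministic and order-independent. `knn_accuracy` supports both
include-self voting (mirroring a classifier fit and queried on the same
set) and leave-one-out voting. The benchmark driver uses leave-one-out:
include-self voting inflates every score and, under the nearest-neighbour
tie-break, the query point wins all-distinct ties so replicate accuracy
saturates near 1.0 even for pure noise. Note that leave-one-out replicate
voting needs k below the replicate count for a perfect score to be
attainable. t-SNE (init='random', learning_rate='auto', perplexity 10 for
replicate plots, 20 for MoA plots) provides the 2-D visual check.

**Multitask bioactivity classification.** A single MLP (3 hidden layers of
256, dropout 0.3, one sigmoid output per task) is trained on train+valid
compounds over all binarized assay tasks jointly, with binary cross-entropy
averaged over observed labels only (the label matrix is sparse). Optimiser:
Adam, learning rate 1e-4, weight decay 1e-5, batch 128, 100 epochs,
cosine-annealing warm restarts every 10 epochs; final-epoch weights are
used (the epoch budget is part of the protocol). Inputs are standardised
with training-set statistics. Training tasks need ≥25 positives, ≥25
negatives and ≥100 observed labels in train+valid; evaluated tasks need
≥25 positives and ≥25 negatives in the test split. Per task we report
AUROC (rank statistic, ties averaged), AUPRC as average precision
(step-wise, no interpolation) and RIPtoP-corrected AUPRC,
`(AUPRC − BASELINE)/(1 − BASELINE)` with BASELINE the positive prevalence
among the scored test labels, so 0 is the random baseline and 1 a perfect
model. The same configuration object is used for every feature type, so
the feature space is the only experimental variable. Feature types are
compared per task by a one-sided Wilcoxon signed-rank test (zero
differences dropped; exact null for n < 25 without ties, else normal
approximation with continuity correction), optionally grouped by protein
target family. The "TX-strong/CP-weak" subset keeps tasks with TX AUROC
strictly above 0.7 and CP AUROC strictly below 0.7.

## Synthetic screen generator

The study's data are proprietary, so the generator produces a linear-
Gaussian stand-in with known ground truth — the simplest structure under
which cross-modal alignment is provably possible, so downstream failures
indict the implementation rather than the data.

Each compound carries a latent state: `d_latent_shared = 16` shared
dimensions holding the MoA structure (class centroids drawn with scale 1.2,
within-class spread 1.0, classes assigned round-robin then shuffled) plus
`d_latent_tx_only = 8` dimensions visible only to TX. TX rows are a fixed
random linear image of the full latent plus i.i.d. noise (sd 0.3). CP
replicates see only the shared dimensions, with heterogeneous gains: half
the shared dimensions are expressed at gain 0.4 (weakly CP-visible biology,
recoverable across 800 features at signal-to-noise ≈ 2 but drowned in raw
Euclidean distances). CP noise has two parts: i.i.d. per-feature noise
(sd 1.5) and a rank-8 structured per-replicate component (sd 1.2) standing
in for plate/batch technical factors — isotropic noise alone barely moves
kNN accuracy in 800 dimensions because high-dimensional distances
concentrate, whereas low-rank noise does, and it is exactly what
cross-modal pretraining can learn to project out since TX never contains
it. An optional per-compound nuisance component (off by default) models
technical effects that survive replicate aggregation. Defaults put
raw-CP replicate kNN accuracy in the realistic low regime while leaving
the latent MoA ceiling near 0.95.

Bioactivity tasks are thresholded noisy linear scores of the latent
(threshold at the score median, so ~50% positives; labels observed with
probability 0.7). A 40% share of tasks weight only TX-only dimensions
(solvable by TX, unsolvable from CP by construction); the rest draw a
random Dirichlet emphasis over the strong-shared / weak-shared / TX-only
dimension groups, emulating assay panels whose biology is variably visible
to morphology. Scaffold groups have geometric sizes (mean 3) independent of
MoA, so the split is a pure generalisation control. Everything is
reproducible bit-for-bit from (config, seed).

What the generator does *not* emulate: images or reads, plate layouts,
batch/plate effects correlated between modalities, dose–response,
non-linear latent-to-profile maps (a config hook, not a default), and the
long-tailed assay/task distributions of a real corporate screening deck.
Passing tests therefore show the algorithms behave as designed under a
faithful-but-idealised screen; they do not certify performance figures on
any real proprietary screen.

## Benchmark profile and expected behaviour

`painttx.benchmark.small_profile(seed)` is the package's CPU-scale
evaluation bundle, used by the test suite and `scripts/acceptance.py`: the
screen keeps full profile widths (800 CP features, 4000 TX genes, 2000
compounds, 3 replicates) while network widths and epochs are reduced to
desk scale (CL encoders [256, 256] → 128, projection 64, 40 epochs; BAE
encoder [256, 128] → 64, 20 epochs; multitask hidden 128 × 2 layers, 60
epochs; learning rate 1e-3 throughout). One full run takes a few minutes
on one CPU core.

Under this profile the pipeline reproduces the qualitative ordering the
method is designed to deliver: contrastive embeddings improve sharply over
raw CP on replicate clustering (~0.89 vs ~0.17 leave-one-out kNN) and
modestly on MoA clustering; on the TX-strong/CP-weak task subset the
CL-embedding multitask model's mean AUROC exceeds the raw-CP model's; the
bimodal autoencoder gives at most minor improvements; label-permuted
control tasks stay at AUROC ≈ 0.5.

## Numerical choices and degenerate inputs

- Cosine similarity raises on zero-norm vectors at the API level; inside
  the training loop norms are clamped at 1e-12 (a freshly initialised
  encoder can emit an all-zero row).
- InfoNCE and the masked BCE use log-sum-exp / log1p stable forms; training
  aborts with diagnostics on non-finite losses.
- MLP weights use He initialisation; dropout is inverted (inference needs
  no rescaling); all randomness flows through `numpy.random.Generator`
  seeded from the config, so every training run is reproducible.
- A single scaffold covering all compounds degenerates to everything-train
  with a warning; MoA evaluation clamps `top_m` to the available classes
  with a warning; tasks with one observed test class are skipped with a
  warning; single-replicate compounds warn under leave-one-out voting.
- Wilcoxon comparisons with all-zero differences return a flagged
  degenerate result instead of a p-value.

## Known limitations

- The neural stack is a purpose-built numpy implementation (no GPU, no
  autograd); it is exact but not fast, which is why the bundled profile
  reduces widths and epochs rather than data dimensions.
- Multitask model selection uses final-epoch weights per protocol; with
  very small label sets this can mildly overfit relative to early stopping.
- The generator's linearity means reported orderings certify correctness
  of the machinery, not performance on real screens.
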