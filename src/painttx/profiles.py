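"""Profile data model: Z-scored CP/TX matrices, pairing, scaffolds, splits.

Cell Painting (CP) profiles are per-replicate morphological feature vectors;
transcriptomics (TX) profiles are per-compound gene-level robust adjusted
Z-scores.  Each compound has exactly one TX row and one or more CP replicate
rows.  Everything downstream (pretraining, clustering, bioactivity modelling)
consumes these containers.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved scaffold key shared by all acyclic molecules (Murcko scaffold of a
#: ring-free molecule is empty); they move through the split as one group.
ACYCLIC_SCAFFOLD = "<acyclic>"

SPLIT_NAMES = ("train", "valid", "test")


@dataclass
class ProfileMatrix:
    """A (rows x features) matrix of profile Z-scores with identifiers.

    Parameters
    ----------
    values
        Float matrix, no missing values.  Rows are replicates (CP) or
        compounds (TX); columns are features.
    row_ids
        Unique identifier per row (e.g. well/replicate id).
    compound_ids
        Compound identifier per row.  For TX there must be exactly one row
        per compound; for CP at least one.
    feature_names
        Column identifiers.
    modality
        Either ``"CP"`` or ``"TX"``.
    """

    values: np.ndarray
    row_ids: list[str]
    compound_ids: list[str]
    feature_names: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.row_ids = [str(r) for r in self.row_ids]
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if self.modality not in ("CP", "TX"):
            raise ValueError(f"modality must be 'CP' or 'TX', got {self.modality!r}")
        n, d = self.values.shape
        if len(self.row_ids) != n or len(self.compound_ids) != n:
            raise ValueError("row_ids/compound_ids length must match value rows")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must match value columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite (no missing values)")
        if len(set(self.row_ids)) != n:
            raise ValueError("row_ids must be unique")
        if self.modality == "TX":
            dupes = [c for c, k in Counter(self.compound_ids).items() if k > 1]
            if dupes:
                raise ValueError(
                    f"TX matrix must have exactly one row per compound; "
                    f"duplicated: {dupes[:5]}"
                )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def compounds(self) -> set[str]:
        return set(self.compound_ids)

    def rows_for(self, compound_ids: Iterable[str]) -> "ProfileMatrix":
        """Subset to rows whose compound is in ``compound_ids`` (order kept)."""
        keep = set(compound_ids)
        idx = [i for i, c in enumerate(self.compound_ids) if c in keep]
        return ProfileMatrix(
            self.values[idx],
            [self.row_ids[i] for i in idx],
            [self.compound_ids[i] for i in idx],
            list(self.feature_names),
            self.modality,
        )

    def row_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.row_ids)}

    def compound_row_index(self) -> dict[str, int]:
        """compound -> row index; only meaningful for compound-level matrices."""
        return {c: i for i, c in enumerate(self.compound_ids)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "compound_id", self.compound_ids)
        df.insert(0, "row_id", self.row_ids)
        return df


def write_profile_matrix(pm: ProfileMatrix, path: str | Path) -> None:
    """Write a wide-format profile table (CSV or Parquet by suffix)."""
    path = Path(path)
    df = pm.to_frame()
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def load_profile_matrix(path: str | Path, modality: str) -> ProfileMatrix:
    """Load a wide-format profile table (row_id, compound_id, features...).

    CSV and Parquet are supported, chosen by file suffix.  Validation of the
    container invariants (TX uniqueness, finiteness, unique row ids) happens
    in :class:`ProfileMatrix`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    for col in ("row_id", "compound_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required id column {col!r}")
    feat_cols = [c for c in df.columns if c not in ("row_id", "compound_id")]
    values = df[feat_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = [c for c in feat_cols if not np.issubdtype(df[c].dtype, np.number)]
        raise ValueError(f"{path}: non-numeric feature columns {bad[:5]}")
    return ProfileMatrix(
        values=values.astype(np.float64),
        row_ids=df["row_id"].astype(str).tolist(),
        compound_ids=df["compound_id"].astype(str).tolist(),
        feature_names=feat_cols,
        modality=modality,
    )


@dataclass
class PairSet:
    """Ordered (CP replicate row, compound) pairs used for pretraining.

    Each CP replicate row of a compound present in both modalities yields one
    pair; the compound's single TX row is the partner of every one of its CP
    replicates.
    """

    cp_row_ids: list[str]
    compound_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.cp_row_ids) != len(self.compound_ids):
            raise ValueError("cp_row_ids and compound_ids must align")

    def __len__(self) -> int:
        return len(self.cp_row_ids)

    def restrict_to(self, compounds: Iterable[str]) -> "PairSet":
        keep = set(compounds)
        idx = [i for i, c in enumerate(self.compound_ids) if c in keep]
        return PairSet(
            [self.cp_row_ids[i] for i in idx],
            [self.compound_ids[i] for i in idx],
        )


def build_pairs(cp: ProfileMatrix, tx: ProfileMatrix) -> PairSet:
    """Group CP replicates with their compound's TX profile into (CP-TX) pairs.

    Compounds missing from either modality are excluded (count is logged).
    Raises if the compound overlap is empty.
    """
    if cp.modality != "CP" or tx.modality != "TX":
        raise ValueError("build_pairs expects (CP, TX) matrices in that order")
    common = cp.compounds & tx.compounds
    if not common:
        raise ValueError("no compounds shared between CP and TX matrices")
    dropped = len((cp.compounds | tx.compounds) - common)
    if dropped:
        logger.info("build_pairs: excluded %d compounds missing a modality", dropped)
    rows = [(r, c) for r, c in zip(cp.row_ids, cp.compound_ids) if c in common]
    return PairSet([r for r, _ in rows], [c for _, c in rows])


@dataclass
class CompoundTable:
    """Per-compound annotations: SMILES, Murcko scaffold key, MoA class."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "compound_id" not in self.frame.columns:
            raise ValueError("compound table needs a compound_id column")
        self.frame = self.frame.copy()
        self.frame["compound_id"] = self.frame["compound_id"].astype(str)
        if self.frame["compound_id"].duplicated().any():
            raise ValueError("compound_id must be unique")
        for col in ("smiles", "scaffold_key", "moa"):
            if col not in self.frame.columns:
                self.frame[col] = pd.NA

    @property
    def compound_ids(self) -> list[str]:
        return self.frame["compound_id"].tolist()

    def scaffold_keys(self) -> dict[str, str]:
        if self.frame["scaffold_key"].isna().any():
            raise ValueError("scaffold_key missing for some compounds; run "
                             "assign_scaffolds or provide keys")
        return dict(zip(self.frame["compound_id"], self.frame["scaffold_key"]))

    def moa_labels(self) -> dict[str, str]:
        """compound -> MoA class, for annotated compounds only."""
        sub = self.frame.dropna(subset=["moa"])
        return dict(zip(sub["compound_id"], sub["moa"].astype(str)))


def load_compound_table(path: str | Path) -> CompoundTable:
    return CompoundTable(pd.read_csv(path, dtype={"compound_id": str}))


def murcko_key(smiles: str) -> str:
    """Canonical Murcko scaffold SMILES; acyclic molecules get the reserved key.

    Raises ``ValueError`` naming the offending SMILES when it cannot be parsed.
    """
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
    return scaffold if scaffold else ACYCLIC_SCAFFOLD


def assign_scaffolds(table: CompoundTable) -> CompoundTable:
    """Fill scaffold_key from SMILES for rows where it is missing."""
    frame = table.frame.copy()
    need = frame["scaffold_key"].isna()
    if need.any():
        if frame.loc[need, "smiles"].isna().any():
            raise ValueError("compounds lack both scaffold_key and smiles")
        frame.loc[need, "scaffold_key"] = [
            murcko_key(s) for s in frame.loc[need, "smiles"]
        ]
    return CompoundTable(frame)


@dataclass
class SplitAssignment:
    """Scaffold-disjoint compound -> {train, valid, test} assignment."""

    assignment: dict[str, str]
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def compounds(self, split: str) -> list[str]:
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}")
        return [c for c, s in self.assignment.items() if s == split]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound_id": list(self.assignment), "split": list(self.assignment.values())}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_split(path: str | Path) -> SplitAssignment:
    df = pd.read_csv(path, dtype=str)
    return SplitAssignment(dict(zip(df["compound_id"], df["split"])))


def scaffold_split(
    compounds: CompoundTable,
    ratios: Sequence[float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Greedy scaffold-grouped 70/10/20 split.

    Scaffold groups are sorted by size (largest first) and each group is
    assigned to the split with the largest remaining deficit relative to its
    target count, so realised proportions track the targets as closely as the
    group sizes allow.  The seed shuffles the order among equal-size groups,
    and compounds sharing a scaffold always land in the same split.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be three proportions summing to 1")
    keys = compounds.scaffold_keys()
    groups: dict[str, list[str]] = {}
    for cid, key in keys.items():
        groups.setdefault(key, []).append(cid)
    n_total = len(keys)
    rng = np.random.default_rng(seed)
    # deterministic order: size desc, random tiebreak among equal sizes
    order = sorted(
        groups.items(),
        key=lambda kv: (-len(kv[1]), rng.random(), kv[0]),
    )
    if len(groups) == 1:
        warnings.warn(
            "all compounds share a single scaffold; assigning everything to train",
            stacklevel=2,
        )
        return SplitAssignment({c: "train" for c in keys}, ratios, seed)

    targets = np.array(ratios) * n_total
    counts = np.zeros(3)
    assignment: dict[str, str] = {}
    for _, members in order:
        deficits = targets - counts
        dest = int(np.argmax(deficits))
        counts[dest] += len(members)
        for cid in members:
            assignment[cid] = SPLIT_NAMES[dest]
    return SplitAssignment(assignment, ratios, seed)


def aggregate_replicates(cp: ProfileMatrix, method: str = "median") -> ProfileMatrix:
    """Collapse CP replicate rows to one row per compound (median or mean).

    The output row_ids are the compound ids, so the result doubles as a
    compound-level feature matrix for MoA clustering and bioactivity
    modelling.  Aggregating an already compound-level matrix is the identity.
    """
    if cp.modality != "CP":
        raise ValueError("aggregate_replicates expects a CP matrix")
    if method not in ("median", "mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    agg = np.median if method == "median" else np.mean
    # preserve first-appearance order of compounds
    seen: dict[str, list[int]] = {}
    for i, c in enumerate(cp.compound_ids):
        seen.setdefault(c, []).append(i)
    rows = np.stack([agg(cp.values[idx], axis=0) for idx in seen.values()])
    cids = list(seen)
    return ProfileMatrix(rows, cids, cids, list(cp.feature_names), "CP")


@dataclass
class BioactivityMatrix:
    """Sparse compound x task binary labels; NaN marks unobserved entries."""

    labels: np.ndarray  # float matrix with values in {0, 1, nan}
    compound_ids: list[str]
    task_ids: list[str]
    family: dict[str, str] = field(default_factory=dict)  # task -> family

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.labels.shape != (len(self.compound_ids), len(self.task_ids)):
            raise ValueError("labels shape must be (n_compounds, n_tasks)")
        observed = self.labels[~np.isnan(self.labels)]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            raise ValueError("observed bioactivity labels must be binary")
        if np.isnan(self.labels).all(axis=0).any():
            raise ValueError("every task needs at least one observed label")

    @property
    def n_tasks(self) -> int:
        return len(self.task_ids)

    def task_index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.task_ids)}

    def rows_for(self, compound_ids: Sequence[str]) -> np.ndarray:
        """Label sub-matrix for the given compounds (rows in given order)."""
        index = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [c for c in compound_ids if c not in index]
        if missing:
            raise KeyError(f"compounds not in label matrix: {missing[:5]}")
        return self.labels[[index[c] for c in compound_ids]]

    def to_triplets(self) -> pd.DataFrame:
        ii, jj = np.where(~np.isnan(self.labels))
        return pd.DataFrame(
            {
                "compound_id": [self.compound_ids[i] for i in ii],
                "task_id": [self.task_ids[j] for j in jj],
                "label": self.labels[ii, jj].astype(int),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_triplets().to_csv(path, index=False)


def load_bioactivity(
    path: str | Path,
    family_path: str | Path | None = None,
) -> BioactivityMatrix:
    """Load a sparse triplet CSV (compound_id, task_id, label in {0,1})."""
    df = pd.read_csv(path, dtype={"compound_id": str, "task_id": str})
    compounds = sorted(df["compound_id"].unique())
    tasks = sorted(df["task_id"].unique())
    ci = {c: i for i, c in enumerate(compounds)}
    tj = {t: j for j, t in enumerate(tasks)}
    labels = np.full((len(compounds), len(tasks)), np.nan)
    labels[df["compound_id"].map(ci), df["task_id"].map(tj)] = df["label"].to_numpy()
    family: dict[str, str] = {}
    if family_path is not None:
        fam = pd.read_csv(family_path, dtype=str)
        family = dict(zip(fam["task_id"], fam["family"]))
    return BioactivityMatrix(labels, compounds, tasks, family)
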