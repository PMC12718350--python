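"""Core data model: snapshots, state partitions, transition costs.

A snapshot is a single-time-point single-cell measurement: a cells x features
count matrix (or a precomputed low-dimensional embedding).  Trajectory
inference additionally requires a partition of the cells into initial states
(e.g. stem cells), terminal states (lineage-committed cells, each carrying a
fate-class label) and intermediate states (everything else).  Transition
costs between cell states are squared Euclidean distances in the embedding,
median-normalized so the entropic regularization strength is comparable
across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

AUX_SUFFIX = "__aux__"
UNKNOWN_FATE = "unknown"


class InvalidInputError(ValueError):
    """Raised when an input matrix or table violates its contract."""


class InvalidParameterError(ValueError):
    """Raised when a parameter is outside its admissible range."""


@dataclass
class Snapshot:
    """A cells x features matrix (raw counts) or a cells x dims embedding.

    Parameters
    ----------
    cell_ids
        Ordered, unique per-cell identifiers.
    values
        Dense array or scipy sparse matrix, one row per cell.  Raw counts
        must be nonnegative and finite; embeddings must be finite.
    is_embedding
        True when ``values`` holds coordinates rather than counts.
    feature_names
        Optional column labels (gene names or ``dim_1 .. dim_k``).
    meta
        Optional per-cell metadata (``time_label``, ``clone_id``,
        ``fate_annotation``, ...), indexed like ``cell_ids``.
    """

    cell_ids: np.ndarray
    values: np.ndarray | sp.spmatrix
    is_embedding: bool = False
    feature_names: np.ndarray | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise InvalidInputError("cell_ids must be unique")
        if self.values.shape[0] != len(self.cell_ids):
            raise InvalidInputError(
                f"values has {self.values.shape[0]} rows for "
                f"{len(self.cell_ids)} cell ids"
            )
        dense = self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)
        if not np.all(np.isfinite(dense)):
            raise InvalidInputError("matrix entries must be finite")
        if not self.is_embedding and dense.size and dense.min() < 0:
            raise InvalidInputError("count matrix entries must be >= 0")
        if self.feature_names is not None:
            self.feature_names = np.asarray(self.feature_names, dtype=object)
        if self.meta is not None and not np.array_equal(
            np.asarray(self.meta.index, dtype=object), self.cell_ids
        ):
            self.meta = self.meta.reindex(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        """Return the value matrix as a dense float array."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def index_of(self, cell_ids: Sequence) -> np.ndarray:
        """Positional indices of the given cell ids (error on misses)."""
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in cell_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise InvalidInputError(f"unknown cell id {exc.args[0]!r}") from exc


@dataclass
class StatePartition:
    """Disjoint index sets of initial (X0), intermediate (X) and terminal
    (XF) states over a snapshot's cell order, with a fate-class label for
    every terminal state.

    Indices are 0-based positions into the snapshot's ``cell_ids``.
    """

    X0: np.ndarray
    X: np.ndarray
    XF: np.ndarray
    fate_of: dict[int, str]
    aux_enabled: bool = False

    def __post_init__(self) -> None:
        self.X0 = np.asarray(self.X0, dtype=int)
        self.X = np.asarray(self.X, dtype=int)
        self.XF = np.asarray(self.XF, dtype=int)
        sets = [set(self.X0), set(self.X), set(self.XF)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise InvalidInputError("X0, X, XF must be pairwise disjoint")
        if self.n0 < 1:
            raise InvalidInputError("at least one initial state is required")
        if self.nF < 1:
            raise InvalidInputError("at least one terminal state is required")
        missing = [j for j in self.XF if j not in self.fate_of]
        if missing:
            raise InvalidInputError(f"terminal states without fate label: {missing}")

    @property
    def n0(self) -> int:
        return len(self.X0)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def nF(self) -> int:
        return len(self.XF)

    @property
    def n_cells(self) -> int:
        return self.n0 + self.n + self.nF

    @property
    def fate_classes(self) -> list[str]:
        """Fate-class labels in first-appearance (declaration) order."""
        seen: dict[str, None] = {}
        for j in self.XF:
            seen.setdefault(self.fate_of[j], None)
        return list(seen)

    def terminal_class_indicator(self) -> tuple[np.ndarray, list[str]]:
        """nF x L one-hot matrix mapping terminal states to fate classes."""
        classes = self.fate_classes
        col = {c: k for k, c in enumerate(classes)}
        Z = np.zeros((self.nF, len(classes)))
        for r, j in enumerate(self.XF):
            Z[r, col[self.fate_of[j]]] = 1.0
        return Z, classes


@dataclass
class CostSet:
    """Squared-Euclidean transition costs between the partition blocks.

    ``C_0X``: initial -> intermediate, ``C_0F``: initial -> terminal,
    ``C_XX``: intermediate -> intermediate, ``C_XF``: intermediate ->
    terminal.  ``normalization_factor`` records the pooled median divided
    out (1.0 while unnormalized); ``aux_cost_Q`` the auxiliary-state cost,
    if the auxiliary extension is active.
    """

    C_0X: np.ndarray
    C_0F: np.ndarray
    C_XX: np.ndarray
    C_XF: np.ndarray
    normalization_factor: float = 1.0
    aux_cost_Q: float | None = None

    def __post_init__(self) -> None:
        for name in ("C_0X", "C_0F", "C_XX", "C_XF"):
            M = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, M)
            if M.size and (not np.all(np.isfinite(M)) or M.min() < 0):
                raise InvalidInputError(f"{name} entries must be finite and >= 0")
        if self.normalization_factor <= 0:
            raise InvalidParameterError("normalization_factor must be > 0")

    def matrices(self) -> dict[str, np.ndarray]:
        return {
            "C_0X": self.C_0X,
            "C_0F": self.C_0F,
            "C_XX": self.C_XX,
            "C_XF": self.C_XF,
        }


@dataclass
class MsotConfig:
    """Solver configuration.

    ``T`` transport stages index t = 0..T-1.  The default T=21 gives the
    20 intermediate transport steps used for expression data; the small 2D
    synthetic example uses T=11.  ``epsilon_start`` is the entropic
    regularization of the first proximal round; after ``prox_iters``
    KL-proximal rounds the effective regularization is
    ``epsilon_start / prox_iters``.  Iterations stop when the maximum over
    dual-variable updates and absolute constraint deviations drops below
    ``tol_tau``.
    """

    T: int = 21
    epsilon_start: float = 0.05
    prox_iters: int = 10
    tol_tau: float = 1e-4
    max_inner_iters: int = 50_000
    aux_cost_Q: float | None = None
    seed: int = 0
    log_domain: bool = False

    def __post_init__(self) -> None:
        if self.T < 2:
            raise InvalidParameterError("T must be >= 2")
        if self.epsilon_start <= 0:
            raise InvalidParameterError("epsilon_start must be > 0")
        if self.tol_tau <= 0:
            raise InvalidParameterError("tol_tau must be > 0")
        if self.prox_iters < 1:
            raise InvalidParameterError("prox_iters must be >= 1")

    @property
    def effective_epsilon(self) -> float:
        return self.epsilon_start / self.prox_iters


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_counts(snapshot: Snapshot) -> Snapshot:
    """Library-size normalize to the median total count, then log(x+1).

    Each cell's counts are scaled so its total equals the median total
    count across cells, after which values are log1p-transformed.  The
    input snapshot is not mutated.
    """
    if snapshot.is_embedding:
        raise InvalidInputError("preprocess_counts expects raw counts, got an embedding")
    X = snapshot.dense()
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = np.where(totals <= 0)[0]
        raise InvalidInputError(f"cells with zero total counts: rows {bad.tolist()}")
    target = float(np.median(totals))
    Y = np.log1p(X * (target / totals)[:, None])
    return Snapshot(
        cell_ids=snapshot.cell_ids.copy(),
        values=Y,
        is_embedding=False,
        feature_names=None if snapshot.feature_names is None else snapshot.feature_names.copy(),
        meta=None if snapshot.meta is None else snapshot.meta.copy(),
    )


def pca_embed(snapshot: Snapshot, n_components: int = 50, seed: int = 0) -> Snapshot:
    """Project a preprocessed matrix onto its leading principal components.

    Components are ordered by non-increasing explained variance and the
    result is deterministic for a given seed.
    """
    from sklearn.decomposition import PCA

    X = snapshot.dense()
    if n_components < 1 or n_components > min(X.shape):
        raise InvalidParameterError(
            f"n_components={n_components} not in [1, min(cells, features)={min(X.shape)}]"
        )
    emb = PCA(n_components=n_components, svd_solver="full", random_state=seed).fit_transform(X)
    return Snapshot(
        cell_ids=snapshot.cell_ids.copy(),
        values=emb,
        is_embedding=True,
        feature_names=np.array([f"dim_{k + 1}" for k in range(n_components)], dtype=object),
        meta=None if snapshot.meta is None else snapshot.meta.copy(),
    )


# ---------------------------------------------------------------------------
# costs


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import cdist

    return cdist(A, B, metric="sqeuclidean")


def compute_costs(embedding: Snapshot, partition: StatePartition) -> CostSet:
    """Squared Euclidean distances between the partition blocks.

    The intermediate-to-intermediate diagonal is exactly zero, so mass may
    stay at the same cell across consecutive stages at no cost.
    """
    if not embedding.is_embedding:
        raise InvalidInputError("compute_costs requires an embedding snapshot")
    E = embedding.dense()
    n_cells = E.shape[0]
    for name, idx in (("X0", partition.X0), ("X", partition.X), ("XF", partition.XF)):
        if idx.size and (idx.min() < 0 or idx.max() >= n_cells):
            raise IndexError(f"partition set {name} indexes outside the embedding")
    E0, EX, EF = E[partition.X0], E[partition.X], E[partition.XF]
    C_XX = _sq_dists(EX, EX)
    np.fill_diagonal(C_XX, 0.0)
    return CostSet(
        C_0X=_sq_dists(E0, EX),
        C_0F=_sq_dists(E0, EF),
        C_XX=C_XX,
        C_XF=_sq_dists(EX, EF),
    )


def normalize_costs(costs: CostSet) -> CostSet:
    """Divide every cost by the median of the pooled entries of all four
    matrices, recording the median as ``normalization_factor``.

    After normalization the pooled median equals 1, which puts the entropic
    regularization parameter on a comparable scale across datasets.
    """
    pooled = np.concatenate([M.ravel() for M in costs.matrices().values() if M.size])
    if pooled.size == 0 or not np.any(pooled > 0):
        raise InvalidInputError("cannot normalize an all-zero cost set")
    med = float(np.median(pooled))
    if med == 0:
        # degenerate but legal (over half the costs are 0): fall back to the
        # median of the positive entries so the scale stays meaningful
        med = float(np.median(pooled[pooled > 0]))
    return CostSet(
        C_0X=costs.C_0X / med,
        C_0F=costs.C_0F / med,
        C_XX=costs.C_XX / med,
        C_XF=costs.C_XF / med,
        normalization_factor=costs.normalization_factor * med,
        aux_cost_Q=costs.aux_cost_Q,
    )


def augment_auxiliary(
    costs: CostSet, partition: StatePartition, Q: float = 3.25
) -> tuple[CostSet, StatePartition]:
    """Append one auxiliary initial, intermediate and terminal state.

    Every transition between a real cell and an auxiliary state costs the
    fixed amount ``Q`` (on the median-normalized scale); transitions among
    auxiliary states are free, so the auxiliary channel forms a zero-cost
    internal path whose toll is Q per hop from real cells.  The auxiliary
    terminal state defines the fate class "unknown": cells mostly absorbed
    there are outlier candidates.
    """
    if Q <= 0:
        raise InvalidParameterError("auxiliary cost Q must be > 0")
    n0, n, nF = partition.n0, partition.n, partition.nF

    def pad(M: np.ndarray, row_val: float, col_val: float, corner: float) -> np.ndarray:
        out = np.full((M.shape[0] + 1, M.shape[1] + 1), 0.0)
        out[:-1, :-1] = M
        out[-1, :-1] = row_val
        out[:-1, -1] = col_val
        out[-1, -1] = corner
        return out

    new_costs = CostSet(
        C_0X=pad(costs.C_0X, Q, Q, 0.0),
        C_0F=pad(costs.C_0F, Q, Q, 0.0),
        C_XX=pad(costs.C_XX, Q, Q, 0.0),
        C_XF=pad(costs.C_XF, Q, Q, 0.0),
        normalization_factor=costs.normalization_factor,
        aux_cost_Q=Q,
    )
    # auxiliary members live at positions n_cells .. n_cells+2 of the
    # (conceptually extended) cell order: initial, intermediate, terminal
    base = partition.n_cells
    fate_of = dict(partition.fate_of)
    fate_of[base + 2] = UNKNOWN_FATE
    new_partition = StatePartition(
        X0=np.concatenate([partition.X0, [base]]),
        X=np.concatenate([partition.X, [base + 1]]),
        XF=np.concatenate([partition.XF, [base + 2]]),
        fate_of=fate_of,
        aux_enabled=True,
    )
    return new_costs, new_partition


# ---------------------------------------------------------------------------
# subsetting


def partition_subsets(
    snapshot: Snapshot,
    partition: StatePartition,
    k: int,
    seed: int = 0,
) -> list[tuple[Snapshot, StatePartition]]:
    """Split the data into ``k`` uniformly subsampled disjoint subsets.

    Each subset receives an equal (+-1) share of the initial states and of
    each fate class's terminal states, so every subset poses a complete
    transport problem.  Intermediate cells are spread uniformly; remainders
    go to the last subset.  Deterministic for a given seed.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if k == 1:
        return [(snapshot, partition)]
    rng = np.random.default_rng(seed)
    if partition.n0 < k:
        raise InvalidInputError(f"need >= {k} initial states to form {k} subsets")
    by_class: dict[str, list[int]] = {}
    for j in partition.XF:
        by_class.setdefault(partition.fate_of[j], []).append(j)
    for c, idx in by_class.items():
        if len(idx) < k:
            raise InvalidInputError(
                f"fate class {c!r} has {len(idx)} terminal cells, fewer than k={k}"
            )

    def split(indices: np.ndarray) -> list[np.ndarray]:
        shuffled = rng.permutation(indices)
        parts = [shuffled[i::k] for i in range(k)]
        return parts

    def split_tail(indices: np.ndarray) -> list[np.ndarray]:
        # equal shares, remainder appended to the last subset
        shuffled = rng.permutation(indices)
        q = len(shuffled) // k
        parts = [shuffled[i * q : (i + 1) * q] for i in range(k)]
        parts[-1] = np.concatenate([parts[-1], shuffled[k * q :]])
        return parts

    x0_parts = split(partition.X0)
    x_parts = split_tail(partition.X)
    xf_parts: list[list[int]] = [[] for _ in range(k)]
    for c in partition.fate_classes:
        for i, chunk in enumerate(split(np.array(by_class[c], dtype=int))):
            xf_parts[i].extend(chunk.tolist())

    out: list[tuple[Snapshot, StatePartition]] = []
    values = snapshot.dense()
    for i in range(k):
        members = np.sort(
            np.concatenate([x0_parts[i], x_parts[i], np.array(xf_parts[i], dtype=int)])
        ).astype(int)
        pos = {g: l for l, g in enumerate(members)}
        sub_snap = Snapshot(
            cell_ids=snapshot.cell_ids[members],
            values=values[members],
            is_embedding=snapshot.is_embedding,
            feature_names=snapshot.feature_names,
            meta=None if snapshot.meta is None else snapshot.meta.iloc[members],
        )
        sub_part = StatePartition(
            X0=np.array(sorted(pos[g] for g in x0_parts[i]), dtype=int),
            X=np.array(sorted(pos[g] for g in x_parts[i]), dtype=int),
            XF=np.array(sorted(pos[g] for g in xf_parts[i]), dtype=int),
            fate_of={pos[g]: partition.fate_of[g] for g in xf_parts[i]},
        )
        out.append((sub_snap, sub_part))
    return out
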