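"""Downstream analysis of multistage transport plans.

The stage-resolved plans induce, for every cell, a probability distribution
over differentiation stages (when does the cell transport its mass?), whose
mean gives a pseudotime.  Summing transported mass over all stages gives a
cell-cell affinity matrix which, row-normalized with terminal cells made
absorbing, defines a stationary absorbing Markov chain; absorption
probabilities in each terminal fate class are the cell fate probabilities.
Shannon entropy of a cell's fate vector quantifies its multipotency.  When
the auxiliary-state extension is active, absorption in the auxiliary
terminal ("unknown" fate) flags outlier cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import UNKNOWN_FATE, InvalidParameterError, StatePartition
from .solver import StagePlans


class ContractViolationError(RuntimeError):
    """Plans violate an invariant that converged solves guarantee."""


class AbsorbingChainError(RuntimeError):
    """The transition chain has transient cells that reach no terminal state."""


def _role_masks(partition: StatePartition) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    N = partition.n_cells
    init = np.zeros(N, dtype=bool)
    term = np.zeros(N, dtype=bool)
    init[partition.X0] = True
    term[partition.XF] = True
    aux = np.zeros(N, dtype=bool)
    if partition.aux_enabled:
        # auxiliary members are the last-appended entry of each index set
        aux[[partition.X0[-1], partition.X[-1], partition.XF[-1]]] = True
    return init, term, aux


@dataclass
class StageDistribution:
    """Per-cell probability distribution over transport stages t = 0..T-1.

    Rows follow the global cell order of the partition.  Initial cells have
    all their probability at t = 0 (they only act in stage 0); intermediate
    cells are weighted by outgoing mass per stage; terminal cells by
    incoming mass per stage.
    """

    probs: np.ndarray  # N x T
    partition: StatePartition

    @property
    def T(self) -> int:
        return self.probs.shape[1]


@dataclass
class PseudotimeResult:
    """Mean transport stage per cell and its min-max normalization."""

    raw_mean_stage: np.ndarray
    pseudotime: np.ndarray


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix over all cells.

    ``A`` is the unnormalized stage-aggregated mass matrix; ``P`` its
    row-normalization with terminal cells absorbing (P_jj = 1).
    """

    P: np.ndarray
    A: np.ndarray
    partition: StatePartition


@dataclass
class FateProbabilities:
    """Per-cell absorption probabilities over fate classes.

    ``values`` is N x L in the partition's global cell order; ``classes``
    lists fate labels in declaration order (including "unknown" when the
    auxiliary extension is active).
    """

    values: np.ndarray
    classes: list[str]
    partition: StatePartition
    cell_ids: np.ndarray | None = None

    def column(self, fate: str) -> np.ndarray:
        if fate not in self.classes:
            raise InvalidParameterError(f"unknown fate class {fate!r}")
        return self.values[:, self.classes.index(fate)]

    def dominant(self) -> np.ndarray:
        """Index of each cell's highest-probability class (ties break by
        declaration order, which argmax honors)."""
        return np.argmax(self.values, axis=1)

    def as_frame(self) -> pd.DataFrame:
        idx = self.cell_ids if self.cell_ids is not None else np.arange(len(self.values))
        return pd.DataFrame(self.values, columns=self.classes, index=idx)


# ---------------------------------------------------------------------------


def stage_distributions(plans: StagePlans, partition: StatePartition) -> StageDistribution:
    """Distribute each cell's mass activity over the T stages.

    Initial cells transport only at stage 0.  An intermediate cell's weight
    at stage t is its total outgoing mass (continuing + exiting) there; a
    terminal cell's weight is the mass it receives at stage t.
    """
    T = plans.T
    N = partition.n_cells
    probs = np.zeros((N, T))
    probs[partition.X0, 0] = 1.0
    if partition.n:
        out = np.zeros((partition.n, T))
        for t in range(1, T):
            out[:, t] = plans.mu_hat(t) + (plans.mu_tilde(t) if t <= T - 2 else 0.0)
        totals = out.sum(axis=1)
        if np.any(totals <= 0):
            dead = partition.X[totals <= 0]
            raise ContractViolationError(
                f"intermediate cells with zero throughput: {dead.tolist()}"
            )
        probs[partition.X] = out / totals[:, None]
    inc = np.stack([plans.nu_hat(t) for t in range(T)], axis=1)
    tot = inc.sum(axis=1)
    if np.any(tot <= 0):
        dead = partition.XF[tot <= 0]
        raise ContractViolationError(f"terminal cells receiving zero mass: {dead.tolist()}")
    probs[partition.XF] = inc / tot[:, None]
    return StageDistribution(probs=probs, partition=partition)


def pseudotime(stages: StageDistribution) -> PseudotimeResult:
    """Normalized mean transport stage.

    Raw value is the expected stage under the cell's stage distribution;
    terminal cells get a +1 shift so that a terminal receiving at stage t
    ranks after the cells transporting at stage t.  Pseudotime is the
    min-max normalization to [0, 1] (all-equal raw values map to 0).
    Auxiliary cells, if present, are excluded from the min/max range and
    reported as NaN.
    """
    part = stages.partition
    t_idx = np.arange(stages.T)
    raw = stages.probs @ t_idx
    raw[part.XF] += 1.0
    _, _, aux = _role_masks(part)
    real = ~aux
    lo, hi = raw[real].min(), raw[real].max()
    pt = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    raw = raw.copy()
    pt = pt.copy()
    raw[aux] = np.nan
    pt[aux] = np.nan
    return PseudotimeResult(raw_mean_stage=raw, pseudotime=pt)


def aggregate_transitions(plans: StagePlans, partition: StatePartition) -> TransitionModel:
    """Total mass sent between every cell pair, summed over all stages.

    Transient rows (initial and intermediate cells) of ``P`` are the
    normalized rows of the aggregate; terminal rows are absorbing unit
    self-loops.
    """
    N = partition.n_cells
    A = np.zeros((N, N))
    X0, X, XF = partition.X0, partition.X, partition.XF
    if partition.n:
        A[np.ix_(X0, X)] += plans.Mtilde[0]
        for t in range(1, plans.T - 1):
            A[np.ix_(X, X)] += plans.Mtilde[t]
        for t in range(1, plans.T):
            A[np.ix_(X, XF)] += plans.Mhat[t]
    A[np.ix_(X0, XF)] += plans.Mhat[0]
    P = np.zeros((N, N))
    transient = np.sort(np.concatenate([X0, X]))
    row_mass = A[transient].sum(axis=1)
    if np.any(row_mass <= 0):
        dead = transient[row_mass <= 0]
        raise ContractViolationError(f"transient cells sending zero mass: {dead.tolist()}")
    P[transient] = A[transient] / row_mass[:, None]
    P[XF, XF] = 1.0
    return TransitionModel(P=P, A=A, partition=partition)


def fate_probabilities(model: TransitionModel, partition: StatePartition | None = None) -> FateProbabilities:
    """Absorption probabilities of the stationary absorbing Markov chain.

    Solves (I - P_tt) F = P_tf Z by a linear solve (never explicit matrix
    inversion), where Z maps terminal cells to their fate class.  Terminal
    rows are the indicators of their own class.
    """
    part = partition if partition is not None else model.partition
    Z, classes = part.terminal_class_indicator()
    transient = np.sort(np.concatenate([part.X0, part.X]))
    Ptt = model.P[np.ix_(transient, transient)]
    Ptf = model.P[np.ix_(transient, part.XF)]
    # a transient cell must reach some terminal with positive probability;
    # otherwise the system is singular
    reach = Ptf.sum(axis=1)
    I_minus = np.eye(len(transient)) - Ptt
    try:
        F_trans = np.linalg.solve(I_minus, Ptf @ Z)
    except np.linalg.LinAlgError as exc:
        stuck = transient[reach == 0]
        raise AbsorbingChainError(
            f"transient cells cannot reach any terminal state: {stuck.tolist()}"
        ) from exc
    sums = F_trans.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = transient[np.abs(sums - 1.0) > 1e-6]
        raise AbsorbingChainError(
            f"absorption rows do not sum to 1 for cells {bad.tolist()}; "
            "the chain is not absorbing from these states"
        )
    N = part.n_cells
    F = np.zeros((N, len(classes)))
    F[transient] = np.clip(F_trans, 0.0, None)
    F[transient] /= F[transient].sum(axis=1, keepdims=True)
    F[part.XF] = Z
    return FateProbabilities(values=F, classes=classes, partition=part)


def fate_entropy(fates: FateProbabilities, base: float | None = None) -> tuple[np.ndarray, float]:
    """Shannon entropy of each cell's fate vector, and the mean over
    non-terminal (and non-auxiliary) cells.

    Natural log by default (values in [0, ln L]); pass ``base`` to change.
    High entropy reflects multipotency, zero full commitment.
    """
    F = fates.values
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(F > 0, np.log(F), 0.0)
    H = -np.sum(F * logs, axis=1)
    if base is not None:
        H = H / np.log(base)
    part = fates.partition
    _, term, aux = _role_masks(part)
    mask = ~term & ~aux
    return H, float(H[mask].mean())


def flag_outliers(fates: FateProbabilities, threshold: float = 0.5) -> np.ndarray:
    """Flag cells whose absorption probability in the "unknown" fate (the
    auxiliary terminal state) exceeds ``threshold`` (strictly)."""
    if UNKNOWN_FATE not in fates.classes:
        raise InvalidParameterError(
            "no 'unknown' fate class: outlier flagging requires the auxiliary-state extension"
        )
    flags = fates.column(UNKNOWN_FATE) > threshold
    _, _, aux = _role_masks(fates.partition)
    return flags & ~aux


def gate_cells(
    fates: FateProbabilities,
    target_fates: set[str] | list[str],
    min_target: float = 0.10,
    max_other: float = 0.01,
) -> np.ndarray:
    """Indices of cells committed to every target fate above ``min_target``
    and to every other fate below ``max_other`` (both strict).

    The defaults recover bipotent progenitors: above 10% commitment in each
    of the two target fates and below 1% everywhere else.
    """
    targets = list(target_fates)
    if not targets:
        raise InvalidParameterError("target_fates must be nonempty")
    unknown = [c for c in targets if c not in fates.classes]
    if unknown:
        raise InvalidParameterError(f"unknown fate classes: {unknown}")
    cols = [fates.classes.index(c) for c in targets]
    others = [k for k in range(len(fates.classes)) if k not in cols]
    ok = np.all(fates.values[:, cols] > min_target, axis=1)
    if others:
        ok &= np.all(fates.values[:, others] < max_other, axis=1)
    _, _, aux = _role_masks(fates.partition)
    return np.where(ok & ~aux)[0]
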