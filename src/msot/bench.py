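"""Baseline predictor and fate-prediction benchmark metrics.

The inverse-distance-weighted (IDW) baseline predicts fate potential from
relative Euclidean distances to the terminal cells of each fate class; it
involves no optimal transport and serves as the naive reference.  The
benchmark machinery builds per-cell "ground truth" fate distributions from
clonal lineage-tracing metadata (the annotated fates of a founder cell's
clonal sisters at later time points) and scores predictions by total
variation distance, dominant-fate accuracy, total-fate accuracy and a
threshold sweep over categorical fate assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InvalidInputError, InvalidParameterError, Snapshot, StatePartition
from .analysis import FateProbabilities


@dataclass
class ClonalReference:
    """Empirical sister-fate distributions for eligible early cells.

    ``distributions`` has one row per eligible early cell (indexed by
    cell_id) and one column per fate class; rows sum to 1.  Early cells
    with no fate-annotated sisters at later time points are ineligible and
    carry no distribution.
    """

    distributions: pd.DataFrame
    classes: list[str]

    @property
    def cell_ids(self) -> np.ndarray:
        return np.asarray(self.distributions.index, dtype=object)

    @property
    def n_eligible(self) -> int:
        return len(self.distributions)


@dataclass
class MetricReport:
    mean_tv: float
    dominant_fate_accuracy: float
    total_fate_accuracy: float
    delta_curve: list[tuple[float, float]]
    n_evaluated: int

    def to_dict(self) -> dict:
        return {
            "mean_tv": self.mean_tv,
            "dominant_fate_accuracy": self.dominant_fate_accuracy,
            "total_fate_accuracy": self.total_fate_accuracy,
            "delta_curve": [[d, f] for d, f in self.delta_curve],
            "n_evaluated": self.n_evaluated,
        }


# ---------------------------------------------------------------------------
# IDW baseline


def idw_fates(
    embedding: Snapshot, partition: StatePartition, power: float = 2.0
) -> FateProbabilities:
    """Inverse-distance-weighted fate prediction.

    For each cell the distance to a fate class is the minimum Euclidean
    distance to any of that class's terminal cells; fate weights are
    d^(-power), normalized per cell.  A cell coinciding with a terminal
    cell gets the indicator of that class.  Rows are invariant to global
    rescaling of the embedding.
    """
    if power <= 0:
        raise InvalidParameterError("power must be > 0")
    E = embedding.dense()
    classes = partition.fate_classes
    if not classes:
        raise InvalidInputError("partition has no fate classes")
    D = np.empty((E.shape[0], len(classes)))
    for k, c in enumerate(classes):
        members = [j for j in partition.XF if partition.fate_of[j] == c]
        dists = np.linalg.norm(E[:, None, :] - E[members][None, :, :], axis=-1)
        D[:, k] = dists.min(axis=1)
    F = np.zeros_like(D)
    zero = D == 0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        W = D ** (-power)
    F[~any_zero] = W[~any_zero] / W[~any_zero].sum(axis=1, keepdims=True)
    F[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    return FateProbabilities(
        values=F, classes=classes, partition=partition, cell_ids=embedding.cell_ids
    )


# ---------------------------------------------------------------------------
# clonal ground truth


def clonal_reference(
    meta: pd.DataFrame,
    early_time: str = "early",
    late_times: list[str] | tuple[str, ...] = ("late",),
    classes: list[str] | None = None,
) -> ClonalReference:
    """Build sister-fate reference distributions from lineage metadata.

    ``meta`` needs columns cell_id, clone_id, time_label, fate_annotation.
    For each cell at ``early_time``, the fate annotations of same-clone
    cells at ``late_times`` are counted into an empirical distribution;
    early cells without annotated sisters are ineligible.
    """
    required = {"cell_id", "clone_id", "time_label", "fate_annotation"}
    missing = required - set(meta.columns)
    if missing:
        raise InvalidInputError(f"metadata missing columns: {sorted(missing)}")
    late = meta[meta["time_label"].isin(list(late_times)) & meta["fate_annotation"].notna()]
    if classes is None:
        classes = sorted(late["fate_annotation"].unique())
    else:
        bad = set(late["fate_annotation"]) - set(classes)
        if bad:
            raise InvalidInputError(f"fate annotations outside the class set: {sorted(bad)}")
    counts_by_clone = (
        late.groupby("clone_id")["fate_annotation"].value_counts().unstack(fill_value=0)
    )
    counts_by_clone = counts_by_clone.reindex(columns=classes, fill_value=0)
    rows = {}
    for _, r in meta[meta["time_label"] == early_time].iterrows():
        if r["clone_id"] not in counts_by_clone.index:
            continue  # ineligible: no annotated sisters at late times
        counts = counts_by_clone.loc[r["clone_id"]].to_numpy(dtype=float)
        if counts.sum() == 0:
            continue
        rows[r["cell_id"]] = counts / counts.sum()
    dist = pd.DataFrame.from_dict(rows, orient="index", columns=classes)
    return ClonalReference(distributions=dist, classes=list(classes))


# ---------------------------------------------------------------------------
# metrics


def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Total variation distance (1/2) * sum |p - q| between two
    probability vectors on the same class support."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InvalidInputError(f"mismatched supports: {p.shape} vs {q.shape}")
    for v, name in ((p, "p"), (q, "q")):
        if abs(v.sum() - 1.0) > 1e-6 or v.min() < -1e-12:
            raise InvalidInputError(f"{name} is not a probability vector")
    return 0.5 * float(np.abs(p - q).sum())


def _aligned(pred: FateProbabilities, ref: ClonalReference) -> tuple[np.ndarray, np.ndarray]:
    """Prediction rows for the reference's eligible cells, columns in the
    reference class order."""
    if pred.cell_ids is None:
        raise InvalidInputError("predictions carry no cell ids")
    cols = []
    for c in ref.classes:
        if c not in pred.classes:
            raise InvalidInputError(f"prediction lacks fate class {c!r}")
        cols.append(pred.classes.index(c))
    lookup = {cid: i for i, cid in enumerate(pred.cell_ids)}
    try:
        rows = np.array([lookup[cid] for cid in ref.cell_ids])
    except KeyError as exc:
        raise InvalidInputError(f"no prediction for cell {exc.args[0]!r}") from exc
    P = pred.values[np.ix_(rows, cols)]
    # renormalize over the evaluated classes (extra classes, e.g. "unknown",
    # hold negligible mass for non-outliers)
    P = P / P.sum(axis=1, keepdims=True)
    return P, ref.distributions.to_numpy(dtype=float)


def mean_tv_distance(pred: FateProbabilities, ref: ClonalReference) -> float:
    """Mean total variation distance between predictions and sister-fate
    references over the eligible cells."""
    P, R = _aligned(pred, ref)
    return float(0.5 * np.abs(P - R).sum(axis=1).mean())


def dominant_fate_accuracy(pred: FateProbabilities, ref: ClonalReference) -> float:
    """Fraction of eligible cells whose highest-probability predicted fate
    equals the most common sister fate.

    Reference ties (several equally-most-common sister fates) count as
    correct when the prediction matches any tied mode; prediction ties
    break by class declaration order.
    """
    P, R = _aligned(pred, ref)
    if len(P) == 0:
        raise InvalidInputError("no eligible cells")
    pred_top = np.argmax(P, axis=1)
    ref_max = R.max(axis=1)
    hits = R[np.arange(len(R)), pred_top] >= ref_max - 1e-12
    return float(hits.mean())


def total_fate_accuracy(pred: FateProbabilities, ref: ClonalReference) -> float:
    """Fraction of eligible cells whose observed sister-fate set equals the
    set of their k highest predicted fates (k = number of observed fates)."""
    P, R = _aligned(pred, ref)
    if len(P) == 0:
        raise InvalidInputError("no eligible cells")
    correct = 0
    for p_row, r_row in zip(P, R):
        observed = set(np.where(r_row > 0)[0])
        k = len(observed)
        top_k = set(np.argsort(-p_row, kind="stable")[:k])
        correct += top_k == observed
    return correct / len(P)


def delta_sweep(
    pred: FateProbabilities,
    ref: ClonalReference,
    grid: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """Fraction of cells whose thresholded fate assignment matches the
    observed sister-fate set exactly, for each threshold delta.

    A cell is assigned every fate with predicted probability strictly above
    delta; the assignment is correct only on exact set equality.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    P, R = _aligned(pred, ref)
    curve = []
    for d in np.asarray(grid, dtype=float):
        if not 0.0 <= d <= 1.0:
            raise InvalidParameterError(f"delta {d} outside [0, 1]")
        correct = 0
        for p_row, r_row in zip(P, R):
            correct += set(np.where(p_row > d)[0]) == set(np.where(r_row > 0)[0])
        curve.append((float(d), correct / len(P) if len(P) else 0.0))
    return curve


def annotation_accuracy(pred: FateProbabilities, labels: pd.Series) -> float:
    """Fraction of annotated cells whose dominant predicted fate equals
    their annotation.

    ``labels`` maps cell_id -> fate label; NaN entries are skipped.
    """
    if pred.cell_ids is None:
        raise InvalidInputError("predictions carry no cell ids")
    labels = labels.dropna()
    if labels.empty:
        raise InvalidInputError("no annotated cells")
    bad = set(labels.unique()) - set(pred.classes)
    if bad:
        raise InvalidInputError(f"annotations outside the class set: {sorted(bad)}")
    lookup = {cid: i for i, cid in enumerate(pred.cell_ids)}
    rows = np.array([lookup[cid] for cid in labels.index])
    dominant = np.array(pred.classes, dtype=object)[np.argmax(pred.values[rows], axis=1)]
    return float((dominant == labels.to_numpy(dtype=object)).mean())


def benchmark_report(
    pred: FateProbabilities,
    ref: ClonalReference,
    grid: np.ndarray | None = None,
) -> MetricReport:
    """All four benchmark metrics in one report."""
    return MetricReport(
        mean_tv=mean_tv_distance(pred, ref),
        dominant_fate_accuracy=dominant_fate_accuracy(pred, ref),
        total_fate_accuracy=total_fate_accuracy(pred, ref),
        delta_curve=delta_sweep(pred, ref, grid),
        n_evaluated=ref.n_eligible,
    )
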