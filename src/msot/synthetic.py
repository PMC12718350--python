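"""Seeded generators for branching 2D snapshots with ground truth.

The generator emulates a developmental landscape in the unit square: cells
sample positions along a skeleton consisting of a trunk from a root point
plus several diverging arms, with isotropic Gaussian noise.  Cells nearest
the root become initial states; cells nearest each arm tip become that
fate's terminal states.  Optional extras inject a far-displaced outlier
cluster and simulate clonal lineage metadata (founder cells at an early
position with fate-annotated sisters in the arms), providing ground truth
for pseudotime, fate prediction, outlier detection and benchmark metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .core import InvalidInputError, InvalidParameterError, Snapshot, StatePartition

_SQRT2 = np.sqrt(2.0)
#: default arm directions from the trunk end: up-left, up-right, left, right
DEFAULT_ARMS: tuple[tuple[float, float], ...] = (
    (-1 / _SQRT2, 1 / _SQRT2),
    (1 / _SQRT2, 1 / _SQRT2),
    (-1.0, 0.0),
    (1.0, 0.0),
)


@dataclass
class SkeletonSpec:
    """Geometry and sampling parameters of the branching skeleton.

    The default four-arm skeleton (root near the bottom of the unit
    square, short trunk, four arms of length 0.5) mirrors a developmental
    process with one origin and four diverging fates, sized so that a full
    multistage solve with T=11 runs in seconds.
    """

    root: tuple[float, float] = (0.5, 0.05)
    trunk_end: tuple[float, float] = (0.5, 0.4)
    arms: tuple[tuple[float, float], ...] = DEFAULT_ARMS
    arm_length: float = 0.5
    n_cells: int = 400
    noise_sd: float = 0.02
    n_initial: int = 5
    n_terminal_per_arm: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < self.n_initial + len(self.arms) * self.n_terminal_per_arm:
            raise InvalidParameterError("n_cells too small for the requested designations")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        for p in [self.root, self.trunk_end, *self.tips()]:
            if not (0 <= p[0] <= 1 and 0 <= p[1] <= 1):
                raise InvalidParameterError(f"skeleton point {p} outside the unit square")
        # arms must be mutually separable for fate labels to be meaningful
        tips = np.array(self.tips())
        if len(tips) > 1:
            d = np.linalg.norm(tips[:, None] - tips[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 6 * self.noise_sd:
                raise InvalidParameterError(
                    "arm tips closer than 6 * noise_sd: fates not separable"
                )

    def tips(self) -> list[tuple[float, float]]:
        e = np.asarray(self.trunk_end)
        return [tuple(e + self.arm_length * np.asarray(d)) for d in self.arms]

    @property
    def trunk_length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.trunk_end) - np.asarray(self.root)))

    @property
    def path_length(self) -> float:
        return self.trunk_length + self.arm_length


@dataclass
class GroundTruth:
    """Ground truth accompanying a synthetic snapshot.

    ``s`` is the arc-length fraction along the root -> tip path (the true
    developmental time, in [0, 1]); ``arm`` the true fate label ("trunk"
    for pre-branch cells); ``outlier`` marks injected outliers, which have
    no skeleton position (s = NaN, arm = "outlier").
    """

    s: np.ndarray
    arm: np.ndarray
    outlier: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s": self.s, "arm": self.arm, "outlier": self.outlier})


def _arm_names(n: int) -> list[str]:
    return [f"arm_{chr(ord('A') + i)}" for i in range(n)]


def make_branching_snapshot(
    spec: SkeletonSpec | None = None,
) -> tuple[Snapshot, StatePartition, GroundTruth]:
    """Sample a branching snapshot in the unit square.

    Arc-length positions are uniform on [0, 1]; cells past the trunk are
    split uniformly among the arms.  Isotropic Gaussian noise (sd =
    ``noise_sd``) is added and points are clipped to the unit square.  The
    ``n_initial`` cells nearest the root form X0 and, per arm, the
    ``n_terminal_per_arm`` cells nearest the tip form that fate's XF.
    Deterministic for a given seed.
    """
    spec = spec or SkeletonSpec()
    rng = np.random.default_rng(spec.seed)
    root = np.asarray(spec.root)
    trunk_end = np.asarray(spec.trunk_end)
    dirs = [np.asarray(d) / np.linalg.norm(d) for d in spec.arms]
    names = _arm_names(len(spec.arms))

    s = rng.uniform(0.0, 1.0, size=spec.n_cells)
    arm_choice = rng.integers(0, len(dirs), size=spec.n_cells)
    trunk_frac = spec.trunk_length / spec.path_length
    pts = np.empty((spec.n_cells, 2))
    labels = np.empty(spec.n_cells, dtype=object)
    on_trunk = s < trunk_frac
    frac = np.divide(s, trunk_frac, out=np.zeros_like(s), where=trunk_frac > 0)
    pts[on_trunk] = root + frac[on_trunk, None] * (trunk_end - root)
    labels[on_trunk] = "trunk"
    for k, d in enumerate(dirs):
        m = ~on_trunk & (arm_choice == k)
        along = (s[m] - trunk_frac) / (1 - trunk_frac) * spec.arm_length
        pts[m] = trunk_end + along[:, None] * d
        labels[m] = names[k]
    pts = np.clip(pts + rng.normal(0.0, spec.noise_sd, size=pts.shape), 0.0, 1.0)

    # designate initial / terminal states by proximity to root and tips
    d_root = np.linalg.norm(pts - root, axis=1)
    X0 = np.argsort(d_root, kind="stable")[: spec.n_initial]
    taken = set(X0.tolist())
    XF: list[int] = []
    fate_of: dict[int, str] = {}
    for k, tip in enumerate(spec.tips()):
        d_tip = np.linalg.norm(pts - np.asarray(tip), axis=1)
        picked = 0
        for idx in np.argsort(d_tip, kind="stable"):
            if int(idx) not in taken:
                taken.add(int(idx))
                XF.append(int(idx))
                fate_of[int(idx)] = names[k]
                picked += 1
                if picked == spec.n_terminal_per_arm:
                    break
    X = np.array([i for i in range(spec.n_cells) if i not in taken], dtype=int)

    cell_ids = np.array([f"cell_{i:04d}" for i in range(spec.n_cells)], dtype=object)
    snapshot = Snapshot(
        cell_ids=cell_ids,
        values=pts,
        is_embedding=True,
        feature_names=np.array(["dim_1", "dim_2"], dtype=object),
    )
    partition = StatePartition(X0=np.sort(X0), X=X, XF=np.sort(np.array(XF)), fate_of=fate_of)
    truth = GroundTruth(s=s, arm=labels, outlier=np.zeros(spec.n_cells, dtype=bool))
    return snapshot, partition, truth


def inject_outliers(
    snapshot: Snapshot,
    truth: GroundTruth,
    m: int,
    displacement: float = 3.0,
    cluster_sd: float = 0.05,
    seed: int = 0,
) -> tuple[Snapshot, GroundTruth]:
    """Append ``m`` outlier points in a compact cluster far from the data.

    The cluster centroid is placed at Euclidean distance >= ``displacement``
    from every original point (along the diagonal away from the data's
    centroid); points scatter around it with sd ``cluster_sd``.  Outliers
    carry no skeleton position and enter any downstream partition as
    intermediate states.
    """
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    if displacement <= 0:
        raise InvalidParameterError("displacement must be > 0")
    rng = np.random.default_rng(seed)
    pts = snapshot.dense()
    center = pts.mean(axis=0)
    direction = np.array([1.0, 1.0]) / _SQRT2
    # walk outward until the centroid clears every original point
    centroid = center + direction * displacement
    while np.linalg.norm(pts - centroid, axis=1).min() < displacement:
        centroid = centroid + direction * 0.1
    cluster = centroid + rng.normal(0.0, cluster_sd, size=(m, 2))
    if np.min(np.linalg.norm(pts[:, None] - cluster[None, :], axis=-1)) < displacement / 2:
        warnings.warn("outlier cluster overlaps the data", stacklevel=2)
    new_ids = np.array([f"outlier_{i:03d}" for i in range(m)], dtype=object)
    out_snap = Snapshot(
        cell_ids=np.concatenate([snapshot.cell_ids, new_ids]),
        values=np.vstack([pts, cluster]),
        is_embedding=True,
        feature_names=snapshot.feature_names,
    )
    out_truth = GroundTruth(
        s=np.concatenate([truth.s, np.full(m, np.nan)]),
        arm=np.concatenate([truth.arm, np.full(m, "outlier", dtype=object)]),
        outlier=np.concatenate([truth.outlier, np.ones(m, dtype=bool)]),
    )
    return out_snap, out_truth


def simulate_clones(
    snapshot: Snapshot,
    truth: GroundTruth,
    n_clones: int,
    sisters_per_clone: int = 4,
    early_cutoff: float = 0.3,
    late_cutoff: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate clonal lineage-tracing metadata over a synthetic snapshot.

    Each clone gets a founder among early cells (skeleton position s below
    ``early_cutoff``, time_label "early") and ``sisters_per_clone`` sisters
    among late arm cells (s above ``late_cutoff``, time_label "late"),
    annotated with their true arm fate.  Trunk founders draw sisters from
    any arm; founders already inside an arm only from their own arm.
    Returns a tidy frame with columns cell_id, clone_id, time_label,
    fate_annotation (NaN for founders).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    real = ~truth.outlier
    early = np.where(real & (truth.s < early_cutoff))[0]
    late = np.where(real & (truth.s > late_cutoff) & (truth.arm != "trunk"))[0]
    if len(early) < n_clones:
        raise InvalidInputError(f"only {len(early)} early cells for {n_clones} clones")
    if len(late) < sisters_per_clone:
        raise InvalidInputError("not enough late arm cells to draw sisters")
    if len(late) < n_clones * sisters_per_clone:
        raise InvalidInputError(
            f"need {n_clones * sisters_per_clone} late arm cells, have {len(late)}"
        )
    founders = rng.choice(early, size=n_clones, replace=False)
    arms = sorted(set(truth.arm[late]))
    available = np.ones(len(late), dtype=bool)
    rows: list[dict] = []
    for c, fi in enumerate(founders):
        clone = f"clone_{c:03d}"
        rows.append(
            {
                "cell_id": snapshot.cell_ids[fi],
                "clone_id": clone,
                "time_label": "early",
                "fate_annotation": np.nan,
            }
        )
        if truth.arm[fi] == "trunk":
            reachable = arms
        else:
            reachable = [truth.arm[fi]]
        pool_mask = available & np.isin(truth.arm[late], reachable)
        pool = late[pool_mask]
        if len(pool) < sisters_per_clone:
            raise InvalidInputError(
                f"clone {c}: only {len(pool)} unassigned late cells in arms {reachable}"
            )
        sisters = rng.choice(pool, size=sisters_per_clone, replace=False)
        available[np.isin(late, sisters)] = False
        for si in sisters:
            rows.append(
                {
                    "cell_id": snapshot.cell_ids[si],
                    "clone_id": clone,
                    "time_label": "late",
                    "fate_annotation": truth.arm[si],
                }
            )
    return pd.DataFrame(rows)
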