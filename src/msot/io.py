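"""Readers and writers for the standard file interfaces.

Expression input: dense CSV/TSV (cells in rows, first column cell_id,
header = feature names), Matrix Market sparse with sidecar cell/feature id
files, or h5ad.  Roles file: CSV with cell_id, role in {initial,
intermediate, terminal} and fate_label (required for terminal rows).
Embeddings travel as CSV with cell_id + dim_1..dim_k columns.  Results are
written as plain CSV / Matrix Market / JSON so every run is inspectable
with standard tools.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import InvalidInputError, Snapshot, StatePartition
from .analysis import FateProbabilities, PseudotimeResult, StageDistribution, TransitionModel
from .solver import StagePlans


class FormatError(InvalidInputError):
    """A file does not match its declared format."""


# ---------------------------------------------------------------------------
# reading


def _read_table(path: Path, sep: str) -> Snapshot:
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a cell_id column plus feature columns")
    cell_ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    if len(set(cell_ids)) != len(cell_ids):
        dup = pd.Series(cell_ids).value_counts()
        raise FormatError(f"{path}: duplicate cell ids {dup[dup > 1].index.tolist()}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise FormatError(f"{path}: NaN at row {r} ({cell_ids[r]}), column {df.columns[c + 1]}")
    features = df.columns[1:].to_numpy(dtype=object)
    is_embedding = all(str(f).startswith("dim_") for f in features)
    return Snapshot(
        cell_ids=cell_ids, values=values, is_embedding=is_embedding, feature_names=features
    )


def read_snapshot(
    path: str | Path,
    format: str = "auto",
    cells_file: str | Path | None = None,
    features_file: str | Path | None = None,
) -> Snapshot:
    """Read a snapshot from CSV/TSV, Matrix Market, or h5ad.

    ``format="auto"`` dispatches on the file suffix.  For Matrix Market
    input the sidecar files default to ``<stem>.cells.txt`` and
    ``<stem>.features.txt`` next to the matrix.
    """
    path = Path(path)
    if format == "auto":
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx", ".h5ad": "h5ad"}.get(
            path.suffix, ""
        )
        if not format:
            raise FormatError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "csv":
        return _read_table(path, ",")
    if format == "tsv":
        return _read_table(path, "\t")
    if format == "mtx":
        M = scipy.io.mmread(path).tocsr()
        cells = Path(cells_file) if cells_file else path.with_suffix("").with_suffix(".cells.txt")
        feats = (
            Path(features_file)
            if features_file
            else path.with_suffix("").with_suffix(".features.txt")
        )
        cell_ids = np.array(cells.read_text().split(), dtype=object)
        feature_names = np.array(feats.read_text().split(), dtype=object)
        if M.shape != (len(cell_ids), len(feature_names)):
            raise FormatError(
                f"{path}: matrix is {M.shape} but sidecars list "
                f"{len(cell_ids)} cells x {len(feature_names)} features"
            )
        return Snapshot(cell_ids=cell_ids, values=M, feature_names=feature_names)
    if format == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        return Snapshot(
            cell_ids=np.asarray(adata.obs_names, dtype=object),
            values=adata.X,
            feature_names=np.asarray(adata.var_names, dtype=object),
            meta=adata.obs.copy() if len(adata.obs.columns) else None,
        )
    raise FormatError(f"unrecognized format {format!r}")


_ROLES = {"initial", "intermediate", "terminal"}


def read_roles(path: str | Path, snapshot: Snapshot) -> StatePartition:
    """Build a StatePartition from a roles CSV, validated against the
    snapshot.  Cells not listed default to intermediate."""
    df = pd.read_csv(path)
    required = {"cell_id", "role"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    if "fate_label" not in df.columns:
        df["fate_label"] = np.nan
    lookup = {c: i for i, c in enumerate(snapshot.cell_ids)}
    X0, XF, fate_of = [], [], {}
    listed = set()
    for row_no, r in df.iterrows():
        cid = str(r["cell_id"])
        if cid not in lookup:
            raise FormatError(f"{path} row {row_no}: cell_id {cid!r} not in snapshot")
        if cid in listed:
            raise FormatError(f"{path} row {row_no}: duplicate cell_id {cid!r}")
        listed.add(cid)
        role = str(r["role"])
        if role not in _ROLES:
            raise FormatError(f"{path} row {row_no}: role {role!r} not in {sorted(_ROLES)}")
        idx = lookup[cid]
        if role == "initial":
            X0.append(idx)
        elif role == "terminal":
            if pd.isna(r["fate_label"]):
                raise FormatError(f"{path} row {row_no}: terminal cell without fate_label")
            XF.append(idx)
            fate_of[idx] = str(r["fate_label"])
    if not X0:
        raise FormatError(f"{path}: no initial cells listed")
    if not XF:
        raise FormatError(f"{path}: no terminal cells listed")
    X = [i for i in range(snapshot.n_cells) if i not in set(X0) | set(XF)]
    return StatePartition(
        X0=np.array(sorted(X0)), X=np.array(X), XF=np.array(sorted(XF)), fate_of=fate_of
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read benchmark metadata (cell_id, clone_id, time_label,
    fate_annotation)."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# writing


def write_embedding_csv(snapshot: Snapshot, path: str | Path) -> None:
    E = snapshot.dense()
    df = pd.DataFrame(E, columns=[f"dim_{k + 1}" for k in range(E.shape[1])])
    df.insert(0, "cell_id", snapshot.cell_ids)
    df.to_csv(path, index=False)


def write_roles_csv(snapshot: Snapshot, partition: StatePartition, path: str | Path) -> None:
    rows = []
    for i in partition.X0:
        rows.append({"cell_id": snapshot.cell_ids[i], "role": "initial", "fate_label": ""})
    for i in partition.XF:
        rows.append(
            {"cell_id": snapshot.cell_ids[i], "role": "terminal", "fate_label": partition.fate_of[i]}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pseudotime_csv(
    cell_ids: np.ndarray, result: PseudotimeResult, path: str | Path, keep: np.ndarray | None = None
) -> None:
    raw, pt = result.raw_mean_stage, result.pseudotime
    if keep is not None:
        raw, pt = raw[keep], pt[keep]
    pd.DataFrame(
        {"cell_id": cell_ids, "raw_mean_stage": raw, "pseudotime": pt}
    ).to_csv(path, index=False)


def write_fates_csv(fates: FateProbabilities, path: str | Path, keep: np.ndarray | None = None) -> None:
    df = fates.as_frame()
    if keep is not None:
        df = df.iloc[keep]
    df.insert(0, "cell_id", df.index)
    df.to_csv(path, index=False)


def write_stage_distributions_csv(
    cell_ids: np.ndarray,
    stages: StageDistribution,
    path: str | Path,
    keep: np.ndarray | None = None,
) -> None:
    probs = stages.probs if keep is None else stages.probs[keep]
    df = pd.DataFrame(probs, columns=[f"stage_{t}" for t in range(stages.T)])
    df.insert(0, "cell_id", cell_ids)
    df.to_csv(path, index=False)


def write_transitions_mtx(model: TransitionModel, cell_ids: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    scipy.io.mmwrite(path, sp.csr_matrix(model.P))
    ids = path.with_suffix("").with_suffix(".cells.txt")
    ids.write_text("\n".join(str(c) for c in cell_ids) + "\n")


def write_plans_mtx(plans: StagePlans, out_dir: str | Path, prefix: str = "plan") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t, M in enumerate(plans.Mtilde):
        scipy.io.mmwrite(out / f"{prefix}_continuing_stage{t}.mtx", sp.csr_matrix(M))
    for t, M in enumerate(plans.Mhat):
        scipy.io.mmwrite(out / f"{prefix}_exiting_stage{t}.mtx", sp.csr_matrix(M))


# ---------------------------------------------------------------------------
# run manifest


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of a pipeline run: configuration, input file
    digests, seed, software version, per-subset solver reports."""

    config: dict
    input_digests: dict[str, str]
    seed: int
    version: str
    reports: list[dict] = field(default_factory=list)
    timestamp: str | None = None
    status: str = "ok"

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "input_digests": self.input_digests,
                "seed": self.seed,
                "version": self.version,
                "reports": self.reports,
                "timestamp": self.timestamp,
                "status": self.status,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @staticmethod
    def from_json(text: str) -> "RunManifest":
        d = json.loads(text)
        return RunManifest(
            config=d["config"],
            input_digests=d["input_digests"],
            seed=d["seed"],
            version=d["version"],
            reports=d.get("reports", []),
            timestamp=d.get("timestamp"),
            status=d.get("status", "ok"),
        )
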