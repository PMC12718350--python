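"""End-to-end pipeline: preprocess -> embed -> costs -> solve -> analyze.

For large snapshots the data is split into uniformly subsampled disjoint
subsets, each receiving its share of initial and terminal states; the
multistage problem is solved independently per subset and per-cell results
are pooled by cell id (pseudotime re-normalized jointly over the pooled raw
mean stages).  All outputs are plain CSV / Matrix Market / JSON files plus
a manifest that records configuration, input digests and solver reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    MsotConfig,
    Snapshot,
    StatePartition,
    augment_auxiliary,
    compute_costs,
    normalize_costs,
    partition_subsets,
    pca_embed,
    preprocess_counts,
)
from .analysis import (
    FateProbabilities,
    aggregate_transitions,
    fate_entropy,
    fate_probabilities,
    flag_outliers,
    pseudotime,
    stage_distributions,
)
from .io import (
    RunManifest,
    write_stage_distributions_csv,
    write_transitions_mtx,
)
from .solver import proximal_solve


@dataclass
class PipelineResult:
    """Pooled per-cell results of a pipeline run, in input cell order."""

    pseudotime: pd.DataFrame  # cell_id, raw_mean_stage, pseudotime
    fates: pd.DataFrame  # cell_id + one column per fate class
    entropy: pd.DataFrame  # cell_id, fate_entropy
    outliers: pd.DataFrame | None  # cell_id, unknown_probability, flagged
    mean_entropy: float
    reports: list[dict]
    manifest: RunManifest
    subsets: list[dict] = field(default_factory=list)  # per-subset objects


def run_pipeline(
    snapshot: Snapshot,
    partition: StatePartition,
    config: MsotConfig | None = None,
    *,
    n_components: int = 50,
    n_subsets: int = 1,
    outlier_threshold: float = 0.5,
    out_dir: str | Path | None = None,
    input_digests: dict[str, str] | None = None,
    write_stage_distributions: bool = False,
) -> PipelineResult:
    """Run the full inference chain and optionally write result files.

    Counts input is library-size normalized, log1p-transformed and PCA
    embedded; embedding input is used as-is.  The auxiliary-state
    extension (outlier detection) is enabled by setting
    ``config.aux_cost_Q``.  Deterministic: identical inputs and
    configuration produce byte-identical outputs.
    """
    config = config or MsotConfig()
    if snapshot.is_embedding:
        embedding = snapshot
    else:
        embedding = pca_embed(preprocess_counts(snapshot), n_components, seed=config.seed)

    pieces = partition_subsets(embedding, partition, n_subsets, seed=config.seed)

    frames: list[pd.DataFrame] = []
    reports: list[dict] = []
    subset_objects: list[dict] = []
    for s_idx, (sub_emb, sub_part) in enumerate(pieces):
        costs = normalize_costs(compute_costs(sub_emb, sub_part))
        solve_part = sub_part
        if config.aux_cost_Q is not None:
            costs, solve_part = augment_auxiliary(costs, sub_part, config.aux_cost_Q)
        plans, report = proximal_solve(costs, solve_part, config)
        stages = stage_distributions(plans, solve_part)
        pt = pseudotime(stages)
        model = aggregate_transitions(plans, solve_part)
        fates = fate_probabilities(model, solve_part)
        H, _ = fate_entropy(fates)
        n_real = sub_part.n_cells  # auxiliary rows (if any) come after
        df = pd.DataFrame(
            {
                "cell_id": sub_emb.cell_ids,
                "raw_mean_stage": pt.raw_mean_stage[:n_real],
                "fate_entropy": H[:n_real],
            }
        )
        for c in fates.classes:
            df[c] = fates.column(c)[:n_real]
        if config.aux_cost_Q is not None:
            df["outlier_flag"] = flag_outliers(fates, outlier_threshold)[:n_real]
        frames.append(df)
        reports.append(report.to_dict())
        subset_objects.append(
            {
                "snapshot": sub_emb,
                "partition": sub_part,
                "solve_partition": solve_part,
                "costs": costs,
                "plans": plans,
                "report": report,
                "stages": stages,
                "transition_model": model,
                "fates": fates,
            }
        )

    pooled = pd.concat(frames, ignore_index=True)
    order = {c: i for i, c in enumerate(snapshot.cell_ids)}
    pooled = pooled.sort_values("cell_id", key=lambda s: s.map(order)).reset_index(drop=True)
    raw = pooled["raw_mean_stage"].to_numpy()
    lo, hi = np.nanmin(raw), np.nanmax(raw)
    pooled["pseudotime"] = 0.0 if hi == lo else (raw - lo) / (hi - lo)

    classes = [c for c in frames[0].columns if c not in
               {"cell_id", "raw_mean_stage", "fate_entropy", "outlier_flag"}]
    terminal_mask = np.zeros(snapshot.n_cells, dtype=bool)
    terminal_mask[partition.XF] = True
    mean_H = float(pooled.loc[~terminal_mask, "fate_entropy"].mean())

    pseudotime_df = pooled[["cell_id", "raw_mean_stage", "pseudotime"]]
    fates_df = pooled[["cell_id", *classes]]
    entropy_df = pooled[["cell_id", "fate_entropy"]]
    outliers_df = None
    if config.aux_cost_Q is not None:
        outliers_df = pd.DataFrame(
            {
                "cell_id": pooled["cell_id"],
                "unknown_probability": pooled["unknown"],
                "flagged": pooled["outlier_flag"],
            }
        )

    manifest = RunManifest(
        config={
            "T": config.T,
            "epsilon_start": config.epsilon_start,
            "prox_iters": config.prox_iters,
            "tol_tau": config.tol_tau,
            "max_inner_iters": config.max_inner_iters,
            "aux_cost_Q": config.aux_cost_Q,
            "log_domain": config.log_domain,
            "n_components": n_components,
            "n_subsets": n_subsets,
            "outlier_threshold": outlier_threshold,
        },
        input_digests=input_digests or {},
        seed=config.seed,
        version=__version__,
        reports=reports,
    )

    result = PipelineResult(
        pseudotime=pseudotime_df,
        fates=fates_df,
        entropy=entropy_df,
        outliers=outliers_df,
        mean_entropy=mean_H,
        reports=reports,
        manifest=manifest,
        subsets=subset_objects,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), write_stage_distributions)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path, with_stages: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.pseudotime.to_csv(out_dir / "pseudotime.csv", index=False)
    result.fates.to_csv(out_dir / "fate_probabilities.csv", index=False)
    result.entropy.to_csv(out_dir / "fate_entropy.csv", index=False)
    if result.outliers is not None:
        result.outliers.to_csv(out_dir / "outliers.csv", index=False)
    for s_idx, sub in enumerate(result.subsets):
        suffix = "" if len(result.subsets) == 1 else f"_subset{s_idx}"
        solve_part = sub["solve_partition"]
        ids = list(sub["snapshot"].cell_ids)
        if solve_part.aux_enabled:
            ids += ["aux_initial", "aux_intermediate", "aux_terminal"]
        write_transitions_mtx(sub["transition_model"], np.array(ids, dtype=object),
                              out_dir / f"transitions{suffix}.mtx")
        if with_stages:
            write_stage_distributions_csv(
                np.array(ids, dtype=object), sub["stages"],
                out_dir / f"stage_distributions{suffix}.csv",
            )
    import json

    (out_dir / "report.json").write_text(json.dumps(result.reports, indent=2) + "\n")
    result.manifest.write(out_dir / "manifest.json")
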