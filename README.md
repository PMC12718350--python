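# msot — multistage optimal transport for snapshot trajectory inference

A single-cell RNA-sequencing snapshot captures cells from every stage of a
differentiation process at one moment in time, with no temporal labels.
`msot` infers the hidden developmental progression from such a snapshot:
given user-designated **initial states** (e.g. stem cells) and **terminal
states** (lineage-committed cells, each carrying a fate label), it computes

- a **pseudotime** for every cell (its normalized mean transport stage),
- **cell–cell transition probabilities** (a stationary absorbing Markov
  chain over the snapshot),
- **fate probabilities** (absorption probabilities in each terminal fate
  class) and their Shannon entropy as a multipotency score, and
- **outlier flags** for cells that do not belong to the differentiation
  process at all.

It is aimed at computational biologists studying branching differentiation
systems (hematopoiesis being the motivating case) who can name where a
process starts and ends but need the intermediate structure resolved.

## The model

Let X0, X, XF be the initial, intermediate and terminal cell states with
cardinalities n0, n, nF, and let the transition cost between two cells be
the squared Euclidean distance between their (PCA-embedded) expression
profiles, median-normalized. Differentiation is modeled as mass transport
over T discrete stages: at stage t, continuing transport M̃ₜ moves mass into
intermediate states while exiting transport M̂ₜ moves mass into terminal
states. The latent stage marginals μ̃ₜ (mass that continues) and μ̂ₜ (mass
that exits) are unknowns of the optimization:

```
minimize    Σₜ₌₀..T₋₂ ⟨C̃ₜ, M̃ₜ⟩ + Σₜ₌₀..T₋₁ ⟨Ĉₜ, M̂ₜ⟩ + ε Σ m(log m − 1)
subject to  μ̃₀ + μ̂₀ ≥ 1ₙ₀                      every initial cell emits
            col(M̃ₜ₋₁) = μ̃ₜ + μ̂ₜ                 stage coupling (μ̃_{T−1} = 0)
            Σₜ₌₁..T₋₂ μ̃ₜ + Σₜ₌₁..T₋₁ μ̂ₜ ≥ 1ₙ     every intermediate cell is used
            Σₜ ν̂ₜ ≥ 1ₙ_F                         every terminal cell receives
```

where ν̂ₜ is the mass received by terminal cells at stage t. This is a
convex program solved by a generalized Sinkhorn scheme: block coordinate
ascent on the entropic dual, with free scaling factors for the coupling
equalities and scaling factors clipped at 1 for the inequality marginals,
nested in a proximal point loop that divides the effective regularization
ε by the number of rounds. Stage-resolved plans then yield pseudotime
(mean transport stage), and their stage-aggregated row-normalization
defines an absorbing Markov chain whose absorption probabilities are the
fate probabilities.

An optional extension appends one auxiliary initial/intermediate/terminal
state reachable from any cell at a fixed cost Q (default 3.25 on the
normalized cost scale). Cells far from the main process route their mass
through this auxiliary channel and absorb in the auxiliary terminal state
("unknown fate"); cells with unknown-fate probability above 0.5 are
flagged as outliers.

## Worked example

```python
from scipy.stats import spearmanr
from msot import MsotConfig, make_branching_snapshot, run_pipeline

snapshot, partition, truth = make_branching_snapshot()   # 400 cells, 4 fates
config = MsotConfig(T=11, epsilon_start=0.05, prox_iters=10, tol_tau=1e-4)
result = run_pipeline(snapshot, partition, config)

print(spearmanr(result.pseudotime["pseudotime"], truth.s).statistic)
```

Running `examples/01_pseudotime_and_fates.py` (this example with the
ground-truth checks spelled out) prints:

```
solver converged: True (residual 1.0e-04, transport cost 25.78)
Spearman(pseudotime, true position) = 0.990
dominant-fate accuracy on arm-interior cells: 100.0%
mean fate entropy: trunk 1.146, arm interior 0.000 (max possible ln 4 = 1.386)
```

Pseudotime reproduces the true ordering along the branching skeleton
(rank correlation 0.99); every cell deep inside an arm is assigned its own
arm as dominant fate; cells before the branch point score high fate
entropy (multipotent) while committed cells score zero. The other
examples cover outlier detection (`02`), benchmarking against simulated
clonal lineage tracing (`03`), bipotent-progenitor gating (`04`) and the
command-line interface (`05`).

For real data, `msot fit --snapshot counts.csv --roles roles.csv --out
results/` runs the full chain (library-size normalization, log1p, 50
principal components, T−1 = 20 intermediate transport steps by default);
counts can also be Matrix Market or h5ad. See `docs/methods.md` for the
model details and parameter guidance.

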