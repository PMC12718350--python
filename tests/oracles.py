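"""Independent oracles used by the test suite.

These deliberately avoid the package's own solution paths: the flow-polytope
LP is solved by scipy's HiGHS backend on an explicitly assembled constraint
matrix, absorption probabilities are estimated by simulating random walks,
and metric values are recomputed by plain per-cell loops.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from msot import CostSet, StatePartition, normalize_costs


def lp_flow_oracle(costs: CostSet, part: StatePartition, T: int) -> float:
    """Minimum transport cost over the multistage flow polytope (no
    entropy), by linear programming on explicitly enumerated variables."""
    n0, n, nF = part.n0, part.n, part.nF
    blocks = [("Mt0", (n0, n))]
    blocks += [(f"Mt{t}", (n, n)) for t in range(1, T - 1)]
    blocks += [("Mh0", (n0, nF))]
    blocks += [(f"Mh{t}", (n, nF)) for t in range(1, T)]
    offsets, total = {}, 0
    for name, shape in blocks:
        offsets[name] = (total, shape)
        total += shape[0] * shape[1]

    c = np.zeros(total)

    def put_cost(name: str, M: np.ndarray) -> None:
        o, shape = offsets[name]
        c[o : o + shape[0] * shape[1]] = M.ravel()

    put_cost("Mt0", costs.C_0X)
    put_cost("Mh0", costs.C_0F)
    for t in range(1, T - 1):
        put_cost(f"Mt{t}", costs.C_XX)
    for t in range(1, T):
        put_cost(f"Mh{t}", costs.C_XF)

    def rowsum(name: str, i: int) -> np.ndarray:
        o, (r, k) = offsets[name]
        v = np.zeros(total)
        v[o + i * k : o + (i + 1) * k] = 1
        return v

    def colsum(name: str, j: int) -> np.ndarray:
        o, (r, k) = offsets[name]
        v = np.zeros(total)
        v[o + j : o + r * k : k] = 1
        return v

    A_eq, b_eq = [], []
    for t in range(1, T):
        prev = "Mt0" if t == 1 else f"Mt{t - 1}"
        for j in range(n):
            v = colsum(prev, j)
            if t <= T - 2:
                v -= rowsum(f"Mt{t}", j)
            v -= rowsum(f"Mh{t}", j)
            A_eq.append(v)
            b_eq.append(0.0)
    A_ub, b_ub = [], []
    for i in range(n0):
        A_ub.append(-(rowsum("Mt0", i) + rowsum("Mh0", i)))
        b_ub.append(-1.0)
    for j in range(n):
        v = np.zeros(total)
        for t in range(1, T - 1):
            v += rowsum(f"Mt{t}", j)
        for t in range(1, T):
            v += rowsum(f"Mh{t}", j)
        A_ub.append(-v)
        b_ub.append(-1.0)
    for l in range(nF):
        v = colsum("Mh0", l)
        for t in range(1, T):
            v += colsum(f"Mh{t}", l)
        A_ub.append(-v)
        b_ub.append(-1.0)
    res = linprog(
        c,
        A_ub=np.array(A_ub),
        b_ub=np.array(b_ub),
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if A_eq else None,
        bounds=(0, None),
        method="highs",
    )
    assert res.status == 0, res.message
    return float(res.fun)


def random_geometric_instance(
    rng: np.random.Generator, n0: int, n: int, nF: int
) -> tuple[CostSet, StatePartition]:
    """Random cells in the unit square, median-normalized squared-Euclidean
    costs, one fate class per terminal cell (cycled over two labels)."""
    pts = rng.random((n0 + n + nF, 2))
    part = StatePartition(
        X0=np.arange(n0),
        X=np.arange(n0, n0 + n),
        XF=np.arange(n0 + n, n0 + n + nF),
        fate_of={int(n0 + n + l): ("A" if l % 2 == 0 else "B") for l in range(nF)},
    )
    E0, EX, EF = pts[:n0], pts[n0 : n0 + n], pts[n0 + n :]
    C_XX = cdist(EX, EX, "sqeuclidean")
    np.fill_diagonal(C_XX, 0.0)
    costs = CostSet(
        C_0X=cdist(E0, EX, "sqeuclidean"),
        C_0F=cdist(E0, EF, "sqeuclidean"),
        C_XX=C_XX,
        C_XF=cdist(EX, EF, "sqeuclidean"),
    )
    return normalize_costs(costs), part


def mc_absorption(
    P: np.ndarray,
    transient: np.ndarray,
    terminal: np.ndarray,
    class_of: np.ndarray,
    n_classes: int,
    n_walks: int,
    seed: int,
    max_steps: int = 10_000,
) -> np.ndarray:
    """Absorption frequencies by simulating random walks from every
    transient state (rows: transient order; cols: class index)."""
    rng = np.random.default_rng(seed)
    term_set = {int(j): int(class_of[k]) for k, j in enumerate(terminal)}
    freqs = np.zeros((len(transient), n_classes))
    cum = P.cumsum(axis=1)
    for r, start in enumerate(transient):
        draws = rng.random((n_walks, max_steps))
        for w in range(n_walks):
            state = int(start)
            for step in range(max_steps):
                if state in term_set:
                    freqs[r, term_set[state]] += 1
                    break
                state = int(np.searchsorted(cum[state], draws[w, step], side="right"))
            else:  # pragma: no cover - walk did not absorb
                raise AssertionError("random walk failed to absorb")
    return freqs / n_walks
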