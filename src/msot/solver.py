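"""Multistage entropic optimal transport solver.

Cells move from designated initial states (X0) through intermediate states
(X) into terminal states (XF) over T discrete transport stages.  At stage 0
each initial cell emits at least one unit of mass, split between a
continuing plan M~_0 (into X) and an exiting plan M^_0 (into XF).  At every
later stage t the mass arriving at an intermediate cell is re-emitted,
again split between continuing (M~_t) and exiting (M^_t) transport; mass
reaching the final stage must exit to XF.  Lower bounds force every
intermediate cell to process at least one unit over the course of the
process and every terminal cell to receive at least one unit, while the
latent stage marginals themselves (how much mass moves at which stage) are
free variables learned by the optimization:

    minimize   sum_t <C~_t, M~_t> + sum_t <C^_t, M^_t>  + eps * entropy
    subject to row(M~_0) + row(M^_0) >= 1            (initial emission)
               col(M~_{t-1}) = row(M~_t) + row(M^_t) (stage coupling)
               sum_t row(M~_t) + row(M^_t) >= 1      (throughput, t >= 1)
               sum_t col(M^_t) >= 1                  (terminal reception)

The entropic problem is solved by block coordinate ascent on the dual: each
constraint block corresponds to a diagonal scaling of the stage kernels
K = exp(-C/eps); equality blocks get free scalings (geometric-mean update),
inequality blocks get scalings clipped at 1.  Nesting the solve in a
KL-proximal loop (each round's kernel is the previous round's plan times
exp(-C/eps)) divides the effective regularization by the round count,
reaching small effective eps without numerical underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CostSet, InvalidInputError, InvalidParameterError, MsotConfig, StatePartition


class NumericalInstabilityError(ArithmeticError):
    """A scaling kernel underflowed to an all-zero row or column.

    Typically caused by cells at extreme distances from all others.  Remedies:
    increase the regularization, enable log-domain updates, or add auxiliary
    states so that outliers have a bounded-cost escape route.
    """


@dataclass
class StagePlans:
    """Transport plans of a multistage solve.

    ``Mtilde[0]`` is n0 x n (initial -> intermediate), ``Mtilde[t]`` is
    n x n for t = 1..T-2.  ``Mhat[0]`` is n0 x nF, ``Mhat[t]`` is n x nF
    for t = 1..T-1.  Latent marginals are derived sums: ``mu_tilde[t]`` /
    ``mu_hat[t]`` are row sums (mass continuing / exiting at stage t) and
    ``nu_hat[t]`` are column sums (mass received by terminal cells).
    """

    Mtilde: list[np.ndarray]
    Mhat: list[np.ndarray]

    @property
    def T(self) -> int:
        return len(self.Mhat)

    def mu_tilde(self, t: int) -> np.ndarray:
        return self.Mtilde[t].sum(axis=1)

    def mu_hat(self, t: int) -> np.ndarray:
        return self.Mhat[t].sum(axis=1)

    def nu_hat(self, t: int) -> np.ndarray:
        return self.Mhat[t].sum(axis=0)

    def transport_cost(self, costs: CostSet) -> float:
        total = float(np.sum(self.Mtilde[0] * costs.C_0X)) + float(
            np.sum(self.Mhat[0] * costs.C_0F)
        )
        for t in range(1, self.T - 1):
            total += float(np.sum(self.Mtilde[t] * costs.C_XX))
        for t in range(1, self.T):
            total += float(np.sum(self.Mhat[t] * costs.C_XF))
        return total

    def copy(self) -> "StagePlans":
        return StagePlans([M.copy() for M in self.Mtilde], [M.copy() for M in self.Mhat])


@dataclass
class SolveReport:
    converged: bool
    inner_iterations: list[int]
    prox_steps_done: int
    final_residual: float
    transport_cost: float
    effective_epsilon: float

    def to_dict(self) -> dict:
        return {
            "converged": self.converged,
            "inner_iterations": list(self.inner_iterations),
            "prox_steps_done": self.prox_steps_done,
            "final_residual": self.final_residual,
            "transport_cost": self.transport_cost,
            "effective_epsilon": self.effective_epsilon,
        }


# ---------------------------------------------------------------------------
# bimarginal building block


def sinkhorn_bimarginal(
    C: np.ndarray,
    mu1: np.ndarray,
    mu2: np.ndarray,
    epsilon: float,
    tau: float = 1e-9,
    max_iters: int = 100_000,
) -> np.ndarray:
    """Entropy-regularized bimarginal transport by Sinkhorn scaling.

    Returns the plan minimizing <C, M> + eps * sum m (log m - 1) subject to
    row sums mu1 and column sums mu2 (which must balance).
    """
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    if epsilon <= 0:
        raise InvalidParameterError("epsilon must be > 0")
    s1, s2 = mu1.sum(), mu2.sum()
    if s1 <= 0 or abs(s1 - s2) > 1e-9 * max(s1, s2):
        raise InvalidInputError(f"marginal masses must balance: {s1} vs {s2}")
    K = np.exp(-np.asarray(C, dtype=float) / epsilon)
    if np.any(K.sum(axis=1) == 0) or np.any(K.sum(axis=0) == 0):
        raise NumericalInstabilityError(
            "kernel exp(-C/eps) underflowed to an empty row/column; "
            "increase epsilon or use log-domain mode"
        )
    v = np.ones(len(mu2))
    for _ in range(max_iters):
        u = mu1 / (K @ v)
        v_new = mu2 / (K.T @ u)
        if np.max(np.abs(np.log(v_new / v))) * epsilon < tau:
            v = v_new
            break
        v = v_new
    return u[:, None] * K * v[None, :]


# ---------------------------------------------------------------------------
# multistage solver internals


def _logsumexp_mv(logK: np.ndarray, logv: np.ndarray, axis: int) -> np.ndarray:
    """log of (exp(logK) @ exp(logv)) along the given axis."""
    from scipy.special import logsumexp

    if axis == 1:
        return logsumexp(logK + logv[None, :], axis=1)
    return logsumexp(logK + logv[:, None], axis=0)


class _MultistageState:
    """Scaling state for one proximal round (linear or log domain).

    Kernels are per stage: ``K0X`` (n0 x n), ``KXX[t]`` for t = 1..T-2,
    ``K0F`` (n0 x nF), ``KXF[t]`` for t = 1..T-1.  Scalings: ``u0`` (rows
    of the stage-0 plans, clipped >= 1), ``w[t]`` (free coupling scalings
    at stages 1..T-1), ``g`` (throughput, clipped >= 1), ``f`` (terminal,
    clipped >= 1).  In log domain all quantities are stored as logs.
    """

    def __init__(
        self,
        K0X: np.ndarray,
        K0F: np.ndarray,
        KXX: list[np.ndarray],
        KXF: list[np.ndarray],
        T: int,
        log_domain: bool,
    ) -> None:
        self.T = T
        self.log = log_domain
        n0, n = K0X.shape
        nF = K0F.shape[1]
        self.n0, self.n, self.nF = n0, n, nF
        if log_domain:
            with np.errstate(divide="ignore"):
                self.K0X, self.K0F = np.log(K0X), np.log(K0F)
                self.KXX = [None if K is None else np.log(K) for K in KXX]
                self.KXF = [None if K is None else np.log(K) for K in KXF]
            self.u0 = np.zeros(n0)
            self.w = [np.zeros(n) for _ in range(T)]  # w[0] unused
            self.g = np.zeros(n)
            self.f = np.zeros(nF)
        else:
            self.K0X, self.K0F, self.KXX, self.KXF = K0X, K0F, KXX, KXF
            self.u0 = np.ones(n0)
            self.w = [np.ones(n) for _ in range(T)]
            self.g = np.ones(n)
            self.f = np.ones(nF)

    # -- linear-domain primitives ------------------------------------------
    def _mv(self, K: np.ndarray, v: np.ndarray, axis: int) -> np.ndarray:
        if self.log:
            return _logsumexp_mv(K, v, axis)
        return K @ v if axis == 1 else K.T @ v

    def _checked(self, x: np.ndarray, what: str) -> np.ndarray:
        bad = ~np.isfinite(x) if self.log else (x <= 0) | ~np.isfinite(x)
        if np.any(bad):
            cells = np.where(bad)[0].tolist()
            raise NumericalInstabilityError(
                f"kernel underflow while updating {what}: cells {cells} have no "
                "feasible transitions at this regularization (extreme distances); "
                "increase epsilon, enable log_domain, or add auxiliary states"
            )
        return x

    def _clip1(self, target_over_s: np.ndarray) -> np.ndarray:
        # inequality dual: scaling factor clipped at 1 (log: at 0)
        return np.maximum(0.0 if self.log else 1.0, target_over_s)

    # -- sending-side row factors ------------------------------------------
    def _row_factor(self, t: int) -> np.ndarray:
        """Row scaling of the stage-t plans over X: g / w[t]."""
        return self.g - self.w[t] if self.log else self.g / self.w[t]

    def _beta(self, t: int) -> np.ndarray:
        """Row sums of stage-t sending plans, excluding the 1/w[t] factor
        but including g (n-vector)."""
        acc = self._mv(self.KXF[t], self.f, 1)
        if t <= self.T - 2:
            cont = self._mv(self.KXX[t], self.w[t + 1], 1)
            acc = np.logaddexp(acc, cont) if self.log else acc + cont
        return (self.g + acc) if self.log else (self.g * acc)

    def _alpha(self, t: int) -> np.ndarray:
        """Column sums of M~_{t-1}, excluding the w[t] factor (n-vector)."""
        if t == 1:
            return self._mv(self.K0X, self.u0, 0)
        return self._mv(self.KXX[t - 1], self._row_factor(t - 1), 0)

    # -- one sweep over all constraint blocks ------------------------------
    def sweep(self, epsilon: float) -> float:
        """Update every scaling block once; return the max dual update
        (epsilon * max |log change|)."""
        delta = 0.0

        # 1) initial emission inequality
        s = self._mv(self.K0X, self.w[1], 1) if self.n else None
        sF = self._mv(self.K0F, self.f, 1)
        if self.n:
            tot = np.logaddexp(s, sF) if self.log else s + sF
        else:
            tot = sF
        self._checked(tot, "initial states")
        new_u0 = self._clip1(-tot if self.log else 1.0 / tot)
        delta = max(delta, float(np.max(np.abs(new_u0 - self.u0 if self.log else np.log(new_u0 / self.u0)))))
        self.u0 = new_u0

        if self.n:
            # 2) stage-coupling equalities, t = 1..T-1 in order
            for t in range(1, self.T):
                a = self._checked(self._alpha(t), f"stage {t} (incoming)")
                b = self._checked(self._beta(t), f"stage {t} (outgoing)")
                new_w = 0.5 * (b - a) if self.log else np.sqrt(b / a)
                delta = max(
                    delta,
                    float(np.max(np.abs((new_w - self.w[t]) if self.log else np.log(new_w / self.w[t])))),
                )
                self.w[t] = new_w

            # 3) throughput inequality over X
            acc = None
            for t in range(1, self.T):
                term = self._mv(self.KXF[t], self.f, 1)
                if t <= self.T - 2:
                    cont = self._mv(self.KXX[t], self.w[t + 1], 1)
                    term = np.logaddexp(term, cont) if self.log else term + cont
                term = (term - self.w[t]) if self.log else (term / self.w[t])
                if acc is None:
                    acc = term
                else:
                    acc = np.logaddexp(acc, term) if self.log else acc + term
            self._checked(acc, "intermediate states")
            new_g = self._clip1(-acc if self.log else 1.0 / acc)
            delta = max(delta, float(np.max(np.abs((new_g - self.g) if self.log else np.log(new_g / self.g)))))
            self.g = new_g

        # 4) terminal reception inequality
        sig = self._mv(self.K0F, self.u0, 0)
        for t in range(1, self.T):
            term = self._mv(self.KXF[t], self._row_factor(t), 0)
            sig = np.logaddexp(sig, term) if self.log else sig + term
        self._checked(sig, "terminal states")
        new_f = self._clip1(-sig if self.log else 1.0 / sig)
        delta = max(delta, float(np.max(np.abs((new_f - self.f) if self.log else np.log(new_f / self.f)))))
        self.f = new_f

        return epsilon * delta

    # -- materialize plans --------------------------------------------------
    def plans(self) -> StagePlans:
        T, n0, n, nF = self.T, self.n0, self.n, self.nF

        def combine(K, r, c):
            if self.log:
                return np.exp(K + r[:, None] + c[None, :])
            return r[:, None] * K * c[None, :]

        Mtilde = [combine(self.K0X, self.u0, self.w[1]) if n else np.zeros((n0, 0))]
        for t in range(1, T - 1):
            Mtilde.append(combine(self.KXX[t], self._row_factor(t), self.w[t + 1]))
        Mhat = [combine(self.K0F, self.u0, self.f)]
        for t in range(1, T):
            Mhat.append(
                combine(self.KXF[t], self._row_factor(t), self.f) if n else np.zeros((0, nF))
            )
        return StagePlans(Mtilde, Mhat)


def _base_kernels(costs: CostSet, T: int, epsilon: float, n: int):
    K0X = np.exp(-costs.C_0X / epsilon)
    K0F = np.exp(-costs.C_0F / epsilon)
    KXX = [None] + [np.exp(-costs.C_XX / epsilon) for _ in range(1, T - 1)]
    KXF = [None] + [np.exp(-costs.C_XF / epsilon) for _ in range(1, T)]
    return K0X, K0F, KXX, KXF


def _prior_kernels(costs: CostSet, T: int, epsilon: float, prior: StagePlans):
    """KL-proximal kernels: previous plan elementwise times exp(-C/eps)."""
    K0X = prior.Mtilde[0] * np.exp(-costs.C_0X / epsilon)
    K0F = prior.Mhat[0] * np.exp(-costs.C_0F / epsilon)
    KXX = [None] + [prior.Mtilde[t] * np.exp(-costs.C_XX / epsilon) for t in range(1, T - 1)]
    KXF = [None] + [prior.Mhat[t] * np.exp(-costs.C_XF / epsilon) for t in range(1, T)]
    return K0X, K0F, KXX, KXF


def constraint_residuals(plans: StagePlans, partition: StatePartition) -> dict[str, float]:
    """Maximum absolute stage-coupling residual and the max violation of
    each lower-bound constraint (0 when satisfied)."""
    T = plans.T
    n0, n, nF = partition.n0, partition.n, partition.nF
    if plans.Mhat[0].shape != (n0, nF):
        raise InvalidInputError(
            f"stage-0 exiting plan has shape {plans.Mhat[0].shape}, expected {(n0, nF)}"
        )
    coupling = 0.0
    if n:
        for t in range(1, T):
            incoming = plans.Mtilde[t - 1].sum(axis=0)
            outgoing = plans.mu_hat(t) + (plans.mu_tilde(t) if t <= T - 2 else 0.0)
            coupling = max(coupling, float(np.max(np.abs(incoming - outgoing))))
    initial = float(np.max(np.maximum(0.0, 1.0 - (plans.mu_tilde(0) + plans.mu_hat(0)))))
    if n:
        through = np.zeros(n)
        for t in range(1, T):
            through += plans.mu_hat(t) + (plans.mu_tilde(t) if t <= T - 2 else 0.0)
        throughput = float(np.max(np.maximum(0.0, 1.0 - through)))
    else:
        throughput = 0.0
    received = sum(plans.nu_hat(t) for t in range(T))
    terminal = float(np.max(np.maximum(0.0, 1.0 - received)))
    return {
        "coupling": coupling,
        "initial_lower_bound": initial,
        "throughput_lower_bound": throughput,
        "terminal_lower_bound": terminal,
    }


def _max_residual(plans: StagePlans, partition: StatePartition) -> float:
    return max(constraint_residuals(plans, partition).values())


def solve_msot_entropic(
    costs: CostSet,
    partition: StatePartition,
    config: MsotConfig,
    prior: StagePlans | None = None,
) -> tuple[StagePlans, SolveReport]:
    """Solve one entropy-regularized multistage transport problem.

    Runs generalized Sinkhorn sweeps (one update of every constraint block
    per sweep, in the fixed order: initial inequality, coupling equalities
    t = 1..T-1, throughput inequality, terminal inequality) until the
    maximum over dual-variable updates and absolute constraint deviations
    falls below ``config.tol_tau``.  When ``prior`` is given the entropy is
    taken relative to it (KL-proximal step).
    """
    T = config.T
    n = partition.n
    if costs.C_0X.shape != (partition.n0, n) or costs.C_XF.shape != (n, partition.nF):
        raise InvalidInputError("cost matrices inconsistent with partition sizes")
    eps = config.epsilon_start
    if prior is None:
        K0X, K0F, KXX, KXF = _base_kernels(costs, T, eps, n)
    else:
        if prior.T != T or prior.Mhat[0].shape != costs.C_0F.shape:
            raise InvalidInputError("prior plans have inconsistent shapes")
        K0X, K0F, KXX, KXF = _prior_kernels(costs, T, eps, prior)
    state = _MultistageState(K0X, K0F, KXX, KXF, T, config.log_domain)

    iters = 0
    converged = False
    residual = np.inf
    check_every = 10
    while iters < config.max_inner_iters:
        delta = state.sweep(eps)
        iters += 1
        if delta < config.tol_tau and (iters % check_every == 0 or delta < 0.1 * config.tol_tau):
            plans = state.plans()
            residual = _max_residual(plans, partition)
            if max(delta, residual) < config.tol_tau:
                converged = True
                break
    plans = state.plans()
    residual = _max_residual(plans, partition)
    report = SolveReport(
        converged=converged,
        inner_iterations=[iters],
        prox_steps_done=1,
        final_residual=residual,
        transport_cost=plans.transport_cost(costs),
        effective_epsilon=eps,
    )
    return plans, report


def proximal_solve(
    costs: CostSet,
    partition: StatePartition,
    config: MsotConfig,
) -> tuple[StagePlans, SolveReport]:
    """Solve the multistage problem at effective regularization
    ``epsilon_start / prox_iters`` by KL-proximal iteration.

    Each round re-solves the entropic problem with the previous round's
    plans as prior, so after k rounds the accumulated kernel equals
    exp(-k C / epsilon_start) times scalings — the effective epsilon is
    epsilon_start / k.  Returns the final plans and a cumulative report.
    """
    plans: StagePlans | None = None
    inner: list[int] = []
    converged = True
    residual = np.inf
    for k in range(config.prox_iters):
        plans, report = solve_msot_entropic(costs, partition, config, prior=plans)
        inner.extend(report.inner_iterations)
        residual = report.final_residual
        if not report.converged:
            converged = False
            break
    assert plans is not None
    rounds_done = len(inner)
    return plans, SolveReport(
        converged=converged,
        inner_iterations=inner,
        prox_steps_done=rounds_done,
        final_residual=residual,
        transport_cost=plans.transport_cost(costs),
        effective_epsilon=config.epsilon_start / max(1, rounds_done),
    )
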