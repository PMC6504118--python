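"""Information-processing capacity of the microcircuit.

The circuit is treated as a reservoir: an i.i.d. input sequence
u[n] ~ U[0, 1] is injected as a piecewise-constant current, the E-population
membrane potentials sampled once per input step form the state matrix
X (N_E x T), and the capacity to reconstruct a target function z from the
states with an ordinary-least-squares linear readout is

    C[X, z] = 1 - ||z - z_hat||^2 / ||z||^2   (mean-centered, clipped to [0, 1])

which equals 1 iff some linear combination of the states equals z.  Target
functions are finite products of normalized Legendre polynomials of delayed
inputs, y_{d_k} = prod_k P_{d_k}(2 u[n-k] - 1); under the uniform input
measure they form an orthonormal basis, so their capacities measure
independent properties.  The linear memory capacity C_M sums the degree-1
capacities over delays (the fading-memory function); the total capacity C_T
sums over all evaluated basis functions, partitioned by total degree
(nonlinearity).

Finite samples inflate small capacities by about N_state/T; capacities below
a threshold (default 2 N_state/T) are zeroed before aggregation and the
threshold is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import eval_legendre

from .engine import (Microcircuit, StimulusProgram, choose_input_targets,
                     make_input_signal, simulate)

__all__ = [
    "StateMatrix",
    "CapacityResult",
    "legendre_poly",
    "build_target",
    "harvest_states",
    "StateDecomposition",
    "capacity_score",
    "memory_capacity",
    "total_capacity",
    "optimal_resolution",
]


def legendre_poly(d: int, s, normalized: bool = True):
    """Legendre polynomial P_d(s) on [-1, 1], optionally scaled by
    sqrt(2d + 1) so the family is orthonormal under the uniform measure."""
    if d < 0 or int(d) != d:
        raise ValueError("degree must be a nonnegative integer")
    v = eval_legendre(int(d), np.asarray(s, dtype=float))
    if normalized:
        v = v * np.sqrt(2.0 * d + 1.0)
    return v


def build_target(u, basis: dict[int, int], normalized: bool = True):
    """Target sequence z[n] = prod_k P_{d_k}(2 u[n-k] - 1) for n >= max k.

    ``basis`` maps delay k -> degree d_k (all degrees >= 1).  The input is
    affinely mapped from [0, 1] to [-1, 1] before evaluating the
    polynomials, which is what makes the product family orthonormal for
    u ~ U[0, 1].  Returns (z, offset): z has length len(u) - offset and
    pairs with state columns offset..len(u)-1.
    """
    if not basis:
        raise ValueError("basis must contain at least one delay term")
    if min(basis.values()) < 1:
        raise ValueError("basis degrees must be >= 1")
    if min(basis.keys()) < 0:
        raise ValueError("delays must be nonnegative")
    u = np.asarray(u, dtype=float)
    k_max = max(basis)
    if k_max >= len(u):
        raise ValueError("maximum delay must be below the sequence length")
    s = 2.0 * u - 1.0
    n = np.arange(k_max, len(u))
    z = np.ones(len(n))
    for k, d in basis.items():
        z = z * legendre_poly(d, s[n - k], normalized=normalized)
    return z, k_max


@dataclass
class StateMatrix:
    """Sampled E-population states paired with the driving input."""

    X: np.ndarray          # (N_E, T) membrane potentials, one column per step
    u: np.ndarray          # (T,)
    dt_input: float        # ms
    washout: int           # input steps discarded before the first column

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.X.shape[1] != len(self.u):
            raise ValueError("state columns must match the input length")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("state matrix contains non-finite entries")

    @property
    def n_state(self) -> int:
        return self.X.shape[0]

    @property
    def T(self) -> int:
        return self.X.shape[1]


def harvest_states(circuit: Microcircuit, T: int, dt_input: float,
                   rho_u: float, nu_in: float, washout: int = 100,
                   seed=None, resolution: float = 0.1,
                   target_idx=None) -> StateMatrix:
    """Drive the circuit with a fresh input sequence and collect states.

    Initial membrane potentials are randomized (V0 ~ U[E_leak, V_thresh]),
    the signal runs for T + washout steps of dt_input ms, each E neuron's
    membrane potential is sampled at the last grid point of every input
    step, and the washout columns are discarded.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    s_u, s_tgt, s_sim = ss.spawn(3)
    u_full, _ = make_input_signal(T + washout, dt_input, rho_u, seed=s_u,
                                  resolution=resolution)
    if target_idx is None:
        target_idx = choose_input_targets(circuit, seed=s_tgt)
    program = StimulusProgram(nu_in=nu_in, u=u_full, dt_input=dt_input,
                              rho_u=rho_u, target_idx=target_idx)
    duration = (T + washout) * dt_input
    res = simulate(circuit, program, duration=duration, resolution=resolution,
                   seed=s_sim, init="random", record_v="E",
                   rec_every_ms=dt_input)
    X = res.V_rec.T  # rows: E neurons, columns: end of each input step
    return StateMatrix(X=X[:, washout:], u=u_full[washout:],
                       dt_input=dt_input, washout=washout)


class StateDecomposition:
    """Orthonormal decomposition of mean-centered states for fast scoring.

    A thin SVD of the centered state matrix turns each capacity evaluation
    into a projection onto at most rank(X) orthonormal time courses, so
    thousands of basis functions can be scored without refitting readouts.
    The result is identical to the ordinary-least-squares readout score
    C = 1 - ||z - z_hat||^2 / ||z_c||^2.
    """

    def __init__(self, X, offset: int = 0, rcond: float = 1e-10):
        Xc = np.asarray(X, dtype=float)[:, offset:]
        Xc = Xc - Xc.mean(axis=1, keepdims=True)
        # rows = time, columns = state variables
        U, s, _ = np.linalg.svd(Xc.T, full_matrices=False)
        keep = s > rcond * s[0] if len(s) and s[0] > 0 else slice(0)
        self.U = U[:, keep]
        self.rank = self.U.shape[1]
        self.T = Xc.shape[1]
        self.offset = offset

    def score(self, z) -> float:
        z = np.asarray(z, dtype=float)
        if len(z) != self.T:
            raise ValueError("target length must match the state columns")
        zc = z - z.mean()
        denom = zc @ zc
        if denom <= 0:
            raise ValueError("target function is constant/zero")
        proj = self.U.T @ zc
        return float(np.clip((proj @ proj) / denom, 0.0, 1.0))


def capacity_score(X, z) -> float:
    """Capacity C[X, z] in [0, 1] of a linear readout of z from states X.

    ``X`` is (N_state, T) (or a StateMatrix), ``z`` a length-T target.
    States and target are mean-centered; the readout is ordinary least
    squares via the pseudo-inverse, and the score is the captured fraction
    of the target's variance, clipped to [0, 1].
    """
    if isinstance(X, StateMatrix):
        X = X.X
    return StateDecomposition(X).score(z)


@dataclass
class CapacityResult:
    """Per-basis capacities and their aggregates."""

    entries: list          # dicts: {basis, degree, capacity, kept}
    threshold: float
    n_state: int
    T: int
    memory_curve: np.ndarray | None = None
    C_M: float | None = None
    per_degree: dict = field(default_factory=dict)
    C_T: float | None = None
    meta: dict = field(default_factory=dict)


def _default_threshold(n_state, T):
    return 2.0 * n_state / T


def memory_capacity(X, u, k_max: int = 100, threshold: float | None = None):
    """Fading-memory function C(k) and linear memory capacity C_M.

    C(k) is the capacity to reconstruct u[n-k] (degree-1 Legendre target)
    for k = 0..k_max; values below the significance threshold are zeroed.
    C_M = sum_k C(k).
    """
    if isinstance(X, StateMatrix):
        u = X.u if u is None else u
        X = X.X
    u = np.asarray(u, dtype=float)
    T = X.shape[1]
    if k_max >= T:
        raise ValueError("k_max must be below the number of state columns")
    thr = _default_threshold(X.shape[0], T) if threshold is None else threshold
    dec = StateDecomposition(X, offset=k_max)
    curve = np.empty(k_max + 1)
    for k in range(k_max + 1):
        z, _ = build_target(u, {k: 1})
        c = dec.score(z[k_max - k:] if k < k_max else z)
        curve[k] = c if c >= thr else 0.0
    return curve, float(curve.sum())


def total_capacity(X, u, d_max: int = 4, k_max: int = 100,
                   threshold: float | None = None, max_terms: int = 3,
                   shell_epsilon: float = 1e-3,
                   budget: int = 30000) -> CapacityResult:
    """Total information-processing capacity over Legendre product bases.

    Enumerates basis functions {delay k -> degree d_k} with total degree
    sum(d_k) from 1 to ``d_max``, delays in [0, k_max] and at most
    ``max_terms`` simultaneous factors.  For every structure the delay
    combinations are swept in increasing maximal delay and the sweep stops
    early once a full delay shell contributes less than ``shell_epsilon``
    (the capacity space is enormous and fades with delay, so exhaustive
    enumeration is neither possible nor informative).  Capacities below the
    significance threshold count as zero.  C_T <= rank(X) by construction.
    """
    if isinstance(X, StateMatrix):
        u = X.u if u is None else u
        X = X.X
    u = np.asarray(u, dtype=float)
    T = X.shape[1]
    thr = _default_threshold(X.shape[0], T) if threshold is None else threshold
    dec = StateDecomposition(X, offset=min(k_max, T - 1))
    off = dec.offset
    k_max = off  # delays beyond the discarded prefix cannot be aligned

    entries = []
    per_degree = {}
    n_evaluated = 0
    truncated = False

    def score_basis(basis):
        nonlocal n_evaluated
        z, k0 = build_target(u, basis)
        z = z[off - k0:] if k0 < off else z
        c = dec.score(z)
        n_evaluated += 1
        kept = c >= thr
        entries.append(dict(basis=dict(basis), degree=sum(basis.values()),
                            capacity=c, kept=bool(kept)))
        return c if kept else 0.0

    for degree in range(1, d_max + 1):
        tot = 0.0
        # partitions of `degree` into at most max_terms positive parts
        for parts in _partitions(degree, max_terms):
            m = len(parts)
            if n_evaluated >= budget:
                truncated = True
                break
            # sweep delay shells: max delay grows until a shell adds nothing
            gained_any = False
            for shell in range(0, k_max + 1):
                shell_gain = 0.0
                for combo in _delay_combos(shell, m):
                    for assign in _assignments(parts, combo):
                        if n_evaluated >= budget:
                            truncated = True
                            break
                        shell_gain += score_basis(assign)
                    if truncated:
                        break
                tot += shell_gain
                if truncated:
                    break
                if shell >= m - 1 and shell_gain < shell_epsilon:
                    if gained_any or shell > 2 * m:
                        break
                if shell_gain >= shell_epsilon:
                    gained_any = True
            if truncated:
                break
        per_degree[degree] = tot
        if truncated:
            break

    return CapacityResult(
        entries=entries, threshold=thr, n_state=X.shape[0], T=T,
        per_degree=per_degree, C_T=float(sum(per_degree.values())),
        meta=dict(d_max=d_max, k_max=k_max, max_terms=max_terms,
                  n_evaluated=n_evaluated, truncated=truncated,
                  rank=dec.rank),
    )


def _partitions(total, max_terms):
    """Partitions of ``total`` into at most ``max_terms`` positive parts
    (non-increasing order)."""
    out = []

    def rec(rest, most, acc):
        if rest == 0:
            out.append(tuple(acc))
            return
        if len(acc) == max_terms:
            return
        for p in range(min(rest, most), 0, -1):
            rec(rest - p, p, acc + [p])

    rec(total, total, [])
    return out


def _delay_combos(shell, m):
    """Delay sets of size m whose maximum equals ``shell``."""
    if m == 1:
        yield (shell,)
        return
    if shell < m - 1:
        return
    for rest in combinations(range(shell), m - 1):
        yield rest + (shell,)


def _assignments(parts, delays):
    """Distinct assignments of degree parts to the delay set."""
    seen = set()
    from itertools import permutations
    for perm in permutations(parts):
        if perm in seen:
            continue
        seen.add(perm)
        yield dict(zip(delays, perm))


def optimal_resolution(circuit: Microcircuit, dt_grid, T: int, rho_u: float,
                       nu_in: float, seeds=(0,), washout: int = 100,
                       criterion: float = 0.99, resolution: float = 0.1):
    """Smallest input step dt at which the circuit tracks its input.

    For each dt in the (ascending) grid, states are harvested and the
    capacity at degree 1, delay 0 is computed; the optimal resolution is the
    smallest dt whose mean capacity over seeds reaches ``criterion``.
    Returns (dt_star, curve); dt_star is NaN when the criterion is never met
    (the full curve is always returned).
    """
    dt_grid = np.sort(np.asarray(dt_grid, dtype=float))
    curve = np.empty(len(dt_grid))
    for i, dtu in enumerate(dt_grid):
        cs = []
        for s in seeds:
            sm = harvest_states(circuit, T=T, dt_input=float(dtu),
                                rho_u=rho_u, nu_in=nu_in, washout=washout,
                                seed=s, resolution=resolution)
            z, _ = build_target(sm.u, {0: 1})
            cs.append(capacity_score(sm.X, z))
        curve[i] = float(np.mean(cs))
    hit = np.flatnonzero(curve >= criterion)
    dt_star = float(dt_grid[hit[0]]) if len(hit) else float("nan")
    return dt_star, dict(dt_grid=dt_grid, capacity=curve)
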