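"""Microcircuit assembly and network simulation.

A :class:`Microcircuit` holds the three neuron populations (E, I1, I2 with
sizes 0.8 N, 0.35*0.2 N and 0.65*0.2 N) and the nine connection blocks for
one heterogeneity condition:

- ``Hom``: all components homogeneous;
- ``Neu``: per-neuron physiological parameters drawn from distributions;
- ``Syn``: lognormal per-connection weights and delays;
- ``Str``: skewed in-/out-degree distributions on the connections that carry
  a nonzero skewness parameter;
- ``Het``: all of the above, plus endpoint weight correlations (which apply
  only when structural and synaptic heterogeneity are combined).

The circuit is driven by homogeneous Poisson background (rate K_in * nu_in
per neuron, delivered through the class's excitatory receptor set with the
class's mean excitatory weight and delay) and, in the active state, by a
piecewise-constant current signal rho_u * u[n], u[n] ~ U[0, 1], injected
into a random 25% subset of the E population.

All randomness derives from named seed-sequence children of a single master
seed, so conditions sharing a component (e.g. Hom and Str share neuron
parameters and weights) realize it identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import params as P
from . import _kernel
from .connectivity import (ConnectionBlock, apply_weight_correlations,
                           build_block_skewed, build_block_uniform)
from .neurons import NeuronPopulation, default_class_spec, sample_population
from .synapses import (default_receptor, default_synapse_spec,
                       receptor_amplitude, sample_weights_delays)

__all__ = [
    "Microcircuit",
    "StimulusProgram",
    "SimulationResult",
    "population_sizes",
    "build_microcircuit",
    "make_background",
    "make_input_signal",
    "choose_input_targets",
    "initialize_states",
    "simulate",
]

BLOCK_ORDER = tuple(P.CONNECTIONS.keys())


def population_sizes(N: int) -> dict[str, int]:
    """Class sizes for total circuit size N (largest-remainder rounding).

    Fractions: E 0.8, I1 0.07, I2 0.13 of N.
    """
    fracs = P.POPULATION_FRACTIONS
    raw = {k: N * f for k, f in fracs.items()}
    sizes = {k: int(np.floor(v)) for k, v in raw.items()}
    short = N - sum(sizes.values())
    order = sorted(fracs, key=lambda k: raw[k] - sizes[k], reverse=True)
    for k in order[:short]:
        sizes[k] += 1
    if min(sizes.values()) <= 0:
        raise ValueError(f"N={N} too small: every population must be nonempty")
    return sizes


@dataclass
class Microcircuit:
    """Populations plus connection blocks for one heterogeneity condition."""

    N: int
    condition: str
    neuronal: bool
    synaptic: bool
    structural: bool
    populations: dict[str, NeuronPopulation]
    blocks: dict[tuple[str, str], ConnectionBlock]
    seed: int
    tau_w: float = P.TAU_W_DEFAULT
    normalize_peak: bool = False

    @property
    def sizes(self) -> dict[str, int]:
        return {k: pop.n for k, pop in self.populations.items()}

    @property
    def offsets(self) -> dict[str, int]:
        """Global index offset of each class (order E, I1, I2)."""
        out, off = {}, 0
        for label in P.CLASS_LABELS:
            out[label] = off
            off += self.populations[label].n
        return out

    def class_slice(self, label: str) -> slice:
        off = self.offsets[label]
        return slice(off, off + self.populations[label].n)


def build_microcircuit(N: int, condition: str, seed: int,
                       tau_w: float = P.TAU_W_DEFAULT,
                       normalize_peak: bool = False,
                       resolution: float = 0.1) -> Microcircuit:
    """Assemble a microcircuit of size N for one heterogeneity condition.

    The master seed is split into a fixed layout of seed-sequence children
    (3 neuron classes, 9 adjacency blocks, 9 weight/delay blocks, 9
    weight-correlation blocks), so circuits differing only in condition
    realize their shared components identically.
    """
    if condition not in P.CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"choose from {sorted(P.CONDITIONS)}")
    neuronal, synaptic, structural = P.CONDITIONS[condition]
    sizes = population_sizes(N)
    children = np.random.SeedSequence(seed).spawn(3 + 3 * len(BLOCK_ORDER))
    neuron_seeds = dict(zip(P.CLASS_LABELS, children[:3]))
    adj_seeds = dict(zip(BLOCK_ORDER, children[3:12]))
    wd_seeds = dict(zip(BLOCK_ORDER, children[12:21]))
    corr_seeds = dict(zip(BLOCK_ORDER, children[21:30]))

    populations = {
        label: sample_population(default_class_spec(label, tau_w=tau_w),
                                 sizes[label], heterogeneous=neuronal,
                                 seed=neuron_seeds[label])
        for label in P.CLASS_LABELS
    }

    blocks = {}
    for pair in BLOCK_ORDER:
        pre, post = pair
        spec = default_synapse_spec(pre, post)
        n_pre, n_post = sizes[pre], sizes[post]
        if structural and (spec.k_in > 0 or spec.k_out > 0):
            block = build_block_skewed(n_pre, n_post, spec.p,
                                       k_out=spec.k_out, k_in=spec.k_in,
                                       seed=adj_seeds[pair], pre=pre, post=post)
        else:
            block = build_block_uniform(n_pre, n_post, spec.p,
                                        seed=adj_seeds[pair], pre=pre, post=post)
        w, d = sample_weights_delays(spec, block.n_edges,
                                     heterogeneous=synaptic,
                                     seed=wd_seeds[pair],
                                     resolution=resolution)
        block.weights, block.delays = w, d
        if structural and synaptic and (spec.c_in > 0 or spec.c_out > 0):
            apply_weight_correlations(block, c_in=spec.c_in, c_out=spec.c_out,
                                      seed=corr_seeds[pair])
        blocks[pair] = block

    return Microcircuit(N=N, condition=condition, neuronal=neuronal,
                        synaptic=synaptic, structural=structural,
                        populations=populations, blocks=blocks, seed=seed,
                        tau_w=tau_w, normalize_peak=normalize_peak)


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

@dataclass
class StimulusProgram:
    """Background rate and (optional) injected current signal."""

    nu_in: float                      # spikes/s per background source
    K_in: int = P.K_IN                # effective number of background synapses
    u: np.ndarray | None = None       # input sequence, values in [0, 1]
    dt_input: float = 0.0             # ms, input step duration
    rho_u: float = 0.0                # pA, current amplitude scale
    target_idx: np.ndarray | None = None  # E-population indices (local)

    def __post_init__(self):
        if self.nu_in < 0:
            raise ValueError("background rate must be nonnegative")
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)
            if self.u.size and (self.u.min() < 0 or self.u.max() > 1):
                raise ValueError("input sequence values must lie in [0, 1]")
            if self.dt_input <= 0:
                raise ValueError("dt_input must be positive with a signal")


def make_background(nu_in: float, K_in: int, n_neurons: int, duration: float,
                    dt: float = 0.1, seed=None) -> np.ndarray:
    """Per-neuron, per-step background event counts.

    Counts are Poisson with mean K_in * nu_in * dt, independent across
    neurons and steps — the exact statistical collapse of K_in independent
    Poisson sources sharing one weight and delay.  Intended for inspection
    and testing at moderate sizes; the simulator draws identical statistics
    internally.
    """
    if nu_in < 0:
        raise ValueError("background rate must be nonnegative")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    lam = K_in * nu_in * dt / 1000.0
    return rng.poisson(lam, size=(n_neurons, n_steps))


def make_input_signal(T_steps: int, dt_input: float, rho_u: float, seed=None,
                      resolution: float = 0.1):
    """Piecewise-constant input signal: u[n] ~ U[0, 1] i.i.d., held for
    dt_input ms and scaled by rho_u.  Returns (u, current_trace)."""
    if T_steps < 1:
        raise ValueError("T_steps must be at least 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=T_steps)
    reps = int(round(dt_input / resolution))
    current = rho_u * np.repeat(u, max(reps, 1))
    return u, current


def choose_input_targets(circuit: Microcircuit,
                         fraction: float = P.INPUT_TARGET_FRACTION,
                         seed=None) -> np.ndarray:
    """Random subset of the E population receiving the injected current."""
    rng = np.random.default_rng(seed)
    n_e = circuit.populations["E"].n
    n_t = int(round(fraction * n_e))
    return np.sort(rng.choice(n_e, size=n_t, replace=False))


def initialize_states(circuit: Microcircuit, mode: str = "rest", seed=None):
    """Initial (V, I_adapt) arrays over the full circuit.

    ``rest``: V = E_leak, I_adapt = 0.  ``random``: V ~ U[E_leak, V_thresh]
    per neuron, I_adapt = 0.
    """
    if mode not in ("rest", "random"):
        raise ValueError("mode must be 'rest' or 'random'")
    rng = np.random.default_rng(seed)
    V0 = np.empty(circuit.N)
    for label in P.CLASS_LABELS:
        pop = circuit.populations[label]
        sl = circuit.class_slice(label)
        if mode == "rest":
            V0[sl] = pop.E_leak
        else:
            V0[sl] = rng.uniform(pop.E_leak, pop.V_thresh)
    return V0, np.zeros(circuit.N)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Spike trains, sampled traces and summary state of one simulation."""

    circuit_condition: str
    N: int
    duration: float
    resolution: float
    rec_every_ms: float
    spike_times: np.ndarray       # ms
    spike_ids: np.ndarray         # global neuron indices
    offsets: dict
    sizes: dict
    rec_times: np.ndarray         # ms, common clock of all traces
    v_rec_idx: np.ndarray
    V_rec: np.ndarray             # (n_rec, len(v_rec_idx)), mV, float64
    cur_rec_idx: np.ndarray
    I_exc: np.ndarray             # (n_rec, len(cur_rec_idx)), pA, signed
    I_inh: np.ndarray
    G_mean: np.ndarray            # (N,), nS, time-averaged total conductance
    u: np.ndarray | None
    seed: int | None
    meta: dict = field(default_factory=dict)

    def spikes_of(self, label: str):
        """(times, local ids) of one population's spikes."""
        off = self.offsets[label]
        n = self.sizes[label]
        m = (self.spike_ids >= off) & (self.spike_ids < off + n)
        return self.spike_times[m], self.spike_ids[m] - off

    def spike_trains(self, label: str, t_start=0.0, t_stop=None):
        """List of per-neuron spike-time arrays for one population."""
        t_stop = self.duration if t_stop is None else t_stop
        times, ids = self.spikes_of(label)
        m = (times >= t_start) & (times <= t_stop)
        times, ids = times[m], ids[m]
        order = np.lexsort((times, ids))
        times, ids = times[order], ids[order]
        bounds = np.searchsorted(ids, np.arange(self.sizes[label] + 1))
        return [times[bounds[i]:bounds[i + 1]]
                for i in range(self.sizes[label])]

    def mean_rate(self, label: str, t_start=0.0, t_stop=None) -> float:
        """Population mean firing rate (spikes/s)."""
        t_stop = self.duration if t_stop is None else t_stop
        times, _ = self.spikes_of(label)
        m = (times >= t_start) & (times <= t_stop)
        span_s = (t_stop - t_start) / 1000.0
        return float(m.sum()) / (self.sizes[label] * span_s)

    def fraction_active(self, label: str) -> float:
        """Fraction of the population emitting at least one spike."""
        _, ids = self.spikes_of(label)
        return len(np.unique(ids)) / self.sizes[label]

    def save_spikes_text(self, path):
        np.savetxt(path, np.column_stack([self.spike_times, self.spike_ids]),
                   fmt=["%.1f", "%d"], header="time_ms neuron_id")


def _receptor_layout(circuit: Microcircuit, dt: float):
    """Per-neuron component increment and decay arrays (N, 16)."""
    N = circuit.N
    inc = np.zeros((N, _kernel.N_COMP))
    dec = np.zeros((N, _kernel.N_COMP))
    mg_coef = np.empty(N)
    E_ga = np.empty(N)
    E_gb = np.empty(N)
    for label in P.CLASS_LABELS:
        sl = circuit.class_slice(label)
        for name, (lo, hi) in _kernel.SLOTS.items():
            rec = default_receptor(label, name)
            amp = receptor_amplitude(rec, circuit.normalize_peak)
            comps = rec.components()
            if len(comps) > hi - lo:
                raise RuntimeError("receptor needs more than 4 components")
            for c, (coef, tau) in enumerate(comps):
                inc[sl, lo + c] = amp * coef
                dec[sl, lo + c] = np.exp(-dt / tau)
            if name == "NMDA":
                mg_coef[sl] = rec.Mg_conc / 3.57
            elif name == "GABA_A":
                E_ga[sl] = rec.E_rev
            elif name == "GABA_B":
                E_gb[sl] = rec.E_rev
    return inc, dec, mg_coef, E_ga, E_gb


def _flatten_edges(circuit: Microcircuit, dt: float):
    """Global CSR-by-source edge arrays (dst, weight, delay steps)."""
    offsets = circuit.offsets
    srcs, dsts, ws, ds = [], [], [], []
    for (pre, post), block in circuit.blocks.items():
        if block.n_edges == 0:
            continue
        srcs.append(block.pre_idx + offsets[pre])
        dsts.append(block.post_idx + offsets[post])
        ws.append(block.weights)
        ds.append(block.delays)
    if srcs:
        src = np.concatenate(srcs)
        dst = np.concatenate(dsts).astype(np.int64)
        w = np.concatenate(ws).astype(float)
        dsteps = np.maximum(np.round(np.concatenate(ds) / dt), 1).astype(np.int64)
    else:
        src = np.empty(0, dtype=np.int64)
        dst = np.empty(0, dtype=np.int64)
        w = np.empty(0)
        dsteps = np.empty(0, dtype=np.int64)
    order = np.argsort(src, kind="stable")
    src, dst, w, dsteps = src[order], dst[order], w[order], dsteps[order]
    ptr = np.searchsorted(src, np.arange(circuit.N + 1)).astype(np.int64)
    return ptr, dst, w, dsteps


def _neuron_arrays(circuit: Microcircuit):
    N = circuit.N
    out = {k: np.empty(N) for k in
           ("EL", "Vth", "Vr", "gL", "Cm", "a", "b", "inv_tau_w")}
    t_ref = np.empty(N)
    for label in P.CLASS_LABELS:
        pop = circuit.populations[label]
        sl = circuit.class_slice(label)
        out["EL"][sl] = pop.E_leak
        out["Vth"][sl] = pop.V_thresh
        out["Vr"][sl] = pop.V_reset
        out["gL"][sl] = pop.g_leak
        out["Cm"][sl] = pop.C_m
        out["a"][sl] = pop.a
        out["b"][sl] = pop.b
        out["inv_tau_w"][sl] = 1.0 / pop.tau_w
        t_ref[sl] = pop.t_ref
    return out, t_ref


def _resolve_indices(spec, circuit: Microcircuit) -> np.ndarray:
    """Recording-subset spec -> sorted global indices."""
    if spec is None:
        return np.empty(0, dtype=np.int64)
    if isinstance(spec, str):
        if spec == "all":
            return np.arange(circuit.N, dtype=np.int64)
        if spec in P.CLASS_LABELS:
            sl = circuit.class_slice(spec)
            return np.arange(sl.start, sl.stop, dtype=np.int64)
        raise ValueError(f"unknown recording spec {spec!r}")
    return np.sort(np.asarray(spec, dtype=np.int64))


def simulate(circuit: Microcircuit, program: StimulusProgram,
             duration: float, resolution: float = 0.1, seed=None,
             init="rest", record_v="all", record_currents=None,
             rec_every_ms: float = 1.0, max_mean_rate: float = 400.0,
             forced_spikes=None) -> SimulationResult:
    """Integrate the circuit dynamics and return spikes plus sampled traces.

    ``init`` is 'rest', 'random', or a (V0, I_adapt0) pair.  ``record_v`` /
    ``record_currents`` select traced neurons ('all', a class label, an index
    array or None).  ``forced_spikes`` is an optional (step, global neuron
    id) array whose entries are delivered through the neuron's outgoing
    synapses without the neuron itself spiking (used for single-PSP
    protocols).  Identical (circuit, program, seed) inputs reproduce spike
    trains bit-for-bit.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = resolution
    n_steps = int(round(duration / dt))
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed if seed is not None else 0)
    init_seed, kernel_seed = ss.spawn(2)

    if isinstance(init, str):
        V0, w0 = initialize_states(circuit, init, seed=init_seed)
    else:
        V0, w0 = (np.array(init[0], dtype=float), np.array(init[1], dtype=float))

    pars, t_ref = _neuron_arrays(circuit)
    ref_steps = np.ceil(t_ref / dt - 1e-12).astype(np.int64)
    inc, dec, mg_coef, E_ga, E_gb = _receptor_layout(circuit, dt)
    ptr, dst, w, dsteps = _flatten_edges(circuit, dt)

    # background: class mean excitatory weight/delay, lambda = K_in*nu_in*dt
    bg_lambda = np.zeros(circuit.N)
    bg_w = np.zeros(circuit.N)
    bg_d = np.ones(circuit.N, dtype=np.int64)
    if program.nu_in > 0:
        lam = program.K_in * program.nu_in * dt / 1000.0
        for label in P.CLASS_LABELS:
            sl = circuit.class_slice(label)
            spec = default_synapse_spec("E", label)
            bg_lambda[sl] = lam
            bg_w[sl] = spec.mu_w
            bg_d[sl] = max(int(round(spec.mu_d / dt)), 1)

    # injected current signal
    inj_amp = np.zeros(circuit.N)
    if program.u is not None and len(program.u) and program.rho_u != 0.0:
        if program.target_idx is None:
            raise ValueError("a stimulus program with a signal needs target_idx")
        steps_per_input = int(round(program.dt_input / dt))
        if steps_per_input < 1 or not np.isclose(
                steps_per_input * dt, program.dt_input):
            raise ValueError("dt_input must be a positive multiple of the "
                             "simulation resolution")
        off = circuit.offsets["E"]
        inj_amp[np.asarray(program.target_idx) + off] = program.rho_u
        u_seq = np.asarray(program.u, dtype=float)
    else:
        steps_per_input = 0
        u_seq = np.zeros(1)

    rec_every = max(int(round(rec_every_ms / dt)), 1)
    n_rec = n_steps // rec_every
    v_idx = _resolve_indices(record_v, circuit)
    c_idx = _resolve_indices(record_currents, circuit)
    V_rec = np.empty((n_rec, len(v_idx)))
    I_exc = np.empty((n_rec, len(c_idx)))
    I_inh = np.empty((n_rec, len(c_idx)))
    G_sum = np.zeros(circuit.N)

    max_spikes = int(circuit.N * (duration / 1000.0) * max_mean_rate) + 1000
    spike_step = np.empty(max_spikes, dtype=np.int64)
    spike_id = np.empty(max_spikes, dtype=np.int64)

    kseed = int(kernel_seed.generate_state(1)[0] % (2**31 - 1))

    if forced_spikes is not None and len(forced_spikes):
        fs = np.asarray(forced_spikes, dtype=np.int64).reshape(-1, 2)
        order = np.argsort(fs[:, 0], kind="stable")
        forced_steps = fs[order, 0].copy()
        forced_ids = fs[order, 1].copy()
    else:
        forced_steps = np.empty(0, dtype=np.int64)
        forced_ids = np.empty(0, dtype=np.int64)

    n_spikes, status = _kernel.run_network(
        n_steps, dt, circuit.populations["E"].n,
        pars["EL"], pars["Vth"], pars["Vr"], pars["gL"], pars["Cm"],
        ref_steps, pars["a"], pars["b"], pars["inv_tau_w"], mg_coef,
        E_ga, E_gb, inc, dec, ptr, dst, w, dsteps,
        bg_lambda, bg_w, bg_d, inj_amp, u_seq, steps_per_input,
        forced_steps, forced_ids,
        V0, w0, kseed, rec_every, v_idx, c_idx,
        V_rec, I_exc, I_inh, G_sum, spike_step, spike_id,
    )
    if status == _kernel.STATUS_SPIKE_OVERFLOW:
        raise RuntimeError(
            f"spike budget exceeded ({max_spikes}); raise max_mean_rate")
    if status == _kernel.STATUS_NOT_FINITE:
        raise FloatingPointError("membrane potential diverged (NaN/inf)")

    return SimulationResult(
        circuit_condition=circuit.condition, N=circuit.N, duration=duration,
        resolution=dt, rec_every_ms=rec_every * dt,
        spike_times=spike_step[:n_spikes] * dt,
        spike_ids=spike_id[:n_spikes].copy(),
        offsets=circuit.offsets, sizes=circuit.sizes,
        rec_times=(np.arange(n_rec) + 1.0) * rec_every * dt,
        v_rec_idx=v_idx, V_rec=V_rec, cur_rec_idx=c_idx,
        I_exc=I_exc, I_inh=I_inh,
        G_mean=G_sum / n_steps, u=program.u,
        seed=seed,
        meta=dict(condition=circuit.condition, n_steps=n_steps,
                  kernel_seed=kseed, nu_in=program.nu_in, K_in=program.K_in,
                  rho_u=program.rho_u, dt_input=program.dt_input,
                  flags=dict(neuronal=circuit.neuronal,
                             synaptic=circuit.synaptic,
                             structural=circuit.structural)),
    )
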