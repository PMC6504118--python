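"""Conductance-based receptor kinetics and synaptic parameter sampling.

A single presynaptic event elicits, on receptor ``rec`` of the postsynaptic
neuron, the conductance transient

    g(t) = g_bar * n(V) * A * (1 - exp(-t/tau_rise))
           * (r exp(-t/tau_f) + (1 - r) exp(-t/tau_s)) * Theta(t)

where ``n(V)`` is 1 for all receptors except NMDA, whose voltage-dependent
magnesium block follows  n(V) = (1 + [Mg]/3.57 * exp(-0.062 V))^-1.

By default A = 1, i.e. ``g_bar`` multiplies the raw product shape (whose
maximum lies below 1): this convention reproduces the reference single-spike
PSP amplitudes, most precisely the 0.82 mV excitatory PSP on E cells.
Setting ``normalize_peak=True`` instead rescales the shape so the realized
single-spike conductance peaks exactly at ``g_bar``.

The product form expands into at most four pure exponentials, so the
superposition over a spike train is maintained exactly by exponentially
decaying state variables that receive weighted jumps at spike arrival.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from . import params as P
from .neurons import lognormal_shape_params, scalar_params

__all__ = [
    "ReceptorParams",
    "SynapseTypeSpec",
    "PSPSummary",
    "default_receptor",
    "default_synapse_spec",
    "nmda_gating",
    "conductance_waveform",
    "peak_normalization",
    "receptor_amplitude",
    "ReceptorBank",
    "psp_response",
    "fit_double_exponential",
    "sample_weights_delays",
]

RECEPTOR_NAMES = ("AMPA", "NMDA", "GABA_A", "GABA_B")
EXC_RECEPTORS = ("AMPA", "NMDA")
INH_RECEPTORS = ("GABA_A", "GABA_B")


@dataclass(frozen=True)
class ReceptorParams:
    """Kinetic parameters of one receptor type on one neuron class."""

    name: str
    g_bar: float              # nS, realized single-spike peak conductance
    E_rev: float              # mV
    tau_rise: float           # ms
    r: float                  # fast/slow decay balance in [0, 1]
    tau_decay_fast: float | None  # ms, absent when r = 0
    tau_decay_slow: float | None  # ms, absent when r = 1
    Mg_conc: float = P.MG_CONC

    def __post_init__(self):
        if self.tau_rise <= 0:
            raise ValueError("tau_rise must be positive")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")
        if self.r > 0 and (self.tau_decay_fast is None or
                           self.tau_decay_fast <= self.tau_rise):
            raise ValueError("tau_decay_fast must exceed tau_rise")
        if self.r < 1 and (self.tau_decay_slow is None or
                           self.tau_decay_slow <= self.tau_rise):
            raise ValueError("tau_decay_slow must exceed tau_rise")

    @property
    def voltage_gated(self) -> bool:
        return self.name == "NMDA"

    def components(self) -> list[tuple[float, float]]:
        """Expand the transient into (coefficient, tau) exponential pairs.

        (1-e^{-t/tr})(r e^{-t/tf} + (1-r) e^{-t/ts}) =
            r e^{-t/tf} + (1-r) e^{-t/ts}
          - r e^{-t/t_rf} - (1-r) e^{-t/t_rs}
        with 1/t_rx = 1/tr + 1/tx.  Zero-coefficient terms are dropped.
        """
        comps = []
        for coef, tau in ((self.r, self.tau_decay_fast),
                          (1.0 - self.r, self.tau_decay_slow)):
            if coef > 0:
                tau_mix = 1.0 / (1.0 / self.tau_rise + 1.0 / tau)
                comps.append((coef, tau))
                comps.append((-coef, tau_mix))
        return comps

    @property
    def slowest_tau(self) -> float:
        return max(tau for _, tau in self.components())


def default_receptor(post_class: str, name: str) -> ReceptorParams:
    """Reference receptor parameters for ``name`` on class ``post_class``."""
    return ReceptorParams(name=name, **P.RECEPTORS[post_class][name])


def nmda_gating(V, Mg_conc: float = P.MG_CONC):
    """Voltage-dependent NMDA magnesium-block factor in (0, 1).

    n(V) = (1 + [Mg]/3.57 mM * exp(-0.062 V))^-1, strictly increasing in V.
    """
    return 1.0 / (1.0 + (Mg_conc / 3.57) * np.exp(-0.062 * np.asarray(V, dtype=float)))


def _unit_shape(rec: ReceptorParams, t):
    """Unnormalized transient shape (peak < 1) evaluated at times t (ms)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    acc = np.zeros_like(tp)
    for coef, tau in rec.components():
        acc += coef * np.exp(-tp / tau)
    out[pos] = acc
    return out


@lru_cache(maxsize=64)
def _peak_normalization_cached(key) -> float:
    rec = ReceptorParams(*key)
    hi = 20.0 * rec.slowest_tau
    res = minimize_scalar(lambda t: -_unit_shape(rec, np.array([t]))[0],
                          bounds=(1e-6, hi), method="bounded",
                          options={"xatol": 1e-10})
    peak = -res.fun
    if peak <= 0:
        raise RuntimeError("degenerate receptor shape")
    return 1.0 / peak


def peak_normalization(rec: ReceptorParams) -> float:
    """Constant A such that the single-spike conductance peaks at g_bar."""
    key = (rec.name, rec.g_bar, rec.E_rev, rec.tau_rise, rec.r,
           rec.tau_decay_fast, rec.tau_decay_slow, rec.Mg_conc)
    return _peak_normalization_cached(key)


def receptor_amplitude(rec: ReceptorParams, normalize_peak: bool = False) -> float:
    """Multiplier applied to the unit shape: g_bar, optionally rescaled so
    that the realized single-spike peak equals g_bar exactly."""
    amp = rec.g_bar
    if normalize_peak:
        amp *= peak_normalization(rec)
    return amp


def conductance_waveform(rec: ReceptorParams, t, V=0.0,
                         normalize_peak: bool = False):
    """Single-spike conductance (nS) at times ``t`` (ms after spike arrival).

    For NMDA the magnesium block is evaluated at membrane potential ``V``.
    """
    g = receptor_amplitude(rec, normalize_peak) * _unit_shape(rec, t)
    if rec.voltage_gated:
        g = g * nmda_gating(V, rec.Mg_conc)
    return g


class ReceptorBank:
    """Exponential-state realization of one receptor on ``n`` neurons.

    The conductance is maintained as a linear combination of exponentially
    decaying state variables such that summing spike-triggered waveforms
    reproduces the superposition of single-spike transients exactly (up to
    floating point) on the integration grid.
    """

    def __init__(self, rec: ReceptorParams, n: int = 1, dt: float = 0.1,
                 normalize_peak: bool = False):
        self.rec = rec
        self.n = n
        self.dt = dt
        comps = rec.components()
        amp = receptor_amplitude(rec, normalize_peak)
        self._coefs = np.array([amp * c for c, _ in comps])
        self._decay = np.exp(-dt / np.array([tau for _, tau in comps]))
        self.state = np.zeros((len(comps), n))

    def deliver_spike(self, weight=1.0, index=slice(None)):
        """Register spike arrival (weight may be a scalar or per-target array)."""
        if np.ndim(weight) == 0:
            self.state[:, index] += self._coefs[:, None] * weight
        else:
            self.state[:, index] += np.multiply.outer(self._coefs, weight)

    def step(self):
        """Advance the states by one dt of exact exponential decay."""
        self.state *= self._decay[:, None]

    def conductance(self, V=None):
        """Current conductance (nS) per neuron; NMDA gated at potential V."""
        g = self.state.sum(axis=0)
        if self.rec.voltage_gated and V is not None:
            g = g * nmda_gating(V, self.rec.Mg_conc)
        return g


@dataclass
class PSPSummary:
    """Double-exponential characterization of a single-spike PSP."""

    J_syn: float          # mV, signed peak amplitude
    tau_rise_fit: float   # ms
    tau_decay_fit: float  # ms
    residual: float       # rms of fit residual (mV)
    fit_ok: bool
    t: np.ndarray | None = None
    v: np.ndarray | None = None


def fit_double_exponential(t, v):
    """Least-squares fit of A (exp(-t/tau_d) - exp(-t/tau_r)) to a PSP trace.

    ``t`` is time since spike arrival (ms).  Initialization uses the 20-80%
    rise time and the post-peak log-slope.  Returns (A, tau_r, tau_d,
    rms_residual, ok); on failure the peak value and NaN time constants are
    returned with ok=False.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    sign = 1.0 if abs(v.max()) >= abs(v.min()) else -1.0
    u = sign * v
    i_peak = int(np.argmax(u))
    peak = u[i_peak]
    if peak <= 0:
        return 0.0, np.nan, np.nan, float(np.sqrt(np.mean(v**2))), False

    # 20-80% rise time -> tau_r guess
    pre = u[: i_peak + 1]
    try:
        t20 = t[np.searchsorted(pre, 0.2 * peak)]
        t80 = t[np.searchsorted(pre, 0.8 * peak)]
        tau_r0 = max((t80 - t20) / np.log(4.0), 0.05)
    except IndexError:
        tau_r0 = 1.0
    # post-peak log slope -> tau_d guess
    post = u[i_peak:]
    tpost = t[i_peak:]
    above = post > 0.1 * peak
    if above.sum() > 2:
        coef = np.polyfit(tpost[above], np.log(post[above]), 1)[0]
        tau_d0 = -1.0 / coef if coef < 0 else t[-1] / 2.0
    else:
        tau_d0 = t[-1] / 2.0
    tau_d0 = float(np.clip(tau_d0, tau_r0 * 1.5, 10 * t[-1]))

    def model(tt, A, tau_r, tau_d):
        return A * (np.exp(-tt / tau_d) - np.exp(-tt / tau_r))

    try:
        popt, _ = curve_fit(
            model, t, u, p0=(peak * 1.5, tau_r0, tau_d0),
            bounds=([0.0, 1e-3, 1e-3], [np.inf, t[-1], 50 * t[-1]]),
            maxfev=20000,
        )
        A, tau_r, tau_d = popt
        if tau_r > tau_d:  # symmetric parameterization; order them
            tau_r, tau_d = tau_d, tau_r
            A = -A
        resid = float(np.sqrt(np.mean((model(t, *popt) - u) ** 2)))
        return sign * A, float(tau_r), float(tau_d), resid, True
    except RuntimeError:
        return sign * peak, np.nan, np.nan, float("nan"), False


def psp_response(post_class: str, polarity: str, holding="rest",
                 weight: float = 1.0, tau_w: float = P.TAU_W_DEFAULT,
                 duration: float = 300.0, dt: float = 0.1) -> PSPSummary:
    """Voltage response of a homogeneous neuron to one presynaptic spike.

    The neuron starts at its sub-threshold fixed point: at rest
    (``holding='rest'``) or depolarized to a holding potential (mV) by a
    constant current.  A single spike of the given ``weight`` is delivered at
    t = 0 through the class's excitatory (AMPA+NMDA) or inhibitory
    (GABA_A+GABA_B) receptor set, the deflection is recorded and a double
    exponential is fitted from spike arrival over the full window.
    """
    if polarity not in ("exc", "inh"):
        raise ValueError("polarity must be 'exc' or 'inh'")
    p = scalar_params(post_class, tau_w=tau_w)
    V0 = p.E_leak if holding == "rest" else float(holding)
    w0 = p.a * (V0 - p.E_leak)
    I_hold = (p.g_leak + p.a) * (V0 - p.E_leak)

    names = EXC_RECEPTORS if polarity == "exc" else INH_RECEPTORS
    banks = [ReceptorBank(default_receptor(post_class, nm), n=1, dt=dt)
             for nm in names]
    for bank in banks:
        bank.deliver_spike(weight)

    n_steps = int(round(duration / dt))
    V = V0
    w = w0
    trace = np.empty(n_steps + 1)
    trace[0] = V
    gL, EL, Cm, a, tw = p.g_leak, p.E_leak, p.C_m, p.a, p.tau_w
    for t in range(n_steps):
        gs = [(bank.conductance(np.array([V]))[0], bank.rec.E_rev)
              for bank in banks]

        def f(V_, w_):
            I_syn = sum(g * (V_ - E) for g, E in gs)
            return ((-gL * (V_ - EL) - w_ - I_syn + I_hold) / Cm,
                    (-w_ + a * (V_ - EL)) / tw)

        k1 = f(V, w)
        k2 = f(V + 0.5 * dt * k1[0], w + 0.5 * dt * k1[1])
        k3 = f(V + 0.5 * dt * k2[0], w + 0.5 * dt * k2[1])
        k4 = f(V + dt * k3[0], w + dt * k3[1])
        V += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        w += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        for bank in banks:
            bank.step()
        trace[t + 1] = V

    t_axis = np.arange(n_steps + 1) * dt
    defl = trace - V0
    if weight == 0 or np.allclose(defl, 0.0):
        return PSPSummary(0.0, np.nan, np.nan, 0.0, True, t_axis, defl)
    i_ext = int(np.argmax(np.abs(defl)))
    J = float(defl[i_ext])
    _, tau_r, tau_d, resid, ok = fit_double_exponential(t_axis, defl)
    return PSPSummary(J, tau_r, tau_d, resid, ok, t_axis, defl)


@dataclass
class SynapseTypeSpec:
    """Weight/delay statistics and structural-bias parameters of one
    connection type (ordered pre class -> post class)."""

    pre: str
    post: str
    p: float
    mu_w: float
    sigma_w: float
    mu_d: float       # ms
    sigma_d: float    # ms
    k_in: float = 0.0
    k_out: float = 0.0
    c_in: float = 0.0
    c_out: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("connection density must lie in [0, 1]")
        if self.sigma_w < 0 or self.sigma_d < 0:
            raise ValueError("distribution sds must be nonnegative")
        if min(self.k_in, self.k_out, self.c_in, self.c_out) < 0:
            raise ValueError("structural-bias parameters must be nonnegative")

    @property
    def receptors(self) -> tuple[str, ...]:
        return EXC_RECEPTORS if self.pre == "E" else INH_RECEPTORS


def default_synapse_spec(pre: str, post: str) -> SynapseTypeSpec:
    return SynapseTypeSpec(pre=pre, post=post, **P.CONNECTIONS[(pre, post)])


DELAY_TRUNCATION = 0.1  # ms, left truncation of heterogeneous delay draws


def sample_weights_delays(spec: SynapseTypeSpec, n_connections: int,
                          heterogeneous: bool, seed=None,
                          resolution: float = 0.1):
    """Per-connection weights and delays for one connection type.

    Homogeneous: every weight equals mu_w and every delay equals mu_d rounded
    to the simulation grid.  Heterogeneous: independent lognormal draws with
    distribution mean/sd (mu_w, sigma_w) and (mu_d, sigma_d); delay draws
    below 0.1 ms are resampled and all delays are rounded to the nearest
    multiple of ``resolution``.
    """
    if n_connections < 0:
        raise ValueError("n_connections must be nonnegative")
    if spec.mu_d < resolution:
        raise ValueError("mean delay below the simulation resolution")
    rng = np.random.default_rng(seed)
    if not heterogeneous:
        weights = np.full(n_connections, spec.mu_w)
        delays = np.full(n_connections, round(spec.mu_d / resolution) * resolution)
        return weights, np.maximum(delays, resolution)

    mu, sigma = lognormal_shape_params(spec.mu_w, spec.sigma_w)
    weights = rng.lognormal(mu, sigma, size=n_connections)
    mu_d, sigma_d = lognormal_shape_params(spec.mu_d, spec.sigma_d)
    delays = rng.lognormal(mu_d, sigma_d, size=n_connections)
    for _ in range(1000):
        bad = delays < DELAY_TRUNCATION
        if not bad.any():
            break
        delays[bad] = rng.lognormal(mu_d, sigma_d, size=int(bad.sum()))
    delays = np.round(delays / resolution) * resolution
    return weights, np.maximum(delays, resolution)
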