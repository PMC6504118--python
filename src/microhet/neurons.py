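"""Adaptive leaky integrate-and-fire neuron classes.

The membrane potential of each neuron follows

    C_m dV/dt = -g_leak (V - E_leak) - I_adapt - I_syn + I_inj

with an adaptation current

    tau_w dI_adapt/dt = -I_adapt + a (V - E_leak)

incremented by ``b`` at every spike.  When V crosses ``V_thresh`` a spike is
emitted and V is clamped at ``V_reset`` for the refractory period ``t_ref``.
With a = b = 0 the model reduces exactly to the plain leaky
integrate-and-fire neuron.

Three parameterizations (classes ``E``, ``I1``, ``I2``) are provided, each
either homogeneous (every neuron identical) or heterogeneous (parameters
drawn independently per neuron from normal/lognormal distributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import params as P

__all__ = [
    "NeuronClassSpec",
    "NeuronPopulation",
    "default_class_spec",
    "lognormal_shape_params",
    "sample_population",
    "membrane_derivatives",
    "integrate_single_neuron",
    "fi_curve",
    "rheobase_closed_form",
]


def lognormal_shape_params(mean: float, sd: float) -> tuple[float, float]:
    """Convert a lognormal's distribution mean/sd to shape parameters (mu, sigma).

    sigma^2 = ln(1 + sd^2/mean^2),  mu = ln(mean^2 / sqrt(mean^2 + sd^2)).
    """
    if mean <= 0:
        raise ValueError("lognormal distribution mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return float(mu), float(np.sqrt(sigma2))


@dataclass
class NeuronClassSpec:
    """Parameter set for one neuron class.

    ``homogeneous`` maps parameter name -> scalar; ``heterogeneous`` maps
    parameter name -> (family, mean, sd) with family in {normal, lognormal}.
    """

    label: str
    homogeneous: dict = field(default_factory=dict)
    heterogeneous: dict = field(default_factory=dict)
    a: float = 0.0       # nS, sub-threshold adaptation coupling
    b: float = 0.0       # pA, spike-triggered adaptation increment
    tau_w: float = P.TAU_W_DEFAULT  # ms

    def __post_init__(self):
        if self.label not in P.CLASS_LABELS:
            raise ValueError(f"unknown neuron class label {self.label!r}")
        hom = self.homogeneous
        if hom:
            if not hom["V_reset"] < hom["V_thresh"]:
                raise ValueError("V_reset must lie below V_thresh")
            for name in ("g_leak", "C_m"):
                if hom[name] <= 0:
                    raise ValueError(f"{name} must be strictly positive")
            if hom["t_ref"] < 0:
                raise ValueError("t_ref must be nonnegative")
        for name, (family, mean, sd) in self.heterogeneous.items():
            if family not in ("normal", "lognormal"):
                raise ValueError(f"unknown distribution family {family!r}")
            if sd < 0:
                raise ValueError(f"negative sd for {name}")


def default_class_spec(label: str, tau_w: float = P.TAU_W_DEFAULT) -> NeuronClassSpec:
    """Reference spec for class ``label`` (E, I1 or I2)."""
    if label not in P.CLASS_LABELS:
        raise ValueError(f"unknown neuron class label {label!r}")
    a, b = P.ADAPTATION[label]
    return NeuronClassSpec(
        label=label,
        homogeneous=dict(P.NEURON_HOMOGENEOUS[label]),
        heterogeneous=dict(P.NEURON_HETEROGENEOUS[label]),
        a=a, b=b, tau_w=tau_w,
    )


@dataclass
class NeuronPopulation:
    """Realized per-neuron physiological parameters for one class."""

    label: str
    n: int
    E_leak: np.ndarray
    V_thresh: np.ndarray
    V_reset: np.ndarray
    g_leak: np.ndarray
    C_m: np.ndarray
    t_ref: np.ndarray
    a: float
    b: float
    tau_w: float
    seed: int | None = None

    def __post_init__(self):
        for arr in (self.E_leak, self.V_thresh, self.V_reset,
                    self.g_leak, self.C_m, self.t_ref):
            if len(arr) != self.n:
                raise ValueError("population arrays must have length n")
        if self.n:
            if not np.all(self.V_reset < self.V_thresh):
                raise ValueError("V_reset must lie below V_thresh for every neuron")
            if not (np.all(self.g_leak > 0) and np.all(self.C_m > 0)):
                raise ValueError("conductances and capacitances must be positive")
            if not np.all(self.t_ref >= 0):
                raise ValueError("t_ref must be nonnegative")

    @property
    def tau_m(self) -> np.ndarray:
        """Membrane time constant C_m / g_leak (ms)."""
        return self.C_m / self.g_leak


def _draw(family: str, mean: float, sd: float, n: int, rng: np.random.Generator):
    if family == "normal":
        return rng.normal(mean, sd, size=n)
    mu, sigma = lognormal_shape_params(mean, sd)
    return rng.lognormal(mu, sigma, size=n)


def sample_population(spec: NeuronClassSpec, n: int, heterogeneous: bool,
                      seed=None, g_leak_mode: str = "direct") -> NeuronPopulation:
    """Realize ``n`` neurons of one class.

    Homogeneous mode copies the scalar parameter set into every neuron.
    Heterogeneous mode draws the dynamical parameters (E_leak, V_thresh,
    V_reset, g_leak, C_m, t_ref) independently per neuron from the stated
    distributions; tau_m and R_m are then implied quantities.  With
    ``g_leak_mode='from_tau_m'`` the tau_m distribution is sampled instead
    and g_leak derived as C_m / tau_m (this widens g_leak well beyond its
    stated distribution, so the direct reading is the default).  Draws
    violating V_reset < V_thresh or positivity are rejected and resampled.
    """
    if n < 0:
        raise ValueError("population size must be nonnegative")
    if g_leak_mode not in ("direct", "from_tau_m"):
        raise ValueError("g_leak_mode must be 'direct' or 'from_tau_m'")
    rng = np.random.default_rng(seed)

    if not heterogeneous:
        hom = spec.homogeneous
        cols = {k: np.full(n, hom[k]) for k in
                ("E_leak", "V_thresh", "V_reset", "g_leak", "C_m", "t_ref")}
    else:
        het = spec.heterogeneous
        g_name = "g_leak" if g_leak_mode == "direct" else "tau_m"
        names = ("E_leak", "V_thresh", "V_reset", "C_m", g_name, "t_ref")
        cols = {k: np.empty(n) for k in names}
        todo = np.arange(n)
        for _ in range(1000):
            m = len(todo)
            if m == 0:
                break
            draw = {k: _draw(*het[k], m, rng) for k in names}
            ok = (
                (draw["V_reset"] < draw["V_thresh"])
                & (draw["C_m"] > 0)
                & (draw[g_name] > 0)
                & (draw["t_ref"] >= 0)
            )
            for k in names:
                cols[k][todo[ok]] = draw[k][ok]
            todo = todo[~ok]
        else:
            raise RuntimeError("rejection sampling failed to converge")
        if g_leak_mode == "from_tau_m":
            cols["g_leak"] = cols["C_m"] / cols.pop("tau_m")

    return NeuronPopulation(
        label=spec.label, n=n, a=spec.a, b=spec.b, tau_w=spec.tau_w,
        seed=seed if isinstance(seed, int) else None, **cols,
    )


def membrane_derivatives(V, I_adapt, pop, I_syn_total=0.0, I_inj=0.0,
                         index=None):
    """Time derivatives (dV/dt, dI_adapt/dt) of the sub-threshold dynamics.

    ``pop`` may be a NeuronPopulation (optionally indexed by ``index``) or any
    object exposing scalar/array attributes E_leak, g_leak, C_m, a, tau_w.
    ``I_syn_total`` follows the sign convention of the membrane equation
    (positive = hyperpolarizing).
    """
    if index is not None:
        E_leak, g_leak, C_m = (pop.E_leak[index], pop.g_leak[index], pop.C_m[index])
    else:
        E_leak, g_leak, C_m = pop.E_leak, pop.g_leak, pop.C_m
    dV = (-g_leak * (V - E_leak) - I_adapt - I_syn_total + I_inj) / C_m
    dI = (-I_adapt + pop.a * (V - E_leak)) / pop.tau_w
    return dV, dI


@dataclass
class _ScalarParams:
    E_leak: float
    V_thresh: float
    V_reset: float
    g_leak: float
    C_m: float
    t_ref: float
    a: float
    b: float
    tau_w: float


def scalar_params(label: str, tau_w: float = P.TAU_W_DEFAULT) -> _ScalarParams:
    """Homogeneous parameters of one class as a flat record."""
    hom = P.NEURON_HOMOGENEOUS[label]
    a, b = P.ADAPTATION[label]
    return _ScalarParams(
        E_leak=hom["E_leak"], V_thresh=hom["V_thresh"], V_reset=hom["V_reset"],
        g_leak=hom["g_leak"], C_m=hom["C_m"], t_ref=hom["t_ref"],
        a=a, b=b, tau_w=tau_w,
    )


def rheobase_closed_form(p) -> float:
    """Minimal constant current (pA) driving sustained firing.

    At the sub-threshold fixed point I_adapt = a (V - E_leak), so the
    steady-state voltage under constant injection I is
    V_inf = E_leak + I / (g_leak + a); firing requires V_inf >= V_thresh.
    """
    return (p.g_leak + p.a) * (p.V_thresh - p.E_leak)


def integrate_single_neuron(p, I_inj, duration, dt=0.1, V0=None, w0=0.0,
                            record=True):
    """Fixed-step RK4 integration of one adaptive-LIF neuron.

    ``I_inj`` is a scalar or an array of per-step injected currents (pA).
    Returns (t, V, I_adapt, spike_times).  The reset rule clamps V at
    V_reset for t in (t_f, t_f + t_ref].
    """
    n_steps = int(round(duration / dt))
    I = np.broadcast_to(np.asarray(I_inj, dtype=float), (n_steps,)) \
        if np.ndim(I_inj) == 0 else np.asarray(I_inj, dtype=float)
    if len(I) < n_steps:
        raise ValueError("injected-current array shorter than duration")
    V = p.E_leak if V0 is None else float(V0)
    w = float(w0)
    ref_steps = int(np.ceil(p.t_ref / dt - 1e-12))
    refr_until = -1
    spikes = []
    V_rec = np.empty(n_steps + 1) if record else None
    w_rec = np.empty(n_steps + 1) if record else None
    if record:
        V_rec[0], w_rec[0] = V, w

    gL, EL, Cm, a, tw = p.g_leak, p.E_leak, p.C_m, p.a, p.tau_w
    for t in range(n_steps):
        Ii = I[t]
        if t >= refr_until:
            def f(V_, w_):
                return ((-gL * (V_ - EL) - w_ + Ii) / Cm,
                        (-w_ + a * (V_ - EL)) / tw)
            k1 = f(V, w)
            k2 = f(V + 0.5 * dt * k1[0], w + 0.5 * dt * k1[1])
            k3 = f(V + 0.5 * dt * k2[0], w + 0.5 * dt * k2[1])
            k4 = f(V + dt * k3[0], w + dt * k3[1])
            V += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            w += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            if V >= p.V_thresh:
                spikes.append((t + 1) * dt)
                V = p.V_reset
                w += p.b
                refr_until = t + 1 + ref_steps
        else:
            # refractory: V clamped, adaptation keeps integrating
            V = p.V_reset
            dw = (-w + a * (V - EL)) / tw
            w += dt * dw
        if record:
            V_rec[t + 1], w_rec[t + 1] = V, w

    t_axis = np.arange(n_steps + 1) * dt
    return (t_axis, V_rec, w_rec, np.asarray(spikes)) if record else \
        (t_axis, None, None, np.asarray(spikes))


def fi_curve(p, I_grid, duration=1000.0, dt=0.1):
    """Rate-vs-current curve of a single neuron under 1-s current steps.

    Returns a dict with the rheobase (first grid current eliciting >= 1
    spike; ``inf`` if the grid never fires), the rate just above rheobase
    (``nu_min``), the rate at the maximum grid current (``nu_max``), the
    least-squares slope of the supra-threshold segment (spikes/s per pA) and
    the full rate array.
    """
    if duration < 1000.0:
        raise ValueError("duration must be at least 1000 ms")
    I_grid = np.sort(np.asarray(I_grid, dtype=float))
    rates = np.empty(len(I_grid))
    for i, I in enumerate(I_grid):
        *_, spikes = integrate_single_neuron(p, I, duration, dt, record=False)
        rates[i] = len(spikes) / (duration / 1000.0)
    active = np.flatnonzero(rates > 0)
    if len(active) == 0:
        return dict(I_rh=np.inf, nu_min=0.0, nu_max=0.0, slope=0.0,
                    I_grid=I_grid, rates=rates)
    i0 = active[0]
    if len(active) > 1:
        slope = float(np.polyfit(I_grid[active], rates[active], 1)[0])
    else:
        slope = 0.0
    return dict(I_rh=float(I_grid[i0]), nu_min=float(rates[i0]),
                nu_max=float(rates[-1]), slope=slope,
                I_grid=I_grid, rates=rates)
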