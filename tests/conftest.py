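import numpy as np
import pytest

from microhet.engine import (Microcircuit, StimulusProgram,
                             build_microcircuit, simulate)
from microhet.neurons import sample_population, default_class_spec
from microhet.connectivity import ConnectionBlock


def make_ou_trace(tau_ms, duration_ms, dt_ms, seed=0, sigma=1.0):
    """Exact-discretization Ornstein-Uhlenbeck trace with correlation time
    tau_ms (stationary autocorrelation exp(-lag/tau))."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / dt_ms))
    rho = np.exp(-dt_ms / tau_ms)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    noise = rng.normal(0.0, sigma * np.sqrt(1 - rho**2), size=n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + noise[i]
    return x


def poisson_trains(rate_hz, duration_ms, n_neurons, seed=0):
    """Independent homogeneous Poisson spike trains (times in ms)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_neurons):
        n = rng.poisson(rate_hz * duration_ms / 1000.0)
        out.append(np.sort(rng.uniform(0.0, duration_ms, size=n)))
    return out


def two_neuron_circuit(weight=1.0, delay=1.0, pre_label="E", post_label="E"):
    """Minimal circuit: one connection pre -> post, nothing else.

    The presynaptic neuron is neuron 0 of its class; the postsynaptic neuron
    is the last neuron of its class, so within-class blocks are legal.
    """
    pops = {lab: sample_population(default_class_spec(lab),
                                   2 if lab in (pre_label, post_label) else 1,
                                   heterogeneous=False, seed=0)
            for lab in ("E", "I1", "I2")}
    pre_i = 0
    post_i = pops[post_label].n - 1
    blocks = {
        (pre_label, post_label): ConnectionBlock(
            pre=pre_label, post=post_label,
            n_pre=pops[pre_label].n, n_post=pops[post_label].n,
            pre_idx=np.array([pre_i]), post_idx=np.array([post_i]),
            weights=np.array([float(weight)]),
            delays=np.array([float(delay)]),
        )
    }
    circ = Microcircuit(N=sum(p.n for p in pops.values()), condition="Hom",
                        neuronal=False, synaptic=False, structural=False,
                        populations=pops, blocks=blocks, seed=0)
    post_global = circ.offsets[post_label] + post_i
    pre_global = circ.offsets[pre_label] + pre_i
    return circ, pre_global, post_global


@pytest.fixture(scope="session")
def fixture_circuit():
    """Reduced-scale homogeneous circuit shared across tests."""
    return build_microcircuit(250, "Hom", seed=7)


@pytest.fixture(scope="session")
def fixture_quiet_run(fixture_circuit):
    """2-s quiet-state run of the reduced circuit."""
    return simulate(fixture_circuit, StimulusProgram(nu_in=10.0),
                    duration=2000.0, seed=11, record_currents="E")
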