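"""Reference parameter tables for the layer 2/3 microcircuit model.

Three neuron classes are distinguished: excitatory pyramidal cells (``E``),
fast-spiking interneurons (``I1``) and non-fast-spiking interneurons (``I2``).
Each class carries a homogeneous (scalar) parameter set and, for the
heterogeneous condition, a per-parameter distribution descriptor.  Lognormal
descriptors are stated as the *distribution* mean and standard deviation, not
the underlying shape parameters.

Synapses are conductance based.  Excitatory synapses activate the AMPA and
NMDA receptors of the postsynaptic class, inhibitory synapses the GABA_A and
GABA_B receptors.  The nine connection types (all ordered class pairs) each
have a connection density, weight and delay statistics, and structural-bias
parameters (degree skewness ``k_in``/``k_out`` and weight-correlation
strengths ``c_in``/``c_out``).
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# population composition
# ---------------------------------------------------------------------------

CLASS_LABELS = ("E", "I1", "I2")

#: fraction of the total circuit size N per class: 80% excitatory; the
#: inhibitory 20% splits 35%/65% into fast-spiking / non-fast-spiking cells.
POPULATION_FRACTIONS = {"E": 0.8, "I1": 0.35 * 0.2, "I2": 0.65 * 0.2}

#: background input: each neuron receives, on average, input through K_in
#: synapses, each firing at nu_in spikes/s.
K_IN = 1000

#: extracellular magnesium concentration (mM) entering the NMDA voltage gate.
MG_CONC = 1.0

#: adaptation-current time constant (ms).  Not constrained by the data the
#: model was built from; 144 ms is a conventional value for this model family
#: and the fast-spiking class (a = b = 0) is unaffected by it.
TAU_W_DEFAULT = 144.0

#: default fraction of the E population receiving the injected current signal.
INPUT_TARGET_FRACTION = 0.25

# ---------------------------------------------------------------------------
# single-neuron parameters
# ---------------------------------------------------------------------------

#: homogeneous (scalar) parameter set per class.  Units: mV, nS, pF, ms.
NEURON_HOMOGENEOUS = {
    "E": {
        "E_leak": -76.43, "V_thresh": -44.45, "V_reset": -54.18,
        "g_leak": 4.64, "C_m": 116.52, "t_ref": 2.05,
        "tau_m": 25.11, "R_m": 215.54,
    },
    "I1": {
        "E_leak": -64.33, "V_thresh": -38.97, "V_reset": -57.47,
        "g_leak": 9.75, "C_m": 104.52, "t_ref": 0.52,
        "tau_m": 10.72, "R_m": 102.53,
    },
    "I2": {
        "E_leak": -61.0, "V_thresh": -34.44, "V_reset": -47.11,
        "g_leak": 4.61, "C_m": 102.87, "t_ref": 1.34,
        "tau_m": 22.33, "R_m": 217.10,
    },
}

#: heterogeneous distribution descriptors: (family, mean, sd) with family in
#: {"normal", "lognormal"}; lognormal entries give distribution mean/sd.
NEURON_HETEROGENEOUS = {
    "E": {
        "E_leak": ("normal", -73.0, 4.0),
        "V_thresh": ("normal", -42.0, 4.0),
        "V_reset": ("normal", -52.0, 5.0),
        "g_leak": ("normal", 4.73, 0.38),
        "C_m": ("normal", 114.0, 8.7),
        "t_ref": ("lognormal", 1.8, 0.25),
        "tau_m": ("lognormal", 22.0, 2.0),
        "R_m": ("lognormal", 160.0, 50.0),
    },
    "I1": {
        "E_leak": ("normal", -67.5, 2.0),
        "V_thresh": ("normal", -40.0, 4.0),
        "V_reset": ("normal", -58.0, 6.4),
        "g_leak": ("normal", 9.09, 0.75),
        "C_m": ("lognormal", 68.9, 35.6),
        "t_ref": ("lognormal", 0.5, 0.01),
        "tau_m": ("lognormal", 9.5, 2.0),
        "R_m": ("lognormal", 100.0, 10.0),
    },
    "I2": {
        "E_leak": ("normal", -62.6, 2.0),
        "V_thresh": ("normal", -36.0, 2.0),
        "V_reset": ("normal", -54.0, 5.4),
        "g_leak": ("normal", 4.5, 0.2),
        "C_m": ("lognormal", 82.24, 17.7),
        "t_ref": ("lognormal", 1.3, 0.05),
        "tau_m": ("lognormal", 20.0, 2.0),
        "R_m": ("lognormal", 210.0, 10.0),
    },
}

#: adaptation couplings per class: a (nS, sub-threshold), b (pA,
#: spike-triggered).  Fast-spiking cells carry no intrinsic adaptation.
ADAPTATION = {"E": (4.0, 30.0), "I1": (0.0, 0.0), "I2": (2.0, 10.0)}

# ---------------------------------------------------------------------------
# receptor kinetics (per postsynaptic class)
# ---------------------------------------------------------------------------

#: per receptor: peak conductance g_bar (nS), reversal potential E_rev (mV),
#: tau_rise (ms), fast/slow balance r, tau_decay_fast (ms), tau_decay_slow
#: (ms; None where r = 1 makes the slow branch absent, and tau_decay_fast is
#: None where r = 0 makes the fast branch absent).
RECEPTORS = {
    "E": {
        "AMPA":   dict(g_bar=0.9,   E_rev=0.0,   tau_rise=0.3,  r=1.0, tau_decay_fast=2.0,   tau_decay_slow=None),
        "NMDA":   dict(g_bar=0.14,  E_rev=0.0,   tau_rise=1.0,  r=0.0, tau_decay_fast=None,  tau_decay_slow=100.0),
        "GABA_A": dict(g_bar=0.15,  E_rev=-75.0, tau_rise=0.25, r=1.0, tau_decay_fast=6.0,   tau_decay_slow=None),
        "GABA_B": dict(g_bar=0.009, E_rev=-90.0, tau_rise=30.0, r=0.8, tau_decay_fast=200.0, tau_decay_slow=600.0),
    },
    "I1": {
        "AMPA":   dict(g_bar=1.6,   E_rev=0.0,   tau_rise=0.1,  r=1.0, tau_decay_fast=0.7,   tau_decay_slow=None),
        "NMDA":   dict(g_bar=0.003, E_rev=0.0,   tau_rise=1.0,  r=0.0, tau_decay_fast=None,  tau_decay_slow=100.0),
        "GABA_A": dict(g_bar=1.0,   E_rev=-75.0, tau_rise=0.1,  r=1.0, tau_decay_fast=2.5,   tau_decay_slow=None),
        "GABA_B": dict(g_bar=0.022, E_rev=-90.0, tau_rise=25.0, r=0.8, tau_decay_fast=50.0,  tau_decay_slow=400.0),
    },
    "I2": {
        "AMPA":   dict(g_bar=0.8,   E_rev=0.0,   tau_rise=0.2,  r=1.0, tau_decay_fast=1.8,   tau_decay_slow=None),
        "NMDA":   dict(g_bar=0.012, E_rev=0.0,   tau_rise=1.0,  r=0.0, tau_decay_fast=None,  tau_decay_slow=100.0),
        "GABA_A": dict(g_bar=0.7,   E_rev=-75.0, tau_rise=0.2,  r=1.0, tau_decay_fast=5.0,   tau_decay_slow=None),
        "GABA_B": dict(g_bar=0.025, E_rev=-90.0, tau_rise=25.0, r=0.8, tau_decay_fast=150.0, tau_decay_slow=500.0),
    },
}

#: reference single-spike PSPs per (post class, polarity): amplitude (mV) and
#: double-exponential fit time constants (ms), measured at rest for E cells
#: and at a -55 mV holding potential for interneurons.
REFERENCE_PSPS = {
    ("E", "exc"):  dict(J_syn=0.82,  tau_rise=3.16, tau_decay=17.8),
    ("E", "inh"):  dict(J_syn=-0.1,  tau_rise=3.2,  tau_decay=64.3),
    ("I1", "exc"): dict(J_syn=0.5,   tau_rise=0.8,  tau_decay=10.7),
    ("I1", "inh"): dict(J_syn=-0.25, tau_rise=1.65, tau_decay=17.5),
    ("I2", "exc"): dict(J_syn=0.6,   tau_rise=2.4,  tau_decay=17.3),
    ("I2", "inh"): dict(J_syn=-0.6,  tau_rise=3.2,  tau_decay=42.0),
}

# ---------------------------------------------------------------------------
# connection (synapse type) parameters
# ---------------------------------------------------------------------------

#: per ordered (pre, post) pair: connection density p, weight distribution
#: mean/sd (dimensionless multipliers on the receptor conductances), delay
#: distribution mean/sd (ms), degree-skewness parameters and
#: weight-correlation strengths.  Entries the data could not constrain are 0.
CONNECTIONS = {
    ("E", "E"):   dict(p=0.168, mu_w=0.45,  sigma_w=0.10, mu_d=1.8, sigma_d=0.25, k_in=5.0, k_out=5.0, c_in=1.0, c_out=0.0),
    ("E", "I1"):  dict(p=0.575, mu_w=1.65,  sigma_w=0.10, mu_d=1.2, sigma_d=0.2,  k_in=5.0, k_out=0.0, c_in=1.0, c_out=1.0),
    ("E", "I2"):  dict(p=0.244, mu_w=0.638, sigma_w=0.11, mu_d=1.5, sigma_d=0.2,  k_in=0.0, k_out=0.0, c_in=1.0, c_out=0.0),
    ("I1", "E"):  dict(p=0.60,  mu_w=5.148, sigma_w=0.11, mu_d=0.8, sigma_d=0.1,  k_in=0.0, k_out=0.0, c_in=0.0, c_out=0.0),
    ("I2", "E"):  dict(p=0.465, mu_w=4.85,  sigma_w=0.11, mu_d=1.5, sigma_d=0.2,  k_in=0.0, k_out=0.0, c_in=0.0, c_out=0.0),
    ("I1", "I1"): dict(p=0.55,  mu_w=2.22,  sigma_w=0.14, mu_d=1.0, sigma_d=0.1,  k_in=0.0, k_out=0.0, c_in=0.0, c_out=0.0),
    ("I1", "I2"): dict(p=0.241, mu_w=1.4,   sigma_w=0.25, mu_d=1.2, sigma_d=0.3,  k_in=0.0, k_out=0.0, c_in=0.0, c_out=0.0),
    ("I2", "I1"): dict(p=0.379, mu_w=1.47,  sigma_w=0.10, mu_d=1.5, sigma_d=0.5,  k_in=0.0, k_out=0.0, c_in=0.0, c_out=0.0),
    ("I2", "I2"): dict(p=0.381, mu_w=0.83,  sigma_w=0.2,  mu_d=1.5, sigma_d=0.3,  k_in=0.0, k_out=0.0, c_in=0.0, c_out=0.0),
}

#: realistic population mean-rate bounds (spikes/s) used when tuning the
#: active-state input parameters.
ACTIVE_RATE_BOUNDS = {"E": (0.5, 5.0), "I1": (10.0, 25.0), "I2": (3.0, 15.0)}

#: heterogeneity-condition flags: (neuronal, synaptic, structural).
CONDITIONS = {
    "Hom": (False, False, False),
    "Neu": (True, False, False),
    "Syn": (False, True, False),
    "Str": (False, False, True),
    "Het": (True, True, True),
}
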