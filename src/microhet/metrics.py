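"""Population-activity statistics.

Spiking statistics: mean rate, pairwise spike-count correlation (CC) over
randomly sampled disjoint neuron pairs, coefficient of variation of
inter-spike intervals (CV_ISI), burstiness as the 5th percentile of the ISI
distribution (ISI_5%), and the entropy of the log-ISI density (H_ISI,
bits).

Sub-threshold statistics: mean and variance of the membrane potential,
distance to threshold, mean excitatory/inhibitory synaptic currents and
their zero-lag correlation (E/I balance), the effective membrane time
constant tau_eff = C_m / <G_total>, and the intrinsic timescale tau_int
obtained by fitting a * [exp(-lag/tau_int) + b] to the membrane-potential
autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SpikingProfile",
    "spike_statistics",
    "ei_balance",
    "autocorrelation",
    "intrinsic_timescale",
    "intrinsic_timescale_population",
    "effective_time_constant",
    "subthreshold_profile",
    "rate_transfer",
]

MIN_ISI_COUNT = 10  # neurons with fewer ISIs are excluded from CV/H/ISI_5%


@dataclass
class SpikingProfile:
    """Population summary of spiking statistics over one window."""

    n_neurons: int
    window: tuple
    rate_mean: float
    rates: np.ndarray
    cc_mean: float
    cc_pairs: np.ndarray
    cc_binsize: float
    cv_isi_mean: float
    cv_isi: np.ndarray
    isi5_mean: float        # seconds
    isi5: np.ndarray
    h_isi_mean: float       # bits
    h_isi: np.ndarray
    n_excluded: int         # neurons below the ISI-count threshold
    meta: dict = field(default_factory=dict)


def _binned_counts(trains, t_start, t_stop, binsize):
    edges = np.arange(t_start, t_stop + binsize, binsize)
    return np.stack([np.histogram(tr, bins=edges)[0] for tr in trains])


def _entropy_log_isi(isis):
    """Entropy (bits) of the binned natural-log-ISI density.

    Bin width follows the Freedman-Diaconis rule on ln(ISI); a single-valued
    ISI distribution has zero entropy by convention.
    """
    x = np.log(isis)
    n = len(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        return 0.0
    width = 2.0 * iqr / n ** (1.0 / 3.0)
    n_bins = max(int(np.ceil((x.max() - x.min()) / width)), 1)
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def spike_statistics(trains, window, n_pairs: int = 500,
                     cc_binsize: float = 2.0, seed=None) -> SpikingProfile:
    """Spiking-statistics profile of one population.

    ``trains`` is a list of per-neuron spike-time arrays (ms); ``window`` a
    (t_start, t_stop) pair in ms.  CC is the mean Pearson correlation of
    spike counts in ``cc_binsize`` ms bins over ``n_pairs`` random disjoint
    pairs of neurons that spiked at least twice.  Per-neuron statistics
    needing ISIs use only neurons with at least MIN_ISI_COUNT intervals; the
    number excluded is reported.
    """
    t_start, t_stop = window
    rng = np.random.default_rng(seed)
    trains = [np.asarray(tr)[(np.asarray(tr) >= t_start)
                             & (np.asarray(tr) <= t_stop)] for tr in trains]
    n = len(trains)
    span_s = (t_stop - t_start) / 1000.0
    rates = np.array([len(tr) / span_s for tr in trains])

    # pairwise correlations over disjoint random pairs
    active = [i for i, tr in enumerate(trains) if len(tr) >= 2]
    cc_pairs = np.array([])
    if len(active) >= 2:
        k = min(n_pairs, len(active) // 2)
        chosen = rng.permutation(active)[: 2 * k].reshape(k, 2)
        counts = _binned_counts([trains[i] for i in chosen.ravel()],
                                t_start, t_stop, cc_binsize)
        counts = counts - counts.mean(axis=1, keepdims=True)
        sd = counts.std(axis=1)
        ccs = []
        for p in range(k):
            c1, c2 = counts[2 * p], counts[2 * p + 1]
            s1, s2 = sd[2 * p], sd[2 * p + 1]
            if s1 > 0 and s2 > 0:
                ccs.append((c1 * c2).mean() / (s1 * s2))
        cc_pairs = np.asarray(ccs)

    cv, isi5, h = [], [], []
    excluded = 0
    for tr in trains:
        isis = np.diff(tr)
        if len(isis) < MIN_ISI_COUNT:
            excluded += 1
            continue
        cv.append(isis.std() / isis.mean())
        isi5.append(np.percentile(isis, 5) / 1000.0)
        h.append(_entropy_log_isi(isis))
    cv, isi5, h = map(np.asarray, (cv, isi5, h))

    def _mean(x):
        return float(np.mean(x)) if len(x) else float("nan")

    return SpikingProfile(
        n_neurons=n, window=(t_start, t_stop),
        rate_mean=float(rates.mean()) if n else float("nan"), rates=rates,
        cc_mean=_mean(cc_pairs), cc_pairs=cc_pairs, cc_binsize=cc_binsize,
        cv_isi_mean=_mean(cv), cv_isi=cv,
        isi5_mean=_mean(isi5), isi5=isi5,
        h_isi_mean=_mean(h), h_isi=h,
        n_excluded=excluded,
    )


def ei_balance(I_exc, I_inh):
    """Excitation/inhibition balance summary from current traces.

    ``I_exc``/``I_inh`` have shape (n_samples, n_neurons), signed following
    the membrane equation (excitatory currents negative below 0 mV).
    Returns per-neuron means, the absolute mean difference, the zero-lag
    Pearson correlation per neuron, and population mean/sd of each.
    """
    I_exc = np.atleast_2d(np.asarray(I_exc, dtype=float))
    I_inh = np.atleast_2d(np.asarray(I_inh, dtype=float))
    if I_exc.shape != I_inh.shape:
        raise ValueError("current traces must have matching shapes")
    if I_exc.size == 0:
        raise ValueError("current traces are empty")
    mean_exc = I_exc.mean(axis=0)
    mean_inh = I_inh.mean(axis=0)
    abs_diff = np.abs(mean_inh + mean_exc)  # signed currents cancel when balanced
    e = I_exc - mean_exc
    i = I_inh - mean_inh
    sd_e = e.std(axis=0)
    sd_i = i.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = (e * i).mean(axis=0) / (sd_e * sd_i)
    return dict(
        mean_exc=mean_exc, mean_inh=mean_inh, abs_diff=abs_diff, cc=cc,
        mean_exc_pop=(float(mean_exc.mean()), float(mean_exc.std())),
        mean_inh_pop=(float(mean_inh.mean()), float(mean_inh.std())),
        abs_diff_pop=(float(abs_diff.mean()), float(abs_diff.std())),
        cc_pop=(float(np.nanmean(cc)), float(np.nanstd(cc))),
    )


def autocorrelation(v, max_lag_samples: int) -> np.ndarray:
    """Empirical autocorrelation R(lag) of a trace, lags 0..max_lag (FFT)."""
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    n = len(v)
    f = np.fft.rfft(v, 2 * n)
    ac = np.fft.irfft(f * np.conj(f))[: max_lag_samples + 1]
    if ac[0] <= 0:
        return np.full(max_lag_samples + 1, np.nan)
    return ac / ac[0]


def intrinsic_timescale(v, dt: float, max_lag: float | None = None):
    """Decay constant of the membrane-potential autocorrelation.

    Fits a * [exp(-lag/tau_int) + b] over lags (0, max_lag] by nonlinear
    least squares.  ``max_lag`` (ms) defaults to one tenth of the trace
    duration, the largest window for which the trace is long enough (the
    estimate requires trace length >= 10 * max_lag).  Returns (tau_int,
    info); a non-decaying autocorrelation is flagged and tau_int reported as
    the window length (an upper bound).
    """
    v = np.asarray(v, dtype=float)
    span = len(v) * dt
    if max_lag is None:
        max_lag = span / 10.0
    if span < 10.0 * max_lag:
        raise ValueError("trace must be at least 10x the lag window")
    L = int(round(max_lag / dt))
    ac = autocorrelation(v, L)
    if np.any(~np.isfinite(ac)):
        return float("nan"), dict(ok=False, reason="degenerate trace")
    lags = np.arange(1, L + 1) * dt
    # initialize the decay constant from the first 1/e crossing: this keeps
    # the fit identifiable both for slow traces and for white noise, whose
    # autocorrelation collapses within one sampling interval
    below = np.flatnonzero(ac < np.exp(-1.0))
    tau0 = (below[0] if len(below) else L) * dt
    tau0 = max(tau0 * 0.8, 0.25 * dt)
    try:
        popt, _ = curve_fit(
            lambda t, a, tau, b: a * (np.exp(-t / tau) + b),
            lags, ac[1:], p0=(1.0, tau0, 0.0),
            bounds=([0.0, dt * 1e-3, -1.0], [10.0, 1e6, 1.0]), maxfev=10000)
        a, tau, b = popt
        resid = float(np.sqrt(np.mean(
            (a * (np.exp(-lags / tau) + b) - ac[1:]) ** 2)))
        if tau >= max_lag:
            return float(max_lag), dict(ok=False, reason="non-decaying",
                                        upper_bound=True, a=a, b=b)
        return float(tau), dict(ok=True, a=float(a), b=float(b), resid=resid)
    except RuntimeError:
        return float("nan"), dict(ok=False, reason="fit failure")


def intrinsic_timescale_population(V, dt: float, max_lag: float | None = None):
    """Per-neuron tau_int over trace matrix V (n_samples, n_neurons)."""
    V = np.asarray(V, dtype=float)
    taus = np.empty(V.shape[1])
    ok = np.zeros(V.shape[1], dtype=bool)
    for j in range(V.shape[1]):
        taus[j], info = intrinsic_timescale(V[:, j], dt, max_lag)
        ok[j] = info.get("ok", False)
    return taus, ok


def effective_time_constant(G_mean, C_m):
    """tau_eff = C_m / <G_total> per neuron (ms); G includes the leak."""
    G_mean = np.asarray(G_mean, dtype=float)
    if np.any(G_mean <= 0):
        raise ValueError("mean total conductance must be positive")
    return np.asarray(C_m, dtype=float) / G_mean


def subthreshold_profile(V, V_thresh):
    """Mean/variance of V_m and distance to threshold per neuron."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    mean_v = V.mean(axis=0)
    return dict(mean_v=mean_v, var_v=V.var(axis=0),
                dist_thresh=np.abs(mean_v - np.asarray(V_thresh)))


def rate_transfer(results_by_nu: dict, baseline_by_nu: dict | None = None,
                  rate_threshold: float = 0.01):
    """Population rate transfer function and (gain, offset) summaries.

    ``results_by_nu`` maps input rate nu_in -> {population label -> mean
    output rate}.  The offset is the lowest nu_in with rate above
    ``rate_threshold`` spikes/s; the gain is the least-squares slope over
    the upper half of the active range.  When ``baseline_by_nu`` (the
    homogeneous condition) is given, Delta-gain (percent change) and
    Delta-offset are reported per population.
    """
    nus = np.array(sorted(results_by_nu))
    labels = list(next(iter(results_by_nu.values())))
    out = {}
    for lab in labels:
        rates = np.array([results_by_nu[nu][lab] for nu in nus])
        out[lab] = dict(nu_in=nus, rates=rates,
                        **_gain_offset(nus, rates, rate_threshold))
    if baseline_by_nu is not None:
        base = rate_transfer(baseline_by_nu, None, rate_threshold)
        for lab in labels:
            g0 = base[lab]["gain"]
            out[lab]["delta_offset"] = out[lab]["offset"] - base[lab]["offset"]
            out[lab]["delta_gain_pct"] = (
                100.0 * (out[lab]["gain"] - g0) / g0 if g0 else float("nan"))
    return out


def _gain_offset(nus, rates, thr):
    active = np.flatnonzero(rates > thr)
    if len(active) == 0:
        return dict(offset=float("inf"), gain=0.0)
    offset = float(nus[active[0]])
    upper = active[len(active) // 2:]
    gain = (float(np.polyfit(nus[upper], rates[upper], 1)[0])
            if len(upper) >= 2 else 0.0)
    return dict(offset=offset, gain=gain)
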