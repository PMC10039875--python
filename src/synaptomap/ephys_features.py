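"""Intrinsic electrophysiology from current steps; fluorescence-based spike
validation of stimulated targets.

Passive properties come from the hyperpolarizing sweeps of a square-pulse
protocol (~-200 to +400 pA): input resistance from the peak deflection at
the smallest negative current, the membrane time constant from an
exponential fit a*(1 - exp(-t/tau)) + c over 10-90% of the peak, membrane
capacitance as tau/R, and the sag ratio (V_min - V_ss)/(V_min - V_bl) from
the strongest hyperpolarizing sweep (V_min within the first 30% of the
pulse).  Active properties (gain, maximal rate, bursting and adaptation
indices, spike waveform) come from the suprathreshold sweeps.  Whether a
stimulated target actually spiked is validated from the slope of its raw
calcium-indicator fluorescence across the stimulus train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class Sweep:
    current_pa: float
    voltage_mv: np.ndarray
    rate: float
    pulse_start_s: float
    pulse_dur_s: float

    def pulse_slice(self) -> slice:
        i0 = int(self.pulse_start_s * self.rate)
        return slice(i0, i0 + int(self.pulse_dur_s * self.rate))


@dataclass
class StepProtocol:
    sweeps: list[Sweep]

    def hyperpolarizing(self) -> list[Sweep]:
        return [s for s in self.sweeps if s.current_pa < 0]


@dataclass
class PassiveFeatures:
    r_in_mohm: float = np.nan
    tau_m_ms: float = np.nan
    c_m_pf: float = np.nan
    sag_ratio: float = np.nan
    defined: bool = True


@dataclass
class ActiveFeatures:
    gain_hz_per_pa: float = np.nan
    max_rate_hz: float = np.nan
    bursting_index: float = np.nan
    adaptation_index: float = np.nan
    spike_threshold_mv: float = np.nan
    spike_amplitude_mv: float = np.nan
    spike_halfwidth_ms: float = np.nan
    indices_defined: bool = True


# ---------------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------------

def passive_properties(protocol: StepProtocol,
                       dv_dt_threshold: float = 20.0) -> PassiveFeatures:
    hyp = protocol.hyperpolarizing()
    if not hyp:
        return PassiveFeatures(defined=False)
    smallest = min(hyp, key=lambda s: abs(s.current_pa))
    strongest = min(hyp, key=lambda s: s.current_pa)

    v = smallest.voltage_mv
    sl = smallest.pulse_slice()
    v_bl = float(np.mean(v[max(0, sl.start - int(0.05 * smallest.rate)):
                           sl.start]))
    seg = v[sl]
    peak_idx = int(np.argmin(seg))
    dv_peak = v_bl - float(seg[peak_idx])                   # mV, positive
    r_in = dv_peak / abs(smallest.current_pa) * 1e6 * 1e-3  # mV/pA -> MOhm

    # exponential fit over the 10-90% rise toward the peak deflection
    t = np.arange(len(seg)) / smallest.rate * 1000.0        # ms
    dv = v_bl - seg                                         # positive-going
    i10 = int(np.argmax(dv[: peak_idx + 1] >= 0.1 * dv_peak))
    i90 = int(np.argmax(dv[: peak_idx + 1] >= 0.9 * dv_peak))
    tau_m = np.nan
    if i90 > i10 + 3:
        tt, yy = t[i10:i90 + 1], dv[i10:i90 + 1]
        try:
            popt, _ = optimize.curve_fit(
                lambda x, a, tau, c: a * (1 - np.exp(-x / tau)) + c,
                tt, yy, p0=(dv_peak, max(t[i90] - t[i10], 1.0), 0.0),
                maxfev=10000)
            tau_m = float(abs(popt[1]))
        except RuntimeError:
            pass
    c_m = tau_m / r_in * 1000.0 if np.isfinite(tau_m) and r_in > 0 else np.nan

    sag = _sag_ratio(strongest)
    return PassiveFeatures(r_in_mohm=float(r_in), tau_m_ms=tau_m,
                           c_m_pf=float(c_m), sag_ratio=sag)


def _sag_ratio(sweep: Sweep) -> float:
    v = sweep.voltage_mv
    sl = sweep.pulse_slice()
    seg = v[sl]
    n = len(seg)
    v_bl = float(np.mean(v[max(0, sl.start - int(0.05 * sweep.rate)):
                           sl.start]))
    v_min = float(np.min(seg[: max(1, int(0.3 * n))]))
    v_ss = float(np.mean(seg[int(0.7 * n):]))
    denom = v_min - v_bl
    if denom == 0:
        return 0.0
    return float((v_min - v_ss) / denom)


# ---------------------------------------------------------------------------
# spiking properties
# ---------------------------------------------------------------------------

def _spike_times(sweep: Sweep, dv_dt_threshold: float = 20.0,
                 peak_mv: float = -10.0) -> np.ndarray:
    """Spike times (s) from upward peaks above ``peak_mv``."""
    from scipy.signal import find_peaks

    v = sweep.voltage_mv
    peaks, _ = find_peaks(v, height=peak_mv,
                          distance=max(1, int(0.002 * sweep.rate)))
    return peaks / sweep.rate


def active_properties(protocol: StepProtocol,
                      dv_dt_threshold: float = 20.0,
                      gain_mode: str = "regression") -> ActiveFeatures:
    """Gain, maximal rate, ISI indices and spike-waveform features.

    Gain is the slope of the firing rate vs injected current relation over
    the sweeps spanning the minimal to maximal firing rates (regression by
    default, the two-point slope as an option).  Bursting (ISI2/ISI1) and
    adaptation (ISIlast/ISI2) indices use the sweep closest to 80% of the
    maximal rate (ties toward the lower current); waveform features use the
    first spike of the lowest-rate spiking sweep.
    """
    rates, currents, spikes_per_sweep = [], [], []
    for s in protocol.sweeps:
        st = _spike_times(s, dv_dt_threshold)
        st = st[(st >= s.pulse_start_s)
                & (st < s.pulse_start_s + s.pulse_dur_s)]
        spikes_per_sweep.append(st)
        currents.append(s.current_pa)
        rates.append(len(st) / s.pulse_dur_s)
    rates = np.array(rates)
    currents = np.array(currents)
    spiking = rates > 0
    if spiking.sum() < 2:
        return ActiveFeatures(indices_defined=False)

    max_rate = float(rates.max())
    min_rate = float(rates[spiking].min())
    in_range = spiking & (rates >= min_rate) & (rates <= max_rate)
    if gain_mode == "two_point":
        i_lo = np.nonzero(rates == min_rate)[0][0]
        i_hi = np.nonzero(rates == max_rate)[0][0]
        gain = ((rates[i_hi] - rates[i_lo])
                / (currents[i_hi] - currents[i_lo]))
    else:
        gain = float(np.polyfit(currents[in_range], rates[in_range], 1)[0])

    # index sweep: closest to 80% of max rate, ties toward lower current
    target = 0.8 * max_rate
    order = np.lexsort((currents, np.abs(rates - target)))
    idx80 = next(i for i in order if spiking[i])
    st = spikes_per_sweep[idx80]
    bursting = adaptation = np.nan
    defined = True
    if len(st) >= 3:
        isi = np.diff(st)
        bursting = float(isi[1] / isi[0])
        adaptation = float(isi[-1] / isi[1])
    else:
        defined = False

    lowest = next(i for i in np.argsort(rates) if spiking[i])
    thr, amp, hw = _spike_waveform(protocol.sweeps[lowest],
                                   spikes_per_sweep[lowest][0],
                                   dv_dt_threshold)
    return ActiveFeatures(gain_hz_per_pa=float(gain), max_rate_hz=max_rate,
                          bursting_index=bursting,
                          adaptation_index=adaptation,
                          spike_threshold_mv=thr, spike_amplitude_mv=amp,
                          spike_halfwidth_ms=hw, indices_defined=defined)


def _spike_waveform(sweep: Sweep, spike_t: float, dv_dt_threshold: float):
    """Threshold (first dV/dt crossing before the peak), amplitude
    (peak - threshold) and half-width (at threshold + amplitude/2)."""
    v = sweep.voltage_mv
    rate = sweep.rate
    pk = int(round(spike_t * rate))
    lo = max(0, pk - int(0.005 * rate))
    dvdt = np.gradient(v, 1000.0 / rate)  # mV/ms
    pre = np.nonzero(dvdt[lo:pk] > dv_dt_threshold)[0]
    if len(pre) == 0:
        return np.nan, np.nan, np.nan
    i_thr = lo + pre[0]
    thr = float(v[i_thr])
    peak = float(v[pk])
    amp = peak - thr
    half = thr + amp / 2.0
    above = np.nonzero(v[i_thr: pk + int(0.01 * rate)] >= half)[0]
    if len(above) == 0:
        return thr, amp, np.nan
    hw = (above[-1] - above[0] + 1) * 1000.0 / rate
    return thr, amp, float(hw)


# ---------------------------------------------------------------------------
# fluorescence-based spike validation
# ---------------------------------------------------------------------------

@dataclass
class SpikeValidation:
    validated: bool
    slope: float
    slope_ci: tuple[float, float]
    dff: np.ndarray = field(default_factory=lambda: np.array([]))


def gcamp_spike_validation(fluorescence: np.ndarray,
                           conf: float = 0.95) -> SpikeValidation:
    """Validate spiking from the per-stimulus fluorescence trend.

    The slope of raw fluorescence vs stimulus index is fit by ordinary
    least squares; the target is excluded when the lower 95% confidence
    bound of the slope is negative.  dF/F0 uses the first stimulus as F0
    (indicator onset is slow relative to one stimulus).
    """
    f = np.asarray(fluorescence, float)
    if len(f) < 5:
        raise ValueError("need at least 5 per-stimulus fluorescence values")
    x = np.arange(len(f), dtype=float)
    if np.all(f == f[0]):
        return SpikeValidation(False, 0.0, (0.0, 0.0),
                               dff=np.zeros_like(f))
    res = stats.linregress(x, f)
    dof = len(f) - 2
    tcrit = stats.t.ppf(0.5 + conf / 2, dof)
    lo = res.slope - tcrit * res.stderr
    hi = res.slope + tcrit * res.stderr
    f0 = f[0] if f[0] != 0 else np.nan
    dff = (f - f0) / f0 if np.isfinite(f0) else np.full_like(f, np.nan)
    return SpikeValidation(validated=bool(lo >= 0), slope=float(res.slope),
                           slope_ci=(float(lo), float(hi)), dff=dff)
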