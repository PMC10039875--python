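"""Synthetic recordings, stimulation logs, cell volumes and pair tables.

Every downstream stage of the mapping pipeline is exercised on data from
this module: continuous voltage-clamp traces with spontaneous (Poisson) and
stimulation-locked (gamma-latency) EPSCs, colored drift and optional direct
photocurrents; stimulation schedules; epoch-level event data generated
directly under the connectivity models; homogeneous 3-D cell volumes;
current-step protocols with planted intrinsic properties; and cell-pair
feature tables with a known logistic connectivity model.

Defaults mirror the mapping experiment the package models: 10 pulses per
train at 10 Hz (7.2 ms pulses), up to three protocol repetitions, evoked
latencies with mean 12.96 ms and SD 6.33 ms (the gamma fit k=4.1896,
theta=3.0942 to the population peristimulus time histogram), an assumed
0.5 evoked events per stimulation for connected cells, a 2 Hz spontaneous
EPSC rate, and a ~420 x 420 x 300 um^3 scanned volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd
from scipy import special

from .epsc_detect import SweepTrace, synaptic_kernel

#: gamma fit to the population PSTH of evoked EPSC latencies
PSTH_GAMMA_SHAPE = 4.1896
PSTH_GAMMA_SCALE = 3.0942  # ms
BUMP_MEAN_MS = PSTH_GAMMA_SHAPE * PSTH_GAMMA_SCALE            # 12.96 ms
BUMP_SD_MS = np.sqrt(PSTH_GAMMA_SHAPE) * PSTH_GAMMA_SCALE     # 6.33 ms

SCAN_VOLUME_UM = (420.0, 420.0, 300.0)


# ---------------------------------------------------------------------------
# stimulation schedules
# ---------------------------------------------------------------------------

@dataclass
class TrainSpec:
    """One stimulation train: pulses per train, inter-pulse interval,
    pulse duration and protocol repetitions."""

    n_pulses: int = 10
    ipi_ms: float = 100.0
    pulse_ms: float = 7.2
    repetitions: int = 2
    inter_train_gap_ms: float = 400.0


@dataclass
class StimSchedule:
    """Targets with 3-D positions and the full pulse-time table."""

    target_ids: np.ndarray
    positions_um: np.ndarray          # (n_targets, 3)
    pulses: pd.DataFrame              # target_id, repetition, pulse_index, time_s
    trains: TrainSpec = field(default_factory=TrainSpec)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def duration_s(self) -> float:
        return float(self.pulses.time_s.max()
                     + self.trains.inter_train_gap_ms / 1000.0)

    def stimulations_per_target(self) -> pd.Series:
        return self.pulses.groupby("target_id").size()

    def pulse_times(self, target_id: int) -> pd.DataFrame:
        return self.pulses[self.pulses.target_id == target_id]


def make_stim_schedule(n_targets: int, trains: TrainSpec | None = None,
                       seed: int = 0,
                       box_um: tuple = SCAN_VOLUME_UM) -> StimSchedule:
    """Sequential-stimulation schedule: each protocol repetition sweeps all
    targets once; trains of distinct targets never overlap."""
    trains = trains or TrainSpec()
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if trains.n_pulses < 1 or trains.repetitions < 1:
        raise ValueError("pulse and repetition counts must be positive")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, np.asarray(box_um, float), size=(n_targets, 3))

    span_s = (trains.n_pulses * trains.ipi_ms + trains.inter_train_gap_ms) / 1000.0
    rows = []
    cursor = trains.inter_train_gap_ms / 1000.0
    for rep in range(trains.repetitions):
        for tid in range(n_targets):
            for p in range(trains.n_pulses):
                rows.append((tid, rep, p, cursor + p * trains.ipi_ms / 1000.0))
            cursor += span_s
    pulses = pd.DataFrame(rows, columns=["target_id", "repetition",
                                         "pulse_index", "time_s"])
    return StimSchedule(target_ids=np.arange(n_targets),
                        positions_um=positions, pulses=pulses, trains=trains)


# ---------------------------------------------------------------------------
# ground truth for trace simulation
# ---------------------------------------------------------------------------

@dataclass
class AmplitudeSpec:
    """Lognormal EPSC amplitude distribution, parameterized by its mean (pA).

    The spontaneous amplitude distribution is not constrained by the mapping
    experiment itself; lognormal is the conventional choice for synaptic
    amplitudes and is exposed here as configuration.
    """

    mean_pa: float = 15.0
    sigma_log: float = 0.4

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mu = np.log(self.mean_pa) - 0.5 * self.sigma_log ** 2
        return rng.lognormal(mu, self.sigma_log, size=n)


@dataclass
class PhotocurrentSpec:
    """Direct-photocurrent contamination for one target: a reproducible
    low-latency waveform added at every stimulation of that target."""

    amplitude_pa: float = 30.0
    latency_ms: float = 0.8
    tau_rise_ms: float = 2.0
    tau_decay_ms: float = 20.0


@dataclass
class GroundTruth:
    """Per-target connectivity truth plus global noise configuration."""

    connected: np.ndarray                       # bool per target
    e_p: np.ndarray                             # evoked events/stimulus
    bump_center_ms: np.ndarray                  # latency-distribution mean
    bump_sd_ms: np.ndarray                      # latency-distribution sd
    spont_rate_hz: float = 2.0
    amplitudes: AmplitudeSpec = field(default_factory=AmplitudeSpec)
    noise_sd_pa: float = 2.0
    drift_sd_pa: float = 4.0
    latency_family: str = "gamma"               # "gamma" or "normal"
    photocurrents: dict[int, PhotocurrentSpec] = field(default_factory=dict)

    def __post_init__(self):
        self.connected = np.asarray(self.connected, bool)
        self.e_p = np.asarray(self.e_p, float)
        self.bump_center_ms = np.asarray(self.bump_center_ms, float)
        self.bump_sd_ms = np.asarray(self.bump_sd_ms, float)
        if np.any(self.e_p < 0) or self.spont_rate_hz < 0:
            raise ValueError("rates must be nonnegative")
        if np.any((self.bump_center_ms <= 0) | (self.bump_center_ms >= 90)):
            raise ValueError("bump center must lie in (0, 90) ms")


def make_ground_truth(n_targets: int, connected_fraction: float = 0.5,
                      e_p: float = 0.5, bump_center_ms: float = BUMP_MEAN_MS,
                      bump_sd_ms: float = BUMP_SD_MS, seed: int = 0,
                      **kwargs) -> GroundTruth:
    rng = np.random.default_rng(seed)
    n_conn = int(round(connected_fraction * n_targets))
    connected = np.zeros(n_targets, bool)
    connected[rng.choice(n_targets, n_conn, replace=False)] = True
    return GroundTruth(
        connected=connected,
        e_p=np.where(connected, e_p, 0.0),
        bump_center_ms=np.full(n_targets, bump_center_ms),
        bump_sd_ms=np.full(n_targets, bump_sd_ms),
        **kwargs)


# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------

def _sample_latencies(rng, family, center, sd, n):
    if family == "gamma":
        shape = (center / sd) ** 2
        scale = sd ** 2 / center
        return rng.gamma(shape, scale, size=n)
    if family == "normal":
        lat = rng.normal(center, sd, size=n)
        while np.any((lat < 0) | (lat >= 90)):   # keep within the window
            bad = (lat < 0) | (lat >= 90)
            lat[bad] = rng.normal(center, sd, size=bad.sum())
        return lat
    raise ValueError(f"unknown latency family {family!r}")


def _colored_drift(rng, n, rate, sd_pa, f_lo=0.05, f_hi=1.0, n_comp=24):
    """Slow 1/f-like drift: superposed sinusoids with 1/f amplitude decay."""
    if sd_pa == 0:
        return np.zeros(n)
    t = np.arange(n) / rate
    freqs = np.exp(rng.uniform(np.log(f_lo), np.log(f_hi), n_comp))
    phases = rng.uniform(0, 2 * np.pi, n_comp)
    amps = 1.0 / freqs
    drift = (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t
                                    + phases[:, None])).sum(axis=0)
    drift = drift - drift.mean()
    s = drift.std()
    return drift * (sd_pa / s) if s > 0 else drift


def render_events(events: pd.DataFrame, n_samples: int,
                  rate: float) -> np.ndarray:
    """Noiseless negative-going trace from an event ground-truth table.

    Rendering is linear: each event contributes amplitude x unit-peak kernel
    at its onset, with inward currents negative.
    """
    trace = np.zeros(n_samples)
    t_all = np.arange(n_samples) / rate * 1000.0  # ms
    for ev in events.itertuples():
        i0 = int(np.floor(ev.onset_ms / 1000.0 * rate))
        # kernel support: ~ tau_decay * ln(1e4/eps) ahead of onset
        span = int((ev.tau_decay_ms * 12 + 5 * ev.tau_rise_ms) / 1000.0 * rate)
        i1 = min(n_samples, i0 + span)
        i0 = max(i0, 0)
        if i0 >= n_samples:
            continue
        dt = t_all[i0:i1] - ev.onset_ms
        trace[i0:i1] -= ev.amplitude_pa * synaptic_kernel(
            dt, ev.tau_rise_ms, ev.tau_decay_ms, normalized=True)
    return trace


def simulate_trace(schedule: StimSchedule, truth: GroundTruth,
                   rate: float = 5000.0, seed: int = 0,
                   duration_s: float | None = None,
                   tau_rise_ms: float = 0.7, tau_decay_ms: float = 3.5
                   ) -> tuple[SweepTrace, pd.DataFrame]:
    """Render a full voltage-clamp recording plus its event ground truth.

    Spontaneous events are homogeneous Poisson at ``truth.spont_rate_hz``;
    each stimulation of a connected target evokes Poisson(e_p) events with
    latencies from the target's bump distribution.  Gaussian noise, slow
    colored drift and optional photocurrent artifacts are added on top.
    """
    if rate < 5000:
        raise ValueError("sampling rate must be >= 5000 samples/s")
    if duration_s is None:
        duration_s = schedule.duration_s
    elif schedule.duration_s > duration_s:
        raise ValueError("schedule is longer than the requested trace")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))

    rows = []
    n_spont = rng.poisson(truth.spont_rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0, duration_s * 1000.0, n_spont))
    for o, a in zip(onsets, truth.amplitudes.sample(rng, n_spont)):
        rows.append(dict(onset_ms=o, amplitude_pa=a, source="spontaneous",
                         target_id=-1, tau_rise_ms=tau_rise_ms,
                         tau_decay_ms=tau_decay_ms))

    for tid in schedule.target_ids:
        times = schedule.pulse_times(tid).time_s.to_numpy()
        if truth.connected[tid] and truth.e_p[tid] > 0:
            for t0 in times:
                k = rng.poisson(truth.e_p[tid])
                if k == 0:
                    continue
                lat = _sample_latencies(rng, truth.latency_family,
                                        truth.bump_center_ms[tid],
                                        truth.bump_sd_ms[tid], k)
                for o, a in zip(t0 * 1000.0 + lat,
                                truth.amplitudes.sample(rng, k)):
                    rows.append(dict(onset_ms=o, amplitude_pa=a,
                                     source="evoked", target_id=int(tid),
                                     tau_rise_ms=tau_rise_ms,
                                     tau_decay_ms=tau_decay_ms))
        pc = truth.photocurrents.get(int(tid))
        if pc is not None:
            for t0 in times:
                rows.append(dict(onset_ms=t0 * 1000.0 + pc.latency_ms,
                                 amplitude_pa=pc.amplitude_pa,
                                 source="photocurrent", target_id=int(tid),
                                 tau_rise_ms=pc.tau_rise_ms,
                                 tau_decay_ms=pc.tau_decay_ms))

    events = pd.DataFrame(rows, columns=["onset_ms", "amplitude_pa", "source",
                                         "target_id", "tau_rise_ms",
                                         "tau_decay_ms"])
    events = events.sort_values("onset_ms").reset_index(drop=True)

    trace = render_events(events, n, rate)
    trace += _colored_drift(rng, n, rate, truth.drift_sd_pa)
    if truth.noise_sd_pa > 0:
        trace += rng.normal(0, truth.noise_sd_pa, n)
    sweep = SweepTrace(current_pa=trace, rate=rate,
                       stim_table=schedule.pulses.copy())
    return sweep, events


# ---------------------------------------------------------------------------
# epoch-level simulation (direct draws under the connectivity models)
# ---------------------------------------------------------------------------

def simulate_epoch_data(n_stimuli: int = 20, spont_rate_hz: float = 2.0,
                        e_p: float = 0.0, bump_center_ms: float = 13.0,
                        bump_sd_ms: float = 5.0, n_repetitions: int = 1,
                        n_spont_segments: int | None = None,
                        latency_family: str = "normal", seed: int = 0):
    """Draw per-target epoch data directly from the generative model.

    Evoked segments are 90 ms; each contains Poisson(rate x 90ms) background
    events at uniform times plus, if ``e_p > 0``, Poisson(e_p) evoked events
    with latencies from the bump distribution.  Spontaneous segments are
    90 ms stretches with Poisson counts at the same background rate.
    Returns a ``connect_infer.StimEpochData``.
    """
    from .connect_infer import StimEpochData

    rng = np.random.default_rng(seed)
    rate_ms = spont_rate_hz / 1000.0
    if n_spont_segments is None:
        n_spont_segments = n_stimuli
    per_rep = max(1, n_stimuli // n_repetitions)

    spont_t, spont_n, evoked_t, evoked_n, rep_idx, ev_rep = \
        [], [], [], [], [], []
    times, times_rep = [], []
    for rep in range(n_repetitions):
        for _ in range(n_spont_segments // n_repetitions or 1):
            spont_t.append(90.0)
            spont_n.append(rng.poisson(rate_ms * 90.0))
            rep_idx.append(rep)
        for _ in range(per_rep):
            bg = rng.poisson(rate_ms * 90.0)
            t = list(rng.uniform(0, 90, bg))
            if e_p > 0:
                k = rng.poisson(e_p)
                t += list(_sample_latencies(rng, latency_family,
                                            bump_center_ms, bump_sd_ms, k))
            t = [x for x in t if 0 <= x < 90]
            evoked_t.append(90.0)
            evoked_n.append(len(t))
            times.extend(sorted(t))
            times_rep.extend([rep] * len(t))
            ev_rep.append(rep)
    return StimEpochData(
        spont_time_ms=np.array(spont_t), num_events_spont=np.array(spont_n),
        evoked_time_ms=np.array(evoked_t), num_events_evoked=np.array(evoked_n),
        event_times_ms=np.array(times), spont_repetition=np.array(rep_idx),
        evoked_repetition=np.array(ev_rep),
        event_repetition=np.array(times_rep, dtype=int))


# ---------------------------------------------------------------------------
# cell volumes
# ---------------------------------------------------------------------------

def simulate_cell_volume(density_per_mm3: float,
                         box_um: tuple = SCAN_VOLUME_UM,
                         seed: int = 0) -> pd.DataFrame:
    """Homogeneous Poisson point process in a box; positions in um."""
    if density_per_mm3 <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    box = np.asarray(box_um, float)
    volume_mm3 = np.prod(box) * 1e-9
    n = rng.poisson(density_per_mm3 * volume_mm3)
    pos = rng.uniform(0, box, size=(n, 3))
    return pd.DataFrame(pos, columns=["x_um", "y_um", "z_um"])


# ---------------------------------------------------------------------------
# cell-pair feature tables
# ---------------------------------------------------------------------------

def simulate_pair_features(n_pairs: int, coefficients: np.ndarray,
                           seed: int = 0,
                           correlation: np.ndarray | None = None,
                           ar1_rho: float = 0.5) -> pd.DataFrame:
    """Cell-pair features with a known logistic connectivity model.

    ``coefficients`` is [intercept, beta_1..beta_p].  Features are drawn
    from a correlated Gaussian (default AR(1) correlation, to exercise the
    whitening step); labels are Bernoulli(inverse-logit(b0 + X beta)).
    The marginal prevalence is reported in ``DataFrame.attrs``.
    """
    coefficients = np.asarray(coefficients, float)
    p = len(coefficients) - 1
    if p < 1:
        raise ValueError("need an intercept plus at least one feature weight")
    if correlation is None:
        idx = np.arange(p)
        correlation = ar1_rho ** np.abs(idx[:, None] - idx[None, :])
    correlation = np.asarray(correlation, float)
    try:
        chol = np.linalg.cholesky(correlation)
    except np.linalg.LinAlgError as err:
        raise ValueError("requested correlation matrix is singular") from err
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_pairs, p)) @ chol.T
    logits = coefficients[0] + X @ coefficients[1:]
    y = rng.random(n_pairs) < special.expit(logits)
    df = pd.DataFrame(X, columns=[f"feat_{i:02d}" for i in range(p)])
    df["connected"] = y.astype(int)
    df.attrs["prevalence"] = float(y.mean())
    return df


# ---------------------------------------------------------------------------
# current-step protocols with planted intrinsic properties
# ---------------------------------------------------------------------------

def simulate_step_protocol(r_in_mohm: float = 100.0, tau_m_ms: float = 20.0,
                           sag_ratio: float = 0.0,
                           gain_hz_per_pa: float = 0.2,
                           rheobase_pa: float = 50.0,
                           bursting_index: float = 1.0,
                           adaptation_index: float = 1.0,
                           currents_pa: np.ndarray | None = None,
                           v_rest_mv: float = -70.0,
                           threshold_mv: float = -40.0,
                           spike_peak_mv: float = 30.0,
                           spike_halfwidth_ms: float = 1.0,
                           rate: float = 20000.0,
                           pulse_s: float = 1.0, pad_s: float = 0.2,
                           noise_sd_mv: float = 0.0, seed: int = 0):
    """Construct current-clamp sweeps with known passive and spiking truth.

    Subthreshold sweeps follow an RC charging curve (with an optional sag
    relaxation); suprathreshold sweeps place stereotyped spikes so that the
    firing rate is gain x (I - rheobase) and the inter-spike-interval
    pattern realizes the requested bursting (ISI2/ISI1) and adaptation
    (ISIlast/ISI2) indices.  Returns ``ephys_features.StepProtocol``.
    """
    from .ephys_features import StepProtocol, Sweep

    rng = np.random.default_rng(seed)
    if currents_pa is None:
        currents_pa = np.arange(-200.0, 401.0, 50.0)
    n_pad = int(pad_s * rate)
    n_pulse = int(pulse_s * rate)
    n_total = 2 * n_pad + n_pulse
    t_pulse = np.arange(n_pulse) / rate  # s

    sweeps = []
    for i_pa in currents_pa:
        v = np.full(n_total, v_rest_mv)
        if i_pa <= 0 or i_pa < rheobase_pa:
            # RC response: dV = I*R*(1 - exp(-t/tau)); mV = pA * MOhm * 1e-3
            dv_ss = i_pa * r_in_mohm * 1e-6 * 1e3
            resp = dv_ss * (1 - np.exp(-t_pulse / (tau_m_ms / 1000.0)))
            if i_pa < 0 and sag_ratio > 0:
                # charge to the sag peak dv_ss/(1-sag), then relax slowly
                # back toward dv_ss (h-current-like rebound)
                dv_min = dv_ss / (1.0 - sag_ratio)
                t_peak = 5.0 * tau_m_ms / 1000.0
                sag_tau = 0.15  # s
                charge = dv_min * (1 - np.exp(-t_pulse / (tau_m_ms / 1000.0)))
                relax = dv_ss + (dv_min - dv_ss) * np.exp(
                    -(t_pulse - t_peak) / sag_tau)
                resp = np.where(t_pulse <= t_peak, charge, relax)
            v[n_pad:n_pad + n_pulse] += resp
        else:
            n_spikes = int(round(gain_hz_per_pa * (i_pa - rheobase_pa)
                                 * pulse_s))
            if n_spikes >= 1:
                spike_times = _isi_pattern(n_spikes, pulse_s,
                                           bursting_index, adaptation_index)
                v[n_pad:n_pad + n_pulse] += 10.0  # depolarized plateau
                for st in spike_times:
                    _add_spike(v, n_pad + int(st * rate), rate,
                               v_rest_mv + 10.0, threshold_mv, spike_peak_mv,
                               spike_halfwidth_ms)
        if noise_sd_mv > 0:
            v += rng.normal(0, noise_sd_mv, n_total)
        sweeps.append(Sweep(current_pa=float(i_pa), voltage_mv=v, rate=rate,
                            pulse_start_s=pad_s, pulse_dur_s=pulse_s))
    return StepProtocol(sweeps=sweeps)


def _isi_pattern(n_spikes, pulse_s, bursting, adaptation):
    """Spike times whose ISI sequence realizes the planted indices."""
    if n_spikes == 1:
        return np.array([0.05 * pulse_s])
    n_isi = n_spikes - 1
    isi = np.ones(n_isi)
    if n_isi >= 2:
        isi[0] = 1.0 / bursting             # ISI2/ISI1 = bursting
        isi[1:] = np.geomspace(1.0, adaptation, n_isi - 1)  # ISIlast/ISI2
    total = isi.sum()
    isi *= 0.9 * pulse_s / total
    times = np.concatenate([[0.02 * pulse_s],
                            0.02 * pulse_s + np.cumsum(isi)])
    return times


def _add_spike(v, i0, rate, base_mv, threshold_mv, peak_mv, halfwidth_ms):
    """Stereotyped spike: fast linear rise to peak, linear fall, at i0."""
    # rise from base through threshold to peak; dV/dt >> 20 mV/ms above thr
    rise_ms, fall_ms = 0.4, 2 * halfwidth_ms - 0.4
    n_rise = max(2, int(rise_ms / 1000.0 * rate))
    n_fall = max(2, int(fall_ms / 1000.0 * rate))
    up = np.linspace(base_mv, peak_mv, n_rise)
    down = np.linspace(peak_mv, base_mv, n_fall)
    wave = np.concatenate([up, down[1:]])
    i1 = min(len(v), i0 + len(wave))
    v[i0:i1] = np.maximum(v[i0:i1], wave[: i1 - i0])


# ---------------------------------------------------------------------------
# IO: HDF5 traces, CSV/JSON schedules and ground truth
# ---------------------------------------------------------------------------

def write_trace_h5(path, sweep: SweepTrace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trace_pa", data=sweep.current_pa)
        f.attrs["rate"] = sweep.rate
        if sweep.stim_table is not None:
            g = f.create_group("stim")
            for col in sweep.stim_table.columns:
                g.create_dataset(col, data=sweep.stim_table[col].to_numpy())


def read_trace_h5(path) -> SweepTrace:
    with h5py.File(path, "r") as f:
        trace = f["trace_pa"][:]
        rate = float(f.attrs["rate"])
        stim = None
        if "stim" in f:
            stim = pd.DataFrame({k: f["stim"][k][:] for k in f["stim"]})
    return SweepTrace(current_pa=trace, rate=rate, stim_table=stim)


def write_schedule(schedule: StimSchedule, csv_path, json_path) -> None:
    schedule.pulses.to_csv(csv_path, index=False)
    meta = dict(target_ids=schedule.target_ids.tolist(),
                positions_um=schedule.positions_um.tolist(),
                trains=asdict(schedule.trains))
    with open(json_path, "w") as f:
        json.dump(meta, f, indent=1)


def read_schedule(csv_path, json_path) -> StimSchedule:
    pulses = pd.read_csv(csv_path)
    with open(json_path) as f:
        meta = json.load(f)
    return StimSchedule(target_ids=np.asarray(meta["target_ids"]),
                        positions_um=np.asarray(meta["positions_um"]),
                        pulses=pulses, trains=TrainSpec(**meta["trains"]))
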