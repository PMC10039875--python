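"""Detection and kinetic decomposition of EPSCs in voltage-clamp traces.

The pipeline operates on a continuous membrane-current recording and runs in
six stages: (1) detrend the inverted trace and estimate the noise level,
(2) sparse nonnegative deconvolution against a canonical synaptic kernel,
(3) peak detection on the smoothed deconvolved trace, (4) clustering of
temporally overlapping events, (5) per-cluster least-squares decomposition
into a sum of synaptic kernels, and (6) amplitude thresholding.

All timestamps are milliseconds from trace start; the internal sampling rate
is fixed at 5000 samples/s (traces recorded faster are polyphase-resampled).
Inward synaptic currents are negative in stored traces; the detector works on
the inverted (positive-going) trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal

INTERNAL_RATE = 5000.0  # samples/s after resampling
MS_PER_SAMPLE = 1000.0 / INTERNAL_RATE


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DetectionParams:
    """Tunable parameters of the detection pipeline.

    Defaults follow the canonical configuration: a difference-of-exponentials
    kernel with tau_decay=3.5 ms and tau_rise=0.7 ms, sparsity-constrained
    deconvolution at a noise level of 0.8 x the robust noise SD, peak
    detection at 0.5 x SD with 2 ms dead time, clustering of the denoised
    trace above 1.8 x SD, and a final amplitude threshold of 2.5 x SD.
    """

    tau_decay_ms: float = 3.5
    tau_rise_ms: float = 0.7
    # detrending
    percentile: float = 10.0
    percentile_width_ms: float = 50.0
    smooth_rate: float = 200.0
    median_width_ms: float = 15.0
    # deconvolution
    noise_level: float = 0.8          # x SD residual target
    max_outer_iter: int = 10
    inner_iter: int = 60
    # detection
    triangle_width_ms: float = 2.5
    peak_threshold_sd: float = 0.5    # height and prominence
    min_distance_ms: float = 2.0
    area_window_ms: tuple[float, float] = (-0.4, 0.8)
    # clustering
    cluster_threshold_sd: float = 1.8
    extend_before_ms: float = 10.0
    extend_after_ms: float = 20.0
    event_pad_ms: float = 10.0
    singleton_span_ms: tuple[float, float] = (10.0, 30.0)
    # fitting
    height_box: tuple[float, float] = (1.0 / 15.0, 3.0)
    onset_box_ms: float = 10.0
    tau_decay_bounds_ms: tuple[float, float] = (0.5, 50.0)
    tau_rise_bounds_ms: tuple[float, float] = (0.1, 10.0)
    onset_penalty_scale: float = 5.0
    anneal_iter_per_event: int = 60
    seed: int = 0
    # thresholding
    height_threshold_sd: float = 2.5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SweepTrace:
    """Uniformly sampled membrane current (pA) with aligned stimulus markers.

    ``stim_table`` has one row per stimulation pulse with at least the
    columns ``target_id``, ``repetition`` and ``time_s``.
    """

    current_pa: np.ndarray
    rate: float
    stim_table: pd.DataFrame | None = None

    @property
    def duration_s(self) -> float:
        return len(self.current_pa) / self.rate


@dataclass
class ZeroBaselineTrace:
    """Inverted, baseline-subtracted current at the internal rate."""

    samples: np.ndarray        # pA, positive-going events
    noise_sd: float            # robust SD = 1.4826 x MAD
    rate: float = INTERNAL_RATE

    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) * (1000.0 / self.rate)


@dataclass
class DeconvResult:
    deconvolved: np.ndarray    # nonnegative event-mass series
    denoised: np.ndarray       # deconvolved convolved with the kernel
    converged: bool = True


@dataclass
class EventCluster:
    start: int                 # sample indices into the zero-baseline trace
    stop: int
    members: list[int] = field(default_factory=list)  # indices into event list


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

def synaptic_kernel(t_ms, tau_rise_ms: float, tau_decay_ms: float,
                    normalized: bool = False):
    """Canonical EPSC waveform k(t) = exp(-t/tau_d) * (1 - exp(-t/tau_r)).

    Zero for t < 0. With ``normalized=True`` the kernel is scaled to unit
    peak so that a multiplicative height equals the event amplitude in pA.
    """
    if not tau_decay_ms > tau_rise_ms > 0:
        raise ValueError(
            f"require tau_decay > tau_rise > 0, got "
            f"tau_decay={tau_decay_ms}, tau_rise={tau_rise_ms}")
    t = np.asarray(t_ms, dtype=float)
    out = np.where(
        t >= 0,
        np.exp(-np.clip(t, 0, None) / tau_decay_ms)
        * (1.0 - np.exp(-np.clip(t, 0, None) / tau_rise_ms)),
        0.0,
    )
    if normalized:
        out = out / kernel_peak_value(tau_rise_ms, tau_decay_ms)
    if np.isscalar(t_ms):
        return float(out)
    return out


def kernel_peak_time(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Closed-form argmax of the kernel: tau_r * ln(1 + tau_d/tau_r)."""
    return tau_rise_ms * np.log1p(tau_decay_ms / tau_rise_ms)


def kernel_peak_value(tau_rise_ms: float, tau_decay_ms: float) -> float:
    return float(synaptic_kernel(kernel_peak_time(tau_rise_ms, tau_decay_ms),
                                 tau_rise_ms, tau_decay_ms))


def discretized_kernel(params: DetectionParams, rate: float = INTERNAL_RATE,
                       normalized: bool = True) -> np.ndarray:
    """Kernel sampled at trace resolution, truncated below 1e-4 of peak."""
    dt = 1000.0 / rate
    # decay to 1e-4 of peak happens within ~ tau_decay * ln(1e4) + rise time
    n = int(np.ceil((params.tau_decay_ms * np.log(1e4)
                     + 5 * params.tau_rise_ms) / dt)) + 1
    t = np.arange(n) * dt
    k = synaptic_kernel(t, params.tau_rise_ms, params.tau_decay_ms,
                        normalized=normalized)
    keep = k >= 1e-4 * k.max()
    last = np.nonzero(keep)[0][-1]
    return k[: last + 1]


# ---------------------------------------------------------------------------
# step 1: detrending
# ---------------------------------------------------------------------------

def detrend_and_noise(raw: SweepTrace,
                      params: DetectionParams | None = None) -> ZeroBaselineTrace:
    """Invert, resample to 5 kHz, subtract a slow percentile baseline.

    The baseline is a 10th-percentile filter of 50 ms width, smoothed by
    downsampling to 200 Hz, median filtering with a 15 ms window and
    upsampling back.  The output is shifted to zero median and the noise SD
    is the robust estimate 1.4826 x MAD.
    """
    params = params or DetectionParams()
    x = np.asarray(raw.current_pa, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("raw trace contains non-finite samples")
    if raw.rate < INTERNAL_RATE:
        raise ValueError(f"sampling rate must be >= {INTERNAL_RATE} Hz")
    if raw.rate != INTERNAL_RATE:
        up, down = (np.array([INTERNAL_RATE, raw.rate])
                    / np.gcd(int(INTERNAL_RATE), int(raw.rate))).astype(int)
        x = signal.resample_poly(x, up, down)
    inv = -x

    width = int(round(params.percentile_width_ms / MS_PER_SAMPLE))
    if len(inv) <= width:
        raise ValueError("trace shorter than the percentile filter width")
    baseline = ndimage.percentile_filter(inv, params.percentile, size=width,
                                         mode="nearest")
    # smooth: downsample to 200 Hz, median filter 15 ms, upsample back
    step = int(round(INTERNAL_RATE / params.smooth_rate))
    coarse = baseline[::step]
    med_n = max(1, int(round(params.median_width_ms
                             * params.smooth_rate / 1000.0)))
    if med_n % 2 == 0:
        med_n += 1
    coarse = ndimage.median_filter(coarse, size=med_n, mode="nearest")
    t_coarse = np.arange(len(coarse)) * step
    baseline = np.interp(np.arange(len(inv)), t_coarse, coarse)

    z = inv - baseline
    z = z - np.median(z)
    mad = np.median(np.abs(z - np.median(z)))
    return ZeroBaselineTrace(samples=z, noise_sd=1.4826 * float(mad))


# ---------------------------------------------------------------------------
# step 2: deconvolution
# ---------------------------------------------------------------------------

def _fista_nonneg_l1(y: np.ndarray, k: np.ndarray, lam: float,
                     n_iter: int, x0: np.ndarray | None = None) -> np.ndarray:
    """FISTA for min 0.5||k*x - y||^2 + lam*sum(x), x >= 0 (FFT convolution)."""
    n = len(y)
    nfft = int(2 ** np.ceil(np.log2(n + len(k))))
    K = np.fft.rfft(k, nfft)
    L = float(np.max(np.abs(K) ** 2))  # Lipschitz constant of the gradient

    def conv(v, spec):
        return np.fft.irfft(np.fft.rfft(v, nfft) * spec, nfft)[:n]

    Kc = np.conj(K)
    x = np.zeros(n) if x0 is None else x0.copy()
    z = x.copy()
    t = 1.0
    for _ in range(n_iter):
        r = conv(z, K) - y
        # adjoint of causal convolution is correlation with the kernel
        grad = np.fft.irfft(np.fft.rfft(r, nfft) * Kc, nfft)[:n]
        x_new = np.maximum(z - (grad + lam) / L, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
    return x


def deconvolve(z: ZeroBaselineTrace,
               params: DetectionParams | None = None) -> DeconvResult:
    """Sparsity-constrained nonnegative deconvolution of the trace.

    Solves an L1-penalized nonnegative inverse problem against the unit-peak
    synaptic kernel, iterating the penalty (up to ``max_outer_iter`` outer
    iterations) so that the residual RMS approaches ``noise_level`` x the
    robust noise SD, in the spirit of noise-constrained spike deconvolution.
    Returns the nonnegative deconvolved series and the denoised trace (its
    convolution with the kernel).
    """
    params = params or DetectionParams()
    k = discretized_kernel(params)
    y = z.samples
    target = params.noise_level * z.noise_sd
    if not np.any(y):
        return DeconvResult(np.zeros_like(y), np.zeros_like(y))
    if np.sqrt(np.mean(y ** 2)) <= target:
        # the whole trace is within the noise allowance: maximally sparse
        # solution is no events at all
        return DeconvResult(np.zeros_like(y), np.zeros_like(y))

    # bisection on log-lambda toward the target residual RMS
    lam_lo, lam_hi = 0.0, None
    lam = max(target, 1e-12) * np.sum(k) * 0.5
    x = None
    converged = False
    for _ in range(params.max_outer_iter):
        x = _fista_nonneg_l1(y, k, lam, params.inner_iter, x0=x)
        denoised = signal.fftconvolve(x, k)[: len(y)]
        rms = float(np.sqrt(np.mean((y - denoised) ** 2)))
        if target > 0 and abs(rms - target) < 0.02 * target:
            converged = True
            break
        if rms > target:      # over-penalized -> decrease lambda
            lam_hi = lam
            lam = 0.5 * (lam_lo + lam) if lam_lo > 0 else lam / 4.0
        else:                 # residual too small -> increase lambda
            lam_lo = lam
            lam = 0.5 * (lam + lam_hi) if lam_hi is not None else lam * 4.0
    else:
        if target <= 0.01:   # (near-)noiseless: plain least-squares limit
            converged = True
        else:
            warnings.warn("deconvolution did not reach the target residual; "
                          "returning best iterate", RuntimeWarning)
    x = np.maximum(x, 0.0)
    denoised = signal.fftconvolve(x, k)[: len(y)]
    return DeconvResult(deconvolved=x, denoised=denoised, converged=converged)


# ---------------------------------------------------------------------------
# step 3: detection
# ---------------------------------------------------------------------------

def detect_putative_events(d: DeconvResult, z: ZeroBaselineTrace,
                           params: DetectionParams | None = None
                           ) -> list[tuple[float, float]]:
    """Provisional (onset ms, height pA) pairs from deconvolved-trace peaks.

    Peaks of the triangle-filtered (2.5 ms) deconvolved trace with height
    and prominence of at least 0.5 x SD and at least 2.0 ms apart; the
    provisional height is the deconvolved mass in [-0.4, +0.8] ms around
    the peak (in pA thanks to the unit-peak kernel normalization).
    """
    params = params or DetectionParams()
    ntri = max(3, int(round(params.triangle_width_ms / MS_PER_SAMPLE)))
    tri = signal.windows.triang(ntri)
    tri = tri / tri.sum()
    filt = signal.fftconvolve(d.deconvolved, tri, mode="same")
    # absolute floor guards the noiseless limit where the robust SD is ~0
    thr = max(params.peak_threshold_sd * z.noise_sd, 0.01)
    dist = max(1, int(round(params.min_distance_ms / MS_PER_SAMPLE)))
    peaks, _ = signal.find_peaks(filt, height=thr, prominence=thr,
                                 distance=dist)
    lo = int(round(params.area_window_ms[0] / MS_PER_SAMPLE))
    hi = int(round(params.area_window_ms[1] / MS_PER_SAMPLE))
    out = []
    for p in peaks:
        a, b = max(0, p + lo), min(len(d.deconvolved), p + hi + 1)
        h_hat = float(np.sum(d.deconvolved[a:b]))
        out.append((p * MS_PER_SAMPLE, h_hat))
    return out


# ---------------------------------------------------------------------------
# step 4: clustering
# ---------------------------------------------------------------------------

def cluster_events(d: DeconvResult, events: list[tuple[float, float]],
                   z: ZeroBaselineTrace,
                   params: DetectionParams | None = None) -> list[EventCluster]:
    """Group events whose denoised-trace excursions overlap.

    Segments where the denoised trace exceeds 1.8 x SD are extended by 10 ms
    before and 20 ms after, further extended by +/-10 ms around member
    events, and merged when overlapping.  Events falling outside every
    segment get a singleton segment spanning [-10, +30] ms around them.
    """
    params = params or DetectionParams()
    n = len(d.denoised)
    # same absolute floor as detection, for the near-noiseless limit
    thr = max(params.cluster_threshold_sd * z.noise_sd, 0.01)
    above = d.denoised > thr
    pad_b = int(round(params.extend_before_ms / MS_PER_SAMPLE))
    pad_a = int(round(params.extend_after_ms / MS_PER_SAMPLE))
    pad_e = int(round(params.event_pad_ms / MS_PER_SAMPLE))

    segs: list[list[int]] = []
    if np.any(above):
        edges = np.diff(above.astype(int))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        stops = list(np.nonzero(edges == -1)[0] + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            stops.append(n)
        segs = [[max(0, s - pad_b), min(n, e + pad_a)]
                for s, e in zip(starts, stops)]

    ev_samples = [int(round(o / MS_PER_SAMPLE)) for o, _ in events]
    for i, p in enumerate(ev_samples):
        inside = any(s <= p < e for s, e in segs)
        if inside:
            continue
        lo = int(round(params.singleton_span_ms[0] / MS_PER_SAMPLE))
        hi = int(round(params.singleton_span_ms[1] / MS_PER_SAMPLE))
        segs.append([max(0, p - lo), min(n, p + hi)])

    # widen segments around their member events, then merge overlaps
    for s in segs:
        for p in ev_samples:
            if s[0] <= p < s[1]:
                s[0] = max(0, min(s[0], p - pad_e))
                s[1] = min(n, max(s[1], p + pad_e))
    segs.sort()
    merged: list[list[int]] = []
    for s in segs:
        if merged and s[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], s[1])
        else:
            merged.append(list(s))

    clusters = [EventCluster(start=s, stop=e) for s, e in merged]
    for i, p in enumerate(ev_samples):
        for c in clusters:
            if c.start <= p < c.stop:
                c.members.append(i)
                break
    return [c for c in clusters if c.members]


# ---------------------------------------------------------------------------
# step 5: fitting
# ---------------------------------------------------------------------------

def _render_cluster(t_ms, theta, n_events):
    """Sum of kernels; theta = [c, (log h, o, log tau_d, log tau_r) x n]."""
    out = np.full_like(t_ms, theta[0])
    for i in range(n_events):
        logh, o, ltd, ltr = theta[1 + 4 * i: 5 + 4 * i]
        td, tr = np.exp(ltd), np.exp(ltr)
        if td <= tr:
            continue
        dt = t_ms - o
        out = out + np.exp(logh) * synaptic_kernel(dt, tr, td, normalized=True)
    return out


def fit_cluster(z: ZeroBaselineTrace, cluster: EventCluster,
                events: list[tuple[float, float]],
                params: DetectionParams | None = None) -> pd.DataFrame:
    """Decompose one cluster into a sum of synaptic kernels.

    Minimizes RMS(S - model)/SD + RMS(o - o_hat)/5 over per-event height,
    onset and time constants plus a shared offset, with height and time
    constants optimized in log scale.  A global annealing search whose
    effort grows with the cluster size is followed by Powell refinement.
    """
    params = params or DetectionParams()
    members = cluster.members
    n_ev = len(members)
    if n_ev == 0:
        raise ValueError("cluster has no member events")
    seg = z.samples[cluster.start: cluster.stop]
    t_ms = (cluster.start + np.arange(len(seg))) * MS_PER_SAMPLE
    sd = max(z.noise_sd, 1e-9)

    o_hat = np.array([events[i][0] for i in members])
    h_hat = np.array([max(events[i][1], 10 * np.finfo(float).tiny)
                      for i in members])

    off = max(3 * sd, 0.5)  # keep the offset box nondegenerate
    bounds = [(-off, off)]
    for oh, hh in zip(o_hat, h_hat):
        bounds.append((np.log(hh * params.height_box[0]),
                       np.log(hh * params.height_box[1])))
        bounds.append((oh - params.onset_box_ms, oh + params.onset_box_ms))
        bounds.append((np.log(params.tau_decay_bounds_ms[0]),
                       np.log(params.tau_decay_bounds_ms[1])))
        bounds.append((np.log(params.tau_rise_bounds_ms[0]),
                       np.log(params.tau_rise_bounds_ms[1])))
    bounds = np.array(bounds, dtype=float)

    def objective(theta):
        pen = 0.0
        for i in range(n_ev):
            ltd, ltr = theta[3 + 4 * i], theta[4 + 4 * i]
            if ltd <= ltr:  # tau_decay must exceed tau_rise
                pen += 1e3 * (1.0 + ltr - ltd)
        model = _render_cluster(t_ms, theta, n_ev)
        rms = np.sqrt(np.mean((seg - model) ** 2))
        onsets = theta[2::4]
        o_rms = np.sqrt(np.mean((onsets - o_hat) ** 2))
        return rms / sd + o_rms / params.onset_penalty_scale + pen

    x0 = np.zeros(1 + 4 * n_ev)
    x0[1::4] = np.log(h_hat)
    x0[2::4] = o_hat
    x0[3::4] = np.log(params.tau_decay_ms)
    x0[4::4] = np.log(params.tau_rise_ms)
    x0 = np.clip(x0, bounds[:, 0], bounds[:, 1])

    failed = False
    try:
        res = optimize.dual_annealing(
            objective, bounds=bounds, x0=x0,
            maxiter=params.anneal_iter_per_event * n_ev,
            seed=params.seed, no_local_search=True)
        res = optimize.minimize(objective, res.x, method="Powell",
                                bounds=bounds)
        theta = np.clip(res.x, bounds[:, 0], bounds[:, 1])
        if not np.isfinite(objective(theta)):
            raise RuntimeError("non-finite objective at optimum")
    except Exception:
        failed = True
        theta = x0

    rows = []
    for i in range(n_ev):
        logh, o, ltd, ltr = theta[1 + 4 * i: 5 + 4 * i]
        td, tr = float(np.exp(ltd)), float(np.exp(ltr))
        if td <= tr:  # enforce the kinetic ordering on degenerate optima
            td = tr * 1.01
        rows.append(dict(onset_ms=float(o), height_pa=float(np.exp(logh)),
                         tau_rise_ms=tr, tau_decay_ms=td,
                         provisional_onset_ms=float(o_hat[i]),
                         provisional_height_pa=float(h_hat[i]),
                         fit_failed=failed))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# step 6: full pipeline with thresholding
# ---------------------------------------------------------------------------

def detect_epscs(raw: SweepTrace,
                 params: DetectionParams | None = None) -> pd.DataFrame:
    """Run the full pipeline and return the thresholded event table.

    Events with fitted height <= 2.5 x SD are discarded.  The table is
    sorted by onset and carries cluster ids and all kinetic parameters.
    """
    params = params or DetectionParams()
    z = detrend_and_noise(raw, params)
    d = deconvolve(z, params)
    events = detect_putative_events(d, z, params)
    if not events:
        return _empty_event_table()
    clusters = cluster_events(d, events, z, params)
    frames = []
    for cid, c in enumerate(clusters):
        df = fit_cluster(z, c, events, params)
        df["cluster_id"] = cid
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table = table[table.height_pa > params.height_threshold_sd * z.noise_sd]
    table = table.sort_values("onset_ms").reset_index(drop=True)
    table.attrs["noise_sd"] = z.noise_sd
    return table


def _empty_event_table() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "onset_ms", "height_pa", "tau_rise_ms", "tau_decay_ms",
        "provisional_onset_ms", "provisional_height_pa", "fit_failed",
        "cluster_id"])


# ---------------------------------------------------------------------------
# event-table IO
# ---------------------------------------------------------------------------

def write_event_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
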