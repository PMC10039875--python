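"""Per-target Bayesian connectivity calls and population EPSC-time models.

For each stimulated target the event record around its stimulation train is
summarized as counts in evoked (90 ms post-stimulus) and spontaneous
(reference) segments plus exact event latencies within evoked segments.
Three pairs of models are compared, each pair pitting a "not connected"
against a "connected" hypothesis:

* rate-and-time (models 1 vs 2): Poisson segment counts plus a mixture
  likelihood on event latencies (uniform vs uniform + latency bump);
* time-only (models 3 vs 4): only the latency mixture, with a Beta(2, 2)
  prior directly on the bump weight (the null, model 3, has no parameters);
* rate-only (models 5 vs 6): only the Poisson counts.

Posteriors are sampled by gradient-based MCMC; each comparison yields the
pseudo-BMA weight of the connected model from Pareto-smoothed
importance-sampling leave-one-out ELPDs.  A target is called connected when
(w_rt >= 0.5) and (w_t >= 0.4) and (w_r >= 0.4).  For connected targets a
variable-bump model (model 7, normal bump with inferred center and bounded
width) supports connection-strength measurement as a bump-weighted average
of EPSC amplitudes in a 2-30 ms post-stimulus window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, expit, gammaln, logit

from ._mcmc import (SamplerConfig, bb_pseudo_bma_weights, loo_elpd_pointwise,
                    sample_hmc, split_rhat)

EVOKED_WINDOW_MS = 90.0
STRENGTH_WINDOW_MS = (2.0, 30.0)

#: latency-bump defaults from the population PSTH gamma fit (mean k*theta,
#: sd sqrt(k)*theta for k=4.1896, theta=3.0942 ms)
DEFAULT_BUMP_CENTER_MS = 4.1896 * 3.0942
DEFAULT_BUMP_WIDTH_MS = float(np.sqrt(4.1896) * 3.0942)


# ---------------------------------------------------------------------------
# gamma-distribution constructors (both parameterizations are used)
# ---------------------------------------------------------------------------

def gamma_from_mean_sd(mu: float, sigma: float) -> tuple[float, float]:
    """(shape, scale) of a gamma distribution with given mean and sd."""
    if mu <= 0 or sigma <= 0:
        raise ValueError("gamma mean and sd must be positive")
    return (mu / sigma) ** 2, sigma ** 2 / mu


def gamma_from_shape_scale(shape: float, scale: float) -> tuple[float, float]:
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    return shape, scale


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StimEpochData:
    """Evoked/spontaneous segment summaries for one stimulated target."""

    spont_time_ms: np.ndarray       # per spontaneous segment, <= 90 ms
    num_events_spont: np.ndarray
    evoked_time_ms: np.ndarray      # per evoked segment, = 90 ms
    num_events_evoked: np.ndarray
    event_times_ms: np.ndarray      # latencies of events in evoked segments
    spont_repetition: np.ndarray
    evoked_repetition: np.ndarray
    event_repetition: np.ndarray | None = None

    def __post_init__(self):
        for name in ("spont_time_ms", "num_events_spont", "evoked_time_ms",
                     "num_events_evoked", "event_times_ms",
                     "spont_repetition", "evoked_repetition"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.event_repetition is None:
            self.event_repetition = np.zeros(len(self.event_times_ms), int)
        else:
            self.event_repetition = np.asarray(self.event_repetition, int)
        if np.any((self.event_times_ms < 0)
                  | (self.event_times_ms >= EVOKED_WINDOW_MS)):
            raise ValueError("event latencies must lie in [0, 90) ms")

    @property
    def n_repetitions(self) -> int:
        reps = np.concatenate([self.spont_repetition, self.evoked_repetition])
        return int(reps.max()) + 1 if len(reps) else 1

    def empirical_spont_rate(self) -> float:
        """Spontaneous event rate in events/ms."""
        total_t = float(np.sum(self.spont_time_ms))
        if total_t == 0:
            return 0.0
        return float(np.sum(self.num_events_spont)) / total_t


@dataclass
class ModelWeights:
    """Connected-model weights of the three model comparisons."""

    w_rt: float
    w_t: float
    w_r: float
    divergences: int = 0
    max_rhat: float = 1.0
    unreliable: bool = False


@dataclass
class BumpFit:
    """Posterior summary of the variable-bump (model 7) fit."""

    bump_center_ms: float
    bump_width_ms: float
    spont_rate_per_ms: float
    evoked_per_trial: float
    center_q: tuple[float, float]
    width_q: tuple[float, float]
    draws: np.ndarray | None = None
    divergences: int = 0


@dataclass
class MixturePsthFit:
    """Maximum-likelihood gamma + uniform mixture fit of pooled latencies."""

    shape: float
    scale_ms: float
    weight: float
    shape_ci: tuple[float, float]
    scale_ci: tuple[float, float]
    weight_ci: tuple[float, float]
    loglik: float
    degenerate: bool = False


@dataclass
class ConnectivityCall:
    target_id: int
    weights: ModelWeights
    connected: bool
    bump: BumpFit | None = None
    strength_pa: float = 0.0
    per_stimulation_pa: np.ndarray | None = None


@dataclass
class ModelPriors:
    """Prior hyperparameters of models 1-7.

    Rates are events/ms.  ``rate_mu=None`` uses the empirical spontaneous
    rate of the recording (sd equal to the mean).  The fixed bump of models
    1-6 defaults to the population PSTH gamma fit; the model-7 priors put a
    gamma on the bump center and a [3, 8] ms bounded gamma on its width.
    ``width_uses_center_hyperparams`` switches to the literal reading in
    which the width prior reuses the center hyperparameters.
    """

    rate_mu: float | None = None
    rate_sigma: float | None = None
    evoked_mu: float = 0.5
    evoked_sigma: float = 0.5
    bump_center_ms: float = DEFAULT_BUMP_CENTER_MS
    bump_width_ms: float = DEFAULT_BUMP_WIDTH_MS
    center_mu: float = 13.0
    center_sigma: float = 5.0
    width_mu: float = 5.5
    width_sigma: float = 1.5
    width_bounds: tuple[float, float] = (3.0, 8.0)
    width_uses_center_hyperparams: bool = False
    rate_floor: float = 1e-4   # events/ms, guards empty recordings

    def resolved_rate_prior(self, data: StimEpochData) -> tuple[float, float]:
        mu = self.rate_mu
        if mu is None:
            mu = max(data.empirical_spont_rate(), self.rate_floor)
        sigma = self.rate_sigma if self.rate_sigma is not None else mu
        return mu, sigma


# ---------------------------------------------------------------------------
# epoch segmentation
# ---------------------------------------------------------------------------

def segment_epochs(events: pd.DataFrame, schedule, target_id: int,
                   spont_within_s: float = 5.0) -> StimEpochData:
    """Carve evoked and spontaneous segments for one target.

    Evoked segments are the [0, 90) ms windows after each stimulus of the
    target (the last 10 ms of a 100 ms inter-pulse interval is a guard).
    Spontaneous segments are unstimulated stretches (outside every
    stimulation window of *any* target) within +/-5 s of the target's
    trains, chopped into pieces of at most 90 ms.
    """
    pulses = schedule.pulses
    if target_id not in set(pulses.target_id):
        raise ValueError(f"target {target_id} absent from schedule")
    onsets = np.sort(events.onset_ms.to_numpy()) if len(events) else np.array([])

    all_windows = np.sort(pulses.time_s.to_numpy()) * 1000.0  # ms
    own = pulses[pulses.target_id == target_id]

    spont_t, spont_n, spont_rep = [], [], []
    ev_t, ev_n, ev_rep, times, times_rep = [], [], [], [], []

    for rep, grp in own.groupby("repetition"):
        for t0 in grp.time_s.to_numpy() * 1000.0:
            lo, hi = t0, t0 + EVOKED_WINDOW_MS
            in_win = onsets[(onsets >= lo) & (onsets < hi)]
            ev_t.append(EVOKED_WINDOW_MS)
            ev_n.append(len(in_win))
            ev_rep.append(int(rep))
            times.extend((in_win - t0).tolist())
            times_rep.extend([int(rep)] * len(in_win))

        train_lo = grp.time_s.min() * 1000.0 - spont_within_s * 1000.0
        train_hi = (grp.time_s.max() * 1000.0 + EVOKED_WINDOW_MS
                    + spont_within_s * 1000.0)
        blocked = [(t, t + EVOKED_WINDOW_MS) for t in all_windows
                   if t + EVOKED_WINDOW_MS > train_lo and t < train_hi]
        free, cursor = [], max(train_lo, 0.0)
        for lo, hi in blocked:
            if lo > cursor:
                free.append((cursor, lo))
            cursor = max(cursor, hi)
        if cursor < train_hi:
            free.append((cursor, train_hi))
        for lo, hi in free:
            pos = lo
            while pos < hi - 1e-9:
                end = min(pos + EVOKED_WINDOW_MS, hi)
                if end - pos >= 1.0:  # skip sub-ms slivers
                    n = int(np.sum((onsets >= pos) & (onsets < end)))
                    spont_t.append(end - pos)
                    spont_n.append(n)
                    spont_rep.append(int(rep))
                pos = end

    return StimEpochData(
        spont_time_ms=np.array(spont_t), num_events_spont=np.array(spont_n),
        evoked_time_ms=np.array(ev_t), num_events_evoked=np.array(ev_n),
        event_times_ms=np.array(times), spont_repetition=np.array(spont_rep),
        evoked_repetition=np.array(ev_rep),
        event_repetition=np.array(times_rep, dtype=int))


# ---------------------------------------------------------------------------
# model log-posteriors (batched over draws; unconstrained parameterization)
# ---------------------------------------------------------------------------

def _gamma_logpdf(x, shape, scale):
    return ((shape - 1) * np.log(x) - x / scale
            - shape * np.log(scale) - gammaln(shape))


def _poisson_ll(n, lam):
    return n * np.log(np.clip(lam, 1e-300, None)) - lam - gammaln(n + 1)


class _ConnModel:
    """One connectivity model: batched logp plus pointwise log-likelihood.

    ``kind`` selects the likelihood blocks: "rt" (rate-and-time), "t"
    (time-only) or "r" (rate-only); ``connected`` adds the evoked-rate
    parameter and the latency bump.  Parameters are log rates per protocol
    repetition, then log evoked-per-trial, then (model 7 only) log bump
    center and a logit-bounded bump width.
    """

    def __init__(self, data: StimEpochData, priors: ModelPriors, kind: str,
                 connected: bool, variable_bump: bool = False):
        self.data = data
        self.priors = priors
        self.kind = kind
        self.connected = connected
        self.variable_bump = variable_bump
        self.R = data.n_repetitions

        self.rate_k, self.rate_th = gamma_from_mean_sd(
            *priors.resolved_rate_prior(data))
        self.ev_k, self.ev_th = gamma_from_mean_sd(priors.evoked_mu,
                                                   priors.evoked_sigma)
        if variable_bump:
            self.c_k, self.c_th = gamma_from_mean_sd(priors.center_mu,
                                                     priors.center_sigma)
            if priors.width_uses_center_hyperparams:
                self.w_k, self.w_th = self.c_k, self.c_th
            else:
                self.w_k, self.w_th = gamma_from_mean_sd(priors.width_mu,
                                                         priors.width_sigma)
        # fixed-bump density at the observed latencies
        bk, bth = gamma_from_mean_sd(priors.bump_center_ms,
                                     priors.bump_width_ms)
        self.bump_pdf = stats.gamma.pdf(data.event_times_ms, bk, scale=bth)

        if kind == "t":
            self.dim = 1 if connected else 0
        else:
            self.dim = self.R + (1 if connected else 0)
            if variable_bump:
                self.dim += 2

    # -- parameter unpacking ------------------------------------------------
    def _unpack(self, q):
        d = {}
        if self.kind == "t":
            d["w"] = expit(q[:, 0])
            return d
        d["rate"] = np.exp(q[:, : self.R])                  # (M, R)
        if self.connected:
            d["e"] = np.exp(q[:, self.R])                   # (M,)
        if self.variable_bump:
            d["center"] = np.exp(q[:, self.R + 1])
            lo, hi = self.priors.width_bounds
            d["width"] = lo + (hi - lo) * expit(q[:, self.R + 2])
            d["_width_raw"] = q[:, self.R + 2]
        return d

    # -- log posterior ------------------------------------------------------
    def logp(self, q):
        q = np.atleast_2d(q)
        p = self._unpack(q)
        data = self.data
        out = np.zeros(q.shape[0])

        if self.kind == "t":
            w = np.clip(p["w"], 1e-12, 1 - 1e-12)
            out += 2 * np.log(w) + 2 * np.log1p(-w) - betaln(2, 2)  # +jacobian
            dens = (w[:, None] * self.bump_pdf[None, :]
                    + (1 - w)[:, None] / EVOKED_WINDOW_MS)
            out += np.sum(np.log(np.clip(dens, 1e-300, None)), axis=1)
            return out

        rate = p["rate"]
        out += np.sum(_gamma_logpdf(rate, self.rate_k, self.rate_th)
                      + np.log(rate), axis=1)               # prior + jacobian
        if self.connected:
            e = p["e"]
            out += _gamma_logpdf(e, self.ev_k, self.ev_th) + np.log(e)
        if self.variable_bump:
            c = p["center"]
            out += _gamma_logpdf(c, self.c_k, self.c_th) + np.log(c)
            lo, hi = self.priors.width_bounds
            wdt, raw = p["width"], p["_width_raw"]
            s = expit(raw)
            out += (_gamma_logpdf(wdt, self.w_k, self.w_th)
                    + np.log((hi - lo) * s * (1 - s)))

        if self.kind in ("rt", "r"):
            r_s = rate[:, data.spont_repetition]            # (M, ns)
            out += np.sum(_poisson_ll(data.num_events_spont[None, :],
                                      r_s * data.spont_time_ms[None, :]),
                          axis=1)
            lam_e = rate[:, data.evoked_repetition] * data.evoked_time_ms
            if self.connected:
                lam_e = lam_e + p["e"][:, None]
            out += np.sum(_poisson_ll(data.num_events_evoked[None, :], lam_e),
                          axis=1)
        if self.kind == "rt" and len(data.event_times_ms):
            out += np.sum(self._event_ll(p), axis=1)
        return out

    def _event_ll(self, p):
        data = self.data
        if not self.connected:
            return np.full((len(p["rate"]), len(data.event_times_ms)),
                           -np.log(EVOKED_WINDOW_MS))
        r_ev = p["rate"][:, data.event_repetition]          # (M, m)
        e = p["e"][:, None]
        w = e / (e + r_ev * EVOKED_WINDOW_MS)
        if self.variable_bump:
            g = stats.norm.pdf(data.event_times_ms[None, :],
                               p["center"][:, None], p["width"][:, None])
        else:
            g = self.bump_pdf[None, :]
        dens = w * g + (1 - w) / EVOKED_WINDOW_MS
        return np.log(np.clip(dens, 1e-300, None))

    # -- pointwise log-likelihood for PSIS-LOO ------------------------------
    def pointwise(self, q):
        q = np.atleast_2d(q)
        p = self._unpack(q) if self.dim else {}
        data = self.data
        blocks = []
        if self.kind == "t":
            if self.dim:
                w = np.clip(p["w"], 1e-12, 1 - 1e-12)[:, None]
                dens = (w * self.bump_pdf[None, :]
                        + (1 - w) / EVOKED_WINDOW_MS)
            else:
                dens = np.full((q.shape[0] if q.size else 1,
                                len(data.event_times_ms)),
                               1.0 / EVOKED_WINDOW_MS)
            return np.log(np.clip(dens, 1e-300, None))
        rate = p["rate"]
        r_s = rate[:, data.spont_repetition]
        blocks.append(_poisson_ll(data.num_events_spont[None, :],
                                  r_s * data.spont_time_ms[None, :]))
        lam_e = rate[:, data.evoked_repetition] * data.evoked_time_ms
        if self.connected:
            lam_e = lam_e + p["e"][:, None]
        blocks.append(_poisson_ll(data.num_events_evoked[None, :], lam_e))
        if self.kind == "rt":
            blocks.append(self._event_ll(p))
        return np.concatenate(blocks, axis=1)

    def initial(self) -> np.ndarray:
        if self.kind == "t":
            return np.array([logit(0.3)])
        x = np.full(self.dim, np.log(max(self.data.empirical_spont_rate(),
                                         self.priors.rate_floor)))
        if self.connected:
            x[self.R] = np.log(self.priors.evoked_mu)
        if self.variable_bump:
            x[self.R + 1] = np.log(self.priors.center_mu)
            x[self.R + 2] = 0.0
        return x


def _fit_pair(data, priors, kind, config, seed_pair):
    """Fit a (not-connected, connected) model pair, return connected weight
    plus diagnostics."""
    m0 = _ConnModel(data, priors, kind, connected=False,
                    variable_bump=False)
    m1 = _ConnModel(data, priors, kind, connected=True, variable_bump=False)
    div, rhat_max = 0, 1.0
    elpds = []
    for model, seed in ((m0, seed_pair[0]), (m1, seed_pair[1])):
        if model.dim == 0:
            ll = model.pointwise(np.zeros((1, 0)))
            elpds.append(loo_elpd_pointwise(ll))
            continue
        cfg = SamplerConfig(n_tune=config.n_tune, n_draws=config.n_draws,
                            n_chains=config.n_chains,
                            target_accept=config.target_accept,
                            max_leapfrog=config.max_leapfrog, seed=seed)
        res = sample_hmc(model, cfg, init=model.initial())
        div += res.divergences
        rhat_max = max(rhat_max, float(np.max(split_rhat(res.draws))))
        ll = model.pointwise(res.flat())
        elpds.append(loo_elpd_pointwise(ll))
    if elpds[0].size == 0:          # no observations in this block
        return 0.5, div, rhat_max
    w = bb_pseudo_bma_weights(elpds, seed=seed_pair[0])
    return float(w[1]), div, rhat_max


def fit_connectivity_models(data: StimEpochData,
                            priors: ModelPriors | None = None,
                            config: SamplerConfig | None = None
                            ) -> ModelWeights:
    """Run the three connected-vs-not model comparisons for one target."""
    priors = priors or ModelPriors()
    config = config or SamplerConfig.fast()
    seeds = np.random.SeedSequence(config.seed).generate_state(6) % (2 ** 31)
    w_rt, d1, r1 = _fit_pair(data, priors, "rt", config, seeds[0:2])
    w_t, d2, r2 = _fit_pair(data, priors, "t", config, seeds[2:4])
    w_r, d3, r3 = _fit_pair(data, priors, "r", config, seeds[4:6])
    div = d1 + d2 + d3
    rhat = max(r1, r2, r3)
    return ModelWeights(w_rt=w_rt, w_t=w_t, w_r=w_r, divergences=div,
                        max_rhat=rhat,
                        unreliable=bool(div > 0.01 * config.n_draws
                                        * config.n_chains or rhat > 1.05))


def decide_connected(w: ModelWeights) -> bool:
    """Decision rule: (w_rt >= 0.5) and (w_t >= 0.4) and (w_r >= 0.4)."""
    for v in (w.w_rt, w.w_t, w.w_r):
        if not 0.0 <= v <= 1.0:
            raise ValueError("model weights must lie in [0, 1]")
    return bool(w.w_rt >= 0.5 and w.w_t >= 0.4 and w.w_r >= 0.4)


def fit_bump(data: StimEpochData, priors: ModelPriors | None = None,
             config: SamplerConfig | None = None) -> BumpFit:
    """Model 7: infer the latency bump's center and bounded width."""
    priors = priors or ModelPriors()
    config = config or SamplerConfig.fast()
    model = _ConnModel(data, priors, "rt", connected=True, variable_bump=True)
    res = sample_hmc(model, config, init=model.initial())
    flat = res.flat()
    R = model.R
    center = np.exp(flat[:, R + 1])
    lo, hi = priors.width_bounds
    width = lo + (hi - lo) * expit(flat[:, R + 2])
    rate = np.exp(flat[:, :R]).mean(axis=1)
    e = np.exp(flat[:, R])
    return BumpFit(
        bump_center_ms=float(np.median(center)),
        bump_width_ms=float(np.median(width)),
        spont_rate_per_ms=float(np.median(rate)),
        evoked_per_trial=float(np.median(e)),
        center_q=(float(np.quantile(center, 0.025)),
                  float(np.quantile(center, 0.975))),
        width_q=(float(np.quantile(width, 0.025)),
                 float(np.quantile(width, 0.975))),
        draws=flat, divergences=res.divergences)


# ---------------------------------------------------------------------------
# connection strength
# ---------------------------------------------------------------------------

def stimulation_strengths(events: pd.DataFrame, schedule, target_id: int,
                          bump: BumpFit,
                          window_ms: tuple[float, float] = STRENGTH_WINDOW_MS
                          ) -> tuple[np.ndarray, float]:
    """Bump-weighted EPSC amplitude per stimulation and the per-connection
    mean.

    For each stimulus, events with latency in [2, 30) ms are averaged with
    weights equal to the normal bump density at their latency; stimuli with
    no in-window events contribute strength 0.
    """
    pulses = schedule.pulse_times(target_id).time_s.to_numpy() * 1000.0
    onsets = events.onset_ms.to_numpy()
    heights = events.height_pa.to_numpy()
    strengths = np.zeros(len(pulses))
    for i, t0 in enumerate(pulses):
        rel = onsets - t0
        sel = (rel >= window_ms[0]) & (rel < window_ms[1])
        if not np.any(sel):
            continue
        phi = stats.norm.pdf(rel[sel], bump.bump_center_ms,
                             bump.bump_width_ms)
        if phi.sum() <= 0:
            phi = np.ones(sel.sum())
        strengths[i] = float(np.sum(heights[sel] * phi) / np.sum(phi))
    return strengths, float(strengths.mean()) if len(strengths) else 0.0


# ---------------------------------------------------------------------------
# population PSTH mixture
# ---------------------------------------------------------------------------

def fit_psth_mixture(latencies_ms: np.ndarray,
                     window_ms: float = EVOKED_WINDOW_MS) -> MixturePsthFit:
    """Maximum-likelihood gamma + uniform mixture fit of pooled latencies.

    Density w * Gamma(k, theta) + (1 - w) * Uniform(0, window); confidence
    intervals from the observed information (finite-difference Hessian of
    the negative log-likelihood at the optimum).
    """
    t = np.asarray(latencies_ms, float)
    if len(t) < 100:
        raise ValueError("need at least 100 latencies")
    if np.any((t < 0) | (t > window_ms)):
        raise ValueError("latencies must lie within the window")
    u = 1.0 / window_ms
    tp = np.clip(t, 1e-9, None)

    def nll_natural(theta):
        k, sc, w = theta
        g = stats.gamma.pdf(tp, k, scale=sc)
        return -np.sum(np.log(np.clip(w * g + (1 - w) * u, 1e-300, None)))

    def nll_trans(x):
        return nll_natural((np.exp(x[0]), np.exp(x[1]), expit(x[2])))

    x0 = np.array([np.log(4.0), np.log(3.0), logit(0.1)])
    res = optimize.minimize(nll_trans, x0, method="Nelder-Mead",
                            options=dict(maxiter=4000, xatol=1e-8,
                                         fatol=1e-10))
    res = optimize.minimize(nll_trans, res.x, method="BFGS")
    k, sc, w = np.exp(res.x[0]), np.exp(res.x[1]), float(expit(res.x[2]))

    degenerate = w < 1e-4
    theta = np.array([k, sc, w])
    se = np.full(3, np.nan)
    if not degenerate:
        hess = _fd_hessian(nll_natural, theta)
        try:
            cov = np.linalg.inv(hess)
            diag = np.diag(cov)
            se = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:
            pass
    ci = [(float(v - 1.96 * s), float(v + 1.96 * s)) if np.isfinite(s)
          else (np.nan, np.nan) for v, s in zip(theta, se)]
    return MixturePsthFit(shape=float(k), scale_ms=float(sc), weight=w,
                          shape_ci=ci[0], scale_ci=ci[1], weight_ci=ci[2],
                          loglik=-float(res.fun), degenerate=degenerate)


def _fd_hessian(f, x, rel=1e-4):
    n = len(x)
    h = np.maximum(np.abs(x), 1e-3) * rel
    hess = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                val = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                val = (f(x + ei + ej) - f(x + ei - ej)
                       - f(x - ei + ej) + f(x - ei - ej)) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


# ---------------------------------------------------------------------------
# population connected-fraction estimate
# ---------------------------------------------------------------------------

def estimate_connected_fraction(total_events: float, bump_fraction: float,
                                n_stimulated: float, mean_stimulations: float,
                                evoked_per_stim: float) -> float:
    """Estimated fraction of connected cells, c = E*f / (N*n*e_p).

    ``total_events`` (E) is the pooled EPSC count, ``bump_fraction`` (f) the
    gamma-component weight of the PSTH mixture, ``n_stimulated`` (N) the
    number of stimulated cells, ``mean_stimulations`` (n) the average
    stimulations per cell and ``evoked_per_stim`` (e_p) the assumed evoked
    events per stimulation for a connected cell.
    """
    if not 0 <= bump_fraction <= 1:
        raise ValueError("bump fraction must lie in [0, 1]")
    denom = n_stimulated * mean_stimulations * evoked_per_stim
    if denom <= 0:
        raise ValueError("N * n * e_p must be positive")
    if total_events < 0:
        raise ValueError("event count must be nonnegative")
    return total_events * bump_fraction / denom


# ---------------------------------------------------------------------------
# end-to-end per-target call
# ---------------------------------------------------------------------------

def infer_target(events: pd.DataFrame, schedule, target_id: int,
                 priors: ModelPriors | None = None,
                 config: SamplerConfig | None = None,
                 override: bool | None = None) -> ConnectivityCall:
    """Segment, compare models, decide, and (if connected) fit the bump and
    measure strengths for one stimulated target.

    ``override`` forces the connectivity call (manual-curation hook).
    """
    data = segment_epochs(events, schedule, target_id)
    weights = fit_connectivity_models(data, priors, config)
    connected = decide_connected(weights) if override is None else override
    bump, strength, per_stim = None, 0.0, None
    if connected:
        bump = fit_bump(data, priors, config)
        per_stim, strength = stimulation_strengths(events, schedule,
                                                   target_id, bump)
    return ConnectivityCall(target_id=target_id, weights=weights,
                            connected=connected, bump=bump,
                            strength_pa=strength,
                            per_stimulation_pa=per_stim)
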