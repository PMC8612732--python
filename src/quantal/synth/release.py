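"""Stochastic per-active-zone release model with docking-site depletion and
refill.

Each active zone (AZ) carries ``slots_per_az`` docking sites. On every
stimulus an occupied site fuses its vesicle with probability
``p_eff = p_v * (1 - theta)``, where ``theta`` is a Tomosyn-like inhibition
factor: high ``theta`` throttles vesicle usage, producing tonic (low-Pr,
depression-resistant) output; low ``theta`` yields phasic (high-Pr, rapidly
depressing) output. Between stimuli each empty site refills with probability
``rho``. The per-site occupancy therefore evolves as

    o <- o * (1 - p_eff)            (release)
    o <- o + (1 - o) * rho          (refill before the next stimulus)

whose fixed point is ``o* = rho / (1 - (1 - p_eff)(1 - rho))``; the expected
steady-state release rate per site is ``o* * p_eff``.

Released vesicles receive latencies from a synchronous Gaussian
(``sync_mu``, ``sync_sigma``) with probability ``1 - f_async`` and from an
asynchronous exponential (``tau_async``) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .._rng import derive_rng
from ..datatypes import StimProtocol

__all__ = [
    "ReleaseModelParams",
    "ReleaseRecord",
    "simulate_release",
    "steady_state_occupancy",
    "expected_occupancy_trajectory",
    "expected_cumulative_line",
]


@dataclass
class ReleaseModelParams:
    """Parameters of the release model and of trace rendering.

    Probabilities are per stimulus (``p_v``) or per interstimulus interval
    (``rho``). Quantal-current parameters (``q_mean`` in nA, ``tau_rise`` /
    ``tau_decay`` in ms) describe the single-vesicle waveform; ``mini_rate``
    (Hz) and ``noise_sigma`` (nA) describe spontaneous events and recording
    noise. Defaults emulate a control tonic (Ib-like) terminal: ~300 AZs,
    quantal size 0.58 nA, mini rate 2.7 Hz.
    """

    n_az: int = 300
    slots_per_az: int = 1
    p_v: float = 0.5
    theta: float = 0.0
    rho: float = 0.5
    pr_heterogeneity: tuple[float, float] | None = None
    theta_scales_refill: bool = False
    q_mean: float = 0.58
    q_cv: float = 0.3
    tau_rise: float = 1.0
    tau_decay: float = 6.0
    sync_mu: float = 1.5
    sync_sigma: float = 0.3
    f_async: float = 0.1
    tau_async: float = 30.0
    mini_rate: float = 2.7
    noise_sigma: float = 0.05
    fs: float = 10_000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("p_v", "theta", "rho", "f_async"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.n_az < 1:
            raise ValueError(f"n_az must be >= 1, got {self.n_az!r}")
        if self.slots_per_az < 1:
            raise ValueError(f"slots_per_az must be >= 1, got {self.slots_per_az!r}")
        if not (np.isfinite(self.q_mean) and self.q_mean > 0):
            raise ValueError(f"q_mean must be positive, got {self.q_mean!r}")
        if self.q_cv < 0:
            raise ValueError(f"q_cv must be >= 0, got {self.q_cv!r}")
        if not (0 < self.tau_rise < self.tau_decay):
            raise ValueError(
                f"need tau_decay > tau_rise > 0, got tau_rise={self.tau_rise!r}, "
                f"tau_decay={self.tau_decay!r}")
        for name in ("sync_sigma", "tau_async", "mini_rate", "noise_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be >= 0 and finite, got {v!r}")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs!r}")
        if self.pr_heterogeneity is not None:
            a, b = self.pr_heterogeneity
            if a <= 0 or b <= 0:
                raise ValueError(f"pr_heterogeneity shapes must be positive, got {self.pr_heterogeneity!r}")
            if self.slots_per_az != 1:
                raise ValueError("pr_heterogeneity requires slots_per_az = 1")

    @property
    def p_eff(self) -> float:
        """Effective per-site fusion probability ``p_v * (1 - theta)``."""
        return self.p_v * (1.0 - self.theta)

    @property
    def rho_eff(self) -> float:
        """Refill probability, optionally scaled by the inhibition factor."""
        return self.rho * (1.0 - self.theta) if self.theta_scales_refill else self.rho

    def with_(self, **kwargs) -> "ReleaseModelParams":
        return replace(self, **kwargs)


@dataclass
class ReleaseRecord:
    """Ground-truth record of a simulated release run.

    ``vesicles`` has one row per released vesicle with columns
    ``stimulus`` (0-based index), ``az`` (0-based AZ id) and ``latency_ms``
    (relative to the stimulus). ``occupancy_pre`` holds the mean site
    occupancy immediately before each stimulus; ``counts`` the per-stimulus,
    per-AZ release counts.
    """

    vesicles: pd.DataFrame
    occupancy_pre: np.ndarray
    counts: np.ndarray
    params: ReleaseModelParams
    protocol: StimProtocol
    az_p_eff: np.ndarray = field(default=None)  # per-AZ p_eff actually used

    @property
    def n_released(self) -> int:
        return len(self.vesicles)

    @property
    def releases_per_stimulus(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def event_times(self) -> np.ndarray:
        """Absolute release times in seconds."""
        stim_t = self.protocol.stim_times[self.vesicles["stimulus"].to_numpy()]
        return stim_t + self.vesicles["latency_ms"].to_numpy() / 1000.0


def steady_state_occupancy(p_eff: float, rho: float) -> float:
    """Fixed point ``o* = rho / (1 - (1 - p_eff)(1 - rho))`` of the
    deplete-then-refill site dynamics."""
    denom = 1.0 - (1.0 - p_eff) * (1.0 - rho)
    if denom == 0.0:  # p_eff == rho == 0: any occupancy is stationary
        return 1.0
    return rho / denom

def expected_occupancy_trajectory(p_eff: float, rho: float, n_stims: int) -> np.ndarray:
    """Expected pre-stimulus occupancy o_n for n = 1..n_stims (o_1 = 1)."""
    o_star = steady_state_occupancy(p_eff, rho)
    lam = (1.0 - p_eff) * (1.0 - rho)
    n = np.arange(n_stims)
    return o_star + (1.0 - o_star) * lam**n


def expected_cumulative_line(params: ReleaseModelParams) -> tuple[float, float]:
    """Asymptote of expected cumulative release vs stimulus number.

    Returns ``(intercept, slope)`` of the line the cumulative-quanta curve
    approaches at steady state: slope ``N * p_eff * o*`` (quanta/stimulus)
    and intercept ``N * p_eff * (1 - o*) / (1 - lambda)`` with
    ``lambda = (1 - p_eff)(1 - rho)`` — the closed-form target of
    back-extrapolation estimates of the releasable pool.
    """
    n_sites = params.n_az * params.slots_per_az
    p, r = params.p_eff, params.rho_eff
    o_star = steady_state_occupancy(p, r)
    lam = (1.0 - p) * (1.0 - r)
    slope = n_sites * p * o_star
    intercept = n_sites * p * (1.0 - o_star) / (1.0 - lam) if lam < 1.0 else 0.0
    return intercept, slope


def simulate_release(params: ReleaseModelParams, protocol: StimProtocol,
                     rng: np.random.Generator | None = None) -> ReleaseRecord:
    """Simulate per-AZ vesicle release over a stimulation protocol.

    Sites start fully occupied. Returns the ground-truth release record; all
    draws come from ``params.seed`` (stream ``"release"``) unless an explicit
    ``rng`` is supplied.
    """
    params.validate()
    if protocol.n_stims < 1:
        raise ValueError("protocol must contain at least one stimulus")
    if rng is None:
        rng = derive_rng(params.seed, "release")

    n_az, slots = params.n_az, params.slots_per_az
    if params.pr_heterogeneity is not None:
        a, b = params.pr_heterogeneity
        az_p = rng.beta(a, b, size=n_az)
    else:
        az_p = np.full(n_az, params.p_eff)
    rho = params.rho_eff

    occ = np.ones((n_az, slots), dtype=bool)
    n_stims = protocol.n_stims
    counts = np.zeros((n_stims, n_az), dtype=np.int32)
    occupancy_pre = np.empty(n_stims)
    p_mat = az_p[:, None]

    for s in range(n_stims):
        occupancy_pre[s] = occ.mean()
        fused = occ & (rng.random(occ.shape) < p_mat)
        counts[s] = fused.sum(axis=1)
        occ &= ~fused
        if s < n_stims - 1:
            occ |= (~occ) & (rng.random(occ.shape) < rho)

    total = int(counts.sum())
    per_stim = counts.sum(axis=1)
    stim_idx = np.repeat(np.arange(n_stims), per_stim)
    az_idx = np.concatenate(
        [np.repeat(np.arange(n_az), counts[s]) for s in range(n_stims)]
    ) if total else np.empty(0, dtype=int)

    is_async = rng.random(total) < params.f_async
    lat = np.empty(total)
    n_async = int(is_async.sum())
    lat[is_async] = params.sync_mu + rng.exponential(params.tau_async, size=n_async)
    lat[~is_async] = rng.normal(params.sync_mu, params.sync_sigma, size=total - n_async)
    np.clip(lat, 0.0, None, out=lat)

    vesicles = pd.DataFrame({
        "stimulus": stim_idx.astype(np.int32),
        "az": az_idx.astype(np.int32),
        "latency_ms": lat,
    })
    return ReleaseRecord(vesicles=vesicles, occupancy_pre=occupancy_pre,
                         counts=counts, params=params, protocol=protocol,
                         az_p_eff=az_p)
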