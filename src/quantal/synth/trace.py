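"""Render release records as voltage-clamp current traces.

Each released vesicle contributes a quantal current: a difference-of-
exponentials waveform ``exp(-t/tau_decay) - exp(-t/tau_rise)`` normalized to
unit peak on the sampling grid, scaled by an amplitude drawn as
``q_mean * (1 + q_cv * N(0, 1))`` (clipped at zero). Spontaneous minis are a
homogeneous Poisson process with the same amplitude law. Superposition is
linear; Gaussian recording noise is added last. Inward currents are negative.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .._rng import derive_rng
from ..datatypes import StimProtocol, Trace
from .release import ReleaseModelParams, ReleaseRecord

__all__ = ["quantal_kernel", "kernel_charge", "synthesize_trace", "synthesize_mini_trace"]


def quantal_kernel(tau_rise: float, tau_decay: float, fs: float,
                   n_tau: float = 10.0) -> np.ndarray:
    """Unit-peak quantal waveform sampled at ``fs``.

    Peak-normalized on the sampling grid so that a grid-aligned event of
    amplitude ``q`` produces a trace extremum of exactly ``q``.
    """
    if tau_decay <= tau_rise or tau_rise <= 0:
        raise ValueError("need tau_decay > tau_rise > 0")
    dt_ms = 1000.0 / fs
    if dt_ms > tau_rise / 2.0:
        raise ValueError(
            f"fs={fs} Hz too low to resolve tau_rise={tau_rise} ms "
            f"(sample step {dt_ms:.3f} ms > tau_rise/2)")
    t = np.arange(0.0, n_tau * tau_decay, dt_ms)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def kernel_charge(params: ReleaseModelParams) -> float:
    """Charge (nA*ms) of a unit-amplitude quantal waveform at ``params.fs``."""
    k = quantal_kernel(params.tau_rise, params.tau_decay, params.fs)
    return float(k.sum() * 1000.0 / params.fs)


def _add_events(impulses: np.ndarray, times_s: np.ndarray, amps: np.ndarray,
                fs: float, t0: float) -> None:
    idx = np.round((times_s - t0) * fs).astype(int)
    keep = (idx >= 0) & (idx < impulses.size)
    np.add.at(impulses, idx[keep], amps[keep])


def synthesize_trace(record: ReleaseRecord, params: ReleaseModelParams | None = None,
                     protocol: StimProtocol | None = None,
                     duration: float | None = None,
                     rng: np.random.Generator | None = None) -> Trace:
    """Render a release record as a Trace (evoked quanta + minis + noise)."""
    params = params or record.params
    protocol = protocol or record.protocol
    if rng is None:
        rng = derive_rng(params.seed, "trace")
    fs = params.fs
    if duration is None:
        duration = float(protocol.stim_times[-1]) + 0.3
    n = int(round(duration * fs))
    impulses = np.zeros(n)

    ev_times = record.event_times()
    q = params.q_mean * (1.0 + params.q_cv * rng.standard_normal(ev_times.size))
    np.clip(q, 0.0, None, out=q)
    _add_events(impulses, ev_times, q, fs, 0.0)

    if params.mini_rate > 0:
        n_minis = rng.poisson(params.mini_rate * duration)
        mt = rng.uniform(0.0, duration, size=n_minis)
        mq = params.q_mean * (1.0 + params.q_cv * rng.standard_normal(n_minis))
        np.clip(mq, 0.0, None, out=mq)
        _add_events(impulses, mt, mq, fs, 0.0)

    kernel = quantal_kernel(params.tau_rise, params.tau_decay, fs)
    current = -fftconvolve(impulses, kernel)[:n]
    if params.noise_sigma > 0:
        current += params.noise_sigma * rng.standard_normal(n)
    meta = {"kind": "synthetic", "modality": protocol.modality}
    return Trace(current, fs=fs, metadata=meta)


def synthesize_mini_trace(params: ReleaseModelParams, duration: float,
                          rng: np.random.Generator | None = None
                          ) -> tuple[Trace, np.ndarray]:
    """Stimulus-free trace of spontaneous minis; also returns true mini times.

    Useful ground truth for validating mini detection: returns the trace and
    the sorted vector of true event onset times (seconds).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = derive_rng(params.seed, "mini-trace")
    fs = params.fs
    n = int(round(duration * fs))
    impulses = np.zeros(n)
    n_minis = rng.poisson(params.mini_rate * duration)
    mt = np.sort(rng.uniform(0.0, duration, size=n_minis))
    mq = params.q_mean * (1.0 + params.q_cv * rng.standard_normal(n_minis))
    np.clip(mq, 0.0, None, out=mq)
    _add_events(impulses, mt, mq, fs, 0.0)
    kernel = quantal_kernel(params.tau_rise, params.tau_decay, fs)
    current = -fftconvolve(impulses, kernel)[:n]
    if params.noise_sigma > 0:
        current += params.noise_sigma * rng.standard_normal(n)
    return Trace(current, fs=fs, metadata={"kind": "synthetic-minis"}), mt
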