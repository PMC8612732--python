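"""Synthetic Ca2+-indicator movies of per-active-zone quantal release.

Each released vesicle produces a postsynaptic indicator flash: a 2-D
Gaussian (SD ``psf_sigma`` px, peak ``df_quantum``) centred on its AZ in the
frame containing the release time, decaying exponentially over subsequent
frames with constant ``indicator_decay`` (frames). Baseline fluorescence is
``f0`` everywhere; Gaussian read noise (and optional Poisson photon noise)
is applied last. A two-channel reference stack marks the PSD positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._rng import derive_rng
from .release import ReleaseRecord

__all__ = ["SyntheticMovieParams", "synthesize_movie", "synthesize_reference_stack",
           "grid_az_positions"]


@dataclass
class SyntheticMovieParams:
    """Imaging parameters of the synthetic movie.

    ``az_positions`` are (x, y) pixel coordinates, one per AZ; ``stim_frames``
    the frame indices containing the stimuli (derived from the protocol with
    ``frames_for_protocol``). ``indicator_decay`` is the exponential decay
    constant in frames. Defaults mirror 8 Hz imaging at 0.26 µm/px.
    """

    az_positions: np.ndarray
    shape: tuple[int, int]
    n_frames: int
    frame_rate: float = 8.0
    psf_sigma: float = 1.5
    f0: float = 100.0
    df_quantum: float = 50.0
    indicator_decay: float = 2.0
    noise_sigma: float = 10.0
    poisson_noise: bool = False
    pixel_size: float = 0.26
    stim_frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.az_positions = np.atleast_2d(np.asarray(self.az_positions, dtype=float))
        self.stim_frames = np.asarray(self.stim_frames, dtype=int)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        h, w = self.shape
        x, y = self.az_positions[:, 0], self.az_positions[:, 1]
        if np.any(x < 0) or np.any(x >= w) or np.any(y < 0) or np.any(y >= h):
            raise ValueError("az_positions must lie within the image bounds")
        if len(self.az_positions) > 1:
            d2 = ((self.az_positions[:, None, :] - self.az_positions[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            if d2.min() < 1.0:
                raise ValueError("two AZ positions are closer than 1 px: ground truth unresolvable")

    @property
    def n_az(self) -> int:
        return len(self.az_positions)


def grid_az_positions(n_az: int, spacing: float = 9.0, margin: float = 8.0
                      ) -> tuple[np.ndarray, tuple[int, int]]:
    """Lay out ``n_az`` positions on a square grid; returns (positions, shape)."""
    n_cols = int(np.ceil(np.sqrt(n_az)))
    n_rows = int(np.ceil(n_az / n_cols))
    xs = margin + spacing * np.arange(n_cols)
    ys = margin + spacing * np.arange(n_rows)
    xx, yy = np.meshgrid(xs, ys)
    pos = np.column_stack([xx.ravel(), yy.ravel()])[:n_az]
    shape = (int(ys[-1] + margin) + 1, int(xs[-1] + margin) + 1)
    return pos, shape


def frames_for_protocol(stim_times_s: np.ndarray, frame_rate: float) -> np.ndarray:
    """Frame index containing each stimulus time."""
    return np.floor(np.asarray(stim_times_s) * frame_rate).astype(int)


def _gauss_patch(sigma: float) -> tuple[np.ndarray, int]:
    r = max(2, int(np.ceil(4 * sigma)))
    ax = np.arange(-r, r + 1)
    xx, yy = np.meshgrid(ax, ax)
    return np.exp(-(xx**2 + yy**2) / (2 * sigma**2)), r


def synthesize_movie(record: ReleaseRecord, movie_params: SyntheticMovieParams,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a release record as a movie stack plus ground-truth event list.

    Returns ``(stack, truth)``: ``stack`` is float32 of shape
    (n_frames, H, W); ``truth`` has one row per released vesicle with columns
    ``frame``, ``az_id``, ``x_px``, ``y_px``, ``stimulus``.
    """
    mp = movie_params
    if mp.n_az != record.params.n_az:
        raise ValueError(
            f"movie has {mp.n_az} AZ positions but release record has "
            f"{record.params.n_az} AZs")
    if rng is None:
        rng = derive_rng(record.params.seed, "movie")

    stim_frames = mp.stim_frames
    if stim_frames.size == 0:
        stim_frames = frames_for_protocol(record.protocol.stim_times, mp.frame_rate)
    ev_frames = frames_for_protocol(record.event_times(), mp.frame_rate)
    az_ids = record.vesicles["az"].to_numpy()
    keep = ev_frames < mp.n_frames
    ev_frames, az_ids = ev_frames[keep], az_ids[keep]
    stim_of_event = record.vesicles["stimulus"].to_numpy()[keep]

    h, w = mp.shape
    stack = np.full((mp.n_frames, h, w), mp.f0, dtype=np.float32)

    # per-AZ amplitude time series: impulse + exponential indicator decay
    n_decay = max(1, int(np.ceil(6 * mp.indicator_decay)))
    decay = np.exp(-np.arange(n_decay + 1) / mp.indicator_decay).astype(np.float32)
    patch, r = _gauss_patch(mp.psf_sigma)
    patch = patch.astype(np.float32)

    for az in np.unique(az_ids):
        frames_az = ev_frames[az_ids == az]
        amp = np.zeros(mp.n_frames + n_decay + 1, dtype=np.float32)
        np.add.at(amp, frames_az, mp.df_quantum)
        series = np.convolve(amp, decay)[: mp.n_frames]
        nz = np.nonzero(series > 1e-3 * mp.df_quantum)[0]
        if nz.size == 0:
            continue
        x, y = mp.az_positions[az]
        xi, yi = int(round(x)), int(round(y))
        y0, y1 = max(0, yi - r), min(h, yi + r + 1)
        x0, x1 = max(0, xi - r), min(w, xi + r + 1)
        sub = patch[(y0 - yi + r):(y1 - yi + r), (x0 - xi + r):(x1 - xi + r)]
        stack[nz, y0:y1, x0:x1] += series[nz, None, None] * sub

    if mp.poisson_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(np.float32)
    if mp.noise_sigma > 0:
        for f0_ in range(0, mp.n_frames, 512):  # chunked to bound memory
            f1 = min(mp.n_frames, f0_ + 512)
            stack[f0_:f1] += mp.noise_sigma * rng.standard_normal(
                (f1 - f0_, h, w)).astype(np.float32)

    truth = pd.DataFrame({
        "frame": ev_frames.astype(int),
        "az_id": az_ids.astype(int),
        "x_px": mp.az_positions[az_ids, 0],
        "y_px": mp.az_positions[az_ids, 1],
        "stimulus": stim_of_event.astype(int),
    })
    return stack, truth


def synthesize_reference_stack(mp: SyntheticMovieParams, spot_amplitude: float = 200.0,
                               spot_sigma: float | None = None,
                               noise_sigma: float = 10.0,
                               rng: np.random.Generator | None = None) -> np.ndarray:
    """Two-channel reference image: channel 0 marks PSD spots, channel 1 the
    baseline indicator. Shape (2, H, W)."""
    if rng is None:
        rng = np.random.default_rng(0)
    sigma = spot_sigma if spot_sigma is not None else mp.psf_sigma
    h, w = mp.shape
    ref = np.zeros((2, h, w), dtype=np.float32)
    patch, r = _gauss_patch(sigma)
    for x, y in mp.az_positions:
        xi, yi = int(round(x)), int(round(y))
        y0, y1 = max(0, yi - r), min(h, yi + r + 1)
        x0, x1 = max(0, xi - r), min(w, xi + r + 1)
        ref[0, y0:y1, x0:x1] += spot_amplitude * patch[
            (y0 - yi + r):(y1 - yi + r), (x0 - xi + r):(x1 - xi + r)]
    ref[1] = mp.f0
    ref += noise_sigma * rng.standard_normal(ref.shape).astype(np.float32)
    return ref
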