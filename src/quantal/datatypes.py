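"""Core data containers: voltage-clamp traces, stimulation protocols and
EM annotations.

Conventions
-----------
* Currents are stored in nA with inward (synaptic) current **negative**;
  figure-style positive display is a rendering choice only.
* Traces are uniformly sampled; time is implicit (``t0 + i / fs``).
* EM coordinates are continuous, in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["Trace", "StimProtocol", "EMAnnotation"]


@dataclass
class Trace:
    """Uniformly sampled membrane-current recording.

    Parameters
    ----------
    current : ndarray
        Current in nA, inward negative.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    metadata : dict
        Free-form labels (genotype, condition, ...).
    """

    current: np.ndarray
    fs: float
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.current.ndim != 1:
            raise ValueError("current must be one-dimensional")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("fs must be positive and finite")

    @property
    def n_samples(self) -> int:
        return self.current.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds (uniform grid)."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def index_of(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (seconds)."""
        idx = int(round((t - self.t0) * self.fs))
        if idx < 0 or idx >= self.n_samples:
            raise ValueError(f"time {t} s outside trace [{self.t0}, {self.t0 + self.duration}] s")
        return idx

    def to_csv(self, path: str | Path) -> None:
        """Write a two-column CSV (time_s, current_nA)."""
        df = pd.DataFrame({"time_s": self.time, "current_nA": self.current})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, metadata: dict | None = None) -> "Trace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError("trace CSV must contain at least two samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12) or dt[0] <= 0:
            raise ValueError("trace CSV must be uniformly sampled with increasing time")
        return cls(df["current_nA"].to_numpy(dtype=float), fs=1.0 / dt[0], t0=float(t[0]),
                   metadata=metadata or {})


@dataclass
class StimProtocol:
    """Stimulation times for electrical or optical stimulation."""

    stim_times: np.ndarray
    frequency: float
    modality: str = "electrical"

    def __post_init__(self) -> None:
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.stim_times.ndim != 1 or self.stim_times.size == 0:
            raise ValueError("stim_times must be a non-empty 1-D array")
        if np.any(np.diff(self.stim_times) <= 0):
            raise ValueError("stim_times must be strictly increasing")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.modality not in ("electrical", "optical"):
            raise ValueError("modality must be 'electrical' or 'optical'")

    @property
    def n_stims(self) -> int:
        return self.stim_times.size

    @classmethod
    def periodic(cls, n_stims: int, frequency: float, start: float = 0.1,
                 modality: str = "electrical") -> "StimProtocol":
        """Regular train: ``n_stims`` stimuli at ``frequency`` Hz from ``start`` s."""
        if n_stims < 1:
            raise ValueError("n_stims must be >= 1")
        times = start + np.arange(n_stims) / frequency
        return cls(times, frequency=frequency, modality=modality)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "frequency_hz": float(self.frequency),
            "modality": self.modality,
            "stim_times_s": [float(t) for t in self.stim_times],
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StimProtocol":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(np.asarray(payload["stim_times_s"], dtype=float),
                   frequency=float(payload["frequency_hz"]),
                   modality=payload.get("modality", "electrical"))


@dataclass
class EMAnnotation:
    """Annotated single EM section of a presynaptic bouton.

    ``sv_centers`` are SV center points (nm), ``tbar`` the T-bar base point,
    ``az_density`` the contoured electron-dense active-zone line (polyline of
    >= 2 points, nm). ``bouton_area`` is in µm²; ``nm_per_px`` records the
    calibration used to convert pixel annotations to nm.
    """

    sv_centers: np.ndarray
    tbar: np.ndarray
    az_density: np.ndarray
    sv_diameters: np.ndarray | None = None
    bouton_area: float | None = None
    nm_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.sv_centers = np.atleast_2d(np.asarray(self.sv_centers, dtype=float))
        self.tbar = np.asarray(self.tbar, dtype=float).reshape(2)
        self.az_density = np.atleast_2d(np.asarray(self.az_density, dtype=float))
        if self.az_density.shape[0] < 2 or self.az_density.shape[1] != 2:
            raise ValueError("az_density polyline needs >= 2 points of shape (n, 2)")
        for name in ("sv_centers", "tbar", "az_density"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite coordinates")
        if self.sv_diameters is not None:
            self.sv_diameters = np.asarray(self.sv_diameters, dtype=float)
            if self.sv_diameters.size != self.sv_centers.shape[0]:
                raise ValueError("sv_diameters length must match sv_centers")
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px calibration must be positive")

    @property
    def n_sv(self) -> int:
        return self.sv_centers.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """CSV with a calibration header and one row per annotated feature."""
        rows = []
        for i, (x, y) in enumerate(self.sv_centers):
            d = float(self.sv_diameters[i]) if self.sv_diameters is not None else np.nan
            rows.append(("sv", x, y, d))
        rows.append(("tbar", self.tbar[0], self.tbar[1], np.nan))
        for x, y in self.az_density:
            rows.append(("az_density", x, y, np.nan))
        df = pd.DataFrame(rows, columns=["kind", "x_nm", "y_nm", "diameter_nm"])
        with open(path, "w") as fh:
            fh.write(f"# nm_per_px: {self.nm_per_px}\n")
            if self.bouton_area is not None:
                fh.write(f"# bouton_area_um2: {self.bouton_area}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EMAnnotation":
        nm_per_px, bouton_area = 1.0, None
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if not line.startswith("#"):
                break
            body_start += 1
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "nm_per_px":
                nm_per_px = float(val)
            elif key.strip() == "bouton_area_um2":
                bouton_area = float(val)
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])))
        sv = df[df.kind == "sv"]
        tbar = df[df.kind == "tbar"]
        az = df[df.kind == "az_density"]
        if len(tbar) != 1:
            raise ValueError("annotation CSV must contain exactly one tbar row")
        diam = sv["diameter_nm"].to_numpy(dtype=float)
        return cls(
            sv_centers=sv[["x_nm", "y_nm"]].to_numpy(dtype=float),
            tbar=tbar[["x_nm", "y_nm"]].to_numpy(dtype=float)[0],
            az_density=az[["x_nm", "y_nm"]].to_numpy(dtype=float),
            sv_diameters=None if np.all(np.isnan(diam)) else diam,
            bouton_area=bouton_area,
            nm_per_px=nm_per_px,
        )
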