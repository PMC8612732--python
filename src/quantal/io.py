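"""File IO: TIFF movie stacks, event tables, and simulation configs.

Traces travel as two-column CSV (``time_s``, ``current_nA``) via
``Trace.to_csv`` / ``Trace.from_csv``; stimulation protocols as YAML
sidecars; EM annotations as calibrated CSV via ``EMAnnotation``. Movies are
written as multipage 16-bit TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .datatypes import StimProtocol
from .synth.release import ReleaseModelParams

__all__ = ["save_movie", "load_movie", "load_sim_config"]


def save_movie(path: str | Path, stack: np.ndarray) -> None:
    """Write a (T, H, W) stack as multipage uint16 TIFF (values clipped)."""
    data = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)


def load_movie(path: str | Path) -> np.ndarray:
    """Read a multipage TIFF as float32 (T, H, W)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.float32)


def load_sim_config(path: str | Path, seed: int | None = None
                    ) -> tuple[ReleaseModelParams, StimProtocol, dict]:
    """Parse a simulation config file.

    YAML with a ``release`` mapping (ReleaseModelParams fields), a
    ``protocol`` mapping (``n_stims``, ``frequency_hz``, optional ``start_s``
    and ``modality``) and an optional ``movie`` mapping passed through as a
    dict. A ``seed`` argument overrides the config seed.
    """
    payload = yaml.safe_load(Path(path).read_text()) or {}
    rel = dict(payload.get("release", {}))
    if seed is not None:
        rel["seed"] = int(seed)
    params = ReleaseModelParams(**rel)
    prot_cfg = payload.get("protocol", {})
    protocol = StimProtocol.periodic(
        int(prot_cfg.get("n_stims", 1)),
        float(prot_cfg.get("frequency_hz", 0.33)),
        start=float(prot_cfg.get("start_s", 0.1)),
        modality=prot_cfg.get("modality", "electrical"),
    )
    return params, protocol, dict(payload.get("movie", {}))
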