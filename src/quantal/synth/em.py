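"""Synthetic single-section EM annotations with a known docked subpopulation.

Vesicle centers are placed relative to a curved active-zone electron-density
polyline: docked vesicles at < 50 nm from the polyline, the remainder beyond
a 60 nm guard band, with a minimum center-to-center spacing of one vesicle
diameter. The construction records ground-truth docked ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import derive_rng
from ..datatypes import EMAnnotation

__all__ = ["EMGeometry", "synthesize_em"]

DOCKED_THRESHOLD_NM = 50.0
GUARD_BAND_NM = 60.0


@dataclass
class EMGeometry:
    """Geometry of the synthetic bouton section (all lengths nm)."""

    az_length: float = 400.0
    az_sag: float = 30.0          # arc depth of the AZ density polyline
    az_points: int = 9
    bouton_radius: float = 600.0  # extent of the SV field above the AZ
    sv_diameter_mean: float = 33.0
    sv_diameter_sd: float = 3.0
    docked_min_dist: float = 8.0  # membrane offset of docked centers


def _polyline(geom: EMGeometry) -> np.ndarray:
    x = np.linspace(-geom.az_length / 2, geom.az_length / 2, geom.az_points)
    y = -geom.az_sag * (1 - (2 * x / geom.az_length) ** 2)
    return np.column_stack([x, y])


def _dist_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    p = np.atleast_2d(points)
    a, b = poly[:-1], poly[1:]
    ab = b - a
    ap = p[:, None, :] - a[None, :, :]
    denom = (ab**2).sum(axis=1)
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.sqrt(((p[:, None, :] - proj) ** 2).sum(axis=2))
    return d.min(axis=1)


def synthesize_em(n_sv: int, docked_fraction: float,
                  geometry: EMGeometry | None = None,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None
                  ) -> tuple[EMAnnotation, np.ndarray]:
    """Generate one annotated section; returns (annotation, docked ids).

    ``round(docked_fraction * n_sv)`` vesicles are docked by construction.
    Raises ``RuntimeError`` if the requested packing density is infeasible.
    """
    if not 0.0 <= docked_fraction <= 1.0:
        raise ValueError(f"docked_fraction must be in [0, 1], got {docked_fraction!r}")
    if n_sv < 0:
        raise ValueError("n_sv must be >= 0")
    geom = geometry or EMGeometry()
    if rng is None:
        rng = derive_rng(seed, "em")
    poly = _polyline(geom)
    tbar = poly[len(poly) // 2].copy()
    n_docked = int(round(docked_fraction * n_sv))

    diam = np.clip(rng.normal(geom.sv_diameter_mean, geom.sv_diameter_sd, size=n_sv),
                   geom.sv_diameter_mean / 2, None)
    min_spacing = float(diam.mean()) if n_sv else geom.sv_diameter_mean

    centers: list[np.ndarray] = []

    def _try_place(candidate: np.ndarray, lo: float, hi: float) -> bool:
        d = _dist_to_polyline(candidate, poly)[0]
        if not (lo <= d < hi):
            return False
        if centers:
            arr = np.asarray(centers)
            if np.min(np.hypot(arr[:, 0] - candidate[0, 0],
                               arr[:, 1] - candidate[0, 1])) < min_spacing:
                return False
        centers.append(candidate[0])
        return True

    max_tries = 20_000
    tries = 0
    while len(centers) < n_docked:
        if tries > max_tries:
            raise RuntimeError("infeasible packing density for docked vesicles")
        tries += 1
        u = rng.uniform(-geom.az_length / 2, geom.az_length / 2)
        d = rng.uniform(geom.docked_min_dist, DOCKED_THRESHOLD_NM - 1.0)
        # above the arc: offset along +y from the local polyline height
        y_arc = -geom.az_sag * (1 - (2 * u / geom.az_length) ** 2)
        _try_place(np.array([[u, y_arc + d]]), 0.0, DOCKED_THRESHOLD_NM)

    tries = 0
    while len(centers) < n_sv:
        if tries > max_tries:
            raise RuntimeError("infeasible packing density for reserve vesicles")
        tries += 1
        r = geom.bouton_radius * np.sqrt(rng.uniform(0.06, 1.0))
        ang = rng.uniform(0.15 * np.pi, 0.85 * np.pi)
        cand = tbar + np.array([[r * np.cos(ang), r * np.sin(ang)]])
        _try_place(cand, GUARD_BAND_NM, np.inf)

    sv = np.asarray(centers) if centers else np.empty((0, 2))
    area_um2 = np.pi * (geom.bouton_radius / 1000.0) ** 2 / 2.0
    ann = EMAnnotation(sv_centers=sv, tbar=tbar, az_density=poly,
                       sv_diameters=diam, bouton_area=area_um2, nm_per_px=1.0)
    return ann, np.arange(n_docked)
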