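"""EM geometry statistics for single presynaptic bouton sections.

A synaptic vesicle (SV) counts as *docked* when its annotated center lies
strictly closer than 50 nm to the active-zone electron-density contour
(point-to-polyline distance via per-segment orthogonal projection). Radial
counts around the T-bar, nearest-neighbor spacing, SV density per bouton
area and diameter summaries follow the per-micrograph convention: one value
per section, no 3-D reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datatypes import EMAnnotation

__all__ = ["EMStats", "point_to_polyline_distance", "docked_svs",
           "radial_counts", "docked_distance_profile", "spacing_and_density",
           "em_stats", "DOCKED_THRESHOLD_NM"]

DOCKED_THRESHOLD_NM = 50.0


@dataclass
class EMStats:
    docked_count: int
    nn_mean: float | None          # nm; None for < 2 SVs
    count_within_100nm: int
    count_within_150nm: int
    sv_density: float | None       # SVs / µm²
    diameter_mean: float | None    # nm
    n_sv: int


def point_to_polyline_distance(points: np.ndarray, polyline: np.ndarray
                               ) -> np.ndarray:
    """Minimum Euclidean distance from each point to a polyline.

    Distances are measured to the closest point of any segment (orthogonal
    projection clamped to the segment ends), not to vertices only.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polyline, dtype=float)
    if poly.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    if p.size == 0:
        return np.empty(0)
    a, b = poly[:-1], poly[1:]
    ab = b - a
    denom = (ab**2).sum(axis=1)
    degenerate = denom == 0
    denom = np.where(degenerate, 1.0, denom)
    ap = p[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    t = np.where(degenerate[None, :], 0.0, t)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.sqrt(((p[:, None, :] - proj) ** 2).sum(axis=2))
    return d.min(axis=1)


def docked_svs(annotation: EMAnnotation, threshold: float = DOCKED_THRESHOLD_NM
               ) -> tuple[np.ndarray, int]:
    """Ids and count of docked SVs (center strictly < ``threshold`` nm from
    the AZ density contour)."""
    d = point_to_polyline_distance(annotation.sv_centers, annotation.az_density)
    ids = np.nonzero(d < threshold)[0]
    return ids, int(ids.size)


def radial_counts(annotation: EMAnnotation, radii_nm=(100.0, 150.0)
                  ) -> dict[float, int]:
    """SV counts strictly within each radius of the T-bar center."""
    if annotation.n_sv == 0:
        return {float(r): 0 for r in radii_nm}
    d = np.hypot(*(annotation.sv_centers - annotation.tbar).T)
    return {float(r): int((d < r).sum()) for r in radii_nm}


def docked_distance_profile(annotation: EMAnnotation,
                            threshold: float = DOCKED_THRESHOLD_NM
                            ) -> pd.DataFrame:
    """Cumulative docked-SV count and fraction versus distance from the
    T-bar center, one row per docked SV, sorted by distance."""
    ids, n = docked_svs(annotation, threshold)
    if n == 0:
        return pd.DataFrame(columns=["distance_nm", "cumulative_count",
                                     "cumulative_fraction"])
    d = np.sort(np.hypot(*(annotation.sv_centers[ids] - annotation.tbar).T))
    count = np.arange(1, n + 1)
    return pd.DataFrame({"distance_nm": d, "cumulative_count": count,
                         "cumulative_fraction": count / n})


def spacing_and_density(annotation: EMAnnotation
                        ) -> tuple[float | None, float | None, float | None]:
    """(nn_mean, sv_density, diameter_mean) for one micrograph.

    Nearest-neighbor mean needs >= 2 SVs (None otherwise); density is
    n_sv / bouton_area when the area is annotated.
    """
    nn_mean = None
    if annotation.n_sv >= 2:
        tree = cKDTree(annotation.sv_centers)
        dist, _ = tree.query(annotation.sv_centers, k=2)
        nn_mean = float(dist[:, 1].mean())
    density = None
    if annotation.bouton_area is not None and annotation.bouton_area > 0:
        density = annotation.n_sv / annotation.bouton_area
    diameter = None
    if annotation.sv_diameters is not None and annotation.sv_diameters.size:
        diameter = float(np.mean(annotation.sv_diameters))
    return nn_mean, density, diameter


def em_stats(annotation: EMAnnotation, threshold: float = DOCKED_THRESHOLD_NM
             ) -> EMStats:
    """All per-micrograph geometry statistics in one record."""
    _, docked = docked_svs(annotation, threshold)
    counts = radial_counts(annotation)
    nn_mean, density, diameter = spacing_and_density(annotation)
    return EMStats(docked_count=docked, nn_mean=nn_mean,
                   count_within_100nm=counts[100.0],
                   count_within_150nm=counts[150.0],
                   sv_density=density, diameter_mean=diameter,
                   n_sv=annotation.n_sv)
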