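"""Wash-in-slope habitat localisation.

The habitat of a biopsied lesion is found in four steps: (1) fit every
prostate voxel's time-activity curve and store its wash-in slope
wi = sp / tau in a parametric map; (2) form a sphere (default radius 15 mm,
accounting for TRUS/MRI fusion error) around the biopsy location, clipped to
the prostate and to whichever zone (peripheral or transition) holds the
larger share of the lesion contour; (3) keep the voxels at or above the
75th percentile of wi within that bounded sphere; (4) average their curves
into a representative time-activity curve for feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import TimeActivityCurve, extract_features, fit_curves_batch
from .preprocess import DCESeries
from .synthetic import sphere_mask

__all__ = [
    "WashInMap",
    "Habitat",
    "washin_map",
    "search_sphere",
    "compute_habitat",
    "representative_curve",
    "dice",
    "DEFAULT_SPHERE_RADIUS_MM",
    "UPPER_QUARTILE",
]

DEFAULT_SPHERE_RADIUS_MM = 15.0
UPPER_QUARTILE = 0.75


@dataclass
class WashInMap:
    """Voxel-wise wash-in slopes, defined only inside a mask.

    ``values`` is NaN outside the defining mask; degenerate per-voxel fits
    (flat curves) carry wi = 0 and a flag, so they stay in percentile pools.
    """

    values: np.ndarray
    defined: np.ndarray
    fit_flags: np.ndarray  # True where the per-voxel fit was degenerate

    def __post_init__(self) -> None:
        if self.values.shape != self.defined.shape:
            raise ValueError("map and mask grids differ")


@dataclass
class Habitat:
    """The selected voxel set plus its provenance."""

    voxels: np.ndarray
    search_region: np.ndarray
    threshold: float
    bounding_zone: str  # "PZ" | "TZ"
    flags: list[str] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def washin_map(series: DCESeries, mask: np.ndarray,
               refine: bool = True) -> WashInMap:
    """Per-voxel wash-in slope map over a mask (typically the prostate).

    Each voxel curve inside the mask is fitted with the bi-exponential model
    and wi = sp / tau recorded.  Degenerate fits (flat or peakless curves)
    contribute wi = 0 with a flag rather than being dropped.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != series.shape:
        raise ValueError(f"mask grid {mask.shape} != series grid {series.shape}")
    if not mask.any():
        raise ValueError("wash-in map mask is empty")
    curves = series.intensities[mask]  # (n_voxels, n_t)
    fits = fit_curves_batch(series.times, curves, refine=refine)
    wi = np.full(mask.shape, np.nan)
    flags = np.zeros(mask.shape, dtype=bool)
    wi_vals = np.empty(len(fits))
    flag_vals = np.empty(len(fits), dtype=bool)
    for i, fit in enumerate(fits):
        feats = extract_features(fit)
        degenerate = fit.degenerate or not np.isfinite(feats.wi)
        wi_vals[i] = 0.0 if degenerate else feats.wi
        flag_vals[i] = degenerate
    wi[mask] = wi_vals
    flags[mask] = flag_vals
    return WashInMap(values=wi, defined=mask, fit_flags=flags)


def search_sphere(
    biopsy_xyz_mm: tuple[float, float, float],
    masks: dict[str, np.ndarray],
    voxel_spacing: tuple[float, float, float],
    radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
    lesion_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, str]:
    """Bounded search sphere around a biopsy point.

    The sphere (voxel-centre membership, anisotropic spacing honoured) is
    intersected with the prostate and with the zone — PZ or TZ — holding the
    larger share of the lesion contour.  With no lesion mask the zone of the
    biopsy point itself decides.  Returns (mask, bounding_zone).
    """
    prostate = masks["prostate"].astype(bool)
    pz, tz = masks["pz"].astype(bool), masks["tz"].astype(bool)
    shape = prostate.shape
    if radius_mm == 0.0:
        idx = tuple(int(round(c / s)) for c, s in zip(biopsy_xyz_mm, voxel_spacing))
        sphere = np.zeros(shape, dtype=bool)
        if all(0 <= i < n for i, n in zip(idx, shape)):
            sphere[idx] = True
    else:
        sphere = sphere_mask(shape, voxel_spacing, biopsy_xyz_mm, radius_mm)

    if lesion_mask is not None and lesion_mask.any():
        n_tz = int((lesion_mask & tz).sum())
        n_pz = int((lesion_mask & pz).sum())
        zone_name = "TZ" if n_tz >= n_pz else "PZ"
    else:
        idx = tuple(int(round(c / s)) for c, s in zip(biopsy_xyz_mm, voxel_spacing))
        in_grid = all(0 <= i < n for i, n in zip(idx, shape))
        zone_name = "TZ" if (in_grid and tz[idx]) else "PZ"
    zone = tz if zone_name == "TZ" else pz

    region = sphere & prostate & zone
    if not region.any():
        raise ValueError(
            f"empty search region: sphere(r={radius_mm} mm) ∩ prostate ∩ "
            f"{zone_name} has no voxels at biopsy {biopsy_xyz_mm}"
        )
    return region, zone_name


def compute_habitat(wi_map: WashInMap, search: np.ndarray,
                    quantile: float = UPPER_QUARTILE,
                    bounding_zone: str = "PZ") -> Habitat:
    """Upper-quartile selection of the wash-in map within the search region.

    threshold = linear-interpolation quantile of wi over search voxels;
    habitat = voxels with wi >= threshold (ties included).  An all-equal map
    returns the whole search region with a degeneracy flag.
    """
    search = np.asarray(search).astype(bool)
    if not search.any():
        raise ValueError("search region is empty")
    if not wi_map.defined[search].all():
        raise ValueError("wash-in map is not defined on the whole search region")
    vals = wi_map.values[search]
    threshold = float(np.quantile(vals, quantile))
    flags = []
    if np.ptp(vals) == 0.0:
        flags.append("uniform_washin_map")
    voxels = search & (wi_map.values >= threshold) & wi_map.defined
    return Habitat(voxels=voxels, search_region=search, threshold=threshold,
                   bounding_zone=bounding_zone, flags=flags)


def representative_curve(series: DCESeries, habitat: Habitat) -> TimeActivityCurve:
    """Mean DCE signal over the habitat voxels at each sampling time."""
    if habitat.n_voxels == 0:
        raise ValueError("habitat is empty")
    return series.mean_curve(habitat.voxels)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a∩b| / (|a|+|b|); 0 by convention when both are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / (na + nb)
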