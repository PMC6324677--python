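"""ADC radiomics on the habitat region.

Implements the descriptors used downstream of habitat localisation: the
histogram-gradient grey levels, the intensity-volume-histogram fraction
differences, voxel-face morphology (surface area, principal axis lengths),
and a standard set of first-order intensity statistics.  Definitions follow
the conventional radiomics (IBSI-style) meanings of the feature names; the
binning and fraction thresholds are explicit parameters.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = [
    "intensity_histogram",
    "hist_gradient_features",
    "fraction_difference_features",
    "morphology_features",
    "intensity_statistics",
    "adc_feature_vector",
    "ADC_FEATURE_REGISTRY",
    "DEFAULT_N_BINS",
]

DEFAULT_N_BINS = 16
FRACTION_LO = 0.10
FRACTION_HI = 0.90


def intensity_histogram(values: np.ndarray, n_bins: int = DEFAULT_N_BINS
                        ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Equal-width histogram over the region's own [min, max].

    Returns (bin_centers, counts, degenerate); counts always sum to the
    number of voxels.  A constant region occupies a single bin and is
    flagged degenerate.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot histogram an empty region")
    lo, hi = float(v.min()), float(v.max())
    degenerate = lo == hi
    if degenerate:
        hi = lo + 1.0  # arbitrary width; all mass falls in bin 0
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    if degenerate:
        counts = np.zeros(n_bins, dtype=counts.dtype)
        counts[0] = v.size
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts, degenerate


def hist_gradient_features(centers: np.ndarray, counts: np.ndarray
                           ) -> tuple[float, float, bool]:
    """Grey levels at the extrema of the histogram-count gradient.

    The gradient is taken by central differences on the counts (one-sided at
    the edges); MaxHistGrad / MinHistGrad are the bin grey levels where it is
    largest / smallest, with ties resolved toward the lowest grey level.
    Returns (max_grad_level, min_grad_level, degenerate).
    """
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if counts.size < 3:
        raise ValueError("histogram gradient needs at least 3 bins")
    grad = np.gradient(counts)  # central differences, one-sided at edges
    degenerate = bool(np.ptp(grad) == 0.0)
    i_max = int(np.argmax(grad))  # argmax/argmin take the first (lowest) tie
    i_min = int(np.argmin(grad))
    return float(centers[i_max]), float(centers[i_min]), degenerate


def _volume_fraction_above(values: np.ndarray, intensity_fraction: float) -> float:
    """Fraction of voxels with intensity >= the given fraction of the range."""
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = v.min(), v.max()
    threshold = lo + intensity_fraction * (hi - lo)
    return float((v >= threshold).mean())


def _intensity_at_volume_fraction(values: np.ndarray, volume_fraction: float) -> float:
    """Largest intensity such that >= the given fraction of voxels lie at or
    above it (the intensity-volume-histogram threshold)."""
    v = np.sort(np.asarray(values, dtype=float).ravel())[::-1]
    k = max(int(math.ceil(volume_fraction * v.size)), 1)
    return float(v[k - 1])


def fraction_difference_features(values: np.ndarray) -> tuple[float, float, bool]:
    """Intensity-volume-histogram difference features.

    VolIFractDiff = V10 - V90 where Vx is the volume fraction above x% of
    the intensity range; IntVFractDiff = I10 - I90 where Ix is the intensity
    at volume fraction x%.  Both are >= 0; a constant region returns (0, 0)
    flagged degenerate.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot compute fraction features on an empty region")
    if v.min() == v.max():
        return 0.0, 0.0, True
    vol_diff = (_volume_fraction_above(v, FRACTION_LO)
                - _volume_fraction_above(v, FRACTION_HI))
    int_diff = (_intensity_at_volume_fraction(v, FRACTION_LO)
                - _intensity_at_volume_fraction(v, FRACTION_HI))
    return float(vol_diff), float(int_diff), False


def morphology_features(mask: np.ndarray,
                        spacing: tuple[float, float, float]
                        ) -> dict[str, float]:
    """Voxel-face surface area and principal axis lengths of a 3-D mask.

    Surface area sums the exposed faces of mask voxels in mm² (a documented
    overestimate relative to a meshed surface).  Axis lengths are
    4·sqrt(lambda_i) for the ordered eigenvalues of the voxel-centre
    coordinate covariance in mm — the axes of the ellipsoid with matching
    second moments; a single voxel has zero axis lengths.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("morphology features need a non-empty mask")
    sx, sy, sz = (float(s) for s in spacing)
    face_areas = (sy * sz, sx * sz, sx * sy)
    surf = 0.0
    for axis, area in enumerate(face_areas):
        padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        surf += float(np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum()) * area

    coords = np.argwhere(mask).astype(float) * np.array([sx, sy, sz])
    flagged = coords.shape[0] < 2
    if flagged:
        lengths = np.zeros(3)
    else:
        cov = np.cov(coords, rowvar=False, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        lengths = 4.0 * np.sqrt(np.maximum(eig, 0.0))
    return {
        "SurfArea": surf,
        "MajorAxisL": float(lengths[0]),
        "MinorAxisL": float(lengths[1]),
        "LeastAxisL": float(lengths[2]),
        "degenerate": float(flagged),
    }


def intensity_statistics(values: np.ndarray) -> dict[str, float]:
    """Standard first-order statistics of the region intensities."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty region")
    centers, counts, degenerate = intensity_histogram(v)
    p = counts / counts.sum()
    p = p[p > 0]
    out = {
        "Mean": float(v.mean()),
        "Std": float(v.std()),
        "Min": float(v.min()),
        "Max": float(v.max()),
        "Range": float(np.ptp(v)),
        "Median": float(np.median(v)),
        "P10": float(np.percentile(v, 10)),
        "P25": float(np.percentile(v, 25)),
        "P75": float(np.percentile(v, 75)),
        "P90": float(np.percentile(v, 90)),
        "IQR": float(np.percentile(v, 75) - np.percentile(v, 25)),
        "Skewness": float(stats.skew(v)) if v.std() > 0 else 0.0,
        "Kurtosis": float(stats.kurtosis(v)) if v.std() > 0 else 0.0,
        "Energy": float((v**2).sum()),
        "RMS": float(np.sqrt((v**2).mean())),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "MAD": float(np.abs(v - v.mean()).mean()),
        "CoV": float(v.std() / v.mean()) if v.mean() != 0 else float("nan"),
    }
    return out


def adc_feature_vector(adc: np.ndarray, habitat_mask: np.ndarray,
                       spacing: tuple[float, float, float],
                       n_bins: int = DEFAULT_N_BINS) -> dict[str, float]:
    """All ADC descriptors of a habitat region on a (standardized) ADC map."""
    mask = np.asarray(habitat_mask).astype(bool)
    if mask.shape != adc.shape:
        raise ValueError("habitat mask grid does not match the ADC grid")
    if not mask.any():
        raise ValueError("habitat mask is empty")
    vals = np.asarray(adc, dtype=float)[mask]
    centers, counts, _ = intensity_histogram(vals, n_bins=n_bins)
    max_hg, min_hg, _ = hist_gradient_features(centers, counts)
    vol_fd, int_fd, _ = fraction_difference_features(vals)
    feats: dict[str, float] = {
        "MaxHistGrad": max_hg,
        "MinHistGrad": min_hg,
        "VolIFractDiff": vol_fd,
        "IntVFractDiff": int_fd,
    }
    feats.update({k: val for k, val in morphology_features(mask, spacing).items()
                  if k != "degenerate"})
    feats.update(intensity_statistics(vals))
    return feats


ADC_FEATURE_REGISTRY: dict[str, dict[str, str]] = {
    "MaxHistGrad": {"units": "grey level",
                    "definition": "grey level at the maximum of the histogram-count gradient"},
    "MinHistGrad": {"units": "grey level",
                    "definition": "grey level at the minimum of the histogram-count gradient"},
    "VolIFractDiff": {"units": "proportion",
                      "definition": "V10 - V90: volume fractions above 10%/90% of the intensity range"},
    "IntVFractDiff": {"units": "grey level",
                      "definition": "I10 - I90: intensities at 10%/90% volume fractions"},
    "SurfArea": {"units": "mm^2", "definition": "total exposed voxel-face area"},
    "MajorAxisL": {"units": "mm", "definition": "4*sqrt(largest covariance eigenvalue)"},
    "MinorAxisL": {"units": "mm", "definition": "4*sqrt(second covariance eigenvalue)"},
    "LeastAxisL": {"units": "mm", "definition": "4*sqrt(smallest covariance eigenvalue)"},
    "Mean": {"units": "grey level", "definition": "mean intensity"},
    "Std": {"units": "grey level", "definition": "population standard deviation"},
    "Min": {"units": "grey level", "definition": "minimum intensity"},
    "Max": {"units": "grey level", "definition": "maximum intensity"},
    "Range": {"units": "grey level", "definition": "max - min"},
    "Median": {"units": "grey level", "definition": "median intensity"},
    "P10": {"units": "grey level", "definition": "10th percentile"},
    "P25": {"units": "grey level", "definition": "25th percentile"},
    "P75": {"units": "grey level", "definition": "75th percentile"},
    "P90": {"units": "grey level", "definition": "90th percentile"},
    "IQR": {"units": "grey level", "definition": "interquartile range"},
    "Skewness": {"units": "dimensionless", "definition": "third standardized moment"},
    "Kurtosis": {"units": "dimensionless", "definition": "excess kurtosis"},
    "Energy": {"units": "grey level^2", "definition": "sum of squared intensities"},
    "RMS": {"units": "grey level", "definition": "root mean square intensity"},
    "Entropy": {"units": "bits", "definition": "Shannon entropy of the 16-bin histogram"},
    "MAD": {"units": "grey level", "definition": "mean absolute deviation from the mean"},
    "CoV": {"units": "dimensionless", "definition": "coefficient of variation"},
}
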