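"""Synthetic mpMRI cohort generator.

Builds per-patient bundles with the statistical structure the downstream
analysis assumes: a voxelized ellipsoidal prostate split into a transition
zone (inner ellipsoid) and peripheral zone (shell), spherical lesions whose
enhancement follows the bi-exponential model with class-conditional
parameters (clinically significant lesions wash in faster, wash out more
strongly and sit on lower ADC), a weakly enhancing prostate background, an
arterial region with an early high-amplitude bolus, and additive Gaussian
noise on the magnitude images (a high-SNR approximation to Rician noise).

Geometry is exact by construction — solid ellipsoids/spheres voxelized by
voxel-centre membership on the stated mm grid — so morphology features have
closed-form oracles.  Everything is deterministic given (seed, patient
index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .model import BiExpFit, model_curve
from .preprocess import DCESeries

__all__ = [
    "ClassParams",
    "CohortConfig",
    "BiopsySample",
    "LesionTruth",
    "SyntheticPatient",
    "PlacementError",
    "generate_patient",
    "generate_cohort",
]


class PlacementError(RuntimeError):
    """A lesion could not be placed inside the prostate."""


@dataclass(frozen=True)
class ClassParams:
    """Normal (mean, sd) sampling distributions for one lesion class.

    Curve parameters follow the bi-exponential model; ``adc`` is the mean
    lesion ADC level in 1e-6 mm^2/s.
    """

    s0: tuple[float, float] = (100.0, 5.0)
    t0: tuple[float, float] = (30.0, 3.0)
    k_in: tuple[float, float] = (0.10, 0.01)
    k_out: tuple[float, float] = (0.006, 0.001)
    amplitude: tuple[float, float] = (90.0, 10.0)
    adc: tuple[float, float] = (700.0, 60.0)


# defaults for clinically significant vs insignificant lesions: the
# significant class washes in ~2.5x faster, washes out faster, enhances more
# and sits on markedly lower ADC (dense tumor tissue); separations are
# several pooled standard deviations, i.e. a clearly learnable effect
SIGNIFICANT_DEFAULTS = ClassParams(
    t0=(28.0, 3.0), k_in=(0.10, 0.01), k_out=(0.006, 0.001),
    amplitude=(90.0, 10.0), adc=(700.0, 60.0),
)
INSIGNIFICANT_DEFAULTS = ClassParams(
    t0=(32.0, 3.0), k_in=(0.04, 0.01), k_out=(0.0025, 0.0008),
    amplitude=(60.0, 10.0), adc=(1150.0, 90.0),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n_patients: int = 40
    lesions_per_patient: tuple[int, int] = (1, 1)
    temporal_resolution: float = 7.0  # seconds per frame
    n_timepoints: int = 50
    grid_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    prostate_semi_axes: tuple[float, float, float] = (22.0, 18.0, 16.0)  # mm
    tz_fraction: float = 0.62  # TZ = inner ellipsoid with scaled semi-axes
    lesion_radius_mm: tuple[float, float] = (4.0, 7.0)
    fraction_significant: float = 0.4
    class_params_significant: ClassParams = SIGNIFICANT_DEFAULTS
    class_params_insignificant: ClassParams = INSIGNIFICANT_DEFAULTS
    noise_sigma: float = 4.0  # intensity units, DCE magnitude noise
    adc_noise_sigma: float = 60.0
    biopsy_jitter_mm: float = 3.0  # uniform-in-ball TRUS/MRI fusion error
    contour_margin_mm: float = 2.0  # radiologist contour = lesion +/- margin
    pre_contrast_frames: int = 2
    artery_params: BiExpFit = field(
        default_factory=lambda: BiExpFit(s0=120.0, A=400.0, t0=16.0,
                                         k_in=0.5, k_out=0.004)
    )
    background_params: BiExpFit = field(
        default_factory=lambda: BiExpFit(s0=100.0, A=20.0, t0=30.0,
                                         k_in=0.03, k_out=0.001)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        # YAML/JSON configs deliver sequences as lists; normalise to tuples
        for name in ("lesions_per_patient", "grid_shape", "voxel_spacing",
                     "prostate_semi_axes", "lesion_radius_mm"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        for name in ("class_params_significant", "class_params_insignificant"):
            value = getattr(self, name)
            if isinstance(value, dict):
                object.__setattr__(
                    self, name,
                    ClassParams(**{k: tuple(v) for k, v in value.items()}))
        if isinstance(self.artery_params, dict):
            object.__setattr__(self, "artery_params",
                               BiExpFit(**self.artery_params))
        if isinstance(self.background_params, dict):
            object.__setattr__(self, "background_params",
                               BiExpFit(**self.background_params))
        if self.temporal_resolution <= 0:
            raise ValueError("temporal_resolution must be positive")
        if self.n_timepoints < 5:
            raise ValueError("at least 5 timepoints are required")
        if not 0.0 <= self.fraction_significant <= 1.0:
            raise ValueError("fraction_significant must lie in [0, 1]")
        if self.lesion_radius_mm[1] >= min(self.prostate_semi_axes):
            raise ValueError("lesion radius must be below the smallest "
                             "prostate semi-axis")
        if not 0.0 < self.tz_fraction < 1.0:
            raise ValueError("tz_fraction must lie in (0, 1)")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.temporal_resolution


@dataclass
class LesionTruth:
    """Ground truth for one planted lesion."""

    lesion_index: int
    significant: bool
    center_mm: tuple[float, float, float]
    radius_mm: float
    params: BiExpFit
    adc_level: float
    dominant_zone: str  # "PZ" or "TZ"


@dataclass
class BiopsySample:
    """One synthetic biopsy row (position in mm + Gleason pattern)."""

    biopsy_id: str
    patient_id: str
    x_mm: float
    y_mm: float
    z_mm: float
    gleason_primary: int
    gleason_secondary: int
    lesion_index: int


@dataclass
class SyntheticPatient:
    patient_id: str
    dce: DCESeries
    adc: np.ndarray
    masks: dict[str, np.ndarray]  # prostate, pz, tz, artery, lesion_<i>, contour_<i>
    biopsies: list[BiopsySample]
    truth: list[LesionTruth]
    motion_artifact: bool = False


# ---------------------------------------------------------------------------
# geometry helpers (voxel-centre membership on the mm grid)


def _coord_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    X, Y, Z = _coord_grids(shape, spacing)
    q = (
        ((X - center_mm[0]) / semi_axes_mm[0]) ** 2
        + ((Y - center_mm[1]) / semi_axes_mm[1]) ** 2
        + ((Z - center_mm[2]) / semi_axes_mm[2]) ** 2
    )
    return q <= 1.0


def sphere_mask(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    """Solid sphere by voxel-centre distance (anisotropic spacing honoured)."""
    return _ellipsoid_mask(shape, spacing, center_mm,
                           (radius_mm, radius_mm, radius_mm))


def _margin_mask(mask: np.ndarray, margin_mm: float, spacing) -> np.ndarray:
    """Dilate (margin > 0) or erode (margin < 0) a mask by a mm distance."""
    if margin_mm == 0.0:
        return mask.copy()
    if margin_mm > 0.0:
        dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
        return mask | (dist <= margin_mm)
    dist = ndimage.distance_transform_edt(mask, sampling=spacing)
    return dist > -margin_mm


def _center_of_mass_mm(mask: np.ndarray, spacing) -> tuple[float, float, float]:
    com = ndimage.center_of_mass(mask)
    return tuple(float(c * s) for c, s in zip(com, spacing))


# ---------------------------------------------------------------------------
# sampling helpers


def _draw(rng: np.random.Generator, mean_sd: tuple[float, float],
          lo: float = -np.inf, hi: float = np.inf) -> float:
    mean, sd = mean_sd
    for _ in range(100):
        x = float(rng.normal(mean, sd))
        if lo < x < hi:
            return x
    return float(np.clip(mean, lo + 1e-9, hi - 1e-9))


def _draw_lesion_params(rng: np.random.Generator, cp: ClassParams) -> BiExpFit:
    k_out = _draw(rng, cp.k_out, lo=1e-5)
    k_in = _draw(rng, cp.k_in, lo=k_out * 1.5)
    return BiExpFit(
        s0=_draw(rng, cp.s0, lo=0.0),
        A=_draw(rng, cp.amplitude, lo=1.0),
        t0=_draw(rng, cp.t0, lo=0.0),
        k_in=k_in,
        k_out=k_out,
    )


def _draw_gleason(rng: np.random.Generator, significant: bool) -> tuple[int, int]:
    if not significant:
        return 3, 3
    patterns = [(3, 4), (4, 3), (4, 4), (4, 5)]
    i = rng.choice(len(patterns), p=[0.5, 0.3, 0.15, 0.05])
    return patterns[i]


# ---------------------------------------------------------------------------
# generation


def generate_patient(config: CohortConfig, patient_index: int) -> SyntheticPatient:
    """Generate one synthetic patient, deterministic in (seed, index)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), int(patient_index)])
    )
    shape, spacing = config.grid_shape, config.voxel_spacing
    center = tuple((n - 1) * s / 2.0 for n, s in zip(shape, spacing))

    prostate = _ellipsoid_mask(shape, spacing, center, config.prostate_semi_axes)
    tz_axes = tuple(a * config.tz_fraction for a in config.prostate_semi_axes)
    tz = _ellipsoid_mask(shape, spacing, center, tz_axes)
    pz = prostate & ~tz

    # arterial region: a small tube along z near the volume edge, well
    # outside the prostate, with an early sharp bolus
    artery_center_xy = (2.5 * spacing[0], 2.5 * spacing[1])
    X, Y, Z = _coord_grids(shape, spacing)
    artery = (
        ((X - artery_center_xy[0]) ** 2 + (Y - artery_center_xy[1]) ** 2
         <= (2.0 * max(spacing[:2])) ** 2)
        & (np.abs(Z - center[2]) <= 10.0)
    )
    if (artery & prostate).any():
        raise PlacementError("artery tube overlaps the prostate; enlarge the grid")

    # lesions
    n_lo, n_hi = config.lesions_per_patient
    n_lesions = int(rng.integers(n_lo, n_hi + 1))
    lesions: list[np.ndarray] = []
    truth: list[LesionTruth] = []
    occupied = np.zeros(shape, dtype=bool)
    for li in range(n_lesions):
        radius = float(rng.uniform(*config.lesion_radius_mm))
        placed = False
        for _ in range(200):
            # candidate centre inside the prostate shrunk by the radius
            u = rng.uniform(-1.0, 1.0, size=3)
            if (u**2).sum() > 1.0:
                continue
            cand = tuple(
                c + u[i] * max(a - radius, 1e-3)
                for i, (c, a) in enumerate(zip(center, config.prostate_semi_axes))
            )
            les = sphere_mask(shape, spacing, cand, radius)
            if not les.any() or not (les <= prostate).all() or (les & occupied).any():
                continue
            significant = bool(rng.random() < config.fraction_significant)
            cp = (config.class_params_significant if significant
                  else config.class_params_insignificant)
            params = _draw_lesion_params(rng, cp)
            n_tz = int((les & tz).sum())
            zone = "TZ" if n_tz * 2 >= int(les.sum()) else "PZ"
            lesions.append(les)
            occupied |= les
            truth.append(LesionTruth(
                lesion_index=li, significant=significant, center_mm=cand,
                radius_mm=radius, params=params,
                adc_level=_draw(rng, cp.adc, lo=50.0), dominant_zone=zone,
            ))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a radius-{radius:.1f} mm lesion inside the "
                f"prostate after 200 attempts (patient {patient_index})"
            )

    # assemble the 4-D DCE series: air background, prostate background,
    # artery bolus, then per-lesion curves; finally magnitude noise
    times = config.times
    n_t = times.size
    dce = np.empty(shape + (n_t,), dtype=float)
    dce[...] = 20.0  # non-anatomy background
    bg_curve = model_curve(config.background_params, times)
    dce[prostate] = bg_curve
    dce[artery] = model_curve(config.artery_params, times)
    for les, tr in zip(lesions, truth):
        dce[les] = model_curve(tr.params, times)
    if config.noise_sigma > 0:
        dce += rng.normal(0.0, config.noise_sigma, size=dce.shape)

    # ADC map: bright non-prostate background, intermediate gland, dark(er)
    # lesions; voxel-level Gaussian noise
    adc = np.full(shape, 1400.0)
    adc[prostate] = 1300.0
    for les, tr in zip(lesions, truth):
        adc[les] = tr.adc_level
    if config.adc_noise_sigma > 0:
        adc = adc + rng.normal(0.0, config.adc_noise_sigma, size=shape)

    # biopsies: lesion centre of mass + uniform-in-ball jitter (fusion error)
    patient_id = f"P{patient_index:03d}"
    biopsies: list[BiopsySample] = []
    for les, tr in zip(lesions, truth):
        com = _center_of_mass_mm(les, spacing)
        loc = None
        for _ in range(50):
            u = rng.uniform(-1.0, 1.0, size=3)
            if (u**2).sum() > 1.0:
                continue
            cand = tuple(c + config.biopsy_jitter_mm * u[i]
                         for i, c in enumerate(com))
            idx = tuple(int(round(c / s)) for c, s in zip(cand, spacing))
            if all(0 <= i < n for i, n in zip(idx, shape)) and prostate[idx]:
                loc = cand
                break
        if loc is None:
            loc = com
        gp, gs = _draw_gleason(rng, tr.significant)
        biopsies.append(BiopsySample(
            biopsy_id=f"{patient_id}_B{tr.lesion_index}", patient_id=patient_id,
            x_mm=loc[0], y_mm=loc[1], z_mm=loc[2],
            gleason_primary=gp, gleason_secondary=gs,
            lesion_index=tr.lesion_index,
        ))

    masks: dict[str, np.ndarray] = {
        "prostate": prostate, "pz": pz, "tz": tz, "artery": artery,
    }
    for les, tr in zip(lesions, truth):
        masks[f"lesion_{tr.lesion_index}"] = les
        masks[f"contour_{tr.lesion_index}"] = _margin_mask(
            les, config.contour_margin_mm, spacing
        )

    series = DCESeries(
        intensities=dce, times=times, voxel_spacing=spacing,
        temporal_resolution=config.temporal_resolution,
        pre_contrast_frames=config.pre_contrast_frames,
    )
    return SyntheticPatient(
        patient_id=patient_id, dce=series, adc=adc, masks=masks,
        biopsies=biopsies, truth=truth,
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate ``config.n_patients`` patients (indices 0..n-1)."""
    patients = []
    for i in range(config.n_patients):
        try:
            patients.append(generate_patient(config, i))
        except PlacementError as err:
            raise PlacementError(f"patient {i}: {err}") from err
    return patients


def vary_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """A copy of the config with a different master seed."""
    return replace(config, seed=seed)
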