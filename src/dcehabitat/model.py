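"""Semi-quantitative bi-exponential modelling of DCE-MRI time-activity curves.

The enhancement of a voxel (or region) after contrast injection is modelled
as a difference of two exponentials on top of a static baseline::

    s(t) = s0                                              for t <= t0
    s(t) = s0 + A * (exp(-k_out*(t-t0)) - exp(-k_in*(t-t0)))   for t >  t0

with wash-in rate ``k_in`` strictly larger than wash-out rate ``k_out``.
The curve rises from the baseline ``s0`` at the start of enhancement ``t0``,
peaks at the analytic time-to-peak

    tau = ln(k_in / k_out) / (k_in - k_out)

and then decays.  The plateau/peak intensity is ``sm = s(t0 + tau)``.

Seven descriptors summarise a fitted curve: peak enhancement ``sp = sm - s0``,
time-to-peak ``tau``, wash-in slope ``wi = sp / tau``, wash-out slope ``wo``
(mean slope of the fitted curve from the peak to 270 s after enhancement
onset), the early and late areas under the baseline-subtracted fitted curve
(``auci`` over [t0, t0+60] s, ``aucf`` over [t0+240, t0+270] s, both in
closed form) and the slope product ``mio = wi * wo``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TimeActivityCurve",
    "BiExpFit",
    "DCEFeatureVector",
    "model_curve",
    "analytic_tau",
    "fit_curve",
    "fit_curves_batch",
    "extract_features",
]

# integration windows for the early/late AUC features, seconds after t0
AUCI_WINDOW = (0.0, 60.0)
AUCF_WINDOW = (240.0, 270.0)
WASHOUT_HORIZON = 270.0

_EXP_CLIP = 700.0  # exp argument floor to avoid overflow warnings


@dataclass(frozen=True)
class TimeActivityCurve:
    """A sampled enhancement curve: times in seconds, dimensionless values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and equally long")
        if t.size < 5:
            raise ValueError("a time-activity curve needs at least 5 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass
class BiExpFit:
    """Fitted bi-exponential parameters plus diagnostics.

    ``s0``  baseline intensity; ``A`` amplitude; ``t0`` start of enhancement
    (s); ``k_in``/``k_out`` wash-in/out rates (1/s).  ``sm``, ``tau`` are
    derived; ``residual_pct`` is the mean absolute residual as a percentage
    of the fitted dynamic range ``sm - s0``.
    """

    s0: float
    A: float
    t0: float
    k_in: float
    k_out: float
    residual_pct: float = 0.0
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.degenerate and self.k_in <= self.k_out:
            raise ValueError(
                f"wash-in rate must exceed wash-out rate (k_in={self.k_in}, "
                f"k_out={self.k_out})"
            )

    @property
    def tau(self) -> float:
        if self.degenerate or self.A == 0.0:
            return math.nan
        return analytic_tau(self.k_in, self.k_out)

    @property
    def sm(self) -> float:
        if self.degenerate or self.A == 0.0:
            return self.s0
        return float(model_curve(self, np.array([self.t0 + self.tau]))[0])

    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.A, self.t0, self.k_in, self.k_out])


@dataclass
class DCEFeatureVector:
    """The seven perfusion descriptors of a fitted enhancement curve."""

    sp: float
    tau: float
    wi: float
    wo: float
    auci: float
    aucf: float
    mio: float
    flags: list[str] = field(default_factory=list)

    NAMES = ("sp", "tau", "wi", "wo", "auci", "aucf", "mio")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.NAMES}


def analytic_tau(k_in: float, k_out: float) -> float:
    """Time from enhancement onset to the curve peak.

    The maximum of ``exp(-k_out u) - exp(-k_in u)`` is at
    ``u = ln(k_in/k_out) / (k_in - k_out)``; for ``k_out -> 0`` the curve
    saturates monotonically and tau diverges (returned as ``inf``).
    """
    if k_in <= k_out:
        raise ValueError("analytic_tau requires k_in > k_out")
    if k_out <= 0.0:
        return math.inf
    return math.log(k_in / k_out) / (k_in - k_out)


def _enhancement(u: np.ndarray, k_in: float, k_out: float) -> np.ndarray:
    """exp(-k_out u) - exp(-k_in u) for u >= 0, zero for u < 0."""
    up = np.maximum(u, 0.0)
    e = np.exp(np.maximum(-k_out * up, -_EXP_CLIP)) - np.exp(
        np.maximum(-k_in * up, -_EXP_CLIP)
    )
    return np.where(u > 0.0, e, 0.0)


def model_curve(params: BiExpFit, times: np.ndarray) -> np.ndarray:
    """Evaluate the bi-exponential model at the given times (seconds)."""
    t = np.asarray(times, dtype=float)
    if not params.degenerate and params.k_in <= params.k_out:
        raise ValueError("invalid parameters: k_in must exceed k_out")
    if params.A == 0.0 or params.degenerate:
        return np.full_like(t, params.s0)
    return params.s0 + params.A * _enhancement(t - params.t0, params.k_in, params.k_out)


def _residual_pct(resid: np.ndarray, dynamic_range: float) -> float:
    mean_abs = float(np.mean(np.abs(resid)))
    if dynamic_range <= 0.0:
        return 0.0 if mean_abs == 0.0 else math.inf
    return 100.0 * mean_abs / dynamic_range


# ---------------------------------------------------------------------------
# fitting


def _theta_curve(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    s0, A, t0, k_out, dk = theta
    return s0 + A * _enhancement(t - t0, k_out + dk, k_out)


def _theta_jac(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    s0, A, t0, k_out, dk = theta
    k_in = k_out + dk
    u = np.maximum(t - t0, 0.0)
    active = (t - t0) > 0.0
    e_out = np.exp(np.maximum(-k_out * u, -_EXP_CLIP))
    e_in = np.exp(np.maximum(-k_in * u, -_EXP_CLIP))
    J = np.zeros((t.size, 5))
    J[:, 0] = 1.0
    J[active, 1] = (e_out - e_in)[active]
    J[active, 2] = A * (k_out * e_out - k_in * e_in)[active]
    J[active, 3] = A * (-u * e_out + u * e_in)[active]
    J[active, 4] = A * (u * e_in)[active]
    return J


# deterministic multi-start grid over (t0 fraction toward the empirical peak,
# k_in, k_out); s0 and A are solved linearly for each grid node
_T0_FRACS = (0.0, 0.25, 0.5, 0.75, 0.9)
_KIN_GRID = (0.02, 0.05, 0.1, 0.2, 0.4)
_KOUT_GRID = (1e-4, 0.002, 0.008, 0.02)


def _start_grid(times: np.ndarray, values: np.ndarray) -> list[tuple[float, float, float]]:
    i_peak = int(np.argmax(values))
    t_peak = times[min(i_peak, times.size - 1)]
    t_lo = times[0]
    starts = []
    for f in _T0_FRACS:
        t0 = t_lo + f * max(t_peak - t_lo, 1e-6)
        for k_in in _KIN_GRID:
            for k_out in _KOUT_GRID:
                if k_in > k_out:
                    starts.append((t0, k_in, k_out))
    return starts


def _linear_s0_A(
    times: np.ndarray, values: np.ndarray, t0: float, k_in: float, k_out: float
) -> tuple[float, float, float]:
    """Best (s0, A >= 0) for fixed shape parameters; returns (s0, A, sse)."""
    phi = _enhancement(times - t0, k_in, k_out)
    n = times.size
    sp_ = float(phi.sum())
    spp = float(phi @ phi)
    sy = float(values.sum())
    syp = float(values @ phi)
    det = n * spp - sp_ * sp_
    if det > 1e-12 * max(n * spp, 1.0):
        A = (n * syp - sp_ * sy) / det
        s0 = (sy - A * sp_) / n
    else:
        A, s0 = 0.0, sy / n
    if A < 0.0:
        A, s0 = 0.0, sy / n
    resid = values - (s0 + A * phi)
    return s0, A, float(resid @ resid)


def fit_curve(
    curve: TimeActivityCurve,
    n_refine: int = 3,
    xtol: float = 1e-14,
) -> BiExpFit:
    """Fit the bi-exponential model by multi-start nonlinear least squares.

    A fixed deterministic grid over (t0, k_in, k_out) — with the baseline and
    amplitude solved linearly at each node — seeds trust-region refinements
    of the ``n_refine`` best nodes; the lowest-cost refinement wins.  An
    (almost) constant curve short-circuits to a degenerate A = 0 fit.
    """
    t, y = curve.times, curve.values
    rng_y = float(np.ptp(y))
    scale = max(rng_y, 1e-12)
    if rng_y <= 1e-12 * max(abs(float(np.mean(y))), 1.0):
        return BiExpFit(
            s0=float(np.mean(y)), A=0.0, t0=t[0], k_in=0.1, k_out=0.001,
            residual_pct=0.0, degenerate=True, flags=["constant_curve"],
        )

    starts = _start_grid(t, y)
    scored = []
    for t0, k_in, k_out in starts:
        s0, A, sse = _linear_s0_A(t, y, t0, k_in, k_out)
        scored.append((sse, (s0, A, t0, k_out, k_in - k_out)))
    scored.sort(key=lambda it: it[0])

    dt = float(np.median(np.diff(t)))
    lb = np.array([-np.inf, 0.0, t[0] - dt, 1e-6, 1e-5])
    ub = np.array([np.inf, np.inf, t[-1], 1.0, 5.0])

    best = None
    for sse, theta0 in scored[:n_refine]:
        theta0 = np.clip(np.asarray(theta0, dtype=float), lb, ub)
        try:
            sol = least_squares(
                lambda th: _theta_curve(th, t) - y,
                theta0,
                jac=lambda th: _theta_jac(th, t),
                bounds=(lb, ub),
                method="trf",
                xtol=xtol, ftol=1e-14, gtol=1e-14,
                max_nfev=400,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            f"bi-exponential fit failed to converge; best grid SSE={scored[0][0]:.4g}"
        )

    s0, A, t0, k_out, dk = best.x
    fit = BiExpFit(s0=float(s0), A=float(A), t0=float(t0),
                   k_in=float(k_out + dk), k_out=float(k_out))
    resid = _theta_curve(best.x, t) - y
    fit.residual_pct = _residual_pct(resid, fit.sm - fit.s0)
    if A <= 1e-9 * scale:
        fit.degenerate = True
        fit.flags.append("near_constant_amplitude")
    return fit


def fit_curves_batch(
    times: np.ndarray,
    values: np.ndarray,
    refine: bool = True,
    xtol: float = 1e-10,
) -> list[BiExpFit]:
    """Fit many curves sharing one time axis (rows of ``values``).

    The multi-start grid search is vectorised across curves (the linear
    sub-problem in s0, A has a closed form); only the single best node per
    curve is refined, which is what makes voxel-wise wash-in maps tractable.
    """
    t = np.asarray(times, dtype=float)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    n_curves, n_t = Y.shape
    if n_t != t.size:
        raise ValueError("values rows must match the time axis length")

    rng_y = np.ptp(Y, axis=1)
    const = rng_y <= 1e-12 * np.maximum(np.abs(Y.mean(axis=1)), 1.0)

    # shared grid: t0 fractions are taken toward the per-curve peak, so the
    # grid nodes are per-curve but the (k_in, k_out) part is shared
    i_peak = np.argmax(Y, axis=1)
    t_peak = t[i_peak]
    combos = [(ki, ko) for ki in _KIN_GRID for ko in _KOUT_GRID if ki > ko]

    best_sse = np.full(n_curves, np.inf)
    best_theta = np.zeros((n_curves, 5))
    best_theta[:, 0] = Y.mean(axis=1)
    best_theta[:, 3] = 0.002
    best_theta[:, 4] = 0.1

    sy = Y.sum(axis=1)
    for f in _T0_FRACS:
        t0s = t[0] + f * np.maximum(t_peak - t[0], 1e-6)  # (n_curves,)
        u = t[None, :] - t0s[:, None]
        for k_in, k_out in combos:
            phi = _enhancement(u, k_in, k_out)  # (n_curves, n_t)
            sp_ = phi.sum(axis=1)
            spp = np.einsum("ij,ij->i", phi, phi)
            syp = np.einsum("ij,ij->i", Y, phi)
            det = n_t * spp - sp_ * sp_
            ok = det > 1e-12 * np.maximum(n_t * spp, 1.0)
            A = np.where(ok, (n_t * syp - sp_ * sy) / np.where(ok, det, 1.0), 0.0)
            A = np.maximum(A, 0.0)
            s0 = (sy - A * sp_) / n_t
            sse = (
                np.einsum("ij,ij->i", Y, Y)
                - 2.0 * (s0 * sy + A * syp)
                + n_t * s0**2 + 2.0 * s0 * A * sp_ + A**2 * spp
            )
            better = sse < best_sse
            if np.any(better):
                best_sse[better] = sse[better]
                best_theta[better, 0] = s0[better]
                best_theta[better, 1] = A[better]
                best_theta[better, 2] = t0s[better]
                best_theta[better, 3] = k_out
                best_theta[better, 4] = k_in - k_out

    dt = float(np.median(np.diff(t)))
    lb = np.array([-np.inf, 0.0, t[0] - dt, 1e-6, 1e-5])
    ub = np.array([np.inf, np.inf, t[-1], 1.0, 5.0])

    fits: list[BiExpFit] = []
    for i in range(n_curves):
        if const[i]:
            fits.append(BiExpFit(
                s0=float(Y[i].mean()), A=0.0, t0=float(t[0]), k_in=0.1,
                k_out=0.001, residual_pct=0.0, degenerate=True,
                flags=["constant_curve"],
            ))
            continue
        theta = np.clip(best_theta[i], lb, ub)
        if refine:
            y = Y[i]
            try:
                sol = least_squares(
                    lambda th: _theta_curve(th, t) - y,
                    theta,
                    jac=lambda th: _theta_jac(th, t),
                    bounds=(lb, ub), method="trf",
                    xtol=xtol, ftol=xtol, gtol=xtol, max_nfev=120,
                )
                theta = sol.x
            except Exception:
                pass
        s0, A, t0, k_out, dk = theta
        fit = BiExpFit(s0=float(s0), A=float(A), t0=float(t0),
                       k_in=float(k_out + dk), k_out=float(k_out))
        resid = _theta_curve(theta, t) - Y[i]
        fit.residual_pct = _residual_pct(resid, fit.sm - fit.s0)
        if A <= 1e-9 * max(rng_y[i], 1e-12):
            fit.degenerate = True
            fit.flags.append("near_constant_amplitude")
        fits.append(fit)
    return fits


# ---------------------------------------------------------------------------
# features


def _auc_closed_form(A: float, k_in: float, k_out: float, a: float, b: float) -> float:
    """∫_a^b A (e^{-k_out u} - e^{-k_in u}) du, u measured from t0."""
    if k_out <= 0.0:
        term_out = b - a
    else:
        term_out = (math.exp(-k_out * a) - math.exp(-k_out * b)) / k_out
    term_in = (math.exp(-k_in * a) - math.exp(-k_in * b)) / k_in
    return A * (term_out - term_in)


def extract_features(fit: BiExpFit) -> DCEFeatureVector:
    """Compute the seven perfusion descriptors from a fitted curve.

    wo is the mean slope of the fitted curve from its peak to 270 s after
    enhancement onset, (s(t0+270) - sm)/(270 - tau); it is typically <= 0.
    The AUCs integrate the baseline-subtracted fitted curve in closed form.
    A degenerate (flat) fit yields all-zero enhancement features.
    """
    flags = list(fit.flags)
    if fit.degenerate or fit.A == 0.0:
        return DCEFeatureVector(sp=0.0, tau=0.0, wi=0.0, wo=0.0, auci=0.0,
                                aucf=0.0, mio=0.0, flags=flags + ["degenerate_fit"])
    tau = fit.tau
    sp = fit.sm - fit.s0
    if not math.isfinite(tau) or tau >= WASHOUT_HORIZON:
        # no peak inside the wash-out window: wo (and mio) undefined
        flags.append("washout_undefined")
        wi = 0.0 if not math.isfinite(tau) else sp / tau
        auci = _auc_closed_form(fit.A, fit.k_in, fit.k_out, *AUCI_WINDOW)
        aucf = _auc_closed_form(fit.A, fit.k_in, fit.k_out, *AUCF_WINDOW)
        return DCEFeatureVector(sp=sp, tau=tau, wi=wi, wo=0.0, auci=auci,
                                aucf=aucf, mio=0.0, flags=flags)
    wi = sp / tau
    s_270 = float(model_curve(fit, np.array([fit.t0 + WASHOUT_HORIZON]))[0])
    wo = (s_270 - fit.sm) / (WASHOUT_HORIZON - tau)
    auci = _auc_closed_form(fit.A, fit.k_in, fit.k_out, *AUCI_WINDOW)
    aucf = _auc_closed_form(fit.A, fit.k_in, fit.k_out, *AUCF_WINDOW)
    return DCEFeatureVector(sp=sp, tau=tau, wi=wi, wo=wo, auci=auci,
                            aucf=aucf, mio=wi * wo, flags=flags)
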