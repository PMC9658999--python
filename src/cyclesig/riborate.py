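"""Maturation-corrected protein synthesis rate from abundance traces.

A fluorescent fusion reports only the *mature* fluorophore pool Pm, while
the protein of interest is synthesized into an immature, non-fluorescent
pool Pi that matures with first-order rate Km:

    dPi/dt = Kp(t) - Km * Pi,      dPm/dt = Km * Pi.

Eliminating Pi gives the inversion used here:

    Kp(t) = Pm''(t) / Km + Pm'(t),

so the time-varying synthesis rate follows from the first two derivatives
of the measured abundance.  Derivatives of noisy single-cell traces are
obtained from a cubic smoothing spline (smoothing chosen by generalized
cross-validation with a cap on the effective degrees of freedom), whose
first derivative is then refitted with a second, closely fitting spline to
estimate the second derivative.  No protein degradation term is included.

The fitting window is extended by a few frames beyond the cycle boundaries
so that spline edge effects fall outside the reported window; the extension
frames never appear in any output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "km_from_halftime",
    "total_abundance",
    "ExtendedWindow",
    "extend_trace",
    "SplineFit",
    "fit_abundance_spline",
    "MaturationFit",
    "estimate_kp",
]

DEFAULT_HALFTIME_MIN = 6.0  # sfGFP maturation half-time


def km_from_halftime(t_half: float) -> float:
    """First-order maturation rate from the maturation half-time: ln2/t_half."""
    if t_half <= 0:
        raise ValueError("maturation half-time must be positive")
    return math.log(2.0) / t_half


def total_abundance(mean_gfp, total_volume) -> np.ndarray:
    """Total abundance = mean concentration x total (mother plus bud) volume.

    Encodes the assumption that the tagged protein's concentration is the
    same in mother and bud, so the mother's mean GFP applies to the whole
    volume.
    """
    gfp = np.asarray(mean_gfp, dtype=float)
    vol = np.asarray(total_volume, dtype=float)
    if gfp.shape != vol.shape:
        raise ValueError("mean GFP and volume series must have equal length")
    if (vol <= 0).any():
        raise ValueError("volumes must be positive")
    return gfp * vol


@dataclass(frozen=True)
class ExtendedWindow:
    """Frame-index window for spline fitting: the cycle frames plus up to
    n_extra frames on each side.  `core` marks the cycle frames within the
    extended window; only those are reported."""

    window: slice  # into the parent trace
    core: np.ndarray  # boolean mask over the window
    leading_truncated: bool
    trailing_truncated: bool


def extend_trace(times, t_start: float, t_end: float, n_extra: int = 3) -> ExtendedWindow:
    """Extend the [t_start, t_end] frame window by n_extra frames per side.

    If the parent trace is too short the extension is truncated gracefully
    and flagged.
    """
    times = np.asarray(times, dtype=float)
    idx = np.where((times >= t_start) & (times <= t_end))[0]
    if len(idx) == 0:
        raise ValueError("cycle window contains no frames")
    lo = idx[0] - n_extra
    hi = idx[-1] + n_extra
    leading = lo < 0
    trailing = hi > len(times) - 1
    lo = max(lo, 0)
    hi = min(hi, len(times) - 1)
    core = np.zeros(hi - lo + 1, dtype=bool)
    core[idx[0] - lo : idx[-1] - lo + 1] = True
    return ExtendedWindow(
        window=slice(lo, hi + 1),
        core=core,
        leading_truncated=leading,
        trailing_truncated=trailing,
    )


@dataclass
class SplineFit:
    """A fitted cubic smoothing spline with its penalty and effective dof."""

    spline: object  # scipy BSpline
    lam: float
    edf: float

    def __call__(self, t):
        return self.spline(np.asarray(t, dtype=float))

    def derivative(self, t, nu: int = 1):
        return self.spline.derivative(nu)(np.asarray(t, dtype=float))


def _edf(times, lam: float) -> float:
    """Effective degrees of freedom = trace of the linear smoother matrix,
    obtained by probing with unit vectors (the solver is linear in y for
    fixed penalty)."""
    n = len(times)
    tr = 0.0
    e = np.zeros(n)
    for j in range(n):
        e[j] = 1.0
        tr += float(make_smoothing_spline(times, e, lam=lam)(times[j]))
        e[j] = 0.0
    return tr


def _hat_matrix(times, lam: float) -> np.ndarray:
    n = len(times)
    H = np.empty((n, n))
    e = np.zeros(n)
    for j in range(n):
        e[j] = 1.0
        H[:, j] = make_smoothing_spline(times, e, lam=lam)(times)
        e[j] = 0.0
    return H


def _gcv_lambda(times, values, max_edf: float, grid_size: int = 41):
    """Penalty minimizing the GCV score over a log grid, subject to the
    effective-dof cap."""
    n = len(times)
    span = float(times[-1] - times[0])
    # natural penalty scale ~ (span/n)^3 for a cubic smoothing spline
    scale = (span / n) ** 3
    lams = scale * np.logspace(-8, 10, grid_size)
    best_lam, best_score = None, np.inf
    for lam in lams:
        H = _hat_matrix(times, lam)
        edf = float(np.trace(H))
        if edf > max_edf:
            continue
        resid = values - H @ values
        score = (resid @ resid / n) / (1.0 - edf / n) ** 2
        if score < best_score:
            best_lam, best_score = float(lam), score
    if best_lam is None:  # every grid point exceeded the cap; take the smoothest
        best_lam = float(lams[-1])
    return best_lam


def _lambda_for_edf(times, target_edf: float):
    """Bisection on log-penalty so the smoother's effective dof hits target."""
    n = len(times)
    span = float(times[-1] - times[0])
    scale = (span / n) ** 3
    lo, hi = math.log(scale * 1e-8), math.log(scale * 1e10)
    # edf is monotonically decreasing in lambda
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _edf(times, math.exp(mid)) > target_edf:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def fit_abundance_spline(times, abundance, smoothing: float | None = None) -> SplineFit:
    """Cubic smoothing spline of an abundance trace.

    The penalty minimizes the generalized cross-validation score unless
    given explicitly; the effective degrees of freedom are capped at n/2 so
    the fit rejects artifacts and outliers instead of chasing them.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(abundance, dtype=float)
    if len(times) < 8:
        raise ValueError("need at least 8 points in the fitting window")
    if smoothing is None:
        lam = _gcv_lambda(times, values, max_edf=len(times) / 2.0)
    else:
        lam = float(smoothing)
    spl = make_smoothing_spline(times, values, lam=lam)
    return SplineFit(spline=spl, lam=lam, edf=_edf(times, lam))


@dataclass
class MaturationFit:
    """Recovered synthesis rate for one cycle.

    `kp` (and `kp_per_volume`, in a.u./min/fL, when volumes are given) is
    reported only on the original cycle window; negative values are kept
    as-is but flagged — they diagnose over-smoothing.
    """

    km: float
    abundance_spline: SplineFit
    d1_spline: SplineFit
    times: np.ndarray
    d1: np.ndarray
    kp: np.ndarray
    kp_per_volume: np.ndarray | None
    has_negative_kp: bool


def estimate_kp(
    times,
    abundance,
    km: float,
    volumes=None,
    core=None,
    smoothing: float | None = None,
    d1_edf_frac: float = 0.8,
) -> MaturationFit:
    """Recover Kp(t) = Pm''/Km + Pm' from an abundance trace.

    `times`/`abundance` span the extended fitting window; `core` is a
    boolean mask selecting the original cycle frames (all frames when
    omitted).  The abundance spline's first derivative on the frame grid is
    refitted with a closely fitting spline (effective dof ~ d1_edf_frac * n)
    whose derivative supplies Pm''.
    """
    if km <= 0:
        raise ValueError("maturation rate km must be set and positive")
    times = np.asarray(times, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    core = np.ones(len(times), dtype=bool) if core is None else np.asarray(core, bool)
    if core.shape != times.shape:
        raise ValueError("core mask must match the fitting window")

    pm_spline = fit_abundance_spline(times, abundance, smoothing=smoothing)
    d1 = pm_spline.derivative(times, nu=1)
    lam2 = _lambda_for_edf(times, d1_edf_frac * len(times))
    d1_fit = make_smoothing_spline(times, d1, lam=lam2)
    d1_spline = SplineFit(spline=d1_fit, lam=lam2, edf=_edf(times, lam2))
    d2 = d1_spline.derivative(times, nu=1)
    kp_full = d2 / km + d1_spline(times)

    t_core = times[core]
    kp = kp_full[core]
    kp_per_volume = None
    if volumes is not None:
        volumes = np.asarray(volumes, dtype=float)
        if volumes.shape != times.shape:
            raise ValueError("volume series must match the fitting window")
        kp_per_volume = kp / volumes[core]
    negative = bool((kp < 0).any())
    if negative:
        warnings.warn(
            "recovered synthesis rate goes negative; possible over-smoothing",
            stacklevel=2,
        )
    return MaturationFit(
        km=km,
        abundance_spline=pm_spline,
        d1_spline=d1_spline,
        times=t_core,
        d1=d1[core],
        kp=kp,
        kp_per_volume=kp_per_volume,
        has_negative_kp=negative,
    )
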