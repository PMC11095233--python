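"""Trajectory analysis for eggs approaching a magnet.

Input is a digitized track of axial distance-to-magnet versus time (as
exported by video tracking software).  The procedure mirrors standard
single-particle practice: smooth ``x(t)`` with a least-squares polynomial and
differentiate it analytically, and in parallel compute raw velocity and
acceleration with second-order finite differences (exact 3-point stencils on
possibly nonuniform time steps).  Velocity and acceleration are also
re-parameterized by position, and onset-based capture metrics (observed
effective range and capture time) are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "SmoothFit",
    "KinematicsProfile",
    "CaptureMetrics",
    "NotAttractedError",
    "fit_polynomial",
    "differentiate_fit",
    "finite_difference_kinematics",
    "kinematics_profile",
    "profile_vs_position",
    "capture_metrics",
    "estimate_speed_noise",
    "read_trajectory_csv",
    "write_kinematics_csv",
]


class NotAttractedError(ValueError):
    """No motion onset detected: the egg was never attracted."""


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped axial positions.

    ``t`` in seconds, strictly increasing; ``x`` in metres, the distance from
    the egg (centre) to the magnet face, non-negative.  ``frame_rate`` (Hz)
    and ``pixel_scale`` (m/px) are optional acquisition metadata.
    """

    t: np.ndarray
    x: np.ndarray
    frame_rate: float | None = None
    pixel_scale: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        if t.ndim != 1 or x.ndim != 1 or len(t) != len(x):
            raise ValueError("t and x must be 1-D arrays of equal length")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing (duplicate timestamps?)")
        if np.any(x < 0):
            raise ValueError("x must be >= 0 (distance to the magnet face)")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class SmoothFit:
    """Least-squares polynomial smoothing of x(t).

    ``coefficients`` are ascending power-series coefficients in the raw
    (unscaled) time variable; ``residual_sd`` is in metres.
    """

    coefficients: np.ndarray
    degree: int
    residual_sd: float

    def __call__(self, t):
        return np.polynomial.polynomial.polyval(np.asarray(t, float), self.coefficients)


@dataclass(frozen=True)
class KinematicsProfile:
    """Sampled kinematics: position, velocity and acceleration series (SI).

    ``v`` and ``a`` are signed (dx/dt; negative while approaching the
    magnet)."""

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.v) == len(self.a) == n):
            raise ValueError("t, x, v, a must have equal lengths")


@dataclass(frozen=True)
class CaptureMetrics:
    """Observed effective range (m) and capture time (s) from a track."""

    effective_range_obs: float
    capture_time_obs: float

    def __post_init__(self) -> None:
        if self.effective_range_obs < 0 or self.capture_time_obs < 0:
            raise ValueError("capture metrics must be >= 0")


def fit_polynomial(traj: Trajectory, degree: int | str = "auto") -> SmoothFit:
    """Least-squares polynomial of x over t.

    With ``degree="auto"`` the degree in [3, 8] minimizing the small-sample
    corrected Akaike criterion is chosen.  Raises ``ValueError`` when the fit
    is underdetermined (fewer than degree + 2 points).
    """
    n = len(traj)
    if degree == "auto":
        candidates = [d for d in range(3, 9) if n > d + 2]
        if not candidates:
            raise ValueError(f"too few points ({n}) for automatic degree selection")
        best = None
        for d in candidates:
            fit = _fit_fixed(traj, d)
            rss = max(np.sum((fit(traj.t) - traj.x) ** 2), 1e-300)
            k = d + 2  # coefficients + noise variance
            aicc = n * np.log(rss / n) + 2 * k
            if n - k - 1 > 0:
                aicc += 2 * k * (k + 1) / (n - k - 1)
            if best is None or aicc < best[0]:
                best = (aicc, fit)
        return best[1]
    degree = int(degree)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if n <= degree + 1:
        raise ValueError(f"underdetermined fit: {n} points for degree {degree}")
    return _fit_fixed(traj, degree)


def _fit_fixed(traj: Trajectory, degree: int) -> SmoothFit:
    poly = np.polynomial.Polynomial.fit(traj.t, traj.x, degree)
    resid = traj.x - poly(traj.t)
    dof = max(len(traj) - (degree + 1), 1)
    coeffs = poly.convert().coef
    if len(coeffs) < degree + 1:  # trailing zero coefficients dropped by convert
        coeffs = np.pad(coeffs, (0, degree + 1 - len(coeffs)))
    return SmoothFit(
        coefficients=coeffs,
        degree=degree,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def differentiate_fit(fit: SmoothFit):
    """Analytic first and second derivatives of the fitted polynomial.

    Returns ``(v_fn, a_fn)``: callables evaluating dx/dt and d2x/dt2.
    """
    c = fit.coefficients
    dc = np.polynomial.polynomial.polyder(c)
    ddc = np.polynomial.polynomial.polyder(c, 2)

    def v_fn(t):
        return np.polynomial.polynomial.polyval(np.asarray(t, float), dc)

    def a_fn(t):
        return np.polynomial.polynomial.polyval(np.asarray(t, float), ddc)

    return v_fn, a_fn


def finite_difference_kinematics(traj: Trajectory):
    """Second-order velocity and acceleration series by finite differences.

    Interior points use the exact 3-point stencil for nonuniform steps
    (central when steps are equal); endpoints use one-sided second-order
    3-point stencils.  Both stencils are exact on quadratics.
    Returns ``(v, a)`` arrays of the same length as the trajectory.
    """
    t, x = traj.t, traj.x
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 points for finite differences")
    v = np.empty(n)
    a = np.empty(n)
    h1 = t[1:-1] - t[:-2]
    h2 = t[2:] - t[1:-1]
    v[1:-1] = (
        -h2 / (h1 * (h1 + h2)) * x[:-2]
        + (h2 - h1) / (h1 * h2) * x[1:-1]
        + h1 / (h2 * (h1 + h2)) * x[2:]
    )
    a[1:-1] = 2.0 * (
        x[:-2] / (h1 * (h1 + h2)) - x[1:-1] / (h1 * h2) + x[2:] / (h2 * (h1 + h2))
    )
    # one-sided second-order endpoints: derivatives of the parabola through
    # the three nearest samples
    v[0], a[0] = _lagrange_derivs(t[0], t[1], t[2], x[0], x[1], x[2])
    v[-1], a[-1] = _lagrange_derivs(t[-1], t[-2], t[-3], x[-1], x[-2], x[-3])
    return v, a


def _lagrange_derivs(t0, t1, t2, x0, x1, x2):
    """First and second derivative at t0 of the parabola through 3 points."""
    d01, d02, d12 = t0 - t1, t0 - t2, t1 - t2
    # derivative of Lagrange basis at t0
    l0 = (2 * t0 - t1 - t2) / (d01 * d02)
    l1 = d02 / (-d01 * d12)
    l2 = d01 / (d02 * d12)
    d1 = x0 * l0 + x1 * l1 + x2 * l2
    d2 = 2.0 * (
        x0 / (d01 * d02) + x1 / (-d01 * d12) + x2 / (d02 * d12)
    )
    return float(d1), float(d2)


def kinematics_profile(traj: Trajectory, degree: int | str | None = None) -> KinematicsProfile:
    """Full kinematics of a track.

    With ``degree`` given (or "auto"), velocity/acceleration come from
    analytic differentiation of the polynomial smoothing; with ``degree=None``
    they come from raw finite differences.
    """
    if degree is None:
        v, a = finite_difference_kinematics(traj)
        return KinematicsProfile(t=traj.t, x=traj.x, v=v, a=a)
    fit = fit_polynomial(traj, degree)
    v_fn, a_fn = differentiate_fit(fit)
    return KinematicsProfile(t=traj.t, x=fit(traj.t), v=v_fn(traj.t), a=a_fn(traj.t))


def estimate_speed_noise(traj: Trajectory) -> float:
    """Robust speed-noise scale (m/s) of a track.

    Localization noise of standard deviation ``s`` contributes a second
    difference of x with standard deviation ``sqrt(6) s`` while the smooth
    motion contributes only O(dt^2); the median absolute second difference is
    therefore a trend-immune noise estimate.  Converted to a speed scale via
    ``sigma_v = sqrt(2) s / dt``.
    """
    if len(traj) < 4:
        return 0.0
    d2 = np.diff(traj.x, 2)
    sigma_x = 1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0)
    dt = float(np.median(np.diff(traj.t)))
    return float(np.sqrt(2.0) * sigma_x / dt)


def _onset_index(speed: np.ndarray, floor: float, run: int = 3) -> int | None:
    """First index opening a run of ``run`` consecutive samples above floor."""
    above = speed > floor
    count = 0
    for i, flag in enumerate(above):
        count = count + 1 if flag else 0
        if count >= run:
            return i - run + 1
    return None


def capture_metrics(traj: Trajectory, noise_floor: float | None = None) -> CaptureMetrics:
    """Onset-based capture metrics of a track ending at the magnet.

    Onset is the first time the finite-difference speed exceeds
    ``noise_floor`` for at least 3 consecutive samples; the observed
    effective range is ``x`` at onset and the observed capture time is the
    remaining duration of the track.  With ``noise_floor=None`` the floor
    defaults to 3x the robust speed-noise estimate of
    :func:`estimate_speed_noise`.

    Raises
    ------
    NotAttractedError
        No onset detected.
    ValueError
        The track does not end at its minimum distance.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 samples")
    if traj.x[-1] > np.min(traj.x) + 1e-12 + 1e-9 * np.ptp(traj.x):
        raise ValueError("trajectory must reach its minimum distance at the end")
    v, _ = finite_difference_kinematics(traj)
    speed = np.abs(v)
    if len(speed) >= 3:
        # 3-point median filter: a single noisy dip must not delay the onset
        med = speed.copy()
        med[1:-1] = np.median(np.stack([speed[:-2], speed[1:-1], speed[2:]]), axis=0)
        speed = med
    if noise_floor is None:
        noise_floor = 3.0 * estimate_speed_noise(traj)
    onset = _onset_index(speed, noise_floor)
    if onset is None:
        raise NotAttractedError("no sustained motion above the noise floor")
    return CaptureMetrics(
        effective_range_obs=float(traj.x[onset]),
        capture_time_obs=float(traj.t[-1] - traj.t[onset]),
    )


def profile_vs_position(profile: KinematicsProfile, noise_floor: float = 0.0):
    """Velocity and acceleration as functions of position.

    The stationary / jittery prefix before sustained motion is trimmed and
    the remaining monotone (decreasing-x) segment is re-parameterized by x.
    Returns ``(x_seg, v_of_x, a_of_x)`` with ``x_seg`` increasing.

    Raises ``ValueError`` when no monotone motion segment exists.
    """
    speed = np.abs(profile.v)
    onset = _onset_index(speed, noise_floor)
    if onset is None:
        raise ValueError("no motion segment found")
    # longest suffix on which x strictly decreases
    start = onset
    dx = np.diff(profile.x)
    for i in range(len(profile.x) - 2, onset - 1, -1):
        if dx[i] >= 0:
            start = i + 1
            break
    x_seg = profile.x[start:]
    if len(x_seg) < 2:
        raise ValueError("no monotone motion segment found")
    order = np.argsort(x_seg)
    return x_seg[order], profile.v[start:][order], profile.a[start:][order]


def read_trajectory_csv(path, pixel_scale: float | None = None) -> Trajectory:
    """Read a track CSV: either ``t,x`` (seconds, metres) or tracker-style
    ``t,x_pixels`` with ``pixel_scale`` (m/px) supplied."""
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise ValueError("trajectory CSV must contain a 't' column")
    if "x" in df.columns:
        x = df["x"].to_numpy(float)
    elif "x_pixels" in df.columns:
        if pixel_scale is None:
            raise ValueError("pixel_scale required for an 'x_pixels' column")
        x = df["x_pixels"].to_numpy(float) * pixel_scale
    else:
        raise ValueError("trajectory CSV must contain 'x' or 'x_pixels'")
    return Trajectory(t=df["t"].to_numpy(float), x=x, pixel_scale=pixel_scale)


def write_kinematics_csv(path, profile: KinematicsProfile) -> None:
    """Write a kinematics table as ``t_s, x_mm, v_mm_s, a_mm_s2``."""
    pd.DataFrame(
        {
            "t_s": profile.t,
            "x_mm": profile.x * 1e3,
            "v_mm_s": profile.v * 1e3,
            "a_mm_s2": profile.a * 1e3,
        }
    ).to_csv(path, index=False)
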