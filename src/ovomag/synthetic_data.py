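"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its parameters and a seed (its own
`numpy.random.Generator`; no process-global state), so outputs are
reproducible across runs and test orderings.  Four input kinds are covered:

* Hall-probe field scans: the cylinder field plus i.i.d. Gaussian noise;
* capture 'videos': the simulated trajectory sampled at a camera frame rate
  with Gaussian localization noise and an optional stationary lead-in;
* attraction/implantation count tables: independent binomial draws;
* egg micrographs: bright background, darker egg disc, darkest particle
  dots placed in the zona annulus until a target covered-area fraction is
  reached, plus Gaussian pixel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinematics import Trajectory
from .magnet_field import FieldMeasurement, MagnetSpec, axial_field
from .magnetophoresis import CaptureScenario, simulate_scenario
from .zp_coverage import Micrograph

__all__ = [
    "CoverageInfeasibleError",
    "SyntheticMicrograph",
    "gen_field_scan",
    "gen_capture_video",
    "gen_attraction_counts",
    "gen_egg_micrograph",
]


class CoverageInfeasibleError(ValueError):
    """The requested dot coverage cannot be reached in the band."""


def gen_field_scan(
    magnet: MagnetSpec,
    br_true: float,
    z_grid,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> list[FieldMeasurement]:
    """Noisy axial field scan of ``magnet`` with true remanence ``br_true``.

    ``z_grid`` in metres (non-negative); ``noise_sd`` in tesla.
    """
    z = np.asarray(z_grid, dtype=float)
    if z.size == 0:
        raise ValueError("z_grid must be non-empty")
    if np.any(z < 0):
        raise ValueError("z_grid must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    mag = MagnetSpec(magnet.radius, magnet.length, br_true, magnet.label)
    b = np.atleast_1d(axial_field(mag, z)).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        b = b + rng.normal(0.0, noise_sd, size=b.shape)
    sd = noise_sd if noise_sd > 0 else None
    return [FieldMeasurement(float(zi), float(bi), sd) for zi, bi in zip(z, b)]


def gen_capture_video(
    scenario: CaptureScenario,
    frame_rate: float = 30.0,
    localization_sd: float = 5e-6,
    seed: int | None = 0,
    lead_in: float = 1.0,
    quasistatic: bool = False,
) -> Trajectory:
    """Camera-sampled capture trajectory with localization noise.

    The capture is simulated (see :func:`ovomag.magnetophoresis.simulate_capture`),
    sampled at ``frame_rate`` Hz, prefixed by ``lead_in`` seconds of the egg
    stationary at the start position (the recording begins before the magnet
    takes hold), and i.i.d. Gaussian position noise of ``localization_sd``
    metres is added.  Time zero is the first video frame.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    if localization_sd < 0:
        raise ValueError("localization_sd must be >= 0")
    res = simulate_scenario(scenario, quasistatic=quasistatic)
    if not res.captured:
        raise ValueError("scenario does not produce a capture; nothing to film")
    dt = 1.0 / frame_rate
    n_lead = int(round(lead_in / dt))
    t_motion = np.arange(0.0, res.capture_time + dt / 2, dt)
    # piecewise interpolation of the dense simulated track onto frames
    x_motion = np.interp(t_motion, res.trajectory.t, res.trajectory.x)
    t = np.concatenate([np.arange(-n_lead, 0) * dt, t_motion]) + n_lead * dt
    x = np.concatenate([np.full(n_lead, scenario.z0), x_motion])
    if localization_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, localization_sd, size=x.shape)
    return Trajectory(t=t, x=np.maximum(x, 0.0), frame_rate=frame_rate)


def gen_attraction_counts(p_true, n, labels=None, seed: int | None = 0):
    """Independent binomial draws per label, as a ``ProportionSeries``.

    ``p_true`` and ``n`` are per-label arrays; ``labels`` default to
    0, 1, 2, ...
    """
    from .attraction_stats import ProportionSeries

    p = np.atleast_1d(np.asarray(p_true, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=int))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_true must lie in [0, 1]")
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    if labels is None:
        labels = np.arange(len(p), dtype=float)
    rng = np.random.default_rng(seed)
    succ = rng.binomial(n, p)
    return ProportionSeries(labels=np.asarray(labels, float), successes=succ, totals=n)


@dataclass(frozen=True)
class SyntheticMicrograph:
    """A generated micrograph plus its ground truth."""

    micrograph: Micrograph
    realized_coverage: float  # fraction of the band actually covered by dots
    n_dots: int
    dot_mask: np.ndarray
    band_mask: np.ndarray


def gen_egg_micrograph(
    egg_diameter_um: float = 150.0,
    band_width_um: float = 19.0,
    coverage: float = 0.25,
    dot_diameter_um: float = 2.0,
    pixel_size_um: float = 0.5,
    noise_sd: float = 3.0,
    seed: int | None = 0,
    background_level: float = 200.0,
    egg_level: float = 120.0,
    dot_level: float = 40.0,
    margin_um: float = 25.0,
    max_attempts: int = 400_000,
) -> SyntheticMicrograph:
    """Brightfield-like egg micrograph with particle dots in the zona band.

    Dot centres are drawn independently and uniformly over the band annulus
    (overlaps allowed -- projected particle aggregates overlap in real
    images) until the realized covered-area fraction of the band, tracked
    exactly on pixels, reaches ``coverage``; by this stopping rule the
    realized value overshoots the target by at most one dot area.  Gaussian
    pixel noise of ``noise_sd`` grey levels is added last.

    Raises :class:`CoverageInfeasibleError` when the target is not reached
    within the iteration cap (coverage too close to 1 for the dot size).
    """
    if not (0.0 <= coverage < 1.0):
        raise CoverageInfeasibleError("coverage must be in [0, 1)")
    if dot_diameter_um > band_width_um:
        raise CoverageInfeasibleError("dots do not fit inside the band")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    r_egg = egg_diameter_um / 2.0
    half = r_egg + margin_um
    n_px = int(round(2 * half / pixel_size_um))
    coords = (np.arange(n_px) + 0.5) * pixel_size_um - half
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    rr = np.hypot(yy, xx)
    egg = rr <= r_egg
    band = egg & (rr > r_egg - band_width_um)
    n_band = int(band.sum())

    img = np.full((n_px, n_px), background_level, dtype=float)
    img[egg] = egg_level

    dot_r = dot_diameter_um / 2.0
    r_in = r_egg - band_width_um + dot_r
    r_out = r_egg - dot_r
    dot_mask = np.zeros_like(egg, dtype=bool)
    covered = 0
    n_dots = 0
    target_px = coverage * n_band
    attempts = 0
    stamp_half = int(math.ceil(dot_r / pixel_size_um)) + 1
    while covered < target_px:
        attempts += 1
        if attempts > max_attempts:
            raise CoverageInfeasibleError(
                f"coverage {coverage} not reached after {max_attempts} dots"
            )
        r = math.sqrt(rng.uniform(r_in**2, r_out**2))
        theta = rng.uniform(0.0, 2.0 * math.pi)
        cy, cx = r * math.sin(theta), r * math.cos(theta)
        iy = int((cy + half) / pixel_size_um)
        ix = int((cx + half) / pixel_size_um)
        y0, y1 = max(iy - stamp_half, 0), min(iy + stamp_half + 1, n_px)
        x0, x1 = max(ix - stamp_half, 0), min(ix + stamp_half + 1, n_px)
        local = np.hypot(yy[y0:y1, x0:x1] - cy, xx[y0:y1, x0:x1] - cx) <= dot_r
        new = local & ~dot_mask[y0:y1, x0:x1] & band[y0:y1, x0:x1]
        gained = int(new.sum())
        if gained == 0:
            continue
        dot_mask[y0:y1, x0:x1] |= local
        covered += gained
        n_dots += 1

    dot_mask &= band
    img[dot_mask] = dot_level
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    return SyntheticMicrograph(
        micrograph=Micrograph(intensities=img, pixel_size=pixel_size_um),
        realized_coverage=covered / n_band,
        n_dots=n_dots,
        dot_mask=dot_mask,
        band_mask=band,
    )
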