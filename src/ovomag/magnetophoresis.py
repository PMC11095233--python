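"""Force balance and capture dynamics of a nanoparticle-coated egg.

The egg sits on the bottom of a dish, on the axis of a cylindrical magnet.
Four forces act along the axis:

* the magnetic pull ``F(z) = n * m(B(z)) * |dB/dz|`` on the ``n`` surface
  particles, where the per-particle moment ``m(B)`` is linear in the field at
  low field and saturates at ``m_s`` (superparamagnetic beads);
* Stokes drag ``gamma * v`` with ``gamma = 3 pi eta d`` (wall factor optional);
* Coulomb friction against the dish, ``mu * W`` with ``W`` the immersed
  weight, including stiction (no motion until ``F > mu_s * W``);
* inertia ``m_egg * dv/dt`` (negligible in practice: the Stokes relaxation
  time is ~1 ms against multi-second captures, and a quasi-static mode is
  provided).

The module computes the *effective range* (largest distance at which the
magnetic pull overcomes static friction) and simulates the capture
trajectory with event detection at egg-magnet contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.constants import g as G_STANDARD
from scipy.constants import mu_0
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .kinematics import Trajectory
from .magnet_field import MAGNETS, MagnetSpec, axial_field, axial_gradient

__all__ = [
    "NanoparticleSpec",
    "EggBody",
    "EggLoad",
    "Medium",
    "FrictionSpec",
    "CaptureResult",
    "CaptureScenario",
    "ESTAPOR_PARTICLE",
    "DEFAULT_EGG",
    "PBS",
    "DEFAULT_FRICTION",
    "HEX_PACKING",
    "UnboundedRangeError",
    "NeverMovesError",
    "particles_from_coverage",
    "particle_moment",
    "saturation_field",
    "magnetic_force",
    "drag_coefficient",
    "net_weight",
    "effective_range",
    "start_distance_for_speed",
    "simulate_capture",
    "default_scenario",
    "simulate_scenario",
]

#: Densest 2-D packing of equal discs, pi / (2 sqrt(3)).
HEX_PACKING = math.pi / (2.0 * math.sqrt(3.0))


class UnboundedRangeError(ValueError):
    """No friction threshold: every distance is within range."""


class NeverMovesError(ValueError):
    """Static friction exceeds the magnetic pull even at contact."""


@dataclass(frozen=True)
class NanoparticleSpec:
    """Superparamagnetic bead: diameter (m), per-particle saturation moment
    (A m^2), volume susceptibility (SI), density (kg/m^3)."""

    diameter: float
    saturation_moment: float
    susceptibility: float
    density: float = 1400.0

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValueError("particle diameter must be > 0")
        if self.saturation_moment < 0:
            raise ValueError("saturation_moment must be >= 0")
        if self.susceptibility < 0:
            raise ValueError("susceptibility must be >= 0")

    @property
    def volume(self) -> float:
        return math.pi / 6.0 * self.diameter**3


@dataclass(frozen=True)
class EggBody:
    """Spherical egg: diameter (m) and density (kg/m^3)."""

    diameter: float = 150e-6
    density: float = 1030.0

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValueError("egg diameter must be > 0")
        if not (self.density > 0):
            raise ValueError("egg density must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        return math.pi / 6.0 * self.diameter**3

    @property
    def mass(self) -> float:
        return self.density * self.volume


@dataclass(frozen=True)
class EggLoad:
    """Number of particles attached to the zona surface, and their spec."""

    n_particles: int
    particle: NanoparticleSpec

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")


@dataclass(frozen=True)
class Medium:
    """Newtonian fluid: viscosity (Pa s), density (kg/m^3)."""

    viscosity: float
    density: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.viscosity > 0):
            raise ValueError("viscosity must be > 0")
        if not (self.density > 0):
            raise ValueError("medium density must be > 0")


@dataclass(frozen=True)
class FrictionSpec:
    """Static and kinetic Coulomb friction coefficients (dimensionless)."""

    mu_static: float = 0.1
    mu_kinetic: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.mu_kinetic <= self.mu_static):
            raise ValueError("require 0 <= mu_kinetic <= mu_static")


# Defaults.  Particle magnetics correspond to ~30% w/w magnetite
# (sigma_s ~ 92 A m^2/kg, rho ~ 5200 kg/m^3) in a 0.365 um polymer bead of
# density ~1400 kg/m^3: m_s = 0.3 * rho_bead * V_bead * sigma_s ~ 1e-15 A m^2.
# These are assumed, configurable values, not measured ones.
ESTAPOR_PARTICLE = NanoparticleSpec(
    diameter=0.365e-6, saturation_moment=1.0e-15, susceptibility=1.4, density=1400.0
)
DEFAULT_EGG = EggBody(diameter=150e-6, density=1030.0)
PBS = Medium(viscosity=1.0e-3, density=1005.0, name="PBS")
DEFAULT_FRICTION = FrictionSpec(0.1, 0.1)

#: Fraction of the zona surface covered by particles in the default scenario
#: (the level measured after a 30 min incubation, at which most eggs respond).
DEFAULT_COVERAGE = 0.25


def particles_from_coverage(
    coverage_fraction: float,
    egg: EggBody = DEFAULT_EGG,
    particle: NanoparticleSpec = ESTAPOR_PARTICLE,
    packing_fraction: float = HEX_PACKING,
) -> int:
    """Particle count equivalent to covering a fraction of the egg surface.

    ``count = round(coverage * packing * 4 pi R_egg^2 / (pi r_p^2))`` -- the
    projected cross-section of each bead occupies part of the spherical zona
    surface, discounted by the 2-D packing fraction.
    """
    if not (0.0 <= coverage_fraction <= 1.0):
        raise ValueError("coverage_fraction must be in [0, 1]")
    if not (0.0 < packing_fraction <= 1.0):
        raise ValueError("packing_fraction must be in (0, 1]")
    sphere_area = math.pi * egg.diameter**2
    cross_section = math.pi * (particle.diameter / 2.0) ** 2
    return int(round(coverage_fraction * packing_fraction * sphere_area / cross_section))


def saturation_field(particle: NanoparticleSpec) -> float:
    """Flux density B* (T) at which the linear branch meets saturation."""
    chi_v = particle.susceptibility * particle.volume
    if chi_v == 0:
        return math.inf
    return mu_0 * particle.saturation_moment / chi_v


def particle_moment(particle: NanoparticleSpec, B):
    """Per-particle magnetic moment m(B) = min(chi V B / mu0, m_s) in A m^2.

    Continuous, non-decreasing, linear at low field and saturating at high
    field -- the piecewise idealization of a superparamagnetic bead.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("flux density must be >= 0")
    linear = particle.susceptibility * particle.volume * B / mu_0
    out = np.minimum(linear, particle.saturation_moment)
    return out if out.ndim else float(out)


def magnetic_force(load: EggLoad, magnet: MagnetSpec, z):
    """Axial pull (N, toward the magnet) on the whole particle load at
    distance ``z`` (m): ``n * m(B(z)) * |dB/dz|(z)``."""
    B = axial_field(magnet, z)
    grad = axial_gradient(magnet, z)
    out = load.n_particles * particle_moment(load.particle, B) * np.abs(grad)
    return out if np.ndim(out) else float(out)


def drag_coefficient(egg: EggBody, medium: Medium, wall_factor: float = 1.0) -> float:
    """Stokes drag coefficient gamma = 3 pi eta d * wall_factor (kg/s)."""
    if wall_factor < 1.0:
        raise ValueError("wall_factor must be >= 1 (wall proximity only adds drag)")
    return 3.0 * math.pi * medium.viscosity * egg.diameter * wall_factor


def net_weight(egg: EggBody, medium: Medium) -> float:
    """Immersed weight W = (rho_egg - rho_medium) V g (N).

    Positive when the egg is denser than the medium and rests on the dish;
    negative flags a floating egg (no frictional contact)."""
    return (egg.density - medium.density) * egg.volume * G_STANDARD


def _largest_root(f, z_lo: float, z_hi: float, n_grid: int = 4096) -> float:
    """Largest z in [z_lo, z_hi] with f(z) = 0, for f eventually negative."""
    zs = np.linspace(z_lo, z_hi, n_grid)
    vals = f(zs)
    above = np.nonzero(vals >= 0)[0]
    if len(above) == 0:
        raise NeverMovesError("threshold exceeds the driving force everywhere")
    i = above[-1]
    if i == n_grid - 1:
        return float(zs[-1])
    return float(brentq(f, zs[i], zs[i + 1], xtol=1e-12))


def effective_range(
    load: EggLoad,
    egg: EggBody = DEFAULT_EGG,
    magnet: MagnetSpec = MAGNETS["S-02-02"],
    medium: Medium = PBS,
    friction: FrictionSpec = DEFAULT_FRICTION,
    z_max: float = 0.2,
) -> float:
    """Largest distance (m) at which the magnetic pull overcomes static
    friction, i.e. the unique root of ``F(z) = mu_s * W`` on the decaying
    force curve.

    Raises
    ------
    UnboundedRangeError
        ``mu_s * W == 0``: there is no threshold and the range is unbounded.
    NeverMovesError
        The threshold exceeds the pull even at contact.
    ValueError
        ``W <= 0`` (floating egg: the contact-friction range is undefined)
        or an empty particle load.
    """
    w = net_weight(egg, medium)
    if w <= 0:
        raise ValueError("net weight must be > 0 (egg must rest on the dish)")
    if load.n_particles == 0:
        raise NeverMovesError("empty particle load: no magnetic force")
    threshold = friction.mu_static * w
    if threshold == 0:
        raise UnboundedRangeError("zero static friction: effective range is unbounded")
    f = lambda zz: magnetic_force(load, magnet, zz) - threshold
    if f(np.array([egg.radius]))[0] < 0:
        raise NeverMovesError("static friction exceeds the magnetic pull at contact")
    # expand the bracket until the force has decayed below threshold
    hi = z_max
    while f(np.array([hi]))[0] >= 0:
        hi *= 2.0
        if hi > 1.0:
            raise UnboundedRangeError("force above threshold out to 1 m")
    return _largest_root(f, egg.radius, hi)


def start_distance_for_speed(
    load: EggLoad,
    egg: EggBody = DEFAULT_EGG,
    magnet: MagnetSpec = MAGNETS["S-02-02"],
    medium: Medium = PBS,
    friction: FrictionSpec = DEFAULT_FRICTION,
    v_start: float = 1.0e-3,
    wall_factor: float = 1.0,
) -> float:
    """Distance (m) at which the quasi-static approach speed equals
    ``v_start`` -- the 'barely but visibly attracted' starting position used
    by the default capture scenario (see docs/methods.md)."""
    if v_start <= 0:
        raise ValueError("v_start must be > 0")
    w = max(net_weight(egg, medium), 0.0)
    gamma = drag_coefficient(egg, medium, wall_factor)
    target = gamma * v_start + friction.mu_kinetic * w
    f = lambda zz: magnetic_force(load, magnet, zz) - target
    hi = 0.2
    while f(np.array([hi]))[0] >= 0:
        hi *= 2.0
        if hi > 1.0:
            raise UnboundedRangeError("requested start speed reached beyond 1 m")
    z0 = _largest_root(f, egg.radius, hi)
    # guarantee the start is strictly inside the stiction threshold
    thr = friction.mu_static * w
    while magnetic_force(load, magnet, z0) <= thr:
        z0 *= 0.99
    return z0


@dataclass(frozen=True)
class CaptureResult:
    """Simulated approach of an egg toward the magnet.

    ``trajectory`` holds time (s) and distance-to-face of the egg centre (m);
    ``v``/``a`` are speed (m/s, positive toward the magnet) and acceleration
    along the samples; ``energy`` maps 'magnetic', 'drag', 'friction',
    'kinetic' to cumulative energies (J) on the same samples."""

    trajectory: Trajectory
    captured: bool
    capture_time: float | None
    v: np.ndarray | None = None
    a: np.ndarray | None = None
    energy: dict | None = None
    floating: bool = False


def simulate_capture(
    load: EggLoad,
    egg: EggBody = DEFAULT_EGG,
    magnet: MagnetSpec = MAGNETS["S-02-02"],
    medium: Medium = PBS,
    friction: FrictionSpec = DEFAULT_FRICTION,
    z0: float = 3.0e-3,
    *,
    quasistatic: bool = False,
    force_fn=None,
    wall_factor: float = 1.0,
    n_samples: int = 1000,
    rtol: float = 1e-9,
    atol: float | None = None,
    t_max: float | None = None,
) -> CaptureResult:
    """Integrate the capture dynamics from rest at distance ``z0``.

    The full model is ``m dv/dt = F(z) - gamma v - mu_k W`` with stiction (no
    motion unless ``F(z0) > mu_s W``) and a terminal event at egg-magnet
    contact ``z = R_egg``.  With ``quasistatic=True`` the inertial term is
    dropped and ``v(z) = (F(z) - mu_k W) / gamma`` directly.

    ``force_fn`` overrides the magnetic force curve (e.g. a constant-force
    harness for validation); it receives z in metres and returns newtons.

    ``capture_time`` is measured from motion onset (t = 0) to contact.
    """
    r_egg = egg.radius
    if not np.isfinite(z0) or z0 <= r_egg:
        raise ValueError("z0 must be finite and exceed the egg radius (contact distance)")
    gamma = drag_coefficient(egg, medium, wall_factor)
    w_raw = net_weight(egg, medium)
    floating = w_raw <= 0
    w = 0.0 if floating else w_raw  # a floating egg has no frictional contact
    mass = egg.mass
    if force_fn is None:
        force_fn = lambda zz: magnetic_force(load, magnet, zz)
    f_s = friction.mu_static * w
    f_k = friction.mu_kinetic * w

    if force_fn(z0) <= f_s:
        # stiction holds: the egg never starts to move
        t = np.array([0.0, 1.0])
        traj = Trajectory(t=t, x=np.full(2, z0))
        return CaptureResult(
            trajectory=traj, captured=False, capture_time=None,
            v=np.zeros(2), a=np.zeros(2), floating=floating,
        )

    def qs_speed(zz):
        return max(force_fn(zz) - f_k, 0.0) / gamma

    v0 = qs_speed(z0)
    travel = z0 - r_egg
    if t_max is None:
        # F is non-increasing in z on the approach, so v >= v0 all the way
        t_max = 2.0 * travel / v0 + (0.0 if quasistatic else 50.0 * mass / gamma)
    if atol is None:
        atol = rtol * max(z0, 1e-6)

    def hit(t, y):
        return y[0] - r_egg

    hit.terminal = True
    hit.direction = -1

    if quasistatic:
        def rhs(t, y):
            z, e_mag, e_drag, e_fric = y
            v = qs_speed(z)
            return [-v, force_fn(z) * v, gamma * v * v, f_k * v]

        y0 = [z0, 0.0, 0.0, 0.0]
    else:
        def rhs(t, y):
            z, v, e_mag, e_drag, e_fric = y
            dv = (force_fn(z) - gamma * v - f_k) / mass
            return [-v, dv, force_fn(z) * v, gamma * v * v, f_k * v]

        y0 = [z0, 0.0, 0.0, 0.0, 0.0]

    sol = solve_ivp(
        rhs, (0.0, t_max), y0, method="LSODA", rtol=rtol, atol=atol,
        dense_output=True, events=hit,
    )
    if sol.status != 1 or len(sol.t_events[0]) == 0:
        t_s = sol.t if len(sol.t) >= 2 else np.array([0.0, t_max])
        y_s = sol.sol(t_s)
        traj = Trajectory(t=t_s, x=np.maximum(y_s[0], 0.0))
        return CaptureResult(trajectory=traj, captured=False, capture_time=None,
                             floating=floating)

    t_event = float(sol.t_events[0][0])
    # sample uniformly in position: near the effective range the approach is
    # a slow creep followed by a fast final sprint, and uniform-in-time
    # samples would leave the sprint unresolved
    z_steps = np.append(sol.y[0], r_egg)
    t_steps = np.append(sol.t, t_event)
    z_targets = np.linspace(z0, r_egg, n_samples)
    t_s = np.interp(z_targets[::-1], z_steps[::-1], t_steps[::-1])[::-1]
    t_s[0], t_s[-1] = 0.0, t_event
    t_s = np.maximum.accumulate(t_s)
    keep = np.append(True, np.diff(t_s) > 0)
    t_s = t_s[keep]
    y_s = sol.sol(t_s)
    z_s = np.maximum(y_s[0], r_egg)
    z_s[-1] = r_egg

    if quasistatic:
        v_s = np.array([qs_speed(z) for z in z_s])
        # a = -v dv/dz = v |F'| / gamma along the path
        h = 1e-7
        dF = np.array(
            [(force_fn(z + h) - force_fn(max(z - h, r_egg))) /
             (z + h - max(z - h, r_egg)) for z in z_s]
        )
        a_s = -v_s * dF / gamma
        e_mag, e_drag, e_fric = y_s[1], y_s[2], y_s[3]
        e_kin = np.zeros_like(v_s)
    else:
        v_s = y_s[1]
        a_s = np.array([(force_fn(z) - gamma * v - f_k) / mass for z, v in zip(z_s, v_s)])
        e_mag, e_drag, e_fric = y_s[2], y_s[3], y_s[4]
        e_kin = 0.5 * mass * v_s**2

    traj = Trajectory(t=t_s, x=z_s)
    energy = {"magnetic": e_mag, "drag": e_drag, "friction": e_fric, "kinetic": e_kin}
    return CaptureResult(
        trajectory=traj, captured=True, capture_time=t_event,
        v=v_s, a=a_s, energy=energy, floating=floating,
    )


def characterize_magnet(
    load: EggLoad,
    egg: EggBody = DEFAULT_EGG,
    magnet: MagnetSpec = MAGNETS["S-02-02"],
    medium: Medium = PBS,
    friction: FrictionSpec = DEFAULT_FRICTION,
    margin: float = 0.01,
    **sim_kwargs,
):
    """Effective range and capture time of one magnet, bench-protocol style.

    The egg is released just inside the effective range (at ``(1 - margin)``
    times it, the 'barely attracted' position) and the time to contact is
    simulated.  Returns ``(effective_range, capture_time, CaptureResult)``.
    """
    if not (0.0 < margin < 1.0):
        raise ValueError("margin must be in (0, 1)")
    z_star = effective_range(load, egg, magnet, medium, friction)
    z0 = max((1.0 - margin) * z_star, egg.radius * 1.001)
    res = simulate_capture(load, egg, magnet, medium, friction, z0, **sim_kwargs)
    return z_star, res.capture_time, res


@dataclass(frozen=True)
class CaptureScenario:
    """Bundle of everything a capture simulation needs."""

    magnet: MagnetSpec
    load: EggLoad
    egg: EggBody = DEFAULT_EGG
    medium: Medium = PBS
    friction: FrictionSpec = DEFAULT_FRICTION
    z0: float = 3.0e-3
    wall_factor: float = 1.0


def default_scenario(
    magnet: str | MagnetSpec = "S-02-02",
    coverage: float = DEFAULT_COVERAGE,
    particle: NanoparticleSpec = ESTAPOR_PARTICLE,
    egg: EggBody = DEFAULT_EGG,
    medium: Medium = PBS,
    friction: FrictionSpec = DEFAULT_FRICTION,
    v_start: float = 1.0e-3,
) -> CaptureScenario:
    """Default study conditions: a 25%-covered egg in PBS released where its
    initial quasi-static speed is ``v_start`` (1 mm/s)."""
    if isinstance(magnet, str):
        magnet = MAGNETS[magnet]
    n = particles_from_coverage(coverage, egg, particle)
    load = EggLoad(n_particles=n, particle=particle)
    z0 = start_distance_for_speed(load, egg, magnet, medium, friction, v_start)
    return CaptureScenario(magnet=magnet, load=load, egg=egg, medium=medium,
                           friction=friction, z0=z0)


def simulate_scenario(scenario: CaptureScenario, **kwargs) -> CaptureResult:
    """Run :func:`simulate_capture` on a :class:`CaptureScenario`."""
    return simulate_capture(
        scenario.load, scenario.egg, scenario.magnet, scenario.medium,
        scenario.friction, scenario.z0, wall_factor=scenario.wall_factor, **kwargs
    )
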