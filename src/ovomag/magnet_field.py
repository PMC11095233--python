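"""On-axis field model for cylindrical permanent magnets.

An axially magnetized cylinder of radius ``R``, length ``L`` and remanence
``Br`` produces, on its symmetry axis at distance ``z`` from the near pole
face, the flux density

    B(z) = (Br / 2) * [ (z + L) / sqrt((z + L)^2 + R^2)
                        -  z      / sqrt(z^2 + R^2) ]

which is the standard solenoid-equivalent (surface-current) solution.  This
module provides the field, its axial gradient, and a least-squares calibration
of ``Br`` against Hall-probe scans of the axial field.

All quantities are SI (m, T); CSV interfaces use mm and mT because bench
scans are recorded that way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MagnetSpec",
    "FieldMeasurement",
    "FieldFit",
    "MAGNETS",
    "DEFAULT_REMANENCE_T",
    "axial_field",
    "axial_gradient",
    "fit_remanence",
    "read_field_scan",
    "write_field_scan",
]

#: Typical sintered-NdFeB remanence, used when no field scan is available.
#: Flagged as assumed: the source measurements print no field values.
DEFAULT_REMANENCE_T = 1.3


@dataclass(frozen=True)
class MagnetSpec:
    """Cylindrical magnet geometry and remanence.

    Parameters
    ----------
    radius, length : float
        Cylinder radius and height in metres.
    remanence : float
        Residual flux density Br in tesla.
    label : str
        Catalogue-style name, e.g. ``"S-02-02"`` (2 mm diameter x 2 mm).
    """

    radius: float
    length: float
    remanence: float = DEFAULT_REMANENCE_T
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if not (self.length > 0):
            raise ValueError(f"length must be > 0, got {self.length}")
        if self.remanence < 0:
            raise ValueError(f"remanence must be >= 0, got {self.remanence}")


#: The three magnets used for the egg-capture characterization.
MAGNETS: dict[str, MagnetSpec] = {
    "S-02-02": MagnetSpec(1.0e-3, 2.0e-3, DEFAULT_REMANENCE_T, "S-02-02"),
    "S-02-05": MagnetSpec(1.0e-3, 5.0e-3, DEFAULT_REMANENCE_T, "S-02-05"),
    "S-03-06": MagnetSpec(1.5e-3, 6.0e-3, DEFAULT_REMANENCE_T, "S-03-06"),
}


@dataclass(frozen=True)
class FieldMeasurement:
    """One Hall-probe reading: axial distance from the near pole face (m),
    field (T), optional standard deviation (T)."""

    distance: float
    field: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0 when present")


@dataclass(frozen=True)
class FieldFit:
    """Result of calibrating remanence against a field scan."""

    remanence_hat: float
    residual_rms: float
    n_points: int


def _check_z(z):
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("axial distance z must be >= 0 (measured from the near pole face)")
    return z


def _shape(z, R: float, L: float):
    """Geometric factor B(z) / Br: the field of a unit-remanence cylinder."""
    return 0.5 * ((z + L) / np.hypot(z + L, R) - z / np.hypot(z, R))


def axial_field(magnet: MagnetSpec, z):
    """On-axis flux density B(z) in tesla at distance ``z`` (m) from the face.

    Strictly decreasing and positive on z >= 0 for Br > 0.  Accepts scalars
    or arrays.
    """
    z = _check_z(z)
    out = magnet.remanence * _shape(z, magnet.radius, magnet.length)
    return out if out.ndim else float(out)


def axial_gradient(magnet: MagnetSpec, z):
    """Analytic derivative dB/dz (T/m); negative for z > 0 when Br > 0."""
    z = _check_z(z)
    R, L = magnet.radius, magnet.length
    r2 = R * R
    out = 0.5 * magnet.remanence * (
        r2 / ((z + L) ** 2 + r2) ** 1.5 - r2 / (z * z + r2) ** 1.5
    )
    return out if out.ndim else float(out)


def fit_remanence(
    measurements: Iterable[FieldMeasurement] | Sequence[FieldMeasurement],
    radius: float,
    length: float,
) -> FieldFit:
    """Least-squares remanence from an axial field scan.

    The model is linear in Br (``B = Br * f(z)`` with ``f`` the unit-remanence
    geometric factor), so the ordinary/weighted least-squares solution is in
    closed form.  Measurements carrying an ``sd`` are weighted by inverse
    variance; otherwise the fit is unweighted.

    Raises
    ------
    ValueError
        Fewer than two measurements, or all measurements at the same distance
        (degenerate design).
    """
    meas = list(measurements)
    if len(meas) < 2:
        raise ValueError("need at least 2 measurements to fit remanence")
    z = np.array([m.distance for m in meas])
    b = np.array([m.field for m in meas])
    if np.ptp(z) == 0:
        raise ValueError("degenerate design: all measurements at the same distance")
    sds = [m.sd for m in meas]
    if all(s is not None and s > 0 for s in sds):
        w = 1.0 / np.array(sds, dtype=float) ** 2
    else:
        w = np.ones_like(b)
    f = _shape(z, radius, length)
    denom = float(np.sum(w * f * f))
    if denom == 0:
        raise ValueError("degenerate design: geometric factor vanishes on all points")
    br_hat = float(np.sum(w * f * b) / denom)
    resid = b - br_hat * f
    return FieldFit(
        remanence_hat=br_hat,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=len(meas),
    )


def read_field_scan(path) -> list[FieldMeasurement]:
    """Read a field-scan CSV with columns ``z_mm, B_mT[, sd_mT]``."""
    df = pd.read_csv(path)
    for col in ("z_mm", "B_mT"):
        if col not in df.columns:
            raise ValueError(f"field scan CSV must contain column '{col}'")
    has_sd = "sd_mT" in df.columns
    out = []
    for _, row in df.iterrows():
        sd = float(row["sd_mT"]) * 1e-3 if has_sd and np.isfinite(row["sd_mT"]) else None
        out.append(
            FieldMeasurement(
                distance=float(row["z_mm"]) * 1e-3,
                field=float(row["B_mT"]) * 1e-3,
                sd=sd,
            )
        )
    return out


def write_field_scan(path, measurements: Iterable[FieldMeasurement]) -> None:
    """Write measurements as ``z_mm, B_mT[, sd_mT]`` CSV."""
    meas = list(measurements)
    data = {
        "z_mm": [m.distance * 1e3 for m in meas],
        "B_mT": [m.field * 1e3 for m in meas],
    }
    if any(m.sd is not None for m in meas):
        data["sd_mT"] = [m.sd * 1e3 if m.sd is not None else np.nan for m in meas]
    pd.DataFrame(data).to_csv(path, index=False)
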