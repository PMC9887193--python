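"""Steady two-phase laminar blood flow in a rigid circular vessel.

Blood flowing in a vessel segregates into an RBC-rich core of viscosity
``mu_core`` and a cell-free plasma annulus of viscosity ``mu_plasma`` next to
the wall.  With a piecewise-constant viscosity

    mu(r) = mu_core    for 0 <= r <= lambda * r_vessel
    mu(r) = mu_plasma  for lambda * r_vessel < r <= r_vessel

the steady axisymmetric Stokes equation

    dp/dz = mu(r) * (1/r) d/dr ( r dv_z/dr )

with no-slip at the wall and velocity + shear-stress continuity at the
core/plasma interface has a closed-form solution: a two-segment parabola.
Writing ``A = dp/dz`` (negative for flow in +z) and ``C = -A/4``:

    v_p(r) = (C / mu_plasma) * (r_vessel**2 - r**2)              (plasma)
    v_c(r) = C * [ (lam**2 r_v**2 - r**2) / mu_core
                   + r_v**2 (1 - lam**2) / mu_plasma ]           (core)

The ratio of the quadratic (r**2) coefficients of the two branches,

    a_plasma / a_core = (A / 4 mu_plasma) / (A / 4 mu_core)
                      = mu_core / mu_plasma,

equals the whole blood relative viscosity (WBRV, ``eta_r``): whole-blood
viscosity over plasma viscosity.  Fitting the two parabolas to a measured
velocity profile therefore turns a viscometry problem into an imaging one.

Units
-----
Lengths in mm, velocities in mm/s, viscosities in mPa*s, pressure gradient
in Pa/m.  These units are mutually consistent:
``Pa/m * mm**2 / mPa*s == mm/s`` exactly, so no conversion factors appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg


class OutOfLumenError(ValueError):
    """Radius outside [0, r_vessel]."""


class DegenerateFitError(ValueError):
    """Parabola coefficients unusable (zero core coefficient, empty profile...)."""


class InconsistentFitError(ValueError):
    """Core and plasma branch coefficients have opposite signs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselGeometry:
    """Rigid circular vessel with a cell-free plasma layer at the wall.

    Parameters
    ----------
    r_vessel : float
        Inner (lumen) radius, mm.
    lambda_core : float
        Ratio of the core-region radius to the lumen radius,
        ``lambda = 1 - delta / r_vessel`` where ``delta`` is the
        cell-free-layer width.  In (0, 1].
    """

    r_vessel: float
    lambda_core: float

    def __post_init__(self) -> None:
        if not self.r_vessel > 0:
            raise ValueError(f"r_vessel must be positive, got {self.r_vessel}")
        if not 0 < self.lambda_core <= 1:
            raise ValueError(
                f"lambda_core must be in (0, 1], got {self.lambda_core}"
            )

    @property
    def delta(self) -> float:
        """Cell-free-layer width, mm: ``(1 - lambda) * r_vessel``."""
        return (1.0 - self.lambda_core) * self.r_vessel

    @property
    def r_core(self) -> float:
        """Core-region radius ``lambda * r_vessel``, mm."""
        return self.lambda_core * self.r_vessel

    @classmethod
    def from_delta(cls, r_vessel: float, delta: float) -> "VesselGeometry":
        """Construct from the cell-free-layer width instead of lambda."""
        if not 0 <= delta < r_vessel:
            raise ValueError(f"delta must be in [0, r_vessel), got {delta}")
        return cls(r_vessel=r_vessel, lambda_core=1.0 - delta / r_vessel)


@dataclass(frozen=True)
class TwoPhaseFluid:
    """Two Newtonian phases driven by an axial pressure gradient.

    Parameters
    ----------
    mu_core : float
        Core-region (whole blood) viscosity, mPa*s.
    mu_plasma : float
        Plasma viscosity, mPa*s.
    pressure_gradient : float
        ``A = dp/dz`` in Pa/m; negative for flow in +z.
    """

    mu_core: float
    mu_plasma: float
    pressure_gradient: float

    def __post_init__(self) -> None:
        if not self.mu_plasma > 0:
            raise ValueError(f"mu_plasma must be positive, got {self.mu_plasma}")
        if self.mu_core < self.mu_plasma:
            raise ValueError(
                f"mu_core ({self.mu_core}) must be >= mu_plasma ({self.mu_plasma})"
            )
        if not self.pressure_gradient < 0:
            raise ValueError(
                "pressure_gradient must be negative for forward flow, "
                f"got {self.pressure_gradient}"
            )

    @property
    def eta_r(self) -> float:
        """Whole blood relative viscosity ``mu_core / mu_plasma``."""
        return self.mu_core / self.mu_plasma


@dataclass
class VelocityProfile:
    """Radial grid of streamwise velocities.

    ``radii`` (mm) span [0, r_vessel] or [-r_vessel, r_vessel]; ``velocities``
    (mm/s) are the corresponding v_z values.  No-slip holds at |r| = r_vessel
    and the profile is even in r.
    """

    radii: np.ndarray
    velocities: np.ndarray
    geometry: VesselGeometry

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.radii.shape != self.velocities.shape:
            raise ValueError("radii and velocities must have the same shape")

    def velocity_at(self, r) -> np.ndarray:
        """Interpolate v(|r|) on the stored grid (linear)."""
        return np.interp(np.abs(r), np.abs(self.radii), self.velocities)

    @property
    def v_max(self) -> float:
        return float(np.max(self.velocities))


@dataclass(frozen=True)
class ParabolaPair:
    """Quadratic (r**2) coefficients of the two profile branches.

    Both coefficients are negative for forward flow (parabolas open
    downward); ``|a_plasma| >= |a_core|`` since the plasma is less viscous.
    ``breakpoint`` is the interface radius ``lambda * r_vessel`` in mm.
    """

    a_core: float
    a_plasma: float
    breakpoint: float


# ---------------------------------------------------------------------------
# Closed-form solution
# ---------------------------------------------------------------------------

def analytic_velocity(r, fluid: TwoPhaseFluid, geom: VesselGeometry):
    """Closed-form two-segment parabolic velocity, mm/s.

    Accepts a scalar or array of radii (mm, sign ignored).  Raises
    :class:`OutOfLumenError` for |r| > r_vessel.
    """
    r = np.abs(np.asarray(r, dtype=float))
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    rv = geom.r_vessel
    if np.any(r > rv * (1 + 1e-12)):
        raise OutOfLumenError(f"radius beyond lumen radius {rv} mm")
    c = -fluid.pressure_gradient / 4.0
    lam = geom.lambda_core
    rc = lam * rv
    v_plasma = (c / fluid.mu_plasma) * (rv**2 - r**2)
    v_core = c * (
        (rc**2 - r**2) / fluid.mu_core
        + rv**2 * (1.0 - lam**2) / fluid.mu_plasma
    )
    v = np.where(r <= rc, v_core, v_plasma)
    return float(v[0]) if scalar else v


def pressure_gradient_for_center_velocity(
    v_center: float, mu_core: float, mu_plasma: float, geom: VesselGeometry
) -> float:
    """Pressure gradient A (Pa/m, negative) giving centerline velocity v_center mm/s."""
    if not v_center > 0:
        raise ValueError("v_center must be positive")
    lam = geom.lambda_core
    rv = geom.r_vessel
    shape = (lam * rv) ** 2 / mu_core + rv**2 * (1.0 - lam**2) / mu_plasma
    return -4.0 * v_center / shape


# ---------------------------------------------------------------------------
# Numeric oracle: finite-volume solution of the Stokes BVP
# ---------------------------------------------------------------------------

def _radial_grid(geom: VesselGeometry, n_grid: int) -> np.ndarray:
    """Grid on [0, r_vessel], uniform on each side of the interface.

    The interface radius lambda*r_vessel is always a node so the viscosity
    kink is never smeared across a cell.
    """
    rv, rc = geom.r_vessel, geom.r_core
    if geom.lambda_core >= 1.0:
        return np.linspace(0.0, rv, n_grid)
    n_core = max(2, int(round(n_grid * rc / rv)))
    n_plasma = max(2, n_grid - n_core + 1)
    return np.concatenate(
        [np.linspace(0.0, rc, n_core), np.linspace(rc, rv, n_plasma)[1:]]
    )


def solve_profile_numeric(
    fluid: TwoPhaseFluid, geom: VesselGeometry, n_grid: int = 1000
) -> VelocityProfile:
    """Solve the piecewise-viscosity Stokes equation by finite volumes.

    Independent of the closed form: discretizes the conservative flux form
    ``d/dr ( r mu(r) dv/dr ) = A r`` on [0, r_vessel] with symmetry at the
    axis (zero flux) and no-slip at the wall, and solves the resulting
    tridiagonal system.  Cell-edge viscosity is the cell's own (cells never
    straddle the interface because the interface is a node).
    """
    if n_grid < 50:
        raise ValueError(f"n_grid must be >= 50, got {n_grid}")
    a_grad = fluid.pressure_gradient
    r = _radial_grid(geom, n_grid)
    n = r.size
    r_mid = 0.5 * (r[:-1] + r[1:])  # cell edges, n-1 of them
    h = np.diff(r)
    mu_mid = np.where(r_mid <= geom.r_core, fluid.mu_core, fluid.mu_plasma)
    # conductance of each cell face: r*mu/h
    g = r_mid * mu_mid / h

    # unknowns: v[0..n-2]; v[n-1] = 0 (no-slip)
    m = n - 1
    ab = np.zeros((3, m))
    rhs = np.zeros(m)
    # node 0: control volume [0, r_mid[0]]; zero flux at the axis
    ab[1, 0] = -g[0]
    ab[0, 1] = g[0]
    rhs[0] = a_grad * 0.5 * r_mid[0] ** 2
    for i in range(1, m):
        left = 0.0 if i - 1 < 0 else r_mid[i - 1] ** 2
        rhs[i] = a_grad * 0.5 * (r_mid[i] ** 2 - left)
        ab[1, i] = -(g[i - 1] + g[i])
        ab[2, i - 1] = g[i - 1]
        if i + 1 < m:
            ab[0, i + 1] = g[i]
        # else: couples to v[n-1] = 0, nothing to add to rhs
    v = scipy.linalg.solve_banded((1, 1), ab, rhs)
    velocities = np.concatenate([v, [0.0]])
    return VelocityProfile(radii=r, velocities=velocities, geometry=geom)


# ---------------------------------------------------------------------------
# WBRV identity and profile utilities
# ---------------------------------------------------------------------------

def quadratic_coefficients(fluid: TwoPhaseFluid, geom: VesselGeometry) -> ParabolaPair:
    """r**2 coefficients of the two branches: ``A/(4 mu)`` per phase."""
    a = fluid.pressure_gradient
    return ParabolaPair(
        a_core=a / (4.0 * fluid.mu_core),
        a_plasma=a / (4.0 * fluid.mu_plasma),
        breakpoint=geom.r_core,
    )


def wbrv_from_coefficients(pair: ParabolaPair) -> float:
    """WBRV ``eta_r = a_plasma / a_core`` (= mu_core / mu_plasma)."""
    if pair.a_core == 0:
        raise DegenerateFitError("core-branch quadratic coefficient is zero")
    if pair.a_core * pair.a_plasma < 0:
        raise InconsistentFitError(
            "core and plasma coefficients have opposite signs"
        )
    return pair.a_plasma / pair.a_core


def normalize_profile(profile: VelocityProfile) -> VelocityProfile:
    """Scale velocities so the maximum is 1; shape and breakpoint unchanged."""
    vmax = profile.v_max
    if not vmax > 0:
        raise DegenerateFitError("cannot normalize an all-zero velocity profile")
    return VelocityProfile(
        radii=profile.radii.copy(),
        velocities=profile.velocities / vmax,
        geometry=profile.geometry,
    )


# ---------------------------------------------------------------------------
# Serialization: two-column delimited text with a comment header
# ---------------------------------------------------------------------------

def write_profile(profile: VelocityProfile, path, fluid: TwoPhaseFluid | None = None) -> None:
    header = [
        f"r_vessel_mm = {profile.geometry.r_vessel!r}",
        f"lambda_core = {profile.geometry.lambda_core!r}",
    ]
    if fluid is not None:
        header += [
            f"mu_core_mPas = {fluid.mu_core!r}",
            f"mu_plasma_mPas = {fluid.mu_plasma!r}",
            f"pressure_gradient_Pa_per_m = {fluid.pressure_gradient!r}",
        ]
    header.append("columns: radius_mm velocity_mm_s")
    np.savetxt(
        path,
        np.column_stack([profile.radii, profile.velocities]),
        header="\n".join(header),
        fmt="%.9e",
    )


def read_profile(path) -> VelocityProfile:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    pass
    data = np.loadtxt(path)
    geom = VesselGeometry(
        r_vessel=meta["r_vessel_mm"], lambda_core=meta["lambda_core"]
    )
    return VelocityProfile(radii=data[:, 0], velocities=data[:, 1], geometry=geom)
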