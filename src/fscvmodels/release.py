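"""Striatal dopamine concentration under the three release-model variants.

All variants share the stimulus drive DA_P * I * f * S(t) * A(t) (release
per pulse scaled by the plasticity kinetic A) and Michaelis-Menten DAT
uptake Vm*C/(C+Km):

* Simple Uniform Release (SUR): a single well-mixed compartment,
  d[DA]_S/dt = drive - uptake.
* Spatiotemporal Uniform Release (STUR): radial reaction-diffusion in a
  tissue cylinder of radius R_L with uniformly distributed release sites;
  a "dead space" annulus of width R_D just inside the outer boundary has
  diffusion only (no release, no uptake). The electrode reads the
  concentration at R = R_L.
* Spatiotemporal Discrete Release (STDR): as STUR but release enters at
  discrete radii R_i, each a concentric cylindrical shell source.

The diffusion operator is discretized in conservative finite-volume form
(no-flux at both boundaries), so total dopamine mass is conserved to
round-off when release and uptake are switched off. Time stepping is
Crank-Nicolson in the diffusion operator with the nonlinear reaction
handled explicitly; an explicit-Euler scheme with a stability guard is
available for cross-checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import constants
from ._kernels import pde_forward, sur_forward
from .plasticity import PlasticityParams, simulate_kinetics
from .stimulus import BurstProtocol

__all__ = [
    "ReleaseUptakeParams",
    "GeometryParams",
    "ConcentrationField",
    "mm_uptake",
    "dead_space_mask",
    "simulate_sur",
    "simulate_stur",
    "simulate_stdr",
    "annular_volumes",
    "default_site_positions",
]

#: Negative-concentration tolerance: undershoot within
#: max(NEG_TOL_ABS, NEG_TOL_REL * field max) is clamped with a warning
#: (bounded Crank-Nicolson ringing around sharp sources); anything larger
#: aborts the run as solver instability.
NEG_TOL_ABS = 1e-6
NEG_TOL_REL = 5e-3


@dataclass(frozen=True)
class ReleaseUptakeParams:
    """Release magnitude and DAT uptake parameters.

    da_p is the dopamine released per unit stimulus current: uM/mA for the
    uniform models, uM*um/mA for the discrete model (a shell source has
    units of concentration times length). ``scale`` is an optional
    dimensionless factor on the release drive, default 1.
    """

    da_p: float
    v_m: float
    km: float = constants.KM_DEFAULT
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.da_p < 0:
            raise ValueError("da_p must be non-negative")
        if self.v_m < 0:
            raise ValueError("v_m must be non-negative")
        if self.km <= 0:
            raise ValueError("km must be positive")


@dataclass(frozen=True)
class GeometryParams:
    """Cylinder geometry and diffusion settings for the spatial models.

    r_l : cylinder radius (um); the electrode reads [DA] at R = r_l.
    r_d : dead-space annulus width (um); tissue in [r_l - r_d, r_l] has
          neither release nor uptake. r_d = 0 disables the dead space
          entirely (the limit in which the spatial models reduce to the
          well-mixed one).
    d : dopamine diffusion coefficient (um^2/s), tortuosity-corrected.
    dr : radial grid spacing (um).
    site_positions : radii of discrete release sites (um, STDR only);
          default evenly spaced every 6 um across the active region.
    """

    r_l: float = constants.CYLINDER_RADIUS
    r_d: float = constants.DEAD_SPACE_RADIUS
    d: float = constants.DIFFUSION_COEFF
    dr: float = constants.SOLVER_DR
    site_positions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.r_d < self.r_l):
            raise ValueError("need 0 <= r_d < r_l")
        if self.d <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.dr <= 0 or self.dr >= self.r_l:
            raise ValueError("grid spacing dr must lie in (0, r_l)")
        if self.r_d > 0 and self.dr >= self.r_d:
            raise ValueError("grid spacing dr must resolve the dead space (dr < r_d)")
        if self.site_positions is not None:
            sites = tuple(float(r) for r in self.site_positions)
            object.__setattr__(self, "site_positions", sites)
            for r in sites:
                if not (0 < r < self.r_l - self.r_d):
                    raise ValueError(
                        f"release site at R = {r} um lies outside the active "
                        f"region (0, {self.r_l - self.r_d}) um"
                    )

    @property
    def active_radius(self) -> float:
        """Outer edge of the release/uptake-active region, r_l - r_d (um)."""
        return self.r_l - self.r_d

    def radii(self) -> np.ndarray:
        n = int(round(self.r_l / self.dr))
        if abs(n * self.dr - self.r_l) > 1e-9:
            raise ValueError("dr must divide r_l evenly")
        return np.linspace(0.0, self.r_l, n + 1)


@dataclass
class ConcentrationField:
    """Radial concentration snapshots [DA](R, t) from a spatial model run."""

    radii: np.ndarray
    times: np.ndarray
    values: np.ndarray  # (n_times, n_radii), uM
    dr: float

    def mass(self) -> np.ndarray:
        """Total dopamine per unit axial length at each snapshot (uM*um^2)."""
        v = annular_volumes(self.radii, self.dr)
        return self.values @ v


def mm_uptake(c, v_m: float, km: float):
    """Michaelis-Menten DAT uptake rate Vm*C/(C+Km) in uM/s."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = v_m * c / (c + km)
    return out if out.shape else float(out)


def dead_space_mask(r, geom: GeometryParams):
    """Indicator eta(R): 1 in the active region R < r_l - r_d, else 0.

    With r_d = 0 the whole cylinder (boundary included) is active.
    """
    r = np.asarray(r, dtype=float)
    if geom.r_d == 0:
        out = np.ones_like(r)
    else:
        out = np.where(r < geom.active_radius, 1.0, 0.0)
    return out if out.shape else float(out)


def _eta_cell_fractions(geom: GeometryParams, radii: np.ndarray) -> np.ndarray:
    """Active-volume fraction of each finite-volume cell (solver-internal).

    The Heaviside dead-space mask is rendered on the grid as the exact
    fraction of each cell's annular volume lying inside the active region
    R < r_l - r_d, which keeps the spatial discretization second-order
    across the mask edge (a sharp 0/1 mask would pin the edge to the
    nearest node and reintroduce an O(dr) geometry error).
    """
    if geom.r_d == 0:
        return np.ones(radii.size)
    ra = geom.active_radius
    lo_edge = np.clip(radii - geom.dr / 2.0, 0.0, None)
    hi_edge = np.minimum(radii + geom.dr / 2.0, geom.r_l)
    hi_act = np.clip(np.minimum(hi_edge, ra), lo_edge, None)
    return (hi_act**2 - lo_edge**2) / (hi_edge**2 - lo_edge**2)


def annular_volumes(radii: np.ndarray, dr: float) -> np.ndarray:
    """Finite-volume cell areas (per unit axial length) for the radial grid.

    Interior node i owns the annulus [r_i - dr/2, r_i + dr/2]; the
    boundary nodes own half cells. These weights make the discrete mass
    sum_i V_i C_i exactly conserved by the diffusion operator.
    """
    n = radii.size
    v = 2.0 * np.pi * radii * dr
    v[0] = np.pi * (dr / 2.0) ** 2
    r_n = radii[-1]
    v[-1] = np.pi * (r_n**2 - (r_n - dr / 2.0) ** 2)
    return v


def _diffusion_bands(radii: np.ndarray, dr: float, d: float):
    """Tridiagonal bands of the conservative radial diffusion operator L."""
    n = radii.size
    v = annular_volumes(radii, dr)
    faces = radii[:-1] + dr / 2.0  # r_{i+1/2}
    cond = 2.0 * np.pi * faces * d / dr  # face conductances
    lo = np.zeros(n)
    di = np.zeros(n)
    up = np.zeros(n)
    up[:-1] = cond / v[:-1]
    lo[1:] = cond / v[1:]
    di = -(up + lo)
    return lo, di, up


def _uniform_dt(tgrid: np.ndarray) -> float:
    tgrid = np.asarray(tgrid, dtype=float)
    if tgrid.ndim != 1 or tgrid.size < 2:
        raise ValueError("tgrid must be a 1-D array with >= 2 points")
    steps = np.diff(tgrid)
    dt = float(steps[0])
    if np.any(np.abs(steps - dt) > 1e-9 * max(dt, 1.0)):
        raise ValueError("tgrid must be uniformly spaced")
    return dt


def _drive_half_grid(protocol, plasticity, params, tgrid, initial_H):
    """Release drive DA_P*I*f*S*A on the half-step-resolution grid."""
    dt = _uniform_dt(tgrid)
    n = tgrid.size
    t2 = tgrid[0] + 0.5 * dt * np.arange(2 * n - 1)
    A, _ = simulate_kinetics(protocol, plasticity, t2, initial_H=initial_H)
    S = protocol.indicator(t2)
    amp = params.da_p * protocol.current * protocol.frequency * params.scale
    return amp * S * A, dt


def simulate_sur(
    protocol: BurstProtocol,
    plasticity: PlasticityParams,
    params: ReleaseUptakeParams,
    tgrid: np.ndarray,
    initial_H=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Simple Uniform Release: well-mixed [DA]_S(t) on the given fine grid."""
    drive2, dt = _drive_half_grid(protocol, plasticity, params, tgrid, initial_H)
    return sur_forward(drive2, dt, params.v_m, params.km, 0.0)


def _run_pde(
    protocol,
    plasticity,
    params,
    geom,
    tgrid,
    source_profile,
    eta,
    initial_H,
    scheme,
    initial_field=None,
):
    radii = geom.radii()
    dt = _uniform_dt(tgrid)
    # drive at the quarter-step times t_n + dt/4 and t_n + 3dt/4: the
    # midpoint-rule nodes of the two Strang reaction half-intervals
    n_steps = tgrid.size - 1
    tq = tgrid[0] + 0.25 * dt + 0.5 * dt * np.arange(2 * n_steps)
    A, _ = simulate_kinetics(protocol, plasticity, tq, initial_H=initial_H)
    amp = params.da_p * protocol.current * protocol.frequency * params.scale
    drive_q = amp * protocol.indicator(tq) * A
    lo, di, up = _diffusion_bands(radii, geom.dr, geom.d)
    c0 = (
        np.zeros(radii.size)
        if initial_field is None
        else np.asarray(initial_field, dtype=float).copy()
    )
    snap_every = max(1, int(round((1.0 / constants.FSCV_SAMPLING_RATE) / dt)))
    if scheme == "cn":
        trace, snaps, min_val, max_val = pde_forward(
            c0, lo, di, up, dt, source_profile, eta, drive_q, params.v_m,
            params.km, snap_every,
        )
    elif scheme == "euler":
        mu = geom.d * dt / geom.dr**2
        if mu > 0.5:
            raise ValueError(
                f"explicit scheme unstable: D*dt/dr^2 = {mu:.3g} > 0.5"
            )
        drive_mid = 0.5 * (drive_q[0::2] + drive_q[1::2])
        trace, snaps, min_val, max_val = _euler_pde(
            c0, lo, di, up, dt, source_profile, eta, drive_mid, params.v_m,
            params.km, snap_every,
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    neg_tol = max(NEG_TOL_ABS, NEG_TOL_REL * max_val)
    if min_val < -neg_tol:
        raise RuntimeError(
            f"solver instability: concentration reached {min_val:.3g} uM "
            f"(tolerance {neg_tol:.3g} uM)"
        )
    if min_val < 0.0:
        warnings.warn(
            f"clamped bounded concentration undershoot ({min_val:.3g} uM)",
            RuntimeWarning,
            stacklevel=3,
        )
    snap_times = tgrid[0] + dt * snap_every * np.arange(snaps.shape[0])
    fld = ConcentrationField(radii=radii, times=snap_times, values=snaps, dr=geom.dr)
    return fld, trace


def _euler_pde(c0, lo, di, up, dt, source_profile, eta, drive_mid, vm, km, snap_every):
    n_steps = drive_mid.size
    c = c0.copy()
    trace = np.empty(n_steps + 1)
    trace[0] = c[-1]
    n_snaps = n_steps // snap_every + 1
    snaps = np.empty((n_snaps, c.size))
    snaps[0] = c
    ks = 1
    min_val = 0.0
    max_val = 0.0
    for step in range(n_steps):
        react = source_profile * drive_mid[step] - eta * vm * c / (c + km)
        c = c + dt * react
        lc = di * c
        lc[:-1] += up[:-1] * c[1:]
        lc[1:] += lo[1:] * c[:-1]
        c = c + dt * lc
        m = c.min()
        if m < min_val:
            min_val = m
        mx = c.max()
        if mx > max_val:
            max_val = mx
        np.clip(c, 0.0, None, out=c)
        trace[step + 1] = c[-1]
        if (step + 1) % snap_every == 0 and ks < n_snaps:
            snaps[ks] = c
            ks += 1
    return trace, snaps, min_val, max_val


def simulate_stur(
    protocol: BurstProtocol,
    plasticity: PlasticityParams,
    params: ReleaseUptakeParams,
    geom: GeometryParams,
    tgrid: np.ndarray,
    initial_H=(1.0, 1.0, 1.0),
    scheme: str = "cn",
    initial_field=None,
):
    """Spatiotemporal Uniform Release.

    Returns (ConcentrationField, [DA]_S trace at R = r_l on the fine grid).
    """
    radii = geom.radii()
    eta = _eta_cell_fractions(geom, radii)
    return _run_pde(
        protocol, plasticity, params, geom, tgrid, eta.copy(), eta,
        initial_H, scheme, initial_field,
    )


def default_site_positions(geom: GeometryParams, spacing: float = constants.SITE_SPACING):
    """Evenly spaced discrete release sites across the active region."""
    sites = np.arange(spacing, geom.active_radius, spacing)
    if sites.size == 0:
        raise ValueError("no release sites fit inside the active region")
    return tuple(float(s) for s in sites)


def simulate_stdr(
    protocol: BurstProtocol,
    plasticity: PlasticityParams,
    params: ReleaseUptakeParams,
    geom: GeometryParams,
    tgrid: np.ndarray,
    initial_H=(1.0, 1.0, 1.0),
    scheme: str = "cn",
    initial_field=None,
):
    """Spatiotemporal Discrete Release: shell sources at geom.site_positions.

    Each delta source at R_i is deposited into its nearest grid cell
    (ties toward smaller R), scaled by R_i / (r_cell * dr) so the injected
    mass per unit axial length is exactly 2*pi*R_i * DA_P*I per pulse,
    independent of the grid spacing.
    """
    radii = geom.radii()
    eta = _eta_cell_fractions(geom, radii)
    sites = geom.site_positions
    if sites is None:
        sites = default_site_positions(geom)
    profile = np.zeros(radii.size)
    for r_i in sites:
        if not (0 < r_i < geom.active_radius):
            raise ValueError(f"site at R = {r_i} um lies in the dead space")
        # nearest cell; exact midpoint ties resolve toward smaller R
        j = int(np.ceil(r_i / geom.dr - 0.5))
        j = min(max(j, 1), radii.size - 1)
        profile[j] += r_i / (radii[j] * geom.dr)
    return _run_pde(
        protocol, plasticity, params, geom, tgrid, profile, eta,
        initial_H, scheme, initial_field,
    )
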