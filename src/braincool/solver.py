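"""Finite-volume solver for the nonlinear Pennes bioheat equation.

The probe is an internal Dirichlet boundary (fixed surface temperature); the
outer boundary of the simulated brain volume is fixed at the core temperature.
Two geometries are supported:

* ``axisymmetric`` (default): a cylindrical (r, z) grid with the probe on the
  axis.  The cubic 8e6 mm^3 region of interest is represented by an
  equal-volume cylinder.  This is the workhorse for validation runs and
  design sweeps.
* ``cartesian3d``: a graded tensor-product voxel grid; used to cross-check
  the axisymmetric reduction.

Space is discretized with a conservative finite-volume scheme on graded
grids (fine near the probe, coarse at the far boundary); time with implicit
Euler.  The temperature-dependent perfusion and metabolism coefficients are
lagged and corrected by fixed-point iteration to a stated tolerance each
step, so the scheme is unconditionally stable and the nonlinearity is fully
converged at every accepted time level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import cg, splu
from scipy.special import k0

from .exceptions import GeometryError, SolverError
from .properties import (BloodProperties, TissueProperties, metabolic_rate,
                         perfusion_rate)

_MM = 1e-3  # grid coordinates are mm; assembly is SI


@dataclass(frozen=True)
class ShellSpec:
    """Optional conjugate conductive shell between coolant and tissue.

    Defaults are sapphire.  When present, the Dirichlet condition moves to the
    inner shell surface (``internal_temperature``) and the shell band conducts
    but has no perfusion or metabolism.
    """

    conductivity: float = 25.2
    specific_heat: float = 757.304
    density: float = 3980.0
    thickness: float = 0.5  # mm
    internal_temperature: float = 0.0  # degC


@dataclass(frozen=True)
class ProbeSpec:
    """Cylindrical cooling probe, modeled as a capped cylinder.

    Only the actively cooled tip segment is modeled; geometry in mm.
    """

    outer_diameter: float = 3.3
    tip_length: float = 25.0
    surface_temperature: float = 15.0
    shell: ShellSpec | None = None

    def __post_init__(self) -> None:
        if self.outer_diameter <= 0 or self.tip_length <= 0:
            raise ValueError("probe dimensions must be positive")
        if self.shell is not None and not (0 < self.shell.thickness
                                           < self.outer_diameter / 2):
            raise ValueError("shell thickness must lie in (0, OD/2)")

    @property
    def radius(self) -> float:
        return self.outer_diameter / 2.0


@dataclass(frozen=True)
class SimulationDomain:
    """Simulated brain volume, probe centered at the origin.

    The default is the 8e6 mm^3 region of interest with its outer boundary
    held at 37 degC.  In axisymmetric mode the cube is replaced by an
    equal-volume cylinder of the same height.  ``h_fine`` (mm) is the grid
    spacing near the probe; cells grow geometrically toward the boundary up
    to ``h_max``.
    """

    mode: str = "axisymmetric"
    height: float = 200.0            # mm, z extent
    radius: float | None = None      # mm; default equal-volume cylinder
    extent: tuple[float, float, float] = (200.0, 200.0, 200.0)  # 3-D mode
    volume_mm3: float = 8.0e6
    boundary_temperature: float = 37.0
    axial_boundary: str = "dirichlet"   # or "neumann" (insulated z faces)
    h_fine: float = 0.5
    h_fine3: float = 1.0             # near-probe spacing in cartesian3d
    h_max: float = 4.0
    fine_margin: float = 20.0        # mm of uniformly fine mesh past the probe
    growth: float = 1.3

    def __post_init__(self) -> None:
        if self.mode not in ("axisymmetric", "cartesian3d"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")
        if self.axial_boundary not in ("dirichlet", "neumann"):
            raise ValueError(f"unknown axial boundary {self.axial_boundary!r}")

    @property
    def outer_radius(self) -> float:
        """Axisymmetric outer radius (mm): explicit, or equal-volume default."""
        if self.radius is not None:
            return self.radius
        return math.sqrt(self.volume_mm3 / (math.pi * self.height))


@dataclass(frozen=True)
class SolverOptions:
    """Time stepping and nonlinear iteration controls.

    ``dt_max=1`` reproduces the fixed 1 s stepping used for short validation
    runs; the default lets the step grow geometrically to 60 s for one-hour
    design runs.  ``linearize_at`` freezes perfusion and metabolism at a
    constant temperature (used to compare against the closed-form cylinder
    solution).
    """

    dt_initial: float = 1.0
    dt_growth: float = 1.2
    dt_max: float = 60.0
    tol: float = 1e-6            # degC, fixed-point update per step
    max_iter: int = 50
    steady_tol: float = 1e-7
    max_steady_iter: int = 300
    linearize_at: float | None = None


@dataclass
class ThermalField:
    """Temperature field on a structured grid at one instant.

    ``axes`` are the grid node coordinates in mm — (r, z) for axisymmetric
    fields, (x, y, z) for voxel fields.  ``temperature`` is degC with shape
    ``tuple(map(len, axes))``.  ``probe_mask`` flags nodes inside the probe
    (not tissue); it is None for probe-free synthetic fields.
    """

    mode: str
    axes: tuple[np.ndarray, ...]
    temperature: np.ndarray
    time: float = 0.0
    probe_mask: np.ndarray | None = None
    probe: ProbeSpec | None = None
    domain: SimulationDomain | None = None
    meta: dict = dc_field(default_factory=dict)

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(self.axes, self.temperature,
                                       bounds_error=False, fill_value=None)

    def radial_profile(self, r: np.ndarray, z: float = 0.0,
                       n_angles: int = 16) -> np.ndarray:
        """Temperature vs radial distance from the probe axis at height z.

        Axisymmetric fields are sampled directly; voxel fields are averaged
        over ``n_angles`` azimuthal directions.
        """
        r = np.asarray(r, dtype=float)
        interp = self.interpolator()
        if self.mode == "axisymmetric":
            pts = np.column_stack([r, np.full_like(r, z)])
            return interp(pts)
        theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
        x = r[:, None] * np.cos(theta)[None, :]
        y = r[:, None] * np.sin(theta)[None, :]
        pts = np.column_stack([x.ravel(), y.ravel(),
                               np.full(x.size, z)])
        return interp(pts).reshape(r.size, n_angles).mean(axis=1)


# ---------------------------------------------------------------------------
# grid generation

def _stretched(start: float, stop: float, h0: float, h_max: float,
               growth: float) -> np.ndarray:
    """Nodes from start to stop with spacing h0 growing by `growth` up to
    h_max, rescaled so the last node lands exactly on stop."""
    span = stop - start
    if span <= 1e-12:
        return np.array([start])
    pts = [0.0]
    h = h0
    while pts[-1] < span:
        pts.append(pts[-1] + h)
        h = min(h * growth, h_max)
    arr = np.asarray(pts) * (span / pts[-1])
    return start + arr


def _uniform(start: float, stop: float, h: float) -> np.ndarray:
    n = max(1, int(round((stop - start) / h)))
    return np.linspace(start, stop, n + 1)


def _axial_nodes(domain: SimulationDomain, probe: ProbeSpec | None,
                 h_fine: float) -> np.ndarray:
    """Symmetric z grid with nodes exactly at 0 and the probe cap."""
    half = domain.height / 2.0
    if probe is None:
        zh = _stretched(0.0, half, h_fine, domain.h_max, domain.growth)
    else:
        cap = probe.tip_length / 2.0
        if cap >= half:  # probe spans the full height (infinite-cylinder runs)
            zh = _uniform(0.0, half, min(domain.h_max, 4 * h_fine))
        else:
            fine_end = min(cap + 10.0, half)
            parts = [_uniform(0.0, cap, h_fine)]
            if fine_end > cap:
                parts.append(_uniform(cap, fine_end, h_fine)[1:])
            if fine_end < half:
                parts.append(_stretched(fine_end, half, h_fine * domain.growth,
                                        domain.h_max, domain.growth)[1:])
            zh = np.concatenate(parts)
    return np.concatenate([-zh[::-1][:-1], zh])


def _radial_nodes(domain: SimulationDomain, probe: ProbeSpec | None) -> np.ndarray:
    R = domain.outer_radius
    h = domain.h_fine
    if probe is None:
        fine_end = min(domain.fine_margin, R)
        parts = [_uniform(0.0, fine_end, h)]
    else:
        a = probe.radius
        fine_end = min(a + domain.fine_margin, R)
        parts = [_uniform(0.0, a, h), _uniform(a, fine_end, h)[1:]]
    if fine_end < R:
        parts.append(_stretched(fine_end, R, h * domain.growth,
                                domain.h_max, domain.growth)[1:])
    return np.concatenate(parts)


def _inplane_nodes(half_extent: float, a: float, h: float, h_max: float,
                   growth: float) -> np.ndarray:
    fine_end = min(a + 6.0, half_extent)
    parts = [_uniform(0.0, fine_end, h)]
    if fine_end < half_extent:
        parts.append(_stretched(fine_end, half_extent, h * growth,
                                h_max, growth)[1:])
    xh = np.concatenate(parts)
    return np.concatenate([-xh[::-1][:-1], xh])


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 2.0 * a * b / (a + b)


# ---------------------------------------------------------------------------
# discrete systems

class _System:
    """Assembled finite-volume system shared by both geometries.

    Subclasses provide the grid, the SPD graph-Laplacian ``L`` (W/K), node
    volumes ``V`` (m^3), material arrays and the Dirichlet partition; this
    base class implements the implicit time step and the steady solve.
    """

    domain: SimulationDomain
    probe: ProbeSpec | None
    tissue: TissueProperties
    blood: BloodProperties
    options: SolverOptions
    axes: tuple[np.ndarray, ...]
    shape: tuple[int, ...]
    probe_mask: np.ndarray | None

    def _finalize(self, L: sp.spmatrix, V: np.ndarray, rho_cp: np.ndarray,
                  bio: np.ndarray, dir_mask: np.ndarray,
                  dir_val: np.ndarray) -> None:
        free = ~dir_mask.ravel()
        self._free = free
        self._fixed_T = dir_val.ravel()[~free]
        L = L.tocsr()
        self._Lff = L[free][:, free].tocsr()
        Lfd = L[free][:, ~free].tocsr()
        self._bdry = -Lfd @ self._fixed_T
        self._Vf = V.ravel()[free]
        self._cap_f = (rho_cp.ravel() * V.ravel())[free]   # J/K
        self._bio_f = bio.ravel()[free].astype(float)
        self._dir_val = dir_val
        self._dir_mask = dir_mask
        self._n_free = int(free.sum())
        self._qv = 0.0

    # -- linear algebra ----------------------------------------------------
    def _linsolve(self, M: sp.spmatrix, rhs: np.ndarray,
                  x0: np.ndarray) -> np.ndarray:
        if self._n_free <= 40000:
            return splu(M.tocsc()).solve(rhs)
        precond = sp.diags(1.0 / M.diagonal())
        x, info = cg(M, rhs, x0=x0, rtol=1e-10, atol=0.0, maxiter=5000,
                     M=precond)
        if info != 0:
            raise SolverError(f"conjugate-gradient solve failed (info={info})")
        return x

    def _coefficients(self, T_f: np.ndarray):
        """Perfusion conductance p (W/K) and metabolic power q*V (W) per node."""
        lin = self.options.linearize_at
        T_eval = np.full_like(T_f, lin) if lin is not None else T_f
        w = perfusion_rate(T_eval, self.tissue)
        q = metabolic_rate(T_eval, self.tissue)
        p = self.blood.volumetric_heat_capacity * w * self._Vf * self._bio_f
        src = (q + self._qv) * self._Vf * self._bio_f
        return p, src

    # -- time stepping -----------------------------------------------------
    def _step(self, T_f: np.ndarray, dt: float) -> np.ndarray:
        opts = self.options
        c = self._cap_f / dt
        Tb = self.blood.arterial_temperature
        T_star = T_f.copy()
        for _ in range(opts.max_iter):
            p, src = self._coefficients(T_star)
            M = self._Lff + sp.diags(c + p)
            rhs = c * T_f + self._bdry + p * Tb + src
            T_new = self._linsolve(M, rhs, x0=T_star)
            delta = float(np.max(np.abs(T_new - T_star)))
            T_star = T_new
            if delta < opts.tol:
                return T_star
        raise SolverError("nonlinear iteration did not converge within "
                          f"{opts.max_iter} fixed-point sweeps", residual=delta)

    def solve_transient(self, times) -> list[ThermalField]:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if times.size == 0:
            return []
        if np.any(times < 0) or np.any(np.diff(times) < 0):
            raise ValueError("output times must be nondecreasing and >= 0")
        opts = self.options
        T0 = self.domain.boundary_temperature
        T_f = np.full(self._n_free, T0)
        fields: list[ThermalField] = []
        t = 0.0
        dt_state = opts.dt_initial
        for target in times:
            while t < target - 1e-9:
                dt = min(dt_state, target - t)
                T_f = self._step(T_f, dt)
                t += dt
                dt_state = min(dt_state * opts.dt_growth, opts.dt_max)
            fields.append(self._make_field(T_f, target))
        return fields

    def solve_steady(self) -> ThermalField:
        opts = self.options
        Tb = self.blood.arterial_temperature
        T_star = np.full(self._n_free, self.domain.boundary_temperature)
        alpha, prev_delta = 1.0, np.inf
        for _ in range(opts.max_steady_iter):
            p, src = self._coefficients(T_star)
            M = self._Lff + sp.diags(p)
            rhs = self._bdry + p * Tb + src
            T_new = self._linsolve(M, rhs, x0=T_star)
            delta = float(np.max(np.abs(T_new - T_star)))
            if delta > prev_delta:
                alpha = max(alpha * 0.5, 0.125)
            T_star = T_star + alpha * (T_new - T_star)
            prev_delta = delta
            if delta < opts.steady_tol:
                break
        else:
            raise SolverError("steady fixed-point iteration diverged",
                              residual=delta)
        # converged nonlinear residual, relative to the source magnitude
        p, src = self._coefficients(T_star)
        res = self._Lff @ T_star + p * (T_star - Tb) - src - self._bdry
        scale = float(np.max(np.abs(src)) + np.max(np.abs(self._bdry)) + 1e-30)
        field = self._make_field(T_star, float("inf"))
        field.meta["residual_rel"] = float(np.max(np.abs(res))) / scale
        return field

    def _make_field(self, T_f: np.ndarray, t: float) -> ThermalField:
        T = self._dir_val.astype(float).copy().ravel()
        T[self._free] = T_f
        return ThermalField(mode=self.domain.mode, axes=self.axes,
                            temperature=T.reshape(self.shape), time=t,
                            probe_mask=self.probe_mask, probe=self.probe,
                            domain=self.domain)


class _AxisymmetricSystem(_System):
    def __init__(self, domain, probe, tissue, blood, options):
        self.domain, self.probe = domain, probe
        self.tissue, self.blood, self.options = tissue, blood, options
        r = _radial_nodes(domain, probe)
        z = _axial_nodes(domain, probe, domain.h_fine)
        self.axes = (r, z)
        nr, nz = len(r), len(z)
        self.shape = (nr, nz)
        rm, zm = r * _MM, z * _MM

        kappa = np.full((nr, nz), tissue.thermal_conductivity)
        rho_cp = np.full((nr, nz), tissue.volumetric_heat_capacity)
        bio = np.ones((nr, nz), dtype=bool)
        dir_mask = np.zeros((nr, nz), dtype=bool)
        dir_val = np.full((nr, nz), domain.boundary_temperature)

        self.probe_mask = None
        if probe is not None:
            a, cap = probe.radius, probe.tip_length / 2.0
            if a >= domain.outer_radius:
                raise GeometryError("probe wider than the domain")
            if cap > domain.height / 2.0 + 1e-9:
                raise GeometryError("probe longer than the domain")
            if (cap >= domain.height / 2.0 - 1e-9
                    and domain.axial_boundary == "dirichlet"):
                raise GeometryError("probe touching a Dirichlet z boundary; "
                                    "use axial_boundary='neumann'")
            inside = (r[:, None] <= a + 1e-9) & (np.abs(z)[None, :] <= cap + 1e-9)
            self.probe_mask = inside
            if probe.shell is None:
                dir_mask |= inside
                dir_val[inside] = probe.surface_temperature
            else:
                sh = probe.shell
                interior = ((r[:, None] <= a - sh.thickness + 1e-9)
                            & (np.abs(z)[None, :] <= cap - sh.thickness + 1e-9))
                band = inside & ~interior
                kappa[band] = sh.conductivity
                rho_cp[band] = sh.density * sh.specific_heat
                bio[band] = False
                dir_mask |= interior
                dir_val[interior] = sh.internal_temperature

        dir_mask[-1, :] = True
        dir_val[-1, :] = domain.boundary_temperature
        if domain.axial_boundary == "dirichlet":
            dir_mask[:, 0] = dir_mask[:, -1] = True
            dir_val[:, 0] = dir_val[:, -1] = domain.boundary_temperature

        # control-volume geometry (full 2*pi revolution)
        rf = 0.5 * (rm[:-1] + rm[1:])                    # face radii
        s = np.empty(nr)                                  # radial cell areas/2pi... (m^2)
        s[0] = 0.5 * rf[0] ** 2
        if nr > 2:
            s[1:-1] = 0.5 * (rf[1:] ** 2 - rf[:-1] ** 2)
        s[-1] = 0.5 * (rm[-1] ** 2 - rf[-1] ** 2)
        wz = np.empty(nz)
        wz[0] = 0.5 * (zm[1] - zm[0])
        wz[-1] = 0.5 * (zm[-1] - zm[-2])
        if nz > 2:
            wz[1:-1] = 0.5 * (zm[2:] - zm[:-2])
        V = 2 * np.pi * np.outer(s, wz)

        g_r = (_harmonic(kappa[:-1, :], kappa[1:, :])
               * 2 * np.pi * rf[:, None] * wz[None, :]
               / (rm[1:] - rm[:-1])[:, None])
        g_z = (_harmonic(kappa[:, :-1], kappa[:, 1:])
               * 2 * np.pi * s[:, None] / (zm[1:] - zm[:-1])[None, :])

        idx = np.arange(nr * nz).reshape(nr, nz)
        L = _graph_laplacian(nr * nz, [
            (idx[:-1, :].ravel(), idx[1:, :].ravel(), g_r.ravel()),
            (idx[:, :-1].ravel(), idx[:, 1:].ravel(), g_z.ravel()),
        ])
        self._finalize(L, V, rho_cp, bio, dir_mask, dir_val)


class _Cartesian3DSystem(_System):
    def __init__(self, domain, probe, tissue, blood, options):
        if probe is not None and probe.shell is not None:
            raise NotImplementedError("shell probe model is axisymmetric-only")
        self.domain, self.probe = domain, probe
        self.tissue, self.blood, self.options = tissue, blood, options
        ex, ey, ez = domain.extent
        a = probe.radius if probe is not None else 0.0
        h3 = domain.h_fine3
        x = _inplane_nodes(ex / 2.0, a, h3, domain.h_max, domain.growth)
        y = _inplane_nodes(ey / 2.0, a, h3, domain.h_max, domain.growth)
        dz = replace(domain, height=ez)
        z = _axial_nodes(dz, probe, h3)
        self.axes = (x, y, z)
        nx, ny, nz = len(x), len(y), len(z)
        self.shape = (nx, ny, nz)

        rho_cp = np.full(self.shape, tissue.volumetric_heat_capacity)
        bio = np.ones(self.shape, dtype=bool)
        dir_mask = np.zeros(self.shape, dtype=bool)
        dir_val = np.full(self.shape, domain.boundary_temperature)

        self.probe_mask = None
        if probe is not None:
            cap = probe.tip_length / 2.0
            if cap >= ez / 2.0 or a >= min(ex, ey) / 2.0:
                raise GeometryError("probe must be interior to the domain")
            rr = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
            # classify a node as probe when its grid cell reaches the probe
            # surface (center within a + h/2): a bare node-radius staircase
            # has an effective radius well below the nominal one
            a_eff = a + 0.5 * h3
            inside = ((rr <= a_eff + 1e-9)[:, :, None]
                      & (np.abs(z) <= cap + 1e-9)[None, None, :])
            self.probe_mask = inside
            dir_mask |= inside
            dir_val[inside] = probe.surface_temperature

        dir_mask[0, :, :] = dir_mask[-1, :, :] = True
        dir_mask[:, 0, :] = dir_mask[:, -1, :] = True
        dir_mask[:, :, 0] = dir_mask[:, :, -1] = True
        # boundary value already boundary_temperature everywhere else

        wx, wy, wz = (_cell_widths(ax * _MM) for ax in (x, y, z))
        V = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
        k = tissue.thermal_conductivity
        idx = np.arange(nx * ny * nz).reshape(self.shape)
        gx = k * (wy[None, :, None] * wz[None, None, :]
                  / np.diff(x * _MM)[:, None, None])
        gy = k * (wx[:, None, None] * wz[None, None, :]
                  / np.diff(y * _MM)[None, :, None])
        gz = k * (wx[:, None, None] * wy[None, :, None]
                  / np.diff(z * _MM)[None, None, :])
        L = _graph_laplacian(nx * ny * nz, [
            (idx[:-1, :, :].ravel(), idx[1:, :, :].ravel(),
             np.broadcast_to(gx, (nx - 1, ny, nz)).ravel()),
            (idx[:, :-1, :].ravel(), idx[:, 1:, :].ravel(),
             np.broadcast_to(gy, (nx, ny - 1, nz)).ravel()),
            (idx[:, :, :-1].ravel(), idx[:, :, 1:].ravel(),
             np.broadcast_to(gz, (nx, ny, nz - 1)).ravel()),
        ])
        self._finalize(L, V, rho_cp, bio, dir_mask, dir_val)


def _cell_widths(xm: np.ndarray) -> np.ndarray:
    w = np.empty(len(xm))
    w[0] = 0.5 * (xm[1] - xm[0])
    w[-1] = 0.5 * (xm[-1] - xm[-2])
    if len(xm) > 2:
        w[1:-1] = 0.5 * (xm[2:] - xm[:-2])
    return w


def _graph_laplacian(n: int, edges) -> sp.coo_matrix:
    rows, cols, data = [], [], []
    for p, q, w in edges:
        rows += [p, q, p, q]
        cols += [p, q, q, p]
        data += [w, w, -w, -w]
    return sp.coo_matrix((np.concatenate(data),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(n, n))


# ---------------------------------------------------------------------------
# public API

class PennesSolver:
    """Nonlinear Pennes bioheat solver for a probe in a brain volume."""

    def __init__(self, domain: SimulationDomain | None = None,
                 probe: ProbeSpec | None = None,
                 tissue: TissueProperties | None = None,
                 blood: BloodProperties | None = None,
                 options: SolverOptions | None = None):
        self.domain = domain or SimulationDomain()
        self.probe = probe
        self.tissue = tissue or TissueProperties()
        self.blood = blood or BloodProperties()
        self.options = options or SolverOptions()
        cls = (_AxisymmetricSystem if self.domain.mode == "axisymmetric"
               else _Cartesian3DSystem)
        self._system = cls(self.domain, self.probe, self.tissue,
                           self.blood, self.options)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self._system.shape))

    def solve_transient(self, times) -> list[ThermalField]:
        """Integrate from a uniform initial condition and return fields at
        the requested output times (implicit Euler, adaptive step)."""
        return self._system.solve_transient(times)

    def solve_steady(self) -> ThermalField:
        """Steady nonlinear solution (fixed-point on the lagged coefficients)."""
        return self._system.solve_steady()


def solve_transient(domain=None, probe=None, tissue=None, blood=None,
                    times=(0.0,), options=None) -> list[ThermalField]:
    return PennesSolver(domain, probe, tissue, blood, options).solve_transient(times)


def solve_steady(domain=None, probe=None, tissue=None, blood=None,
                 options=None) -> ThermalField:
    return PennesSolver(domain, probe, tissue, blood, options).solve_steady()


def penetration_length(tissue: TissueProperties, blood: BloodProperties,
                       frozen_T: float) -> float:
    """Thermal penetration length lambda = sqrt(kappa/(rho_b Cb omega_b)), m."""
    w = perfusion_rate(frozen_T, tissue)
    return math.sqrt(tissue.thermal_conductivity
                     / (blood.volumetric_heat_capacity * w))


def analytic_cylinder_profile(r, probe_radius: float, surface_temperature: float,
                              tissue: TissueProperties | None = None,
                              blood: BloodProperties | None = None,
                              frozen_T: float = 37.0):
    """Closed-form steady profile around an infinite cooled cylinder.

    With perfusion and metabolism frozen at ``frozen_T`` the steady Pennes
    equation is linear and the axisymmetric solution is

        T(r) = T_inf + (Ts - T_inf) * K0(r/lambda) / K0(a/lambda)

    with K0 the modified Bessel function of the second kind,
    lambda = sqrt(kappa/(rho_b Cb omega_b(frozen_T))) and T_inf the linear
    far-field equilibrium Tb + Q_met(frozen_T)/(rho_b Cb omega_b(frozen_T)).
    Distances in mm; serves as the independent oracle for the solver.
    """
    tissue = tissue or TissueProperties()
    blood = blood or BloodProperties()
    r = np.asarray(r, dtype=float)
    if np.any(r < probe_radius - 1e-12):
        raise ValueError("r must be >= probe_radius")
    lam = penetration_length(tissue, blood, frozen_T) / _MM  # mm
    w = perfusion_rate(frozen_T, tissue)
    T_inf = blood.arterial_temperature + (
        metabolic_rate(frozen_T, tissue) / (blood.volumetric_heat_capacity * w))
    out = T_inf + (surface_temperature - T_inf) * k0(r / lam) / k0(probe_radius / lam)
    return float(out) if out.ndim == 0 else out
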