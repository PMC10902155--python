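"""2D unsteady incompressible duct solver with forcing boundary conditions.

A desk-scale dynamical stand-in for a full anatomical simulation: plane
channel of height ``2h`` with an optional smooth constriction bump on the
bottom wall, discretized on a staggered (MAC) Cartesian grid and advanced
with an explicit second-order scheme plus a pressure projection each step.
The bump is represented by a blocked-cell (stairstep) mask.

The three global forcings map onto boundary conditions:

* CFR — inlet velocity profile rescaled so the instantaneous inlet flux
  equals ``Q0`` exactly; zero-gradient outflow with a global mass fix.
* CPG — Dirichlet pressure 0 at the inlet plane and ``-dp0`` at the outlet.
* CPI — like CPG, but the outlet pressure is recomputed every step from the
  one-step-lagged controller ``p_th = -P0 / Q_prev``.

All quantities are per unit spanwise depth (the 2D flow rate has units
m^2/s; we treat depth as 1 m so the global bookkeeping matches the 3D
conventions of :mod:`noseflow.forcing`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .forcing import (
    DEFAULT_Q_FLOOR,
    ControllerError,
    ForcingMode,
    ForcingSpec,
    GlobalQuantities,
    cpi_throat_pressure,
    time_average,
)

__all__ = [
    "DuctGeometry",
    "SolverConfig",
    "Grid",
    "FieldState",
    "build_grid",
    "step",
    "run_case",
    "flow_rate",
    "poiseuille_flow_rate",
    "poiseuille_resistance",
]


# ---------------------------------------------------------------------------
# geometry and configuration


@dataclass(frozen=True)
class DuctGeometry:
    """Channel of length ``L`` and height ``2h`` with one smooth wall bump.

    The bump rises from the bottom wall with a cosine-squared profile of
    given ``centre`` and ``width`` (both metres) and relative ``depth`` in
    [0, 1): the open gap at the throat is ``(1 - depth) * 2h``.
    """

    L: float
    h: float
    nx: int
    ny: int
    bump_centre: float | None = None
    bump_width: float | None = None
    bump_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.L <= 0.0 or self.h <= 0.0:
            raise ValueError("duct length and half-height must be positive")
        if self.nx < 4 or self.ny < 4:
            raise ValueError("need at least 4 cells in each direction")
        if not 0.0 <= self.bump_depth < 1.0:
            raise ValueError(f"bump depth must be in [0, 1), got {self.bump_depth!r}")
        if self.bump_depth > 0.0 and (self.bump_centre is None or self.bump_width is None):
            raise ValueError("a bump needs a centre and a width")

    @property
    def height(self) -> float:
        return 2.0 * self.h

    def wall_profile(self, x: np.ndarray) -> np.ndarray:
        """Bottom-wall elevation ``s(x)`` (C^1 cosine-squared bump)."""
        s = np.zeros_like(x, dtype=float)
        if self.bump_depth > 0.0:
            xi = (x - self.bump_centre) / self.bump_width
            inside = np.abs(xi) < 0.5
            s[inside] = self.bump_depth * self.height * np.cos(np.pi * xi[inside]) ** 2
        return s

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "h": self.h,
            "nx": self.nx,
            "ny": self.ny,
            "bump_centre": self.bump_centre,
            "bump_width": self.bump_width,
            "bump_depth": self.bump_depth,
        }


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of a run.

    Fluid defaults are air at 20 C (not a physical claim, just a convention
    recorded in the run metadata).  ``window`` is the total physical time
    integrated; statistics discard the first ``discard_fraction`` of it.
    """

    rho: float = 1.2  # kg/m^3
    nu: float = 1.5e-5  # m^2/s
    cfl: float = 0.3
    max_steps: int = 2_000_000
    window: float = 1.0  # s of physical time to integrate
    discard_fraction: float = 0.3
    div_tol: float = 1e-6  # on |div u| * dx / U
    dt_floor: float = 1e-12
    q_floor: float = DEFAULT_Q_FLOOR
    seed: int | None = None
    perturbation: float = 0.0  # relative amplitude of seeded initial noise
    cpi_warm_start_Q: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cfl < 1.0:
            raise ValueError(f"CFL must be in (0, 1), got {self.cfl!r}")
        if self.nu <= 0.0 or self.rho <= 0.0:
            raise ValueError("fluid properties must be positive")
        if not 0.0 <= self.discard_fraction < 1.0:
            raise ValueError("discard_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "nu": self.nu,
            "cfl": self.cfl,
            "window": self.window,
            "discard_fraction": self.discard_fraction,
            "seed": self.seed,
            "perturbation": self.perturbation,
        }


# ---------------------------------------------------------------------------
# grid


@dataclass
class Grid:
    """Staggered grid with a blocked-cell mask for the bump."""

    geom: DuctGeometry
    dx: float
    dy: float
    fluid: np.ndarray  # (nx, ny) bool, True where the cell is open
    metadata: dict = field(default_factory=dict)

    @property
    def nx(self) -> int:
        return self.geom.nx

    @property
    def ny(self) -> int:
        return self.geom.ny

    def x_centres(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    def y_centres(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    def open_height(self, i: int) -> float:
        """Open (fluid) height of column ``i``."""
        return float(np.count_nonzero(self.fluid[i])) * self.dy

    def u_active(self) -> np.ndarray:
        """(nx+1, ny) mask of u-faces carrying flow (open on both sides)."""
        act = np.zeros((self.nx + 1, self.ny), dtype=bool)
        act[1:-1] = self.fluid[:-1] & self.fluid[1:]
        act[0] = self.fluid[0]
        act[-1] = self.fluid[-1]
        return act

    def v_active(self) -> np.ndarray:
        """(nx, ny+1) mask of interior v-faces (walls stay inactive)."""
        act = np.zeros((self.nx, self.ny + 1), dtype=bool)
        act[:, 1:-1] = self.fluid[:, :-1] & self.fluid[:, 1:]
        return act


def build_grid(geom: DuctGeometry, min_gap_cells: int = 8) -> Grid:
    """Discretize the geometry; cells whose centre lies inside the bump are solid.

    Raises
    ------
    ValueError
        If fewer than ``min_gap_cells`` cells span the constricted gap.
    """
    dx = geom.L / geom.nx
    dy = geom.height / geom.ny
    xc = (np.arange(geom.nx) + 0.5) * dx
    yc = (np.arange(geom.ny) + 0.5) * dy
    s = geom.wall_profile(xc)
    fluid = yc[None, :] >= s[:, None]
    open_cells = fluid.sum(axis=1)
    if open_cells.min() < min_gap_cells:
        raise ValueError(
            f"only {int(open_cells.min())} cells span the constricted gap; "
            f"need at least {min_gap_cells} — increase ny or reduce bump depth"
        )
    throat_open = float(open_cells.min()) * dy
    return Grid(
        geom=geom,
        dx=dx,
        dy=dy,
        fluid=fluid,
        metadata={
            "representation": "stairstep-mask",
            "throat_open_height": throat_open,
            "throat_open_height_exact": (1.0 - geom.bump_depth) * geom.height,
        },
    )


# ---------------------------------------------------------------------------
# field state


@dataclass
class FieldState:
    """Velocity/pressure fields plus bookkeeping for statistics."""

    grid: Grid
    u: np.ndarray  # (nx+1, ny) x-velocity on vertical faces
    v: np.ndarray  # (nx, ny+1) y-velocity on horizontal faces
    p: np.ndarray  # (nx, ny) kinematic pressure p/rho at centres
    t: float = 0.0
    n_steps: int = 0
    p_outlet: float = 0.0  # kinematic, current CPG/CPI outlet value
    # AB2 history
    _hu: np.ndarray | None = None
    _hv: np.ndarray | None = None
    # accumulated mean velocity (time-weighted sums) and weight
    mean_u: np.ndarray | None = None
    mean_v: np.ndarray | None = None
    mean_weight: float = 0.0

    @classmethod
    def from_rest(cls, grid: Grid, cfg: SolverConfig | None = None) -> "FieldState":
        state = cls(
            grid=grid,
            u=np.zeros((grid.nx + 1, grid.ny)),
            v=np.zeros((grid.nx, grid.ny + 1)),
            p=np.zeros((grid.nx, grid.ny)),
        )
        if cfg is not None and cfg.perturbation > 0.0:
            rng = np.random.default_rng(cfg.seed)
            state.u += cfg.perturbation * rng.standard_normal(state.u.shape)
            state.u[~grid.u_active()] = 0.0
        return state

    @classmethod
    def from_uniform_flow(cls, grid: Grid, Q: float) -> "FieldState":
        """Plug flow carrying flux ``Q`` through every column (divergence-free)."""
        state = cls.from_rest(grid)
        uact = grid.u_active()
        for i in range(grid.nx + 1):
            open_cells = uact[i]
            height = open_cells.sum() * grid.dy
            if height > 0:
                state.u[i, open_cells] = Q / height
        return state

    def accumulate_mean(self, dt: float) -> None:
        if self.mean_u is None:
            self.mean_u = np.zeros_like(self.u)
            self.mean_v = np.zeros_like(self.v)
        self.mean_u += dt * self.u
        self.mean_v += dt * self.v
        self.mean_weight += dt

    def mean_fields(self) -> tuple[np.ndarray, np.ndarray]:
        if self.mean_u is None or self.mean_weight == 0.0:
            raise RuntimeError("no mean-field statistics accumulated yet")
        return self.mean_u / self.mean_weight, self.mean_v / self.mean_weight


def flow_rate(state: FieldState, station: int | None = None) -> float:
    """Instantaneous flux through the vertical section at u-face ``station``.

    Defaults to the inlet plane (station 0), where CFR is enforced exactly.
    """
    grid = state.grid
    if station is None:
        station = 0
    if not 0 <= station <= grid.nx:
        raise ValueError(f"station must be in [0, {grid.nx}], got {station}")
    act = grid.u_active()[station]
    return float(np.sum(state.u[station, act]) * grid.dy)


# ---------------------------------------------------------------------------
# pressure Poisson operator (cached per grid + boundary mode)

_DIRICHLET_MODES = (ForcingMode.CPG, ForcingMode.CPI)


class _PoissonSolver:
    """5-point Laplacian on fluid cells with mode-dependent boundary closure.

    Walls and solid cells are Neumann.  For pressure-driven modes the inlet
    and outlet planes are Dirichlet (face value imposed via a ghost with
    half-cell spacing); for CFR everything is Neumann and one cell is pinned.
    """

    def __init__(self, grid: Grid, dirichlet_io: bool):
        self.grid = grid
        self.dirichlet_io = dirichlet_io
        nx, ny = grid.nx, grid.ny
        fluid = grid.fluid
        idx = -np.ones((nx, ny), dtype=np.int64)
        idx[fluid] = np.arange(np.count_nonzero(fluid))
        self.idx = idx
        n = int(np.count_nonzero(fluid))
        self.n = n
        ax, ay = 1.0 / grid.dx**2, 1.0 / grid.dy**2

        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        # boundary-coupling coefficients for the rhs (Dirichlet faces)
        self.inlet_cells = np.where(fluid[0])[0]
        self.outlet_cells = np.where(fluid[-1])[0]
        for i in range(nx):
            for j in range(ny):
                if not fluid[i, j]:
                    continue
                k = idx[i, j]
                # x neighbours
                if i > 0 and fluid[i - 1, j]:
                    rows.append(k); cols.append(idx[i - 1, j]); vals.append(ax)
                    diag[k] -= ax
                elif i == 0 and self.dirichlet_io:
                    diag[k] -= 2.0 * ax  # ghost: p_ghost = 2 p_face - p
                if i < nx - 1 and fluid[i + 1, j]:
                    rows.append(k); cols.append(idx[i + 1, j]); vals.append(ax)
                    diag[k] -= ax
                elif i == nx - 1 and self.dirichlet_io:
                    diag[k] -= 2.0 * ax
                # y neighbours (walls/solids: Neumann, no contribution)
                if j > 0 and fluid[i, j - 1]:
                    rows.append(k); cols.append(idx[i, j - 1]); vals.append(ay)
                    diag[k] -= ay
                if j < ny - 1 and fluid[i, j + 1]:
                    rows.append(k); cols.append(idx[i, j + 1]); vals.append(ay)
                    diag[k] -= ay

        rows.extend(range(n))
        cols.extend(range(n))
        vals.extend(diag.tolist())
        A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        if not dirichlet_io:
            # all-Neumann operator is singular: pin the first fluid cell
            pin = 0
            A = A.tolil()
            A[pin, :] = 0.0
            A[pin, pin] = 1.0
            A = A.tocsc()
            self.pin = pin
        else:
            self.pin = None
        self.lu = splu(A)
        self.ax = ax

    def solve(self, rhs_field: np.ndarray, p_in: float, p_out: float) -> np.ndarray:
        """Solve for cell pressures; ``rhs_field`` is div(u*)/dt on cells."""
        grid = self.grid
        b = rhs_field[grid.fluid]
        if self.dirichlet_io:
            b = b.copy()
            b[self.idx[0, self.inlet_cells]] -= 2.0 * self.ax * p_in
            b[self.idx[-1, self.outlet_cells]] -= 2.0 * self.ax * p_out
        else:
            b = b.copy()
            b[self.pin] = 0.0
        sol = self.lu.solve(b)
        p = np.zeros((grid.nx, grid.ny))
        p[grid.fluid] = sol
        return p


_POISSON_CACHE: dict[tuple[int, bool], _PoissonSolver] = {}


def _poisson_for(grid: Grid, dirichlet_io: bool) -> _PoissonSolver:
    key = (id(grid), dirichlet_io)
    solver = _POISSON_CACHE.get(key)
    if solver is None or solver.grid is not grid:
        solver = _PoissonSolver(grid, dirichlet_io)
        _POISSON_CACHE[key] = solver
    return solver


# ---------------------------------------------------------------------------
# spatial operators (second-order central, ghost reflection at walls)


def _ghost_pad_u(u: np.ndarray) -> np.ndarray:
    """Pad u in y with no-slip reflection ghosts (wall at cell faces)."""
    g = np.empty((u.shape[0], u.shape[1] + 2))
    g[:, 1:-1] = u
    g[:, 0] = -u[:, 0]
    g[:, -1] = -u[:, -1]
    return g


def _terms_u(
    u: np.ndarray, v: np.ndarray, nu: float, dx: float, dy: float
) -> tuple[np.ndarray, np.ndarray]:
    """(advection, diffusion) for interior u-faces (i = 1..nx-1), zero elsewhere."""
    adv_out = np.zeros_like(u)
    diff_out = np.zeros_like(u)
    up = _ghost_pad_u(u)  # (nx+1, ny+2)
    ui = up[1:-1]  # u at faces i=1..nx-1, padded in y -> (nx-1, ny+2)
    # du/dx at interior faces: central over neighbours
    dudx = (up[2:, 1:-1] - up[:-2, 1:-1]) / (2.0 * dx)
    dudy = (ui[:, 2:] - ui[:, :-2]) / (2.0 * dy)
    # v averaged to u-face (i, j): mean of the 4 surrounding v faces
    vbar = 0.25 * (
        v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:]
    )  # (nx-1, ny)
    adv_out[1:-1] = up[1:-1, 1:-1] * dudx + vbar * dudy
    diff_out[1:-1] = nu * (
        (up[2:, 1:-1] - 2.0 * up[1:-1, 1:-1] + up[:-2, 1:-1]) / dx**2
        + (ui[:, 2:] - 2.0 * ui[:, 1:-1] + ui[:, :-2]) / dy**2
    )
    return adv_out, diff_out


def _terms_v(
    u: np.ndarray, v: np.ndarray, nu: float, dx: float, dy: float
) -> tuple[np.ndarray, np.ndarray]:
    """(advection, diffusion) for interior v-faces (j = 1..ny-1), zero elsewhere."""
    adv_out = np.zeros_like(v)
    diff_out = np.zeros_like(v)
    # pad v in x with zero-gradient ghosts (open inlet/outlet); walls handled by mask
    g = np.empty((v.shape[0] + 2, v.shape[1]))
    g[1:-1] = v
    g[0] = v[0]
    g[-1] = v[-1]
    vi = g[:, 1:-1]  # interior j faces, padded in x -> (nx+2, ny-1)
    dvdx = (vi[2:] - vi[:-2]) / (2.0 * dx)
    dvdy = (g[1:-1, 2:] - g[1:-1, :-2]) / (2.0 * dy)
    # u averaged to v-face (i, j): mean of 4 surrounding u faces
    ubar = 0.25 * (
        u[:-1, :-1] + u[1:, :-1] + u[:-1, 1:] + u[1:, 1:]
    )  # (nx, ny-1)
    adv_out[:, 1:-1] = ubar * dvdx + vi[1:-1] * dvdy
    diff_out[:, 1:-1] = nu * (
        (vi[2:] - 2.0 * vi[1:-1] + vi[:-2]) / dx**2
        + (g[1:-1, 2:] - 2.0 * g[1:-1, 1:-1] + g[1:-1, :-2]) / dy**2
    )
    return adv_out, diff_out


def _inlet_profile(grid: Grid, Q: float) -> np.ndarray:
    """Parabolic inlet profile over the open inlet cells with exact flux ``Q``."""
    open_cells = grid.u_active()[0]
    ny_open = int(open_cells.sum())
    prof = np.zeros(grid.ny)
    if ny_open == 0:
        raise RuntimeError("inlet column is fully blocked")
    # parabola on the open span, zero at its edges
    eta = (np.arange(ny_open) + 0.5) / ny_open
    shape = eta * (1.0 - eta)
    shape *= Q / (shape.sum() * grid.dy)  # exact discrete flux
    prof[open_cells] = shape
    return prof


def _stability_dt(state: FieldState, cfg: SolverConfig) -> float:
    grid = state.grid
    umax = float(np.max(np.abs(state.u)))
    vmax = float(np.max(np.abs(state.v)))
    dt_diff = 0.4 / (cfg.nu * (1.0 / grid.dx**2 + 1.0 / grid.dy**2))
    dt = dt_diff
    if umax > 0.0:
        dt = min(dt, cfg.cfl * grid.dx / umax)
    if vmax > 0.0:
        dt = min(dt, cfg.cfl * grid.dy / vmax)
    if dt < cfg.dt_floor:
        raise RuntimeError(
            f"time step collapsed below the floor ({dt:g} s < {cfg.dt_floor:g} s)"
        )
    return dt


# ---------------------------------------------------------------------------
# time stepping


def step(state: FieldState, forcing: ForcingSpec, cfg: SolverConfig) -> FieldState:
    """Advance one time step in place; returns the same state object.

    Explicit AB2 advection-diffusion (Euler on the first step), then a
    pressure projection.  The active global constraint is enforced exactly:
    the inlet flux for CFR, the outlet pressure for CPG, the lagged power
    relation for CPI.
    """
    grid = state.grid
    dt = _stability_dt(state, cfg)
    dirichlet_io = forcing.mode in _DIRICHLET_MODES

    # -- controller: outlet pressure for pressure-driven modes
    if forcing.mode is ForcingMode.CPG:
        state.p_outlet = -forcing.target / cfg.rho
    elif forcing.mode is ForcingMode.CPI:
        Q_prev = flow_rate(state)
        try:
            p_th = cpi_throat_pressure(forcing.target, Q_prev, cfg.q_floor)
        except ControllerError:
            raise
        state.p_outlet = p_th / cfg.rho

    # -- explicit advection-diffusion: AB2 on advection, Euler on diffusion
    # (AB2 halves the usable diffusive step; mixing keeps the Euler limit
    # while the steady state is unaffected by the time scheme)
    adv_u, diff_u = _terms_u(state.u, state.v, cfg.nu, grid.dx, grid.dy)
    adv_v, diff_v = _terms_v(state.u, state.v, cfg.nu, grid.dx, grid.dy)
    if state._hu is None:
        us = state.u + dt * (-adv_u + diff_u)
        vs = state.v + dt * (-adv_v + diff_v)
    else:
        us = state.u + dt * (-(1.5 * adv_u - 0.5 * state._hu) + diff_u)
        vs = state.v + dt * (-(1.5 * adv_v - 0.5 * state._hv) + diff_v)
    state._hu, state._hv = adv_u, adv_v

    # -- velocity boundary conditions on the intermediate field
    uact = grid.u_active()
    vact = grid.v_active()
    if forcing.mode is ForcingMode.CFR:
        us[0] = _inlet_profile(grid, forcing.target)
        us[-1] = us[-2]
        out_flux = float(np.sum(us[-1, uact[-1]]) * grid.dy)
        if abs(out_flux) < 1e-300:
            us[-1] = _inlet_profile(grid, forcing.target)  # degenerate startup
        else:
            us[-1, uact[-1]] *= forcing.target / out_flux
    else:
        us[0] = np.where(uact[0], us[1], 0.0)
        us[-1] = np.where(uact[-1], us[-2], 0.0)
    us[~uact] = 0.0
    vs[~vact] = 0.0

    # -- projection
    div = (us[1:] - us[:-1]) / grid.dx + (vs[:, 1:] - vs[:, :-1]) / grid.dy
    solver = _poisson_for(grid, dirichlet_io)
    phi = solver.solve(div / dt, 0.0, state.p_outlet)

    u_new = us.copy()
    u_new[1:-1] -= dt * (phi[1:] - phi[:-1]) / grid.dx
    v_new = vs.copy()
    v_new[:, 1:-1] -= dt * (phi[:, 1:] - phi[:, :-1]) / grid.dy
    if dirichlet_io:
        # boundary faces feel the half-cell gradient to the imposed face value
        u_new[0] = us[0] - dt * (phi[0] - 0.0) / (0.5 * grid.dx)
        u_new[-1] = us[-1] - dt * (state.p_outlet - phi[-1]) / (0.5 * grid.dx)
    u_new[~uact] = 0.0
    v_new[~vact] = 0.0

    # -- divergence check
    div_post = (u_new[1:] - u_new[:-1]) / grid.dx + (v_new[:, 1:] - v_new[:, :-1]) / grid.dy
    div_post[~grid.fluid] = 0.0
    uscale = max(float(np.max(np.abs(u_new))), 1e-30)
    if float(np.max(np.abs(div_post))) > cfg.div_tol * uscale / min(grid.dx, grid.dy):
        raise RuntimeError(
            f"projection failed to reach the divergence tolerance at t={state.t:g}"
        )

    state.u, state.v, state.p = u_new, v_new, phi
    state.t += dt
    state.n_steps += 1
    return state


def _measured_dp(state: FieldState, forcing: ForcingSpec, cfg: SolverConfig) -> float:
    """Ambient-to-throat pressure drop (Pa, positive for inspiration)."""
    if forcing.mode in _DIRICHLET_MODES:
        return -state.p_outlet * cfg.rho
    # CFR: extrapolate cell-centre pressures to the inlet/outlet planes
    grid = state.grid
    f0 = grid.fluid[0] & grid.fluid[1]
    fN = grid.fluid[-1] & grid.fluid[-2]
    p_in = float(np.mean(1.5 * state.p[0, f0] - 0.5 * state.p[1, f0]))
    p_out = float(np.mean(1.5 * state.p[-1, fN] - 0.5 * state.p[-2, fN]))
    return (p_in - p_out) * cfg.rho


def run_case(
    geom: "DuctGeometry | Grid",
    forcing: ForcingSpec,
    cfg: SolverConfig,
    initial: FieldState | None = None,
) -> tuple[GlobalQuantities, "pd.DataFrame", dict]:
    """Integrate one case and return time-averaged global quantities.

    Returns ``(globals, series, fields)`` where ``series`` is a DataFrame
    with columns ``t, Q, p_th, P`` (SI units) and ``fields`` holds the grid,
    final state and time-averaged velocity over the retained window.

    CPI starts from a warm uniform flow (the lagged controller is singular
    at rest): either ``cfg.cpi_warm_start_Q`` or a Poiseuille-based estimate
    ``Q = sqrt(P0 (2h)^3 / (12 rho nu L))``.
    """
    import pandas as pd

    grid = geom if isinstance(geom, Grid) else build_grid(geom)
    g = grid.geom

    if initial is not None:
        state = initial
    elif forcing.mode is ForcingMode.CPI:
        Q_start = cfg.cpi_warm_start_Q
        if Q_start is None:
            Q_start = math.sqrt(
                forcing.target * g.height**3 / (12.0 * cfg.rho * cfg.nu * g.L)
            )
        Q_start = max(Q_start, 10.0 * cfg.q_floor)
        state = FieldState.from_uniform_flow(grid, Q_start)
    else:
        state = FieldState.from_rest(grid, cfg)

    t_collect = cfg.discard_fraction * cfg.window
    ts, qs, ps = [], [], []
    while state.t < cfg.window:
        if state.n_steps >= cfg.max_steps:
            raise RuntimeError(
                f"max step count {cfg.max_steps} reached at t={state.t:g} "
                f"of {cfg.window:g} s"
            )
        t_before = state.t
        step(state, forcing, cfg)
        ts.append(state.t)
        qs.append(flow_rate(state))
        ps.append(-_measured_dp(state, forcing, cfg))  # p_th, signed
        if state.t >= t_collect:
            state.accumulate_mean(state.t - t_before)

    t_arr = np.asarray(ts)
    q_arr = np.asarray(qs)
    pth_arr = np.asarray(ps)
    power_arr = -q_arr * pth_arr
    Q_mean = time_average(t_arr, q_arr, cfg.discard_fraction)
    dp_mean = time_average(t_arr, -pth_arr, cfg.discard_fraction)
    P_mean = time_average(t_arr, power_arr, cfg.discard_fraction)
    gq = GlobalQuantities(Q_mean=Q_mean, dp_mean=dp_mean, P_mean=P_mean)

    series = pd.DataFrame({"t": t_arr, "Q": q_arr, "p_th": pth_arr, "P": power_arr})
    mean_u, mean_v = state.mean_fields()
    residual = {
        ForcingMode.CFR: abs(Q_mean - forcing.target) / forcing.target,
        ForcingMode.CPG: abs(dp_mean - forcing.target) / forcing.target,
        ForcingMode.CPI: abs(P_mean - forcing.target) / forcing.target,
    }[forcing.mode]
    fields = {
        "grid": grid,
        "state": state,
        "mean_u": mean_u,
        "mean_v": mean_v,
        "constraint_residual": residual,
        "metadata": {
            "forcing": {"mode": forcing.mode.value, "target": forcing.target},
            "config": cfg.to_dict(),
            "geometry": g.to_dict(),
            "grid": grid.metadata,
            "n_steps": state.n_steps,
        },
    }
    return gq, series, fields


# ---------------------------------------------------------------------------
# closed-form references


def poiseuille_flow_rate(dp: float, geom: DuctGeometry, cfg: SolverConfig) -> float:
    """Plane-Poiseuille flux per unit depth: ``dp (2h)^3 / (12 rho nu L)``."""
    return dp * geom.height**3 / (12.0 * cfg.rho * cfg.nu * geom.L)


def poiseuille_resistance(geom: DuctGeometry, cfg: SolverConfig) -> float:
    """Linear resistance ``12 rho nu L / (2h)^3`` of the straight channel."""
    return 12.0 * cfg.rho * cfg.nu * geom.L / geom.height**3
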