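"""Grids, agent source kernels, Douglas ADI stepping and CFL control.

The reaction-diffusion fields (TAF ``c``, drug ``d``, oxygen ``o``) are
advanced with the Douglas alternating-direction-implicit scheme: two
half-sweeps, each implicit in one axis and explicit in the other, with the
reaction evaluated explicitly at the start-of-step state,

    (1 - r_x dxx) U*   = (1 + r_y dyy) U^k + dt/2 f(U^k)
    (1 - r_y dyy) U^k1 = (1 + r_x dxx) U*  + dt/2 f(U^k)

with r = D dt / (2 h^2).  The scheme is unconditionally stable for linear
diffusion and second-order accurate in time and space; in the hybrid loop the
time step is nevertheless tied to the CFL bound of the explicit chemotaxis
update so both solvers share one dt.

Discrete tumor cells and vessel sites act on the fields through normalized
disk indicator kernels of radius ``Rc``: each agent deposits density
1/(pi Rc^2) on the nodes whose centers fall within ``Rc``, renormalized so
its discrete integral is exactly one (source/sink mass bookkeeping is then
exact regardless of how the disk straddles the mesh).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "Grid2D",
    "FieldState",
    "DoseSchedule",
    "CFLReport",
    "deposit_kernels",
    "quadrature_weights",
    "domain_integral",
    "adi_step",
    "step_taf",
    "step_drug",
    "step_oxygen",
    "cfl_dt",
    "OutOfDomainError",
    "CFLViolationError",
    "MissingParameterError",
]


class OutOfDomainError(ValueError):
    """An agent position lies outside the simulation domain."""


class CFLViolationError(RuntimeError):
    """A requested time step exceeds the CFL stability bound."""


class MissingParameterError(ValueError):
    """Michaelis-Menten kinetics selected without its half-saturation constant."""


BoundaryFlavor = Literal["neumann", "periodic"]


@dataclass(frozen=True)
class Grid2D:
    """Uniform rectangular node grid on [0, La] x [0, Lb].

    Axis 0 of field arrays is x (``Nx`` nodes), axis 1 is y.  For Neumann
    boundaries the nodes include both endpoints, ``(Nx-1)*dx = La``; for
    periodic boundaries the right endpoint is identified with the left,
    ``Nx*dx = La``.
    """

    Nx: int
    Ny: int
    La: float
    Lb: float
    bc: BoundaryFlavor = "neumann"

    def __post_init__(self) -> None:
        if self.Nx < 3 or self.Ny < 3:
            raise ValueError("grid needs at least 3 nodes per axis")
        if self.La <= 0 or self.Lb <= 0:
            raise ValueError("domain side lengths must be positive")
        if self.bc not in ("neumann", "periodic"):
            raise ValueError(f"unknown boundary flavor {self.bc!r}")

    @property
    def dx(self) -> float:
        return self.La / (self.Nx - 1) if self.bc == "neumann" else self.La / self.Nx

    @property
    def dy(self) -> float:
        return self.Lb / (self.Ny - 1) if self.bc == "neumann" else self.Lb / self.Ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.Nx, self.Ny)

    def node_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Node coordinate vectors (x of length Nx, y of length Ny)."""
        return (np.arange(self.Nx) * self.dx, np.arange(self.Ny) * self.dy)

    def contains(self, pos: np.ndarray) -> bool:
        x, y = float(pos[0]), float(pos[1])
        return 0.0 <= x <= self.La and 0.0 <= y <= self.Lb

    def nearest_node(self, pos: np.ndarray) -> tuple[int, int]:
        i = int(round(float(pos[0]) / self.dx))
        j = int(round(float(pos[1]) / self.dy))
        return (min(max(i, 0), self.Nx - 1), min(max(j, 0), self.Ny - 1))


@dataclass
class FieldState:
    """The four scalar lattice fields and the current nondimensional time."""

    grid: Grid2D
    n: np.ndarray
    c: np.ndarray
    d: np.ndarray
    o: np.ndarray
    t: float = 0.0

    @classmethod
    def uniform(cls, grid: Grid2D, n=0.0, c=0.0, d=0.0, o=0.0, t=0.0) -> "FieldState":
        mk = lambda v: np.full(grid.shape, float(v))
        return cls(grid, mk(n), mk(c), mk(d), mk(o), t)

    def validate(self) -> None:
        for name in ("n", "c", "d", "o"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"field {name!r} shape {arr.shape} != grid {self.grid.shape}")
            if np.any(arr < 0):
                raise ValueError(f"field {name!r} has negative entries")

    def copy(self) -> "FieldState":
        return FieldState(self.grid, self.n.copy(), self.c.copy(),
                          self.d.copy(), self.o.copy(), self.t)


@dataclass(frozen=True)
class DoseSchedule:
    """Vascular drug supply rate Sd(t): continuous or on/off pulsed dosing."""

    mode: Literal["continuous", "pulsed"] = "continuous"
    Sd_level: float = 2.0
    on_duration: float = 0.0
    off_duration: float = 0.0
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if self.mode == "pulsed" and (self.on_duration <= 0 or self.off_duration <= 0):
            raise ValueError("pulsed schedule requires positive on/off durations")

    def rate(self, t: float) -> float:
        if self.mode == "continuous":
            return self.Sd_level
        if t < self.t_start:
            return 0.0
        phase = (t - self.t_start) % (self.on_duration + self.off_duration)
        return self.Sd_level if phase < self.on_duration else 0.0


# ---------------------------------------------------------------------------
# quadrature and kernel deposition

def quadrature_weights(grid: Grid2D) -> np.ndarray:
    """Node weights of the discrete domain integral.

    Neumann node grids include both endpoints, so the natural quadrature is
    the trapezoid rule (boundary nodes weight 1/2, corners 1/4) — this is
    exactly the discrete mass the mirror-closure ADI scheme conserves.
    Periodic grids use equal weights.
    """
    w = np.ones(grid.shape)
    if grid.bc == "neumann":
        w[0, :] *= 0.5
        w[-1, :] *= 0.5
        w[:, 0] *= 0.5
        w[:, -1] *= 0.5
    return w * (grid.dx * grid.dy)


def domain_integral(arr: np.ndarray, grid: Grid2D) -> float:
    """Discrete integral of a node field over the domain."""
    return float((quadrature_weights(grid) * arr).sum())


def deposit_kernels(
    positions: Sequence[np.ndarray],
    grid: Grid2D,
    Rc: float,
    weights: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Sum of normalized disk indicators sampled on the grid nodes.

    A node belongs to an agent's kernel iff its center lies within ``Rc`` of
    the agent position; the discrete node values are renormalized so each
    agent's discrete integral (node sum times dx*dy) equals exactly its
    weight (default 1).  When the disk is smaller than the mesh and captures
    no node, the mass is assigned to the nearest node.
    """
    if Rc <= 0:
        raise ValueError("Rc must be positive")
    out = np.zeros(grid.shape)
    if len(positions) == 0:
        return out
    if weights is None:
        weights = [1.0] * len(positions)
    dx, dy = grid.dx, grid.dy
    quad = quadrature_weights(grid)
    for pos, w in zip(positions, weights):
        pos = np.asarray(pos, dtype=float)
        if not grid.contains(pos):
            raise OutOfDomainError(f"position {pos} outside [0,{grid.La}]x[0,{grid.Lb}]")
        i_lo = max(int(np.floor((pos[0] - Rc) / dx)), 0)
        i_hi = min(int(np.ceil((pos[0] + Rc) / dx)), grid.Nx - 1)
        j_lo = max(int(np.floor((pos[1] - Rc) / dy)), 0)
        j_hi = min(int(np.ceil((pos[1] + Rc) / dy)), grid.Ny - 1)
        xi = np.arange(i_lo, i_hi + 1) * dx
        yj = np.arange(j_lo, j_hi + 1) * dy
        mask = ((xi[:, None] - pos[0]) ** 2 + (yj[None, :] - pos[1]) ** 2) <= Rc ** 2
        if not mask.any():
            i, j = grid.nearest_node(pos)
            out[i, j] += w / quad[i, j]
        else:
            window = quad[i_lo:i_hi + 1, j_lo:j_hi + 1]
            norm = float(window[mask].sum())
            out[i_lo:i_hi + 1, j_lo:j_hi + 1][mask] += w / norm
    return out


# ---------------------------------------------------------------------------
# discrete Laplacian pieces and tridiagonal solves

def _lap1d(u: np.ndarray, axis: int, bc: BoundaryFlavor) -> np.ndarray:
    """Second central difference along ``axis`` (unscaled by h^2).

    Neumann uses the mirror ghost-node closure (ghost = first interior
    node), giving 2*(u1 - u0) at the boundary rows.
    """
    if axis == 1:
        return _lap1d(u.T, 0, bc).T
    out = np.empty_like(u)
    out[1:-1] = u[:-2] - 2.0 * u[1:-1] + u[2:]
    if bc == "neumann":
        out[0] = 2.0 * (u[1] - u[0])
        out[-1] = 2.0 * (u[-2] - u[-1])
    else:
        out[0] = u[-1] - 2.0 * u[0] + u[1]
        out[-1] = u[-2] - 2.0 * u[-1] + u[0]
    return out


def _solve_implicit(r: float, rhs: np.ndarray, bc: BoundaryFlavor) -> np.ndarray:
    """Solve (1 - r d2) u = rhs along axis 0 for every column of rhs."""
    N = rhs.shape[0]
    if bc == "neumann":
        ab = np.zeros((3, N))
        ab[1, :] = 1.0 + 2.0 * r
        ab[0, 1:] = -r
        ab[2, :-1] = -r
        ab[0, 1] = -2.0 * r      # mirror closure row 0
        ab[2, N - 2] = -2.0 * r  # mirror closure row N-1
        return solve_banded((1, 1), ab, rhs)
    # periodic: cyclic tridiagonal via Sherman-Morrison
    diag = 1.0 + 2.0 * r
    gamma = -diag
    ab = np.zeros((3, N))
    ab[1, :] = diag
    ab[0, 1:] = -r
    ab[2, :-1] = -r
    ab[1, 0] = diag - gamma
    ab[1, -1] = diag - r * r / gamma
    y = solve_banded((1, 1), ab, rhs)
    u = np.zeros(N)
    u[0] = gamma
    u[-1] = -r
    q = solve_banded((1, 1), ab, u)
    # v = [1, 0, ..., 0, -r/gamma]
    vy = y[0] + (-r / gamma) * y[-1]
    vq = q[0] + (-r / gamma) * q[-1]
    return y - np.outer(q, vy / (1.0 + vq)) if rhs.ndim == 2 else y - q * vy / (1.0 + vq)


def adi_step(
    u: np.ndarray,
    Dcoef: float,
    reaction: Callable[[np.ndarray], np.ndarray] | np.ndarray | None,
    dt: float,
    grid: Grid2D,
) -> np.ndarray:
    """One Douglas ADI step of du/dt = D lap(u) + f, reaction explicit."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("non-finite field passed to adi_step")
    if callable(reaction):
        f = reaction(u)
    elif reaction is None:
        f = 0.0
    else:
        f = reaction
    rx = Dcoef * dt / (2.0 * grid.dx ** 2)
    ry = Dcoef * dt / (2.0 * grid.dy ** 2)
    half_f = 0.5 * dt * f
    rhs = u + ry * _lap1d(u, 1, grid.bc) + half_f
    u_half = _solve_implicit(rx, rhs, grid.bc)
    rhs = u_half + rx * _lap1d(u_half, 0, grid.bc) + half_f
    u_new = _solve_implicit(ry, rhs.T, grid.bc).T
    return u_new


# ---------------------------------------------------------------------------
# field-specific steps

def _check_density(name: str, arr: np.ndarray) -> None:
    if np.any(arr < 0):
        raise ValueError(f"{name} density must be nonnegative")


def step_taf(state: FieldState, hypoxic_density: np.ndarray,
             vessel_density: np.ndarray, p, dt: float) -> np.ndarray:
    """Advance TAF: diffusion, decay, secretion by hypoxic cells, vessel uptake."""
    _check_density("hypoxic", hypoxic_density)
    _check_density("vessel", vessel_density)
    f = (-p.xi_c * state.c + p.eta * hypoxic_density
         - p.lam_uptake * state.c * vessel_density)
    return adi_step(state.c, p.Dc, f, dt, state.grid)


def step_drug(state: FieldState, tumor_density: np.ndarray,
              vessel_density: np.ndarray, schedule: DoseSchedule, p, dt: float,
              kinetics: Literal["linear", "michaelis_menten"] = "linear") -> np.ndarray:
    """Advance drug: diffusion, decay, tumor uptake, scheduled vascular supply."""
    _check_density("tumor", tumor_density)
    _check_density("vessel", vessel_density)
    d = state.d
    if kinetics == "michaelis_menten":
        if p.Kd is None:
            raise MissingParameterError("Michaelis-Menten drug uptake requires Kd")
        uptake = p.rho_d * d / (p.Kd + d)
    else:
        uptake = p.rho_d * d
    f = -p.xi_d * d - uptake * tumor_density + schedule.rate(state.t) * vessel_density
    return adi_step(d, p.Dd, f, dt, state.grid)


def step_oxygen(state: FieldState, tumor_density: np.ndarray,
                vessel_density: np.ndarray, p, dt: float,
                kinetics: Literal["linear", "michaelis_menten"] = "linear") -> np.ndarray:
    """Advance oxygen: diffusion, decay, tumor uptake, saturating vessel supply."""
    _check_density("tumor", tumor_density)
    _check_density("vessel", vessel_density)
    o = state.o
    if kinetics == "michaelis_menten":
        if p.Ko is None:
            raise MissingParameterError("Michaelis-Menten oxygen uptake requires Ko")
        uptake = p.rho_o * o / (p.Ko + o)
    else:
        uptake = p.rho_o * o
    f = -p.xi_o * o - uptake * tumor_density + p.So * (1.0 - o) * vessel_density
    return adi_step(o, p.Do, f, dt, state.grid)


# ---------------------------------------------------------------------------
# CFL control

@dataclass(frozen=True)
class CFLReport:
    """Time-step bounds for the explicit chemotaxis scheme.

    ``dt`` is the admissible step (minimum of the diffusive bound h^2/(4 Dn),
    the gradient bound h/(2 ||chi grad c||_inf) and the combined bound
    1/(4 Dn/h^2 + 2 ||chi grad c||_inf / h)); ``mesh_ok`` records whether the
    mesh constraint h <= 2 Dn / ||chi grad c||_inf holds (required for all
    motility weights to stay nonnegative).
    """

    dt: float
    bound_diffusive: float
    bound_gradient: float
    bound_combined: float
    grad_inf: float
    mesh_ok: bool


def chemotactic_grad_inf(p, c: np.ndarray, grid: Grid2D) -> float:
    """sup-norm of chi(c) grad c via centered differences."""
    if not np.all(np.isfinite(c)):
        raise FloatingPointError("non-finite TAF field")
    if grid.bc == "periodic":
        gx = (np.roll(c, -1, 0) - np.roll(c, 1, 0)) / (2 * grid.dx)
        gy = (np.roll(c, -1, 1) - np.roll(c, 1, 1)) / (2 * grid.dy)
    else:
        gx = np.gradient(c, grid.dx, axis=0)
        gy = np.gradient(c, grid.dy, axis=1)
    mag = np.hypot(gx, gy) * p.chi(c)
    return float(mag.max())


def cfl_dt(p, c: np.ndarray, grid: Grid2D) -> CFLReport:
    """Admissible explicit time step for the endothelial chemotaxis scheme."""
    h = min(grid.dx, grid.dy)
    g = chemotactic_grad_inf(p, c, grid)
    b_diff = h ** 2 / (4.0 * p.Dn) if p.Dn > 0 else np.inf
    b_grad = h / (2.0 * g) if g > 0 else np.inf
    denom = (4.0 * p.Dn / h ** 2) + (2.0 * g / h)
    b_comb = 1.0 / denom if denom > 0 else np.inf
    mesh_ok = (g == 0.0) or (h <= 2.0 * p.Dn / g)
    dt = min(b_diff, b_grad, b_comb)
    return CFLReport(dt, b_diff, b_grad, b_comb, g, mesh_ok)
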