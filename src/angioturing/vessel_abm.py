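"""Endothelial tip-cell agents and the vessel network they deposit.

Tip cells live on the lattice.  Each step they may branch (a Poisson event
whose intensity scales with local TAF, gated by a minimum age), migrate to a
von Neumann neighbor with TAF-gradient-biased probabilities, and proliferate
on a fixed doubling clock that elongates the sprout by one lattice step.
The union of all sites a tip has ever visited is the angiogenic network;
vessel sites are permanent (no pruning or regression).  A tip that steps
into a site already holding a tip or vessel anastomoses: its own node joins
the network and the tip retires.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .chemotaxis import DIRECTIONS, motility_probabilities, sample_direction
from .pde_core import Grid2D, MissingParameterError

__all__ = [
    "TipCell",
    "VesselNetwork",
    "branching_intensity",
    "attempt_branch",
    "move_tip",
    "tip_proliferate",
    "initialize_parent_vessel",
]

_tip_ids = itertools.count()

MOORE_OFFSETS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
CARDINAL_OFFSETS = [(-1, 0), (1, 0), (0, -1), (0, 1)]


@dataclass
class TipCell:
    id: int
    node: tuple[int, int]
    age: float = 0.0                       # time since last branching
    heading: Optional[tuple[int, int]] = None  # last successful move direction
    t_last_prolif: float = 0.0

    @classmethod
    def new(cls, node, t: float = 0.0) -> "TipCell":
        return cls(id=next(_tip_ids), node=tuple(node), t_last_prolif=t)


@dataclass
class VesselNetwork:
    """Monotonically growing set of lattice vessel sites."""

    sites: set = field(default_factory=set)
    birth: dict = field(default_factory=dict)  # site -> (time, kind)

    def add(self, node, t: float = 0.0, kind: str = "trail") -> None:
        node = tuple(node)
        if node not in self.sites:
            self.sites.add(node)
            self.birth[node] = (t, kind)

    def is_vessel(self, node) -> bool:
        return tuple(node) in self.sites

    def density(self, grid: Grid2D, tips=(), Rc: Optional[float] = None,
                p=None) -> np.ndarray:
        """Kernel field of all vessel sites plus active tip nodes."""
        from .pde_core import deposit_kernels
        nodes = set(self.sites) | {t.node for t in tips}
        positions = [np.array([i * grid.dx, j * grid.dy]) for (i, j) in nodes]
        radius = Rc if Rc is not None else (p.Rc if p is not None else grid.dx / 2)
        return deposit_kernels(positions, grid, radius)


def _occupied(node, net: VesselNetwork, tips) -> bool:
    return net.is_vessel(node) or any(t.node == tuple(node) for t in tips)


def branching_intensity(tip: TipCell, c: np.ndarray, p,
                        form: Literal["normalized", "michaelis_menten"] = "normalized") -> float:
    """Poisson branching rate at the tip's node.

    Normalized form: c_br * c(node)/max(c) * 1{age >= psi} (zero when the
    TAF field is identically zero); Michaelis-Menten form:
    c_br * c/(Kc + c) * 1{age >= psi}.
    """
    if np.any(c < 0):
        raise ValueError("TAF field must be nonnegative")
    if tip.age < p.psi_age:
        return 0.0
    c_local = float(c[tip.node])
    if form == "michaelis_menten":
        if p.Kc is None:
            raise MissingParameterError("Michaelis-Menten branching requires Kc")
        return p.c_br * c_local / (p.Kc + c_local) if c_local > 0 else 0.0
    cmax = float(c.max())
    if cmax <= 0.0:
        return 0.0
    return p.c_br * c_local / cmax


def _vacant_moore(tip: TipCell, net: VesselNetwork, tips, grid: Grid2D) -> list:
    i, j = tip.node
    out = []
    for di, dj in MOORE_OFFSETS:
        nb = (i + di, j + dj)
        if 0 <= nb[0] < grid.Nx and 0 <= nb[1] < grid.Ny and not _occupied(nb, net, tips):
            out.append(nb)
    return out


def attempt_branch(tip: TipCell, net: VesselNetwork, rate: float, dt_abm: float,
                   rng: np.random.Generator, grid: Grid2D,
                   tips=()) -> Optional[TipCell]:
    """Stochastic branching: new tip at a random vacant Moore neighbor.

    Requires a positive rate (which already encodes the age gate), at least
    one vacant Moore neighbor, and a uniform draw below 1 - exp(-rate*dt).
    Both tips' ages reset to zero on success.
    """
    if rate < 0:
        raise ValueError("branching rate must be nonnegative")
    if rate == 0.0:
        return None
    vacant = _vacant_moore(tip, net, tips, grid)
    if not vacant:
        return None
    if rng.uniform() >= 1.0 - math.exp(-rate * dt_abm):
        return None
    node = vacant[rng.integers(len(vacant))]
    daughter = TipCell.new(node)
    daughter.age = 0.0
    daughter.t_last_prolif = tip.t_last_prolif
    tip.age = 0.0
    return daughter


def _c_patch(c: np.ndarray, node, grid: Grid2D) -> tuple:
    """Von Neumann stencil of c at a node, mirrored across lattice edges."""
    i, j = node

    def at(ii, jj):
        ii = min(max(ii, 0), grid.Nx - 1) if grid.bc == "neumann" else ii % grid.Nx
        jj = min(max(jj, 0), grid.Ny - 1) if grid.bc == "neumann" else jj % grid.Ny
        return c[ii, jj]

    return (at(i, j), at(i - 1, j), at(i + 1, j), at(i, j - 1), at(i, j + 1))


def move_tip(tip: TipCell, c: np.ndarray, net: VesselNetwork, p,
             dt_abm: float, dx: float, rng: np.random.Generator,
             grid: Grid2D, tips=()) -> Literal["moved", "stayed", "anastomosed"]:
    """Gradient-biased lattice migration with trail deposition and anastomosis.

    The origin node is added to the vessel network on any move (the tip's
    cumulative path is the network).  Moving into a site occupied by a tip
    or vessel retires the moving tip (anastomosis): its own node joins the
    network and the caller must drop it from the active set.
    """
    probs = motility_probabilities(_c_patch(c, tip.node, grid), p, dt_abm, dx)
    direction = sample_direction(probs, rng.uniform())
    if direction == "stay":
        return "stayed"
    di, dj = DIRECTIONS[direction]
    target = (tip.node[0] + di, tip.node[1] + dj)
    if not (0 <= target[0] < grid.Nx and 0 <= target[1] < grid.Ny):
        return "stayed"  # moves off-lattice are suppressed (no-flux boundary)
    others = [t for t in tips if t.id != tip.id]
    if _occupied(target, net, others):
        net.add(tip.node, kind="anastomosis")
        return "anastomosed"
    net.add(tip.node, kind="trail")
    tip.node = target
    tip.heading = (di, dj)
    return "moved"


def tip_proliferate(tip: TipCell, net: VesselNetwork, t: float, p,
                    grid: Grid2D, rng: Optional[np.random.Generator] = None,
                    tips=()) -> Literal["none", "proliferated", "anastomosed"]:
    """Timed tip division: stalk segment behind, tip advances one step.

    Fires once ``tau_tip`` has elapsed since the tip's last proliferation.
    The tip's node becomes a stalk vessel site and the tip advances along
    its heading (random cardinal direction if it has never moved).  If the
    target is occupied the anastomosis rule applies; if the target is
    outside the lattice the division is deferred.
    """
    if t - tip.t_last_prolif < p.tau_tip:
        return "none"
    heading = tip.heading
    if heading is None:
        if rng is None:
            raise ValueError("rng required when the tip has no heading")
        heading = CARDINAL_OFFSETS[rng.integers(4)]
    target = (tip.node[0] + heading[0], tip.node[1] + heading[1])
    if not (0 <= target[0] < grid.Nx and 0 <= target[1] < grid.Ny):
        return "none"  # deferred at the boundary
    others = [tt for tt in tips if tt.id != tip.id]
    if _occupied(target, net, others):
        net.add(tip.node, t, kind="stalk")
        tip.t_last_prolif = t
        return "anastomosed"
    net.add(tip.node, t, kind="stalk")
    tip.node = target
    tip.heading = heading
    tip.t_last_prolif = t
    return "proliferated"


def initialize_parent_vessel(grid: Grid2D, n_tips: int = 3,
                             edge: Literal["bottom", "top", "left", "right"] = "bottom",
                             t: float = 0.0) -> tuple[VesselNetwork, list]:
    """Parent vessel: a line of vessel sites along one domain edge with
    ``n_tips`` equally spaced tip cells seeded on it."""
    net = VesselNetwork()
    if edge in ("bottom", "top"):
        j = 0 if edge == "bottom" else grid.Ny - 1
        inward = (0, 1) if edge == "bottom" else (0, -1)
        line = [(i, j) for i in range(grid.Nx)]
        picks = np.linspace(0, grid.Nx - 1, n_tips + 2)[1:-1].round().astype(int)
        tip_nodes = [(int(i), j + inward[1]) for i in picks]
    else:
        i = 0 if edge == "left" else grid.Nx - 1
        inward = (1, 0) if edge == "left" else (-1, 0)
        line = [(i, j) for j in range(grid.Ny)]
        picks = np.linspace(0, grid.Ny - 1, n_tips + 2)[1:-1].round().astype(int)
        tip_nodes = [(i + inward[0], int(j)) for j in picks]
    for node in line:
        net.add(node, t, kind="parent")
    # sprouting tips start one node inward of the parent vessel, headed
    # into the tissue, so their first moves do not immediately anastomose
    tips = []
    for node in tip_nodes:
        tip = TipCell.new(node, t)
        tip.heading = inward
        tips.append(tip)
    return net, tips
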