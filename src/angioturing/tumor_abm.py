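"""Discrete tumor-cell agents.

Each tumor cell is an off-lattice agent carrying sensed oxygen, cumulative
drug exposure, DNA damage, a death threshold, age and mutable traits
(proliferation rate ``alpha_n``, resistance factor ``th_multi``, oxygen
uptake multiplier ``rho_o_mult``).  Per agent-based step a cell

1. senses the local oxygen and drug fields (bilinear interpolation),
2. is classified by oxygen (normoxic / hypoxic / apoptotic),
3. accumulates drug-induced DNA damage with first-order repair and dies
   immediately once damage exceeds its threshold,
4. may mutate (time-continuous Poisson events; each mutable trait rescaled
   independently by Uniform[0.7, 1.7], clamped to [0.5, 4] x baseline),
5. ages (only while normoxic) and divides once its age reaches the cell-cycle
   duration log(2)/alpha_n, unless more than Fmax neighbors crowd within one
   cell radius; daughters split damage and drug load in half,
6. moves by reflected Brownian motion with amplitude eps_motility.

Death before division prevents dead cells from proliferating; the order is
exposed through :func:`angioturing.hybrid_sim.abm_pass` for sensitivity
checks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.spatial import cKDTree

from .pde_core import FieldState, Grid2D

__all__ = [
    "TumorCell",
    "Population",
    "brownian_move",
    "sense_fields",
    "damage_and_death",
    "classify_oxygen",
    "age_and_divide",
    "mutate",
    "initialize_population",
    "interpolate_field",
]

MUTABLE_TRAITS = ("alpha_n", "th_multi", "rho_o_mult")

_id_counter = itertools.count()


def _next_id() -> int:
    return next(_id_counter)


@dataclass
class TumorCell:
    id: int
    x: np.ndarray                      # continuous position, shape (2,)
    a_o: float = 1.0                   # sensed oxygen
    a_d: float = 0.0                   # cumulative drug exposure
    a_dam: float = 0.0                 # DNA damage
    a_death: float = 0.5               # death threshold
    a_age: float = 0.0                 # time since last division
    a_mat: float = 0.625               # cell-cycle duration log(2)/alpha_n
    traits: dict = field(default_factory=dict)
    baselines: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if not self.traits:
            alpha_n = math.log(2.0) / self.a_mat
            self.traits = {"alpha_n": alpha_n, "th_multi": 1.0, "rho_o_mult": 1.0}
        if not self.baselines:
            self.baselines = dict(self.traits)


@dataclass
class Population:
    cells: list
    classification: dict = field(default_factory=dict)  # id -> label

    def __len__(self) -> int:
        return len(self.cells)

    def positions(self) -> np.ndarray:
        if not self.cells:
            return np.empty((0, 2))
        return np.array([c.x for c in self.cells])

    def hypoxic_cells(self) -> list:
        return [c for c in self.cells if self.classification.get(c.id) == "hypoxic"]

    def resistant_fraction(self, a_death_S: float) -> float:
        if not self.cells:
            return 0.0
        return sum(c.a_death > a_death_S for c in self.cells) / len(self.cells)


def interpolate_field(field_arr: np.ndarray, grid: Grid2D, pos: np.ndarray,
                      method: Literal["bilinear", "nearest"] = "bilinear") -> float:
    """Sample a node field at an off-lattice position."""
    if method == "nearest":
        i, j = grid.nearest_node(pos)
        return float(field_arr[i, j])
    fx = float(pos[0]) / grid.dx
    fy = float(pos[1]) / grid.dy
    i0 = min(max(int(np.floor(fx)), 0), grid.Nx - 2)
    j0 = min(max(int(np.floor(fy)), 0), grid.Ny - 2)
    tx = min(max(fx - i0, 0.0), 1.0)
    ty = min(max(fy - j0, 0.0), 1.0)
    f = field_arr
    return float((1 - tx) * (1 - ty) * f[i0, j0] + tx * (1 - ty) * f[i0 + 1, j0]
                 + (1 - tx) * ty * f[i0, j0 + 1] + tx * ty * f[i0 + 1, j0 + 1])


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by successive reflection."""
    span = hi - lo
    if span <= 0:
        return lo
    v = (value - lo) % (2.0 * span)
    return lo + (v if v <= span else 2.0 * span - v)


def brownian_move(cell: TumorCell, p, dt_abm: float, rng: np.random.Generator,
                  domain: Grid2D) -> np.ndarray:
    """Euler-Maruyama step x += eps sqrt(dt) Z with reflecting boundaries."""
    if dt_abm <= 0:
        raise ValueError("dt_abm must be positive")
    step = p.eps_motility * math.sqrt(dt_abm) * rng.standard_normal(2)
    x = cell.x + step
    cell.x = np.array([_reflect(x[0], 0.0, domain.La),
                       _reflect(x[1], 0.0, domain.Lb)])
    return cell.x


def sense_fields(cell: TumorCell, state: FieldState, dt_abm: float,
                 method: Literal["bilinear", "nearest"] = "bilinear") -> None:
    """Update sensed oxygen and accumulate drug exposure at the cell position."""
    cell.a_o = interpolate_field(state.o, state.grid, cell.x, method)
    cell.a_d += interpolate_field(state.d, state.grid, cell.x, method) * dt_abm


def damage_and_death(cell: TumorCell, d_local: float, p,
                     dt_abm: float) -> Literal["alive", "dead"]:
    """Damage update a_dam += (d - p_r a_dam) dt; immediate death past threshold."""
    cell.a_dam += (d_local - p.p_r * cell.a_dam) * dt_abm
    return "dead" if cell.a_dam > cell.a_death else "alive"


def classify_oxygen(a_o: float, p) -> Literal["normoxic", "hypoxic", "apoptotic"]:
    if a_o > p.o_hyp:
        return "normoxic"
    if a_o > p.o_apop:
        return "hypoxic"
    return "apoptotic"


def count_neighbors(cell: TumorCell, pop: Population, radius: float,
                    tree: Optional[cKDTree] = None) -> int:
    """Number of *other* cells whose centers lie within ``radius``."""
    if tree is None:
        pos = pop.positions()
        if len(pos) == 0:
            return 0
        tree = cKDTree(pos)
    hits = tree.query_ball_point(cell.x, radius)
    return max(len(hits) - 1, 0)  # exclude the cell itself


def _make_daughter(mother: TumorCell, x: np.ndarray, p) -> TumorCell:
    traits = dict(mother.traits)
    return TumorCell(
        id=_next_id(), x=np.asarray(x, dtype=float),
        a_o=mother.a_o, a_d=0.5 * mother.a_d, a_dam=0.5 * mother.a_dam,
        a_death=mother.a_death, a_age=0.0,
        a_mat=math.log(2.0) / traits["alpha_n"],
        traits=traits, baselines=dict(mother.baselines),
    )


def age_and_divide(cell: TumorCell, pop: Population, p, dt_abm: float,
                   rng: np.random.Generator, grid: Grid2D,
                   tree: Optional[cKDTree] = None,
                   max_theta_attempts: int = 64) -> list:
    """Age (normoxic cells only) and attempt crowding-gated division.

    Returns ``[]`` (no division; the mother stays, possibly with retained age
    when crowded) or the two daughters replacing the mother: one at the
    mother's position and one offset by 0.1*(cos(2 pi theta) dx,
    sin(2 pi theta) dy), with theta resampled while the offset coincides
    with an existing cell center.
    """
    if pop.classification.get(cell.id) == "normoxic":
        cell.a_age += dt_abm
    if cell.a_age < cell.a_mat:
        return []
    if count_neighbors(cell, pop, p.Rc, tree) > p.Fmax:
        return []  # overcrowded: retain age, retry next step
    existing = pop.positions()
    for _ in range(max_theta_attempts):
        theta = rng.uniform()
        offset = 0.1 * np.array([math.cos(2 * math.pi * theta) * grid.dx,
                                 math.sin(2 * math.pi * theta) * grid.dy])
        x2 = cell.x + offset
        x2 = np.array([_reflect(x2[0], 0.0, grid.La), _reflect(x2[1], 0.0, grid.Lb)])
        if len(existing) == 0 or not np.any(np.all(np.isclose(existing, x2), axis=1)):
            d1 = _make_daughter(cell, cell.x, p)
            d2 = _make_daughter(cell, x2, p)
            return [d1, d2]
    return []  # pathological packing: defer division


def mutate(cell: TumorCell, p, dt_abm: float, rng: np.random.Generator) -> bool:
    """Neutral Poisson mutation; returns True if a mutation event occurred.

    On an event every mutable trait is independently multiplied by
    r ~ Uniform[0.7, 1.7] and clamped to [0.5, 4] times its baseline;
    cell-cycle duration and death threshold are recomputed from the traits.
    """
    if p.mu < 0:
        raise ValueError("mutation intensity must be nonnegative")
    if p.mu == 0 or rng.uniform() >= 1.0 - math.exp(-p.mu * dt_abm):
        return False
    for name in MUTABLE_TRAITS:
        r = rng.uniform(0.7, 1.7)
        base = cell.baselines[name]
        cell.traits[name] = float(np.clip(cell.traits[name] * r, 0.5 * base, 4.0 * base))
    cell.a_mat = math.log(2.0) / cell.traits["alpha_n"]
    cell.a_death = cell.traits["th_multi"] * p.a_death_S
    return True


def initialize_population(n_cells: int, scenario: Literal["preexisting", "spontaneous"],
                          p, rng: np.random.Generator, grid: Grid2D,
                          region: Optional[tuple] = None) -> Population:
    """Seed the zeroth tumor generation.

    Cell-cycle durations are Uniform over the nondimensional range
    ``p.age_range``; initial ages Uniform[0, duration]; damage and drug
    exposure zero.  In the ``preexisting`` scenario each cell is resistant
    with probability 1% (death threshold Th_multi * a_death_S); in the
    ``spontaneous`` scenario all start sensitive.  Positions are uniform
    over ``region`` ((x_lo, x_hi, y_lo, y_hi); default: the whole domain).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if scenario not in ("preexisting", "spontaneous"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if region is None:
        region = (0.0, grid.La, 0.0, grid.Lb)
    x_lo, x_hi, y_lo, y_hi = region
    cells = []
    for _ in range(n_cells):
        a_mat = rng.uniform(*p.age_range)
        alpha_n = math.log(2.0) / a_mat
        resistant = scenario == "preexisting" and rng.uniform() < 0.01
        th_multi = p.Th_multi if resistant else 1.0
        traits = {"alpha_n": alpha_n, "th_multi": th_multi, "rho_o_mult": 1.0}
        cells.append(TumorCell(
            id=_next_id(),
            x=np.array([rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi)]),
            a_o=1.0, a_d=0.0, a_dam=0.0,
            a_death=th_multi * p.a_death_S,
            a_age=rng.uniform(0.0, a_mat), a_mat=a_mat,
            traits=traits, baselines=dict(traits),
        ))
    return Population(cells=cells)
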