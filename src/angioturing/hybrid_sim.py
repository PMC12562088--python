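"""Global PDE <-> agent coupling loop.

Each global iteration advances the chemical fields (TAF, drug, oxygen) by
``m`` ADI substeps of size dt, reaching the agent cadence dt' = m dt, then
runs one agent pass: the tumor pipeline (sense -> classify -> death ->
mutate -> divide -> move) followed by the vessel pipeline (branch -> move /
anastomose -> proliferate).  Agent kernels (hypoxic TAF sources, tumor
uptake sinks, vessel supply sources) are refreshed from the updated
populations before the next block of substeps, closing the two-way coupling.

Endothelial cells have two representations: the continuum density field n
(evolved only in reduced-subsystem studies, ``endothelial_mode='continuum'``)
and the discrete tip/vessel agents (``'agents'``, the default for full
hybrid runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from . import tumor_abm, vessel_abm
from .chemotaxis import endothelial_step
from .pde_core import (CFLViolationError, DoseSchedule, FieldState, Grid2D,
                       cfl_dt, deposit_kernels, domain_integral, step_drug,
                       step_oxygen, step_taf)
from .tumor_abm import (Population, brownian_move, classify_oxygen,
                        damage_and_death, initialize_population,
                        interpolate_field, mutate, sense_fields)
from .vessel_abm import (TipCell, VesselNetwork, attempt_branch,
                         branching_intensity, initialize_parent_vessel,
                         move_tip, tip_proliferate)

__all__ = [
    "SimConfig",
    "SimSummary",
    "SimResult",
    "run_simulation",
    "abm_pass",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    params: object                      # NDParams
    grid: Grid2D
    t_end: float = 10.0
    seed: int = 0
    m_substeps: int = 4
    dt_abm: float = 0.1
    scenario: Literal["preexisting", "spontaneous"] = "preexisting"
    n_tumor_cells: int = 100
    dose: DoseSchedule = field(default_factory=DoseSchedule)
    vessel_init: dict = field(default_factory=lambda: {"n_tips": 3, "edge": "bottom"})
    snapshot_every: Optional[float] = None
    kinetics: Literal["linear", "michaelis_menten"] = "linear"
    branching_form: Literal["normalized", "michaelis_menten"] = "normalized"
    endothelial_mode: Literal["agents", "continuum"] = "agents"
    sense_method: Literal["bilinear", "nearest"] = "bilinear"
    initial_fields: dict = field(default_factory=lambda: {"n": 0.0, "c": 0.0,
                                                          "d": 0.0, "o": 1.0})
    tumor_region: Optional[tuple] = None
    reaction_courant: float = 0.25   # dt_sub * max reaction rate stays below this

    def __post_init__(self) -> None:
        if self.m_substeps < 1:
            raise ConfigurationError("m_substeps must be >= 1")
        if self.t_end <= 0:
            raise ConfigurationError("t_end must be positive")


@dataclass
class SimSummary:
    """Per-agent-step time series of population and field aggregates."""

    rows: list = field(default_factory=list)

    COLUMNS = ("t", "tumor_count", "hypoxic_fraction", "resistant_fraction",
               "vessel_sites", "active_tips", "int_c", "int_d", "int_o",
               "tip_cfl_ok")

    def append(self, **kw) -> None:
        self.rows.append(tuple(kw[c] for c in self.COLUMNS))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)


@dataclass
class SimResult:
    config: SimConfig
    summary: SimSummary
    state: FieldState
    population: Population
    tips: list
    network: VesselNetwork
    snapshots: list = field(default_factory=list)   # (t, FieldState)


def _kernel_fields(pop: Population, tips, net: VesselNetwork, p, grid: Grid2D):
    """Refresh the agent source/sink lattice densities."""
    hyp_pos = [c.x for c in pop.hypoxic_cells()]
    all_pos = [c.x for c in pop.cells]
    o_weights = [c.traits.get("rho_o_mult", 1.0) for c in pop.cells]
    hyp = deposit_kernels(hyp_pos, grid, p.Rc) if hyp_pos else np.zeros(grid.shape)
    tum = deposit_kernels(all_pos, grid, p.Rc) if all_pos else np.zeros(grid.shape)
    tum_o = (deposit_kernels(all_pos, grid, p.Rc, weights=o_weights)
             if all_pos else np.zeros(grid.shape))
    ves = net.density(grid, tips=tips, Rc=p.Rc)
    return hyp, tum, tum_o, ves


def abm_pass(state: FieldState, pop: Population, tips: list,
             net: VesselNetwork, cfg: SimConfig,
             rng: np.random.Generator) -> tuple[Population, list]:
    """One agent update at cadence dt_abm: tumor pipeline then vessel pipeline."""
    p = cfg.params
    grid = state.grid
    dt = cfg.dt_abm

    # --- tumor cells ---------------------------------------------------
    tree = None
    if pop.cells:
        from scipy.spatial import cKDTree
        tree = cKDTree(pop.positions())
    survivors: list = []
    for cell in pop.cells:
        sense_fields(cell, state, dt, cfg.sense_method)
        label = classify_oxygen(cell.a_o, p)
        pop.classification[cell.id] = label
        if label == "apoptotic":
            pop.classification.pop(cell.id, None)
            continue
        d_local = interpolate_field(state.d, grid, cell.x, cfg.sense_method)
        if damage_and_death(cell, d_local, p, dt) == "dead":
            pop.classification.pop(cell.id, None)
            continue
        mutate(cell, p, dt, rng)
        daughters = tumor_abm.age_and_divide(cell, pop, p, dt, rng, grid, tree)
        outcome = daughters if daughters else [cell]
        if daughters:
            for dtr in daughters:
                pop.classification[dtr.id] = label
            pop.classification.pop(cell.id, None)
        for cc in outcome:
            brownian_move(cc, p, dt, rng, grid)
            survivors.append(cc)
    pop.cells = survivors

    # --- vessel tips ----------------------------------------------------
    order = rng.permutation(len(tips))
    active = list(tips)
    retired: set = set()
    for idx in order:
        tip = active[idx]
        if tip.id in retired:
            continue
        tip.age += dt
        live = [t for t in active if t.id not in retired]
        rate = branching_intensity(tip, state.c, p, cfg.branching_form)
        new_tip = attempt_branch(tip, net, rate, dt, rng, grid, tips=live)
        if new_tip is not None:
            new_tip.t_last_prolif = state.t
            active.append(new_tip)
            live.append(new_tip)
        status = move_tip(tip, state.c, net, p, dt, grid.dx, rng, grid, tips=live)
        if status == "anastomosed":
            retired.add(tip.id)
            continue
        live = [t for t in active if t.id not in retired]
        status = tip_proliferate(tip, net, state.t, p, grid, rng, tips=live)
        if status == "anastomosed":
            retired.add(tip.id)
    tips = [t for t in active if t.id not in retired]
    return pop, tips


def run_simulation(cfg: SimConfig) -> SimResult:
    """Run the full hybrid loop to ``t_end``; reproducible from the seed."""
    p = cfg.params
    grid = cfg.grid
    rng = np.random.default_rng(cfg.seed)
    state = FieldState.uniform(grid, **cfg.initial_fields)

    pop = (initialize_population(cfg.n_tumor_cells, cfg.scenario, p, rng, grid,
                                 region=cfg.tumor_region)
           if cfg.n_tumor_cells > 0 else Population(cells=[]))
    if cfg.vessel_init:
        net, tips = initialize_parent_vessel(grid, **cfg.vessel_init)
    else:
        net, tips = VesselNetwork(), []

    # initial sensing/classification so the first kernel refresh is consistent
    for cell in pop.cells:
        cell.a_o = interpolate_field(state.o, grid, cell.x, cfg.sense_method)
        pop.classification[cell.id] = classify_oxygen(cell.a_o, p)

    dt = cfg.dt_abm / cfg.m_substeps
    if cfg.endothelial_mode == "continuum":
        report = cfl_dt(p, state.c, grid)
        if dt > report.dt:
            raise ConfigurationError(
                f"CFL infeasible: dt={dt:.3e} > bound {report.dt:.3e}; "
                "increase m_substeps")

    summary = SimSummary()
    snapshots: list = []

    def record(tip_cfl_ok: bool) -> None:
        ncells = len(pop.cells)
        hyp = (sum(1 for c_ in pop.cells
                   if pop.classification.get(c_.id) == "hypoxic") / ncells
               if ncells else 0.0)
        summary.append(
            t=state.t, tumor_count=ncells, hypoxic_fraction=hyp,
            resistant_fraction=pop.resistant_fraction(p.a_death_S),
            vessel_sites=len(net.sites), active_tips=len(tips),
            int_c=domain_integral(state.c, grid),
            int_d=domain_integral(state.d, grid),
            int_o=domain_integral(state.o, grid),
            tip_cfl_ok=tip_cfl_ok,
        )

    record(True)
    next_snap = cfg.snapshot_every
    t_eps = 1e-9
    while state.t < cfg.t_end - t_eps:
        hyp, tum, tum_o, ves = _kernel_fields(pop, tips, net, p, grid)
        # explicit reaction stability: the concentrated agent kernels make
        # the linear sink coefficients stiff, so each nominal substep is
        # refined until dt_sub * max-rate stays well inside the stability
        # region of forward Euler
        rate = max(
            p.xi_c + p.lam_uptake * float(ves.max(initial=0.0)),
            p.xi_d + p.rho_d * float(tum.max(initial=0.0)),
            p.xi_o + p.rho_o * float(tum_o.max(initial=0.0))
            + p.So * float(ves.max(initial=0.0)),
        )
        refine = max(int(np.ceil(dt * rate / cfg.reaction_courant)), 1)
        dt_sub = dt / refine
        for _ in range(cfg.m_substeps * refine):
            c_new = step_taf(state, hyp, ves, p, dt_sub)
            d_new = step_drug(state, tum, ves, cfg.dose, p, dt_sub, cfg.kinetics)
            o_new = step_oxygen(state, tum_o, ves, p, dt_sub, cfg.kinetics)
            if cfg.endothelial_mode == "continuum":
                state.n = endothelial_step(state.n, state.c, p, dt_sub, grid)
            state.c, state.d, state.o = c_new, d_new, o_new
            state.t += dt_sub
        tip_cfl_ok = cfg.dt_abm <= cfl_dt(p, state.c, grid).dt
        pop, tips = abm_pass(state, pop, tips, net, cfg, rng)
        record(tip_cfl_ok)
        if next_snap is not None and state.t >= next_snap - t_eps:
            snapshots.append((state.t, state.copy()))
            next_snap += cfg.snapshot_every

    return SimResult(config=cfg, summary=summary, state=state, population=pop,
                     tips=tips, network=net, snapshots=snapshots)


# ---------------------------------------------------------------------------
# exports

def export_summary_csv(result: SimResult, path) -> None:
    result.summary.to_dataframe().to_csv(path, index=False)


def export_cell_census_csv(result: SimResult, path) -> None:
    """One row per tumor cell: id, position, label, damage, threshold, traits."""
    rows = []
    for c in result.population.cells:
        rows.append({
            "id": c.id, "x": c.x[0], "y": c.x[1],
            "label": result.population.classification.get(c.id, ""),
            "a_dam": c.a_dam, "a_death": c.a_death, "a_d": c.a_d,
            **{f"trait_{k}": v for k, v in c.traits.items()},
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def export_network_csv(result: SimResult, path) -> None:
    """Edge-list style vessel export: site indices, birth time and type."""
    rows = [{"i": i, "j": j, "birth_time": result.network.birth[(i, j)][0],
             "type": result.network.birth[(i, j)][1]}
            for (i, j) in sorted(result.network.sites)]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_snapshots_h5(result: SimResult, path) -> None:
    """Portable array container with groups fields/{n,c,d,o} over time."""
    import h5py

    snaps = result.snapshots or [(result.state.t, result.state)]
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=np.array([t for t, _ in snaps]))
        grp = fh.create_group("fields")
        for name in ("n", "c", "d", "o"):
            grp.create_dataset(
                name, data=np.stack([getattr(s, name) for _, s in snaps]))
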