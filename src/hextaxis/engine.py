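"""World assembly, the iteration scheduler, and time-series recording.

A simulation couples the vectorized receptor field with the mobile-agent
layer on one lattice.  Each iteration applies, in order:

1. any ligand-schedule change due at this iteration,
2. the synchronous receptor activity update,
3. the shuffled soluble-agent sweep (move, then at most one reaction
   attempt per agent),
4. unimolecular events (anchored-CheA autophosphorylation,
   auto-dephosphorylation),
5. recording, every ``record_interval`` iterations.

Soluble agent counts follow the in vivo stoichiometry 3.4 receptors :
2.4 CheY : 1.6 CheW : 1 CheA : 0.5 CheZ : 0.08 CheB : 0.05 CheR, scaled to
the configured receptor count; all CheA and CheW start mobile and unbound,
so the CheW-CheA-CheW bridge network self-assembles stochastically during
burn-in.  Everything is driven by a single seeded ``numpy.random
.Generator``: a run is bit-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .hexgrid import ReceptorTopology, build_receptor_mask, neighbor_table
from .receptor_field import (TAR, TSR, EnergyParams, LigandEnvironment,
                             LigandSpec, ReceptorField, default_ligands)
from .soluble_agents import CHEA, CHEB, CHER, KIND_NAMES, ReactionTable

__all__ = [
    "RECEPTOR_RATIO",
    "STOICHIOMETRY",
    "SimulationConfig",
    "LigandSchedule",
    "TimeSeries",
    "World",
    "initialize",
    "step",
    "run",
]

log = logging.getLogger("hextaxis")

#: in vivo stoichiometric ratios, relative to 3.4 receptors
RECEPTOR_RATIO = 3.4
STOICHIOMETRY = {"CheY": 2.4, "CheW": 1.6, "CheA": 1.0,
                 "CheZ": 0.5, "CheB": 0.08, "CheR": 0.05}
_KIND_BY_NAME = {name: kind for kind, name in KIND_NAMES.items()}


@dataclass
class LigandSchedule:
    """Step changes in bulk attractant concentration: an ordered list of
    ``(iteration, species, concentration M)``; each change is applied at
    its iteration and held until the next change of that species."""

    changes: list[tuple[int, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        last = -1
        for it, _, conc in self.changes:
            if it < last:
                raise ValueError("schedule iterations must be non-decreasing")
            if conc < 0:
                raise ValueError("concentrations must be non-negative")
            last = it

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, s, _ in self.changes:
            seen.setdefault(s)
        return list(seen)


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run."""

    columns: int = 100
    rows: int = 60
    receptor_region_columns: int = 60
    n_receptors: int = 1083
    frac_tar: float = 1.0
    m_tar: int = 2
    m_tsr: int = 2
    energy: EnergyParams = field(default_factory=EnergyParams)
    reactions: ReactionTable = field(default_factory=ReactionTable)
    ligands: list[LigandSpec] = field(default_factory=default_ligands)
    include_pathway: bool = False
    include_adaptation_enzymes: bool = True
    stoichiometry: dict[str, float] = field(
        default_factory=lambda: dict(STOICHIOMETRY))
    schedule: LigandSchedule = field(default_factory=LigandSchedule)
    iterations: int = 2000
    record_interval: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_tar <= 1.0:
            raise ValueError("frac_tar must be in [0, 1]")
        if self.record_interval < 1:
            raise ValueError("record_interval must be >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        for name, ratio in self.stoichiometry.items():
            if name not in STOICHIOMETRY:
                raise ValueError(f"unknown species {name!r} in stoichiometry")
            if ratio < 0:
                raise ValueError(f"stoichiometry ratio for {name} "
                                 "must be >= 0")

    def agent_counts(self) -> dict[int, int]:
        """Soluble agent counts from the stoichiometric ratios: nearest
        integer of ``n_receptors * ratio / 3.4`` (ties rounded up), with a
        floor of 1 for any included species."""
        if not self.include_pathway:
            return {}
        counts = {}
        for name, ratio in self.stoichiometry.items():
            kind = _KIND_BY_NAME[name]
            if kind in (CHEB, CHER) and not self.include_adaptation_enzymes:
                continue
            if ratio <= 0:
                continue
            n = int(np.floor(self.n_receptors * ratio / RECEPTOR_RATIO + 0.5))
            counts[kind] = max(1, n)
        return counts

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TimeSeries:
    """Recorded observables, one row per ``record_interval`` iterations
    (iteration 0 included)."""

    iteration: np.ndarray
    frac_active: np.ndarray
    frac_active_tar: np.ndarray
    frac_active_tsr: np.ndarray
    mean_methylation: np.ndarray
    frac_chea_p: np.ndarray
    frac_chey_p: np.ndarray
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    record_interval: int = 100

    def __len__(self) -> int:
        return len(self.iteration)

    def activity(self, readout: str = "total") -> np.ndarray:
        """Activity column by readout: 'total', 'tar' or 'tsr'."""
        return {"total": self.frac_active, "tar": self.frac_active_tar,
                "tsr": self.frac_active_tsr}[readout]

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "iteration": self.iteration,
            "frac_active": self.frac_active,
            "frac_active_tar": self.frac_active_tar,
            "frac_active_tsr": self.frac_active_tsr,
            "mean_methylation": self.mean_methylation,
            "frac_chea_p": self.frac_chea_p,
            "frac_chey_p": self.frac_chey_p,
        }
        for name, arr in self.concentrations.items():
            data[f"conc_{name}"] = arr
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class World:
    """Mutable simulation state: the receptor field plus the agent layer."""

    def __init__(self, config: SimulationConfig, topology: ReceptorTopology,
                 field_: ReceptorField, rng: np.random.Generator):
        self.config = config
        self.topology = topology
        self.field = field_
        self.rng = rng
        self.iteration = 0
        self.env = LigandEnvironment()
        n_cells = config.columns * config.rows
        rows = config.rows

        self.nbr6 = neighbor_table(config.columns, config.rows)
        self.nvalid = (self.nbr6 >= 0).sum(axis=1).astype(np.int32)
        self.fg = np.full(n_cells, -1, dtype=np.int32)
        self.bg_receptor = np.full(n_cells, -1, dtype=np.int32)
        for i, (c, r) in enumerate(topology.sites):
            self.bg_receptor[c * rows + r] = i
        self.bg_chea = np.full(n_cells, -1, dtype=np.int32)
        self.bridge_ok = np.zeros(n_cells, dtype=np.int8)
        self.bridge_recs = np.full((n_cells, 6), -1, dtype=np.int32)
        for cell, recs in zip(topology.bridge_sites,
                              topology.bridge_receptors):
            idx = cell[0] * rows + cell[1]
            self.bridge_ok[idx] = 1
            self.bridge_recs[idx, :len(recs)] = recs

        counts = config.agent_counts()
        n_agents = sum(counts.values())
        self.kind = np.empty(n_agents, dtype=np.int8)
        pos = 0
        for kind in sorted(counts):
            n = counts[kind]
            self.kind[pos:pos + n] = kind
            pos += n
        self.ncw = np.zeros(n_agents, dtype=np.int8)
        self.phos = np.zeros(n_agents, dtype=np.int8)
        self.cell = np.full(n_agents, -1, dtype=np.int32)
        self.alive = np.ones(n_agents, dtype=np.int8)
        self.anchored = np.zeros(n_agents, dtype=np.int8)
        self.att1 = np.full(n_agents, -1, dtype=np.int32)
        self.att2 = np.full(n_agents, -1, dtype=np.int32)
        self._order = np.empty(max(n_agents, 1), dtype=np.int32)
        self.events = np.zeros(K.N_EVENTS, dtype=np.int64)

        if n_agents > n_cells:
            raise ValueError(
                f"{n_agents} agents do not fit on {n_cells} cells")
        if n_agents:
            cells = rng.choice(n_cells, size=n_agents, replace=False)
            self.cell[:] = cells
            self.fg[cells] = np.arange(n_agents, dtype=np.int32)

    @property
    def n_agents(self) -> int:
        return len(self.kind)

    def species_counts(self) -> dict[str, int]:
        """Total copies per protein species, counting complexes by
        composition (CheW = mobile + carried by CheA + receptor-bound)."""
        alive = self.alive == 1
        counts = {name: int(np.sum(alive & (self.kind == kind)))
                  for kind, name in KIND_NAMES.items()}
        counts["CheW"] += int(self.ncw[alive & (self.kind == CHEA)].sum())
        counts["CheW"] += int(self.field.bound_chew.sum())
        return counts

    def phosphoryl_count(self) -> int:
        return int(np.sum((self.alive == 1) & (self.phos == 1)))

    def anchored_chea_fraction(self) -> float:
        chea = (self.alive == 1) & (self.kind == CHEA)
        n = int(chea.sum())
        return float(np.sum(chea & (self.anchored == 1)) / n) if n else 0.0

    def apply_concentration(self, species: str, conc: float) -> None:
        self.env.set(species, conc)
        self.field.set_environment(self.env)

    def measure(self) -> tuple[float, float, float, float, float, float]:
        return K.measure(self.field.a, self.field.m, self.field.rtype,
                         self.kind, self.phos, self.alive)


def initialize(config: SimulationConfig,
               rng: np.random.Generator | None = None) -> World:
    """Build the mask, assign receptor types and methylation, place the
    soluble agents uniformly at random, and draw initial activities."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    topo = build_receptor_mask(config.columns, config.rows,
                               config.receptor_region_columns,
                               config.n_receptors)
    n = topo.n_receptors
    rtype = np.where(rng.random(n) < config.frac_tar, TAR, TSR).astype(np.int8)
    m = np.where(rtype == TAR, config.m_tar, config.m_tsr).astype(np.int8)
    field_ = ReceptorField(topo, rtype, m)
    field_.set_binding(config.ligands)

    world = World(config, topo, field_, rng)
    for it, species, conc in config.schedule.changes:
        if it <= 0:
            world.apply_concentration(species, conc)
    field_.initialize_activity(config.energy, rng)
    return world


def step(world: World, n_iters: int = 1,
         record: tuple[np.ndarray, ...] | None = None,
         record_interval: int | None = None) -> None:
    """Advance the world ``n_iters`` iterations (no schedule handling).

    ``record`` optionally supplies the four output arrays that
    :func:`run` preallocates; slot ``g // record_interval`` is written at
    every multiple of the interval.
    """
    cfg = world.config
    e = cfg.energy
    if record is None:
        # dummy one-slot sinks; record_every > total iterations suppresses
        rec = tuple(np.empty(1) for _ in range(6))
        every = n_iters + world.iteration + 1
    else:
        rec = record
        every = record_interval or cfg.record_interval
    f = world.field
    K.run_chunk(world.rng, n_iters, world.iteration, every,
                f.a, f._a_buf, f.m, f.rtype, f.nbr, f.kd_act, f.kd_inact,
                f.lig,
                e.g0, e.el, e.em, e.ej, e.omega, e.thermal_scale,
                world._order, world.kind, world.ncw, world.phos, world.cell,
                world.alive, world.anchored, world.att1, world.att2,
                world.fg, world.bg_receptor, world.bg_chea,
                world.nbr6, world.nvalid, world.bridge_ok, world.bridge_recs,
                f.trimer_id, f.bound_chew, f.chew_engaged,
                cfg.reactions.as_vector(), world.events,
                *rec)
    world.iteration += n_iters


def run(config: SimulationConfig,
        rng: np.random.Generator | None = None,
        world: World | None = None) -> TimeSeries:
    """Execute the full ligand schedule and return the recorded series."""
    if world is None:
        world = initialize(config, rng)
    R = config.record_interval
    total = config.iterations
    n_rec = total // R + 1
    rec = tuple(np.zeros(n_rec) for _ in range(6))
    frac_active, frac_tar, frac_tsr, mean_m, frac_ap, frac_yp = rec

    conc: dict[str, np.ndarray] = {
        s: np.zeros(n_rec) for s in config.schedule.species()}

    # initial record (iteration 0)
    vals = world.measure()
    for arr, v in zip(rec, vals):
        arr[0] = v
    for s in conc:
        conc[s][0] = world.env.get(s)

    # breakpoints where the environment changes
    changes = [(it, sp, c) for it, sp, c in config.schedule.changes
               if 0 < it <= total]
    breaks = sorted({it for it, _, _ in changes} | {total})
    pos = 0
    for b in breaks:
        if b > pos:
            step(world, b - pos, record=rec, record_interval=R)
            lo, hi = pos // R + 1, b // R + 1
            for s in conc:
                conc[s][lo:hi] = world.env.get(s)
            pos = b
        for it, sp, c in changes:
            if it == b:
                log.info("iteration %d: [%s] -> %.3g M", b, sp, c)
                world.apply_concentration(sp, c)

    return TimeSeries(
        iteration=np.arange(n_rec) * R,
        frac_active=frac_active,
        frac_active_tar=frac_tar,
        frac_active_tsr=frac_tsr,
        mean_methylation=mean_m,
        frac_chea_p=frac_ap,
        frac_chey_p=frac_yp,
        concentrations=conc,
        record_interval=R,
    )


def run_manifest(config: SimulationConfig, outputs: list[str]) -> dict:
    """JSON-serializable record of a run (config echo, seed, outputs)."""
    from . import __version__
    from .config import config_to_dict
    return {
        "config": config_to_dict(config),
        "seed": config.seed,
        "iterations": config.iterations,
        "outputs": outputs,
        "version": __version__,
    }
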