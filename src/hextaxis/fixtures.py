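"""Deterministic miniature worlds for tests and quick exploration.

Kinds:

* ``tiny-lattice`` — a 12x9 grid fully tiled with trimers (receptor-only).
* ``two-trimer`` — exactly two trimers with a bridge site between them,
  one mobile agent of every soluble species.
* ``no-receptors`` — a pure-diffusion world (soluble agents only).
* ``single-agent`` — one CheY on an otherwise empty small grid.
"""

from __future__ import annotations

import numpy as np

from .engine import SimulationConfig, World, initialize

__all__ = ["FIXTURE_KINDS", "make_fixture", "fixture_config"]

FIXTURE_KINDS = ("tiny-lattice", "two-trimer", "no-receptors", "single-agent")


def fixture_config(kind: str, seed: int = 0) -> SimulationConfig:
    """The SimulationConfig behind each fixture kind."""
    if kind == "tiny-lattice":
        return SimulationConfig(columns=12, rows=9,
                                receptor_region_columns=12, n_receptors=36,
                                include_pathway=False, seed=seed)
    if kind == "two-trimer":
        return SimulationConfig(columns=8, rows=6, receptor_region_columns=8,
                                n_receptors=6, include_pathway=True,
                                include_adaptation_enzymes=True, seed=seed)
    if kind == "no-receptors":
        return SimulationConfig(columns=10, rows=10,
                                receptor_region_columns=4, n_receptors=0,
                                include_pathway=True, seed=seed)
    if kind == "single-agent":
        return SimulationConfig(columns=6, rows=6, receptor_region_columns=4,
                                n_receptors=0, include_pathway=True,
                                seed=seed)
    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"choose from {FIXTURE_KINDS}")


def make_fixture(kind: str, seed: int = 0) -> World:
    """Build a small deterministic world of the requested kind."""
    cfg = fixture_config(kind, seed)
    world = initialize(cfg)
    if kind == "two-trimer":
        # trim the stoichiometric counts to exactly one agent per species
        keep: dict[int, int] = {}
        for i in range(world.n_agents):
            k = int(world.kind[i])
            if k in keep:
                world.alive[i] = 0
                world.fg[world.cell[i]] = -1
                world.cell[i] = -1
            else:
                keep[k] = i
    if kind == "single-agent":
        from .soluble_agents import CHEY
        for i in range(world.n_agents):
            if int(world.kind[i]) != CHEY or i != int(
                    np.nonzero(world.kind == CHEY)[0][0]):
                world.alive[i] = 0
                world.fg[world.cell[i]] = -1
                world.cell[i] = -1
    return world
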