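"""Receptor state and the cooperative, methylation-modulated activity update.

Each chemoreceptor dimer is a two-state unit (active ``a=+1`` / inactive
``a=-1``) whose switching probability derives from the free-energy
difference between the two conformations — a linear combination of a
baseline offset ``G0``, a ligand-binding term ``El * F(l)``, a methylation
term ``Em * (m - 2)``, and an Ising-like neighbor-coupling term
``Ej * sum_n gamma(m_n) * a_n`` over the 2 intra-trimer + 2 inter-trimer
neighbors.  The probability of being active on the next iteration is the
Boltzmann logistic

    p = 1 / (1 + exp(dG / thermal_scale))

so negative free energy favors the active state and ``dG = 0`` gives
``p = 0.5``.  Ligand binding is not simulated molecule-by-molecule: because
binding equilibrates orders of magnitude faster than phosphorylation, a
receptor carries the time-averaged fractional occupancy
``F(l) = l / (l + Kd)``, with a dissociation constant that depends on the
receptor's current conformation (active receptors bind attractant more
weakly than inactive ones).

``gamma(m) = max(0, 1 - omega * (m - 2))`` lets the coupling strength fall
off with the neighbor's methylation level; ``omega = 0`` switches the
modulation off and ``gamma(2) = 1`` always, so doubly methylated receptors
couple at full strength.

The vectorized :class:`ReceptorField` is the container the simulation
engine advances; the module-level pure functions give the same arithmetic
for a single receptor and are the unit-test surface.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hexgrid import HexCoord, ReceptorTopology

__all__ = [
    "TAR",
    "TSR",
    "LigandSpec",
    "LigandEnvironment",
    "Receptor",
    "EnergyParams",
    "fractional_occupancy",
    "coupling_weight",
    "activation_probability",
    "ReceptorField",
    "update_field",
    "default_ligands",
]

TAR, TSR = 0, 1
_RTYPE_NAMES = {TAR: "Tar", TSR: "Tsr"}
MAX_METHYLATION = 4

#: MeAsp dissociation constants for Tar (mol/L), conformation dependent.
KD_ACTIVE = 12e-6
KD_INACTIVE = 1.7e-6


@dataclass
class LigandSpec:
    """One attractant species and which receptor types it binds.

    ``multipliers`` maps receptor type (``TAR``/``TSR``) to a dimensionless
    factor >= 1 scaling both dissociation constants for that type; types
    absent from the map do not bind the species at all.  The weak
    cross-recognition of MeAsp by Tsr is expressed as a 1e5 multiplier.
    """

    name: str
    kd_active: float = KD_ACTIVE
    kd_inactive: float = KD_INACTIVE
    multipliers: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kd_active <= 0 or self.kd_inactive <= 0:
            raise ValueError("dissociation constants must be positive")
        for v in self.multipliers.values():
            if v < 1:
                raise ValueError("affinity multipliers must be >= 1")


def default_ligands(cross_binding: bool = False,
                    include_ser: bool = False) -> list[LigandSpec]:
    """The standard attractant set: MeAsp on Tar (optionally also on Tsr at
    1e5-fold weaker affinity) and, if requested, Ser on Tsr."""
    measp_mult = {TAR: 1.0}
    if cross_binding:
        measp_mult[TSR] = 1e5
    out = [LigandSpec("MeAsp", multipliers=measp_mult)]
    if include_ser:
        out.append(LigandSpec("Ser", multipliers={TSR: 1.0}))
    return out


@dataclass
class LigandEnvironment:
    """Spatially uniform bulk attractant concentrations (mol/L)."""

    concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")

    def get(self, name: str) -> float:
        return self.concentrations.get(name, 0.0)

    def set(self, name: str, value: float) -> None:
        if value < 0:
            raise ValueError(f"negative concentration for {name}")
        self.concentrations[name] = value


@dataclass
class Receptor:
    """A single fixed receptor dimer (single-unit view; the engine keeps
    the same state vectorized in :class:`ReceptorField`)."""

    site: HexCoord
    rtype: int = TAR
    m: int = 2
    a: int = 1
    bound_chew: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.m <= MAX_METHYLATION:
            raise ValueError("methylation count must be in 0..4")
        if self.a not in (1, -1):
            raise ValueError("activity state must be +1 or -1")


@dataclass
class EnergyParams:
    """Free-energy coefficients, all in cal/mol except the dimensionless
    ``omega``.

    ``thermal_scale`` divides the free-energy sum inside the logistic.
    On this lattice the physical RT (~600 cal/mol) puts the default
    coupling deep in the all-or-none flipping regime, so the scale is
    treated as the one calibrated parameter: 1070 cal/mol places the
    homogeneous doubly-methylated Tar array at a Hill coefficient near
    10, the experimentally observed lattice gain.
    """

    g0: float = -600.0
    el: float = 2200.0
    em: float = -400.0
    ej: float = -700.0
    omega: float = 0.0
    thermal_scale: float = 1070.0

    def __post_init__(self) -> None:
        if self.thermal_scale <= 0:
            raise ValueError("thermal_scale must be positive")


def fractional_occupancy(l: float, kd: float) -> float:
    """Time-averaged fraction of time a receptor is ligand bound,
    ``l / (l + kd)``; monotone in ``l`` with half-saturation at ``l = kd``."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if l < 0:
        raise ValueError("concentration must be non-negative")
    return l / (l + kd)


def coupling_weight(m_neighbor: int, omega: float) -> float:
    """gamma(m) = max(0, 1 - omega * (m - 2)): the factor by which a
    neighbor at methylation level ``m`` scales the coupling energy."""
    if not 0 <= m_neighbor <= MAX_METHYLATION:
        raise ValueError("methylation count must be in 0..4")
    return max(0.0, 1.0 - omega * (m_neighbor - 2))


def free_energy(receptor: Receptor, occupancy: float,
                neighbor_states: Sequence[tuple[int, int]],
                params: EnergyParams) -> float:
    """dG (cal/mol) of the active state for one receptor.

    ``neighbor_states`` lists ``(a, m)`` pairs of the existing neighbors
    (boundary receptors simply have fewer entries).
    """
    coupling = sum(a_n * coupling_weight(m_n, params.omega)
                   for a_n, m_n in neighbor_states)
    return (params.g0 + params.el * occupancy
            + params.em * (receptor.m - 2) + params.ej * coupling)


def activation_probability(receptor: Receptor, occupancy: float,
                           neighbor_states: Sequence[tuple[int, int]],
                           params: EnergyParams) -> float:
    """Probability that the receptor is active on the next iteration."""
    dg = free_energy(receptor, occupancy, neighbor_states, params)
    return 1.0 / (1.0 + math.exp(dg / params.thermal_scale))


class ReceptorField:
    """Vectorized state of every receptor on a mask.

    Arrays (length ``n``): ``rtype`` (0=Tar, 1=Tsr), ``m`` (0..4), ``a``
    (+1/-1), ``bound_chew`` and ``chew_engaged`` (anchoring bookkeeping for
    the kinase layer), plus a dense ``(n, 4)`` receptor-neighbor index
    table combining intra- and inter-trimer partners (-1 padded).

    Binding is pre-resolved per receptor: ``kd_act``/``kd_inact`` carry the
    conformation-dependent dissociation constants of the one species the
    receptor's type binds (0 if none), and ``lig`` the current bulk
    concentration of that species.
    """

    def __init__(self, topology: ReceptorTopology, rtype: np.ndarray,
                 m_init: np.ndarray):
        n = topology.n_receptors
        if len(rtype) != n or len(m_init) != n:
            raise ValueError("rtype/m arrays must match receptor count")
        self.topology = topology
        self.rtype = np.asarray(rtype, dtype=np.int8)
        self.m = np.asarray(m_init, dtype=np.int8).copy()
        self.a = np.ones(n, dtype=np.int8)
        self.bound_chew = np.zeros(n, dtype=np.int8)
        self.chew_engaged = np.zeros(n, dtype=np.int8)
        self.trimer_id = np.asarray(topology.trimer_id, dtype=np.int32)
        nbr = np.full((n, 4), -1, dtype=np.int32)
        for i in range(n):
            partners = list(topology.intra[i]) + list(topology.inter[i])
            nbr[i, :len(partners)] = partners[:4]
        self.nbr = nbr
        self.kd_act = np.zeros(n, dtype=np.float64)
        self.kd_inact = np.zeros(n, dtype=np.float64)
        self.lig = np.zeros(n, dtype=np.float64)
        self._species_of_type: dict[int, str] = {}
        self._a_buf = np.empty(n, dtype=np.int8)

    @property
    def n(self) -> int:
        return len(self.a)

    def set_binding(self, ligands: Sequence[LigandSpec]) -> None:
        """Resolve which species each receptor binds (at most one per
        receptor type) and fill the per-receptor Kd arrays."""
        self._species_of_type = {}
        self.kd_act[:] = 0.0
        self.kd_inact[:] = 0.0
        for spec in ligands:
            for rt, mult in spec.multipliers.items():
                if rt in self._species_of_type:
                    raise ValueError(
                        f"receptor type {_RTYPE_NAMES[rt]} bound by two "
                        "ligand species; one per type is supported")
                self._species_of_type[rt] = spec.name
                sel = self.rtype == rt
                self.kd_act[sel] = spec.kd_active * mult
                self.kd_inact[sel] = spec.kd_inactive * mult

    def set_environment(self, env: LigandEnvironment) -> None:
        """Refresh the per-receptor bulk concentration from the environment."""
        for rt, name in self._species_of_type.items():
            self.lig[self.rtype == rt] = env.get(name)

    def initialize_activity(self, params: EnergyParams,
                            rng: np.random.Generator) -> None:
        """Draw initial activity from the single-receptor probability with
        no neighbor contribution (relaxation is left to burn-in)."""
        f = np.where(self.kd_act > 0,
                     self.lig / np.where(self.kd_act > 0,
                                         self.lig + self.kd_act, 1.0), 0.0)
        dg = params.g0 + params.el * f + params.em * (self.m - 2.0)
        p = 1.0 / (1.0 + np.exp(dg / params.thermal_scale))
        self.a[:] = np.where(rng.random(self.n) < p, 1, -1).astype(np.int8)

    def update(self, params: EnergyParams, rng: np.random.Generator) -> None:
        """One synchronous activity update (all probabilities computed from
        the previous iteration's states, then independent draws)."""
        from ._kernels import receptor_update
        receptor_update(rng, self.a, self._a_buf, self.m, self.nbr,
                        self.kd_act, self.kd_inact, self.lig,
                        params.g0, params.el, params.em, params.ej,
                        params.omega, params.thermal_scale)

    def mean_activity(self, rtype: int | None = None) -> float:
        """Fraction of receptors active, overall or for one type."""
        sel = slice(None) if rtype is None else self.rtype == rtype
        a = self.a[sel]
        if a.size == 0:
            raise ValueError("no receptors of the requested type")
        return float(np.mean(a == 1))

    def mean_methylation(self) -> float:
        return float(np.mean(self.m))

    def snapshot_csv(self, path) -> None:
        """Dump per-receptor state as CSV (col,row,type,m,a)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["col", "row", "receptor_type", "m", "a"])
            for i, (c, r) in enumerate(self.topology.sites):
                w.writerow([c, r, _RTYPE_NAMES[int(self.rtype[i])],
                            int(self.m[i]), int(self.a[i])])


def update_field(field_: ReceptorField, env: LigandEnvironment,
                 params: EnergyParams, rng: np.random.Generator) -> None:
    """Synchronous stochastic update of a whole field under ``env``."""
    field_.set_environment(env)
    field_.update(params, rng)
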