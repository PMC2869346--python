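"""Mobile cytoplasmic signaling proteins and their stochastic reaction rules.

The cytoplasmic side of the pathway is a population of mobile agents —
CheA, CheW, CheY, CheB, CheZ, CheR — that random-walk over the lattice
foreground (one agent per cell) and react stochastically:

* CheW can bind a receptor (and leaves the foreground, becoming part of
  the fixed background); CheA can complex with up to two CheW.
* A CheA anchors only at a *bridge site* — a cell contacting receptors of
  two distinct trimers — by engaging receptor-bound CheW, forming the
  CheW-CheA-CheW bridges through which receptor state reaches the kinase.
* An anchored CheA autophosphorylates with probability
  ``alpha + beta * lambda`` where ``lambda`` (0, 1 or 2) counts its
  attached receptors currently active; free CheA has ``alpha = 0`` and
  never fires.
* Phosphoryl groups move CheA_p -> CheY / CheB by strict transfer (never
  duplication) when the acceptor stands on the anchored kinase's cell;
  CheZ dephosphorylates adjacent CheY_p; CheY_p / CheB_p also decay
  spontaneously.
* CheR methylates a co-located receptor unconditionally; CheB_p
  demethylates one only in the active conformation — the feedback that
  produces adaptation.

Every rule is an independent Bernoulli draw per opportunity, with the
default probabilities in :class:`ReactionTable`.  The functions here give
the single-agent semantics used by the unit tests; the engine executes the
identical rules over arrays in :mod:`hextaxis._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from . import _kernels as K
from .hexgrid import Grid, HexCoord, ReceptorTopology, neighbors
from .receptor_field import MAX_METHYLATION, Receptor

__all__ = [
    "CHEA", "CHEW", "CHEY", "CHEB", "CHEZ", "CHER",
    "KIND_NAMES",
    "SolubleAgent",
    "ReactionTable",
    "random_walk_step",
    "attempt_complex_formation",
    "attempt_receptor_anchoring",
    "cheA_autophosphorylation",
    "phosphotransfer",
    "methylation_reactions",
    "dephosphorylation_reactions",
]

CHEA, CHEW, CHEY, CHEB, CHEZ, CHER = K.KA, K.KW, K.KY, K.KB, K.KZ, K.KR
KIND_NAMES = {CHEA: "CheA", CHEW: "CheW", CHEY: "CheY",
              CHEB: "CheB", CHEZ: "CheZ", CHER: "CheR"}


@dataclass
class SolubleAgent:
    """One mobile protein (or CheA·CheW complex).

    ``n_chew`` counts CheW units carried by a CheA complex;
    ``attached_receptors`` lists the receptors an anchored CheA reaches
    through receptor-bound CheW (at most two, from distinct trimers).
    """

    kind: int
    position: HexCoord
    phosphorylated: bool = False
    anchored: bool = False
    n_chew: int = 0
    attached_receptors: list[int] = field(default_factory=list)

    @property
    def total_chew(self) -> int:
        """CheW units associated with a CheA: carried plus engaged."""
        return self.n_chew + len(self.attached_receptors)


@dataclass
class ReactionTable:
    """Per-iteration reaction probabilities (defaults as used throughout)."""

    chew_chea: float = 0.01          # CheW + CheA -> CheW-CheA
    receptor_chew: float = 0.001     # Receptor + CheW -> Receptor-CheW
    cheaw_chew: float = 1.0          # CheW-CheA + CheW -> CheW-CheA-CheW
    alpha_chea: float = 0.0          # base CheA autophosphorylation
    beta: float = 0.03               # per attached active receptor
    chea_cheb: float = 0.25          # CheA_p + CheB -> CheA + CheB_p
    chea_chey: float = 1.0           # CheA_p + CheY -> CheA + CheY_p
    cher_methylation: float = 0.05
    cheb_demethylation: float = 0.15
    chey_chez: float = 0.2           # CheY_p + CheZ -> CheY + CheZ
    cheb_autodephos: float = 0.005
    chey_autodephos: float = 0.0001

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be a probability, got {v}")

    def as_vector(self) -> np.ndarray:
        """Pack into the 12-slot layout the kernels consume."""
        v = np.empty(K.N_PROBS, dtype=np.float64)
        v[K.P_CHEW_CHEA] = self.chew_chea
        v[K.P_RECEPTOR_CHEW] = self.receptor_chew
        v[K.P_CHEAW_CHEW] = self.cheaw_chew
        v[K.P_ALPHA] = self.alpha_chea
        v[K.P_BETA] = self.beta
        v[K.P_CHEA_CHEB] = self.chea_cheb
        v[K.P_CHEA_CHEY] = self.chea_chey
        v[K.P_CHER_METH] = self.cher_methylation
        v[K.P_CHEB_DEMETH] = self.cheb_demethylation
        v[K.P_CHEY_CHEZ] = self.chey_chez
        v[K.P_CHEB_AUTO] = self.cheb_autodephos
        v[K.P_CHEY_AUTO] = self.chey_autodephos
        return v


def random_walk_step(agent: SolubleAgent, grid: Grid,
                     rng: np.random.Generator) -> HexCoord:
    """One unbiased random-walk step with foreground exclusion.

    A target is drawn uniformly from the in-bounds neighbors; the move
    happens only if that cell's foreground is free, otherwise the agent
    stays put.  Returns the (possibly unchanged) position.
    """
    if agent.anchored:
        return agent.position
    nbrs = neighbors(agent.position, grid)
    if not nbrs:
        return agent.position
    target = nbrs[rng.integers(0, len(nbrs))]
    if grid.foreground_free(target):
        grid.foreground.pop(agent.position, None)
        grid.foreground[target] = id(agent)
        agent.position = target
    return agent.position


def attempt_complex_formation(a: SolubleAgent, b: SolubleAgent,
                              table: ReactionTable,
                              rng: np.random.Generator) -> SolubleAgent | None:
    """CheA + mobile CheW -> CheA·CheW complex (or second CheW joins).

    On success the CheW is consumed and the complex sits at the CheA's
    cell.  Returns the complex agent, or None if nothing happened.
    """
    chea, chew = (a, b) if a.kind == CHEA else (b, a)
    if chea.kind != CHEA or chew.kind != CHEW:
        return None
    if chea.total_chew >= 2:
        return None
    p = table.chew_chea if chea.total_chew == 0 else table.cheaw_chew
    if rng.random() < p:
        chea.n_chew += 1
        return chea
    return None


def attempt_receptor_anchoring(agent: SolubleAgent,
                               receptor: Receptor | int,
                               topology: ReceptorTopology,
                               table: ReactionTable,
                               rng: np.random.Generator,
                               receptors: list[Receptor] | None = None,
                               bridge_cell: HexCoord | None = None) -> bool:
    """Anchoring of CheW to a receptor, or of CheA at a bridge site.

    For a CheW agent: binds an adjacent (or co-located) receptor with a
    free slot at probability ``receptor_chew``; the CheW leaves the
    foreground (``anchored`` set, position dropped into the receptor).

    For a CheA agent standing on a bridge cell: engages a receptor-bound
    CheW of one flanking receptor (probability ``chew_chea`` for a bare
    CheA, ``cheaw_chew`` once it carries a CheW), becomes fixed background
    at the bridge cell, and immediately tries to engage the second
    flanking receptor from the other trimer.
    """
    if agent.kind == CHEW:
        rec = receptor
        assert isinstance(rec, Receptor)
        if rec.bound_chew >= 2:
            return False
        if rng.random() < table.receptor_chew:
            rec.bound_chew += 1
            agent.anchored = True
            return True
        return False

    if agent.kind != CHEA or agent.anchored or agent.total_chew >= 2:
        return False
    assert receptors is not None and bridge_cell is not None
    try:
        bidx = topology.bridge_sites.index(bridge_cell)
    except ValueError:
        return False  # not a bridge site: anchoring is impossible there
    candidates = [
        r for r in topology.bridge_receptors[bidx]
        if receptors[r].bound_chew - _engaged(receptors[r]) > 0
    ]
    if not candidates:
        return False
    p = table.chew_chea if agent.total_chew == 0 else table.cheaw_chew
    if rng.random() >= p:
        return False
    first = candidates[0]
    agent.anchored = True
    agent.position = bridge_cell
    agent.attached_receptors.append(first)
    t1 = topology.trimer_id[first]
    if agent.total_chew < 2:
        for r2 in candidates[1:]:
            if topology.trimer_id[r2] != t1:
                if rng.random() < table.cheaw_chew:
                    agent.attached_receptors.append(r2)
                break
    return True


def _engaged(receptor: Receptor) -> int:
    # single-agent view has no global engagement registry; the engine
    # tracks engagement per receptor in its own arrays
    return getattr(receptor, "chew_engaged", 0)


def cheA_autophosphorylation(agent: SolubleAgent, table: ReactionTable,
                             rng: np.random.Generator,
                             receptors: list[Receptor] | None = None) -> bool:
    """Autophosphorylation draw: probability ``alpha + beta * lambda`` with
    ``lambda`` the number of attached receptors currently active."""
    if agent.kind != CHEA or agent.phosphorylated:
        return False
    lam = 0
    if receptors is not None:
        lam = sum(1 for r in agent.attached_receptors
                  if receptors[r].a == 1)
    p = table.alpha_chea + table.beta * lam
    if p > 0 and rng.random() < p:
        agent.phosphorylated = True
        return True
    return False


def phosphotransfer(donor: SolubleAgent, acceptor: SolubleAgent,
                    table: ReactionTable, rng: np.random.Generator) -> bool:
    """Strict phosphoryl transfer CheA_p -> CheY/CheB (never duplication)."""
    if donor.kind != CHEA or not donor.phosphorylated:
        return False
    if acceptor.kind not in (CHEY, CHEB) or acceptor.phosphorylated:
        return False
    p = table.chea_chey if acceptor.kind == CHEY else table.chea_cheb
    if rng.random() < p:
        donor.phosphorylated = False
        acceptor.phosphorylated = True
        return True
    return False


def methylation_reactions(enzyme: SolubleAgent, receptor: Receptor,
                          table: ReactionTable,
                          rng: np.random.Generator) -> int:
    """CheR methylation / CheB_p demethylation of a co-located receptor.

    Returns the change in methylation count (-1, 0 or +1).  CheR acts on
    any receptor (clamped at 4 methyl groups); CheB must be phosphorylated
    and the receptor active (clamped at 0).
    """
    if enzyme.kind == CHER:
        if rng.random() < table.cher_methylation:
            if receptor.m < MAX_METHYLATION:
                receptor.m += 1
                return 1
        return 0
    if enzyme.kind == CHEB:
        if not enzyme.phosphorylated or receptor.a != 1:
            return 0
        if rng.random() < table.cheb_demethylation:
            if receptor.m > 0:
                receptor.m -= 1
                return -1
        return 0
    return 0


def dephosphorylation_reactions(agent: SolubleAgent,
                                partner: SolubleAgent | None,
                                table: ReactionTable,
                                rng: np.random.Generator) -> bool:
    """CheZ-catalyzed dephosphorylation of an adjacent CheY_p, or the
    spontaneous decay of CheY_p / CheB_p.  Returns True if a phosphoryl
    group was lost."""
    if agent.kind == CHEZ:
        if partner is None or partner.kind != CHEY or not partner.phosphorylated:
            return False
        if rng.random() < table.chey_chez:
            partner.phosphorylated = False
            return True
        return False
    if agent.phosphorylated and agent.kind in (CHEY, CHEB):
        p = (table.chey_autodephos if agent.kind == CHEY
             else table.cheb_autodephos)
        if rng.random() < p:
            agent.phosphorylated = False
            return True
    return False
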