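"""Single-agent reaction rules: walks, assembly, phosphoryl and methyl flow."""

import numpy as np
import pytest

from hextaxis.hexgrid import Grid, build_receptor_mask, neighbors
from hextaxis.receptor_field import Receptor
from hextaxis.soluble_agents import (CHEA, CHEB, CHER, CHEW, CHEY, CHEZ,
                                     ReactionTable, SolubleAgent,
                                     attempt_complex_formation,
                                     attempt_receptor_anchoring,
                                     cheA_autophosphorylation,
                                     dephosphorylation_reactions,
                                     methylation_reactions, phosphotransfer,
                                     random_walk_step)


@pytest.fixture
def table():
    return ReactionTable()


@pytest.fixture
def certain():
    """All bimolecular probabilities forced to 1 for deterministic checks."""
    return ReactionTable(chew_chea=1.0, receptor_chew=1.0, chea_cheb=1.0,
                        cher_methylation=1.0, cheb_demethylation=1.0,
                        chey_chez=1.0, cheb_autodephos=1.0,
                        chey_autodephos=1.0)


class TestReactionTable:
    def test_defaults_are_printed_values(self, table):
        assert table.chew_chea == 0.01
        assert table.receptor_chew == 0.001
        assert table.cheaw_chew == 1.0
        assert table.alpha_chea == 0.0
        assert table.beta == 0.03
        assert table.chea_cheb == 0.25
        assert table.chea_chey == 1.0
        assert table.cher_methylation == 0.05
        assert table.cheb_demethylation == 0.15
        assert table.chey_chez == 0.2
        assert table.cheb_autodephos == 0.005
        assert table.chey_autodephos == 0.0001

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            ReactionTable(beta=1.5)
        with pytest.raises(ValueError):
            ReactionTable(chey_chez=-0.1)

    def test_vector_roundtrip(self, table):
        v = table.as_vector()
        assert v.shape == (12,)
        assert v.min() >= 0 and v.max() <= 1


class TestRandomWalk:
    def test_surrounded_agent_stays(self):
        grid = Grid(5, 5)
        agent = SolubleAgent(CHEY, (2, 2))
        grid.foreground[(2, 2)] = id(agent)
        for n in neighbors((2, 2), grid):
            grid.foreground[n] = 999
        assert random_walk_step(agent, grid, np.random.default_rng(0)) == (2, 2)

    def test_moves_uniformly_to_free_neighbors(self):
        grid = Grid(9, 9)
        rng = np.random.default_rng(1)
        counts: dict = {}
        for _ in range(3000):
            agent = SolubleAgent(CHEY, (4, 4))
            grid.foreground = {(4, 4): id(agent)}
            pos = random_walk_step(agent, grid, rng)
            counts[pos] = counts.get(pos, 0) + 1
        assert set(counts) == set(neighbors((4, 4), Grid(9, 9)))
        freqs = np.array(list(counts.values())) / 3000
        assert np.all(np.abs(freqs - 1 / 6) < 0.03)

    def test_anchored_agent_never_moves(self):
        grid = Grid(5, 5)
        agent = SolubleAgent(CHEA, (2, 2), anchored=True)
        for _ in range(20):
            assert random_walk_step(agent, grid,
                                    np.random.default_rng(0)) == (2, 2)


class TestComplexFormation:
    def test_chea_chew_merge(self, certain):
        a = SolubleAgent(CHEA, (0, 0))
        w = SolubleAgent(CHEW, (1, 0))
        merged = attempt_complex_formation(a, w, certain,
                                           np.random.default_rng(0))
        assert merged is a
        assert a.n_chew == 1

    def test_second_chew_joins_at_probability_one(self, table):
        # the CheW-CheA + CheW reaction is certain even in the default table
        a = SolubleAgent(CHEA, (0, 0), n_chew=1)
        w = SolubleAgent(CHEW, (1, 0))
        assert attempt_complex_formation(a, w, table,
                                         np.random.default_rng(0)) is a
        assert a.n_chew == 2

    def test_saturated_complex_rejects_third(self, certain):
        a = SolubleAgent(CHEA, (0, 0), n_chew=2)
        w = SolubleAgent(CHEW, (1, 0))
        assert attempt_complex_formation(a, w, certain,
                                         np.random.default_rng(0)) is None
        assert a.n_chew == 2

    def test_incompatible_kinds_noop(self, certain):
        y = SolubleAgent(CHEY, (0, 0))
        z = SolubleAgent(CHEZ, (1, 0))
        assert attempt_complex_formation(y, z, certain,
                                         np.random.default_rng(0)) is None

    def test_default_rate_statistics(self, table):
        rng = np.random.default_rng(3)
        hits = sum(
            attempt_complex_formation(SolubleAgent(CHEA, (0, 0)),
                                      SolubleAgent(CHEW, (1, 0)),
                                      table, rng) is not None
            for _ in range(20000))
        assert hits / 20000 == pytest.approx(0.01, abs=0.003)


class TestReceptorAnchoring:
    def test_chew_binds_receptor(self, certain):
        rec = Receptor((1, 1))
        w = SolubleAgent(CHEW, (1, 0))
        topo = build_receptor_mask(8, 6, 8, 6)
        ok = attempt_receptor_anchoring(w, rec, topo, certain,
                                        np.random.default_rng(0))
        assert ok and rec.bound_chew == 1 and w.anchored

    def test_full_slots_reject_chew(self, certain):
        rec = Receptor((1, 1), bound_chew=2)
        w = SolubleAgent(CHEW, (1, 0))
        topo = build_receptor_mask(8, 6, 8, 6)
        assert not attempt_receptor_anchoring(w, rec, topo, certain,
                                              np.random.default_rng(0))

    def test_chea_bridges_two_trimers(self, certain):
        topo = build_receptor_mask(8, 6, 8, 6)
        receptors = [Receptor(s, bound_chew=1) for s in topo.sites]
        bridge = topo.bridge_sites[0]
        a = SolubleAgent(CHEA, bridge)
        ok = attempt_receptor_anchoring(a, None, topo, certain,
                                        np.random.default_rng(0),
                                        receptors=receptors,
                                        bridge_cell=bridge)
        assert ok and a.anchored
        assert len(a.attached_receptors) == 2
        t = {topo.trimer_id[r] for r in a.attached_receptors}
        assert len(t) == 2

    def test_non_bridge_cell_rejects_chea(self, certain):
        topo = build_receptor_mask(8, 6, 8, 6)
        receptors = [Receptor(s, bound_chew=1) for s in topo.sites]
        a = SolubleAgent(CHEA, (7, 5))
        assert not attempt_receptor_anchoring(a, None, topo, certain,
                                              np.random.default_rng(0),
                                              receptors=receptors,
                                              bridge_cell=(7, 5))

    def test_no_bound_chew_no_anchoring(self, certain):
        topo = build_receptor_mask(8, 6, 8, 6)
        receptors = [Receptor(s) for s in topo.sites]  # no CheW anywhere
        bridge = topo.bridge_sites[0]
        a = SolubleAgent(CHEA, bridge)
        assert not attempt_receptor_anchoring(a, None, topo, certain,
                                              np.random.default_rng(0),
                                              receptors=receptors,
                                              bridge_cell=bridge)


class TestAutophosphorylation:
    def test_free_chea_never_fires(self, table):
        a = SolubleAgent(CHEA, (0, 0))
        rng = np.random.default_rng(0)
        assert not any(cheA_autophosphorylation(a, table, rng, receptors=[])
                       for _ in range(5000))

    def test_two_active_receptors_rate(self, table):
        # alpha + beta*lambda = 0 + 0.03*2 = 0.06
        receptors = [Receptor((0, 0), a=1), Receptor((1, 0), a=1)]
        rng = np.random.default_rng(2)
        n, hits = 20000, 0
        for _ in range(n):
            a = SolubleAgent(CHEA, (0, 0), anchored=True,
                             attached_receptors=[0, 1])
            hits += cheA_autophosphorylation(a, table, rng,
                                             receptors=receptors)
        assert hits / n == pytest.approx(0.06, abs=0.006)

    def test_inactive_receptors_zero_rate(self, table):
        receptors = [Receptor((0, 0), a=-1), Receptor((1, 0), a=-1)]
        a = SolubleAgent(CHEA, (0, 0), anchored=True,
                         attached_receptors=[0, 1])
        rng = np.random.default_rng(0)
        assert not any(cheA_autophosphorylation(a, table, rng,
                                                receptors=receptors)
                       for _ in range(5000))


class TestPhosphotransfer:
    def test_chey_transfer_certain(self, table):
        donor = SolubleAgent(CHEA, (0, 0), phosphorylated=True)
        acc = SolubleAgent(CHEY, (0, 0))
        assert phosphotransfer(donor, acc, table, np.random.default_rng(0))
        assert not donor.phosphorylated and acc.phosphorylated

    def test_occupied_acceptor_noop(self, table):
        donor = SolubleAgent(CHEA, (0, 0), phosphorylated=True)
        acc = SolubleAgent(CHEB, (0, 0), phosphorylated=True)
        assert not phosphotransfer(donor, acc, table,
                                   np.random.default_rng(0))
        assert donor.phosphorylated

    def test_unphosphorylated_donor_noop(self, table):
        donor = SolubleAgent(CHEA, (0, 0))
        acc = SolubleAgent(CHEY, (0, 0))
        assert not phosphotransfer(donor, acc, table,
                                   np.random.default_rng(0))
        assert not acc.phosphorylated

    def test_cheb_rate(self, table):
        rng = np.random.default_rng(4)
        n, hits = 20000, 0
        for _ in range(n):
            donor = SolubleAgent(CHEA, (0, 0), phosphorylated=True)
            hits += phosphotransfer(donor, SolubleAgent(CHEB, (0, 0)),
                                    table, rng)
        assert hits / n == pytest.approx(0.25, abs=0.02)


class TestMethylation:
    def test_cher_ceiling_clamp(self, certain):
        rec = Receptor((0, 0), m=4)
        r = SolubleAgent(CHER, (0, 0))
        assert methylation_reactions(r, rec, certain,
                                     np.random.default_rng(0)) == 0
        assert rec.m == 4

    def test_cher_methylates_any_state(self, certain):
        for a in (1, -1):
            rec = Receptor((0, 0), m=2, a=a)
            r = SolubleAgent(CHER, (0, 0))
            assert methylation_reactions(r, rec, certain,
                                         np.random.default_rng(0)) == 1

    def test_cheb_requires_phosphorylation_and_active_receptor(self, certain):
        rng = np.random.default_rng(0)
        rec = Receptor((0, 0), m=2, a=-1)
        bp = SolubleAgent(CHEB, (0, 0), phosphorylated=True)
        assert methylation_reactions(bp, rec, certain, rng) == 0
        b = SolubleAgent(CHEB, (0, 0))
        rec.a = 1
        assert methylation_reactions(b, rec, certain, rng) == 0
        assert methylation_reactions(bp, rec, certain, rng) == -1
        assert rec.m == 1

    def test_demethylation_floor_clamp(self, certain):
        rec = Receptor((0, 0), m=0, a=1)
        bp = SolubleAgent(CHEB, (0, 0), phosphorylated=True)
        assert methylation_reactions(bp, rec, certain,
                                     np.random.default_rng(0)) == 0
        assert rec.m == 0


class TestDephosphorylation:
    def test_chez_dephosphorylates_adjacent_cheyp(self, certain):
        z = SolubleAgent(CHEZ, (0, 0))
        yp = SolubleAgent(CHEY, (1, 0), phosphorylated=True)
        assert dephosphorylation_reactions(z, yp, certain,
                                           np.random.default_rng(0))
        assert not yp.phosphorylated

    def test_chez_ignores_unphosphorylated(self, certain):
        z = SolubleAgent(CHEZ, (0, 0))
        y = SolubleAgent(CHEY, (1, 0))
        assert not dephosphorylation_reactions(z, y, certain,
                                               np.random.default_rng(0))

    def test_geometric_lifetime(self):
        # lifetime of a phosphorylated CheY under pure auto-decay is
        # geometric with mean 1/p
        table = ReactionTable(chey_autodephos=0.01)
        rng = np.random.default_rng(9)
        lifetimes = []
        for _ in range(400):
            y = SolubleAgent(CHEY, (0, 0), phosphorylated=True)
            t = 0
            while y.phosphorylated:
                t += 1
                dephosphorylation_reactions(y, None, table, rng)
            lifetimes.append(t)
        mean = np.mean(lifetimes)
        se = 100 / np.sqrt(400)
        assert abs(mean - 100) < 4 * se
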