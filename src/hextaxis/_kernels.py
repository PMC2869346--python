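"""Numba kernels for the simulation hot path.

The per-iteration work — the synchronous receptor update and the shuffled
mobile-agent sweep — runs inside ``@njit`` functions over flat numpy
arrays so that full-pathway runs of several hundred thousand iterations
stay in the minutes range on one core.  All randomness flows through a
single ``numpy.random.Generator`` passed in from the engine, which keeps
runs bit-reproducible for a fixed seed.

Array conventions
-----------------
Cells are indexed ``col * rows + row``.  ``fg[cell]`` holds the mobile
agent occupying the cell's foreground (-1 if free); ``bg_receptor`` /
``bg_chea`` hold the fixed receptor / anchored-CheA occupant of the
background.  Agent state is a struct-of-arrays: ``kind`` (0=CheA, 1=CheW,
2=CheY, 3=CheB, 4=CheZ, 5=CheR), ``ncw`` (CheW units carried by a CheA
complex), ``phos``, ``cell``, ``alive``, ``anchored`` and the attached
receptor indices ``att1``/``att2`` of anchored CheA.

Reaction probabilities are passed as a 12-slot vector (see the ``P_*``
constants); stochastic event tallies are accumulated in an 8-slot
``events`` vector (see ``E_*``) for conservation audits.
"""

import numpy as np
from numba import njit

# agent kinds
KA, KW, KY, KB, KZ, KR = 0, 1, 2, 3, 4, 5

# probability vector slots
P_CHEW_CHEA = 0     # CheW + CheA -> CheW-CheA
P_RECEPTOR_CHEW = 1  # Receptor + CheW -> Receptor-CheW
P_CHEAW_CHEW = 2    # CheW-CheA + CheW -> CheW-CheA-CheW
P_ALPHA = 3         # CheA base autophosphorylation chance
P_BETA = 4          # per attached active receptor
P_CHEA_CHEB = 5     # CheA_p + CheB -> CheA + CheB_p
P_CHEA_CHEY = 6     # CheA_p + CheY -> CheA + CheY_p
P_CHER_METH = 7     # CheR methylation
P_CHEB_DEMETH = 8   # CheB_p demethylation (active receptor only)
P_CHEY_CHEZ = 9     # CheY_p + CheZ -> CheY + CheZ
P_CHEB_AUTO = 10    # CheB_p auto-dephosphorylation
P_CHEY_AUTO = 11    # CheY_p auto-dephosphorylation
N_PROBS = 12

# event tally slots
E_AUTOPHOS = 0
E_PT_Y = 1
E_PT_B = 2
E_CHEZ = 3
E_AUTO_Y = 4
E_AUTO_B = 5
E_METH = 6
E_DEMETH = 7
N_EVENTS = 8

# candidate reaction codes (internal to the agent sweep)
_R_ANCHOR = 0
_R_COMPLEX = 1
_R_BINDW = 2
_R_PT = 3
_R_METH = 4
_R_DEMETH = 5
_R_CHEZ = 6

MAX_M = 4


@njit(cache=True)
def receptor_update(rng, a, a_buf, m, nbr, kd_act, kd_inact, lig,
                    g0, el, em, ej, omega, tscale):
    """Synchronous stochastic activity update of the whole receptor field.

    Probabilities are computed from the previous iteration's activities
    (and the previous state picks the conformation-dependent Kd), then
    every receptor draws independently.
    """
    n = a.shape[0]
    for i in range(n):
        f = 0.0
        if kd_act[i] > 0.0:
            kd = kd_act[i] if a[i] == 1 else kd_inact[i]
            f = lig[i] / (lig[i] + kd)
        s = 0.0
        for k in range(nbr.shape[1]):
            j = nbr[i, k]
            if j >= 0:
                g = 1.0 - omega * (m[j] - 2.0)
                if g < 0.0:
                    g = 0.0
                s += g * a[j]
        dg = g0 + el * f + em * (m[i] - 2.0) + ej * s
        p = 1.0 / (1.0 + np.exp(dg / tscale))
        a_buf[i] = 1 if rng.random() < p else -1
    for i in range(n):
        a[i] = a_buf[i]


@njit(cache=True)
def _try_second_engagement(i, rng, cellA, ncw, att1, att2, bridge_recs,
                           trimer_id, bound_chew, chew_engaged, probs):
    """Anchored CheA with one attachment and a free slot tries to engage a
    receptor-bound CheW on a receptor from a *different* trimer."""
    if att2[i] >= 0 or ncw[i] + 1 >= 2:
        return
    c = cellA[i]
    t1 = trimer_id[att1[i]]
    for k in range(bridge_recs.shape[1]):
        r2 = bridge_recs[c, k]
        if r2 < 0:
            break
        if r2 == att1[i] or trimer_id[r2] == t1:
            continue
        if bound_chew[r2] - chew_engaged[r2] > 0:
            if rng.random() < probs[P_CHEAW_CHEW]:
                att2[i] = r2
                chew_engaged[r2] += 1
            return


@njit(cache=True)
def agent_pass(rng, order, kind, ncw, phos, cellA, alive, anchored,
               att1, att2, fg, bg_receptor, bg_chea, nbr6, nvalid,
               bridge_ok, bridge_recs, trimer_id, bound_chew, chew_engaged,
               rec_a, rec_m, probs, events):
    """One full soluble-agent iteration: shuffled move-and-react sweep over
    mobile agents, then the unimolecular phase (anchored-CheA engagement
    and autophosphorylation, auto-dephosphorylation)."""
    n_agents = kind.shape[0]

    # --- shuffled order of live mobile agents ------------------------------
    n_ord = 0
    for i in range(n_agents):
        if alive[i] == 1 and anchored[i] == 0:
            order[n_ord] = i
            n_ord += 1
    for t in range(n_ord - 1, 0, -1):
        j = rng.integers(0, t + 1)
        tmp = order[t]
        order[t] = order[j]
        order[j] = tmp

    cand_code = np.empty(16, np.int32)
    cand_target = np.empty(16, np.int32)

    for oi in range(n_ord):
        i = order[oi]
        if alive[i] == 0 or anchored[i] == 1:
            continue  # consumed or anchored earlier in this sweep
        c = cellA[i]

        # --- random-walk step: uniform over existing neighbors, blocked if
        # the target foreground is occupied -------------------------------
        nv = nvalid[c]
        if nv > 0:
            nb = nbr6[c, rng.integers(0, nv)]
            if fg[nb] < 0:
                fg[c] = -1
                fg[nb] = i
                cellA[i] = nb
                c = nb

        # --- gather eligible bimolecular reactions ------------------------
        nc = 0
        k = kind[i]
        if k == KA:
            if ncw[i] < 2:
                if bridge_ok[c] == 1 and bg_chea[c] < 0:
                    for q in range(bridge_recs.shape[1]):
                        r = bridge_recs[c, q]
                        if r < 0:
                            break
                        if bound_chew[r] - chew_engaged[r] > 0:
                            cand_code[nc] = _R_ANCHOR
                            cand_target[nc] = r
                            nc += 1
                for q in range(nvalid[c]):
                    j = fg[nbr6[c, q]]
                    if j >= 0 and kind[j] == KW:
                        cand_code[nc] = _R_COMPLEX
                        cand_target[nc] = j
                        nc += 1
        elif k == KW:
            r = bg_receptor[c]
            if r >= 0 and bound_chew[r] < 2:
                cand_code[nc] = _R_BINDW
                cand_target[nc] = r
                nc += 1
            for q in range(nvalid[c]):
                r = bg_receptor[nbr6[c, q]]
                if r >= 0 and bound_chew[r] < 2:
                    cand_code[nc] = _R_BINDW
                    cand_target[nc] = r
                    nc += 1
        elif k == KY:
            if phos[i] == 0:
                j = bg_chea[c]
                if j >= 0 and phos[j] == 1:
                    cand_code[nc] = _R_PT
                    cand_target[nc] = j
                    nc += 1
        elif k == KB:
            if phos[i] == 0:
                j = bg_chea[c]
                if j >= 0 and phos[j] == 1:
                    cand_code[nc] = _R_PT
                    cand_target[nc] = j
                    nc += 1
            else:
                r = bg_receptor[c]
                if r >= 0 and rec_a[r] == 1:
                    cand_code[nc] = _R_DEMETH
                    cand_target[nc] = r
                    nc += 1
        elif k == KZ:
            for q in range(nvalid[c]):
                j = fg[nbr6[c, q]]
                if j >= 0 and kind[j] == KY and phos[j] == 1:
                    cand_code[nc] = _R_CHEZ
                    cand_target[nc] = j
                    nc += 1
        elif k == KR:
            r = bg_receptor[c]
            if r >= 0:
                cand_code[nc] = _R_METH
                cand_target[nc] = r
                nc += 1

        if nc == 0:
            continue
        # at most one reaction attempt per agent per iteration; among the
        # eligible partners one is chosen uniformly at random
        pick = rng.integers(0, nc) if nc > 1 else 0
        code = cand_code[pick]
        tgt = cand_target[pick]
        u = rng.random()

        if code == _R_ANCHOR:
            p = probs[P_CHEW_CHEA] if ncw[i] == 0 else probs[P_CHEAW_CHEW]
            if u < p:
                anchored[i] = 1
                fg[c] = -1
                bg_chea[c] = i
                att1[i] = tgt
                chew_engaged[tgt] += 1
                _try_second_engagement(i, rng, cellA, ncw, att1, att2,
                                       bridge_recs, trimer_id, bound_chew,
                                       chew_engaged, probs)
        elif code == _R_COMPLEX:
            p = probs[P_CHEW_CHEA] if ncw[i] == 0 else probs[P_CHEAW_CHEW]
            if u < p:
                ncw[i] += 1
                alive[tgt] = 0
                fg[cellA[tgt]] = -1
                cellA[tgt] = -1
        elif code == _R_BINDW:
            if u < probs[P_RECEPTOR_CHEW]:
                bound_chew[tgt] += 1
                alive[i] = 0
                fg[c] = -1
                cellA[i] = -1
        elif code == _R_PT:
            p = probs[P_CHEA_CHEY] if kind[i] == KY else probs[P_CHEA_CHEB]
            if u < p:
                phos[tgt] = 0
                phos[i] = 1
                if kind[i] == KY:
                    events[E_PT_Y] += 1
                else:
                    events[E_PT_B] += 1
        elif code == _R_METH:
            if u < probs[P_CHER_METH]:
                if rec_m[tgt] < MAX_M:
                    rec_m[tgt] += 1
                    events[E_METH] += 1
        elif code == _R_DEMETH:
            if u < probs[P_CHEB_DEMETH]:
                if rec_m[tgt] > 0:
                    rec_m[tgt] -= 1
                    events[E_DEMETH] += 1
        elif code == _R_CHEZ:
            if u < probs[P_CHEY_CHEZ]:
                phos[tgt] = 0
                events[E_CHEZ] += 1

    # --- unimolecular phase ------------------------------------------------
    for i in range(n_agents):
        if alive[i] == 0:
            continue
        k = kind[i]
        if k == KA:
            if anchored[i] == 1:
                _try_second_engagement(i, rng, cellA, ncw, att1, att2,
                                       bridge_recs, trimer_id, bound_chew,
                                       chew_engaged, probs)
            if phos[i] == 0:
                lam = 0
                if att1[i] >= 0 and rec_a[att1[i]] == 1:
                    lam += 1
                if att2[i] >= 0 and rec_a[att2[i]] == 1:
                    lam += 1
                p = probs[P_ALPHA] + probs[P_BETA] * lam
                if p > 0.0 and rng.random() < p:
                    phos[i] = 1
                    events[E_AUTOPHOS] += 1
        elif k == KY:
            if phos[i] == 1 and probs[P_CHEY_AUTO] > 0.0:
                if rng.random() < probs[P_CHEY_AUTO]:
                    phos[i] = 0
                    events[E_AUTO_Y] += 1
        elif k == KB:
            if phos[i] == 1 and probs[P_CHEB_AUTO] > 0.0:
                if rng.random() < probs[P_CHEB_AUTO]:
                    phos[i] = 0
                    events[E_AUTO_B] += 1


@njit(cache=True)
def measure(rec_a, rec_m, rtype, kind, phos, alive):
    """(fraction active: total / Tar / Tsr, mean methylation, fraction
    CheA phosphorylated, fraction CheY phosphorylated)."""
    n = rec_a.shape[0]
    act = act_tar = act_tsr = n_tar = 0
    msum = 0.0
    for i in range(n):
        if rtype[i] == 0:
            n_tar += 1
        if rec_a[i] == 1:
            act += 1
            if rtype[i] == 0:
                act_tar += 1
            else:
                act_tsr += 1
        msum += rec_m[i]
    fa = act / n if n > 0 else 0.0
    fa_tar = act_tar / n_tar if n_tar > 0 else 0.0
    n_tsr = n - n_tar
    fa_tsr = act_tsr / n_tsr if n_tsr > 0 else 0.0
    mm = msum / n if n > 0 else 0.0
    na = ny = pa = py = 0
    for i in range(kind.shape[0]):
        if alive[i] == 0:
            continue
        if kind[i] == KA:
            na += 1
            if phos[i] == 1:
                pa += 1
        elif kind[i] == KY:
            ny += 1
            if phos[i] == 1:
                py += 1
    fap = pa / na if na > 0 else 0.0
    fyp = py / ny if ny > 0 else 0.0
    return fa, fa_tar, fa_tsr, mm, fap, fyp


@njit(cache=True)
def run_chunk(rng, n_iters, iter_start, record_every,
              # receptor state
              rec_a, a_buf, rec_m, rtype, nbr4, kd_act, kd_inact, lig,
              g0, el, em, ej, omega, tscale,
              # agent state
              order, kind, ncw, phos, cellA, alive, anchored, att1, att2,
              fg, bg_receptor, bg_chea, nbr6, nvalid,
              bridge_ok, bridge_recs, trimer_id, bound_chew, chew_engaged,
              probs, events,
              # output records
              out_frac_active, out_frac_tar, out_frac_tsr,
              out_mean_m, out_frac_ap, out_frac_yp):
    """Advance the world ``n_iters`` iterations, writing a record into
    slot ``g // record_every`` at every global iteration g that is a
    multiple of ``record_every``."""
    has_agents = kind.shape[0] > 0
    for step in range(n_iters):
        g = iter_start + step + 1
        receptor_update(rng, rec_a, a_buf, rec_m, nbr4, kd_act, kd_inact,
                        lig, g0, el, em, ej, omega, tscale)
        if has_agents:
            agent_pass(rng, order, kind, ncw, phos, cellA, alive, anchored,
                       att1, att2, fg, bg_receptor, bg_chea, nbr6, nvalid,
                       bridge_ok, bridge_recs, trimer_id, bound_chew,
                       chew_engaged, rec_a, rec_m, probs, events)
        if g % record_every == 0:
            ridx = g // record_every
            fa, fat, fas, mm, fap, fyp = measure(rec_a, rec_m, rtype, kind,
                                                 phos, alive)
            out_frac_active[ridx] = fa
            out_frac_tar[ridx] = fat
            out_frac_tsr[ridx] = fas
            out_mean_m[ridx] = mm
            out_frac_ap[ridx] = fap
            out_frac_yp[ridx] = fyp
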