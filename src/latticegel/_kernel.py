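"""Compiled (numba) Monte Carlo kernel for production-scale runs.

Implements the same five moves and Hastings weights as
:class:`latticegel.moves.MoveEngine`, restricted to the default interaction
model (specific S-P binding only, no nonspecific contacts) and, for
reptation, to chains with fully implicit linkers.  It operates in place on
the arrays of a :class:`latticegel.lattice.SystemState`, so observers read
the live state between chunks.  Agreement with the reference engine and the
exact-enumeration oracle is enforced by the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .lattice import SystemState
from .moves import MOVE_TYPES

_OFFS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@njit(cache=True)
def _seed_impl(seed):
    np.random.seed(seed)


def seed_kernel(seed: int) -> None:
    """Seed the kernel's private RNG stream (independent of numpy's)."""
    _seed_impl(int(seed) & 0x7FFFFFFF)


@njit(cache=True, inline="always")
def _site(x, y, z, L):
    return (x * L + y) * L + z


@njit(cache=True, inline="always")
def _mi(d, L):
    return (d + L // 2) % L - L // 2


@njit(cache=True)
def _count_opts(pos, occ, kind, partner, L, dom, x, y, z, opts):
    """Admissible bound states of ``dom`` if it sat at (x, y, z).

    Fills ``opts`` with candidate partner bead ids and returns their count
    (the unbound state adds one more admissible state on top).
    """
    want = 1 - kind[dom]
    nn = 3 if L == 2 else 6
    cnt = 0
    for t in range(nn):
        xx = (x + _OFFS[t, 0]) % L
        yy = (y + _OFFS[t, 1]) % L
        zz = (z + _OFFS[t, 2]) % L
        j = occ[_site(xx, yy, zz, L)]
        if j >= 0 and j != dom and kind[j] == want:
            if partner[j] == -1 or partner[j] == dom:
                opts[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True)
def run_kernel_chunk(
    pos,
    occ,
    kind,
    mol,
    partner,
    mol_start,
    mol_len,
    teth_other,
    teth_cap,
    dom_beads,
    end_beads,
    mid_beads,
    rept_mols,
    rept_cap,
    L,
    u_sp,
    probs,
    n_steps,
    energy,
    att,
    acc,
):
    nn = 3 if L == 2 else 6
    n_mol = mol_start.shape[0]
    opts = np.empty(6, dtype=np.int64)
    vals = np.empty(max(2 * L + 1, 18), dtype=np.int64)  # axis values or 6 xyz triples
    cstack = np.empty(n_mol, dtype=np.int64)
    cmark = np.zeros(n_mol, dtype=np.uint8)
    nxyz = np.empty(3, dtype=np.int64)
    pbuf = np.empty(0, dtype=np.int64)

    for _step in range(n_steps):
        r = np.random.random()
        mt = 0
        while mt < 4 and r >= probs[mt]:
            mt += 1
        att[mt] += 1

        # ------------------------------------------------ binding flip
        if mt == 0:
            d = dom_beads[np.random.randint(0, dom_beads.shape[0])]
            cnt = _count_opts(
                pos, occ, kind, partner, L, d, pos[d, 0], pos[d, 1], pos[d, 2], opts
            )
            j = np.random.randint(0, cnt + 1)
            newp = -1 if j == 0 else opts[j - 1]
            oldp = partner[d]
            if newp == oldp:
                acc[0] += 1
                continue
            dE = u_sp * ((newp != -1) - (oldp != -1))
            if dE <= 0.0 or np.random.random() < math.exp(-dE):
                if oldp != -1:
                    partner[oldp] = -1
                partner[d] = newp
                if newp != -1:
                    partner[newp] = d
                energy += dE
                acc[0] += 1

        # ------------------------------------------------ pivot / crankshaft
        elif mt == 1 or mt == 2:
            if mt == 1:
                b = end_beads[np.random.randint(0, end_beads.shape[0])]
                j1 = teth_other[b, 0]
                c1 = teth_cap[b, 0]
                if c1 == 0:
                    t = np.random.randint(0, nn)
                    for ax in range(3):
                        nxyz[ax] = (pos[j1, ax] + _OFFS[t, ax]) % L
                else:
                    for ax in range(3):
                        nxyz[ax] = (pos[j1, ax] + np.random.randint(-c1, c1 + 1)) % L
            else:
                b = mid_beads[np.random.randint(0, mid_beads.shape[0])]
                j1 = teth_other[b, 0]
                c1 = teth_cap[b, 0]
                j2 = teth_other[b, 1]
                c2 = teth_cap[b, 1]
                if c1 > 0 and c2 > 0:
                    for ax in range(3):
                        cv = 0
                        for dd in range(-c1, c1 + 1):
                            v = (pos[j1, ax] + dd) % L
                            if abs(_mi(v - pos[j2, ax], L)) <= c2:
                                vals[cv] = v
                                cv += 1
                        nxyz[ax] = vals[np.random.randint(0, cv)]
                else:
                    if c1 != 0:
                        tmp = j1
                        j1 = j2
                        j2 = tmp
                        tmpc = c1
                        c1 = c2
                        c2 = tmpc
                    # j1 is an adjacency anchor; filter its neighbors by the
                    # second constraint and pick uniformly
                    cv = 0
                    for t in range(nn):
                        xx = (pos[j1, 0] + _OFFS[t, 0]) % L
                        yy = (pos[j1, 1] + _OFFS[t, 1]) % L
                        zz = (pos[j1, 2] + _OFFS[t, 2]) % L
                        dx = abs(_mi(xx - pos[j2, 0], L))
                        dy = abs(_mi(yy - pos[j2, 1], L))
                        dz = abs(_mi(zz - pos[j2, 2], L))
                        ok = (
                            (dx + dy + dz == 1)
                            if c2 == 0
                            else (max(dx, max(dy, dz)) <= c2)
                        )
                        if ok:
                            vals[3 * cv] = xx
                            vals[3 * cv + 1] = yy
                            vals[3 * cv + 2] = zz
                            cv += 1
                    pick = np.random.randint(0, cv)
                    nxyz[0] = vals[3 * pick]
                    nxyz[1] = vals[3 * pick + 1]
                    nxyz[2] = vals[3 * pick + 2]

            tgt = occ[_site(nxyz[0], nxyz[1], nxyz[2], L)]
            if tgt >= 0 and tgt != b:
                continue
            if kind[b] != 2:
                n_c = 1 + _count_opts(
                    pos, occ, kind, partner, L, b, pos[b, 0], pos[b, 1], pos[b, 2], opts
                )
                n_p = 1 + _count_opts(
                    pos, occ, kind, partner, L, b, nxyz[0], nxyz[1], nxyz[2], opts
                )
                jj = np.random.randint(0, n_p)
                newp = -1 if jj == 0 else opts[jj - 1]
                oldp = partner[b]
                dE = u_sp * ((newp != -1) - (oldp != -1))
                w = n_p / n_c
            else:
                newp = -1
                oldp = -1
                dE = 0.0
                w = 1.0
            p = w * math.exp(-dE)
            if p >= 1.0 or np.random.random() < p:
                occ[_site(pos[b, 0], pos[b, 1], pos[b, 2], L)] = -1
                pos[b, 0] = nxyz[0]
                pos[b, 1] = nxyz[1]
                pos[b, 2] = nxyz[2]
                occ[_site(nxyz[0], nxyz[1], nxyz[2], L)] = b
                if kind[b] != 2:
                    if oldp != -1:
                        partner[oldp] = -1
                    partner[b] = newp
                    if newp != -1:
                        partner[newp] = b
                    energy += dE
                acc[mt] += 1

        # ------------------------------------------------ cluster translate
        elif mt == 3:
            m0 = np.random.randint(0, n_mol)
            cstack[0] = m0
            cmark[m0] = 1
            csize = 1
            idx = 0
            while idx < csize:
                m = cstack[idx]
                idx += 1
                for b in range(mol_start[m], mol_start[m] + mol_len[m]):
                    pp = partner[b]
                    if pp >= 0:
                        pm = mol[pp]
                        if cmark[pm] == 0:
                            cmark[pm] = 1
                            cstack[csize] = pm
                            csize += 1
            ax = np.random.randint(0, 3)
            sgn = 1 if np.random.randint(0, 2) == 1 else -1
            ok = True
            for k in range(csize):
                m = cstack[k]
                for b in range(mol_start[m], mol_start[m] + mol_len[m]):
                    xx = pos[b, 0]
                    yy = pos[b, 1]
                    zz = pos[b, 2]
                    if ax == 0:
                        xx = (xx + sgn) % L
                    elif ax == 1:
                        yy = (yy + sgn) % L
                    else:
                        zz = (zz + sgn) % L
                    tgt = occ[_site(xx, yy, zz, L)]
                    if tgt >= 0 and cmark[mol[tgt]] == 0:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                for k in range(csize):
                    m = cstack[k]
                    for b in range(mol_start[m], mol_start[m] + mol_len[m]):
                        occ[_site(pos[b, 0], pos[b, 1], pos[b, 2], L)] = -1
                for k in range(csize):
                    m = cstack[k]
                    for b in range(mol_start[m], mol_start[m] + mol_len[m]):
                        pos[b, ax] = (pos[b, ax] + sgn) % L
                for k in range(csize):
                    m = cstack[k]
                    for b in range(mol_start[m], mol_start[m] + mol_len[m]):
                        occ[_site(pos[b, 0], pos[b, 1], pos[b, 2], L)] = b
                acc[3] += 1
            for k in range(csize):
                cmark[cstack[k]] = 0

        # ------------------------------------------------ reptation (e = 0)
        else:
            ri = np.random.randint(0, rept_mols.shape[0])
            m = rept_mols[ri]
            capn = rept_cap[ri]
            base = mol_start[m]
            nb = mol_len[m]
            head = np.random.randint(0, 2) == 1
            if head:
                dom_old = base
                anch_c = base + 1
                anch_p = base + nb - 1
            else:
                dom_old = base + nb - 1
                anch_c = base + nb - 2
                anch_p = base
            # placements at the target end (segment = the removed domain)
            v_p = 0
            for dx in range(-capn, capn + 1):
                for dy in range(-capn, capn + 1):
                    for dz in range(-capn, capn + 1):
                        xx = (pos[anch_p, 0] + dx) % L
                        yy = (pos[anch_p, 1] + dy) % L
                        zz = (pos[anch_p, 2] + dz) % L
                        t = occ[_site(xx, yy, zz, L)]
                        if t < 0 or t == dom_old:
                            v_p += 1
            if v_p == 0:
                continue
            pick = np.random.randint(0, v_p)
            seen = 0
            found = False
            for dx in range(-capn, capn + 1):
                if found:
                    break
                for dy in range(-capn, capn + 1):
                    if found:
                        break
                    for dz in range(-capn, capn + 1):
                        xx = (pos[anch_p, 0] + dx) % L
                        yy = (pos[anch_p, 1] + dy) % L
                        zz = (pos[anch_p, 2] + dz) % L
                        t = occ[_site(xx, yy, zz, L)]
                        if t < 0 or t == dom_old:
                            if seen == pick:
                                nxyz[0] = xx
                                nxyz[1] = yy
                                nxyz[2] = zz
                                found = True
                                break
                            seen += 1
            v_c = 0
            for dx in range(-capn, capn + 1):
                for dy in range(-capn, capn + 1):
                    for dz in range(-capn, capn + 1):
                        xx = (pos[anch_c, 0] + dx) % L
                        yy = (pos[anch_c, 1] + dy) % L
                        zz = (pos[anch_c, 2] + dz) % L
                        t = occ[_site(xx, yy, zz, L)]
                        if t < 0 or t == dom_old:
                            v_c += 1
            n_c = 1 + _count_opts(
                pos, occ, kind, partner, L, dom_old,
                pos[dom_old, 0], pos[dom_old, 1], pos[dom_old, 2], opts,
            )
            n_p = 1 + _count_opts(
                pos, occ, kind, partner, L, dom_old, nxyz[0], nxyz[1], nxyz[2], opts
            )
            jj = np.random.randint(0, n_p)
            newp = -1 if jj == 0 else opts[jj - 1]
            oldp = partner[dom_old]
            dE = u_sp * ((newp != -1) - (oldp != -1))
            w = (n_p * v_p) / (n_c * v_c)
            p = w * math.exp(-dE)
            if p >= 1.0 or np.random.random() < p:
                if pbuf.shape[0] < nb:
                    pbuf = np.empty(nb, dtype=np.int64)
                for k in range(nb):
                    pbuf[k] = partner[base + k]
                for k in range(nb):
                    if pbuf[k] >= 0:
                        partner[pbuf[k]] = -1
                    partner[base + k] = -1
                for k in range(nb):
                    occ[_site(pos[base + k, 0], pos[base + k, 1], pos[base + k, 2], L)] = -1
                if head:
                    for k in range(nb - 1):
                        pos[base + k, 0] = pos[base + k + 1, 0]
                        pos[base + k, 1] = pos[base + k + 1, 1]
                        pos[base + k, 2] = pos[base + k + 1, 2]
                    pos[base + nb - 1, 0] = nxyz[0]
                    pos[base + nb - 1, 1] = nxyz[1]
                    pos[base + nb - 1, 2] = nxyz[2]
                    for k in range(nb - 1):
                        pp = pbuf[k + 1]
                        if pp >= 0:
                            partner[base + k] = pp
                            partner[pp] = base + k
                    if newp >= 0:
                        partner[base + nb - 1] = newp
                        partner[newp] = base + nb - 1
                else:
                    for k in range(nb - 1, 0, -1):
                        pos[base + k, 0] = pos[base + k - 1, 0]
                        pos[base + k, 1] = pos[base + k - 1, 1]
                        pos[base + k, 2] = pos[base + k - 1, 2]
                    pos[base, 0] = nxyz[0]
                    pos[base, 1] = nxyz[1]
                    pos[base, 2] = nxyz[2]
                    for k in range(1, nb):
                        pp = pbuf[k - 1]
                        if pp >= 0:
                            partner[base + k] = pp
                            partner[pp] = base + k
                    if newp >= 0:
                        partner[base] = newp
                        partner[newp] = base
                for k in range(nb):
                    occ[_site(pos[base + k, 0], pos[base + k, 1], pos[base + k, 2], L)] = base + k
                energy += dE
                acc[4] += 1
    return energy


def kernel_args(state: SystemState) -> tuple:
    """Array bundle the kernel operates on (views into the live state)."""
    if state.interaction.has_nonspecific:
        raise ValueError("kernel supports the default (specific-only) model")
    rept_mols = []
    rept_cap = []
    for m, topo in enumerate(state.topologies):
        lk = topo.uniform_linker
        if topo.valence >= 2 and lk is not None and lk.e == 0:
            rept_mols.append(m)
            rept_cap.append(lk.n)
    return (
        state.pos,
        state.occ,
        state.kind,
        state.mol,
        state.partner,
        state.mol_start,
        state.mol_len,
        state.teth_other,
        state.teth_cap,
        state.domain_beads,
        state.end_beads,
        state.mid_beads,
        np.array(rept_mols, dtype=np.int64),
        np.array(rept_cap, dtype=np.int64),
        state.L,
        float(state.interaction.u_sp),
    )


def schedule_probs(state: SystemState, schedule: dict[str, float] | None) -> np.ndarray:
    """Cumulative move probabilities over the five move codes.

    Defaults to uniform weights over the applicable move types; reptation is
    applicable (in the kernel) only to chains with fully implicit linkers.
    """
    has_rept = any(
        t.valence >= 2 and t.uniform_linker is not None and t.uniform_linker.e == 0
        for t in state.topologies
    )
    applicable = {
        "binding_flip": len(state.domain_beads) > 0,
        "end_pivot": len(state.end_beads) > 0,
        "crankshaft": len(state.mid_beads) > 0,
        "cluster_translate": True,
        "reptation": has_rept,
    }
    weights = np.zeros(5)
    for i, mname in enumerate(MOVE_TYPES):
        if applicable[mname]:
            weights[i] = 1.0 if schedule is None else float(schedule.get(mname, 0.0))
    if weights.sum() <= 0:
        raise ValueError("no applicable moves with positive weight")
    return np.cumsum(weights / weights.sum())
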