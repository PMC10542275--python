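"""Event-driven structured coalescent with recombination (numba core).

Backward-in-time sample genealogy conditioned on a per-generation
derived-allele frequency trajectory.  Lineages are partitioned into a
derived and an ancestral allelic class at the focal site while the focal
allele is polymorphic in the lookback population; class sizes follow the
trajectory.  Per generation, events are scheduled as Bernoulli trials
(at most one coalescence per class per trial); a generation whose total
event probability exceeds 0.1 is subdivided into equal sub-steps so the
small-probability approximation stays accurate.  Recombination acts on the
bp span from the leftmost to the rightmost point of a lineage's ancestral
material and the focal site; the fragment not containing the focal site
re-draws its allelic class from the population frequency of that
generation.  Older than the trajectory's origin (and for unconditioned
runs) a single-class neutral coalescent continues, with waiting times drawn
directly from the per-generation no-event probability, until every bp
position has reached its most recent common ancestor.

The core emits an edge ledger: for every lineage lifetime, (child node,
parent node, duration, ancestral-material intervals with their descendant
sample sets as 128-bit masks).  Mutation dropping and matrix assembly live
in :mod:`sweeppower.coalescent`.
"""

import math

import numpy as np
from numba import njit

OK = 0
ERR_LINEAGE_CAP = 1
ERR_SEGMENT_CAP = 2
ERR_EDGE_CAP = 3
ERR_EDGESEG_CAP = 4
ERR_NODE_CAP = 5
ERR_RUNAWAY = 6

# probability cap per Bernoulli sub-step
_PMAX = 0.1


@njit(cache=True)
def run_structured(
    seed,
    kder,          # int64[G]: derived copies in the population, gen g before present
    twoN_traj,     # int64[G]: total copies 2N(g) along the trajectory
    ep_start,      # float64[E]: epoch start times (generations), ep_start[0] == 0
    ep_twoN,       # int64[E]: 2N per epoch (used for g >= G)
    L,             # region length (bp, float)
    rr,            # recombination rate per site per generation
    focal,         # focal-site bp coordinate
    n,             # sample size (chromosomes), <= 128
    nder_samp,     # sampled derived-class chromosomes (first nder_samp samples)
    node_time,     # out: float64[NODECAP]
    e_child, e_parent,        # out: int64[EDGECAP]
    e_dur,                    # out: float64[EDGECAP]
    e_segstart, e_segcnt,     # out: int64[EDGECAP]
    ds_l, ds_r,               # out: float64[ESEGCAP]
    ds_b0, ds_b1,             # out: uint64[ESEGCAP]
    out_counts,               # out: int64[3] = (n_nodes, n_edges, n_dump_segs)
    MAXLIN, SEGCAP,
):
    np.random.seed(seed)
    G = len(kder)
    E = len(ep_start)
    NODECAP = len(node_time)
    EDGECAP = len(e_child)
    ESEGCAP = len(ds_l)

    # ---- segment pool (linked lists ordered by left endpoint) ----
    sl = np.empty(SEGCAP, np.float64)
    sr = np.empty(SEGCAP, np.float64)
    sb0 = np.empty(SEGCAP, np.uint64)
    sb1 = np.empty(SEGCAP, np.uint64)
    snx = np.empty(SEGCAP, np.int64)
    for i in range(SEGCAP - 1):
        snx[i] = i + 1
    snx[SEGCAP - 1] = -1

    # mutable scalar state lives in arrays so inner closures can update it
    st = np.zeros(6, np.int64)
    FREE, K, NN, NE, NDS, EVENTS = 0, 1, 2, 3, 4, 5

    # ---- lineage table (slots 0 .. st[K)-1 are live) ----
    lin_head = np.full(MAXLIN, -1, np.int64)
    lin_node = np.empty(MAXLIN, np.int64)
    lin_birth = np.empty(MAXLIN, np.float64)
    lin_cls = np.zeros(MAXLIN, np.uint8)
    lin_lo = np.empty(MAXLIN, np.float64)
    lin_hi = np.empty(MAXLIN, np.float64)

    if n >= 64:
        FULL0 = np.uint64(0xFFFFFFFFFFFFFFFF)
    else:
        FULL0 = (np.uint64(1) << np.uint64(n)) - np.uint64(1)
    if n > 64:
        FULL1 = (np.uint64(1) << np.uint64(n - 64)) - np.uint64(1)
    else:
        FULL1 = np.uint64(0)

    def alloc_seg(l, r, b0, b1):
        i = st[FREE]
        if i < 0:
            return -1
        st[FREE] = snx[i]
        sl[i] = l
        sr[i] = r
        sb0[i] = b0
        sb1[i] = b1
        snx[i] = -1
        return i

    def free_chain(h):
        while h >= 0:
            nx = snx[h]
            snx[h] = st[FREE]
            st[FREE] = h
            h = nx

    def new_node(t):
        i = st[NN]
        if i >= NODECAP:
            return -1
        node_time[i] = t
        st[NN] = i + 1
        return i

    def dump_edge(child, parent, t_child, t_parent, head):
        ei = st[NE]
        if ei >= EDGECAP:
            return False
        start = st[NDS]
        cnt = 0
        h = head
        while h >= 0:
            p = st[NDS]
            if p >= ESEGCAP:
                return False
            ds_l[p] = sl[h]
            ds_r[p] = sr[h]
            ds_b0[p] = sb0[h]
            ds_b1[p] = sb1[h]
            st[NDS] = p + 1
            cnt += 1
            h = snx[h]
        e_child[ei] = child
        e_parent[ei] = parent
        e_dur[ei] = t_parent - t_child
        e_segstart[ei] = start
        e_segcnt[ei] = cnt
        st[NE] = ei + 1
        return True

    def chain_bounds(h):
        lo = sl[h]
        hi = sr[h]
        while h >= 0:
            if sr[h] > hi:
                hi = sr[h]
            h = snx[h]
        return lo, hi

    def set_lineage(i, head, cls, node, birth):
        lin_head[i] = head
        lin_cls[i] = cls
        lin_node[i] = node
        lin_birth[i] = birth
        lo, hi = chain_bounds(head)
        lin_lo[i] = lo
        lin_hi[i] = hi

    def remove_lineage(i):
        last = st[K] - 1
        if i != last:
            lin_head[i] = lin_head[last]
            lin_node[i] = lin_node[last]
            lin_birth[i] = lin_birth[last]
            lin_cls[i] = lin_cls[last]
            lin_lo[i] = lin_lo[last]
            lin_hi[i] = lin_hi[last]
        lin_head[last] = -1
        st[K] = last

    def merge_chains(ha, hb):
        """Union two segment chains; strip intervals whose descendant set is
        the full sample (they have found their MRCA).  Frees both inputs.
        Returns the new head, -1 if nothing remains, -2 on pool overflow."""
        if ha < 0:
            return hb
        if hb < 0:
            return ha
        na = 0
        h = ha
        while h >= 0:
            na += 1
            h = snx[h]
        nb = 0
        h = hb
        while h >= 0:
            nb += 1
            h = snx[h]
        al = np.empty(na, np.float64)
        ar = np.empty(na, np.float64)
        a0 = np.empty(na, np.uint64)
        a1 = np.empty(na, np.uint64)
        h = ha
        for i in range(na):
            al[i] = sl[h]
            ar[i] = sr[h]
            a0[i] = sb0[h]
            a1[i] = sb1[h]
            h = snx[h]
        bl = np.empty(nb, np.float64)
        br = np.empty(nb, np.float64)
        b0a = np.empty(nb, np.uint64)
        b1a = np.empty(nb, np.uint64)
        h = hb
        for i in range(nb):
            bl[i] = sl[h]
            br[i] = sr[h]
            b0a[i] = sb0[h]
            b1a[i] = sb1[h]
            h = snx[h]
        cap = 2 * (na + nb) + 2
        ql = np.empty(cap, np.float64)
        qr = np.empty(cap, np.float64)
        q0 = np.empty(cap, np.uint64)
        q1 = np.empty(cap, np.uint64)
        nq = 0
        i = 0
        j = 0
        pos = al[0]
        if nb and bl[0] < pos:
            pos = bl[0]
        while True:
            while i < na and ar[i] <= pos:
                i += 1
            while j < nb and br[j] <= pos:
                j += 1
            if i >= na and j >= nb:
                break
            in_u = i < na and al[i] <= pos
            in_v = j < nb and bl[j] <= pos
            if not in_u and not in_v:
                nxt = 1.0e308
                if i < na and al[i] < nxt:
                    nxt = al[i]
                if j < nb and bl[j] < nxt:
                    nxt = bl[j]
                pos = nxt
                continue
            nxt = 1.0e308
            if i < na:
                if al[i] > pos:
                    if al[i] < nxt:
                        nxt = al[i]
                elif ar[i] < nxt:
                    nxt = ar[i]
            if j < nb:
                if bl[j] > pos:
                    if bl[j] < nxt:
                        nxt = bl[j]
                elif br[j] < nxt:
                    nxt = br[j]
            c0 = np.uint64(0)
            c1 = np.uint64(0)
            if in_u:
                c0 |= a0[i]
                c1 |= a1[i]
            if in_v:
                c0 |= b0a[j]
                c1 |= b1a[j]
            if nxt > pos and not (c0 == FULL0 and c1 == FULL1):
                if nq > 0 and qr[nq - 1] == pos and q0[nq - 1] == c0 and q1[nq - 1] == c1:
                    qr[nq - 1] = nxt
                else:
                    ql[nq] = pos
                    qr[nq] = nxt
                    q0[nq] = c0
                    q1[nq] = c1
                    nq += 1
            pos = nxt
        free_chain(ha)
        free_chain(hb)
        head = -1
        prev = -1
        for q in range(nq):
            si = alloc_seg(ql[q], qr[q], q0[q], q1[q])
            if si < 0:
                return -2
            if prev < 0:
                head = si
            else:
                snx[prev] = si
            prev = si
        return head

    def split_chain(head, b):
        """Split a chain at breakpoint b.  Returns (left_head, right_head);
        (-2, -2) on pool overflow.  Either side may be -1 (empty)."""
        lh = -1
        lt = -1
        rh = -1
        rt = -1
        h = head
        while h >= 0:
            nx = snx[h]
            snx[h] = -1
            if sr[h] <= b:
                if lt < 0:
                    lh = h
                else:
                    snx[lt] = h
                lt = h
            elif sl[h] >= b:
                if rt < 0:
                    rh = h
                else:
                    snx[rt] = h
                rt = h
            else:
                ns = alloc_seg(b, sr[h], sb0[h], sb1[h])
                if ns < 0:
                    return -2, -2
                sr[h] = b
                if lt < 0:
                    lh = h
                else:
                    snx[lt] = h
                lt = h
                if rt < 0:
                    rh = ns
                else:
                    snx[rt] = ns
                rt = ns
            h = nx
        return lh, rh

    # ---- initial sample ----
    status = OK
    for i in range(n):
        if i < 64:
            b0 = np.uint64(1) << np.uint64(i)
            b1 = np.uint64(0)
        else:
            b0 = np.uint64(0)
            b1 = np.uint64(1) << np.uint64(i - 64)
        si = alloc_seg(0.0, L, b0, b1)
        if si < 0:
            return ERR_SEGMENT_CAP
        nd = new_node(0.0)
        cls = np.uint8(1) if i < nder_samp else np.uint8(0)
        set_lineage(i, si, cls, nd, 0.0)
    st[K] = n

    max_events = 64 * EDGECAP

    # =================== phase 1: trajectory-conditioned ===================
    g = 0
    while g < G and st[K] > 0:
        twoNg = twoN_traj[g]
        kd_pop = kder[g]
        ka_pop = twoNg - kd_pop
        # per-generation class counts and recombination span
        kD = 0
        S = 0.0
        for i in range(st[K]):
            if lin_cls[i] == 1:
                kD += 1
            lo = lin_lo[i]
            hi = lin_hi[i]
            if focal < lo:
                lo = focal
            if focal > hi:
                hi = focal
            S += hi - lo
        kA = st[K] - kD
        cD = 0.0
        if kD >= 2:
            nD = kd_pop if kd_pop > kD else kD
            cD = kD * (kD - 1) * 0.5 / nD
        cA = 0.0
        if kA >= 2:
            nA = ka_pop if ka_pop > kA else kA
            cA = kA * (kA - 1) * 0.5 / nA
        rRate = rr * S
        lam = cD + cA + rRate
        if lam <= 0.0:
            g += 1
            continue
        m = 1 + int(lam / _PMAX)
        j = 0
        while j < m and st[K] > 0:
            pr = lam / m
            if pr > 1.0:
                pr = 1.0
            if np.random.random() < pr:
                st[EVENTS] += 1
                if st[EVENTS] > max_events:
                    return ERR_RUNAWAY
                tev = g + (j + 1.0) / m
                u = np.random.random() * lam
                if u < cD + cA:
                    # ---- coalescence within a class ----
                    cls = np.uint8(1) if u < cD else np.uint8(0)
                    kc = kD if cls == 1 else kA
                    a = np.random.randint(0, kc)
                    b = np.random.randint(0, kc - 1)
                    if b >= a:
                        b += 1
                    i1 = -1
                    i2 = -1
                    seen = 0
                    for i in range(st[K]):
                        if lin_cls[i] == cls:
                            if seen == a:
                                i1 = i
                            if seen == b:
                                i2 = i
                            seen += 1
                    if i2 < i1:
                        tmp = i1
                        i1 = i2
                        i2 = tmp
                    w = new_node(tev)
                    if w < 0:
                        return ERR_NODE_CAP
                    if not dump_edge(lin_node[i1], w, lin_birth[i1], tev, lin_head[i1]):
                        return ERR_EDGE_CAP
                    if not dump_edge(lin_node[i2], w, lin_birth[i2], tev, lin_head[i2]):
                        return ERR_EDGE_CAP
                    mh = merge_chains(lin_head[i1], lin_head[i2])
                    if mh == -2:
                        return ERR_SEGMENT_CAP
                    remove_lineage(i2)
                    if mh == -1:
                        remove_lineage(i1)
                    else:
                        set_lineage(i1, mh, cls, w, tev)
                else:
                    # ---- recombination ----
                    target = u - cD - cA
                    acc = 0.0
                    il = st[K] - 1
                    for i in range(st[K]):
                        lo = lin_lo[i]
                        hi = lin_hi[i]
                        if focal < lo:
                            lo = focal
                        if focal > hi:
                            hi = focal
                        acc += rr * (hi - lo)
                        if target < acc:
                            il = i
                            break
                    lo = lin_lo[il]
                    hi = lin_hi[il]
                    if focal < lo:
                        lo = focal
                    if focal > hi:
                        hi = focal
                    bpt = lo + np.random.random() * (hi - lo)
                    lh, rh = split_chain(lin_head[il], bpt)
                    if lh == -2:
                        return ERR_SEGMENT_CAP
                    if focal < bpt:
                        fs = lh
                        os_ = rh
                    else:
                        fs = rh
                        os_ = lh
                    if os_ == -1:
                        # breakpoint separated nothing from the focal side
                        lin_head[il] = fs
                    else:
                        ncls = np.uint8(1) if np.random.random() * twoNg < kd_pop else np.uint8(0)
                        if fs == -1:
                            nn1 = new_node(tev)
                            if nn1 < 0:
                                return ERR_NODE_CAP
                            if not dump_edge(lin_node[il], nn1, lin_birth[il], tev, os_):
                                return ERR_EDGE_CAP
                            set_lineage(il, os_, ncls, nn1, tev)
                        else:
                            nn1 = new_node(tev)
                            nn2 = new_node(tev)
                            if nn1 < 0 or nn2 < 0:
                                return ERR_NODE_CAP
                            if not dump_edge(lin_node[il], nn1, lin_birth[il], tev, fs):
                                return ERR_EDGE_CAP
                            if not dump_edge(lin_node[il], nn2, lin_birth[il], tev, os_):
                                return ERR_EDGE_CAP
                            if st[K] >= MAXLIN:
                                return ERR_LINEAGE_CAP
                            oldcls = lin_cls[il]
                            set_lineage(il, fs, oldcls, nn1, tev)
                            set_lineage(st[K], os_, ncls, nn2, tev)
                            st[K] += 1
                # recompute rates, keep the sub-step grid of this generation
                kD = 0
                S = 0.0
                for i in range(st[K]):
                    if lin_cls[i] == 1:
                        kD += 1
                    lo = lin_lo[i]
                    hi = lin_hi[i]
                    if focal < lo:
                        lo = focal
                    if focal > hi:
                        hi = focal
                    S += hi - lo
                kA = st[K] - kD
                cD = 0.0
                if kD >= 2:
                    nD = kd_pop if kd_pop > kD else kD
                    cD = kD * (kD - 1) * 0.5 / nD
                cA = 0.0
                if kA >= 2:
                    nA = ka_pop if ka_pop > kA else kA
                    cA = kA * (kA - 1) * 0.5 / nA
                rRate = rr * S
                lam = cD + cA + rRate
            j += 1
        g += 1

    # =================== the mutation event at the origin ===================
    if G > 0 and st[K] > 0:
        tor = float(G)
        kD = 0
        for i in range(st[K]):
            if lin_cls[i] == 1:
                kD += 1
        if kD == 1:
            for i in range(st[K]):
                if lin_cls[i] == 1:
                    lin_cls[i] = np.uint8(0)
        elif kD >= 2:
            w = new_node(tor)
            if w < 0:
                return ERR_NODE_CAP
            mh = -1
            first = True
            # dump edges first, then merge all derived chains into one
            i = 0
            while i < st[K]:
                if lin_cls[i] == 1:
                    if not dump_edge(lin_node[i], w, lin_birth[i], tor, lin_head[i]):
                        return ERR_EDGE_CAP
                    if first:
                        mh = lin_head[i]
                        first = False
                    else:
                        mh = merge_chains(mh, lin_head[i])
                        if mh == -2:
                            return ERR_SEGMENT_CAP
                    lin_head[i] = -1
                    remove_lineage(i)
                else:
                    i += 1
            if mh >= 0:
                if st[K] >= MAXLIN:
                    return ERR_LINEAGE_CAP
                set_lineage(st[K], mh, np.uint8(0), w, tor)
                st[K] += 1

    # =================== phase 2: single-class neutral coalescent ===========
    t = float(G)
    ei = 0
    for e in range(E):
        if ep_start[e] <= t:
            ei = e
    while st[K] > 0:
        k = st[K]
        twoNg = ep_twoN[ei]
        S = 0.0
        for i in range(k):
            S += lin_hi[i] - lin_lo[i]
        cC = k * (k - 1) * 0.5 / twoNg
        rRate = rr * S
        lam = cC + rRate
        m = 1 + int(lam / _PMAX)
        qq = 1.0 - lam / m
        if qq < 1.0e-12:
            qq = 1.0e-12
        p0 = qq ** m
        u = np.random.random()
        if u < 1.0e-300:
            u = 1.0e-300
        W = int(math.log(u) / math.log(p0))
        boundary = 1.0e308
        if ei + 1 < E:
            boundary = ep_start[ei + 1]
        if t + W + 1.0 > boundary:
            t = boundary
            ei += 1
            continue
        st[EVENTS] += 1
        if st[EVENTS] > max_events:
            return ERR_RUNAWAY
        v = np.random.random()
        j = int(math.log(1.0 - v * (1.0 - p0)) / math.log(qq))
        if j >= m:
            j = m - 1
        tev = t + W + (j + 1.0) / m
        u2 = np.random.random() * lam
        if u2 < cC:
            a = np.random.randint(0, k)
            b = np.random.randint(0, k - 1)
            if b >= a:
                b += 1
            i1 = a if a < b else b
            i2 = b if a < b else a
            w = new_node(tev)
            if w < 0:
                return ERR_NODE_CAP
            if not dump_edge(lin_node[i1], w, lin_birth[i1], tev, lin_head[i1]):
                return ERR_EDGE_CAP
            if not dump_edge(lin_node[i2], w, lin_birth[i2], tev, lin_head[i2]):
                return ERR_EDGE_CAP
            mh = merge_chains(lin_head[i1], lin_head[i2])
            if mh == -2:
                return ERR_SEGMENT_CAP
            remove_lineage(i2)
            if mh == -1:
                remove_lineage(i1)
            else:
                set_lineage(i1, mh, np.uint8(0), w, tev)
        else:
            target = u2 - cC
            acc = 0.0
            il = k - 1
            for i in range(k):
                acc += rr * (lin_hi[i] - lin_lo[i])
                if target < acc:
                    il = i
                    break
            bpt = lin_lo[il] + np.random.random() * (lin_hi[il] - lin_lo[il])
            lh, rh = split_chain(lin_head[il], bpt)
            if lh == -2:
                return ERR_SEGMENT_CAP
            if lh == -1 or rh == -1:
                lin_head[il] = lh if rh == -1 else rh
            else:
                nn1 = new_node(tev)
                nn2 = new_node(tev)
                if nn1 < 0 or nn2 < 0:
                    return ERR_NODE_CAP
                if not dump_edge(lin_node[il], nn1, lin_birth[il], tev, lh):
                    return ERR_EDGE_CAP
                if not dump_edge(lin_node[il], nn2, lin_birth[il], tev, rh):
                    return ERR_EDGE_CAP
                if st[K] >= MAXLIN:
                    return ERR_LINEAGE_CAP
                set_lineage(il, lh, np.uint8(0), nn1, tev)
                set_lineage(st[K], rh, np.uint8(0), nn2, tev)
                st[K] += 1
        t = tev

    out_counts[0] = st[NN]
    out_counts[1] = st[NE]
    out_counts[2] = st[NDS]
    return OK


@njit(cache=True)
def backward_walk(seed, k0, t_now, ep_start, ep_twoN, s, h, max_len, out_k, out_twoN):
    """Reverse-time Wright-Fisher frequency walk from ``k0`` copies at
    generation ``t_now`` until the mutation's origin.

    Neutral binomial resampling for ``s == 0``; for ``s > 0`` the
    deterministic forward selection increment is subtracted first (the
    standard reverse-time construction for an advantageous allele).
    Writes copy counts and population copy totals per generation outward
    from ``t_now``.  Returns the number of entries on success, -1 when the
    walk is absorbed at fixation (path rejected: the allele must originate
    as a mutation), -2 when ``max_len`` is exceeded.
    """
    np.random.seed(seed)
    E = len(ep_start)
    ei = 0
    for e in range(E):
        if ep_start[e] <= t_now:
            ei = e
    twoN_cur = ep_twoN[ei]
    k = k0
    out_k[0] = k
    out_twoN[0] = twoN_cur
    j = 0
    g = float(t_now)
    while True:
        g += 1.0
        while ei + 1 < E and ep_start[ei + 1] <= g:
            ei += 1
        twoN_next = ep_twoN[ei]
        p = k / twoN_cur
        if s > 0.0:
            q = 1.0 - p
            num = p * p * (1.0 + s) + p * q * (1.0 + h * s)
            wbar = num + p * q * (1.0 + h * s) + q * q
            pstar = num / wbar
            p = 2.0 * p - pstar
            if p < 0.0:
                p = 0.0
            elif p > 1.0:
                p = 1.0
        k = np.random.binomial(twoN_next, p)
        j += 1
        if j >= max_len:
            return -2
        if k >= twoN_next:
            return -1
        if k == 0:
            out_k[j] = 1  # the origin: a single mutant copy
            out_twoN[j] = twoN_next
            return j + 1
        out_k[j] = k
        out_twoN[j] = twoN_next
        twoN_cur = twoN_next
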