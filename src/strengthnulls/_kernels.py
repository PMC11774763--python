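"""Numba kernels for the randomization hot loops.

Everything here works on primitive arrays: a dense float64 weight matrix for
the rewirers (the connectivity guard needs fast neighborhood scans) and flat
edge arrays (u, v, w) for the weight-permutation algorithms.  Each kernel
seeds numba's per-thread legacy RNG explicitly so that every run is
reproducible from its integer seed alone.

Connectivity guards exploit a local criterion: starting from a connected
(resp. strongly connected) graph, swapping edges (a,b),(c,d) -> (a,d),(c,b)
leaves the graph connected iff b is still reachable from a (undirected; c~d
then follows through the new edges c-b, a-d), and strongly connected iff both
a⇝b and c⇝d hold in the updated directed graph.  Any walk through a removed
edge can then be rerouted, so a single truncated BFS per proposal suffices.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _reachable(W, src, dst, directed):
    """BFS on the nonzero pattern of W from src, early exit at dst."""
    n = W.shape[0]
    visited = np.zeros(n, dtype=np.bool_)
    queue = np.empty(n, dtype=np.int64)
    visited[src] = True
    queue[0] = src
    head = 0
    tail = 1
    while head < tail:
        x = queue[head]
        head += 1
        for y in range(n):
            if not visited[y] and (W[x, y] != 0.0 or (not directed and W[y, x] != 0.0)):
                if y == dst:
                    return True
                visited[y] = True
                queue[tail] = y
                tail += 1
    return visited[dst]


@njit(cache=True)
def rewire_und(W, n_target, max_attempts, guard, seed):
    """Maslov–Sneppen double-edge swaps on an undirected matrix, in place.

    Returns (attempted, effected).  Weights travel with their edges.
    """
    np.random.seed(seed)
    n = W.shape[0]
    m = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if W[i, j] != 0.0:
                m += 1
    eu = np.empty(m, dtype=np.int64)
    ev = np.empty(m, dtype=np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if W[i, j] != 0.0:
                eu[k] = i
                ev[k] = j
                k += 1
    attempted = 0
    effected = 0
    for _ in range(n_target):
        for _att in range(max_attempts):
            attempted += 1
            e1 = np.random.randint(m)
            e2 = np.random.randint(m)
            if e1 == e2:
                continue
            a, b = eu[e1], ev[e1]
            c, d = eu[e2], ev[e2]
            if np.random.random() > 0.5:
                c, d = d, c  # choose between the two reconnection patterns
            if a == c or a == d or b == c or b == d:
                continue
            if W[a, d] != 0.0 or W[c, b] != 0.0:
                continue
            w1 = W[a, b]
            w2 = W[c, d]
            # tentative swap: remove a-b, c-d; add a-d, c-b
            W[a, b] = 0.0
            W[b, a] = 0.0
            W[c, d] = 0.0
            W[d, c] = 0.0
            W[a, d] = w1
            W[d, a] = w1
            W[c, b] = w2
            W[b, c] = w2
            ok = True
            if guard:
                ok = _reachable(W, a, b, False)
            if ok:
                eu[e1], ev[e1] = a, d
                eu[e2], ev[e2] = c, b
                effected += 1
                break
            # revert
            W[a, d] = 0.0
            W[d, a] = 0.0
            W[c, b] = 0.0
            W[b, c] = 0.0
            W[a, b] = w1
            W[b, a] = w1
            W[c, d] = w2
            W[d, c] = w2
    return attempted, effected


@njit(cache=True)
def rewire_dir(W, n_target, max_attempts, guard, seed):
    """Directed degree-preserving swaps a->b, c->d  =>  a->d, c->b.

    Weights travel with their source row, so the out-strength sequence is
    preserved exactly.  Guard enforces strong connectivity.
    """
    np.random.seed(seed)
    n = W.shape[0]
    m = 0
    for i in range(n):
        for j in range(n):
            if W[i, j] != 0.0:
                m += 1
    eu = np.empty(m, dtype=np.int64)
    ev = np.empty(m, dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(n):
            if W[i, j] != 0.0:
                eu[k] = i
                ev[k] = j
                k += 1
    attempted = 0
    effected = 0
    for _ in range(n_target):
        for _att in range(max_attempts):
            attempted += 1
            e1 = np.random.randint(m)
            e2 = np.random.randint(m)
            if e1 == e2:
                continue
            a, b = eu[e1], ev[e1]
            c, d = eu[e2], ev[e2]
            if a == d or c == b:
                continue  # would create a self-loop
            if W[a, d] != 0.0 or W[c, b] != 0.0:
                continue
            w1 = W[a, b]
            w2 = W[c, d]
            W[a, b] = 0.0
            W[c, d] = 0.0
            W[a, d] = w1
            W[c, b] = w2
            ok = True
            if guard:
                ok = _reachable(W, a, b, True) and _reachable(W, c, d, True)
            if ok:
                ev[e1] = d
                ev[e2] = b
                effected += 1
                break
            W[a, d] = 0.0
            W[c, b] = 0.0
            W[a, b] = w1
            W[c, d] = w2
    return attempted, effected


@njit(cache=True)
def rewire_signed(W, n_target, max_attempts, seed):
    """Connection switching within sign classes on an undirected signed
    matrix; preserves positive and negative degree sequences exactly.
    No connectedness guarantee."""
    np.random.seed(seed)
    n = W.shape[0]
    mp = 0
    mn = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if W[i, j] > 0.0:
                mp += 1
            elif W[i, j] < 0.0:
                mn += 1
    pu = np.empty(mp, dtype=np.int64)
    pv = np.empty(mp, dtype=np.int64)
    nu = np.empty(mn, dtype=np.int64)
    nv = np.empty(mn, dtype=np.int64)
    kp = 0
    kn = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if W[i, j] > 0.0:
                pu[kp] = i
                pv[kp] = j
                kp += 1
            elif W[i, j] < 0.0:
                nu[kn] = i
                nv[kn] = j
                kn += 1
    m = mp + mn
    attempted = 0
    effected = 0
    for _ in range(n_target):
        for _att in range(max_attempts):
            attempted += 1
            # pick the sign class proportionally to its edge count
            pick = np.random.randint(m)
            if pick < mp:
                if mp < 2:
                    continue
                su, sv = pu, pv
                mc = mp
            else:
                if mn < 2:
                    continue
                su, sv = nu, nv
                mc = mn
            e1 = np.random.randint(mc)
            e2 = np.random.randint(mc)
            if e1 == e2:
                continue
            a, b = su[e1], sv[e1]
            c, d = su[e2], sv[e2]
            if np.random.random() > 0.5:
                c, d = d, c
            if a == c or a == d or b == c or b == d:
                continue
            if W[a, d] != 0.0 or W[c, b] != 0.0:
                continue
            w1 = W[a, b]
            w2 = W[c, d]
            W[a, b] = 0.0
            W[b, a] = 0.0
            W[c, d] = 0.0
            W[d, c] = 0.0
            W[a, d] = w1
            W[d, a] = w1
            W[c, b] = w2
            W[b, c] = w2
            su[e1], sv[e1] = a, d
            su[e2], sv[e2] = c, b
            effected += 1
            break
    return attempted, effected


# ---------------------------------------------------------------------------
# Simulated annealing kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _apply_deltas(s, s_tgt, nodes, deltas, n_aff, n):
    """Energy change (mse contribution) of adding deltas to s at nodes;
    duplicate nodes must have been combined beforehand."""
    dE = 0.0
    for t in range(n_aff):
        v = nodes[t]
        dev = s[v] - s_tgt[v]
        dE += (dev + deltas[t]) ** 2 - dev**2
    return dE / n


@njit(cache=True)
def _combine(nodes_in, deltas_in, nodes_out, deltas_out):
    """Merge duplicate node entries; returns number of distinct nodes."""
    cnt = 0
    for t in range(nodes_in.shape[0]):
        v = nodes_in[t]
        found = -1
        for q in range(cnt):
            if nodes_out[q] == v:
                found = q
                break
        if found >= 0:
            deltas_out[found] += deltas_in[t]
        else:
            nodes_out[cnt] = v
            deltas_out[cnt] = deltas_in[t]
            cnt += 1
    return cnt


@njit(cache=True)
def sa_und(eu, ev, w, s_tgt, n, n_stages, iters, T0, cooling,
           use_threshold, threshold, seed):
    """Weight-pair-swap annealing against an undirected strength target.

    Returns (stage_energies, accepted_per_stage, stages_run, E0, best_E,
    max_drift); ``w`` is permuted in place.
    """
    np.random.seed(seed)
    m = eu.shape[0]
    s = np.zeros(n)
    for e in range(m):
        s[eu[e]] += w[e]
        s[ev[e]] += w[e]
    E = 0.0
    for v in range(n):
        E += (s[v] - s_tgt[v]) ** 2
    E /= n
    E0 = E
    best_E = E
    stage_E = np.zeros(n_stages)
    stage_acc = np.zeros(n_stages, dtype=np.int64)
    nodes4 = np.empty(4, dtype=np.int64)
    del4 = np.empty(4)
    cn = np.empty(4, dtype=np.int64)
    cd = np.empty(4)
    T = T0
    stages_run = 0
    max_drift = 0.0
    for stage in range(n_stages):
        acc = 0
        for _ in range(iters):
            e1 = np.random.randint(m)
            e2 = np.random.randint(m)
            if e1 == e2:
                continue
            delta = w[e2] - w[e1]
            nodes4[0] = eu[e1]
            nodes4[1] = ev[e1]
            nodes4[2] = eu[e2]
            nodes4[3] = ev[e2]
            del4[0] = delta
            del4[1] = delta
            del4[2] = -delta
            del4[3] = -delta
            cnt = _combine(nodes4, del4, cn, cd)
            dE = _apply_deltas(s, s_tgt, cn, cd, cnt, n)
            if dE < 0.0 or np.random.random() < np.exp(-dE / T):
                tmp = w[e1]
                w[e1] = w[e2]
                w[e2] = tmp
                for t in range(cnt):
                    s[cn[t]] += cd[t]
                E += dE
                acc += 1
        # full recomputation at stage end guards against numerical drift
        sfull = np.zeros(n)
        for e in range(m):
            sfull[eu[e]] += w[e]
            sfull[ev[e]] += w[e]
        Ef = 0.0
        for v in range(n):
            Ef += (sfull[v] - s_tgt[v]) ** 2
        Ef /= n
        drift = abs(Ef - E)
        if drift > max_drift:
            max_drift = drift
        E = Ef
        s = sfull
        if E < best_E:
            best_E = E
        stage_E[stage] = E
        stage_acc[stage] = acc
        stages_run = stage + 1
        T *= cooling
        if use_threshold and E <= threshold:
            break
    return stage_E[:stages_run], stage_acc[:stages_run], stages_run, E0, best_E, max_drift


@njit(cache=True)
def sa_dir(eu, ev, w, sin_tgt, sout_tgt, n, n_stages, iters, T0, cooling,
           use_threshold, threshold, seed):
    """Directed annealing; energy = mse(in-strengths) + mse(out-strengths)."""
    np.random.seed(seed)
    m = eu.shape[0]
    sout = np.zeros(n)
    sin = np.zeros(n)
    for e in range(m):
        sout[eu[e]] += w[e]
        sin[ev[e]] += w[e]
    E = 0.0
    for v in range(n):
        E += (sin[v] - sin_tgt[v]) ** 2 + (sout[v] - sout_tgt[v]) ** 2
    E /= n
    E0 = E
    best_E = E
    stage_E = np.zeros(n_stages)
    stage_acc = np.zeros(n_stages, dtype=np.int64)
    on = np.empty(2, dtype=np.int64)
    od = np.empty(2)
    inn = np.empty(2, dtype=np.int64)
    ind = np.empty(2)
    con = np.empty(2, dtype=np.int64)
    cod = np.empty(2)
    cin = np.empty(2, dtype=np.int64)
    cid = np.empty(2)
    T = T0
    stages_run = 0
    max_drift = 0.0
    for stage in range(n_stages):
        acc = 0
        for _ in range(iters):
            e1 = np.random.randint(m)
            e2 = np.random.randint(m)
            if e1 == e2:
                continue
            delta = w[e2] - w[e1]
            on[0] = eu[e1]
            on[1] = eu[e2]
            od[0] = delta
            od[1] = -delta
            inn[0] = ev[e1]
            inn[1] = ev[e2]
            ind[0] = delta
            ind[1] = -delta
            co = _combine(on, od, con, cod)
            ci = _combine(inn, ind, cin, cid)
            dE = _apply_deltas(sout, sout_tgt, con, cod, co, n)
            dE += _apply_deltas(sin, sin_tgt, cin, cid, ci, n)
            if dE < 0.0 or np.random.random() < np.exp(-dE / T):
                tmp = w[e1]
                w[e1] = w[e2]
                w[e2] = tmp
                for t in range(co):
                    sout[con[t]] += cod[t]
                for t in range(ci):
                    sin[cin[t]] += cid[t]
                E += dE
                acc += 1
        sof = np.zeros(n)
        sif = np.zeros(n)
        for e in range(m):
            sof[eu[e]] += w[e]
            sif[ev[e]] += w[e]
        Ef = 0.0
        for v in range(n):
            Ef += (sif[v] - sin_tgt[v]) ** 2 + (sof[v] - sout_tgt[v]) ** 2
        Ef /= n
        drift = abs(Ef - E)
        if drift > max_drift:
            max_drift = drift
        E = Ef
        sout = sof
        sin = sif
        if E < best_E:
            best_E = E
        stage_E[stage] = E
        stage_acc[stage] = acc
        stages_run = stage + 1
        T *= cooling
        if use_threshold and E <= threshold:
            break
    return stage_E[:stages_run], stage_acc[:stages_run], stages_run, E0, best_E, max_drift


@njit(cache=True)
def sa_dir_alt(rowptr, colw, colv, sin_tgt, n, n_stages, iters, T0, cooling,
               use_threshold, threshold, seed):
    """Directed annealing, out-strength-exact variant.

    Edges are stored in CSR-by-source layout (rowptr into colv/colw).  Each
    iteration picks a node at random (resampling nodes with fewer than two
    outgoing edges) and swaps two of its outgoing weights, so row sums —
    hence out-strengths — never change.  Energy is the in-strength mse only.
    """
    np.random.seed(seed)
    sin = np.zeros(n)
    for u in range(n):
        for p in range(rowptr[u], rowptr[u + 1]):
            sin[colv[p]] += colw[p]
    E = 0.0
    for v in range(n):
        E += (sin[v] - sin_tgt[v]) ** 2
    E /= n
    E0 = E
    best_E = E
    stage_E = np.zeros(n_stages)
    stage_acc = np.zeros(n_stages, dtype=np.int64)
    # bail out if no node has >= 2 outgoing edges
    any_valid = False
    for u in range(n):
        if rowptr[u + 1] - rowptr[u] >= 2:
            any_valid = True
            break
    if not any_valid:
        stage_E[0] = E
        return stage_E[:1], stage_acc[:1], 1, E0, E, 0.0
    T = T0
    stages_run = 0
    max_drift = 0.0
    for stage in range(n_stages):
        acc = 0
        for _ in range(iters):
            u = np.random.randint(n)
            deg = rowptr[u + 1] - rowptr[u]
            while deg < 2:
                u = np.random.randint(n)
                deg = rowptr[u + 1] - rowptr[u]
            p1 = rowptr[u] + np.random.randint(deg)
            p2 = rowptr[u] + np.random.randint(deg)
            if p1 == p2:
                continue
            b = colv[p1]
            d = colv[p2]
            delta = colw[p2] - colw[p1]
            devb = sin[b] - sin_tgt[b]
            devd = sin[d] - sin_tgt[d]
            dE = ((devb + delta) ** 2 - devb**2 + (devd - delta) ** 2 - devd**2) / n
            if dE < 0.0 or np.random.random() < np.exp(-dE / T):
                tmp = colw[p1]
                colw[p1] = colw[p2]
                colw[p2] = tmp
                sin[b] += delta
                sin[d] -= delta
                E += dE
                acc += 1
        sif = np.zeros(n)
        for u in range(n):
            for p in range(rowptr[u], rowptr[u + 1]):
                sif[colv[p]] += colw[p]
        Ef = 0.0
        for v in range(n):
            Ef += (sif[v] - sin_tgt[v]) ** 2
        Ef /= n
        drift = abs(Ef - E)
        if drift > max_drift:
            max_drift = drift
        E = Ef
        sin = sif
        if E < best_E:
            best_E = E
        stage_E[stage] = E
        stage_acc[stage] = acc
        stages_run = stage + 1
        T *= cooling
        if use_threshold and E <= threshold:
            break
    return stage_E[:stages_run], stage_acc[:stages_run], stages_run, E0, best_E, max_drift


@njit(cache=True)
def sa_signed(eu, ev, w, spos_tgt, sneg_tgt, n, n_stages, iters, T0, cooling,
              use_threshold, threshold, seed):
    """Signed undirected annealing; swaps restricted within sign class so the
    positive and negative degree sequences stay exact.  Energy =
    mse(positive strengths) + mse(negative strength magnitudes)."""
    np.random.seed(seed)
    m = eu.shape[0]
    # index edges by sign class
    mp = 0
    for e in range(m):
        if w[e] > 0.0:
            mp += 1
    mn = m - mp
    pidx = np.empty(mp, dtype=np.int64)
    nidx = np.empty(mn, dtype=np.int64)
    kp = 0
    kn = 0
    for e in range(m):
        if w[e] > 0.0:
            pidx[kp] = e
            kp += 1
        else:
            nidx[kn] = e
            kn += 1
    spos = np.zeros(n)
    sneg = np.zeros(n)
    for e in range(m):
        if w[e] > 0.0:
            spos[eu[e]] += w[e]
            spos[ev[e]] += w[e]
        else:
            sneg[eu[e]] -= w[e]
            sneg[ev[e]] -= w[e]
    E = 0.0
    for v in range(n):
        E += (spos[v] - spos_tgt[v]) ** 2 + (sneg[v] - sneg_tgt[v]) ** 2
    E /= n
    E0 = E
    best_E = E
    stage_E = np.zeros(n_stages)
    stage_acc = np.zeros(n_stages, dtype=np.int64)
    nodes4 = np.empty(4, dtype=np.int64)
    del4 = np.empty(4)
    cn = np.empty(4, dtype=np.int64)
    cd = np.empty(4)
    T = T0
    stages_run = 0
    max_drift = 0.0
    for stage in range(n_stages):
        acc = 0
        for _ in range(iters):
            pick = np.random.randint(m)
            if pick < mp:
                if mp < 2:
                    continue
                e1 = pidx[np.random.randint(mp)]
                e2 = pidx[np.random.randint(mp)]
                positive = True
            else:
                if mn < 2:
                    continue
                e1 = nidx[np.random.randint(mn)]
                e2 = nidx[np.random.randint(mn)]
                positive = False
            if e1 == e2:
                continue
            delta = abs(w[e2]) - abs(w[e1])
            nodes4[0] = eu[e1]
            nodes4[1] = ev[e1]
            nodes4[2] = eu[e2]
            nodes4[3] = ev[e2]
            del4[0] = delta
            del4[1] = delta
            del4[2] = -delta
            del4[3] = -delta
            cnt = _combine(nodes4, del4, cn, cd)
            if positive:
                dE = _apply_deltas(spos, spos_tgt, cn, cd, cnt, n)
            else:
                dE = _apply_deltas(sneg, sneg_tgt, cn, cd, cnt, n)
            if dE < 0.0 or np.random.random() < np.exp(-dE / T):
                tmp = w[e1]
                w[e1] = w[e2]
                w[e2] = tmp
                if positive:
                    for t in range(cnt):
                        spos[cn[t]] += cd[t]
                else:
                    for t in range(cnt):
                        sneg[cn[t]] += cd[t]
                E += dE
                acc += 1
        spf = np.zeros(n)
        snf = np.zeros(n)
        for e in range(m):
            if w[e] > 0.0:
                spf[eu[e]] += w[e]
                spf[ev[e]] += w[e]
            else:
                snf[eu[e]] -= w[e]
                snf[ev[e]] -= w[e]
        Ef = 0.0
        for v in range(n):
            Ef += (spf[v] - spos_tgt[v]) ** 2 + (snf[v] - sneg_tgt[v]) ** 2
        Ef /= n
        drift = abs(Ef - E)
        if drift > max_drift:
            max_drift = drift
        E = Ef
        spos = spf
        sneg = snf
        if E < best_E:
            best_E = E
        stage_E[stage] = E
        stage_acc[stage] = acc
        stages_run = stage + 1
        T *= cooling
        if use_threshold and E <= threshold:
            break
    return stage_E[:stages_run], stage_acc[:stages_run], stages_run, E0, best_E, max_drift


# ---------------------------------------------------------------------------
# Rubinov–Sporns rank-matching kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def rubinov_sporns_core(eu, ev, s_tgt, weights_desc, seed):
    """Iterative rank-matched weight reassignment on a fixed edge scaffold.

    At each step the remaining original weights (held sorted descending) and
    the unassigned scaffold edges (ranked by expected magnitude
    e_ij = resid_i * resid_j) are ranked; a random unassigned edge receives
    the original weight of its expected-magnitude rank.  Ties in e_ij are
    broken uniformly at random (equivalent to a random shuffle before a
    stable sort).  Returns the assigned weight per edge.
    """
    np.random.seed(seed)
    m = eu.shape[0]
    resid = s_tgt.copy()
    avail_w = weights_desc.copy()
    n_avail = m
    unassigned = np.arange(m)
    n_un = m
    out = np.zeros(m)
    for _ in range(m):
        pos = np.random.randint(n_un)
        e = unassigned[pos]
        ehat = resid[eu[e]] * resid[ev[e]]
        greater = 0
        ties = 0
        for q in range(n_un):
            f = unassigned[q]
            if f == e:
                continue
            val = resid[eu[f]] * resid[ev[f]]
            if val > ehat:
                greater += 1
            elif val == ehat:
                ties += 1
        rank = greater + np.random.randint(ties + 1)
        wsel = avail_w[rank]
        # remove the selected weight, keeping the array sorted
        for q in range(rank, n_avail - 1):
            avail_w[q] = avail_w[q + 1]
        n_avail -= 1
        out[e] = wsel
        resid[eu[e]] -= wsel
        resid[ev[e]] -= wsel
        unassigned[pos] = unassigned[n_un - 1]
        n_un -= 1
    return out
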