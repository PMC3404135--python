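"""Compiled inner loops shared by the neighborhood machinery and the solvers.

Everything here works on integer-coded windows: ``win`` is a ``(W, l)`` int8
matrix holding every length-l window of every input sequence (sequence j owns
rows ``wstart[j] .. wstart[j] + wcount[j])``, local window index == 0-based
offset), ``elig`` flags windows that are usable (inside the alphabet and, when
the preprocessing filter is on, not filtered out).

Motifs are packed into int64 codes base sigma, position 0 least significant
(matching ``Alphabet.encode_int``).

The tree walkers are iterative (explicit per-level state) versions of the
depth-first traversal of the mutation tree T_d(x): a node is (t, p, depth),
children mutate one position right of p to each non-reference character, so
every member of the Hamming ball B_d(x) is visited exactly once.
"""

import numpy as np
from numba import njit

BIG = 1 << 30
_INF8 = 127


@njit(cache=True)
def _encode(t, sigma):
    code = np.int64(0)
    for j in range(t.shape[0] - 1, -1, -1):
        code = code * sigma + t[j]
    return code


@njit(cache=True)
def _decode(code, sigma, t):
    for j in range(t.shape[0]):
        t[j] = code % sigma
        code //= sigma


@njit(cache=True)
def ball_collect(x, d, sigma, out_codes, out_depths):
    """Depth-first traversal of T_d(x); fills packed codes and tree depths.

    Children are visited in increasing mutated position, then character
    order. Returns the number of nodes visited (== the ball size).
    """
    l = x.shape[0]
    t = x.copy()
    mut_pos = np.full(d + 2, -1, dtype=np.int64)
    npos = np.zeros(d + 3, dtype=np.int64)
    nchar = np.zeros(d + 3, dtype=np.int64)
    cnt = 0
    out_codes[cnt] = _encode(t, sigma)
    out_depths[cnt] = 0
    cnt += 1
    k = 0
    npos[1] = 0
    nchar[1] = 0
    while k >= 0:
        descended = False
        if k < d:
            pos = npos[k + 1]
            ch = nchar[k + 1]
            while pos < l:
                if ch >= sigma:
                    pos += 1
                    ch = 0
                    continue
                if ch == x[pos]:
                    ch += 1
                    continue
                break
            if pos < l:
                mut_pos[k + 1] = pos
                t[pos] = ch
                npos[k + 1] = pos
                nchar[k + 1] = ch + 1
                k += 1
                npos[k + 1] = pos + 1
                nchar[k + 1] = 0
                out_codes[cnt] = _encode(t, sigma)
                out_depths[cnt] = k
                cnt += 1
                descended = True
        if not descended:
            if k > 0:
                t[mut_pos[k]] = x[mut_pos[k]]
            k -= 1
    return cnt


@njit(cache=True)
def three_ball_suffix_dp(c1, c2, c3, start, r1, r2, r3, cur, nxt):
    """Exact emptiness test for the intersection of three Hamming balls.

    Decides whether some string z over positions ``start..len-1`` satisfies
    h(z, c1) <= r1, h(z, c2) <= r2 and h(z, c3) <= r3 simultaneously.
    Dynamic program over positions with state (mismatches to c1, mismatches
    to c2) minimizing mismatches to c3. Only the characters present in a
    column are branched on: any other character costs (1,1,1), which is
    pointwise dominated by copying one of the three centers, so the answer
    is exact for every alphabet size >= 2.

    ``cur``/``nxt`` are caller-provided scratch with shape >= (r1+1, r2+1).
    """
    if r1 < 0 or r2 < 0 or r3 < 0:
        return False
    l = c1.shape[0]
    for i in range(r1 + 1):
        for j in range(r2 + 1):
            cur[i, j] = _INF8
    cur[0, 0] = 0
    for pos in range(start, l):
        a1 = c1[pos]
        a2 = c2[pos]
        a3 = c3[pos]
        for i in range(r1 + 1):
            for j in range(r2 + 1):
                nxt[i, j] = _INF8
        alive = False
        for i in range(r1 + 1):
            for j in range(r2 + 1):
                v = cur[i, j]
                if v >= _INF8:
                    continue
                # copy c1's character
                e2 = 1 if a1 != a2 else 0
                e3 = 1 if a1 != a3 else 0
                if j + e2 <= r2:
                    if v + e3 < nxt[i, j + e2]:
                        nxt[i, j + e2] = v + e3
                    alive = True
                # copy c2's character, when distinct
                if a2 != a1:
                    e3 = 1 if a2 != a3 else 0
                    if i + 1 <= r1:
                        if v + e3 < nxt[i + 1, j]:
                            nxt[i + 1, j] = v + e3
                        alive = True
                # copy c3's character, when distinct from both
                if a3 != a1 and a3 != a2:
                    if i + 1 <= r1 and j + 1 <= r2:
                        if v < nxt[i + 1, j + 1]:
                            nxt[i + 1, j + 1] = v
                        alive = True
        if not alive:
            return False
        tmp = cur
        cur = nxt
        nxt = tmp
    for i in range(r1 + 1):
        for j in range(r2 + 1):
            if cur[i, j] <= r3:
                return True
    return False


@njit(cache=True)
def quorum_mask(cands, win, wstart, wcount, elig, d, q, sigma, l):
    """For each packed candidate code, decide quorum membership (Def-style:
    at least q sequences contain an eligible window within distance d)."""
    M = cands.shape[0]
    n = wstart.shape[0]
    keep = np.zeros(M, dtype=np.uint8)
    t = np.empty(l, dtype=np.int8)
    for mi in range(M):
        _decode(cands[mi], sigma, t)
        cnt = 0
        for j in range(n):
            found = False
            for u in range(wcount[j]):
                w = wstart[j] + u
                if not elig[w]:
                    continue
                mism = 0
                ok = True
                for pos in range(l):
                    if t[pos] != win[w, pos]:
                        mism += 1
                        if mism > d:
                            ok = False
                            break
                if ok:
                    found = True
                    break
            if found:
                cnt += 1
            if cnt + (n - 1 - j) < q:
                break
        if cnt >= q:
            keep[mi] = 1
    return keep


@njit(cache=True)
def best_dists(motifs, win, wstart, wcount, elig):
    """Minimum window distance of each motif row to each sequence (BIG when a
    sequence has no eligible window)."""
    M = motifs.shape[0]
    n = wstart.shape[0]
    l = motifs.shape[1]
    out = np.full((M, n), BIG, dtype=np.int32)
    for mi in range(M):
        for j in range(n):
            best = BIG
            for u in range(wcount[j]):
                w = wstart[j] + u
                if not elig[w]:
                    continue
                mism = 0
                for pos in range(l):
                    if motifs[mi, pos] != win[w, pos]:
                        mism += 1
                        if mism >= best:
                            break
                if mism < best:
                    best = mism
                    if best == 0:
                        break
            out[mi, j] = best
    return out


@njit(cache=True)
def build_pair_dists(win, wstart, wcount, elig, pid, npairs, wm, dcap):
    """Cross-window Hamming distances for every unordered sequence pair.

    D[pid[i, j], u, v] = h(window u of s_i, window v of s_j) when both
    windows are eligible and the distance is <= dcap; 255 otherwise.
    Distances above dcap (= 2d for the callers) are never consulted.
    """
    n = wstart.shape[0]
    l = win.shape[1]
    D = np.full((npairs, wm, wm), 255, dtype=np.uint8)
    for i in range(n):
        for j in range(i + 1, n):
            pidx = pid[i, j]
            for u in range(wcount[i]):
                wu = wstart[i] + u
                if not elig[wu]:
                    continue
                for v in range(wcount[j]):
                    wv = wstart[j] + v
                    if not elig[wv]:
                        continue
                    acc = 0
                    for pos in range(l):
                        if win[wu, pos] != win[wv, pos]:
                            acc += 1
                            if acc > dcap:
                                break
                    if acc <= dcap:
                        D[pidx, u, v] = acc
    return D


@njit(cache=True)
def filter_keep(wstart, wcount, elig, pid, D, dcap, q):
    """Preprocessing filter: keep window u of s_i iff at least q-1 of the
    other sequences contain an eligible window within distance dcap (= 2d)."""
    n = wstart.shape[0]
    keep = np.zeros(elig.shape[0], dtype=np.uint8)
    for i in range(n):
        for u in range(wcount[i]):
            w = wstart[i] + u
            if not elig[w]:
                continue
            cnt = 0
            for j in range(n):
                if j == i:
                    continue
                hit = False
                if i < j:
                    pidx = pid[i, j]
                    for v in range(wcount[j]):
                        if D[pidx, u, v] <= dcap:
                            hit = True
                            break
                else:
                    pidx = pid[j, i]
                    for v in range(wcount[j]):
                        if D[pidx, v, u] <= dcap:
                            hit = True
                            break
                if hit:
                    cnt += 1
            if cnt >= q - 1:
                keep[w] = 1
    return keep


@njit(cache=True)
def _qpmsprune_node(win, x, cumx, surv, sbase, scnt,
                    mut_pos, mut_char, k, d, q, i_pivot, use_lists, stats):
    """Process one node (t, p, depth=k) of T_d(x) for qPMSPrune/qPMSPruneI.

    Computes the motif-emission count (sequences within d) and the
    triangle-inequality pruning count (sequences within 2d - depth), dropping
    surviving windows whose minimal descendant distance exceeds d when
    ``use_lists`` is set. Returns (emit, prune).
    """
    n = scnt.shape[0]
    l = x.shape[0]
    p = mut_pos[k]
    rem = d - k
    n1 = 0
    n2 = 0
    for j in range(n):
        if j == i_pivot:
            continue
        base = sbase[j]
        c = scnt[j]
        best = BIG
        wi = 0
        while wi < c:
            w = surv[base + wi]
            delta = 0
            for m in range(1, k + 1):
                mp = mut_pos[m]
                wc = win[w, mp]
                if wc != mut_char[m]:
                    delta += 1
                if wc != x[mp]:
                    delta -= 1
            dist = cumx[w, l] + delta
            stats[2] += 1
            if use_lists:
                a = cumx[w, p + 1] + delta
                extra = (dist - a) - rem
                if extra < 0:
                    extra = 0
                if a + extra > d:
                    c -= 1
                    surv[base + wi] = surv[base + c]
                    surv[base + c] = w
                    continue
            if dist < best:
                best = dist
            wi += 1
        scnt[j] = c
        if best <= d:
            n1 += 1
        if best <= 2 * d - k:
            n2 += 1
    return n1 >= q - 1, n2 < q - 1


@njit(cache=True)
def qpmsprune_tree(win, wstart, wcount, elig, d, q, sigma,
                   i_pivot, x, use_lists, out_codes, stats):
    """Full depth-first search of T_d(x) for one pivot window x of s_i.

    Emits every visited t that is a motif of the strings excluding s_i
    (count within d >= q-1) into ``out_codes`` (packed). Returns the number
    of emissions, or -1 if ``out_codes`` is too small (caller retries with a
    larger buffer and fresh stats).

    stats: int64[3] = nodes_visited, nodes_pruned, distance_updates.
    """
    n = wstart.shape[0]
    l = x.shape[0]
    W = win.shape[0]

    cumx = np.zeros((W, l + 1), dtype=np.int16)
    for w in range(W):
        acc = 0
        for j in range(l):
            if win[w, j] != x[j]:
                acc += 1
            cumx[w, j + 1] = acc

    surv = np.empty(W, dtype=np.int32)
    sbase = np.empty(n, dtype=np.int32)
    scnt = np.empty(n, dtype=np.int32)
    pos_ = 0
    for j in range(n):
        sbase[j] = pos_
        c = 0
        if j != i_pivot:
            for u in range(wcount[j]):
                w = wstart[j] + u
                if elig[w]:
                    surv[pos_ + c] = w
                    c += 1
        scnt[j] = c
        pos_ += wcount[j]

    snap = np.empty((d + 2, n), dtype=np.int32)
    mut_pos = np.full(d + 2, -1, dtype=np.int64)
    mut_char = np.zeros(d + 2, dtype=np.int8)
    npos = np.zeros(d + 3, dtype=np.int64)
    nchar = np.zeros(d + 3, dtype=np.int64)
    pruned = np.zeros(d + 2, dtype=np.uint8)
    t = x.copy()
    emitted = 0
    cap = out_codes.shape[0]

    k = 0
    stats[0] += 1
    emit, prune = _qpmsprune_node(win, x, cumx, surv, sbase, scnt,
                                  mut_pos, mut_char, 0, d, q, i_pivot,
                                  use_lists, stats)
    if emit:
        if emitted >= cap:
            return -1
        out_codes[emitted] = _encode(t, sigma)
        emitted += 1
    if prune:
        stats[1] += 1
    pruned[0] = 1 if prune else 0
    npos[1] = 0
    nchar[1] = 0
    while k >= 0:
        descended = False
        if k < d and pruned[k] == 0:
            pos = npos[k + 1]
            ch = nchar[k + 1]
            while pos < l:
                if ch >= sigma:
                    pos += 1
                    ch = 0
                    continue
                if ch == x[pos]:
                    ch += 1
                    continue
                break
            if pos < l:
                for j in range(n):
                    snap[k + 1, j] = scnt[j]
                mut_pos[k + 1] = pos
                mut_char[k + 1] = ch
                t[pos] = ch
                npos[k + 1] = pos
                nchar[k + 1] = ch + 1
                k += 1
                npos[k + 1] = pos + 1
                nchar[k + 1] = 0
                stats[0] += 1
                emit, prune = _qpmsprune_node(win, x, cumx, surv, sbase, scnt,
                                              mut_pos, mut_char, k, d, q,
                                              i_pivot, use_lists, stats)
                if emit:
                    if emitted >= cap:
                        return -1
                    out_codes[emitted] = _encode(t, sigma)
                    emitted += 1
                if prune:
                    stats[1] += 1
                pruned[k] = 1 if prune else 0
                descended = True
        if not descended:
            if k > 0:
                t[mut_pos[k]] = x[mut_pos[k]]
                for j in range(n):
                    scnt[j] = snap[k, j]
            k -= 1
    return emitted


@njit(cache=True)
def _qpms7_node(win, x, yrow, cumx, cumxy, hxy, surv, sbase, scnt,
                mut_pos, mut_char, dy_delta, ay, k, d, q, r1, r2,
                stats, dp_cur, dp_nxt):
    """Process one node (t, p, depth=k) of the y-restricted traversal.

    A window w of s_j survives iff the three suffix balls around t (= x on
    the suffix), w and y, with radii d-depth, d-a_w, d-a_y, intersect;
    prefix mismatch budgets already spent make the radii shrink. Returns
    (emit, prune): emit when t is within d of y and >= q-2 non-pivot
    sequences hold a surviving window within d of t; prune when fewer than
    q-2 surviving lists are non-empty.
    """
    n = scnt.shape[0]
    l = x.shape[0]
    p = mut_pos[k]
    rem = d - k
    r3s = d - ay[k]
    n1 = 0
    nonempty = 0
    for j in range(n):
        if j == r1 or j == r2:
            continue
        base = sbase[j]
        c = scnt[j]
        wi = 0
        seq_hit = False
        while wi < c:
            w = surv[base + wi]
            delta = 0
            for m in range(1, k + 1):
                mp = mut_pos[m]
                wc = win[w, mp]
                if wc != mut_char[m]:
                    delta += 1
                if wc != x[mp]:
                    delta -= 1
            stats[2] += 1
            a_w = cumx[w, p + 1] + delta
            r2w = d - a_w
            drop = False
            if r2w < 0:
                drop = True
            else:
                sh_xw = cumx[w, l] - cumx[w, p + 1]
                if sh_xw > rem + r2w:
                    drop = True
                else:
                    sh_wy = 0
                    for pos2 in range(p + 1, l):
                        if win[w, pos2] != yrow[pos2]:
                            sh_wy += 1
                    if sh_wy > r2w + r3s:
                        drop = True
                    elif not three_ball_suffix_dp(x, win[w], yrow, p + 1,
                                                  rem, r2w, r3s,
                                                  dp_cur, dp_nxt):
                        drop = True
            if drop:
                c -= 1
                surv[base + wi] = surv[base + c]
                surv[base + c] = w
                continue
            if cumx[w, l] + delta <= d:
                seq_hit = True
            wi += 1
        scnt[j] = c
        if c > 0:
            nonempty += 1
        if seq_hit:
            n1 += 1
    emit = (hxy + dy_delta[k] <= d) and (n1 >= q - 2)
    prune = nonempty < q - 2
    return emit, prune


@njit(cache=True)
def qpms7_pair(win, wstart, wcount, elig, d, q, sigma,
               r1, r2, a_local, D, pid, out_codes, stats):
    """qPMS7 search for one pivot window x = window a_local of s_r1, against
    every eligible window y of s_r2 with h(x, y) <= 2d.

    For each such y, traverses T_d(x) restricted to nodes whose descendants
    can still reach B_d(y), maintaining per-sequence surviving window lists
    via the exact three-ball emptiness test. Emits motifs of the strings
    excluding s_r1 and s_r2 that are within d of both pivots.

    Returns emission count or -1 on buffer overflow (caller retries with a
    larger buffer and fresh stats). stats as in qpmsprune_tree.
    """
    n = wstart.shape[0]
    xw = wstart[r1] + a_local
    x = win[xw].copy()
    l = x.shape[0]
    W = win.shape[0]

    cumx = np.zeros((W, l + 1), dtype=np.int16)
    for w in range(W):
        acc = 0
        for j in range(l):
            if win[w, j] != x[j]:
                acc += 1
            cumx[w, j + 1] = acc

    dp_cur = np.empty((d + 1, d + 1), dtype=np.int16)
    dp_nxt = np.empty((d + 1, d + 1), dtype=np.int16)
    surv = np.empty(W, dtype=np.int32)
    sbase = np.empty(n, dtype=np.int32)
    pos_ = 0
    for j in range(n):
        sbase[j] = pos_
        pos_ += wcount[j]
    scnt = np.zeros(n, dtype=np.int32)
    snap = np.empty((d + 2, n), dtype=np.int32)
    mut_pos = np.full(d + 2, -1, dtype=np.int64)
    mut_char = np.zeros(d + 2, dtype=np.int8)
    dy_delta = np.zeros(d + 2, dtype=np.int64)
    ay = np.zeros(d + 2, dtype=np.int64)
    npos = np.zeros(d + 3, dtype=np.int64)
    nchar = np.zeros(d + 3, dtype=np.int64)
    pruned = np.zeros(d + 2, dtype=np.uint8)
    cumxy = np.zeros(l + 1, dtype=np.int16)
    t = x.copy()
    emitted = 0
    cap = out_codes.shape[0]
    p12 = pid[r1, r2]

    for b_local in range(wcount[r2]):
        yw = wstart[r2] + b_local
        if not elig[yw]:
            continue
        hxy_u8 = D[p12, a_local, b_local]
        if hxy_u8 > 2 * d:
            continue
        hxy = np.int64(hxy_u8)
        yrow = win[yw]
        acc = 0
        cumxy[0] = 0
        for j in range(l):
            if yrow[j] != x[j]:
                acc += 1
            cumxy[j + 1] = acc

        for j in range(n):
            c = 0
            if j != r1 and j != r2:
                base = sbase[j]
                for u in range(wcount[j]):
                    w = wstart[j] + u
                    if not elig[w]:
                        continue
                    if j < r1:
                        dxw = D[pid[j, r1], u, a_local]
                    else:
                        dxw = D[pid[r1, j], a_local, u]
                    if dxw > 2 * d:
                        continue
                    if j < r2:
                        dyw = D[pid[j, r2], u, b_local]
                    else:
                        dyw = D[pid[r2, j], b_local, u]
                    if dyw > 2 * d:
                        continue
                    surv[base + c] = w
                    c += 1
            scnt[j] = c

        dy_delta[0] = 0
        ay[0] = 0
        k = 0
        stats[0] += 1
        emit, prune = _qpms7_node(win, x, yrow, cumx, cumxy, hxy,
                                  surv, sbase, scnt, mut_pos, mut_char,
                                  dy_delta, ay, 0, d, q, r1, r2,
                                  stats, dp_cur, dp_nxt)
        if emit:
            if emitted >= cap:
                return -1
            out_codes[emitted] = _encode(t, sigma)
            emitted += 1
        if prune:
            stats[1] += 1
        pruned[0] = 1 if prune else 0
        npos[1] = 0
        nchar[1] = 0
        while k >= 0:
            descended = False
            if k < d and pruned[k] == 0:
                pos = npos[k + 1]
                ch = nchar[k + 1]
                found = False
                dnew = np.int64(0)
                while pos < l:
                    if ch >= sigma:
                        pos += 1
                        ch = 0
                        continue
                    if ch == x[pos]:
                        ch += 1
                        continue
                    # candidate child mutates pos -> ch; keep it only if some
                    # descendant can still reach B_d(y)
                    dnew = dy_delta[k]
                    if yrow[pos] != ch:
                        dnew += 1
                    if yrow[pos] != x[pos]:
                        dnew -= 1
                    a_y = cumxy[pos + 1] + dnew
                    b_y = (hxy + dnew) - a_y
                    extra = b_y - (d - (k + 1))
                    if extra < 0:
                        extra = 0
                    if a_y + extra <= d:
                        found = True
                        break
                    stats[1] += 1
                    ch += 1
                if found:
                    for j in range(n):
                        snap[k + 1, j] = scnt[j]
                    mut_pos[k + 1] = pos
                    mut_char[k + 1] = ch
                    dy_delta[k + 1] = dnew
                    ay[k + 1] = cumxy[pos + 1] + dnew
                    t[pos] = ch
                    npos[k + 1] = pos
                    nchar[k + 1] = ch + 1
                    k += 1
                    npos[k + 1] = pos + 1
                    nchar[k + 1] = 0
                    stats[0] += 1
                    emit, prune = _qpms7_node(win, x, yrow, cumx, cumxy, hxy,
                                              surv, sbase, scnt, mut_pos,
                                              mut_char, dy_delta, ay, k, d, q,
                                              r1, r2, stats, dp_cur, dp_nxt)
                    if emit:
                        if emitted >= cap:
                            return -1
                        out_codes[emitted] = _encode(t, sigma)
                        emitted += 1
                    if prune:
                        stats[1] += 1
                    pruned[k] = 1 if prune else 0
                    descended = True
                else:
                    npos[k + 1] = pos
                    nchar[k + 1] = ch
            if not descended:
                if k > 0:
                    t[mut_pos[k]] = x[mut_pos[k]]
                    for j in range(n):
                        scnt[j] = snap[k, j]
                k -= 1
    return emitted
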