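"""Low-level numba kernels for pairwise spike-train computations.

Every kernel takes sorted float64 spike-time arrays.  These are internal:
the public measure API lives in :mod:`spikesync.pairwise` and
:mod:`spikesync.measures`.  Algorithms are O(n) or O(n*k) two-pointer scans
except the Victor–Purpura dynamic program, which is O(na*nb) per timescale.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NB_OPTS = dict(cache=True, nogil=True)


@njit(**NB_OPTS)
def _enforce_refractory_nb(times, t_refr, strict):
    out = np.empty(times.size)
    k = 0
    last = -1e30
    for i in range(times.size):
        d = times[i] - last
        ok = d > t_refr if strict else d >= t_refr
        if ok:
            out[k] = times[i]
            k += 1
            last = times[i]
    return out[:k]


def enforce_refractory(times: np.ndarray, t_refr: float, strict: bool = True) -> np.ndarray:
    """Greedy refractory filter: keep a spike only if it follows the last
    kept spike by more than (``strict``) or at least (``not strict``)
    ``t_refr``.  The earlier spike always wins."""
    times = np.ascontiguousarray(times, dtype=np.float64)
    if times.size == 0 or t_refr <= 0:
        return times.copy() if t_refr <= 0 else times
    return _enforce_refractory_nb(times, t_refr, strict)


@njit(**NB_OPTS)
def vp_multi(a, b, qs):
    """Victor–Purpura edit distance for each shift-cost rate q in ``qs``.

    Costs: insert/delete 1, shift q*|dt|.  Standard O(na*nb) DP with
    two rolling rows."""
    na, nb = a.size, b.size
    out = np.empty(qs.size)
    prev = np.empty(nb + 1)
    cur = np.empty(nb + 1)
    for k in range(qs.size):
        q = qs[k]
        for j in range(nb + 1):
            prev[j] = j
        for i in range(1, na + 1):
            cur[0] = i
            ai = a[i - 1]
            for j in range(1, nb + 1):
                c = prev[j - 1] + q * abs(ai - b[j - 1])
                d = prev[j] + 1.0
                if cur[j - 1] + 1.0 < d:
                    d = cur[j - 1] + 1.0
                cur[j] = c if c < d else d
            tmp = prev
            prev = cur
            cur = tmp
        out[k] = prev[nb]
    return out


@njit(**NB_OPTS)
def _exp_one_sided(a, b, tau):
    """sum over pairs with b_j <= a_i of exp(-(a_i - b_j)/tau)."""
    total = 0.0
    run = 0.0
    t_last = 0.0
    j = 0
    for i in range(a.size):
        while j < b.size and b[j] <= a[i]:
            run = run * np.exp(-(b[j] - t_last) / tau) + 1.0
            t_last = b[j]
            j += 1
        if run > 0.0:
            total += run * np.exp(-(a[i] - t_last) / tau)
    return total


@njit(**NB_OPTS)
def _tie_pairs(a, b):
    """number of index pairs (i, j) with a_i == b_j."""
    i = 0
    j = 0
    ties = 0
    while i < a.size and j < b.size:
        if a[i] < b[j]:
            i += 1
        elif a[i] > b[j]:
            j += 1
        else:
            v = a[i]
            ra = 0
            while i < a.size and a[i] == v:
                ra += 1
                i += 1
            rb = 0
            while j < b.size and b[j] == v:
                rb += 1
                j += 1
            ties += ra * rb
    return ties


@njit(**NB_OPTS)
def exp_sum_multi(a, b, taus):
    """sum_ij exp(-|a_i - b_j|/tau) for each tau (van Rossum inner products)."""
    out = np.empty(taus.size)
    ties = _tie_pairs(a, b)
    for k in range(taus.size):
        out[k] = _exp_one_sided(a, b, taus[k]) + _exp_one_sided(b, a, taus[k]) - ties
    return out


@njit(**NB_OPTS)
def gauss_sum_multi(a, b, sigmas):
    """sum_ij exp(-(a_i - b_j)^2 / (4 sigma^2)) for each sigma.

    Pairs beyond 8 sigma are neglected (relative error < 1e-7)."""
    out = np.zeros(sigmas.size)
    for k in range(sigmas.size):
        sig = sigmas[k]
        cut = 8.0 * sig
        inv = 1.0 / (4.0 * sig * sig)
        lo = 0
        tot = 0.0
        for i in range(a.size):
            ai = a[i]
            while lo < b.size and b[lo] < ai - cut:
                lo += 1
            j = lo
            while j < b.size and b[j] <= ai + cut:
                d = ai - b[j]
                tot += np.exp(-d * d * inv)
                j += 1
        out[k] = tot
    return out


@njit(**NB_OPTS)
def coincidence_multi(a, b, taus):
    """number of pairs with |a_i - b_j| <= tau, for each tau (largest first
    not required; simple rescan per tau)."""
    out = np.zeros(taus.size)
    for k in range(taus.size):
        tau = taus[k]
        lo = 0
        cnt = 0
        for i in range(a.size):
            ai = a[i]
            while lo < b.size and b[lo] < ai - tau:
                lo += 1
            j = lo
            while j < b.size and b[j] <= ai + tau:
                cnt += 1
                j += 1
        out[k] = cnt
    return out


@njit(**NB_OPTS)
def nearest_dists(a, b):
    """for each a_i, the distance to the nearest spike of b (b non-empty)."""
    out = np.empty(a.size)
    j = 0
    for i in range(a.size):
        ai = a[i]
        while j + 1 < b.size and b[j + 1] <= ai:
            j += 1
        d = abs(ai - b[j])
        if j + 1 < b.size:
            d2 = abs(b[j + 1] - ai)
            if d2 < d:
                d = d2
        out[i] = d
    return out


@njit(**NB_OPTS)
def qq_counts_multi(a, b, taus):
    """Event-synchronization counts for each tau.

    Returns (c_ab, c_ba): c_ab counts pairs where a fires shortly after b
    (0 < a_i - b_j <= tau), with ties a_i == b_j counted 1/2 in both."""
    c_ab = np.zeros(taus.size)
    c_ba = np.zeros(taus.size)
    for k in range(taus.size):
        tau = taus[k]
        lo = 0
        for i in range(a.size):
            ai = a[i]
            while lo < b.size and b[lo] < ai - tau:
                lo += 1
            j = lo
            while j < b.size and b[j] <= ai + tau:
                d = ai - b[j]
                if d > 0.0:
                    c_ab[k] += 1.0
                elif d < 0.0:
                    c_ba[k] += 1.0
                else:
                    c_ab[k] += 0.5
                    c_ba[k] += 0.5
                j += 1
    return c_ab, c_ba


@njit(**NB_OPTS)
def _local_isi(x, i, big):
    """min of the ISIs adjacent to spike i of x (big when undefined)."""
    left = x[i] - x[i - 1] if i > 0 else big
    right = x[i + 1] - x[i] if i + 1 < x.size else big
    return left if left < right else right


@njit(**NB_OPTS)
def qq_adaptive_counts(a, b, big):
    """Adaptive-timescale event synchronization counts.

    tau_ij = 0.5 * min of the four ISIs surrounding a_i and b_j; returns
    (c_ab, c_ba) with the same conventions as :func:`qq_counts_multi`."""
    c_ab = 0.0
    c_ba = 0.0
    for i in range(a.size):
        ai = a[i]
        la = _local_isi(a, i, big)
        for j in range(b.size):
            d = ai - b[j]
            if abs(d) > 0.5 * la and abs(d) > 0.5 * _local_isi(b, j, big):
                continue
            tau = 0.5 * min(la, _local_isi(b, j, big))
            if abs(d) > tau:
                continue
            if d > 0.0:
                c_ab += 1.0
            elif d < 0.0:
                c_ba += 1.0
            else:
                c_ab += 0.5
                c_ba += 0.5
    return c_ab, c_ba


@njit(**NB_OPTS)
def spike_sync_counts(a, b, big):
    """SPIKE-synchronization coincidence counts.

    A spike is coincident if some spike of the other train lies strictly
    within tau_ij = 0.5*min of the four surrounding ISIs (ties at distance 0
    count).  Returns (n_coinc_a, n_coinc_b)."""
    ca = 0
    for i in range(a.size):
        la = _local_isi(a, i, big)
        for j in range(b.size):
            d = abs(a[i] - b[j])
            tau = 0.5 * min(la, _local_isi(b, j, big))
            if d < tau or d == 0.0:
                ca += 1
                break
    cb = 0
    for j in range(b.size):
        lb = _local_isi(b, j, big)
        for i in range(a.size):
            d = abs(a[i] - b[j])
            tau = 0.5 * min(lb, _local_isi(a, i, big))
            if d < tau or d == 0.0:
                cb += 1
                break
    return ca, cb


@njit(**NB_OPTS)
def phase_stats(x, y):
    """Phases of x's spikes within y's spike cycles.

    phi_i = 2*pi*(x_i - y_k)/(y_{k+1} - y_k) for y_k <= x_i <= y_{k+1};
    spikes outside [y_0, y_last] are skipped.  Returns
    (sum cos, sum sin, count)."""
    sc = 0.0
    ss = 0.0
    n = 0
    if y.size < 2:
        return sc, ss, n
    j = 0
    for i in range(x.size):
        xi = x[i]
        if xi < y[0] or xi > y[y.size - 1]:
            continue
        while j + 2 < y.size and y[j + 1] <= xi:
            j += 1
        isi = y[j + 1] - y[j]
        if isi <= 0.0:
            continue
        phi = 2.0 * np.pi * (xi - y[j]) / isi
        sc += np.cos(phi)
        ss += np.sin(phi)
        n += 1
    return sc, ss, n


@njit(**NB_OPTS)
def _augment(x, T):
    """Add auxiliary spikes at 0 and T (edge correction for profiles)."""
    pre = 1 if (x.size == 0 or x[0] > 0.0) else 0
    post = 1 if (x.size == 0 or x[x.size - 1] < T) else 0
    out = np.empty(x.size + pre + post)
    if pre:
        out[0] = 0.0
    for i in range(x.size):
        out[pre + i] = x[i]
    if post:
        out[out.size - 1] = T
    return out


@njit(**NB_OPTS)
def isi_distance(a, b, T):
    """Time-averaged ISI-distance |x_isi - y_isi| / max(x_isi, y_isi)."""
    aa = _augment(a, T)
    bb = _augment(b, T)
    ia = 0
    ib = 0
    t = 0.0
    total = 0.0
    while t < T:
        while ia + 2 < aa.size and aa[ia + 1] <= t:
            ia += 1
        while ib + 2 < bb.size and bb[ib + 1] <= t:
            ib += 1
        tn = aa[ia + 1] if aa[ia + 1] < bb[ib + 1] else bb[ib + 1]
        if tn > T:
            tn = T
        if tn <= t:
            tn = t + 1e-12
        xi = aa[ia + 1] - aa[ia]
        yi = bb[ib + 1] - bb[ib]
        mx = xi if xi > yi else yi
        if mx > 0.0:
            total += abs(xi - yi) / mx * (tn - t)
        t = tn
    return total / T


@njit(**NB_OPTS)
def spike_distance(a, b, T):
    """Time-averaged SPIKE-distance profile (piecewise-linear, integrated
    exactly by the trapezoid rule on the merged event breakpoints).

    Auxiliary spikes at 0 and T provide the edge correction."""
    aa = _augment(a, T)
    bb = _augment(b, T)
    da = nearest_dists(aa, bb)  # dist of each aa spike to nearest bb spike
    db = nearest_dists(bb, aa)
    ia = 0
    ib = 0
    t = 0.0
    total = 0.0

    while t < T:
        while ia + 2 < aa.size and aa[ia + 1] <= t:
            ia += 1
        while ib + 2 < bb.size and bb[ib + 1] <= t:
            ib += 1
        tn = aa[ia + 1] if aa[ia + 1] < bb[ib + 1] else bb[ib + 1]
        if tn > T:
            tn = T
        if tn <= t:
            tn = t + 1e-12
        xisi = aa[ia + 1] - aa[ia]
        yisi = bb[ib + 1] - bb[ib]
        misi = 0.5 * (xisi + yisi)
        if misi > 0.0:
            s_tot = 0.0
            for tt in (t, tn):
                sx = (da[ia] * (aa[ia + 1] - tt) + da[ia + 1] * (tt - aa[ia])) / xisi
                sy = (db[ib] * (bb[ib + 1] - tt) + db[ib + 1] * (tt - bb[ib])) / yisi
                s_tot += (sx * yisi + sy * xisi) / (2.0 * misi * misi)
            total += 0.5 * s_tot * (tn - t)
        t = tn
    return total / T


@njit(**NB_OPTS)
def _nearest_dist_at(t, x):
    """distance from time t to the nearest spike of sorted x (x non-empty)."""
    lo = 0
    hi = x.size
    while lo < hi:
        mid = (lo + hi) // 2
        if x[mid] < t:
            lo = mid + 1
        else:
            hi = mid
    d = 1e30
    if lo < x.size:
        d = x[lo] - t
    if lo > 0 and t - x[lo - 1] < d:
        d = t - x[lo - 1]
    return d


@njit(**NB_OPTS)
def modulus_metric(a, b, T):
    """Integral over [0, T] of |d_a(t) - d_b(t)|, d_x = distance to the
    nearest spike of x.  Exact piecewise-linear integration: breakpoints at
    spikes and at midpoints of consecutive spikes, sign crossings handled
    analytically."""
    nb_pts = 2 * a.size + 2 * b.size + 2
    pts = np.empty(nb_pts)
    k = 0
    pts[k] = 0.0
    k += 1
    pts[k] = T
    k += 1
    for i in range(a.size):
        pts[k] = a[i]
        k += 1
        if i + 1 < a.size:
            pts[k] = 0.5 * (a[i] + a[i + 1])
            k += 1
    for i in range(b.size):
        pts[k] = b[i]
        k += 1
        if i + 1 < b.size:
            pts[k] = 0.5 * (b[i] + b[i + 1])
            k += 1
    pts = np.sort(pts[:k])
    total = 0.0
    t1 = -1.0
    h1 = 0.0
    started = False
    for idx in range(pts.size):
        t2 = pts[idx]
        if t2 < 0.0 or t2 > T:
            continue
        h2 = _nearest_dist_at(t2, a) - _nearest_dist_at(t2, b)
        if started and t2 > t1:
            seg = t2 - t1
            if h1 * h2 >= 0.0:
                total += 0.5 * (abs(h1) + abs(h2)) * seg
            else:
                s = seg * abs(h1) / (abs(h1) + abs(h2))
                total += 0.5 * (abs(h1) * s + abs(h2) * (seg - s))
        t1 = t2
        h1 = h2
        started = True
    return total


@njit(**NB_OPTS)
def w1_distance(a, b):
    """1-D Wasserstein distance between the empirical distributions of the
    two spike trains (each spike mass 1/n)."""
    i = 0
    j = 0
    fa = 0.0
    fb = 0.0
    wa = 1.0 / a.size
    wb = 1.0 / b.size
    prev = min(a[0], b[0])
    total = 0.0
    while i < a.size or j < b.size:
        if j >= b.size or (i < a.size and a[i] <= b[j]):
            t = a[i]
            total += abs(fa - fb) * (t - prev)
            fa += wa
            i += 1
        else:
            t = b[j]
            total += abs(fa - fb) * (t - prev)
            fb += wb
            j += 1
        prev = t
    return total


@njit(**NB_OPTS)
def lz_complexity(seq):
    """Lempel–Ziv production complexity of a binary sequence.

    Exhaustive-history parsing: each phrase is the longest prefix of the
    remaining input that already occurs as a substring of the preceding
    history, plus one innovative symbol.  Substring queries run on a suffix
    automaton of the history, extended incrementally, so the parse is O(n).
    With this parser a repeated text adds O(1) phrases, which gives the LZ
    distance its near-zero self-distance.
    """
    n = seq.size
    if n == 0:
        return 0
    max_states = 2 * n + 5
    nxt = np.full((max_states, 2), -1, dtype=np.int64)
    link = np.full(max_states, -1, dtype=np.int64)
    length = np.zeros(max_states, dtype=np.int64)
    size = 1  # state 0 is the root
    last = 0

    phrases = 0
    i = 0
    while i < n:
        # longest prefix of seq[i:] present in the parsed history
        node = 0
        j = i
        while j < n and nxt[node, seq[j]] != -1:
            node = nxt[node, seq[j]]
            j += 1
        end = j + 1 if j < n else n
        phrases += 1
        # extend the automaton with the phrase's symbols
        for k in range(i, end):
            c = seq[k]
            cur = size
            size += 1
            length[cur] = length[last] + 1
            p = last
            while p != -1 and nxt[p, c] == -1:
                nxt[p, c] = cur
                p = link[p]
            if p == -1:
                link[cur] = 0
            else:
                q = nxt[p, c]
                if length[p] + 1 == length[q]:
                    link[cur] = q
                else:
                    clone = size
                    size += 1
                    length[clone] = length[p] + 1
                    nxt[clone, 0] = nxt[q, 0]
                    nxt[clone, 1] = nxt[q, 1]
                    link[clone] = link[q]
                    while p != -1 and nxt[p, c] == q:
                        nxt[p, c] = clone
                        p = link[p]
                    link[q] = clone
                    link[cur] = clone
            last = cur
        i = end
    return phrases


@njit(**NB_OPTS)
def lz_concat_complexity(x, y):
    """LZ production complexity of the concatenation x + y."""
    xy = np.empty(x.size + y.size, dtype=np.int64)
    xy[: x.size] = x
    xy[x.size :] = y
    return lz_complexity(xy)
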