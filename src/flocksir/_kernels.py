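"""Numba kernels for the hot loops.

Everything here operates on plain arrays; the public modules wrap these
in the domain containers. All kernels use the minimum-image convention
in a periodic square box of side L and an inclusive contact range
(distance <= r_int).

RNG streams are passed in as ``numpy.random.Generator`` objects so that
the spatial-noise, infection, and recovery streams stay independent:
the spatial trajectory for a fixed spatial generator is bit-identical
whatever the epidemic parameters consume from their own streams.
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True, inline="always")
def _mod_star(x):
    # wrap into [-pi, pi)
    return x - TWO_PI * math.floor((x + math.pi) / TWO_PI)


@njit(cache=True, inline="always")
def _min_image_1d(d, L):
    return d - L * math.floor(d / L + 0.5)


@njit(cache=True)
def _fill_pairs(L, r_int, m, counts, members, xs, ys, ii, jj):
    """Stencil sweep over the binned cells writing pairs into ii/jj.

    Returns the true pair count, which may exceed the capacity of
    ii/jj; the caller must then retry with bigger buffers. Capacity
    handling lives out here so the hot loops never reallocate.
    """
    r2 = r_int * r_int
    cap = ii.size
    k = 0
    for cx in range(m):
        for cy in range(m):
            c = cx * m + cy
            lo = counts[c]
            hi = counts[c + 1]
            if lo == hi:
                continue
            # pairs inside the cell: raw differences are < cell < L/2,
            # so no periodic image is ever needed here
            for p in range(lo, hi):
                xi_ = xs[p]
                yi_ = ys[p]
                for q in range(p + 1, hi):
                    dx = xi_ - xs[q]
                    dy = yi_ - ys[q]
                    if dx * dx + dy * dy <= r2:
                        if k < cap:
                            a = members[p]
                            b = members[q]
                            if a < b:
                                ii[k] = a
                                jj[k] = b
                            else:
                                ii[k] = b
                                jj[k] = a
                        k += 1
            # the four forward neighbor cells; the periodic shift of a
            # wrapped neighbor is known, so the minimum image reduces
            # to adding a precomputed offset
            for s in range(4):
                if s == 0:
                    nxr, nyr = cx + 1, cy
                elif s == 1:
                    nxr, nyr = cx + 1, cy + 1
                elif s == 2:
                    nxr, nyr = cx, cy + 1
                else:
                    nxr, nyr = cx - 1, cy + 1
                offx = 0.0
                offy = 0.0
                nx = nxr
                ny = nyr
                if nxr < 0:
                    nx = nxr + m
                    offx = L  # neighbor image sits L below: dx = xi - xj + L
                elif nxr >= m:
                    nx = nxr - m
                    offx = -L
                if nyr >= m:
                    ny = nyr - m
                    offy = -L
                c2 = nx * m + ny
                lo2 = counts[c2]
                hi2 = counts[c2 + 1]
                if lo2 == hi2:
                    continue
                for p in range(lo, hi):
                    xi_ = xs[p] + offx
                    yi_ = ys[p] + offy
                    for q in range(lo2, hi2):
                        dx = xi_ - xs[q]
                        if dx > r_int or dx < -r_int:
                            continue
                        dy = yi_ - ys[q]
                        if dx * dx + dy * dy <= r2:
                            if k < cap:
                                a = members[p]
                                b = members[q]
                                if a < b:
                                    ii[k] = a
                                    jj[k] = b
                                else:
                                    ii[k] = b
                                    jj[k] = a
                            k += 1
    return k


@njit(cache=True)
def pair_list(pos, L, r_int):
    """All unordered contact pairs with minimum-image distance <= r_int.

    Cell-list search (cell size >= r_int) visiting each unordered cell
    pair once via a half stencil, when the box holds at least 4x4
    cells; brute force otherwise (a stencil would alias cells through
    the periodic wrap for smaller boxes). Output is set-identical to
    the all-pairs scan; pair order is implementation-defined. Returns
    (ii, jj) with ii < jj elementwise.
    """
    n = pos.shape[0]
    r2 = r_int * r_int
    m = int(L / r_int)
    # cap the grid so the cell count stays O(n): in dilute boxes
    # (L >> r_int sqrt(n)) a finer grid only wastes memory and zeroing
    m_cap = max(4, int(math.sqrt(4.0 * n)) + 1)
    if m > m_cap:
        m = m_cap
    if m < 4:
        cap = 64 + 2 * n
        ii = np.empty(cap, np.int64)
        jj = np.empty(cap, np.int64)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                dx = _min_image_1d(pos[i, 0] - pos[j, 0], L)
                dy = _min_image_1d(pos[i, 1] - pos[j, 1], L)
                if dx * dx + dy * dy <= r2:
                    if k >= cap:
                        cap *= 2
                        ii2 = np.empty(cap, np.int64)
                        jj2 = np.empty(cap, np.int64)
                        ii2[:k] = ii[:k]
                        jj2[:k] = jj[:k]
                        ii = ii2
                        jj = jj2
                    ii[k] = i
                    jj[k] = j
                    k += 1
        return ii[:k].copy(), jj[:k].copy()

    cell = L / m
    ncell = m * m
    cell_of = np.empty(n, np.int64)
    counts = np.zeros(ncell + 1, np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cell)
        cy = int(pos[i, 1] / cell)
        if cx >= m:
            cx = m - 1
        if cy >= m:
            cy = m - 1
        c = cx * m + cy
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    # counting sort of agents by cell, gathering coordinates into
    # cell-contiguous arrays so the stencil loops stream sequentially
    members = np.empty(n, np.int64)
    xs = np.empty(n)
    ys = np.empty(n)
    fill = counts[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        members[fill[c]] = i
        xs[fill[c]] = pos[i, 0]
        ys[fill[c]] = pos[i, 1]
        fill[c] += 1

    cap = 64 + 4 * n
    while True:
        ii = np.empty(cap, np.int64)
        jj = np.empty(cap, np.int64)
        k = _fill_pairs(L, r_int, m, counts, members, xs, ys, ii, jj)
        if k <= cap:
            return ii[:k].copy(), jj[:k].copy()
        cap = k + 64


@njit(cache=True)
def csr_from_pairs(n, ii, jj):
    """Symmetric CSR adjacency (indptr, indices) from an i<j pair list."""
    indptr = np.zeros(n + 1, np.int64)
    for k in range(ii.size):
        indptr[ii[k] + 1] += 1
        indptr[jj[k] + 1] += 1
    for i in range(n):
        indptr[i + 1] += indptr[i]
    indices = np.empty(indptr[n], np.int64)
    fill = indptr[:-1].copy()
    for k in range(ii.size):
        i = ii[k]
        j = jj[k]
        indices[fill[i]] = j
        fill[i] += 1
        indices[fill[j]] = i
        fill[j] += 1
    return indptr, indices


@njit(cache=True)
def largest_component_size(n, ii, jj):
    """Size of the largest connected component (union-find over pairs)."""
    parent = np.arange(n)
    size = np.ones(n, np.int64)
    for k in range(ii.size):
        a = ii[k]
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        b = jj[k]
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        if a != b:
            if size[a] < size[b]:
                a, b = b, a
            parent[b] = a
            size[a] += size[b]
    best = 1
    for i in range(n):
        if parent[i] == i and size[i] > best:
            best = size[i]
    return best


@njit(cache=True)
def polarization(theta):
    sx = 0.0
    sy = 0.0
    for i in range(theta.size):
        sx += math.cos(theta[i])
        sy += math.sin(theta[i])
    return math.hypot(sx, sy) / theta.size


@njit(cache=True)
def spatial_update(pos, theta, indptr, indices, L, v0, r_int, sigma, tau, dt, rng):
    """One synchronous Euler–Maruyama step; returns (new_pos, new_theta).

    Heading: theta += (1/tau) <mod*(theta_j - theta_i)>_{S_i} dt
                      + sigma sqrt(dt) xi,   xi ~ N(0, 1) i.i.d.
    Position: r += (v0 n_hat + F) dt with the soft-core repulsion
    F_i = sum_j ((r_int - |r_ji|)/r_int) r_ji/|r_ji|, r_ji = r_i - r_j.
    All right-hand sides use the pre-step state. Exactly N normals are
    drawn from ``rng`` per call, in agent order.
    """
    n = pos.shape[0]
    new_pos = np.empty_like(pos)
    new_theta = np.empty_like(theta)
    sqdt = math.sqrt(dt)
    xi = rng.standard_normal(n)
    for i in range(n):
        ssum = 0.0
        cnt = 0
        fx = 0.0
        fy = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            ssum += _mod_star(theta[j] - theta[i])
            cnt += 1
            dx = _min_image_1d(pos[i, 0] - pos[j, 0], L)
            dy = _min_image_1d(pos[i, 1] - pos[j, 1], L)
            r = math.sqrt(dx * dx + dy * dy)
            if r > 1e-12:
                f = (r_int - r) / r_int
                fx += f * dx / r
                fy += f * dy / r
            else:
                # coincident particles: random unit direction, magnitude 1
                ang = rng.random() * TWO_PI
                fx += math.cos(ang)
                fy += math.sin(ang)
        align = (ssum / cnt) / tau if cnt > 0 else 0.0
        new_theta[i] = _mod_star(theta[i] + align * dt + sigma * sqdt * xi[i])
        x = pos[i, 0] + (v0 * math.cos(theta[i]) + fx) * dt
        y = pos[i, 1] + (v0 * math.sin(theta[i]) + fy) * dt
        x -= L * math.floor(x / L)
        y -= L * math.floor(y / L)
        new_pos[i, 0] = x
        new_pos[i, 1] = y
    return new_pos, new_theta


@njit(cache=True)
def sir_update(labels, indptr, indices, p_unit, p_rec, rng_inf, rng_rec):
    """One synchronous SIR step on a fixed contact graph, in place.

    ``p_unit = beta_b * dt`` is the per-infected-contact step
    probability; a susceptible with k infected contacts is infected with
    probability min(1, k * p_unit). Each infected recovers with
    probability ``p_rec = gamma * dt``. All transitions are evaluated
    against the pre-step labels and applied simultaneously.

    Returns (n_new_infections, n_new_recoveries, n_strained) where
    n_strained counts susceptibles whose step probability exceeded 0.1
    (the linear sum rule is strained there).
    """
    n = labels.size
    new_inf = 0
    new_rec = 0
    strained = 0
    to_infect = np.zeros(n, np.bool_)
    to_recover = np.zeros(n, np.bool_)
    for i in range(n):
        if labels[i] == 0:
            k = 0
            for p in range(indptr[i], indptr[i + 1]):
                if labels[indices[p]] == 1:
                    k += 1
            if k > 0:
                p_i = k * p_unit
                if p_i > 0.1:
                    strained += 1
                if p_i > 1.0:
                    p_i = 1.0
                if rng_inf.random() < p_i:
                    to_infect[i] = True
    for i in range(n):
        if labels[i] == 1:
            if rng_rec.random() < p_rec:
                to_recover[i] = True
    for i in range(n):
        if to_infect[i]:
            labels[i] = 1
            new_inf += 1
        elif to_recover[i]:
            labels[i] = 2
            new_rec += 1
    return new_inf, new_rec, strained


@njit(cache=True, fastmath=True)
def spatial_update_pairs(pos, theta, ii, jj, L, v0, r_int, sigma, tau, dt, rng):
    """Pair-iteration variant of :func:`spatial_update` (same model).

    Accumulates alignment sums and repulsion forces by iterating the
    contact pairs once, then integrates. Equal to the CSR variant up to
    floating-point summation order. Updates ``pos``/``theta`` in place.
    """
    n = pos.shape[0]
    align_sum = np.zeros(n)
    deg = np.zeros(n, np.int64)
    fx = np.zeros(n)
    fy = np.zeros(n)
    for p in range(ii.size):
        i = ii[p]
        j = jj[p]
        d = theta[j] - theta[i]
        align_sum[i] += _mod_star(d)
        align_sum[j] += _mod_star(-d)
        deg[i] += 1
        deg[j] += 1
        dx = _min_image_1d(pos[i, 0] - pos[j, 0], L)
        dy = _min_image_1d(pos[i, 1] - pos[j, 1], L)
        r = math.sqrt(dx * dx + dy * dy)
        if r > 1e-12:
            f = (r_int - r) / (r_int * r)
            fx[i] += f * dx
            fy[i] += f * dy
            fx[j] -= f * dx
            fy[j] -= f * dy
        else:
            # coincident particles: independent random unit kicks
            a1 = rng.random() * TWO_PI
            fx[i] += math.cos(a1)
            fy[i] += math.sin(a1)
            a2 = rng.random() * TWO_PI
            fx[j] += math.cos(a2)
            fy[j] += math.sin(a2)
    sqdt = math.sqrt(dt)
    xi = rng.standard_normal(n)
    for i in range(n):
        align = (align_sum[i] / deg[i]) / tau if deg[i] > 0 else 0.0
        x = pos[i, 0] + (v0 * math.cos(theta[i]) + fx[i]) * dt
        y = pos[i, 1] + (v0 * math.sin(theta[i]) + fy[i]) * dt
        x -= L * math.floor(x / L)
        y -= L * math.floor(y / L)
        pos[i, 0] = x
        pos[i, 1] = y
        theta[i] = _mod_star(theta[i] + align * dt + sigma * sqdt * xi[i])


@njit(cache=True)
def run_spatial(pos, theta, L, v0, r_int, sigma, tau, dt, n_steps,
                record_every, rng, rec_phi, rec_lam):
    """Integrate spatial dynamics for n_steps, recording Phi and Lambda.

    ``pos``/``theta`` are updated in place. Order parameters are stored
    into ``rec_phi``/``rec_lam`` after every ``record_every``-th step;
    returns the number of records written.
    """
    n = pos.shape[0]
    nrec = 0
    for s in range(n_steps):
        ii, jj = pair_list(pos, L, r_int)
        spatial_update_pairs(pos, theta, ii, jj, L, v0, r_int,
                             sigma, tau, dt, rng)
        if (s + 1) % record_every == 0 and nrec < rec_phi.size:
            rec_phi[nrec] = polarization(theta)
            ii2, jj2 = pair_list(pos, L, r_int)
            rec_lam[nrec] = largest_component_size(n, ii2, jj2) / n
            nrec += 1
    return nrec


@njit(cache=True)
def sir_update_pairs(labels, ii, jj, p_unit, p_rec, rng_inf, rng_rec):
    """Pair-iteration variant of :func:`sir_update`; same semantics."""
    n = labels.size
    k_inf = np.zeros(n, np.int64)
    for p in range(ii.size):
        i = ii[p]
        j = jj[p]
        li = labels[i]
        lj = labels[j]
        if li == 0 and lj == 1:
            k_inf[i] += 1
        elif li == 1 and lj == 0:
            k_inf[j] += 1
    new_inf = 0
    new_rec = 0
    strained = 0
    to_infect = np.zeros(n, np.bool_)
    for i in range(n):
        if labels[i] == 0 and k_inf[i] > 0:
            p_i = k_inf[i] * p_unit
            if p_i > 0.1:
                strained += 1
            if p_i > 1.0:
                p_i = 1.0
            if rng_inf.random() < p_i:
                to_infect[i] = True
    for i in range(n):
        if labels[i] == 1:
            if rng_rec.random() < p_rec:
                labels[i] = 2
                new_rec += 1
    for i in range(n):
        if to_infect[i]:
            labels[i] = 1
            new_inf += 1
    return new_inf, new_rec, strained


@njit(cache=True)
def run_coupled(pos, theta, labels, L, v0, r_int, sigma, tau, dt,
                beta_b, gamma, n_sub, max_steps, record_every,
                rng_sp, rng_inf, rng_rec,
                rec_t, rec_S, rec_I, rec_R, rec_phi, rec_lam, t0):
    """Coupled spatial + SIR integration until absorption or max_steps.

    Each spatial step builds the contact graph from the current
    positions; the SIR transitions are advanced on that graph in
    ``n_sub`` synchronous substeps of length ``dt / n_sub`` (the
    epidemic subclock: with fast contagion rates the per-substep
    probabilities stay small while the graph, which only changes on the
    slower movement timescale, is rebuilt once per spatial step). The
    spatial update uses the same pre-step state. Stops as soon as no
    infected agents remain.

    Returns (n_records, substeps_done, finished, peak_I, n_strained);
    durations are substeps * (dt / n_sub). Records are written at step
    0 and after every ``record_every``-th spatial step, plus a final
    record at the stopping step.
    """
    n = pos.shape[0]
    dt_epi = dt / n_sub
    p_unit = beta_b * dt_epi
    p_rec = gamma * dt_epi
    nI = 0
    nR = 0
    for i in range(n):
        if labels[i] == 1:
            nI += 1
        elif labels[i] == 2:
            nR += 1
    nS = n - nI - nR
    peak_I = nI
    strained_total = 0

    nrec = 0
    rec_t[nrec] = t0
    rec_S[nrec] = nS
    rec_I[nrec] = nI
    rec_R[nrec] = nR
    rec_phi[nrec] = polarization(theta)
    ii0, jj0 = pair_list(pos, L, r_int)
    rec_lam[nrec] = largest_component_size(n, ii0, jj0) / n
    nrec += 1

    steps = 0
    substeps = 0
    finished = nI == 0
    while steps < max_steps and nI > 0:
        ii, jj = pair_list(pos, L, r_int)
        for _ in range(n_sub):
            d_inf, d_rec, strained = sir_update_pairs(
                labels, ii, jj, p_unit, p_rec, rng_inf, rng_rec
            )
            strained_total += strained
            nI += d_inf - d_rec
            nR += d_rec
            nS -= d_inf
            substeps += 1
            if nI > peak_I:
                peak_I = nI
            if nI == 0:
                break
        if nI > 0:
            spatial_update_pairs(pos, theta, ii, jj, L, v0, r_int,
                                 sigma, tau, dt, rng_sp)
        steps += 1
        if nI == 0:
            finished = True
        if ((steps % record_every == 0) or nI == 0) and nrec < rec_t.size:
            rec_t[nrec] = t0 + substeps * dt_epi
            rec_S[nrec] = nS
            rec_I[nrec] = nI
            rec_R[nrec] = nR
            rec_phi[nrec] = polarization(theta)
            ii2, jj2 = pair_list(pos, L, r_int)
            rec_lam[nrec] = largest_component_size(n, ii2, jj2) / n
            nrec += 1
    return nrec, substeps, finished, peak_I, strained_total


@njit(cache=True)
def sir_on_static_graph(labels, indptr, indices, p_unit, p_rec, max_steps,
                        rng_inf, rng_rec):
    """Discrete-time SIR on a frozen graph; returns (steps, final labels kept in place)."""
    nI = 0
    for i in range(labels.size):
        if labels[i] == 1:
            nI += 1
    steps = 0
    while nI > 0 and steps < max_steps:
        d_inf, d_rec, _ = sir_update(labels, indptr, indices, p_unit, p_rec,
                                     rng_inf, rng_rec)
        nI += d_inf - d_rec
        steps += 1
    return steps
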