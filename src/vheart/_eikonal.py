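"""Numba kernels for the anisotropic Eikonal fast-iterative solver.

The local update minimizes, over the face of a tetrahedron opposite the
updated node, the arrival time ``T(p) + sqrt((v-p)^T G (v-p))`` with
linear interpolation of T on the face; G is the inverse squared-speed
tensor of the element.  Vertex / edge / face candidates are all solved in
closed form.
"""

import numpy as np
from numba import njit

INF = np.inf


@njit(cache=True, inline="always")
def _gdot(G, a, b):
    return (a[0] * (G[0, 0] * b[0] + G[0, 1] * b[1] + G[0, 2] * b[2])
            + a[1] * (G[1, 0] * b[0] + G[1, 1] * b[1] + G[1, 2] * b[2])
            + a[2] * (G[2, 0] * b[0] + G[2, 1] * b[1] + G[2, 2] * b[2]))


@njit(cache=True)
def _face_update(v, p0, p1, p2, T0, T1, T2, G):
    """Best arrival at v through the triangle (p0,p1,p2); INF if none."""
    best = INF
    e0 = v - p0
    e1 = v - p1
    e2 = v - p2
    # vertex candidates
    if T0 < INF:
        best = min(best, T0 + np.sqrt(max(_gdot(G, e0, e0), 0.0)))
    if T1 < INF:
        best = min(best, T1 + np.sqrt(max(_gdot(G, e1, e1), 0.0)))
    if T2 < INF:
        best = min(best, T2 + np.sqrt(max(_gdot(G, e2, e2), 0.0)))

    # edge candidates: minimize over x on segment (pa, pb)
    for k in range(3):
        if k == 0:
            pa, pb, Ta, Tb = p0, p1, T0, T1
        elif k == 1:
            pa, pb, Ta, Tb = p0, p2, T0, T2
        else:
            pa, pb, Ta, Tb = p1, p2, T1, T2
        if Ta == INF or Tb == INF:
            continue
        d = pb - pa
        w0 = v - pa
        A = _gdot(G, d, d)
        if A <= 0.0:
            continue
        b0 = _gdot(G, d, w0)
        c0 = _gdot(G, w0, w0)
        dt = Tb - Ta
        denom = 1.0 - dt * dt / A
        disc = c0 - b0 * b0 / A
        if denom <= 1e-14 or disc < 0.0:
            continue
        s = np.sqrt(disc / denom)
        lam = (b0 - dt * s) / A
        if 0.0 <= lam <= 1.0:
            cand = Ta + dt * lam + s
            if cand < best:
                best = cand

    # face interior candidate
    if T0 < INF and T1 < INF and T2 < INF:
        d1 = p1 - p0
        d2 = p2 - p0
        w0 = v - p0
        a11 = _gdot(G, d1, d1)
        a12 = _gdot(G, d1, d2)
        a22 = _gdot(G, d2, d2)
        det = a11 * a22 - a12 * a12
        if det > 1e-14:
            b1 = _gdot(G, d1, w0)
            b2 = _gdot(G, d2, w0)
            c0 = _gdot(G, w0, w0)
            t1 = T1 - T0
            t2 = T2 - T0
            # u = A^-1 b, w = A^-1 t
            u1 = (a22 * b1 - a12 * b2) / det
            u2 = (a11 * b2 - a12 * b1) / det
            q1 = (a22 * t1 - a12 * t2) / det
            q2 = (a11 * t2 - a12 * t1) / det
            denom = 1.0 - (t1 * q1 + t2 * q2)
            disc = c0 - (b1 * u1 + b2 * u2)
            if denom > 1e-14 and disc >= 0.0:
                s = np.sqrt(disc / denom)
                lam1 = u1 - q1 * s
                lam2 = u2 - q2 * s
                if lam1 >= 0.0 and lam2 >= 0.0 and lam1 + lam2 <= 1.0:
                    cand = T0 + t1 * lam1 + t2 * lam2 + s
                    if cand < best:
                        best = cand
    return best


@njit(cache=True)
def _local_solve(i, nodes, elems, Gs, indptr, incel, T):
    best = T[i]
    v = nodes[i]
    for q in range(indptr[i], indptr[i + 1]):
        e = incel[q]
        n0, n1, n2, n3 = elems[e, 0], elems[e, 1], elems[e, 2], elems[e, 3]
        if n0 == i:
            a, b, c = n1, n2, n3
        elif n1 == i:
            a, b, c = n0, n2, n3
        elif n2 == i:
            a, b, c = n0, n1, n3
        else:
            a, b, c = n0, n1, n2
        if T[a] == INF and T[b] == INF and T[c] == INF:
            continue
        cand = _face_update(v, nodes[a], nodes[b], nodes[c],
                            T[a], T[b], T[c], Gs[e])
        if cand < best:
            best = cand
    return best


@njit(cache=True)
def solve_fim(nodes, elems, Gs, indptr, incel, src_idx, src_t, tol):
    """Active-list fast-iterative solve; returns per-node arrival times."""
    n = nodes.shape[0]
    T = np.full(n, INF)
    for k in range(len(src_idx)):
        i = src_idx[k]
        if src_t[k] < T[i]:
            T[i] = src_t[k]

    cap = n + 1
    queue = np.empty(cap, dtype=np.int64)
    in_q = np.zeros(n, dtype=np.uint8)
    head = 0
    tail = 0

    # seed: all neighbors of sources
    for k in range(len(src_idx)):
        i = src_idx[k]
        for q in range(indptr[i], indptr[i + 1]):
            e = incel[q]
            for jj in range(4):
                j = elems[e, jj]
                if in_q[j] == 0 and T[j] == INF:
                    in_q[j] = 1
                    queue[tail] = j
                    tail = (tail + 1) % cap

    while head != tail:
        i = queue[head]
        head = (head + 1) % cap
        in_q[i] = 0
        new = _local_solve(i, nodes, elems, Gs, indptr, incel, T)
        if new < T[i] - tol:
            T[i] = new
            for q in range(indptr[i], indptr[i + 1]):
                e = incel[q]
                for jj in range(4):
                    j = elems[e, jj]
                    if j != i and in_q[j] == 0:
                        in_q[j] = 1
                        queue[tail] = j
                        tail = (tail + 1) % cap
    return T
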