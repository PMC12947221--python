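"""Independent brute-force oracles used to cross-check the package.

Everything here is implemented from first principles with a different
algorithm than the library path it checks (quaternion superposition vs
Kabsch, nested-loop histograms vs vectorized numpy, exhaustive path
enumeration vs Brandes) so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Horn quaternion superposition

def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via the Horn quaternion eigenproblem."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    M = a.T @ b
    sxx, sxy, sxz = M[0]
    syx, syy, syz = M[1]
    szx, szy, szz = M[2]
    K = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    ga = (a ** 2).sum()
    gb = (b ** 2).sum()
    msd = max((ga + gb - 2.0 * lam) / a.shape[0], 0.0)
    return math.sqrt(msd)


# ---------------------------------------------------------------------------
# Histogram entropy / MI with explicit loops

def loop_entropy(series, n_bins, low, high) -> tuple[float, int]:
    """(H bits, occupied bins) with manual bin assignment."""
    width = (high - low) / n_bins
    counts = [0] * n_bins
    for x in series:
        k = int((x - low) / width) if x < high else n_bins - 1
        counts[k] += 1
    n = len(series)
    h = 0.0
    occ = 0
    for c in counts:
        if c:
            occ += 1
            p = c / n
            h -= p * math.log2(p)
    return h, occ


def loop_mi(series_i, series_j, bins_i, low_i, high_i,
            bins_j, low_j, high_j):
    """(MI_obs bits, nb_joint, nb_i, nb_j) with nested loops."""
    wi = (high_i - low_i) / bins_i
    wj = (high_j - low_j) / bins_j
    joint = [[0] * bins_j for _ in range(bins_i)]
    n = len(series_i)
    for x, y in zip(series_i, series_j):
        a = int((x - low_i) / wi) if x < high_i else bins_i - 1
        b = int((y - low_j) / wj) if y < high_j else bins_j - 1
        joint[a][b] += 1
    pi = [sum(row) / n for row in joint]
    pj = [sum(joint[a][b] for a in range(bins_i)) / n for b in range(bins_j)]
    mi = 0.0
    nb = 0
    for a in range(bins_i):
        for b in range(bins_j):
            if joint[a][b]:
                nb += 1
                p = joint[a][b] / n
                mi += p * math.log2(p / (pi[a] * pj[b]))
    nbi = sum(1 for p in pi if p > 0)
    nbj = sum(1 for p in pj if p > 0)
    return mi, nb, nbi, nbj


def loop_categorical_mi(a, b):
    """MI_obs (bits) of two categorical sequences by explicit counting."""
    n = len(a)
    from collections import Counter

    ca, cb, cab = Counter(a), Counter(b), Counter(zip(a, b))
    mi = 0.0
    for (x, y), c in cab.items():
        p = c / n
        mi += p * math.log2(p / ((ca[x] / n) * (cb[y] / n)))
    return mi


def scan_bins(series, rel_tol=0.02, cap=None):
    """Literal ascending scan of the bin-convergence criterion."""
    low, high = min(series), max(series)
    if high == low:
        return 1
    cap = cap or max(2, int(math.sqrt(len(series))))
    n = 2
    while n < cap:
        h_n, _ = loop_entropy(series, n, low, high)
        h_n1, _ = loop_entropy(series, n + 1, low, high)
        if h_n > 0 and (h_n1 - h_n) / h_n <= rel_tol:
            return n
        n += 1
    return cap


# ---------------------------------------------------------------------------
# Graph centralities by exhaustive enumeration

def brute_degree(edges, nodes):
    n = len(nodes)
    deg = {v: 0 for v in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    return {v: (deg[v] / (n - 1) if n > 1 else 0.0) for v in nodes}


def brute_betweenness(edges, nodes):
    """Unnormalized betweenness by enumerating every simple path and
    keeping the shortest ones per (s, t) pair. Exponential; fixtures
    stay at <= 12 nodes."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_paths(s, t):
        paths = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return paths

    cb = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in sp if v in p)
            cb[v] += through / len(sp)
    return cb


# ---------------------------------------------------------------------------
# Misc

def brute_rmsip(U, V, k):
    total = 0.0
    for i in range(k):
        for j in range(k):
            total += float(np.dot(U[:, i], V[:, j])) ** 2
    return math.sqrt(total / k)


def brute_projection(frames_flat, mean_flat, vec):
    out = []
    for f in frames_flat:
        s = 0.0
        for a, b, u in zip(f, mean_flat, vec):
            s += (a - b) * u
        out.append(s)
    return np.array(out)


def binned_gaussian_mi(rho: float, edges_x, edges_y, n_sub: int = 60):
    """Exact MI (bits) of a standard bivariate Gaussian with correlation
    rho AFTER discretization onto the given bin edges, by high-resolution
    numerical integration of the density over every bin rectangle."""
    edges_x = np.asarray(edges_x, float)
    edges_y = np.asarray(edges_y, float)
    nx, ny = edges_x.size - 1, edges_y.size - 1
    det = 1 - rho ** 2
    P = np.zeros((nx, ny))
    for a in range(nx):
        xs = np.linspace(edges_x[a], edges_x[a + 1], n_sub)
        dx = xs[1] - xs[0]
        for b in range(ny):
            ys = np.linspace(edges_y[b], edges_y[b + 1], n_sub)
            dy = ys[1] - ys[0]
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            dens = np.exp(-(X ** 2 - 2 * rho * X * Y + Y ** 2) / (2 * det)) \
                / (2 * np.pi * math.sqrt(det))
            P[a, b] = dens.sum() * dx * dy
    P /= P.sum()
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    nz = P > 0
    return float((P[nz] * np.log2(P[nz] / np.outer(px, py)[nz])).sum())


def gaussian_mi_numeric(rho: float, n_grid: int = 2000, lim: float = 8.0):
    """MI (bits) of a bivariate standard Gaussian with correlation rho,
    by high-resolution numerical integration of the density."""
    x = np.linspace(-lim, lim, n_grid)
    dx = x[1] - x[0]
    X, Y = np.meshgrid(x, x, indexing="ij")
    det = 1 - rho ** 2
    p = np.exp(-(X ** 2 - 2 * rho * X * Y + Y ** 2) / (2 * det)) \
        / (2 * np.pi * math.sqrt(det))
    px = p.sum(axis=1) * dx
    py = p.sum(axis=0) * dx
    nz = p > 1e-300
    integrand = np.where(nz, p * np.log2(
        np.where(nz, p / (px[:, None] * py[None, :] + 1e-300), 1.0)), 0.0)
    return float(integrand.sum() * dx * dx)
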