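"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or generic
numerical optimization, sharing no code path with the implementation it
checks.
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_rmsd(mobile, reference, n_starts=40, seed=0):
    """Minimum RMSD over all proper rotations + translations.

    Parameterizes rotation by a rotation vector and minimizes numerically
    from many random starts; translation handled by centroid alignment.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    am = mobile - mobile.mean(axis=0)
    bm = reference - reference.mean(axis=0)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((am @ r.T - bm) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        x0 = rng.uniform(-np.pi, np.pi, size=3)
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


def exhaustive_gdt_fraction(xm, xr, cutoff):
    """Largest fraction of pairs superposable within ``cutoff``: all subsets.

    Enumerates every subset of size >= 3, superposes on the subset with a
    plain Kabsch (written out here, independent of the package), and accepts
    the subset if all its members land within the cutoff.
    """
    xm = np.asarray(xm, float)
    xr = np.asarray(xr, float)
    n = len(xm)

    def kabsch_fit(idx):
        a = xm[list(idx)]
        b = xr[list(idx)]
        ca, cb = a.mean(0), b.mean(0)
        h = (a - ca).T @ (b - cb)
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        return (xm - ca) @ r.T + cb

    best = 0
    for size in range(n, 2, -1):
        if size <= best:
            break
        for idx in itertools.combinations(range(n), size):
            moved = kabsch_fit(idx)
            dist = np.linalg.norm(moved - xr, axis=1)
            if np.all(dist[list(idx)] <= cutoff):
                best = size
                break
    return best / n


def exhaustive_gdt_ha(xm, xr, cutoffs=(0.5, 1.0, 2.0, 4.0)):
    return 100.0 * np.mean([exhaustive_gdt_fraction(xm, xr, c) for c in cutoffs])


def wilcoxon_enumeration_p(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    diffs = np.asarray([d for d in diffs if d != 0.0], float)
    n = len(diffs)
    absd = np.abs(diffs)
    # mid-ranks with ties
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    srt = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and srt[j + 1] == srt[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_plus = ranks[diffs > 0].sum()
    w_minus = ranks[diffs < 0].sum()
    w = min(w_plus, w_minus)
    total = ranks.sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if wp <= w + 1e-12 or wp >= total - w - 1e-12:
            count += 1
    return min(1.0, count / 2 ** n)
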