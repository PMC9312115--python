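"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own numerical paths: the MESE
oracle sums explicitly rotated isochromats (hard pulses, matrix rotations,
uniform crusher dephasing); the two-component oracle exhaustively searches
a dense (T2_water, fat-fraction) grid; clustering-score oracles evaluate
the contingency/pair-counting definitions directly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def isochromat_mese(t2: float, t1: float, b1: float, protocol,
                    n_iso: int = 2000) -> np.ndarray:
    """Brute-force MESE echo magnitudes from ``n_iso`` dephased isochromats.

    Excitation at the nominal flip about y, refocusing at b1-scaled flip
    about x; each half echo-spacing applies relaxation and a per-isochromat
    precession of 2*pi*i/n_iso (one full crusher cycle per half interval).
    """
    phis = 2.0 * np.pi * np.arange(n_iso) / n_iso
    M = np.zeros((n_iso, 3))
    M[:, 2] = 1.0

    def rot_y(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    def rot_x(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    tau = protocol.echo_spacing / 2.0
    e2, e1 = np.exp(-tau / t2), np.exp(-tau / t1)
    cph, sph = np.cos(phis), np.sin(phis)

    def evolve(M):
        M[:, 0] *= e2
        M[:, 1] *= e2
        M[:, 2] = M[:, 2] * e1 + (1.0 - e1)
        x = M[:, 0] * cph - M[:, 1] * sph
        y = M[:, 0] * sph + M[:, 1] * cph
        M[:, 0], M[:, 1] = x, y
        return M

    M = M @ rot_y(np.deg2rad(protocol.excitation_flip)).T
    R = rot_x(np.deg2rad(protocol.refocusing_flip) * b1)
    out = []
    for _ in range(protocol.n_echoes):
        M = evolve(M)
        M = M @ R.T
        M = evolve(M)
        out.append(abs(np.mean(M[:, 0] + 1j * M[:, 1])))
    return np.array(out)


def two_component_grid_search(signal: np.ndarray, dictionary, b1: float,
                              t2w_range=(15.0, 80.0), t2_fat: float = 150.0,
                              ff_step: float = 0.002) -> float:
    """Exhaustive (T2_water, ff) grid search for the best two-pool fit.

    For every water T2 on the dictionary grid inside ``t2w_range`` and
    every fat fraction on a dense grid, the optimal overall amplitude has a
    closed form; returns the ff of the global least-squares minimum.
    """
    jb = int(dictionary.nearest_b1_index(b1))
    curves = dictionary.unnormalized_curves
    fat = curves[int(dictionary.nearest_t2_index(t2_fat)), jb]
    ffs = np.arange(0.0, 1.0 + ff_step / 2, ff_step)
    best = (np.inf, 0.0)
    for it2 in np.where((dictionary.t2_grid >= t2w_range[0])
                        & (dictionary.t2_grid <= t2w_range[1]))[0]:
        water = curves[it2, jb]
        basis = (1 - ffs)[:, None] * water[None] + ffs[:, None] * fat[None]
        dots = basis @ signal
        nn = (basis ** 2).sum(axis=1)
        amp = np.maximum(dots / nn, 0.0)
        resid = (signal ** 2).sum() - 2 * amp * dots + amp ** 2 * nn
        k = int(np.argmin(resid))
        if resid[k] < best[0]:
            best = (resid[k], float(ffs[k]))
    return best[1]


def entropy(labels) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(a, b) -> float:
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    mi = 0.0
    for ai in np.unique(a):
        for bi in np.unique(b):
            nij = np.sum((a == ai) & (b == bi))
            if nij == 0:
                continue
            pij = nij / n
            mi += pij * math.log(pij / ((np.sum(a == ai) / n)
                                        * (np.sum(b == bi) / n)))
    return mi


def nmi_bruteforce(a, b) -> float:
    """MI normalized by the arithmetic mean of the entropies."""
    ha, hb = entropy(a), entropy(b)
    if ha == 0 and hb == 0:
        return 1.0
    denom = (ha + hb) / 2.0
    if denom == 0:
        return 0.0
    return mutual_information(a, b) / denom


def rand_pairs(a, b):
    """Pair-count agreement: (same-same, diff-diff, total pairs)."""
    a, b = np.asarray(a), np.asarray(b)
    ss = dd = tot = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        tot += 1
        sa, sb = a[i] == a[j], b[i] == b[j]
        if sa and sb:
            ss += 1
        elif (not sa) and (not sb):
            dd += 1
    return ss, dd, tot


def ari_bruteforce(a, b) -> float:
    """ARI from the contingency table via the standard comb2 formula."""
    a, b = np.asarray(a), np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    n = len(a)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = sum(comb2(np.sum((a == i) & (b == j)))
                 for i in ua for j in ub)
    sum_a = sum(comb2(np.sum(a == i)) for i in ua)
    sum_b = sum(comb2(np.sum(b == j)) for j in ub)
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
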