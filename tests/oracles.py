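"""Independent brute-force oracles for the texture-matrix features.

Everything here enumerates voxel pairs, runs, zones and neighbourhoods with
plain Python loops and recomputes each feature from its textbook definition,
deliberately sharing no code with the vectorized implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
DIRS_13 = [d for d in DIRS_26 if d > (0, 0, 0)]


def brute_glcm(levels, mask, ng):
    P = np.zeros((ng, ng))
    idx = list(zip(*np.nonzero(mask)))
    inroi = set(idx)
    for (x, y, z) in idx:
        for d in DIRS_13:
            nb = (x + d[0], y + d[1], z + d[2])
            if nb in inroi:
                P[levels[x, y, z] - 1, levels[nb] - 1] += 1
    P = P + P.T
    tot = P.sum()
    if tot == 0:
        vals, counts = np.unique(levels[mask], return_counts=True)
        modal = int(vals[np.argmax(counts)])  # np.unique sorts, so ties pick smallest
        P[modal - 1, modal - 1] = 1.0
        tot = 1.0
    return P / tot


def brute_glcm_features(levels, mask, ng):
    P = brute_glcm(levels, mask, ng)
    feats = {}
    mu = sum((i + 1) * P[i, :].sum() for i in range(ng))
    var = sum((i + 1 - mu) ** 2 * P[i, :].sum() for i in range(ng))
    energy = contrast = entropy = homog = dissim = autoc = sumavg = cross = 0.0
    for i in range(ng):
        for j in range(ng):
            p = P[i, j]
            energy += p * p
            contrast += (i - j) ** 2 * p
            if p > 0:
                entropy -= p * math.log2(p)
            homog += p / (1 + abs(i - j))
            dissim += abs(i - j) * p
            autoc += (i + 1) * (j + 1) * p
            sumavg += (i + 1 + j + 1) * p
            cross += (i + 1) * (j + 1) * p
    corr = (cross - mu * mu) / var if var > 0 else 0.0
    return {
        "energy": energy,
        "contrast": contrast,
        "entropy": entropy,
        "homogeneity": homog,
        "correlation": corr,
        "sum_average": sumavg,
        "variance": var,
        "dissimilarity": dissim,
        "autocorrelation": autoc,
    }


def brute_runs(levels, mask, ng, max_len):
    """Run-length matrix by walking every line in every direction."""
    R = np.zeros((ng, max_len))
    inroi = set(zip(*np.nonzero(mask)))
    for d in DIRS_13:
        starts = [v for v in inroi if (v[0] - d[0], v[1] - d[1], v[2] - d[2]) not in inroi]
        for start in starts:
            v = start
            run_level, run_len = levels[v], 0
            while v in inroi:
                lv = levels[v]
                if lv == run_level:
                    run_len += 1
                else:
                    R[run_level - 1, run_len - 1] += 1
                    run_level, run_len = lv, 1
                v = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            R[run_level - 1, run_len - 1] += 1
    return R


def brute_zones(levels, mask, ng):
    """Size-zone list by flood fill over the 26-neighbourhood."""
    inroi = set(zip(*np.nonzero(mask)))
    seen = set()
    zones = []
    for v in sorted(inroi):
        if v in seen:
            continue
        lv = levels[v]
        stack, zone = [v], set()
        seen.add(v)
        while stack:
            u = stack.pop()
            zone.add(u)
            for d in DIRS_26:
                w = (u[0] + d[0], u[1] + d[1], u[2] + d[2])
                if w in inroi and w not in seen and levels[w] == lv:
                    seen.add(w)
                    stack.append(w)
        zones.append((int(lv), len(zone)))
    return zones


def brute_rl_features(M, n_vox_weighted, names):
    n_runs = M.sum()
    if n_runs == 0:
        return {n: 0.0 for n in names}
    feats = dict.fromkeys(names, 0.0)
    ni, nl = M.shape
    p = M / n_runs
    mu_i = sum((i + 1) * p[i, :].sum() for i in range(ni))
    mu_l = sum((l + 1) * p[:, l].sum() for l in range(nl))
    for i in range(ni):
        for l in range(nl):
            pp = p[i, l]
            gi, gl = i + 1.0, l + 1.0
            feats[names[0]] += pp / gl**2
            feats[names[1]] += pp * gl**2
            feats[names[5]] += pp / gi**2
            feats[names[6]] += pp * gi**2
            feats[names[7]] += pp / (gi**2 * gl**2)
            feats[names[8]] += pp * gi**2 / gl**2
            feats[names[9]] += pp * gl**2 / gi**2
            feats[names[10]] += pp * gi**2 * gl**2
            feats[names[11]] += pp * (gi - mu_i) ** 2
            feats[names[12]] += pp * (gl - mu_l) ** 2
    feats[names[2]] = sum(M[i, :].sum() ** 2 for i in range(ni)) / n_runs
    feats[names[3]] = sum(M[:, l].sum() ** 2 for l in range(nl)) / n_runs
    feats[names[4]] = n_runs / n_vox_weighted
    return feats


def brute_glrlm_features(levels, mask, ng, names):
    R = brute_runs(levels, mask, ng, max_len=max(mask.shape))
    return brute_rl_features(R, 13.0 * mask.sum(), names)


def brute_glszm_features(levels, mask, ng, names):
    zones = brute_zones(levels, mask, ng)
    max_size = max((s for _, s in zones), default=1)
    S = np.zeros((ng, max_size))
    for lv, s in zones:
        S[lv - 1, s - 1] += 1
    return brute_rl_features(S, float(mask.sum()), names)


def brute_ngtdm_features(levels, mask, ng, cap=1e6):
    inroi = set(zip(*np.nonzero(mask)))
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for v in inroi:
        nbs = []
        for d in DIRS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if w in inroi:
                nbs.append(levels[w])
        if nbs:
            lv = levels[v]
            n_i[lv - 1] += 1
            s_i[lv - 1] += abs(lv - sum(nbs) / len(nbs))
    n = n_i.sum()
    p = n_i / n if n > 0 else n_i
    ps = float((p * s_i).sum())
    coarse = min(1.0 / ps if ps > 0 else cap, cap)
    nzi = [i for i in range(ng) if p[i] > 0]
    ngp = len(nzi)
    if ngp <= 1 or n == 0:
        return {"coarseness": coarse, "contrast": 0.0, "busyness": 0.0, "complexity": 0.0, "strength": 0.0}
    contrast = 0.0
    busy_den = 0.0
    complexity = 0.0
    strength = 0.0
    for i in nzi:
        for j in nzi:
            di = (i + 1) - (j + 1)
            contrast += p[i] * p[j] * di**2
            busy_den += abs((i + 1) * p[i] - (j + 1) * p[j])
            complexity += abs(di) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
            strength += (p[i] + p[j]) * di**2
    contrast *= s_i.sum() / n / (ngp * (ngp - 1))
    busyness = ps / busy_den if busy_den > 0 else 0.0
    complexity /= n
    strength = strength / s_i.sum() if s_i.sum() > 0 else 0.0
    return {
        "coarseness": coarse,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def brute_auc(scores, labels):
    """Concordant-pair enumeration with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def brute_relieff(X, y, k):
    """Plain-loop ReliefF (all instances sampled, ties by index)."""
    X = np.asarray(X, float)
    n, p = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span
    Xs[:, hi == lo] = 0.0
    W = np.zeros(p)
    for i in range(n):
        dists = [(np.sum((Xs[i] - Xs[j]) ** 2), j) for j in range(n) if j != i]
        for same in (True, False):
            pool = sorted((d, j) for d, j in dists if (y[j] == y[i]) == same)
            kk = min(k, len(pool))
            sel = [j for _, j in pool[:kk]]
            md = np.abs(Xs[sel] - Xs[i]).mean(axis=0)
            W += md if not same else -md
    return W / n
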