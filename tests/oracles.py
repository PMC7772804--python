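"""Independent brute-force references used by the tests.

Everything here is deliberately naive and self-contained: plain loops and
counting, no calls into the package under test and no scipy/lifelines/
sklearn statistics, so each oracle is an independent route to the same
quantity.
"""

from __future__ import annotations

import numpy as np


def allpairs_auc(scores, labels) -> float:
    """AUC as the all-pairs win fraction, ties counting one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def hand_km(times, events):
    """Product-limit estimator by direct multiplication.

    Returns (event_times, survival_after_each_event_time).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    s = 1.0
    out_t, out_s = [], []
    for tk in sorted(set(t[e == 1])):
        at_risk = int((t >= tk).sum())
        d = int(((t == tk) & (e == 1)).sum())
        s *= (at_risk - d) / at_risk
        out_t.append(tk)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_chi2(times, events, group1_mask) -> float:
    """Two-group Mantel-Cox chi-square by direct summation over event times."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g1 = np.asarray(group1_mask, dtype=bool)
    U = 0.0
    V = 0.0
    for tk in sorted(set(t[e == 1])):
        risk = t >= tk
        n = int(risk.sum())
        n1 = int((risk & g1).sum())
        d = int(((t == tk) & (e == 1)).sum())
        d1 = int(((t == tk) & (e == 1) & g1).sum())
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0
    return U * U / V


def permutation_logrank(times, events, labels, n_perm, rng):
    """Permutation reference for the two-group log-rank test.

    Recomputes the Mantel-Cox chi-square for ``n_perm`` random relabelings
    (vectorized over permutations) and returns (observed_chi2, p) with
    p = P(chi2_perm >= chi2_obs).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    lab = np.asarray(labels).astype(float)
    tk = np.unique(t[e == 1])
    R = (t[:, None] >= tk[None, :]).astype(float)
    D = ((t[:, None] == tk[None, :]) & (e[:, None] == 1)).astype(float)
    dk = D.sum(axis=0)
    nk = R.sum(axis=0)

    def chi2_of(L):
        N1 = L @ R
        D1 = L @ D
        E1 = dk * N1 / nk
        with np.errstate(invalid="ignore", divide="ignore"):
            V = dk * (N1 / nk) * (1 - N1 / nk) * (nk - dk) / (nk - 1)
        V = np.where(nk > 1, V, 0.0)
        U = (D1 - E1).sum(axis=1)
        var = V.sum(axis=1)
        return np.where(var > 0, U * U / np.maximum(var, 1e-300), 0.0)

    obs = float(chi2_of(lab[None, :])[0])
    # one random permutation of the labels per row
    order = np.argsort(rng.random((n_perm, len(t))), axis=1)
    perms = lab[order]
    stats = chi2_of(perms)
    p = float((stats >= obs - 1e-12).mean())
    return obs, p


def exact_mannwhitney_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of group splits."""
    from itertools import combinations

    pooled = list(x) + list(y)
    nx = len(x)

    def u_of(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1
                elif a == b:
                    u += 0.5
        return u

    obs = u_of(x, y)
    mean_u = nx * len(y) / 2.0
    obs_dev = abs(obs - mean_u)
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, nx):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb]
        if abs(u_of(xs, ys) - mean_u) >= obs_dev - 1e-12:
            count += 1
        total += 1
    return count / total
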