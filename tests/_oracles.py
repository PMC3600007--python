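"""Independent brute-force oracles for the similarity-based statistics.

These deliberately use explicit matrix construction and pair loops, not the
package's algebra, so they can serve as an independent check.
"""

import numpy as np


def mdmr_oracle(K, ypm):
    """Direct evaluation of the 4-step distance-matrix-regression recipe."""
    K = np.asarray(K, float)
    n = K.shape[0]
    Y = np.asarray(ypm, float).reshape(n, 1)
    H = Y @ np.linalg.inv(Y.T @ Y) @ Y.T
    D = np.ones((n, n)) - K
    A = -(D**2) / 2.0
    C = np.eye(n) - np.ones((n, n)) / n
    Gc = C @ A @ C
    I = np.eye(n)
    return np.trace(H @ Gc @ H) / np.trace((I - H) @ Gc @ (I - H))


def skat_oracle(K, y01):
    y01 = np.asarray(y01, float)
    n = y01.size
    ybar = y01.sum() / n
    z = y01 - ybar
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += z[i] * K[i][j] * z[j]
    return total / 2.0


def utest_oracle(K, ypm):
    ypm = np.asarray(ypm, float)
    n = ypm.size
    s1 = s0 = 0.0
    na = int(np.sum(ypm == 1))
    nu = n - na
    for i in range(n):
        for j in range(i + 1, n):
            if ypm[i] == 1 and ypm[j] == 1:
                s1 += K[i][j]
            elif ypm[i] == -1 and ypm[j] == -1:
                s0 += K[i][j]
    u1 = s1 / (na * (na - 1))
    u0 = s0 / (nu * (nu - 1))
    return (u1 - u0) ** 2


def kbat_oracle(Ks, ypm, w=None):
    ypm = np.asarray(ypm, float)
    n = ypm.size
    na = int(np.sum(ypm == 1))
    nu = n - na
    w = [1.0] * len(Ks) if w is None else list(w)
    num = den = 0.0
    for wl, Kl in zip(w, Ks):
        s1 = s0 = 0.0
        pairs1, pairs0 = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if ypm[i] == 1 and ypm[j] == 1:
                    s1 += Kl[i][j]
                    pairs1.append(Kl[i][j])
                elif ypm[i] == -1 and ypm[j] == -1:
                    s0 += Kl[i][j]
                    pairs0.append(Kl[i][j])
        u1 = s1 / (na * (na - 1))
        u0 = s0 / (nu * (nu - 1))
        ul = (u1 + u0) / 2.0
        wss = sum((k - u1) ** 2 for k in pairs1) + sum((k - u0) ** 2 for k in pairs0)
        bss = na * (na - 1) * (ul - u1) ** 2 / 2.0 + nu * (nu - 1) * (ul - u0) ** 2 / 2.0
        num += wl * bss
        den += wl * wss
    return num / den


def cross_pair_dissimilarity_sum(K, y01, squared=False):
    """Sum over case-control pairs of (1 - K) or (1 - K)^2."""
    y01 = np.asarray(y01, float)
    n = y01.size
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if y01[i] != y01[j]:
                d = 1.0 - K[i][j]
                total += d * d if squared else d
    return total


def perm_pvalue_oracle(stat_fn, labels, perms):
    """Add-one permutation p-value over an explicit list of permutations."""
    labels = np.asarray(labels)
    obs = stat_fn(labels)
    exceed = sum(1 for perm in perms if stat_fn(labels[perm]) >= obs)
    return (1.0 + exceed) / (len(perms) + 1.0)
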