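"""Independent reference implementations used as test oracles.

Everything here is deliberately written in plain Python (sets, loops,
fractions of sums), sharing no code with the package, so the two routes can
disagree.
"""

from itertools import permutations

import numpy as np

EPS = 1e-9


def sequence_survivors(M, order, T, weighted):
    """Survivor curve a(p) for an explicit plant removal order.

    Recomputes every pollinator's remaining total from scratch after each
    removal (no incremental bookkeeping).
    """
    A = len(M)
    P = len(M[0])
    W = [[(v if weighted else (1.0 if v > 0 else 0.0)) for v in row] for row in M]
    orig = [sum(row) for row in W]
    alive_a = set(range(A))
    alive_p = set(range(P))
    a_curve = [A]
    for e in order:
        alive_p.remove(e)
        dead = []
        for i in alive_a:
            remaining = sum(W[i][j] for j in alive_p)
            if orig[i] - remaining >= T * orig[i] - EPS:
                dead.append(i)
        alive_a -= set(dead)
        a_curve.append(len(alive_a))
    return a_curve


def sequence_robustness(M, order, T, weighted):
    a = sequence_survivors(M, order, T, weighted)
    return sum(a) / (len(M) * len(M[0]))


def enumerate_so_robustness(M, T, weighted):
    """R for every one of the P! equally likely SO plant sequences."""
    P = len(M[0])
    return [sequence_robustness(M, order, T, weighted) for order in permutations(range(P))]


def brute_nodf(B):
    """NODF via set overlap, separate loops for rows and columns."""
    B = np.asarray(B)

    def pair_sum(vectors):
        sets = [frozenset(np.flatnonzero(v)) for v in vectors]
        total = 0.0
        for i in range(len(sets)):
            for j in range(len(sets)):
                if i == j:
                    continue
                if len(sets[i]) > len(sets[j]) > 0:
                    total += 100.0 * len(sets[i] & sets[j]) / len(sets[j])
        return total

    A, P = B.shape
    npairs = A * (A - 1) / 2 + P * (P - 1) / 2
    return (pair_sum(list(B)) + pair_sum(list(B.T))) / npairs


def brute_skewness(xs):
    """Third standardized moment from the raw definition."""
    xs = list(map(float, xs))
    n = len(xs)
    mean = sum(xs) / n
    m2 = sum((x - mean) ** 2 for x in xs) / n
    m3 = sum((x - mean) ** 3 for x in xs) / n
    return m3 / m2 ** 1.5


def brute_spearman(x, y):
    """Rank (average ties) then Pearson."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def brute_shared_matrix(C):
    """F[e,g] by explicit double loop over plant pairs."""
    C = np.asarray(C)
    A, P = C.shape
    F = np.zeros((P, P), dtype=int)
    for e in range(P):
        for g in range(P):
            if e == g:
                continue
            F[e, g] = sum(1 for i in range(A) if C[i, e] > 0 and C[i, g] > 0)
    return F
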