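"""Independent brute-force reimplementations used as oracles.

Everything here is written with plain Python loops and dictionaries, sharing
no code with the package, so agreement with the package is evidence and not
tautology.
"""

import numpy as np


def brute_score(y, x):
    """Score statistic U²/V for one SNP from first principles."""
    n = len(y)
    ybar = sum(y) / n
    xbar = sum(x) / n
    u = sum((y[i] - ybar) * (x[i] - xbar) for i in range(n))
    v = sum(((y[i] - ybar) * (x[i] - xbar)) ** 2 for i in range(n))
    return 0.0 if v == 0 else u * u / v


def brute_perturbed(y, x, g):
    """Normal-weight perturbed statistic Ũ²/V for one SNP."""
    n = len(y)
    ybar = sum(y) / n
    xbar = sum(x) / n
    contrib = [(y[i] - ybar) * (x[i] - xbar) for i in range(n)]
    v = sum(c * c for c in contrib)
    u = sum(contrib[i] * g[i] for i in range(n))
    return 0.0 if v == 0 else u * u / v


def brute_entropy(case, ctrl):
    """Entropy statistic assembled element by element from cluster counts."""
    case = [float(c) for c in case]
    ctrl = [float(c) for c in ctrl]
    c = len(case)
    if any(x == 0 for x in case + ctrl):
        case = [x + 0.5 for x in case]
        ctrl = [x + 0.5 for x in ctrl]
    na, nu = sum(case), sum(ctrl)
    pa = [x / na for x in case]
    pu = [x / nu for x in ctrl]
    diff = np.array([-p * np.log(p) for p in pa]) - np.array(
        [-p * np.log(p) for p in pu]
    )
    w = np.zeros((c, c))
    for p, n in ((pa, na), (pu, nu)):
        for i in range(c):
            for j in range(c):
                sig = p[i] * (1 - p[i]) if i == j else -p[i] * p[j]
                w[i, j] += (1 + np.log(p[i])) * sig * (1 + np.log(p[j])) / n
    drop = int(np.argmax(np.array(case) + np.array(ctrl)))
    keep = [i for i in range(c) if i != drop]
    wr = w[np.ix_(keep, keep)]
    d = diff[keep]
    return float(d @ np.linalg.solve(wr, d))


def brute_gene_entropy(y, x):
    """Whole entropy pipeline — joint counting, penalized-entropy grouping,
    similarity merging, statistic — rebuilt with dictionaries and loops.

    Returns 0.0 when the data collapse to a single cluster.
    """
    n = len(y)
    counts: dict[tuple, list[int]] = {}
    for i in range(n):
        key = tuple(int(v) for v in x[i])
        counts.setdefault(key, [0, 0])
        if y[i] == 1:
            counts[key][0] += 1
        else:
            counts[key][1] += 1
    # sort: pooled count descending, lexicographic among ties
    cats = sorted(counts, key=lambda k: (-(counts[k][0] + counts[k][1]), k))
    pooled = [counts[k][0] + counts[k][1] for k in cats]
    s = len(cats)
    # penalized entropy curve, base-2 logs, pooled frequencies
    pem_prev = None
    cutoff = s
    acc = 0.0
    for k in range(1, s + 1):
        p = pooled[k - 1] / n
        acc += -p * np.log2(p)
        val = acc - 2 * np.log2(k) / pooled[k - 1]
        if pem_prev is not None and val < pem_prev:
            cutoff = k - 1
            break
        pem_prev = val
    commons = cats[:cutoff]
    if cutoff < 2:
        return 0.0
    case = {c: counts[c][0] for c in commons}
    ctrl = {c: counts[c][1] for c in commons}
    for rare in cats[cutoff:]:
        best, best_sim = None, -1
        for com in commons:  # order = frequency then lexicographic
            sim = sum(a == b for a, b in zip(rare, com))
            if sim > best_sim:
                best, best_sim = com, sim
        case[best] += counts[rare][0]
        ctrl[best] += counts[rare][1]
    return brute_entropy([case[c] for c in commons], [ctrl[c] for c in commons])
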