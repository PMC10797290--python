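"""Brute-force reference implementations, kept deliberately naive.

These recompute each statistic from its definition with plain Python loops
so the vectorized engines can be checked against an independent route.
"""

from itertools import combinations


def average_ranks(values):
    """Ascending ranks, ties get their average rank (1-based)."""
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        eq = sum(1 for u in values if u == v)
        ranks.append(less + (eq + 1) / 2.0)
    return ranks


def descending_positions(values):
    """Stable order of indices from the most to the least expressed."""
    return sorted(range(len(values)), key=lambda i: (-values[i], i))


def ssgsea_oracle(values, genes, gene_set, alpha):
    """Integrated running-sum enrichment score, one position at a time."""
    in_set = [g in set(gene_set) for g in genes]
    n = len(genes)
    n_miss = n - sum(in_set)
    ranks = average_ranks(values)
    denom = sum(ranks[i] ** alpha for i in range(n) if in_set[i])
    es, p_hit, p_miss = 0.0, 0.0, 0.0
    for i in descending_positions(values):
        if in_set[i]:
            p_hit += ranks[i] ** alpha / denom
        else:
            p_miss += 1.0 / n_miss
        es += p_hit - p_miss
    return es


def aucell_oracle(values, genes, gene_set, max_rank_fraction):
    """Recovery step-curve area by explicit cumulative summation."""
    import math

    in_set = [g in set(gene_set) for g in genes]
    n = len(genes)
    k = math.ceil(max_rank_fraction * n)
    m = sum(in_set)
    order = descending_positions(values)
    area, found = 0.0, 0
    for pos in range(k):
        if in_set[order[pos]]:
            found += 1
        area += found
    max_area = sum(min(i + 1, m) for i in range(k))
    return area / max_area


def roc_auc_oracle(scores, labels):
    """All positive-negative pair comparison; ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def c_index_oracle(scores, time, event):
    """All comparable pairs per Harrell's definition."""
    n = len(scores)
    num, den = 0.0, 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = event[i] == 1 and (
                time[i] < time[j] or (time[i] == time[j] and event[j] == 0)
            )
            if not comparable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


def exact_wilcoxon_oracle(xa, xb):
    """Two-sided rank-sum p by enumerating every group assignment."""
    na = len(xa)
    combined = list(xa) + list(xb)
    ranks = average_ranks(combined)
    w_obs = sum(ranks[:na])
    sums = [sum(ranks[i] for i in combo) for combo in combinations(range(len(combined)), na)]
    eps = 1e-9
    p_lo = sum(1 for w in sums if w <= w_obs + eps) / len(sums)
    p_hi = sum(1 for w in sums if w >= w_obs - eps) / len(sums)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def logrank_oracle(time, event, group):
    """Observed-minus-expected log-rank chi-square with hypergeometric
    variance, walked event time by event time."""
    times = sorted({t for t, e in zip(time, event) if e == 1})
    o_minus_e, var = 0.0, 0.0
    for t in times:
        at_risk = [i for i in range(len(time)) if time[i] >= t]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if group[i] == 1)
        d = sum(1 for i in range(len(time)) if time[i] == t and event[i] == 1)
        d1 = sum(1 for i in range(len(time)) if time[i] == t and event[i] == 1 and group[i] == 1)
        if n < 2:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
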