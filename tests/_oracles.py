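"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written as a literal, loop-based transcription of the
definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math


def normal_cdf(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def bh_stepup(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, plain transcription."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    running_min = float("inf")
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = pvals[i] * m / rank_from_end
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj


def mann_whitney_u(x, y):
    """U statistic for x vs y: count of (x_i > y_j) pairs + half-weight ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def auc_pair_count(scores, is_positive):
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), by explicit pair counting."""
    pos = [s for s, p in zip(scores, is_positive) if p]
    neg = [s for s, p in zip(scores, is_positive) if not p]
    return mann_whitney_u(pos, neg) / (len(pos) * len(neg))


def rank_average_ties(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman(x, y):
    return pearson(rank_average_ties(x), rank_average_ties(y))


def welch_t(a, b):
    """Welch t statistic for mean(b) - mean(a)."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    return (mb - ma) / math.sqrt(va / na + vb / nb)


def nearest_tss(peak_start, peak_end, tss_list):
    """All-pairs nearest TSS for one half-open peak interval.

    tss_list: (gene, position) pairs. Returns (gene, distance); ties on
    distance go to the lexicographically smallest gene id.
    """
    best = None
    for gene, pos in tss_list:
        if peak_start <= pos <= peak_end - 1:
            d = 0
        else:
            d = min(abs(pos - peak_start), abs(pos - (peak_end - 1)))
        if best is None or d < best[1] or (d == best[1] and gene < best[0]):
            best = (gene, d)
    return best


def gsea_es(scores_desc, in_set, exponent):
    """Weighted KS enrichment score for a descending ranked list.

    scores_desc: ranking scores in descending order. in_set: parallel bools.
    Returns the walk deviation of maximum magnitude.
    """
    n = len(scores_desc)
    k = sum(in_set)
    denom = sum(abs(s) ** exponent for s, m in zip(scores_desc, in_set) if m)
    running = 0.0
    best = 0.0
    for s, m in zip(scores_desc, in_set):
        if m:
            running += (abs(s) ** exponent / denom) if denom > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


def gsea_exhaustive_p(scores_desc, k, observed_abs_es, exponent):
    """Exact two-sided permutation p over all same-size gene sets."""
    n = len(scores_desc)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n), k):
        mask = [i in combo for i in range(n)]
        es = gsea_es(scores_desc, mask, exponent)
        total += 1
        if abs(es) >= observed_abs_es - 1e-12:
            hits += 1
    return hits / total


def gsva_scores(expr, gene_ids, sample_ids, members, bandwidth_divisor=4.0, tau=1.0):
    """Literal transcription of the single-sample rank-walk scoring recipe.

    expr: nested list, genes x samples. Returns {sample_id: ES}.
    """
    p = len(gene_ids)
    n = len(sample_ids)
    # Gaussian-kernel cross-sample CDF per gene
    z = [[0.0] * n for _ in range(p)]
    for gi in range(p):
        row = expr[gi]
        mean = sum(row) / n
        var = sum((v - mean) ** 2 for v in row) / (n - 1)
        sd = math.sqrt(var)
        if sd == 0:
            continue
        h = sd / bandwidth_divisor
        for j in range(n):
            z[gi][j] = sum(normal_cdf((row[j] - row[k]) / h) for k in range(n)) / n
    member_set = set(members)
    out = {}
    for j, sample in enumerate(sample_ids):
        # decreasing statistic, ties by gene id
        order = sorted(range(p), key=lambda gi: (-z[gi][j], gene_ids[gi]))
        # symmetric rank score: position i (0-based) gets |(p - i) - p/2|
        rank_score = {}
        for i, gi in enumerate(order):
            rank_score[gi] = abs((p - i) - p / 2.0)
        k = sum(1 for gi in range(p) if gene_ids[gi] in member_set)
        denom = sum(rank_score[gi] ** tau for gi in range(p) if gene_ids[gi] in member_set)
        running = 0.0
        max_pos = 0.0
        min_neg = 0.0
        for gi in order:
            if gene_ids[gi] in member_set:
                running += (rank_score[gi] ** tau / denom) if denom > 0 else 1.0 / k
            else:
                running -= 1.0 / (p - k)
            max_pos = max(max_pos, running)
            min_neg = min(min_neg, running)
        out[sample] = max_pos + min_neg
    return out
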