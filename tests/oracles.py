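"""Independent brute-force reference implementations used only by tests.

These are deliberately literal (plain Python loops, textbook formulas)
and share no code with the production paths they check.
"""

from __future__ import annotations

import math


def walk_enrichment(genes, scores, members, weight_p):
    """Literal O(N*m) running-sum walk: returns (es, peak_index, running_sum)."""
    members = set(members)
    n = len(genes)
    n_hits = sum(1 for g in genes if g in members)
    assert 0 < n_hits < n
    nr = sum(abs(s) ** weight_p for g, s in zip(genes, scores) if g in members)
    running = []
    total = 0.0
    for g, s in zip(genes, scores):
        if g in members:
            total += (abs(s) ** weight_p) / nr if nr > 0 else 1.0 / n_hits
        else:
            total -= 1.0 / (n - n_hits)
        running.append(total)
    best = 0
    for i, v in enumerate(running):
        if abs(v) > abs(running[best]):
            best = i
    return running[best], best, running


def walk_leading_edge(genes, members, es, peak_index):
    members = set(members)
    if es >= 0:
        return [g for g in genes[: peak_index + 1] if g in members]
    return [g for g in genes[peak_index:] if g in members]


def pearson_sums(x, y):
    """Textbook sum-based Pearson correlation."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def midranks(values):
    """Average ranks for ties, 1-based."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def set_overlap_score(list_a, list_b, alpha, n_top):
    """Literal set-intersection weighted overlap."""
    total = 0.0
    for n in range(1, n_top + 1):
        top = len(set(list_a[:n]) & set(list_b[:n]))
        bot = len(set(list_a[-n:]) & set(list_b[-n:]))
        total += math.exp(-alpha * n) * (top + bot)
    return total
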