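"""Independent brute-force oracles, kept deliberately naive.

Plain Python loops and set arithmetic, written once and never refactored to
share code with the implementation they check.
"""

from __future__ import annotations

import math


def brute_jaccard_binary(a, b) -> float:
    black_a = {(i, j) for i, row in enumerate(a) for j, v in enumerate(row) if v > 0}
    black_b = {(i, j) for i, row in enumerate(b) for j, v in enumerate(row) if v > 0}
    union = black_a | black_b
    inter = black_a & black_b
    return 1.0 - len(inter) / len(union)


def brute_jaccard_weighted(a, b) -> float:
    num = den = 0
    for ra, rb in zip(a, b):
        for va, vb in zip(ra, rb):
            num += min(va, vb)
            den += max(va, vb)
    return 1.0 - num / den


def brute_chic(a, b) -> float:
    xor_sum = 0
    informative = 0
    for ra, rb in zip(a, b):
        for va, vb in zip(ra, rb):
            xor_sum += abs(va - vb)
            if max(va, vb) > 0:
                informative += 1
    return xor_sum / informative


def brute_l1_half(fa, fb) -> float:
    return 0.5 * sum(abs(x - y) for x, y in zip(fa, fb))


def brute_bray_curtis(u, v) -> float:
    num = sum(abs(x - y) for x, y in zip(u, v))
    den = sum(x + y for x, y in zip(u, v))
    return num / den


def brute_stress1(diss_pairs, dist_pairs) -> float:
    """Kruskal stress-1 by explicit PAVA on (dissimilarity, distance) pairs."""
    order = sorted(range(len(diss_pairs)),
                   key=lambda i: (diss_pairs[i], dist_pairs[i]))
    y = [dist_pairs[i] for i in order]
    # pool adjacent violators
    blocks = [[v, 1] for v in y]  # [mean, weight]
    merged = []
    for b in blocks:
        merged.append(b)
        while len(merged) > 1 and merged[-2][0] > merged[-1][0]:
            m2, m1 = merged.pop(), merged.pop()
            w = m1[1] + m2[1]
            merged.append([(m1[0] * m1[1] + m2[0] * m2[1]) / w, w])
    fitted = []
    for mean, w in merged:
        fitted.extend([mean] * w)
    dhat = [0.0] * len(y)
    for pos, i in enumerate(order):
        dhat[i] = fitted[pos]
    num = sum((d - h) ** 2 for d, h in zip(dist_pairs, dhat))
    den = sum(d ** 2 for d in dist_pairs)
    return math.sqrt(num / den)
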