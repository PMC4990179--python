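"""Independent brute-force re-implementations used as oracles in tests.

Deliberately written as plain Python loops, sharing no code with the
package, so agreement is meaningful.
"""


def bf_ratio_area(p1, p2):
    s1 = 0.0
    s2 = 0.0
    for a in p1:
        s1 += a
    for b in p2:
        s2 += b
    return None if s2 < 1.0 else s1 / s2


def _bf_peak_pos(p):
    m = p[0]
    for v in p:
        if v > m:
            m = v
    ties = [i for i, v in enumerate(p) if v == m]
    ties.sort()
    k = len(ties)
    if k % 2:
        return float(ties[k // 2])
    return (ties[k // 2 - 1] + ties[k // 2]) / 2.0


def bf_diff_pos_max(p1, p2):
    if max(p1) < 1.0 or max(p2) < 1.0:
        return None
    return _bf_peak_pos(p1) - _bf_peak_pos(p2)


def bf_ratio_max_max(p1, p2):
    if max(p2) < 1.0:
        return None
    return max(p1) / max(p2)


def bf_ratio_intersect(p1, p2):
    inter = 0.0
    union = 0.0
    for a, b in zip(p1, p2):
        inter += a if a < b else b
        union += a if a > b else b
    return None if union == 0 else inter / union


def bf_ratio_normalized_intersect(p1, p2):
    m1 = sum(p1) / len(p1)
    m2 = sum(p2) / len(p2)
    if m1 == 0 or m2 == 0:
        return None
    return bf_ratio_intersect([a / m1 for a in p1], [b / m2 for b in p2])


def _bf_ranks(p):
    order = sorted(range(len(p)), key=lambda i: p[i])
    ranks = [0.0] * len(p)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and p[order[j + 1]] == p[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def bf_spearman(p1, p2):
    if min(p1) == max(p1) or min(p2) == max(p2):
        return None
    r1 = _bf_ranks(list(p1))
    r2 = _bf_ranks(list(p2))
    n = len(r1)
    m1 = sum(r1) / n
    m2 = sum(r2) / n
    num = sum((a - m1) * (b - m2) for a, b in zip(r1, r2))
    d1 = sum((a - m1) ** 2 for a in r1) ** 0.5
    d2 = sum((b - m2) ** 2 for b in r2) ** 0.5
    return num / (d1 * d2)


BRUTE_FORCE = {
    "RATIO_AREA": bf_ratio_area,
    "DIFF_POS_MAX": bf_diff_pos_max,
    "RATIO_MAX_MAX": bf_ratio_max_max,
    "RATIO_INTERSECT": bf_ratio_intersect,
    "RATIO_NORMALIZED_INTERSECT": bf_ratio_normalized_intersect,
    "SPEARMAN_CORRELATION": bf_spearman,
}
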