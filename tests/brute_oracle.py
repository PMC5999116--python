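"""Independent brute-force reference for binary edge detection.

Counts the 2x2 contingencies of every ordered pair with explicit Python
loops — no numpy, no shared code with the implementation under test.
"""


def brute_force_pair(codes, i, j):
    """(p11, p00) for columns i, j of a row-major 0/1 matrix; None when the
    conditioning count is zero."""
    n11 = n1 = n00 = n0 = 0
    for row in codes:
        if row[i] == 1:
            n1 += 1
            if row[j] == 1:
                n11 += 1
        else:
            n0 += 1
            if row[j] == 0:
                n00 += 1
    p11 = n11 / n1 if n1 else None
    p00 = n00 / n0 if n0 else None
    return p11, p00


def brute_force_edges(codes, gamma):
    """All ordered pairs (i, j, p11, p00) with both probabilities defined
    and >= gamma, i != j, enumerated by direct loops."""
    L = len(codes[0]) if codes else 0
    edges = []
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            p11, p00 = brute_force_pair(codes, i, j)
            if p11 is None or p00 is None:
                continue
            if p11 >= gamma and p00 >= gamma:
                edges.append((i, j, p11, p00))
    return edges
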