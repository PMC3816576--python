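"""Independent brute-force oracles the implementation is checked against.

Everything here is written naively (explicit loops, full recomputation) and
shares no code with the package, so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

from itertools import combinations


def iota_bruteforce(x, y) -> float:
    """ι(x → y) by naive enumeration of all (i, j) crossing tests."""
    m = len(x)
    order = sorted(range(m), key=lambda i: (x[i], i))  # stable ascending
    yt = [y[i] for i in order]
    crossings = 0
    for i in range(m - 1):
        for j in range(i + 1, m - 1):
            if (yt[j] - yt[i]) * (yt[j + 1] - yt[i]) < 0:
                crossings += 1
    return 1.0 - crossings / ((m - 1) * (m - 2) / 2)


def chi2_2x2_closed_form(a, b, c, d) -> float:
    """Pearson chi-square of [[a, b], [c, d]] via the closed 2x2 formula."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def qt_cluster_bruteforce(dist, diameter, min_size):
    """Exhaustive QT clustering on a full distance matrix.

    Candidate clusters are regrown from every seed with the diameter
    recomputed from scratch over all member pairs at each step; growth adds
    the gene giving the smallest resulting diameter (first in input order on
    ties), the largest candidate wins (earliest seed on ties).  Returns a
    list of clusters (lists of indices); indices in no cluster are
    unassigned.
    """
    n = len(dist)

    def full_diameter(members):
        if len(members) < 2:
            return 0.0
        return max(dist[a][b] for a, b in combinations(members, 2))

    def grow(seed, remaining):
        members = [seed]
        while True:
            best_g, best_nd = None, None
            for g in remaining:
                if g in members:
                    continue
                nd = full_diameter(members + [g])
                if best_nd is None or nd < best_nd - 1e-12:
                    best_g, best_nd = g, nd
            if best_g is None or best_nd > diameter + 1e-12:
                return members
            members.append(best_g)

    clusters = []
    remaining = list(range(n))
    while remaining:
        candidates = [grow(seed, remaining) for seed in remaining]
        best = max(candidates, key=len)  # max() keeps the earliest seed on ties
        if len(best) < min_size:
            break
        clusters.append(sorted(best))
        remaining = [g for g in remaining if g not in best]
    return clusters


def scan_motif_bruteforce(seq, pattern):
    """Offsets of IUPAC pattern matches by per-position set membership."""
    codes = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    seq = seq.upper()
    pattern = pattern.upper()
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + j] in codes[pattern[j]] for j in range(len(pattern))):
            hits.append(i)
    return hits
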