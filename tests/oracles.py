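"""Independent reference implementations used only to check the package.

These deliberately share no code with taxonscrub: the distance is a full
uncapped dynamic-programming matrix, and the brute-force matcher is written
directly from the matching contract (scan everything, filter, sort).
"""

from __future__ import annotations

import unicodedata


def osa_distance(a: str, b: str) -> int:
    """Optimal string alignment distance, full uncapped DP matrix."""
    la, lb = len(a), len(b)
    d = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        d[i][0] = i
    for j in range(lb + 1):
        d[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[la][lb]


def _norm(s: str, fold: bool) -> str:
    s = unicodedata.normalize("NFC", s)
    s = " ".join(s.split())
    return s.casefold() if fold else s


def brute_force_candidates(query: str, ranks: set[str], records,
                           max_dist: int, threshold: float, fold: bool,
                           all_matches: bool):
    """Uncapped scan over ``records`` (objects with canonical_name, rank,
    taxon_id), filtered and ordered per the matching contract.

    Returns a list of (taxon_id, distance, similarity).
    """
    q = _norm(query, fold)
    kept = []
    for rec in records:
        if rec.rank not in ranks:
            continue
        t = _norm(rec.canonical_name, fold)
        dist = osa_distance(q, t)
        if dist == 0 or dist > max_dist:
            continue
        sim = 1.0 - dist / max(len(q), len(t))
        if sim >= threshold:
            kept.append((rec, dist, sim))
    kept.sort(key=lambda x: (-x[2], x[1], x[0].canonical_name, x[0].taxon_id))
    if not all_matches:
        kept = kept[:1]
    return [(rec.taxon_id, dist, sim) for rec, dist, sim in kept]
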