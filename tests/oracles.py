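"""Independent reference implementations used only by the test suite.

Each oracle is a literal, separately coded transcription of the quantity it
checks, deliberately structured differently from the package code path:
the cosine oracle materializes explicit union-vocabulary vectors, the I-Sub
oracle uses a dynamic-programming substring table, and the local-query
oracle is a naive triple scan that never touches SPARQL.
"""

from __future__ import annotations

import numpy as np
from rdflib.namespace import RDF


def cosine_oracle(w1: dict, w2: dict) -> float:
    """Brute-force cosine: explicit vectors over the union vocabulary."""
    if not w1 or not w2:
        return 0.0
    vocab = sorted(set(w1) | set(w2))
    v1 = np.array([w1.get(t, 0.0) for t in vocab])
    v2 = np.array([w2.get(t, 0.0) for t in vocab])
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return float(v1 @ v2 / (n1 * n2))


def _dp_longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """(length, start_a, start_b) of the longest common substring.

    DP over suffix lengths; ties resolved to the earliest start in ``a``,
    then the earliest start in ``b``.
    """
    if not a or not b:
        return 0, 0, 0
    la, lb = len(a), len(b)
    table = np.zeros((la + 1, lb + 1), dtype=int)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            if a[i - 1] == b[j - 1]:
                table[i, j] = table[i - 1, j - 1] + 1
    best = int(table.max())
    if best == 0:
        return 0, 0, 0
    ends = np.argwhere(table == best)
    # argwhere is sorted by end position; for fixed length that is also
    # sorted by start position
    i_end, j_end = (int(x) for x in ends[0])
    return best, i_end - best, j_end - best


def isub_oracle(s1: str, s2: str, *, diff_weight: float = 0.6,
                winkler_scale: float = 0.1, max_prefix: int = 4,
                min_substring: int = 2) -> float:
    """Independent transcription of the I-Sub string similarity.

    Comm − Diff + Winkler over case-folded strings; commonality from
    iterative removal of maximal common substrings (of at least
    ``min_substring`` characters); difference discounts the unmatched
    fractions with weight ``diff_weight``; Winkler adds a bonus for a
    common prefix of up to ``max_prefix`` characters; result clamped to
    [0, 1].
    """
    s1, s2 = s1.lower(), s2.lower()
    if not s1 or not s2:
        return 0.0
    if s1 == s2:
        return 1.0
    if s2 < s1:  # canonical order, mirroring the symmetry convention
        s1, s2 = s2, s1
    l1, l2 = len(s1), len(s2)
    a, b = s1, s2
    total = 0
    while True:
        length, i, j = _dp_longest_common_substring(a, b)
        if length < min_substring:
            break
        total += length
        a = a[:i] + a[i + length:]
        b = b[:j] + b[j + length:]
    comm = 2.0 * total / (l1 + l2)
    u1 = (l1 - total) / l1
    u2 = (l2 - total) / l2
    diff = (u1 * u2) / (diff_weight + (1.0 - diff_weight) * (u1 + u2 - u1 * u2))
    prefix = 0
    while prefix < min(l1, l2, max_prefix) and s1[prefix] == s2[prefix]:
        prefix += 1
    winkler = winkler_scale * prefix * (1.0 - comm)
    return float(np.clip(comm - diff + winkler, 0.0, 1.0))


def naive_local_query(lq, dg, text_properties) -> set:
    """Evaluate a LocalQuery by scanning triples, never via SPARQL."""
    g = dg.graph
    text_props = set(text_properties)
    out = set()
    for s in set(g.subjects()):
        if lq.class_pattern is not None and (s, RDF.type, lq.class_pattern) not in g:
            continue
        if lq.property_pattern is not None:
            if next(g.objects(s, lq.property_pattern), None) is None:
                continue
        if lq.keywords:
            texts = [str(o).lower() for p, o in g.predicate_objects(s)
                     if p in text_props]
            if not any(kw.lower() in t for kw in lq.keywords for t in texts):
                continue
        out.add(s)
    return out
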