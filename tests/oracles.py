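"""Independent brute-force oracles used by the test suite."""

import numpy as np


def brute_force_complex_clusters(calls, gap=10):
    """Transitive-closure clustering of calls by reference gap.

    Union-find over *all* pairs on the same chromosome whose intervening
    reference gap is < ``gap`` (independent of the sweep-line chaining in
    the implementation).  Returns a list of clusters (lists of calls).
    """
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = calls[i], calls[j]
            if a.chrom != b.chrom:
                continue
            if a.start > b.start:
                a, b = b, a
            gap_ij = b.start - a.end - 1
            if gap_ij < gap:
                union(i, j)

    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(calls[i])
    return list(clusters.values())


def expected_merge_signature(calls, gap=10, min_members=2):
    """Expected (category-agnostic) event signature set for merge_complex.

    Clusters of >= min_members with uniform zygosity become one complex
    span; every other call stays a singleton.  Signatures are
    (chrom, start, end, n_members, zygosity) tuples.
    """
    signature = set()
    for cluster in brute_force_complex_clusters(calls, gap=gap):
        zygs = {c.zygosity for c in cluster}
        if len(cluster) >= min_members and len(zygs) == 1:
            signature.add((
                cluster[0].chrom,
                min(c.start for c in cluster),
                max(c.end for c in cluster),
                len(cluster),
                cluster[0].zygosity,
            ))
        else:
            for c in cluster:
                signature.add((c.chrom, c.start, c.end, 1, c.zygosity))
    return signature


def pearson_chisq_2x2(table):
    """Textbook Pearson chi-squared on a 2x2 table: sum (O-E)^2 / E."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
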