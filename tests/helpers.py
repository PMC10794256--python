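"""Independent oracles used by the tests.

These deliberately avoid the implementation code paths they check:
alignment scores come from exhaustive enumeration of monotone matchings,
clustering from a hand-written union-find.
"""

from itertools import combinations


def enumerate_matchings(la: int, lb: int):
    """All monotone matchings between positions 0..la-1 and 0..lb-1."""
    for k in range(min(la, lb) + 1):
        for ia in combinations(range(la), k):
            for ib in combinations(range(lb), k):
                yield list(zip(ia, ib))


def brute_force_alignment_score(tokens_a, tokens_b, score_fn, gap_cost=0.0):
    """Best global alignment score by exhaustive enumeration.

    With linear gap cost, every alignment is a monotone matching plus
    gaps for the unmatched positions; the score is the sum of matched
    pair scores minus gap_cost per unmatched position.
    """
    la, lb = len(tokens_a), len(tokens_b)
    best = float("-inf")
    for matching in enumerate_matchings(la, lb):
        gaps = (la - len(matching)) + (lb - len(matching))
        s = sum(score_fn(tokens_a[i], tokens_b[j]) for i, j in matching)
        best = max(best, s - gap_cost * gaps)
    return best


def brute_force_coemission(cols_a, cols_b, column_score_fn, gap_cost=0.0):
    """raw_coemission oracle: enumerate monotone column matchings, floor 0."""
    best = brute_force_alignment_score(
        list(range(len(cols_a))),
        list(range(len(cols_b))),
        lambda i, j: column_score_fn(cols_a[i], cols_b[j]),
        gap_cost=gap_cost,
    )
    return max(best, 0.0)


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self):
        comps = {}
        for x in self.parent:
            comps.setdefault(self.find(x), set()).add(x)
        return {frozenset(c) for c in comps.values()}


def union_find_clusters(ids, edges):
    """Single-linkage clusters from explicit edges (independent oracle)."""
    uf = UnionFind(ids)
    for a, b in edges:
        uf.union(a, b)
    return uf.components()
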