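"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the aligner oracle is a
plain Gotoh dynamic program, the clustering oracle is single-linkage over an
all-pairs identity matrix, and the rank-test oracle computes the
tie-corrected Kruskal–Wallis statistic from first principles.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN_TOTAL = 12  # first gap residue: open 11 + extend 1
GAP_EXTEND = 1


def smith_waterman_score(a: str, b: str) -> float:
    """Brute-force affine-gap local alignment optimum (Gotoh recurrences)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(
                max(M[i - 1][j], Iy[i - 1][j]) - GAP_OPEN_TOTAL,
                Ix[i - 1][j] - GAP_EXTEND,
            )
            Iy[i][j] = max(
                max(M[i][j - 1], Ix[i][j - 1]) - GAP_OPEN_TOTAL,
                Iy[i][j - 1] - GAP_EXTEND,
            )
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s)
            best = max(best, M[i][j])
    return best


def single_linkage_families(
    proteins: list[tuple[str, str, str]],
    identity_fn,
    identity_threshold: float = 95.0,
    min_coverage: float = 0.80,
) -> set[frozenset[str]]:
    """Connected components of the pairwise >=threshold identity graph."""
    ids = [f"{g}|{p}" for g, p, _ in proteins]
    adjacency = defaultdict(set)
    for (i, (_, _, seq_a)), (j, (_, _, seq_b)) in itertools.combinations(
        enumerate(proteins), 2
    ):
        identity, coverage = identity_fn(seq_a, seq_b)
        if identity >= identity_threshold and coverage >= min_coverage:
            adjacency[ids[i]].add(ids[j])
            adjacency[ids[j]].add(ids[i])
    seen: set[str] = set()
    components: set[frozenset[str]] = set()
    for node in ids:
        if node in seen:
            continue
        stack, component = [node], set()
        while stack:
            current = stack.pop()
            if current in component:
                continue
            component.add(current)
            stack.extend(adjacency[current] - component)
        seen |= component
        components.add(frozenset(component))
    return components


def overlap_components(spans: list[tuple[int, int]], min_fraction: float = 0.5) -> list[set[int]]:
    """All-pairs overlap graph components (>50% of the shorter span)."""
    adjacency = defaultdict(set)
    for i, j in itertools.combinations(range(len(spans)), 2):
        (a1, a2), (b1, b2) = spans[i], spans[j]
        overlap = min(a2, b2) - max(a1, b1) + 1
        shorter = min(a2 - a1 + 1, b2 - b1 + 1)
        if overlap > min_fraction * shorter:
            adjacency[i].add(j)
            adjacency[j].add(i)
    seen: set[int] = set()
    components = []
    for node in range(len(spans)):
        if node in seen:
            continue
        stack, component = [node], set()
        while stack:
            current = stack.pop()
            if current in component:
                continue
            component.add(current)
            stack.extend(adjacency[current] - component)
        seen |= component
        components.append(component)
    return components


def kruskal_wallis_h(groups: list[list[float]]) -> float:
    """Tie-corrected Kruskal–Wallis H computed from hand-assigned ranks."""
    pooled = sorted(
        (value, gi) for gi, group in enumerate(groups) for value in group
    )
    n = len(pooled)
    ranks: dict[int, list[float]] = defaultdict(list)
    i = 0
    tie_term = 0.0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        mean_rank = (i + 1 + j) / 2  # average of ranks i+1 .. j
        t = j - i
        tie_term += t**3 - t
        for k in range(i, j):
            ranks[pooled[k][1]].append(mean_rank)
        i = j
    h = 12.0 / (n * (n + 1)) * sum(
        len(r) * (sum(r) / len(r)) ** 2 for r in ranks.values()
    ) - 3 * (n + 1)
    correction = 1 - tie_term / (n**3 - n)
    return h / correction
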