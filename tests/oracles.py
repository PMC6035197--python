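"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit path enumeration,
exhaustive draws, closed-form arithmetic — and shares no code with the
package's computation paths.
"""

from __future__ import annotations

import itertools
import math
from math import comb
from typing import Dict, List


def all_simple_paths(adj: Dict[str, set], s: str, t: str) -> List[List[str]]:
    """Every simple path from s to t by depth-first enumeration."""
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(path)
            return
        for nb in adj[node]:
            if nb not in path:
                walk(nb, path + [nb])

    walk(s, [s])
    return paths


def brute_betweenness(adj: Dict[str, set], w: str, ordered: bool = True) -> float:
    """C_b(w) by enumerating all shortest paths between all pairs."""
    nodes = [n for n in adj if n != w]
    total = 0.0
    for i, j in itertools.permutations(nodes, 2):
        paths = all_simple_paths(adj, i, j)
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        through = [p for p in shortest if w in p[1:-1]]
        total += len(through) / len(shortest)
    return total if ordered else total / 2.0


def brute_clustering(adj: Dict[str, set], i: str) -> float:
    """C_i by counting connected neighbor pairs directly."""
    nbrs = sorted(adj[i])
    k = len(nbrs)
    if k < 2:
        return 0.0
    e = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
    return 2.0 * e / (k * (k - 1))


def brute_pearson(xs, ys) -> float:
    """Pearson r from the definition, no library calls."""
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)


def brute_term_score(
    parents: Dict[str, set],
    gp: Dict[str, int],
    g: str,
    alpha: float,
    include_self: bool = True,
) -> float:
    """score(g) by explicit enumeration of all upward is_a paths.

    For each term, enumerate every parent-chain to g and take the shortest;
    sum gp * alpha^dist over terms that reach g.
    """

    def paths_up(t):
        if t == g:
            return [[t]]
        out = []
        for p in parents.get(t, ()):
            for path in paths_up(p):
                out.append([t] + path)
        return out

    total = 0.0
    for t, n in gp.items():
        if n == 0:
            continue
        up = paths_up(t)
        if not up:
            continue
        d = min(len(p) - 1 for p in up)
        if d == 0 and not include_self:
            continue
        total += n * alpha**d
    return total


def hypergeom_enum(overlap: int, universe: int, pathway: int, module: int) -> float:
    """P(X >= overlap) by exhaustively enumerating all draws."""
    univ = list(range(universe))
    hits = set(range(pathway))
    count = sum(
        1
        for draw in itertools.combinations(univ, module)
        if len(hits.intersection(draw)) >= overlap
    )
    return count / comb(universe, module)


def random_adj(rng, n_max: int = 8) -> Dict[str, set]:
    """A random small undirected graph as an adjacency dict."""
    n = int(rng.integers(2, n_max + 1))
    names = [f"n{i}" for i in range(n)]
    adj = {name: set() for name in names}
    p = rng.uniform(0.2, 0.7)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[names[i]].add(names[j])
                adj[names[j]].add(names[i])
    return adj
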