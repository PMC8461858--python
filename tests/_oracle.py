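"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the scoring definitions with plain
Python loops and no caching or vectorization, so it shares no code path with
the package implementation it checks.
"""

import math

from menc.network import Role


def naive_distance(row_i, row_j):
    return math.sqrt(sum((int(a) - int(b)) ** 2 for a, b in zip(row_i, row_j)))


def naive_mif(scores, m, i, j, mode="gravity"):
    d = naive_distance(m.row(i), m.row(j))
    mi = scores.get(i)
    mj = scores.get(j)
    if mode == "gravity":
        if d < 1.0:
            d = 1.0
        return mi * mj / (d * d)
    if d == 0:
        return mi * mj
    return mi * mj * d * d


def _nsize(G, x, neighbor_count):
    if neighbor_count == "degree":
        return sum(1 for _ in G[x])
    reach = set(G[x])
    for y in list(reach):
        reach |= set(G[y])
    reach.discard(x)
    return len(reach)


def naive_score(net, scores, m, mif_mode="gravity", c_variant="literal",
                neighbor_count="degree"):
    """Literal three-level evaluation of the semi-local objective."""
    G = net.graph
    role = net.role

    def mut(x):
        return role[x] in (Role.MUTATED, Role.BOTH)

    def deg_role(x):
        return role[x] in (Role.DEG, Role.BOTH)

    def N(x):
        return _nsize(G, x, neighbor_count)

    def c(u):
        total = 0.0
        for w in G[u]:
            if mut(w):
                factor = N(u) if c_variant == "literal" else N(w)
                total += factor * naive_mif(scores, m, u, w, mif_mode)
            if deg_role(w):
                total += N(w)
        return total

    def b(u):
        total = 0.0
        for w in G[u]:
            if mut(w):
                total += c(w)
            if deg_role(w):
                total += N(w)
        return total

    v = net.source
    total = float(N(v))
    for u in G[v]:
        if mut(u):
            total += c(u) * naive_mif(scores, m, v, u, mif_mode)
        if deg_role(u):
            total += b(u)
    return total


def naive_curve(ranked_genes, benchmark_members, denom):
    """Set-intersection recomputation of precision/recall/F1 at every cutoff."""
    out = []
    for k in range(1, len(ranked_genes) + 1):
        hits = len(set(ranked_genes[:k]) & set(benchmark_members))
        p = hits / k
        r = hits / denom
        f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        out.append((k, p, r, f1))
    return out
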