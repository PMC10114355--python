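"""Independent brute-force oracles for skeleton measurements.

These re-derive the package's documented conventions (step lengths,
shortcut-diagonal pruning, junction-cluster contraction) by exhaustive
enumeration rather than graph construction, so they can cross-check the
morphology module on small masks.
"""

import math

SQRT2 = math.sqrt(2.0)


def pixel_edges(pixels):
    """All skeleton steps by exhaustive pairwise distance checking.

    Unit steps between axial neighbours, sqrt(2) steps between diagonal
    neighbours unless a shared axial neighbour shortcuts the diagonal.
    """
    pts = sorted(pixels)
    edges = []
    for i, a in enumerate(pts):
        for b in pts[i + 1:]:
            dy, dx = abs(a[0] - b[0]), abs(a[1] - b[1])
            if max(dy, dx) != 1:
                continue
            if dy + dx == 1:
                edges.append((a, b, 1.0))
            elif not ((a[0], b[1]) in pixels or (b[0], a[1]) in pixels):
                edges.append((a, b, SQRT2))
    return edges


def total_length(pixels):
    return sum(w for *_ab, w in pixel_edges(pixels))


def _adjacency(pixels):
    adj = {}
    for a, b, w in pixel_edges(pixels):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    return adj


def junction_clusters(pixels):
    """Connected components of degree->=3 pixels (flood fill)."""
    adj = _adjacency(pixels)
    deg = {p: len(adj.get(p, [])) for p in pixels}
    cluster = {}
    clusters = []
    for p in pixels:
        if deg.get(p, 0) >= 3 and p not in cluster:
            stack, comp = [p], {p}
            while stack:
                q = stack.pop()
                for (r, _w) in adj.get(q, []):
                    if deg.get(r, 0) >= 3 and r not in comp:
                        comp.add(r)
                        stack.append(r)
            for q in comp:
                cluster[q] = frozenset(comp)
            clusters.append(frozenset(comp))
    return cluster, clusters


def branch_point_count(pixels):
    """Junction clusters with at least 3 edges leaving the cluster."""
    adj = _adjacency(pixels)
    cluster, clusters = junction_clusters(pixels)
    count = 0
    for comp in clusters:
        outgoing = sum(1 for p in comp for (q, _w) in adj.get(p, [])
                       if q not in comp)
        if outgoing >= 3:
            count += 1
    return count


def longest_chain(pixels):
    """Exhaustive DFS over simple paths between endpoint pixels on the
    junction-contracted quotient graph. Returns None for skeletons with
    fewer than two endpoints (cycles, lollipops, single pixels)."""
    adj = _adjacency(pixels)
    deg = {p: len(adj.get(p, [])) for p in pixels}
    endpoints = [p for p, d in deg.items() if d == 1]
    if len(endpoints) < 2:
        return None
    cluster, _clusters = junction_clusters(pixels)

    def group(p):
        return cluster.get(p, p)

    qadj = {}
    for a, b, w in pixel_edges(pixels):
        ga, gb = group(a), group(b)
        if ga == gb:
            continue
        qadj.setdefault(ga, {})[gb] = max(qadj.get(ga, {}).get(gb, 0.0), w)
        qadj.setdefault(gb, {})[ga] = max(qadj.get(gb, {}).get(ga, 0.0), w)
    best = 0.0

    def dfs(node, target, seen, acc):
        nonlocal best
        if node == target:
            best = max(best, acc)
            return
        for nxt, w in qadj.get(node, {}).items():
            if nxt not in seen:
                seen.add(nxt)
                dfs(nxt, target, seen, acc + w)
                seen.remove(nxt)

    import itertools
    for a, b in itertools.combinations(endpoints, 2):
        dfs(group(a), group(b), {group(a)}, 0.0)
    return best
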