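"""Independent oracles used by the test suite.

Everything here is deliberately naive and shares no code with the
package: curve areas by explicit threshold enumeration and geometric
trapezoids, triad motifs by exhaustive triple enumeration, and the
D-value by a pure-Python reimplementation (BFS distances, hand-rolled
Jensen-Shannon divergence and Gaussian elimination) so that agreement
with the package is evidence of correctness, not of shared bugs.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations


# ---------------------------------------------------------------------------
# PR / ROC by threshold enumeration


def curve_areas(
    ranked: list[tuple[object, float]],
    positives: set,
    n_universe: int,
) -> tuple[float, float]:
    """(AUPR, AUROC) by placing a threshold at every distinct score.

    ``ranked`` is the trimmed list as (pair, score), already sorted by
    score descending.  Pairs sharing a score cross the threshold
    together.  The PR curve is anchored at (recall 0, precision of the
    first block) and integrated only over the recall actually reached.
    The ROC curve additionally sweeps the implicit final block of all
    unranked universe pairs, ending at (1, 1).
    """
    n_pos = len(positives)
    n_neg = n_universe - n_pos
    # group into tie blocks
    blocks: list[list[object]] = []
    last_score = None
    for pair, score in ranked:
        if blocks and score == last_score:
            blocks[-1].append(pair)
        else:
            blocks.append([pair])
        last_score = score

    pr_pts = []
    roc_pts = [(0.0, 0.0)]
    tp = fp = 0
    for block in blocks:
        for pair in block:
            if pair in positives:
                tp += 1
            else:
                fp += 1
        pr_pts.append((tp / n_pos, tp / (tp + fp)))
        roc_pts.append((fp / n_neg, tp / n_pos))
    if tp + fp < n_universe:  # final block: everything unranked
        roc_pts.append((1.0, 1.0))

    if pr_pts:
        pr_pts = [(0.0, pr_pts[0][1])] + pr_pts
    aupr = 0.0
    for (r0, p0), (r1, p1) in zip(pr_pts, pr_pts[1:]):
        aupr += (r1 - r0) * (p0 + p1) / 2.0
    auroc = 0.0
    for (x0, y0), (x1, y1) in zip(roc_pts, roc_pts[1:]):
        auroc += (x1 - x0) * (y0 + y1) / 2.0
    return aupr, auroc


# ---------------------------------------------------------------------------
# Triad motifs by exhaustive enumeration


def triad_counts(
    nodes: list, arcs: set[tuple], tf_set: set
) -> tuple[int, int, int]:
    """(ffl, complex_ffl, fbl3) over all C(n,3) triples, self-loops ignored."""
    arcs = {(u, v) for u, v in arcs if u != v}
    ffl = cffl = fbl = 0
    for triple in combinations(sorted(nodes), 3):
        sub = {(u, v) for u, v in arcs if u in triple and v in triple}
        matched = False
        for a, b, c in permutations(triple):
            if sub == {(a, b), (a, c), (b, c)}:
                ffl += 1
                matched = True
                break
            if sub == {(a, b), (b, a), (a, c), (b, c)}:
                cffl += 1
                matched = True
                break
        if not matched:
            for a, b, c in permutations(triple):
                if sub == {(a, b), (b, c), (c, a)}:
                    if all(x in tf_set for x in triple):
                        fbl += 1
                    break
    return ffl, cffl, fbl


# ---------------------------------------------------------------------------
# Pure-Python D-value


def _bfs_row(adj: dict, src, nodes: list) -> list[float]:
    """Distance distribution of one node: bins d=1..n-1 plus unreachable."""
    n = len(nodes)
    dist = {src: 0}
    frontier = [src]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    row = [0.0] * n
    for v, dd in dist.items():
        if dd >= 1:
            row[dd - 1] += 1
    row[n - 1] += (n - 1) - (len(dist) - 1)
    return [x / (n - 1) for x in row]


def _entropy(p: list[float]) -> float:
    return -sum(x * math.log(x) for x in p if x > 0)


def _jsd(rows: list[list[float]]) -> float:
    k = len(rows)
    mean = [sum(r[i] for r in rows) / k for i in range(len(rows[0]))]
    return _entropy(mean) - sum(_entropy(r) for r in rows) / k


def _gauss_solve(a: list[list[float]], b: list[float]) -> list[float]:
    """Gaussian elimination with partial pivoting."""
    n = len(b)
    m = [row[:] + [b[i]] for i, row in enumerate(a)]
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(m[r][col]))
        m[col], m[piv] = m[piv], m[col]
        for r in range(col + 1, n):
            f = m[r][col] / m[col][col]
            for c in range(col, n + 1):
                m[r][c] -= f * m[col][c]
    x = [0.0] * n
    for r in range(n - 1, -1, -1):
        x[r] = (m[r][n] - sum(m[r][c] * x[c] for c in range(r + 1, n))) / m[r][r]
    return x


def _alpha_dist(adj_pairs: set[tuple], nodes: list) -> list[float]:
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = [[0.0] * n for _ in range(n)]
    for u, v in adj_pairs:
        a[idx[u]][idx[v]] = 1.0
        a[idx[v]][idx[u]] = 1.0
    deg = [sum(row) for row in a]
    system = [
        [(1.0 if i == j else 0.0) - a[j][i] / n for j in range(n)] for i in range(n)
    ]
    e = [d / (n - 1) for d in deg]
    x = _gauss_solve(system, e)
    r = sorted(v / (n * n) for v in x)
    r.append(max(0.0, 1.0 - sum(r)))
    return r


def _pad_pair(p: list[float], q: list[float]) -> tuple[list[float], list[float]]:
    m = max(len(p), len(q))

    def pad(v):
        return v[:-1] + [0.0] * (m - len(v)) + [v[-1]]

    return pad(p), pad(q)


def d_value_oracle(
    edges1: set[tuple], nodes1: list, edges2: set[tuple], nodes2: list,
    w1: float = 0.45, w2: float = 0.45, w3: float = 0.10,
) -> float:
    """Pure-Python D-value on undirected simple graphs."""

    def prep(edges, nodes):
        adj = {v: set() for v in nodes}
        und = set()
        for u, v in edges:
            if u != v:
                adj[u].add(v)
                adj[v].add(u)
                und.add((min(u, v), max(u, v)))
        rows = [_bfs_row(adj, v, nodes) for v in sorted(nodes)]
        n = len(nodes)
        mu = [sum(r[i] for r in rows) / n for i in range(n)]
        # NND: JS of rows over log(bins); bins = finite diameter (+1 disc bin)
        has_disc = any(r[-1] > 0 for r in rows)
        diam = 0
        for i in range(n - 1):
            if any(r[i] > 0 for r in rows):
                diam = i + 1
        bins = diam + (2 if has_disc else 1)
        nnd = _jsd(rows) / math.log(bins) if bins >= 2 else 0.0
        comp = {
            (a, b)
            for a, b in combinations(sorted(nodes), 2)
            if (a, b) not in und
        }
        return mu, nnd, und, comp

    mu1, nnd1, und1, comp1 = prep(edges1, nodes1)
    mu2, nnd2, und2, comp2 = prep(edges2, nodes2)
    p, q = _pad_pair(mu1, mu2)
    t1 = math.sqrt(_jsd([p, q]) / math.log(2))
    t2 = abs(math.sqrt(nnd1) - math.sqrt(nnd2))
    c1 = _alpha_dist(und1, sorted(nodes1))
    c2 = _alpha_dist(und2, sorted(nodes2))
    cc1 = _alpha_dist(comp1, sorted(nodes1))
    cc2 = _alpha_dist(comp2, sorted(nodes2))
    pa, qa = _pad_pair(c1, c2)
    pb, qb = _pad_pair(cc1, cc2)
    t3 = 0.5 * (
        math.sqrt(_jsd([pa, qa]) / math.log(2))
        + math.sqrt(_jsd([pb, qb]) / math.log(2))
    )
    return w1 * t1 + w2 * t2 + w3 * t3
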