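"""Independent brute-force oracles used by the test suite.

Everything here re-derives expected results by exhaustive enumeration or
closed form, sharing no scanning/alignment code with the package.
"""

from __future__ import annotations

import numpy as np

HEPTA = "WRKYGQK"


def brute_heptapeptide(seq: str, max_mismatch: int, require_w: bool = True):
    """All 7-windows within Hamming distance of WRKYGQK, by direct check."""
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - 6):
        w = seq[i : i + 7]
        if require_w and w[0] != "W":
            continue
        d = sum(a != b for a, b in zip(w, HEPTA))
        if d <= max_mismatch:
            hits.append((i, w, d))
    return hits


def brute_domains(
    seq: str,
    max_mismatch: int = 1,
    s1_range=(4, 8),
    s2_range=(22, 28),
    s3_range=(1, 2),
    linker_window: int = 30,
    max_span: int = 80,
):
    """Expected scan_domains output by enumerating every ligand quadruple.

    For each heptapeptide window, every (c1, c2, h, t) position quadruple
    satisfying the spacing grammar and the linker window is enumerated;
    the minimum by (c1, spacer1, spacer2, spacer3) is the paired finger.
    Nested domains are then removed.  Returns (start, end, c1, c2, h, t)
    tuples sorted by start.
    """
    seq = seq.upper()
    n = len(seq)
    raw = []
    for start, _, _ in brute_heptapeptide(seq, max_mismatch):
        from_pos = start + 7
        candidates = []
        for c1 in range(from_pos, min(n, from_pos + linker_window)):
            if seq[c1] != "C":
                continue
            for c2 in range(c1 + 1, n):
                s1 = c2 - c1 - 1
                if s1 > s1_range[1]:
                    break
                if seq[c2] != "C" or s1 < s1_range[0]:
                    continue
                for h in range(c2 + 1, n):
                    s2 = h - c2 - 1
                    if s2 > s2_range[1]:
                        break
                    if seq[h] != "H" or s2 < s2_range[0]:
                        continue
                    for t in range(h + 1, n):
                        s3 = t - h - 1
                        if s3 > s3_range[1]:
                            break
                        if seq[t] not in "HC" or s3 < s3_range[0]:
                            continue
                        candidates.append((c1, s1, s2, s3, c2, h, t))
        if not candidates:
            continue
        c1, s1, s2, s3, c2, h, t = min(candidates)
        if t + 1 - start <= max_span:
            raw.append((start, t + 1, c1, c2, h, t))
    kept = [
        d
        for d in raw
        if not any(
            e != d and e[0] <= d[0] and d[1] <= e[1] and (e[0] < d[0] or d[1] < e[1])
            for e in raw
        )
    ]
    return sorted(kept)


def brute_windows(seq: str, length: int, predicate):
    """All window starts of given length satisfying a predicate."""
    return [i for i in range(len(seq) - length + 1) if predicate(seq[i : i + length])]


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b) strings."""

    def rec(i, j, ra, rb):
        if i == len(a) and j == len(b):
            yield "".join(ra), "".join(rb)
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, ra + [a[i]], rb + [b[j]])
        if i < len(a):
            yield from rec(i + 1, j, ra + [a[i]], rb + ["-"])
        if j < len(b):
            yield from rec(i, j + 1, ra + ["-"], rb + [b[j]])

    yield from rec(0, 0, [], [])


def affine_alignment_score(row_a: str, row_b: str, sub, gap_open: float, gap_extend: float):
    """Score an explicit alignment: substitutions plus affine gap costs."""
    score = 0.0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            score += sub[x, y]
    for row in (row_a, row_b):
        in_gap = False
        for c in row:
            if c == "-":
                score -= gap_extend if in_gap else gap_open
                in_gap = True
            else:
                in_gap = False
    return score


def brute_best_alignment_score(a, b, sub, gap_open, gap_extend):
    return max(
        affine_alignment_score(ra, rb, sub, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )


def random_additive_tree(n: int, rng: np.random.Generator):
    """A random binary tree on n leaves with positive branch lengths.

    Returns (leaf labels, distance matrix, bipartition set) where the
    distance matrix is exactly additive on the tree and the bipartitions
    are its nontrivial splits canonicalized as the side not containing
    the lexicographically smallest leaf.
    """
    labels = [f"T{i}" for i in range(n)]
    # grow by random leaf attachment: start from a 3-star
    # adjacency: node -> list of (node, length)
    next_internal = [n]
    adj: dict[int, list[tuple[int, float]]] = {}

    def link(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def new_internal():
        k = next_internal[0]
        next_internal[0] += 1
        return k

    def blen():
        return float(rng.uniform(0.5, 3.0))

    center = new_internal()
    for leaf in range(3):
        link(leaf, center, blen())
    edges = [(leaf, center) for leaf in range(3)]
    for leaf in range(3, n):
        u, v = edges[rng.integers(0, len(edges))]
        w = dict(adj[u])[v]
        mid = new_internal()
        adj[u] = [(x, l) for x, l in adj[u] if x != v]
        adj[v] = [(x, l) for x, l in adj[v] if x != u]
        w1 = w * float(rng.uniform(0.2, 0.8))
        link(u, mid, w1)
        link(mid, v, w - w1)
        link(leaf, mid, blen())
        edges.remove((u, v))
        edges.extend([(u, mid), (mid, v), (leaf, mid)])

    # all-pairs path lengths between leaves by BFS/DFS
    d = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in range(n):
            d[src, dst] = dist[dst]

    # bipartitions: cut each internal edge, collect leaves on one side
    ref = min(labels)
    biparts = set()
    for u in adj:
        for v, _ in adj[u]:
            if u < v and u >= n and v >= n:  # internal edge
                side = set()
                stack = [u]
                seen = {u, v}
                while stack:
                    x = stack.pop()
                    if x < n:
                        side.add(labels[x])
                    for y, _w in adj[x]:
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                if 2 <= len(side) <= n - 2:
                    all_set = frozenset(labels)
                    fs = frozenset(side)
                    biparts.add(fs if ref not in fs else all_set - fs)
    return labels, d, biparts


def oracle_nj_bipartitions(labels, d):
    """Independent array-based NJ; returns canonical nontrivial splits.

    Written separately from the package implementation (plain index
    arithmetic, no cluster-key bookkeeping) for use as a replicate
    engine in bootstrap cross-checks.
    """
    n = len(labels)
    clusters = [frozenset([lab]) for lab in labels]
    D = [list(row) for row in d]
    splits = []
    while len(clusters) > 3:
        m = len(clusters)
        totals = [sum(D[i]) for i in range(m)]
        best, best_q = None, None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i][j] - totals[i] - totals[j]
                key = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                if best_q is None or q < best_q[0] - 1e-12 or (
                    abs(q - best_q[0]) <= 1e-12 and key < best_q[1]
                ):
                    best_q, best = (q, key), (i, j)
        i, j = best
        merged = clusters[i] | clusters[j]
        if 2 <= len(merged) <= n - 2:
            splits.append(merged)
        new_row = [
            0.5 * (D[i][k] + D[j][k] - D[i][j])
            for k in range(m)
            if k not in (i, j)
        ]
        keep = [k for k in range(m) if k not in (i, j)]
        D = [[D[a][b] for b in keep] for a in keep]
        for r, val in zip(D, new_row):
            r.append(val)
        D.append(new_row + [0.0])
        clusters = [clusters[k] for k in keep] + [merged]
    all_set = frozenset(labels)
    ref = min(labels)
    return {
        s if ref not in s else all_set - s
        for s in splits
        if 2 <= len(s) <= n - 2
    }


def grid_isoelectric_point(seq, pka, step=0.001):
    """Vectorized 0-to-14 grid search for the zero-charge pH."""
    grid = np.arange(0.0, 14.0, step)
    charge = 1.0 / (1.0 + 10.0 ** (grid - pka["Nterm"]))
    charge = charge - 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - grid))
    for res in "HKR":
        charge = charge + seq.count(res) / (1.0 + 10.0 ** (grid - pka[res]))
    for res in "CDEY":
        charge = charge - seq.count(res) / (1.0 + 10.0 ** (pka[res] - grid))
    return float(grid[np.argmin(np.abs(charge))])
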