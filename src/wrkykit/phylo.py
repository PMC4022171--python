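"""Distance-based phylogeny of WRKY domain sequences.

The chain is: global pairwise alignment (Needleman-Wunsch with affine
gaps, BLOSUM62, gap open 10 / extend 0.5) -> p-distance (mismatched
fraction of gap-free aligned columns) -> neighbor joining (Saitou-Nei
Q-criterion) -> nonparametric bootstrap over alignment columns.

Trees are unrooted; NJ returns a trifurcation at the last join.  Ties in
the Q-criterion break to the lexicographically smallest pair of cluster
keys (a cluster's key is its lexicographically smallest leaf), so the
whole chain is deterministic.  Negative NJ branch lengths are clamped to
zero with a warning, a standard presentation choice.

A small progressive aligner (NJ join order as guide, profile-profile NW)
stands in for an external MSA program when more than two sequences must
share a coordinate system, e.g. for the bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "pairwise_align",
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "align_progressive",
    "to_newick",
    "parse_newick",
    "robinson_foulds",
]

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

_NEG_INF = float("-inf")

_blosum62_cache = None


def blosum62():
    """BLOSUM62 substitution scores as a plain dict of residue pairs."""
    global _blosum62_cache
    if _blosum62_cache is None:
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        table = {}
        for a in mat.alphabet:
            for b in mat.alphabet:
                table[a, b] = float(mat[a, b])
        _blosum62_cache = table
    return _blosum62_cache


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")

    @property
    def identity(self) -> float:
        """Matches over alignment length (gap columns count the length)."""
        matches = sum(
            x == y and x != "-" for x, y in zip(self.aligned_a, self.aligned_b)
        )
        return matches / len(self.aligned_a) if self.aligned_a else 0.0


def pairwise_align(
    a: str,
    b: str,
    matrix: dict | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Optimal global alignment with affine gaps (Gotoh three-state DP).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  Ties in
    the traceback prefer substitution over a gap in ``a`` over a gap in
    ``b``, making the reported alignment deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    sub = blosum62() if matrix is None else matrix
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)

    # D: ends in substitution; P: ends with gap in b (consumes a);
    # Q: ends with gap in a (consumes b)
    D = np.full((n + 1, m + 1), _NEG_INF)
    P = np.full((n + 1, m + 1), _NEG_INF)
    Q = np.full((n + 1, m + 1), _NEG_INF)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        P[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Q[0, j] = -gap_open - (j - 1) * gap_extend

    for i in range(1, n + 1):
        ai = a[i - 1]
        Di_1, Pi_1, Qi_1 = D[i - 1], P[i - 1], Q[i - 1]
        Di, Pi, Qi = D[i], P[i], Q[i]
        for j in range(1, m + 1):
            s = sub[ai, b[j - 1]]
            Di[j] = max(Di_1[j - 1], Pi_1[j - 1], Qi_1[j - 1]) + s
            Pi[j] = max(Di_1[j] - gap_open, Pi_1[j] - gap_extend, Qi_1[j] - gap_open)
            Qi[j] = max(Di[j - 1] - gap_open, Pi[j - 1] - gap_open, Qi[j - 1] - gap_extend)

    # traceback; preference order: substitution, gap-in-a (Q), gap-in-b (P)
    i, j = n, m
    states = [("D", D), ("Q", Q), ("P", P)]
    best = max(D[n, m], Q[n, m], P[n, m])
    state = next(name for name, M in states if M[n, m] == best)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "D":
            s = sub[a[i - 1], b[j - 1]]
            prev = D[i, j] - s
            for name, M in states:
                if M[i - 1, j - 1] == prev:
                    state = name
                    break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == "Q":  # gap in a
            if j == 0:
                state = "P"
                continue
            val = Q[i, j]
            if D[i, j - 1] - gap_open == val:
                state = "D"
            elif P[i, j - 1] - gap_open == val:
                state = "P"
            # else stay in Q (gap extension)
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        else:  # P: gap in b
            if i == 0:
                state = "Q"
                continue
            val = P[i, j]
            if D[i - 1, j] - gap_open == val:
                state = "D"
            elif Q[i - 1, j] - gap_open == val:
                state = "Q"
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(best))


def p_distance(alignment: Alignment) -> float:
    """Mismatch fraction over aligned columns without gaps, in [0, 1]."""
    compared = 0
    mismatches = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError("no gap-free columns to compare")
    return mismatches / compared


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "d", d)

    @classmethod
    def from_sequences(cls, records: list[tuple[str, str]], **align_kwargs) -> "DistanceMatrix":
        """Pairwise-align every pair and take p-distances."""
        ids = tuple(r[0] for r in records)
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                aln = pairwise_align(records[i][1], records[j][1], **align_kwargs)
                d[i, j] = d[j, i] = p_distance(aln)
        return cls(ids, d)

    @classmethod
    def from_msa(cls, msa: list[tuple[str, str]]) -> "DistanceMatrix":
        """p-distances over shared columns of an existing alignment."""
        ids = tuple(r[0] for r in msa)
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = p_distance(Alignment(msa[i][1], msa[j][1], 0.0))
        return cls(ids, d)


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary root (NJ's final join)."""

    root: TreeNode
    n_boot: int | None = None

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial bipartitions, each canonicalized as the leaf set on
        the far side of a fixed reference leaf (the lexicographic min)."""
        all_leaves = frozenset(self.leaves())
        ref = min(all_leaves)
        out: set[frozenset] = set()

        def walk(node: TreeNode):
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset()
            for child, _ in node.children:
                below |= walk(child)
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if ref not in below else all_leaves - below
                out.add(side)
            return below

        walk(self.root)
        return out

    def supports(self) -> dict[frozenset, int]:
        """Map each nontrivial bipartition to its bootstrap count."""
        all_leaves = frozenset(self.leaves())
        ref = min(all_leaves)
        result: dict[frozenset, int] = {}

        def walk(node: TreeNode):
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset()
            for child, _ in node.children:
                below |= walk(child)
            if (
                node is not self.root
                and 2 <= len(below) <= len(all_leaves) - 2
                and node.support is not None
            ):
                side = below if ref not in below else all_leaves - below
                result[side] = node.support
            return below

        walk(self.root)
        return result


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei agglomeration with the standard Q-criterion.

    The pair minimizing Q joins at each step; ties break to the
    lexicographically smallest (sorted) pair of cluster keys, where a
    cluster's key is the smallest leaf label under it.  Negative branch
    lengths are clamped to zero with a warning.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if len(set(dm.ids)) != n:
        raise ValueError("duplicate taxon ids")

    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in dm.ids}
    # active cluster keys -> nodes; distances keyed by sorted key pair
    active = {lab: nodes[lab] for lab in dm.ids}
    dist = {
        tuple(sorted((a, b))): float(dm.d[i, j])
        for i, a in enumerate(dm.ids)
        for j, b in enumerate(dm.ids)
        if i < j
    }

    def d_of(a: str, b: str) -> float:
        return dist[tuple(sorted((a, b)))]

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn(f"negative NJ branch length {x:.6g} clamped to 0", stacklevel=3)
            return 0.0
        return x

    while len(active) > 3:
        keys = sorted(active)
        r = len(keys)
        totals = {k: sum(d_of(k, other) for other in keys if other != k) for k in keys}
        best_pair = None
        best_q = None
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                q = (r - 2) * d_of(a, b) - totals[a] - totals[b]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best_pair = q, (a, b)
                # ties resolve to the smallest sorted key pair, which the
                # ascending iteration order already guarantees
        a, b = best_pair
        dab = d_of(a, b)
        la = 0.5 * dab + (totals[a] - totals[b]) / (2.0 * (r - 2))
        lb = dab - la
        parent = TreeNode(children=[(active[a], clamp(la)), (active[b], clamp(lb))])
        new_key = min(a, b)
        new_dists = {
            k: max(0.5 * (d_of(a, k) + d_of(b, k) - dab), 0.0)
            for k in keys
            if k not in (a, b)
        }
        for pair in [p for p in dist if a in p or b in p]:
            del dist[pair]
        for k, v in new_dists.items():
            dist[tuple(sorted((new_key, k)))] = v
        del active[a], active[b]
        active[new_key] = parent

    # final trifurcation via the three-point formulas
    x, y, z = sorted(active)
    dxy, dxz, dyz = d_of(x, y), d_of(x, z), d_of(y, z)
    lx = clamp(0.5 * (dxy + dxz - dyz))
    ly = clamp(0.5 * (dxy + dyz - dxz))
    lz = clamp(0.5 * (dxz + dyz - dxy))
    root = TreeNode(children=[(active[x], lx), (active[y], ly), (active[z], lz)])
    return Tree(root=root)


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Symmetric difference of nontrivial bipartition sets."""
    if set(t1.leaves()) != set(t2.leaves()):
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def bootstrap_support(
    msa: list[tuple[str, str]],
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    ref_tree: Tree | None = None,
) -> Tree:
    """Bootstrap column resampling; supports annotate the reference tree.

    Columns are resampled with replacement ``n_boot`` times; each
    replicate's NJ tree contributes one count to every reference
    bipartition it contains.  Fixed seed -> identical supports.
    """
    if not msa:
        raise ValueError("empty alignment")
    ncols = len(msa[0][1])
    if ncols < 1 or any(len(s) != ncols for _, s in msa):
        raise ValueError("alignment rows must share a positive common length")
    ids = [i for i, _ in msa]
    rows = np.array([list(s) for _, s in msa])
    gap = rows == "-"

    def dm_from_columns(cols: np.ndarray) -> DistanceMatrix:
        sub = rows[:, cols]
        subgap = gap[:, cols]
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~subgap[i] & ~subgap[j]
                compared = int(ok.sum())
                if compared == 0:
                    raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
                mm = int((sub[i, ok] != sub[j, ok]).sum())
                d[i, j] = d[j, i] = mm / compared
        return DistanceMatrix(tuple(ids), d)

    if ref_tree is None:
        ref_tree = neighbor_joining(dm_from_columns(np.arange(ncols)))
    ref_biparts = ref_tree.bipartitions()
    counts = {bp: 0 for bp in ref_biparts}
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # replicate trees may clamp lengths
        for _ in range(n_boot):
            cols = rng.integers(0, ncols, size=ncols)
            rep = neighbor_joining(dm_from_columns(cols))
            for bp in rep.bipartitions():
                if bp in counts:
                    counts[bp] += 1

    # annotate a copy of the reference tree
    all_leaves = frozenset(ref_tree.leaves())
    ref_leaf = min(all_leaves)

    def annotate(node: TreeNode, is_root: bool) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset()
        for child, _ in node.children:
            below |= annotate(child, False)
        if not is_root and 2 <= len(below) <= len(all_leaves) - 2:
            side = below if ref_leaf not in below else all_leaves - below
            node.support = counts[side]
        return below

    annotate(ref_tree.root, True)
    ref_tree.n_boot = n_boot
    return ref_tree


# -- progressive multiple alignment ----------------------------------------


def align_progressive(
    records: list[tuple[str, str]],
    matrix: dict | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[tuple[str, str]]:
    """Progressive MSA: NJ join order as guide, profile-profile NW merges.

    Column score between profiles is the mean substitution score over
    gap-free residue pairs; gap penalties are as in the pairwise aligner.
    Input order is preserved in the output.
    """
    if len(records) == 0:
        return []
    if len(records) == 1:
        return list(records)
    sub = blosum62() if matrix is None else matrix
    if len(records) == 2:
        aln = pairwise_align(records[0][1], records[1][1], sub, gap_open, gap_extend)
        return [(records[0][0], aln.aligned_a), (records[1][0], aln.aligned_b)]

    dm = DistanceMatrix.from_sequences(records, matrix=sub, gap_open=gap_open, gap_extend=gap_extend)
    order = {rid: k for k, (rid, _) in enumerate(records)}
    # profiles keyed like NJ clusters: key = smallest member id
    profiles: dict[str, list[tuple[str, str]]] = {rid: [(rid, s)] for rid, s in records}
    dist = {
        tuple(sorted((a, b))): float(dm.d[i, j])
        for i, a in enumerate(dm.ids)
        for j, b in enumerate(dm.ids)
        if i < j
    }

    def d_of(a, b):
        return dist[tuple(sorted((a, b)))]

    active = sorted(profiles)
    while len(active) > 1:
        if len(active) == 2:
            a, b = active
        else:
            r = len(active)
            totals = {k: sum(d_of(k, o) for o in active if o != k) for k in active}
            best_q, best = None, None
            for i, a_ in enumerate(active):
                for b_ in active[i + 1 :]:
                    q = (r - 2) * d_of(a_, b_) - totals[a_] - totals[b_]
                    if best_q is None or q < best_q - 1e-12:
                        best_q, best = q, (a_, b_)
            a, b = best
        merged = _profile_align(profiles[a], profiles[b], sub, gap_open, gap_extend)
        new_key = min(a, b)
        new_dists = {
            k: max(0.5 * (d_of(a, k) + d_of(b, k) - d_of(a, b)), 0.0)
            for k in active
            if k not in (a, b)
        }
        for pair in [p for p in dist if a in p or b in p]:
            del dist[pair]
        for k, v in new_dists.items():
            dist[tuple(sorted((new_key, k)))] = v
        profiles[new_key] = merged
        del profiles[a if new_key == b else b]
        active = sorted(profiles)
    final = profiles[active[0]]
    return sorted(final, key=lambda r: order[r[0]])


def _profile_align(pa, pb, sub, gap_open, gap_extend):
    """NW with affine gaps over two profiles (lists of aligned rows)."""
    cols_a = list(zip(*[s for _, s in pa]))
    cols_b = list(zip(*[s for _, s in pb]))
    n, m = len(cols_a), len(cols_b)

    def col_score(ca, cb):
        tot, cnt = 0.0, 0
        for x in ca:
            if x == "-":
                continue
            for y in cb:
                if y == "-":
                    continue
                tot += sub[x, y]
                cnt += 1
        return tot / cnt if cnt else 0.0

    D = np.full((n + 1, m + 1), _NEG_INF)
    P = np.full((n + 1, m + 1), _NEG_INF)
    Q = np.full((n + 1, m + 1), _NEG_INF)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        P[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Q[0, j] = -gap_open - (j - 1) * gap_extend
    S = np.array([[col_score(ca, cb) for cb in cols_b] for ca in cols_a]) if n and m else np.zeros((n, m))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[i - 1, j - 1]
            D[i, j] = max(D[i - 1, j - 1], P[i - 1, j - 1], Q[i - 1, j - 1]) + s
            P[i, j] = max(D[i - 1, j] - gap_open, P[i - 1, j] - gap_extend, Q[i - 1, j] - gap_open)
            Q[i, j] = max(D[i, j - 1] - gap_open, P[i, j - 1] - gap_open, Q[i, j - 1] - gap_extend)

    i, j = n, m
    best = max(D[n, m], Q[n, m], P[n, m])
    state = "D" if D[n, m] == best else ("Q" if Q[n, m] == best else "P")
    steps = []  # "M", "A" (column from a only), "B" (column from b only)
    while i > 0 or j > 0:
        if state == "D" and i > 0 and j > 0:
            prev = D[i, j] - S[i - 1, j - 1]
            for name, M in (("D", D), ("Q", Q), ("P", P)):
                if M[i - 1, j - 1] == prev:
                    state_next = name
                    break
            steps.append("M")
            i, j, state = i - 1, j - 1, state_next
        elif state == "Q" or (i == 0 and j > 0):
            val = Q[i, j]
            if j > 0 and D[i, j - 1] - gap_open == val:
                state_next = "D"
            elif j > 0 and P[i, j - 1] - gap_open == val:
                state_next = "P"
            else:
                state_next = "Q"
            steps.append("B")
            j, state = j - 1, state_next
        else:
            val = P[i, j]
            if i > 0 and D[i - 1, j] - gap_open == val:
                state_next = "D"
            elif i > 0 and Q[i - 1, j] - gap_open == val:
                state_next = "Q"
            else:
                state_next = "P"
            steps.append("A")
            i, state = i - 1, state_next
    steps.reverse()

    out_a = {rid: [] for rid, _ in pa}
    out_b = {rid: [] for rid, _ in pb}
    ia = ib = 0
    for st in steps:
        if st in ("M", "A"):
            for (rid, s) in pa:
                out_a[rid].append(s[ia])
            ia += 1
        else:
            for (rid, _) in pa:
                out_a[rid].append("-")
        if st in ("M", "B"):
            for (rid, s) in pb:
                out_b[rid].append(s[ib])
            ib += 1
        else:
            for (rid, _) in pb:
                out_b[rid].append("-")
    return [(rid, "".join(out_a[rid])) for rid, _ in pa] + [
        (rid, "".join(out_b[rid])) for rid, _ in pb
    ]


# -- newick serialization ---------------------------------------------------


def to_newick(tree: Tree) -> str:
    """Newick string with bootstrap counts as internal node labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return _escape_label(node.label)
        inner = ",".join(f"{fmt(c)}:{bl:.10g}" for c, bl in node.children)
        label = "" if node.support is None else str(node.support)
        return f"({inner}){label}"

    return fmt(tree.root) + ";"


def _escape_label(label: str) -> str:
    if any(c in label for c in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(s: str) -> Tree:
    """Parse a newick string produced by :func:`to_newick`.

    Internal node labels are read as integer bootstrap supports when they
    parse as integers, else kept as labels.  Raises ``ValueError`` on
    malformed input.
    """
    text = s.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    pos = 0
    text = text[:-1]

    def error(msg):
        raise ValueError(f"newick parse error at position {pos}: {msg}")

    def parse_label():
        nonlocal pos
        if pos < len(text) and text[pos] == "'":
            pos += 1
            out = []
            while pos < len(text):
                if text[pos] == "'":
                    if pos + 1 < len(text) and text[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(text[pos])
                pos += 1
            error("unterminated quoted label")
        start = pos
        while pos < len(text) and text[pos] not in "(),:;":
            pos += 1
        return text[start:pos]

    def parse_node() -> TreeNode:
        nonlocal pos
        if pos < len(text) and text[pos] == "(":
            pos += 1
            children = []
            while True:
                child = parse_node()
                bl = 0.0
                if pos < len(text) and text[pos] == ":":
                    pos += 1
                    start = pos
                    while pos < len(text) and (text[pos].isdigit() or text[pos] in ".eE+-"):
                        pos += 1
                    try:
                        bl = float(text[start:pos])
                    except ValueError:
                        error(f"bad branch length {text[start:pos]!r}")
                children.append((child, bl))
                if pos >= len(text):
                    error("unexpected end inside group")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {text[pos]!r}")
            node = TreeNode(children=children)
            label = parse_label()
            if label:
                try:
                    node.support = int(label)
                except ValueError:
                    node.label = label
            return node
        label = parse_label()
        if not label:
            error("empty leaf label")
        return TreeNode(label=label)

    root = parse_node()
    if pos != len(text):
        raise ValueError(f"trailing characters after newick tree: {text[pos:]!r}")
    return Tree(root=root)
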