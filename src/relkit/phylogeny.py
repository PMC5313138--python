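"""Distance-based neighbor-joining phylogeny with bootstrap supports.

Pipeline: progressive center-star alignment -> pairwise distances
(Poisson-corrected by default) -> Saitou-Nei neighbor joining with a
deterministic tie-break -> bootstrap supports -> condensed tree and a
two-clade partition of the leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._align import _nw_kernel, _sw_score_only, encode_protein
from .core_seq import Msa, ProteinSeq, SequenceSet
from .homology_search import GAP_EXTEND, GAP_OPEN, blosum62


# ---------------------------------------------------------------------------
# tree structure

@dataclass
class TreeNode:
    name: str | None = None  # leaf name; None for internal
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0       # branch length to parent
    support: float | None = None  # bootstrap support of the edge to parent

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary (usually trifurcating) root."""

    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def internal_edges(self) -> list[TreeNode]:
        """Nodes whose edge to their parent is internal (non-leaf, non-root)."""
        out = []
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            out.append(node)
        return out

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Internal-edge bipartitions keyed by canonical leaf-side."""
        all_leaves = frozenset(self.leaves())
        ref = min(all_leaves)
        out = {}
        for node in self.internal_edges():
            side = frozenset(node.leaves())
            if ref in side:
                side = all_leaves - side
            out[side] = node
        return out

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:.0f}"
            return f"({inner}){label}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


@dataclass
class CladePartition:
    assignment: dict[str, int]  # leaf -> 1 or 2

    def clade(self, k: int) -> set[str]:
        return {l for l, c in self.assignment.items() if c == k}


# ---------------------------------------------------------------------------
# alignment and distances

def filter_by_length(seqs: SequenceSet, min_len: int = 300) -> SequenceSet:
    """Keep sequences strictly longer than ``min_len`` residues."""
    return seqs.subset([r.id for r in seqs if len(r.residues) > min_len])


def build_msa(seqs: SequenceSet) -> Msa:
    """Deterministic center-star progressive alignment.

    The center is the sequence with the maximal sum of pairwise local
    alignment scores (ties by id); all others are aligned to it globally
    with free end gaps and merged with the once-a-gap-always-a-gap rule.
    """
    records = list(seqs)
    if len(records) < 2:
        return Msa([r.id for r in records], [r.residues for r in records])
    sub = blosum62()
    enc = {r.id: encode_protein(r.residues) for r in records}
    sums = {r.id: 0.0 for r in records}
    for a, b in combinations(records, 2):
        s = _sw_score_only(enc[a.id], enc[b.id], sub, GAP_OPEN, GAP_EXTEND)
        sums[a.id] += s
        sums[b.id] += s
    center = max(records, key=lambda r: (sums[r.id], r.id))
    others = [r for r in records if r.id != center.id]
    clen = len(center.residues)
    # per-alignment: for each of clen+1 inter-positions, the inserted residues
    aligned = []
    max_ins = np.zeros(clen + 1, dtype=int)
    for rec in others:
        _, _, _, _, pairs = _nw_kernel(enc[center.id], enc[rec.id], sub,
                                       GAP_OPEN, GAP_EXTEND, True)
        ins = [[] for _ in range(clen + 1)]
        match = {}  # center pos -> other pos
        cpos = 0
        for qi, ti in pairs:
            if qi >= 0 and ti >= 0:
                match[qi] = ti
                cpos = qi + 1
            elif ti >= 0:  # insertion relative to center
                ins[cpos].append(ti)
        aligned.append((rec, match, ins))
        for k in range(clen + 1):
            max_ins[k] = max(max_ins[k], len(ins[k]))
    ids = [center.id]
    row = []
    for k in range(clen + 1):
        row.append("-" * max_ins[k])
        if k < clen:
            row.append(center.residues[k])
    rows = ["".join(row)]
    for rec, match, ins in aligned:
        parts = []
        for k in range(clen + 1):
            chunk = "".join(rec.residues[t] for t in ins[k])
            parts.append(chunk + "-" * (max_ins[k] - len(ins[k])))
            if k < clen:
                parts.append(rec.residues[match[k]] if k in match else "-")
        ids.append(rec.id)
        rows.append("".join(parts))
    return Msa(ids, rows)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")


def distances(msa: Msa, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gapped columns.

    ``p`` is the raw mismatch fraction; ``poisson`` applies d = -ln(1 - p).
    """
    if msa.n_rows < 3:
        raise ValueError("need at least 3 rows")
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    arr = np.array([list(r) for r in msa.rows])
    gap = arr == "-"
    unknown = arr == "X"
    n = msa.n_rows
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        ok = ~gap[i] & ~gap[j]
        ncmp = int(ok.sum())
        if ncmp == 0:
            raise ValueError(
                f"gap-only overlap between {msa.ids[i]!r} and {msa.ids[j]!r}")
        mism = (arr[i] != arr[j]) | unknown[i] | unknown[j]
        p = float((mism & ok).sum()) / ncmp
        if model == "p":
            dist = p
        else:
            if p >= 1.0:
                raise ValueError(
                    f"saturated distance (p=1) between {msa.ids[i]!r} "
                    f"and {msa.ids[j]!r}")
            dist = -np.log(1.0 - p)
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(msa.ids), d)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Negative branch lengths are clamped to 0; Q-ties are broken by the
    smallest (i, j) index pair in the current active matrix.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))
    while len(active) > 3:
        na = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        ai, aj = divmod(flat, na)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (na - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_d
        d[active, k] = new_d
        d[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return Tree(root)


def bootstrap_supports(msa: Msa, n_reps: int = 1000, seed: int = 0,
                       model: str = "poisson") -> Tree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement; support is the percentage of
    replicates whose NJ tree contains each internal bipartition of the
    point-estimate tree.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = neighbor_joining(distances(msa, model))
    biparts = point.bipartitions()
    counts = {side: 0 for side in biparts}
    rng = np.random.default_rng(seed)
    ncols = msa.n_cols
    arr_rows = msa.rows
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep_rows = ["".join(row[c] for c in cols) for row in arr_rows]
        rep = Msa(list(msa.ids), rep_rows)
        try:
            rep_tree = neighbor_joining(distances(rep, model))
        except ValueError:  # saturated replicate
            continue
        rep_sides = set(rep_tree.bipartitions())
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    for side, node in biparts.items():
        node.support = 100.0 * counts[side] / n_reps
    return point


def condense(tree: Tree, min_support: float = 50.0) -> Tree:
    """Zero the length of internal branches with support below threshold."""
    for node in tree.internal_edges():
        if node.support is not None and node.support < min_support:
            node.length = 0.0
    return tree


def split_two_clades(tree: Tree) -> CladePartition:
    """Two-way leaf partition at the strongest deep internal branch.

    The cut branch maximizes support x length x smaller-side size
    (support treated as 100 when absent): the balance factor selects the
    best-supported *deep* bipartition rather than a well-supported cherry.
    Ties prefer the more balanced split, then the lexicographically
    smallest side.  Clade 1 is the side containing the lexicographically
    smallest leaf.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    if len(leaves) == 2:
        return CladePartition({leaves[0]: 1, leaves[1]: 2})
    candidates = []
    all_leaves = frozenset(leaves)
    for node in tree.internal_edges():
        side = frozenset(node.leaves())
        support = 100.0 if node.support is None else node.support
        small = min(len(side), len(all_leaves) - len(side))
        score = support * node.length * small
        candidates.append((score, small, tuple(sorted(side)), side))
    if not candidates:
        raise ValueError("star tree has no internal branch")
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    side = candidates[0][3]
    ref = min(all_leaves)
    clade1 = side if ref in side else all_leaves - side
    return CladePartition({l: (1 if l in clade1 else 2) for l in leaves})


def write_clades(partition: CladePartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("leaf\tclade\n")
        for leaf in sorted(partition.assignment):
            fh.write(f"{leaf}\t{partition.assignment[leaf]}\n")
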