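"""Independent brute-force oracles used by the test suite.

These are deliberately written from the operation definitions, not from
the package implementation: a top-down recursive local aligner, a pure
path-enumeration aligner for very short strings, additive-tree distance
construction, and a literal-minded repeat enumerator.
"""

from functools import lru_cache

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_local_enum(a, b, score, gap_open, gap_extend):
    """Exhaustive enumeration of every local alignment path (tiny inputs).

    Gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    best = 0.0

    def rec(i, j, acc, state):
        nonlocal best
        if acc > best:
            best = acc
        if i < n and j < m:
            rec(i + 1, j + 1, acc + score(a[i], b[j]), 0)
        if j < m:
            cost = gap_extend if state == 1 else gap_open + gap_extend
            rec(i, j + 1, acc - cost, 1)
        if i < n:
            cost = gap_extend if state == 2 else gap_open + gap_extend
            rec(i + 1, j, acc - cost, 2)

    for i in range(n):
        for j in range(m):
            rec(i, j, 0.0, 0)
    return best


def brute_local_memo(a, b, score, gap_open, gap_extend):
    """Memoized top-down recursion over (i, j, state); independent of the
    forward-matrix kernel formulation."""
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def ext(i, j, state):
        """Best score of any alignment extension starting at (i, j)."""
        options = [0.0]
        if i < n and j < m:
            options.append(score(a[i], b[j]) + ext(i + 1, j + 1, 0))
        if j < m:
            cost = gap_extend if state == 1 else gap_open + gap_extend
            options.append(-cost + ext(i, j + 1, 1))
        if i < n:
            cost = gap_extend if state == 2 else gap_open + gap_extend
            options.append(-cost + ext(i + 1, j, 2))
        return max(options)

    best = 0.0
    for i in range(n):
        for j in range(m):
            v = ext(i, j, 0)
            if v > best:
                best = v
    ext.cache_clear()
    return best


# ---------------------------------------------------------------------------
# additive trees for NJ consistency

def random_additive_tree(n_taxa, rng):
    """Random binary unrooted tree; returns (adjacency, leaf names,
    bipartitions as frozensets of leaf names)."""
    names = [f"t{i}" for i in range(n_taxa)]
    adj = {0: {}, 1: {}}
    blen = lambda: float(rng.uniform(0.05, 1.0))
    adj[0][1] = adj[1][0] = blen()
    next_node = 2
    leaves = {0: names[0], 1: names[1]}
    for k in range(2, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(0, len(edges))]
        w = next_node
        leaf = next_node + 1
        next_node += 2
        d_uv = adj[u].pop(v)
        adj[v].pop(u)
        adj.setdefault(w, {})
        adj.setdefault(leaf, {})
        split = float(rng.uniform(0.2, 0.8)) * d_uv
        adj[u][w] = adj[w][u] = split
        adj[w][v] = adj[v][w] = d_uv - split
        adj[w][leaf] = adj[leaf][w] = blen()
        leaves[leaf] = names[k]
    return adj, leaves


def tree_distances(adj, leaves):
    """All-pairs path-length distances between leaves."""
    import heapq
    names = sorted(leaves.values())
    node_of = {v: k for k, v in leaves.items()}
    dist = {}
    for a in names:
        src = node_of[a]
        d = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            dd, u = heapq.heappop(heap)
            if dd > d.get(u, float("inf")):
                continue
            for v, w in adj[u].items():
                nd = dd + w
                if nd < d.get(v, float("inf")):
                    d[v] = nd
                    heapq.heappush(heap, (nd, v))
        for b in names:
            dist[(a, b)] = d[node_of[b]]
    return names, dist


def tree_bipartitions(adj, leaves):
    """Non-trivial bipartitions (frozenset of one side's leaf names)."""
    all_names = frozenset(leaves.values())
    ref = min(all_names)
    out = set()
    for u in adj:
        for v in adj[u]:
            if u > v:
                continue
            # leaves on v's side when edge (u,v) removed
            seen = {u, v}
            stack = [v]
            side = set()
            while stack:
                x = stack.pop()
                if x in leaves:
                    side.add(leaves[x])
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if 2 <= len(side) <= len(all_names) - 2:
                fs = frozenset(side)
                if ref in fs:
                    fs = all_names - fs
                out.add(fs)
    return out


# ---------------------------------------------------------------------------
# repeats

def oracle_inverted(s, min_arm, max_loop, max_mismatch):
    """All (arm1_start, arm2_start, arm_len, loop, mism) 1-based hits,
    maximal outward extension per (loop position, loop length), with
    trailing-mismatch trimming; mirrors the documented definition."""
    n = len(s)
    hits = []
    for g in range(0, max_loop + 1):
        for a in range(1, n):
            if a + g >= n:
                break
            mism = 0
            L = 0
            best = None
            while a - L - 1 >= 0 and a + g + L < n:
                c1, c2 = s[a - L - 1], s[a + g + L]
                if COMP.get(c2) != c1 or c1 == "N":
                    mism += 1
                    if mism > max_mismatch:
                        break
                L += 1
                if L >= min_arm:
                    best = (L, mism)
            if best:
                L, mism = best
                while L > min_arm:
                    c1, c2 = s[a - L], s[a + g + L - 1]
                    if COMP.get(c2) != c1 or c1 == "N":
                        L -= 1
                        mism -= 1
                    else:
                        break
                hits.append((a - L + 1, a + g + 1, L, g, mism))
    return hits


def oracle_direct(s, min_arm, max_mismatch):
    n = len(s)
    hits = []
    for i in range(n):
        for j in range(i + min_arm, n):
            mism = 0
            L = 0
            best = None
            while i + L < j and j + L < n:
                if s[i + L] != s[j + L] or s[i + L] == "N":
                    mism += 1
                    if mism > max_mismatch:
                        break
                L += 1
                if L >= min_arm:
                    best = (L, mism)
            if best:
                L, mism = best
                while L > min_arm and (s[i + L - 1] != s[j + L - 1]
                                       or s[i + L - 1] == "N"):
                    L -= 1
                    mism -= 1
                hits.append((i + 1, j + 1, L, j - i - L, mism))
    return hits


def naive_inverted_words(s, min_arm, max_loop):
    """All exact inverted-repeat word pairs found by brute substring
    comparison: (arm1_start, arm2_start, arm_len, loop) 1-based."""
    n = len(s)
    out = []
    for L in range(min_arm, n // 2 + 1):
        for i in range(n - L + 1):
            word = s[i:i + L]
            rc = "".join(COMP.get(c, "N") for c in reversed(word))
            if "N" in word:
                continue
            for g in range(0, max_loop + 1):
                j = i + L + g
                if j + L > n:
                    break
                if s[j:j + L] == rc:
                    out.append((i + 1, j + 1, L, g))
    return out


def naive_direct_words(s, min_arm):
    """All exact direct-repeat word pairs (non-overlapping)."""
    n = len(s)
    out = []
    for L in range(min_arm, n // 2 + 1):
        for i in range(n - L + 1):
            if "N" in s[i:i + L]:
                continue
            for j in range(i + L, n - L + 1):
                if s[j:j + L] == s[i:i + L]:
                    out.append((i + 1, j + 1, L))
    return out
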