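"""Independent oracles used by the test suite.

These deliberately avoid the package's implementation paths: a plain-python
affine-gap dynamic program with exhaustive backtracking over all optimal
alignments, a cut-edge enumeration for monophyly, and the Jukes-Cantor
closed form. They are slow and simple on purpose.
"""

from __future__ import annotations

import math
import random

NEG = -(10 ** 9)


# -- alignment oracle ------------------------------------------------------

def score_alignment(row_a: str, row_b: str, match=2, mismatch=-3,
                    gap_open=-5, gap_extend=-2):
    """Score a gapped pair column by column; terminal gap runs (a maximal
    run of gaps touching either end of the alignment, in one row) are free.
    Gap runs cost gap_open + len * gap_extend. Returns
    (score, internal_gap_columns, identical, denominator, a_res, b_res)
    where denominator/identical are over the non-terminal region."""
    L = len(row_a)
    assert len(row_b) == L

    def first_res(row):
        return L - len(row.lstrip("-"))

    def last_res(row):
        return len(row.rstrip("-"))

    lo = max(first_res(row_a), first_res(row_b))
    hi = min(last_res(row_a), last_res(row_b))
    if hi <= lo:
        return 0, 0, 0, 0, 0, 0
    score = 0
    gapcols = 0
    ident = 0
    a_res = b_res = 0
    k = lo
    while k < hi:
        ca, cb = row_a[k], row_b[k]
        if ca != "-" and cb != "-":
            score += match if ca == cb else mismatch
            ident += ca == cb
            a_res += 1
            b_res += 1
            k += 1
        else:
            row = row_a if ca == "-" else row_b
            g = 0
            while k < hi and row[k] == "-":
                if row is row_a:
                    b_res += 1
                else:
                    a_res += 1
                g += 1
                k += 1
            score += gap_open + g * gap_extend
            gapcols += g
    return score, gapcols, ident, hi - lo, a_res, b_res


def _dp(a: str, b: str, match, mismatch, gap_open, gap_extend):
    n, m = len(a), len(b)
    go = gap_open + gap_extend
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + go)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + go)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + sub, E[i][j], F[i][j])
    return H, E, F


def optimal_alignments(a: str, b: str, match=2, mismatch=-3, gap_open=-5,
                       gap_extend=-2, cap=20000):
    """Every optimal-score semi-global alignment as a gapped pair."""
    n, m = len(a), len(b)
    go = gap_open + gap_extend
    H, E, F = _dp(a, b, match, mismatch, gap_open, gap_extend)
    best = max(max(H[n]), max(H[i][m] for i in range(n + 1)))
    ends = [(n, j) for j in range(m + 1) if H[n][j] == best]
    ends += [(i, m) for i in range(n) if H[i][m] == best]

    out = []

    def emit(path, i, j, ie, je):
        ra = list("-" * j + a[:i])
        rb = list(b[:j] + "-" * i)
        pa, pb = i, j
        for op in reversed(path):
            if op == "d":
                ra.append(a[pa]); rb.append(b[pb]); pa += 1; pb += 1
            elif op == "u":
                ra.append(a[pa]); rb.append("-"); pa += 1
            else:
                ra.append("-"); rb.append(b[pb]); pb += 1
        ra += list(a[ie:]) + ["-"] * (m - je)
        rb += ["-"] * (n - ie) + list(b[je:])
        out.append(("".join(ra), "".join(rb)))

    def walk(i, j, state, path, ie, je):
        if len(out) >= cap:
            return
        if state == "H":
            if i == 0 or j == 0:
                emit(path, i, j, ie, je)
                return
            sub = match if a[i - 1] == b[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + sub:
                walk(i - 1, j - 1, "H", path + ["d"], ie, je)
            if H[i][j] == F[i][j]:
                walk(i, j, "F", path, ie, je)
            if H[i][j] == E[i][j]:
                walk(i, j, "E", path, ie, je)
        elif state == "F":
            if F[i][j] == H[i - 1][j] + go:
                walk(i - 1, j, "H", path + ["u"], ie, je)
            if F[i][j] == F[i - 1][j] + gap_extend:
                walk(i - 1, j, "F", path + ["u"], ie, je)
        else:
            if E[i][j] == H[i][j - 1] + go:
                walk(i, j - 1, "H", path + ["l"], ie, je)
            if E[i][j] == E[i][j - 1] + gap_extend:
                walk(i, j - 1, "E", path + ["l"], ie, je)

    for (ie, je) in ends:
        walk(ie, je, "H", [], ie, je)
    assert out, "no optimal alignment reconstructed"
    return best, out


def oracle_stats(a: str, b: str, match=2, mismatch=-3, gap_open=-5,
                 gap_extend=-2):
    """(best score, min internal gap columns among optimal alignments,
    set of (identical, denominator, a_res, b_res) over optimal alignments
    with that minimal gap-column count)."""
    best, alns = optimal_alignments(a, b, match, mismatch, gap_open,
                                    gap_extend)
    scored = []
    for ra, rb in alns:
        s, g, ident, denom, a_res, b_res = score_alignment(
            ra, rb, match, mismatch, gap_open, gap_extend)
        assert s == best, (ra, rb, s, best)
        scored.append((g, ident, denom, a_res, b_res))
    min_g = min(s[0] for s in scored)
    stats = {(i, d, ar, br) for g, i, d, ar, br in scored if g == min_g}
    return best, min_g, stats


# -- monophyly oracle ------------------------------------------------------

def monophyly_by_edge_cut(tree, species_of):
    """Brute-force monophyly by cutting every edge of the (unrooted) tree.

    ``tree`` is a dendropy tree whose internal node labels are supports.
    Returns {species: (n_tips, is_monophyletic, support)} for every species.
    Support is read from the internal endpoint on the species' side of the
    separating edge.
    """
    import collections

    adj = collections.defaultdict(set)
    labels = {}
    leaves = {}
    child_edges = []  # (tail, head): the head is the node "below" the edge
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        adj[edge.tail_node].add(edge.head_node)
        adj[edge.head_node].add(edge.tail_node)
        child_edges.append((edge.tail_node, edge.head_node))
    for node in tree.preorder_node_iter():
        labels[node] = node.label
        if node.is_leaf():
            leaves[node] = node.taxon.label
    all_tips = frozenset(leaves.values())

    def side_of(u, v):
        """Leaf labels reachable from u without crossing edge (u, v)."""
        seen = {v, u}
        stack = [u]
        tips = set()
        while stack:
            x = stack.pop()
            if x in leaves:
                tips.add(leaves[x])
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(tips)

    def label_of(node):
        if node in leaves or labels[node] is None:
            return None
        try:
            return float(labels[node])
        except ValueError:
            return None

    tips_by_sp = collections.defaultdict(set)
    for leaf_label in all_tips:
        tips_by_sp[species_of[leaf_label]].add(leaf_label)

    # each child edge's split, read from the head (the rooted-newick node
    # that carries the edge's support label)
    splits = [(side_of(head, tail), label_of(head))
              for tail, head in child_edges]

    out = {}
    for sp, tips in tips_by_sp.items():
        tips = frozenset(tips)
        n = len(tips)
        if n == 1 or tips == all_tips:
            out[sp] = (n, True, None)
            continue
        found = False
        tips_side = []
        other_side = []
        for s, lab in splits:
            if s == tips:
                found = True
                if lab is not None:
                    tips_side.append(lab)
            elif s == all_tips - tips:
                found = True
                if lab is not None:
                    other_side.append(lab)
        if tips_side:
            support = max(tips_side)
        elif other_side:
            support = max(other_side)
        else:
            support = None
        out[sp] = (n, found, support if found else None)
    return out


def random_newick(rng: random.Random, n_leaves: int,
                  support_low=0, support_high=100) -> tuple[str, dict]:
    """A random rooted-binary newick over t1..tN with every internal node
    labeled with an integer support, plus a random species mapping that mixes
    planted clades and scattered assignments."""
    labels = [f"t{i + 1}" for i in range(n_leaves)]
    rng.shuffle(labels)

    def build(items):
        if len(items) == 1:
            return items[0], [items[0]]
        k = rng.randint(1, len(items) - 1)
        left, lt = build(items[:k])
        right, rt = build(items[k:])
        sup = rng.randint(support_low, support_high)
        return f"({left},{right}){sup}", lt + rt

    nwk, _ = build(labels)
    clades = []

    # species: some leaves share species at random, some form planted pairs
    species_of = {}
    pool = labels[:]
    sp = 0
    while pool:
        sp += 1
        size = min(len(pool), rng.choice([1, 1, 1, 2, 2, 3]))
        for leaf in pool[:size]:
            species_of[leaf] = f"sp{sp:03d}"
        pool = pool[size:]
    return nwk + ";", species_of


# -- Jukes-Cantor ----------------------------------------------------------

def jc_expected_identity(total_branch_length: float) -> float:
    """Expected percent identity across a JC branch of the given length."""
    return 100.0 * (1.0 - 0.75 * (1.0 - math.exp(
        -4.0 * total_branch_length / 3.0)))
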