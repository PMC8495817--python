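"""Supported-monophyly counting on specimen trees, plus a stand-in builder.

Phylogenetic resolution counts, among species with more than one sampled
specimen, those recovered as monophyletic with bootstrap support at or above
a threshold (default 70). Monophyly is defined on unrooted bipartitions: a
species is monophyletic iff some internal edge separates exactly its tip set
from all other tips, and the support of that edge is the species' support.
A species whose tips hang off one polytomy without an exclusive edge is not
monophyletic.

Trees are accepted from any external inference as newick with supports on
internal node labels. The package's own builder is neighbor joining over
p-distances with nonparametric column-bootstrap supports -- a self-contained
stand-in for heavier ML inference, which is out of scope here.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SupportTree:
    """An (effectively unrooted) tree whose leaves are specimen ids; internal
    node labels, when parseable as numbers, are percent supports in [0, 100].
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dups}")
        for sup in self.supports().values():
            if sup is not None and not 0 <= sup <= 100:
                raise ValueError(f"support {sup} outside [0, 100]")

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def supports(self) -> dict[frozenset[str], float | None]:
        """Map each nontrivial unrooted split (as the normalized side not
        containing the reference leaf) to its support, or None if unlabeled."""
        return _split_supports(self.tree)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)


@dataclass(frozen=True)
class PhyloConfig:
    min_support: float = 70.0
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_support <= 100:
            raise ValueError("min_support must lie in [0, 100]")


@dataclass(frozen=True)
class MonophylyResult:
    species: str
    n_tips: int
    is_monophyletic: bool
    support: float | None
    counted_as_MS: bool


def read_newick_with_support(path: str | Path) -> SupportTree:
    """Parse newick; supports are internal node labels. Duplicate leaf labels
    or malformed newick are fatal."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"cannot parse newick file {path}: {exc}") from exc
    return SupportTree(tree)


def write_newick(tree: SupportTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick())


def _parse_support(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        return None


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= below[ch]
            below[node] = frozenset(acc)
    return below


def _normalize(side: frozenset[str], all_leaves: frozenset[str],
               ref: str) -> frozenset[str]:
    return frozenset(all_leaves - side) if ref in side else side


def _oriented_supports(
    tree: dendropy.Tree,
) -> dict[frozenset[str], float | None]:
    """Support label of each non-seed node keyed by its descendant leaf set
    (the rooted orientation in which the newick was written). Leaves appear
    too -- their pendant edges are genuine unrooted splits -- but never carry
    a support."""
    below = _leafsets(tree)
    all_leaves = below[tree.seed_node]
    out: dict[frozenset[str], float | None] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = below[node]
        if len(side) == 0 or len(side) >= len(all_leaves):
            continue  # a root with one child spans every leaf: no split
        sup = None if node.is_leaf() else _parse_support(node.label)
        if side not in out or (out[side] is None and sup is not None):
            out[side] = sup
    return out


def _split_supports(
    tree: dendropy.Tree,
) -> dict[frozenset[str], float | None]:
    """Unrooted splits (normalized to the side not containing the smallest
    leaf label) with a support each. A rooted binary representation
    duplicates the root split across the two root-child edges; whichever
    carries a label wins, ties by the larger support."""
    below = _leafsets(tree)
    all_leaves = below[tree.seed_node]
    ref = min(all_leaves)
    out: dict[frozenset[str], float | None] = {}
    for side, sup in _oriented_supports(tree).items():
        key = _normalize(side, all_leaves, ref)
        prev = out.get(key)
        if key not in out or (prev is None and sup is not None) or (
                prev is not None and sup is not None and sup > prev):
            out[key] = sup
    return out


def species_monophyly(
    tree: SupportTree,
    species_of: Mapping[str, str],
    cfg: PhyloConfig = PhyloConfig(),
) -> list[MonophylyResult]:
    """Monophyly and support of every species on the tree.

    Every leaf must map to a species. Species with one tip are trivially
    monophyletic but never counted toward MS; a species comprising all tips
    has no separating bipartition and is reported monophyletic with no
    support.
    """
    leaves = frozenset(tree.leaf_labels)
    unmapped = sorted(leaves - set(species_of))
    if unmapped:
        raise KeyError(f"leaves without species mapping: {unmapped}")
    ref = min(leaves)
    splits = tree.supports()
    oriented = _oriented_supports(tree.tree)
    tips_by_species: dict[str, set[str]] = {}
    for leaf in leaves:
        tips_by_species.setdefault(species_of[leaf], set()).add(leaf)
    results: list[MonophylyResult] = []
    for sp in sorted(tips_by_species):
        tips = frozenset(tips_by_species[sp])
        n = len(tips)
        if n == 1:
            results.append(MonophylyResult(sp, 1, True, None, False))
            continue
        if tips == leaves:
            results.append(MonophylyResult(sp, n, True, None, False))
            continue
        key = _normalize(tips, leaves, ref)
        if key in splits:
            # prefer the label of the node whose descendants are exactly the
            # species (matters only for the duplicated root split of a
            # rooted binary representation)
            sup = oriented.get(tips)
            if sup is None:
                sup = splits[key]
            counted = sup is not None and sup >= cfg.min_support
            results.append(MonophylyResult(sp, n, True, sup, counted))
        else:
            results.append(MonophylyResult(sp, n, False, None, False))
    return results


def phylo_summary(
    results: Sequence[MonophylyResult],
) -> tuple[int, int, int, int]:
    """(SSA, SMA, MS, NMS): single-accession species, multi-accession species,
    supported-monophyletic among them, and the remainder."""
    SSA = sum(1 for r in results if r.n_tips == 1)
    SMA = sum(1 for r in results if r.n_tips >= 2)
    MS = sum(1 for r in results if r.counted_as_MS)
    return SSA, SMA, MS, SMA - MS


def nj_tree(distance: pd.DataFrame) -> SupportTree:
    """Neighbor-joining topology from a symmetric distance matrix (supports
    absent; negative branch lengths clamped to 0)."""
    ids = list(distance.index)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if list(distance.columns) != ids:
        raise ValueError("distance matrix rows and columns must match")
    arr = distance.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if (arr < 0).any():
        raise ValueError("distances must be nonnegative")
    buf = io.StringIO()
    pd.DataFrame(arr, index=ids, columns=ids).to_csv(buf)
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.label = None
    tree.is_rooted = False
    return SupportTree(tree)


def p_distance_matrix(aligned: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise proportion of differing sites over columns where neither row
    has a gap (0 when no comparable column exists)."""
    ids = sorted(aligned)
    lens = {len(aligned[i]) for i in ids}
    if len(lens) != 1:
        raise ValueError("aligned rows must have equal length")
    mat = np.frombuffer("".join(aligned[i] for i in ids).encode(),
                        dtype=np.uint8).reshape(len(ids), -1)
    gap = mat == ord("-")
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            tot = int(ok.sum())
            d = float((mat[i][ok] != mat[j][ok]).sum() / tot) if tot else 0.0
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


def bootstrap_supports(
    aligned: Mapping[str, str],
    cfg: PhyloConfig = PhyloConfig(),
    builder: Callable[[pd.DataFrame], SupportTree] = nj_tree,
) -> SupportTree:
    """Nonparametric column-bootstrap supports over a distance tree builder.

    The original tree is built from the full alignment; each replicate
    resamples alignment columns with replacement, rebuilds, and each original
    bipartition's support is the percentage of replicates containing it.
    Deterministic given cfg.seed.
    """
    if cfg.n_bootstrap <= 0:
        raise ValueError("n_bootstrap must be positive")
    if len(aligned) < 3:
        raise ValueError("need at least 3 specimens")
    ids = sorted(aligned)
    L = len(aligned[ids[0]])
    original = builder(p_distance_matrix(aligned))
    below = _leafsets(original.tree)
    all_leaves = below[original.tree.seed_node]
    ref = min(all_leaves)
    target_splits = set(_split_supports(original.tree))

    counts = {k: 0 for k in target_splits}
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.n_bootstrap):
        idx = rng.integers(0, L, size=L)
        resampled = {i: "".join(aligned[i][j] for j in idx) for i in ids}
        rep = builder(p_distance_matrix(resampled))
        rep_splits = set(_split_supports(rep.tree))
        for k in target_splits & rep_splits:
            counts[k] += 1

    for node in original.tree.preorder_node_iter():
        if node is original.tree.seed_node or node.is_leaf():
            continue
        side = below[node]
        key = _normalize(side, all_leaves, ref)
        if key in counts:
            pct = 100.0 * counts[key] / cfg.n_bootstrap
            node.label = f"{pct:g}"
    return SupportTree(original.tree)


def monophyly_to_frame(results: Sequence[MonophylyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "n_tips": r.n_tips,
                "is_monophyletic": r.is_monophyletic,
                "support": "" if r.support is None else r.support,
                "counted_as_MS": r.counted_as_MS,
            }
            for r in results
        ],
        columns=["species", "n_tips", "is_monophyletic", "support",
                 "counted_as_MS"],
    )


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_distance_matrix(distance: pd.DataFrame, path: str | Path) -> None:
    distance.to_csv(path, sep="\t", index_label="")
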