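"""Phylogeny-based resolution of ambiguous kinase classifications.

Catalytic domains are stacked into a common column space by aligning each
sequence independently to the domain profile (insertions relative to the
profile are discarded), low-occupancy columns are removed, and a
neighbor-joining tree is built from protein distances.  Bootstrap support
comes from column resampling; rooting on a designated outgroup allows
unlabeled leaves to inherit the majority group label of their smallest
well-supported enclosing clade.

Trees are :class:`dendropy.Tree` objects throughout; Newick export carries
branch lengths and integer bootstrap values as internal-node labels.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np

from .domain_scan import DomainProfile, align_sequence_to_profile

#: Distances larger than this are capped (Kimura correction log singularity).
MAX_DISTANCE = 10.0


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over a shared column space."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must share one length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def column_occupancy(self) -> np.ndarray:
        """Fraction of non-gap characters per column."""
        arr = np.array([list(r) for r in self.rows])
        return (arr != "-").mean(axis=0)


# ---------------------------------------------------------------------------
# alignment to the profile and block selection
# ---------------------------------------------------------------------------

def align_to_profile(domains: Sequence[tuple[str, str]],
                     profile: DomainProfile) -> MultipleAlignment:
    """Align each ``(id, sequence)`` pair to the profile match states.

    Every sequence is aligned independently, so all rows share the
    profile-relative column space (one column per match state).  Profile
    positions skipped by a sequence become gaps; sequence residues inserted
    between match states are discarded.  Sequences without a
    positive-scoring path are excluded with a warning.
    """
    ids: list[str] = []
    rows: list[str] = []
    for name, seq in domains:
        score, path = align_sequence_to_profile(seq, profile)
        if score <= 0:
            warnings.warn(
                f"sequence {name!r} has no positive-scoring alignment to the "
                "profile; excluded", stacklevel=2,
            )
            continue
        row = ["-"] * profile.length
        for state, i, j in path:
            if state == "M":
                row[i] = seq[j]
        ids.append(name)
        rows.append("".join(row))
    return MultipleAlignment(ids=ids, rows=rows)


def select_blocks(msa: MultipleAlignment,
                  min_occupancy: float = 0.8) -> MultipleAlignment:
    """Keep only columns whose occupancy reaches ``min_occupancy``.

    A non-positive threshold is clamped to the smallest positive fraction
    (one sequence), so all-gap columns never survive.
    """
    if min_occupancy > 1:
        raise ValueError("min_occupancy must be <= 1")
    min_occupancy = max(min_occupancy, 1.0 / max(len(msa.rows), 1))
    occ = msa.column_occupancy
    keep = np.where(occ >= min_occupancy)[0]
    if keep.size == 0:
        raise ValueError(
            "no columns reach the occupancy threshold; lower min_occupancy"
        )
    rows = ["".join(r[c] for c in keep) for r in msa.rows]
    return MultipleAlignment(ids=list(msa.ids), rows=rows)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_matrix(msa: MultipleAlignment, model: str = "p_distance",
                    max_distance: float = MAX_DISTANCE) -> np.ndarray:
    """Pairwise distances over columns where both rows are non-gap.

    ``p_distance`` is the raw mismatch fraction; ``kimura_protein`` applies
    the correction ``d = -ln(1 - p - p^2/5)``, capped at ``max_distance``
    (with a warning) once ``p >= 0.85`` where the logarithm diverges.
    """
    if model not in ("p_distance", "kimura_protein"):
        raise ValueError(f"unknown distance model {model!r}")
    n = len(msa.rows)
    if n < 3:
        raise ValueError("distance matrix requires >= 3 sequences")
    arr = np.array([list(r) for r in msa.rows])
    nongap = arr != "-"
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no "
                    "comparable columns"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / m
            if model == "p_distance":
                d = p
            else:
                if p >= 0.85:
                    warnings.warn(
                        f"p={p:.3f} beyond the Kimura correction range for "
                        f"({msa.ids[i]!r}, {msa.ids[j]!r}); capping distance",
                        stacklevel=2,
                    )
                    d = max_distance
                else:
                    d = min(-np.log(1.0 - p - 0.2 * p * p), max_distance)
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(D: np.ndarray, ids: Sequence[str]) -> dendropy.Tree:
    """Canonical Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing
    ``Q(i, j) = (m - 2) D(i, j) - sum_k D(i, k) - sum_k D(j, k)``,
    breaking ties by the smallest index pair.  Negative branch-length
    estimates are clamped to zero with the deficit moved to the sibling
    branch.  The result is unrooted (trifurcating seed node).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(ids):
        raise ValueError("distance matrix and ids have inconsistent shapes")
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in ids:
        taxon = tns.new_taxon(label=label)
        nodes.append(dendropy.Node(taxon=taxon))

    W = D.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = W.sum(axis=1)
        Q = (m - 2) * W - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * W[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = W[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        d_new = 0.5 * (W[i, :] + W[j, :] - W[i, j])
        W[i, :] = d_new
        W[:, i] = d_new
        W[i, i] = 0.0
        nodes[i] = parent
        W = np.delete(np.delete(W, j, axis=0), j, axis=1)
        del nodes[j]

    root = dendropy.Node()
    a = 0.5 * (W[0, 1] + W[0, 2] - W[1, 2])
    b = 0.5 * (W[0, 1] + W[1, 2] - W[0, 2])
    c = 0.5 * (W[0, 2] + W[1, 2] - W[0, 1])
    for node, length in zip(nodes, (a, b, c)):
        root.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += -li
        li = 0.0
    if lj < 0:
        li += -lj
        lj = 0.0
    return li, max(lj, 0.0)


def path_length_matrix(tree: dendropy.Tree,
                       ids: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths, ordered like ``ids``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
            out[i, j] = out[j, i] = d
    return out


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions keyed by their rooting-independent leaf set.

    Each internal edge is represented by the side of its bipartition that
    does not contain the lexicographically smallest leaf, so the encoding
    is invariant to rooting.
    """
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves)
    parts: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if ref not in below else leaves - below
        if 2 <= len(side) <= len(leaves) - 2:
            parts[side] = node
    return parts


def bootstrap_support(
    msa: MultipleAlignment,
    B: int = 1000,
    seed: int = 0,
    model: str = "p_distance",
    tree_builder: Callable[[np.ndarray, Sequence[str]], dendropy.Tree] = nj_tree,
) -> dendropy.Tree:
    """Column-resampling bootstrap of the distance/NJ tree.

    Builds the tree from the full alignment, resamples columns with
    replacement ``B`` times, rebuilds, and annotates each internal node with
    ``node.support``: the percentage of replicates containing the same
    (rooting-independent) bipartition.  Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    tree = tree_builder(distance_matrix(msa, model), msa.ids)
    parts = _bipartitions(tree)
    counts = {side: 0 for side in parts}
    rng = np.random.default_rng(seed)
    n_cols = msa.n_columns
    rows = np.array([list(r) for r in msa.rows])
    for _ in range(B):
        cols = rng.integers(0, n_cols, size=n_cols)
        boot = MultipleAlignment(
            ids=list(msa.ids),
            rows=["".join(row) for row in rows[:, cols]],
        )
        try:
            rep = tree_builder(distance_matrix(boot, model), boot.ids)
        except ValueError:
            continue  # a replicate may lose all comparable columns
        rep_parts = set(_bipartitions(rep))
        for side in counts:
            if side in rep_parts:
                counts[side] += 1
    for side, node in parts.items():
        node.support = 100.0 * counts[side] / B
        node.label = str(int(round(node.support)))
    return tree


def support_by_bipartition(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Map each annotated bipartition to its bootstrap percentage."""
    out = {}
    for side, node in _bipartitions(tree).items():
        support = getattr(node, "support", None)
        if support is None and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        if support is not None:
            out[side] = support
    return out


# ---------------------------------------------------------------------------
# clade-majority reclassification
# ---------------------------------------------------------------------------

def reclassify_by_clade(tree: dendropy.Tree,
                        labels: Mapping[str, str],
                        outgroup: str,
                        k: int = 3,
                        s: float = 50.0) -> dict[str, str]:
    """Transfer group labels to unlabeled leaves by clade majority.

    The tree is rooted on ``outgroup``; each unlabeled leaf inherits the
    majority label of its smallest enclosing clade holding at least ``k``
    labeled leaves, provided the clade's bootstrap support is at least
    ``s``.  In a tree without any support annotation every clade passes;
    in an annotated tree a clade lacking a support value (e.g. the root)
    does not.  Ties on the majority are broken lexicographically.  Returns
    ``{leaf: new_label}`` for the leaves that could be labeled.
    """
    if not labels:
        raise ValueError("at least one labeled leaf is required")
    support = support_by_bipartition(tree)
    leaves_all = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves_all)

    work = tree.clone(depth=1)
    og = work.find_node_with_taxon_label(outgroup)
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    work.reroot_at_edge(og.edge, update_bipartitions=False)

    def clade_support(node: dendropy.Node) -> float | None:
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if ref not in below else leaves_all - below
        return support.get(side)

    new_labels: dict[str, str] = {}
    for leaf in work.leaf_node_iter():
        name = leaf.taxon.label
        if name in labels or name == outgroup:
            continue
        node = leaf.parent_node
        while node is not None:
            clade_labels = [
                labels[l.taxon.label] for l in node.leaf_iter()
                if l.taxon.label in labels
            ]
            if len(clade_labels) >= k:
                sup = clade_support(node)
                if (sup is None and not support) or (sup is not None
                                                     and sup >= s):
                    counts = Counter(clade_labels)
                    top = max(counts.values())
                    new_labels[name] = min(
                        lbl for lbl, c in counts.items() if c == top
                    )
                    break
            node = node.parent_node
    return new_labels


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write the tree with branch lengths and support labels."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))
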