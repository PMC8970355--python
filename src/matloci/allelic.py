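"""Allelic-class inference from amino-acid identity and gene trees.

Mating-gene proteins are grouped into allelic classes by single-linkage
clustering of pairwise amino-acid identity (AAI) at a threshold (86% by
default): two strains share a class iff they are connected by a chain of
pairs each with AAI >= tau.  Distinct classes behave as distinct mating
specificities.  Classes are cross-checked against a phylogeny (clade
concordance) and gene trees are tested for reciprocal monophyly of the two
species -- its failure at a locus is the trans-species-polymorphism signal.

Class labels are canonical (decreasing class size, ties broken by the
lexicographically smallest member) so outputs are order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .io import SpeciesAlignment, read_newick


@dataclass
class AAIMatrix:
    """Symmetric pairwise percent amino-acid identity, diagonal 100."""

    strains: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.strains)
        if self.matrix.shape != (n, n):
            raise ValidationError("AAI matrix shape does not match strain list")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValidationError("AAI matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 100.0):
            raise ValidationError("AAI matrix diagonal must be 100")
        if self.matrix.min() < 0 or self.matrix.max() > 100:
            raise ValidationError("AAI values must lie in [0, 100]")

    def value(self, s1: str, s2: str) -> float:
        i, j = self.strains.index(s1), self.strains.index(s2)
        return float(self.matrix[i, j])


@dataclass
class AllelicClassification:
    gene_id: str
    class_of: dict[str, int]
    threshold: float
    n_classes: int
    concordant_with_tree: dict[int, bool] | None = None

    def members(self, label: int) -> list[str]:
        return [s for s, c in self.class_of.items() if c == label]


def pairwise_aai(aln: SpeciesAlignment) -> AAIMatrix:
    """Percent identity per pair: identical non-gap residues / columns where
    at least one of the pair is non-gap.  Gap-vs-residue counts as mismatch;
    gap-vs-gap columns are excluded from the denominator."""
    if aln.alphabet != "protein":
        raise ValidationError("pairwise_aai requires a protein alignment")
    strains = aln.strains
    if not strains:
        raise ValidationError("empty alignment")
    rows = {s: np.frombuffer(aln.seqs[s].encode(), dtype="S1") for s in strains}
    gap = b"-"
    n = len(strains)
    mat = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        a, b = rows[strains[i]], rows[strains[j]]
        scored = (a != gap) | (b != gap)
        ns = int(scored.sum())
        if ns == 0:
            ident = 100.0  # two all-gap rows: vacuously identical
        else:
            match = (a == b) & (a != gap)
            ident = 100.0 * int(match.sum()) / ns
        mat[i, j] = mat[j, i] = ident
    return AAIMatrix(strains=strains, matrix=mat)


def _canonical_labels(groups: list[list[str]], strains: list[str]) -> dict[str, int]:
    groups = sorted(groups, key=lambda g: (-len(g), min(g)))
    out: dict[str, int] = {}
    for label, members in enumerate(groups, start=1):
        for s in members:
            out[s] = label
    return {s: out[s] for s in strains}


def aai_cluster(
    matrix: AAIMatrix,
    tau: float = 86.0,
    gene_id: str = "",
    method: str = "single",
) -> AllelicClassification:
    """Cluster strains into allelic classes at AAI threshold tau.

    Single linkage (the default, matching the chain-within-clade structure
    of allelic classes) is computed as connected components of the
    AAI >= tau graph; ``method="average"`` (UPGMA cut at 100 - tau) is
    available for exploration.
    """
    if not (0.0 < tau <= 100.0):
        raise ValidationError(f"tau must be in (0, 100], got {tau}")
    strains = matrix.strains
    n = len(strains)
    if method == "single":
        adj = csr_matrix(matrix.matrix >= tau)
        _, comp = connected_components(adj, directed=False)
    elif method == "average":
        if n < 2:
            comp = np.zeros(n, dtype=int)
        else:
            dist = squareform(100.0 - matrix.matrix, checks=False)
            comp = fcluster(linkage(dist, method="average"), 100.0 - tau, "distance")
    else:
        raise ValidationError(f"unknown linkage method {method!r}")
    groups: dict[int, list[str]] = {}
    for s, c in zip(strains, comp):
        groups.setdefault(int(c), []).append(s)
    class_of = _canonical_labels(list(groups.values()), strains)
    return AllelicClassification(
        gene_id=gene_id,
        class_of=class_of,
        threshold=tau,
        n_classes=len(groups),
    )


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(matrix: AAIMatrix) -> str:
    """Saitou-Nei neighbor joining on d = (100 - AAI) / 100.

    Ties in the Q matrix are broken by the smallest (i, j) index pair, so
    the output is deterministic.  Returns an unrooted Newick string with
    branch lengths (negative estimates reported as computed).
    """
    labels = list(matrix.strains)
    if len(labels) < 3:
        raise ValidationError("nj_tree requires at least 3 taxa")
    d = (100.0 - matrix.matrix.astype(float)) / 100.0
    nodes = [f"{l}" for l in labels]  # newick fragments
    active = list(range(len(labels)))
    dist = {(i, j): d[i, j] for i in range(len(labels)) for j in range(len(labels))}
    frag = {i: nodes[i] for i in active}
    next_id = len(labels)
    while len(active) > 2:
        r = len(active)
        totals = {i: sum(dist[(i, j)] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist[(i, j)] - totals[i] - totals[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = dist[(i, j)]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2.0 * (r - 2))
        lj = dij - li
        frag[next_id] = f"({frag[i]}:{li:.10f},{frag[j]}:{lj:.10f})"
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (dist[(i, k)] + dist[(j, k)] - dij)
            dist[(next_id, k)] = dist[(k, next_id)] = dk
        dist[(next_id, next_id)] = 0.0
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    i, j = active
    return f"({frag[i]}:{dist[(i, j)] / 2:.10f},{frag[j]}:{dist[(i, j)] / 2:.10f});"


# ---------------------------------------------------------------------------
# Tree-based checks


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return read_newick(tree)


def _edge_leafsets(tree: dendropy.Tree) -> list[frozenset[str]]:
    sets = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([node.taxon.label])
        else:
            node._leafset = frozenset().union(*(c._leafset for c in node.child_nodes()))
        if node.parent_node is not None:
            sets.append(node._leafset)
    return sets


def clade_concordance(
    classification: AllelicClassification, tree
) -> dict[int, bool]:
    """Per-class flag: a class is concordant iff its strain set forms a
    clade under some rooting of the tree, i.e. the set or its complement is
    a split of the unrooted tree."""
    tree = _as_tree(tree)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    classified = frozenset(classification.class_of)
    if leaves != classified:
        diff = sorted(leaves.symmetric_difference(classified))
        raise ValidationError(
            f"tree/classification leaf mismatch: {diff}"
        )
    splits = set(_edge_leafsets(tree))
    flags: dict[int, bool] = {}
    for label in sorted(set(classification.class_of.values())):
        members = frozenset(classification.members(label))
        comp = leaves - members
        flags[label] = (
            len(members) == 1
            or len(comp) == 0
            or members in splits
            or comp in splits
        )
    classification.concordant_with_tree = flags
    return flags


def reciprocal_monophyly(
    tree,
    species_of: dict[str, str],
    outgroup_label: str | None = None,
) -> tuple[dict[str, bool], bool]:
    """Monophyly of each species on a gene tree.

    With an outgroup the tree is rooted on it and a species is monophyletic
    iff its tips form a clade.  Without an outgroup the unrooted criterion
    is used: the species' tips (or their complement) form a split.
    Returns (per-species flags, overall flag).
    """
    tree = _as_tree(tree)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    if outgroup_label is not None:
        if outgroup_label not in leaves:
            raise ValidationError(f"outgroup {outgroup_label!r} not in tree")
        node = tree.find_node_with_taxon_label(outgroup_label)
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
        leaves = leaves - {outgroup_label}
    splits = set(_edge_leafsets(tree))
    missing = [s for s in leaves if s not in species_of]
    if missing:
        raise ValidationError(f"tips without species label: {sorted(missing)}")
    flags: dict[str, bool] = {}
    for sp in sorted(set(species_of[l] for l in leaves)):
        tips = frozenset(l for l in leaves if species_of[l] == sp)
        comp = leaves - tips
        if outgroup_label is not None:
            # rooted: the tips themselves must be a clade (the outgroup side
            # of the root breaks complement symmetry)
            flags[sp] = len(tips) == 1 or tips in splits
        else:
            flags[sp] = (
                len(tips) == 1 or len(comp) == 0 or tips in splits or comp in splits
            )
    return flags, all(flags.values())
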