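"""Distance and likelihood phylogenetics under the Jukes-Cantor model.

Workflow mirrors the classic ITS analysis: complete deletion of gapped
or ambiguous alignment columns, JC69 pairwise distances, neighbor
joining, maximum-likelihood branch lengths on the NJ topology via
Felsenstein pruning, and a seeded bootstrap with majority-rule
consensus whose supports are bipartition frequencies in percent.

Trees are held as :class:`dendropy.Tree` objects; newick serialization
writes bootstrap supports as internal node labels.

Under JC69 the transition probability along a branch of length t
(substitutions/site) is P(same) = 1/4 + 3/4 e^(-4t/3) and
P(different) = 1/4 - 1/4 e^(-4t/3), with stationary base frequencies
of 1/4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .align import Alignment

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

SATURATION_CAP = 5.0
_MIN_BRANCH = 1e-8
_MAX_BRANCH = 10.0


class EmptyAlignmentError(ValueError):
    """Raised when complete deletion removes every column."""


class SaturatedRowError(ValueError):
    """Raised when a taxon is saturated against every other taxon."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    saturated: np.ndarray  # boolean mask of capped entries

    def __post_init__(self) -> None:
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal not zero")

    def to_phylip(self) -> str:
        lines = [str(len(self.labels))]
        for label, row in zip(self.labels, self.d):
            lines.append(label + "\t" + "\t".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def complete_deletion(aln: Alignment) -> Alignment:
    """Keep exactly the columns where every row is an unambiguous base."""
    if len(aln.rows) < 2:
        raise ValueError("need >= 2 rows")
    keep = [
        j
        for j in range(aln.ncols)
        if all(ch in _BASES for ch in aln.column(j))
    ]
    if not keep:
        raise EmptyAlignmentError("no ungapped unambiguous columns survive")
    rows = [
        (rid, "".join(gapped[j] for j in keep)) for rid, gapped in aln.rows
    ]
    return Alignment(rows, aln.params)


def jc69_distance(
    row_a: str, row_b: str, cap: float = SATURATION_CAP
) -> tuple[float, bool]:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); (distance, saturated flag).

    p >= 3/4 lies outside the model's domain; such pairs are flagged and
    assigned the configured cap.
    """
    if len(row_a) != len(row_b) or len(row_a) == 0:
        raise ValueError("rows must have equal positive length")
    mismatches = sum(1 for x, y in zip(row_a, row_b) if x != y)
    p = mismatches / len(row_a)
    if p >= 0.75:
        return cap, True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def jc69_matrix(aln: Alignment, cap: float = SATURATION_CAP) -> DistanceMatrix:
    """All-pairs JC69 distances from a complete-deleted alignment."""
    n = len(aln.rows)
    enc = np.array(
        [[_BASE_INDEX[ch] for ch in gapped] for _rid, gapped in aln.rows],
        dtype=np.int8,
    )
    L = enc.shape[1]
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        mism = (enc[i] != enc[i + 1:]).sum(axis=1)
        p = mism / L
        with np.errstate(invalid="ignore"):
            dist = np.where(p < 0.75, -0.75 * np.log(np.maximum(1 - 4 * p / 3, 1e-300)), cap)
        d[i, i + 1:] = dist
        d[i + 1:, i] = dist
        sat[i, i + 1:] = p >= 0.75
        sat[i + 1:, i] = p >= 0.75
    mat = DistanceMatrix(aln.ids, d, sat)
    off_diag_sat = sat & ~np.eye(n, dtype=bool)
    fully = off_diag_sat.sum(axis=1) == n - 1
    if fully.any():
        bad = [aln.ids[i] for i in np.nonzero(fully)[0]]
        raise SaturatedRowError(f"taxa saturated against all others: {bad}")
    return mat


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou & Nei)
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard NJ; deterministic tie-breaking by (row, column) index.

    Negative branch lengths are clamped to zero with the deficit moved
    to the sibling branch, preserving the pair's summed length.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes = [
        dendropy.Node(taxon=taxa.get_taxon(label)) for label in dm.labels
    ]
    D = dm.d.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # ties -> smallest flat index = (row, col) order
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # New distances to the joined node, stored in slot i.
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = parent
        active.remove(j)

    i, j = active
    if nodes[i].is_leaf():
        i, j = j, i
    root = nodes[i]
    last = nodes[j]
    root.add_child(last)
    last.edge.length = max(D[i, j], 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# JC69 likelihood via Felsenstein pruning
# ---------------------------------------------------------------------------

def _jc_pmatrix(t: float) -> np.ndarray:
    if t < 0:
        raise ValueError("negative branch length")
    e = math.exp(-4.0 * t / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


def _leaf_partials(aln: Alignment) -> dict[str, np.ndarray]:
    partials = {}
    for rid, gapped in aln.rows:
        arr = np.zeros((4, len(gapped)))
        for j, ch in enumerate(gapped):
            arr[_BASE_INDEX[ch], j] = 1.0
        partials[rid] = arr
    return partials


def _postorder_partials(tree: dendropy.Tree, leaf_partials) -> dict:
    """Subtree conditional likelihoods at every node (4 x L)."""
    partials = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partials[node] = leaf_partials[node.taxon.label]
        else:
            prod = None
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                contrib = _jc_pmatrix(t) @ partials[child]
                prod = contrib if prod is None else prod * contrib
            partials[node] = prod
    return partials


def jc_log_likelihood(tree: dendropy.Tree, aln: Alignment) -> float:
    """Felsenstein pruning under JC69, summed over alignment columns."""
    _check_leaves(tree, aln)
    partials = _postorder_partials(tree, _leaf_partials(aln))
    root = tree.seed_node
    site_l = 0.25 * partials[root].sum(axis=0)
    if (site_l <= 0).any():
        return -math.inf
    return float(np.log(site_l).sum())


def _check_leaves(tree: dendropy.Tree, aln: Alignment) -> None:
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if leaves != set(aln.ids):
        raise ValueError("tree leaves and alignment rows differ")


def _outside_partials(tree, partials):
    """Likelihood of everything outside each node's subtree, evaluated
    at the node's parent (includes the root prior)."""
    outside = {tree.seed_node: np.full((4, partials[tree.seed_node].shape[1]), 0.25)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node.parent_node
        acc = outside[parent].copy()
        for sib in parent.child_nodes():
            if sib is node:
                continue
            acc *= _jc_pmatrix(sib.edge.length or 0.0) @ partials[sib]
        outside[node] = acc
    return outside


def optimize_branch_lengths(
    tree: dendropy.Tree,
    aln: Alignment,
    tol: float = 1e-6,
    max_sweeps: int = 20,
) -> dendropy.Tree:
    """Coordinate ascent over branches; log-likelihood never decreases.

    Each branch is optimised exactly (1-D bounded scalar optimisation)
    against freshly computed inside/outside partials, so every update is
    a true ascent step.  Stops when a full sweep improves the total
    log-likelihood by less than ``tol``.
    """
    _check_leaves(tree, aln)
    leaf_partials = _leaf_partials(aln)
    prev_ll = jc_log_likelihood(tree, aln)
    for _sweep in range(max_sweeps):
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            partials = _postorder_partials(tree, leaf_partials)
            outside = _outside_partials(tree, partials)
            U = outside[node]      # outside partial at parent incl. prior
            Dn = partials[node]    # subtree partial at node
            su = U.sum(axis=0)
            sd = Dn.sum(axis=0)
            alpha = 0.25 * su * sd
            beta = (U * Dn).sum(axis=0) - alpha
            # log L(t) = sum log(alpha + beta * exp(-4t/3))

            def neg_ll(t: float) -> float:
                u = math.exp(-4.0 * t / 3.0)
                vals = alpha + beta * u
                if (vals <= 0).any():
                    return math.inf
                return -float(np.log(vals).sum())

            res = minimize_scalar(
                neg_ll, bounds=(_MIN_BRANCH, _MAX_BRANCH), method="bounded",
                options={"xatol": 1e-8},
            )
            current = neg_ll(node.edge.length or 0.0)
            if res.fun < current:
                node.edge.length = float(res.x)
        ll = jc_log_likelihood(tree, aln)
        if ll - prev_ll < tol:
            break
        prev_ll = ll
    return tree


# ---------------------------------------------------------------------------
# Bootstrap and majority-rule consensus
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree, ref: str) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalised as the side not holding ref."""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    splits = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = frozenset(leaves - side)
        if 1 < len(side) < len(leaves) - 1:
            splits.add(side)
    return splits


class _CNode:
    __slots__ = ("children", "leaf", "support")

    def __init__(self, leaf: str | None = None):
        self.children: list[_CNode] = []
        self.leaf = leaf
        self.support: float | None = None

    def leafset(self) -> frozenset[str]:
        if self.leaf is not None:
            return frozenset([self.leaf])
        return frozenset().union(*(c.leafset() for c in self.children))

    def newick(self) -> str:
        if self.leaf is not None:
            return self.leaf
        inner = ",".join(c.newick() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}"


def majority_rule_consensus(
    trees: list[dendropy.Tree],
) -> dendropy.Tree:
    """Majority-rule (>50%) consensus with supports in percent.

    Splits above half frequency are mutually compatible, so they are
    inserted greedily by decreasing support into a star tree.
    """
    if not trees:
        raise ValueError("no trees")
    labels = sorted(leaf.taxon.label for leaf in trees[0].leaf_node_iter())
    ref = labels[0]
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for split in _bipartitions(t, ref):
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    majority = [
        (split, 100.0 * c / n)
        for split, c in counts.items()
        if c / n > 0.5
    ]
    majority.sort(key=lambda x: (-x[1], sorted(x[0])))

    root = _CNode()
    root.children = [_CNode(leaf=label) for label in labels]
    for split, support in majority:
        _insert_split(root, split, support)
    newick = root.newick() + ";"
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree.get(
        data=newick, schema="newick", taxon_namespace=taxa,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = False
    return tree


def _insert_split(root: _CNode, split: frozenset[str], support: float) -> None:
    node = root
    while True:
        for child in node.children:
            ls = child.leafset()
            if split < ls:
                node = child
                break
        else:
            break
    members = [c for c in node.children if c.leafset() <= split]
    covered = frozenset().union(*(c.leafset() for c in members)) if members else frozenset()
    if covered != split:
        return  # incompatible with already-inserted splits; skip
    new = _CNode()
    new.children = members
    new.support = support
    node.children = [c for c in node.children if c not in members]
    node.children.append(new)


def bootstrap_consensus(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    cap: float = SATURATION_CAP,
    optimize: bool = True,
    max_sweeps: int = 2,
) -> tuple[dendropy.Tree, list[dendropy.Tree]]:
    """Seeded column bootstrap: JC distances -> NJ -> ML branch lengths
    per replicate, then majority-rule consensus with percent supports.

    The input alignment must already be complete-deleted.  Returns the
    consensus and the replicate trees.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ncols = aln.ncols
    reps = []
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rows = [
            (rid, "".join(gapped[j] for j in cols))
            for rid, gapped in aln.rows
        ]
        rep_aln = Alignment(rows, aln.params)
        dm = jc69_matrix(rep_aln, cap=cap)
        tree = neighbor_joining(dm)
        if optimize:
            optimize_branch_lengths(tree, rep_aln, max_sweeps=max_sweeps)
        reps.append(tree)
    consensus = majority_rule_consensus(reps)
    return consensus, reps


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
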