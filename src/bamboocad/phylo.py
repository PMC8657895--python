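"""Distance-based phylogeny: neighbor joining with column-resampling bootstrap.

The tree-building chain is: aligned protein sequences -> pairwise distances
(p-distance or Poisson-corrected, pairwise gap deletion) -> Saitou-Nei
neighbor joining -> Newick with per-internal-edge bootstrap support.

Neighbor joining is exact on additive metrics: when the input distances are
realizable as path lengths on a weighted tree, the output reproduces both
the topology and the metric.  That property anchors the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

GAP = "-"


class SaturationError(ValueError):
    """Distance undefined: p-distance of 1 under the Poisson correction."""


class NoSharedColumnsError(ValueError):
    """A pair of sequences shares no ungapped column."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length, gap-aware protein sequences with unique IDs."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment IDs must be unique")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        object.__setattr__(self, "seqs", tuple(s.upper() for s in self.seqs))

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: sample columns with replacement."""
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        seqs = tuple("".join(s[c] for c in cols) for s in self.seqs)
        return Alignment(ids=self.ids, seqs=seqs)


def read_alignment_fasta(path) -> Alignment:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"no records in alignment {path}")
    return Alignment(
        ids=tuple(r.id for r in recs), seqs=tuple(str(r.seq) for r in recs)
    )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances (substitutions per site)."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} labels")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(m < -1e-12):
            raise ValueError("distances must be non-negative")
        m = np.clip((m + m.T) / 2.0, 0.0, None)
        np.fill_diagonal(m, 0.0)
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return len(self.labels)


def pairwise_distance(
    aln: Alignment, model: str = "poisson", gap_mode: str = "pairwise"
) -> DistanceMatrix:
    """Pairwise distances under ``p_distance`` or ``poisson`` correction.

    ``gap_mode='pairwise'`` compares, per pair, the columns where neither
    sequence has a gap; ``'complete'`` first drops every column containing
    any gap.  p = mismatches / compared columns; Poisson d = -ln(1 - p).
    """
    if model not in {"p_distance", "p", "poisson"}:
        raise ValueError(f"unknown model {model!r}")
    if gap_mode not in {"pairwise", "complete"}:
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    seqs = aln.seqs
    if gap_mode == "complete":
        keep = [
            c for c in range(aln.n_columns) if all(s[c] != GAP for s in seqs)
        ]
        seqs = tuple("".join(s[c] for c in keep) for s in seqs)
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = seqs[i], seqs[j]
            compared = 0
            mism = 0
            for a, b in zip(si, sj):
                if a == GAP or b == GAP:
                    continue
                compared += 1
                if a != b:
                    mism += 1
            if compared == 0:
                raise NoSharedColumnsError(
                    f"{aln.ids[i]} and {aln.ids[j]} share no ungapped columns"
                )
            p = mism / compared
            if model == "poisson":
                if p >= 1.0:
                    raise SaturationError(
                        f"p-distance 1.0 between {aln.ids[i]} and {aln.ids[j]}: "
                        "Poisson correction undefined"
                    )
                dist = -math.log(1.0 - p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=aln.ids, matrix=d)


@dataclass
class TreeNode:
    """Node of a phylogenetic tree; the root of an unrooted tree is a
    degree-3 (or, for 3 taxa, the single internal) vertex."""

    name: Optional[str] = None
    length: float = 0.0  # length of the edge to the parent
    support: Optional[float] = None  # bootstrap %, internal edges only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]  # type: ignore[misc]


@dataclass(frozen=True)
class PhyloTree:
    """Unrooted weighted tree, held rooted at a trifurcation."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self, with_support: bool = False):
        """Non-trivial bipartitions as canonical frozensets of leaf names.

        Each internal edge splits the leaves in two; the canonical form is
        the side not containing the lexicographically smallest leaf.  With
        ``with_support`` a dict {bipartition: support} is returned.
        """
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        out: dict[frozenset, Optional[float]] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = all_leaves - below if ref in below else below
                out[side] = node.support
            return below

        walk(self.root)
        return out if with_support else set(out)

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (the tree's additive metric)."""
        leaves = sorted(self.leaf_names)
        index = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> list[tuple[int, float]]:
            # (leaf index, distance from node) for leaves below node
            if node.is_leaf:
                return [(index[node.name], 0.0)]
            groups = []
            for c in node.children:
                below = [(i, dist + c.length) for i, dist in walk(c)]
                groups.append(below)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i, di in groups[gi]:
                        for j, dj in groups[gj]:
                            d[i, j] = d[j, i] = di + dj
            return [pair for g in groups for pair in g]

        walk(self.root)
        return DistanceMatrix(labels=tuple(leaves), matrix=d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken by the lowest current (i, j) index
    pair; estimated negative branch lengths are clamped to zero.  For an
    additive input metric the returned tree's path metric equals the input
    exactly (up to floating error).
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.matrix.copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        # evaluate Q on the upper triangle only (i < j); np.argmin takes the
        # first minimal entry in row-major order, i.e. the lowest-index pair
        iu, ju = np.triu_indices(m, k=1)
        k = int(np.argmin(q[iu, ju]))
        i, j = int(iu[k]), int(ju[k])
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = max(li, 0.0)
        b.length = max(lj, 0.0)
        parent.children = [a, b]
        dk = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    # connect the last three nodes at a trifurcating root (3-point formula)
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    root = TreeNode()
    for node, length in zip(nodes, lengths):
        node.length = max(length, 0.0)
        root.children.append(node)
    return PhyloTree(root=root)


@dataclass(frozen=True)
class BootstrapResult:
    """Per-bipartition support mapped onto the full-data tree."""

    tree: PhyloTree  # full-data tree with .support set on internal nodes
    replicates: int
    skipped: int
    seed: int
    support: dict  # bipartition frozenset -> percentage in [0, 100]


def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    model: str = "poisson",
    seed: int = 0,
    gap_mode: str = "pairwise",
) -> BootstrapResult:
    """Column-resampling bootstrap of the NJ tree.

    Each replicate resamples alignment columns with replacement, recomputes
    distances and the NJ tree, and tallies non-trivial bipartitions.
    Support is the percentage of successful replicates containing each
    internal bipartition of the full-data tree.  Replicates with a
    saturated or undefined distance are skipped; more than 50% skipped is
    an error.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    full_tree = neighbor_joining(pairwise_distance(aln, model, gap_mode))
    target = full_tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    skipped = 0
    for _ in range(replicates):
        rep = aln.resample_columns(rng)
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep, model, gap_mode))
        except (SaturationError, NoSharedColumnsError):
            skipped += 1
            continue
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if skipped > replicates / 2:
        raise RuntimeError(
            f"{skipped}/{replicates} bootstrap replicates had undefined "
            "distances; the alignment is too saturated or gappy"
        )
    ok = replicates - skipped
    support = {bp: 100.0 * c / ok for bp, c in counts.items()}
    _annotate_support(full_tree, support)
    return BootstrapResult(
        tree=full_tree,
        replicates=replicates,
        skipped=skipped,
        seed=seed,
        support=support,
    )


def _annotate_support(tree: PhyloTree, support: dict) -> None:
    all_leaves = frozenset(tree.leaf_names)
    ref = min(all_leaves)

    def walk(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 2 <= len(below) <= len(all_leaves) - 2:
            side = all_leaves - below if ref in below else below
            if side in support:
                node.support = support[side]
        return below

    walk(tree.root)


_NEWICK_UNSAFE = set("()[]{}:;,'\" \t\n")


def _quote(label: str) -> str:
    if set(label) & _NEWICK_UNSAFE:
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree: PhyloTree, include_support: bool = True) -> str:
    """Serialize to Newick; bootstrap supports become internal node labels."""
    if not tree.root.children:
        raise ValueError("cannot serialize an empty tree")

    def fmt(node: TreeNode, top: bool = False) -> str:
        if node.is_leaf:
            body = _quote(node.name or "")
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if include_support and node.support is not None and not top:
                body += f"{node.support:g}"
        if top:
            return body
        return f"{body}:{node.length:.12g}"

    return fmt(tree.root, top=True) + ";"


def write_newick(tree: PhyloTree, path, include_support: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree, include_support=include_support) + "\n")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Tab-separated square distance matrix with a label header."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(dm.labels) + "\n")
        for i, lab in enumerate(dm.labels):
            row = "\t".join(f"{x:.10g}" for x in dm.matrix[i])
            fh.write(f"{lab}\t{row}\n")
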