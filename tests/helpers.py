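"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the motif oracle is
a per-window literal comparison, the promoter oracle an exhaustive window
scan with its own IUPAC table, the Pearson oracle a direct two-pass
formula, and the topology oracle an exhaustive least-squares fit over all
unrooted binary topologies.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ----------------------------------------------------------- motif oracle


def brute_force_site_scan(sequence, literals, span, max_mismatch):
    """Every window with <= max_mismatch mismatches at literal positions.

    ``literals`` maps 1-based in-window positions to required residues.
    Returns [(start_1based, mismatches)] sorted by (mismatches, start).
    """
    hits = []
    for start0 in range(len(sequence) - span + 1):
        window = sequence[start0 : start0 + span]
        mm = sum(1 for pos, res in literals.items() if window[pos - 1] != res)
        if mm <= max_mismatch:
            hits.append((start0 + 1, mm))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


# -------------------------------------------------------- promoter oracle

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
         "B": "V", "V": "B", "D": "H", "H": "D"}


def revcomp(s):
    return "".join(_COMP[c] for c in reversed(s))


def brute_force_promoter_scan(seq, consensus):
    """All (start_1based, strand) exact IUPAC matches, both strands,
    minus-strand hits in forward coordinates; N in the sequence matches
    only an N consensus symbol."""

    def matches(window, cons):
        for b, s in zip(window, cons):
            if b == "N":
                if s != "N":
                    return False
            elif b not in _IUPAC[s]:
                return False
        return True

    L = len(consensus)
    rc = revcomp(consensus)
    out = []
    for start0 in range(len(seq) - L + 1):
        window = seq[start0 : start0 + L]
        if matches(window, consensus):
            out.append((start0 + 1, "+"))
        if matches(window, rc):
            out.append((start0 + 1, "-"))
    return sorted(out)


# --------------------------------------------------------- pearson oracle


def two_pass_pearson(x, y):
    """Direct product-moment formula, no numpy linear algebra."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


# -------------------------------------------- least-squares topology oracle


def enumerate_topologies(labels):
    """All unrooted binary topologies on ``labels`` as edge structures.

    Yields (edges, node_count) where edges are (u, v) over integer node
    ids; leaf i is node i (in the order of ``labels``).
    """
    n = len(labels)
    assert n >= 3
    # start: star on leaves 0,1,2 with internal node n
    base_edges = [(0, n), (1, n), (2, n)]
    trees = [(base_edges, n + 1)]
    for leaf in range(3, n):
        new_trees = []
        for edges, next_id in trees:
            for k, (u, v) in enumerate(edges):
                w = next_id
                e = edges[:k] + edges[k + 1 :] + [(u, w), (w, v), (leaf, w)]
                new_trees.append((e, next_id + 1))
        trees = new_trees
    return trees


def _edge_paths(edges, n_leaves):
    """For each leaf pair, the set of edge indices on the connecting path."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    paths = {}
    for a in range(n_leaves):
        # BFS recording edge sets
        seen = {a: frozenset()}
        queue = [a]
        while queue:
            node = queue.pop()
            for nb, idx in adj[node]:
                if nb not in seen:
                    seen[nb] = seen[node] | {idx}
                    queue.append(nb)
        for b in range(a + 1, n_leaves):
            paths[(a, b)] = seen[b]
    return paths


def topology_bipartitions(edges, labels):
    """Non-trivial bipartitions of a topology, canonicalized like
    PhyloTree.bipartitions (side not containing the smallest label)."""
    n = len(labels)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    all_set = frozenset(labels)
    ref = min(all_set)
    bips = set()
    for u, v in edges:
        # leaves on v's side when edge (u, v) removed
        seen = {v}
        stack = [v]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb != u and nb not in seen and not (node == v and nb == u):
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(labels[i] for i in seen if i < n)
        if 2 <= len(side) <= n - 2:
            side = all_set - side if ref in side else side
            bips.add(side)
    return bips


def least_squares_topology(dm_labels, dm_matrix):
    """Bipartition set of the minimum least-squares topology.

    Fits branch lengths by unconstrained least squares for every unrooted
    binary topology and returns the bipartitions of the best fit.
    """
    labels = list(dm_labels)
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    d = np.array([dm_matrix[i, j] for i, j in pairs])
    best = None
    for edges, _ in enumerate_topologies(labels):
        paths = _edge_paths(edges, n)
        A = np.zeros((len(pairs), len(edges)))
        for row, (a, b) in enumerate(pairs):
            for idx in paths[(a, b)]:
                A[row, idx] = 1.0
        b, residual, *_ = np.linalg.lstsq(A, d, rcond=None)
        rss = float(np.sum((A @ b - d) ** 2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, edges)
    return topology_bipartitions(best[1], labels)
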