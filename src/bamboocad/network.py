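"""Pearson co-expression network construction.

Pairwise Pearson correlation coefficients (PCC) over gene expression
profiles, thresholded into a signed network: pairs with PCC >= 0.7 are
positive edges, PCC <= -0.5 negative edges (inclusive bounds, both
configurable).  No p-values or multiple-testing correction are applied;
the thresholds act on the raw PCC.  Edge lists are exported as TSV or as
Cytoscape SIF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_POS_THRESHOLD = 0.7
DEFAULT_NEG_THRESHOLD = -0.5


class ZeroVarianceError(ValueError):
    """Correlation undefined: a profile has zero variance."""


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length profiles (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("profiles must have length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero-variance profile: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    # guard against floating overshoot
    return max(-1.0, min(1.0, r))


@dataclass(frozen=True)
class NetworkSpec:
    """Thresholds and optional seed-gene restriction for the network."""

    pos_threshold: float = DEFAULT_POS_THRESHOLD
    neg_threshold: float = DEFAULT_NEG_THRESHOLD
    seed_genes: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if not (self.neg_threshold < 0 < self.pos_threshold):
            raise ValueError(
                "require neg_threshold < 0 < pos_threshold, got "
                f"({self.neg_threshold}, {self.pos_threshold})"
            )
        if self.pos_threshold > 1 or self.neg_threshold < -1:
            raise ValueError("thresholds must lie in [-1, 1]")


@dataclass(frozen=True)
class CoexpressionEdge:
    """An unordered co-expressed gene pair (gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    pcc: float
    sign_class: str  # positive | negative


def build_network(
    em: pd.DataFrame, spec: NetworkSpec = NetworkSpec()
) -> list[CoexpressionEdge]:
    """Threshold all pairwise PCCs of a (filtered) expression matrix.

    With ``spec.seed_genes`` set, only pairs touching at least one seed
    gene are evaluated (seed x universe mode); otherwise all unordered
    pairs.  Zero-variance genes are skipped with a warning.  Edges are
    returned sorted by (gene_a, gene_b).
    """
    if em.shape[0] < 2:
        raise ValueError("need at least 2 genes to build a network")
    if em.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    values = em.to_numpy(dtype=float)
    genes = list(em.index)
    variable = np.ptp(values, axis=1) != 0
    dropped = [g for g, ok in zip(genes, variable) if not ok]
    if dropped:
        warnings.warn(
            f"skipping {len(dropped)} zero-variance gene(s): {dropped[:5]}...",
            stacklevel=2,
        )
    keep_idx = np.flatnonzero(variable)
    genes_kept = [genes[i] for i in keep_idx]
    if len(genes_kept) < 2:
        raise ValueError("fewer than 2 genes with non-zero variance")
    corr = np.corrcoef(values[keep_idx])
    corr = np.clip(corr, -1.0, 1.0)
    seed_set = set(spec.seed_genes) if spec.seed_genes is not None else None
    if seed_set is not None:
        missing = seed_set - set(genes)
        if missing:
            raise ValueError(f"seed genes absent from matrix: {sorted(missing)}")
    edges: list[CoexpressionEdge] = []
    n = len(genes_kept)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = genes_kept[i], genes_kept[j]
            if seed_set is not None and gi not in seed_set and gj not in seed_set:
                continue
            r = float(corr[i, j])
            if r >= spec.pos_threshold:
                sign = "positive"
            elif r <= spec.neg_threshold:
                sign = "negative"
            else:
                continue
            a, b = sorted((gi, gj))
            edges.append(CoexpressionEdge(a, b, r, sign))
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    n_pos = sum(e.sign_class == "positive" for e in edges)
    logger.info(
        "co-expression network: %d positive, %d negative edges over %d genes",
        n_pos,
        len(edges) - n_pos,
        len(genes_kept),
    )
    return edges


def positive_components(
    edges: Sequence[CoexpressionEdge], genes: Sequence[str]
) -> list[frozenset]:
    """Connected components of the positive-edge subgraph over ``genes``."""
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(
        (e.gene_a, e.gene_b) for e in edges if e.sign_class == "positive"
    )
    return [frozenset(c) for c in nx.connected_components(g)]


def edges_table(edges: Sequence[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": e.gene_a,
                "gene_b": e.gene_b,
                "pcc": e.pcc,
                "sign_class": e.sign_class,
            }
            for e in edges
        ],
        columns=["gene_a", "gene_b", "pcc", "sign_class"],
    )


def export_network(edges: Sequence[CoexpressionEdge], path, fmt: str = "tsv") -> None:
    """Write the edge list as TSV (with header) or Cytoscape SIF.

    Output is deterministically ordered by (gene_a, gene_b); SIF relation
    tokens are ``pos`` and ``neg``.
    """
    ordered = sorted(edges, key=lambda e: (e.gene_a, e.gene_b))
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tpcc\tsign_class\n")
            for e in ordered:
                fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.pcc:.10g}\t{e.sign_class}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for e in ordered:
                rel = "pos" if e.sign_class == "positive" else "neg"
                fh.write(f"{e.gene_a}\t{rel}\t{e.gene_b}\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'tsv' or 'sif')")


def read_network_tsv(path) -> list[CoexpressionEdge]:
    df = pd.read_csv(path, sep="\t")
    return [
        CoexpressionEdge(r.gene_a, r.gene_b, float(r.pcc), r.sign_class)
        for r in df.itertuples()
    ]


def read_network_sif(path) -> list[tuple[str, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                a, rel, b = line.split("\t")
                out.append((a, rel, b))
    return out
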