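"""Ground-truthed synthetic inputs for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and
returns (or writes) both the data and a ledger recording everything that
was planted — site positions and mutation counts, the generating tree,
module memberships, fold changes, element positions — so expected outputs
of every downstream stage are computable from the ledger alone.

The generators emulate the shape of the real study inputs (protein
families with the three CAD signature sites, alignments evolved along a
known tree, 26-tissue FPKM matrices with correlated modules,
control/treatment tables with planted inductions, 2 kb promoters with
planted elements) without any of the real data's biological structure.
"""

from __future__ import annotations

import json
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .phylo import Alignment, PhyloTree, TreeNode
from .promoters import IUPAC_DNA, CisElement, default_elements
from .sites import (
    DEFAULT_TOLERANCE,
    ProteinRecord,
    SitePattern,
    default_patterns,
    scan_sites,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def save_ledger(ledger: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_ledger(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------- proteins


def _site_instance(
    pattern: SitePattern, n_mismatches: int, rng: np.random.Generator
) -> tuple[str, int]:
    """A concrete site: literals in place, random wildcard fillers, and
    ``n_mismatches`` literal positions substituted to a different residue."""
    chars = [rng.choice(list(AA)) for _ in range(pattern.span)]
    for pos, res in pattern.literals.items():
        chars[pos - 1] = res
    mutate = rng.choice(
        sorted(pattern.literals), size=n_mismatches, replace=False
    )
    for pos in mutate:
        original = pattern.literals[pos]
        alternatives = [a for a in AA if a != original]
        chars[pos - 1] = rng.choice(alternatives)
    return "".join(chars), int(n_mismatches)


def make_protein_family(
    n_pos: int,
    n_decoy: int,
    max_mismatches_per_site: int = 2,
    backbone_length: int = 360,
    seed: int = 0,
    patterns: Optional[Mapping[str, SitePattern]] = None,
    guard_tolerance: Optional[Mapping[str, int]] = None,
) -> tuple[list[ProteinRecord], dict]:
    """Synthesize a protein family of planted positives and decoys.

    Positives carry all three signature sites at recorded positions, each
    with 0..``max_mismatches_per_site`` literal mutations (uniform).
    Decoys omit at least one site; the generator verifies that the omitted
    sites do not arise by chance within ``guard_tolerance`` mismatches
    (default: the classifier's default budgets) and redraws otherwise, so
    the ledger's is_cad labels are exact ground truth.
    """
    if patterns is None:
        patterns = default_patterns()
    guard = dict(DEFAULT_TOLERANCE)
    if guard_tolerance:
        guard.update(guard_tolerance)
    names = list(patterns)
    spans = {name: patterns[name].span for name in names}
    needed = sum(spans.values()) + 2 * len(names)
    if backbone_length < needed:
        raise ValueError(
            f"backbone_length={backbone_length} too short; need >= {needed}"
        )
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    ledger: dict = {
        "seed": int(seed),
        "max_mismatches_per_site": int(max_mismatches_per_site),
        "backbone_length": int(backbone_length),
        "proteins": [],
    }

    def background(length: int) -> list[str]:
        return list(rng.choice(list(AA), size=length))

    def site_slots() -> dict[str, int]:
        # one site per equal-width block, random offset inside the block
        block = backbone_length // len(names)
        slots = {}
        for k, name in enumerate(names):
            lo = k * block
            hi = (k + 1) * block - spans[name]
            slots[name] = int(rng.integers(lo, hi + 1))
        return slots

    for idx in range(n_pos):
        pid = f"POS{idx + 1:03d}"
        chars = background(backbone_length)
        slots = site_slots()
        planted = {}
        for name in names:
            k = int(rng.integers(0, max_mismatches_per_site + 1))
            inst, mm = _site_instance(patterns[name], k, rng)
            start0 = slots[name]
            chars[start0 : start0 + spans[name]] = list(inst)
            planted[name] = {"start": start0 + 1, "mismatches": mm}
        records.append(ProteinRecord(id=pid, sequence="".join(chars)))
        ledger["proteins"].append(
            {"id": pid, "is_cad": True, "sites": planted}
        )

    for idx in range(n_decoy):
        pid = f"DEC{idx + 1:03d}"
        n_omit = int(rng.integers(1, len(names) + 1))
        omitted = sorted(
            rng.choice(names, size=n_omit, replace=False).tolist()
        )
        for _attempt in range(200):
            chars = background(backbone_length)
            slots = site_slots()
            planted = {}
            for name in names:
                if name in omitted:
                    continue
                k = int(rng.integers(0, max_mismatches_per_site + 1))
                inst, mm = _site_instance(patterns[name], k, rng)
                start0 = slots[name]
                chars[start0 : start0 + spans[name]] = list(inst)
                planted[name] = {"start": start0 + 1, "mismatches": mm}
            rec = ProteinRecord(id=pid, sequence="".join(chars))
            clean = all(
                not scan_sites(rec, patterns[name], guard[name])
                for name in omitted
            )
            if clean:
                break
        else:  # pragma: no cover - 200 redraws never exhausted in practice
            raise RuntimeError(f"could not generate clean decoy {pid}")
        records.append(rec)
        ledger["proteins"].append(
            {"id": pid, "is_cad": False, "sites": planted, "omitted": omitted}
        )
    return records, ledger


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ------------------------------------------------------------- alignments


def evolve_alignment(tree: PhyloTree, n_columns: int, seed: int = 0) -> Alignment:
    """Evolve i.i.d. columns along a tree (Poisson-style contract).

    The root sequence is uniform over the 20 residues; along each branch of
    length b every site experiences a substitution event with probability
    1 - e^(-b), redrawing the residue uniformly over all 20 (so an event
    leaves the residue unchanged 1/20 of the time, and an infinitely long
    branch leaves an expected 19/20 of sites differing from the parent).
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA))
    root_seq = rng.integers(0, 20, size=n_columns)
    out: dict[str, str] = {}

    def descend(node: TreeNode, parent_seq: np.ndarray) -> None:
        p_sub = 1.0 - np.exp(-node.length)
        seq = parent_seq.copy()
        hit = rng.random(n_columns) < p_sub
        if hit.any():
            seq[hit] = rng.integers(0, 20, size=int(hit.sum()))
        if node.is_leaf:
            out[node.name] = "".join(aa[seq])
        else:
            for child in node.children:
                descend(child, seq)

    for child in tree.root.children:
        descend(child, root_seq)
    ids = tree.leaf_names
    return Alignment(ids=tuple(ids), seqs=tuple(out[i] for i in ids))


def random_additive_tree(
    n_taxa: int,
    seed: int = 0,
    min_length: float = 0.1,
    max_length: float = 1.0,
    labels: Optional[Sequence[str]] = None,
) -> PhyloTree:
    """Random unrooted binary tree with uniform branch lengths.

    Its path-length matrix is an additive metric whose unique generating
    topology is the tree itself — the oracle for NJ exactness tests.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"T{i + 1}" for i in range(n_taxa)]

    def rand_len() -> float:
        return float(rng.uniform(min_length, max_length))

    nodes = [TreeNode(name=lab, length=rand_len()) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        parent = TreeNode(length=rand_len(), children=[nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return PhyloTree(root=root)


# ------------------------------------------------------------- expression


def make_expression_matrix(
    modules: Sequence[tuple[int, float]],
    n_samples: int = 26,
    n_background: int = 0,
    n_low_expression: int = 0,
    log_mean: float = 1.0,
    log_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """FPKM matrix with block-correlated modules (latent-factor model).

    Genes of module m share a latent factor F_m: on the latent (Gaussian)
    scale gene g is z_g = sqrt(rho) * F_m + sqrt(1 - rho) * eps_g, so each
    within-module pair has latent correlation rho.  FPKM values are
    exp(log_mean + log_sd * z): non-negative and right-skewed like real
    FPKM.  Optional background genes are independent; optional planted
    low-expression genes stay below 0.05 FPKM in every sample, so the
    0.05/>=7-sample expression filter removes exactly them.
    """
    for size, rho in modules:
        if not (0.0 < rho < 1.0):
            raise ValueError(f"module correlation must be in (0,1), got {rho}")
        if size < 1:
            raise ValueError("module size must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    index = []
    ledger: dict = {
        "seed": int(seed),
        "n_samples": int(n_samples),
        "modules": {},
        "background": [],
        "low_expression": [],
    }
    for m, (size, rho) in enumerate(modules, start=1):
        factor = rng.standard_normal(n_samples)
        genes = [f"M{m}G{g + 1:03d}" for g in range(size)]
        ledger["modules"][f"module{m}"] = {"genes": genes, "rho": rho}
        for gene in genes:
            eps = rng.standard_normal(n_samples)
            z = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * eps
            rows.append(np.exp(log_mean + log_sd * z))
            index.append(gene)
    for b in range(n_background):
        gene = f"BG{b + 1:03d}"
        z = rng.standard_normal(n_samples)
        rows.append(np.exp(log_mean + log_sd * z))
        index.append(gene)
        ledger["background"].append(gene)
    for l in range(n_low_expression):
        gene = f"LOW{l + 1:03d}"
        rows.append(rng.uniform(0.0, 0.04, size=n_samples))
        index.append(gene)
        ledger["low_expression"].append(gene)
    samples = [f"tissue{s + 1:02d}" for s in range(n_samples)]
    em = pd.DataFrame(np.array(rows), index=index, columns=samples)
    em.index.name = "gene_id"
    return em, ledger


def make_stress_experiment(
    n_genes: int = 20,
    conditions: Sequence[str] = ("NaCl", "PEG", "SA", "ABA"),
    timepoints: Sequence[str] = ("3h", "24h"),
    n_replicates: int = 3,
    planted_fc: Optional[Mapping[tuple[str, str, str], float]] = None,
    n_low_expression: int = 0,
    base_fpkm: float = 10.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Control/treatment FPKM table with planted fold changes.

    ``planted_fc`` maps (gene, condition, timepoint) -> true fold change;
    unmapped combinations have true fold change 1.  Replicate values are
    the group mean times exp(noise_sd * N(0,1)) — multiplicative noise
    small enough that the two-fold caller recovers the plantings exactly.
    Planted low-expression genes sit below 1 FPKM in every sample and must
    be flagged rather than called.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{g + 1:03d}" for g in range(n_genes)]
    low_genes = [f"LOW{l + 1:03d}" for l in range(n_low_expression)]
    planted_fc = dict(planted_fc or {})
    for gene, cond, tp in planted_fc:
        if gene not in genes:
            raise ValueError(f"planted gene {gene!r} not among generated genes")
        if cond not in conditions or tp not in timepoints:
            raise ValueError(f"planted condition {(cond, tp)} not in design")
    base = {
        g: float(base_fpkm * np.exp(rng.uniform(-0.5, 0.5))) for g in genes
    }
    base.update({g: float(rng.uniform(0.05, 0.3)) for g in low_genes})
    all_genes = genes + low_genes
    design_rows = []
    columns: dict[str, np.ndarray] = {}
    groups = [("control", tp) for tp in timepoints] + [
        (c, tp) for c in conditions for tp in timepoints
    ]
    for cond, tp in groups:
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_{tp}_r{rep}"
            design_rows.append(
                {
                    "sample": sample,
                    "condition": cond,
                    "timepoint": tp,
                    "replicate": str(rep),
                }
            )
            vals = np.empty(len(all_genes))
            for gi, g in enumerate(all_genes):
                fc = planted_fc.get((g, cond, tp), 1.0) if cond != "control" else 1.0
                vals[gi] = base[g] * fc * np.exp(noise_sd * rng.standard_normal())
            columns[sample] = vals
    em = pd.DataFrame(columns, index=all_genes)
    em.index.name = "gene_id"
    design = pd.DataFrame(design_rows)
    ledger = {
        "seed": int(seed),
        "genes": genes,
        "low_expression": low_genes,
        "planted_fc": [
            {"gene": g, "condition": c, "timepoint": t, "fc": fc}
            for (g, c, t), fc in sorted(planted_fc.items())
        ],
        "noise_sd": noise_sd,
    }
    return em, design, ledger


# -------------------------------------------------------------- promoters


def make_promoters(
    n_genes: int,
    length: int = 2000,
    plantings: Optional[Sequence[tuple[str, str, int, str]]] = None,
    elements: Optional[Sequence[CisElement]] = None,
    seed: int = 0,
) -> tuple[dict[str, str], dict]:
    """Random promoters with exact element consensi planted.

    ``plantings`` is a sequence of (gene_id, element_name, 1-based start,
    strand).  Planted instances are concrete sequences drawn from the
    IUPAC consensus (reverse-complemented for minus-strand plantings).
    Overlapping plantings within a gene are an error.  Gene IDs are
    PROM001..PROMn.
    """
    rng = np.random.default_rng(seed)
    if elements is None:
        elements = default_elements()
    by_name = {e.name: e for e in elements}
    genes = [f"PROM{i + 1:03d}" for i in range(n_genes)]
    seqs = {
        g: list(rng.choice(list("ACGT"), size=length)) for g in genes
    }
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in genes}
    ledger: dict = {
        "seed": int(seed),
        "length": int(length),
        "genes": genes,
        "plantings": [],
    }
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for gene, name, start, strand in plantings or []:
        if gene not in seqs:
            raise ValueError(f"unknown gene {gene!r}")
        if name not in by_name:
            raise ValueError(f"unknown element {name!r}")
        if strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {strand!r}")
        cons = by_name[name].consensus
        L = len(cons)
        if start < 1 or start + L - 1 > length:
            raise ValueError(f"planting {name} at {start} exceeds promoter")
        lo, hi = start, start + L - 1
        for (plo, phi) in occupied[gene]:
            if lo <= phi and plo <= hi:
                raise ValueError(
                    f"overlapping plantings in {gene}: [{plo},{phi}] vs [{lo},{hi}]"
                )
        occupied[gene].append((lo, hi))
        concrete = "".join(
            rng.choice(sorted(IUPAC_DNA[sym])) for sym in cons
        )
        forward = (
            concrete
            if strand == "+"
            else "".join(comp[b] for b in reversed(concrete))
        )
        seqs[gene][start - 1 : start - 1 + L] = list(forward)
        ledger["plantings"].append(
            {
                "gene": gene,
                "element": name,
                "start": int(start),
                "strand": strand,
                "instance": concrete,
                "forward_sequence": forward,
            }
        )
    return {g: "".join(s) for g, s in seqs.items()}, ledger


def generate_fixture_set(outdir, seed: int = 0) -> dict:
    """Write a complete synthetic input set for the pipeline.

    Produces proteins.fasta, alignment.fasta, promoters.fasta,
    expression.tsv, stress_expression.tsv, design.tsv, seed_genes.txt and
    ledger.json in ``outdir``; returns the combined ledger.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sub = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(s.generate_state(1, dtype=np.uint32)[0] % (2**31)) for s in sub]

    records, prot_ledger = make_protein_family(8, 8, seed=seeds[0])
    write_fasta(records, outdir / "proteins.fasta")

    tree = random_additive_tree(6, seed=seeds[1], min_length=0.05, max_length=0.4)
    aln = evolve_alignment(tree, n_columns=500, seed=seeds[1])
    with open(outdir / "alignment.fasta", "w") as fh:
        for gid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{gid}\n{seq}\n")

    plantings = [
        ("PROM001", "CGTCA-motif", 101, "+"),
        ("PROM001", "ABRE", 500, "-"),
        ("PROM002", "MBS", 1200, "+"),
        ("PROM003", "TGACG-motif", 700, "-"),
    ]
    seqs, prom_ledger = make_promoters(4, plantings=plantings, seed=seeds[2])
    write_dna_fasta(seqs, outdir / "promoters.fasta")

    em, em_ledger = make_expression_matrix(
        modules=[(8, 0.9), (8, 0.9)],
        n_background=4,
        n_low_expression=3,
        seed=seeds[3],
    )
    em.to_csv(outdir / "expression.tsv", sep="\t")
    with open(outdir / "seed_genes.txt", "w") as fh:
        for gene in em_ledger["modules"]["module1"]["genes"][:3]:
            fh.write(gene + "\n")

    planted_fc = {
        ("G001", "NaCl", "24h"): 4.0,
        ("G002", "NaCl", "24h"): 4.0,
        ("G003", "PEG", "3h"): 0.25,
    }
    sem, design, stress_ledger = make_stress_experiment(
        n_genes=10, planted_fc=planted_fc, n_low_expression=2, seed=seeds[4]
    )
    sem.to_csv(outdir / "stress_expression.tsv", sep="\t")
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)

    ledger = {
        "seed": int(seed),
        "proteins": prot_ledger,
        "tree_bipartitions": [sorted(bp) for bp in sorted(
            tree.bipartitions(), key=lambda b: sorted(b)
        )],
        "promoters": prom_ledger,
        "expression": em_ledger,
        "stress": stress_ledger,
    }
    save_ledger(ledger, outdir / "ledger.json")
    return ledger


def write_dna_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for gid, seq in seqs.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
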