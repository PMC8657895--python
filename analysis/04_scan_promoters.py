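"""Scan the synthetic 2 kb promoters for stress-related cis-elements.

Both strands are scanned with the default PlantCARE-derived consensus
table (ABRE, CGTCA-motif, GARE-motif, LTR, MBS, MRE, MYB, P-box,
TCA-element, TCT-motif, TGACG-motif); planted elements must all be
recovered at their recorded positions and strands.
"""

from pathlib import Path

from Bio import SeqIO

from bamboocad.promoters import (
    default_elements,
    element_count_matrix,
    hits_table,
    scan_promoter_fasta,
)
from bamboocad.simulate import load_ledger

IN = Path("results/synthetic")
OUT = Path("results")

elements = default_elements()
hits = scan_promoter_fasta(IN / "promoters.fasta", elements)
hits_table(hits).to_csv(OUT / "promoter_hits.tsv", sep="\t", index=False)
gene_ids = [r.id for r in SeqIO.parse(str(IN / "promoters.fasta"), "fasta")]
counts = element_count_matrix(hits, gene_ids, elements)
counts.to_csv(OUT / "promoter_counts.tsv", sep="\t")

planted = load_ledger(IN / "ledger.json")["promoters"]["plantings"]
found = {(h.gene_id, h.element, h.start, h.strand) for h in hits}
n_rec = sum(
    (p["gene"], p["element"], p["start"], p["strand"]) in found for p in planted
)
print(f"{len(hits)} hits over {len(gene_ids)} promoters -> {OUT}/promoter_hits.tsv")
print(f"  planted elements recovered: {n_rec}/{len(planted)}")
print(f"  counts matrix ({counts.shape[0]} genes x {counts.shape[1]} elements) "
      f"-> {OUT}/promoter_counts.tsv")
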