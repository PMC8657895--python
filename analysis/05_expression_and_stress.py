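"""Filter the tissue FPKM matrix, prepare the heatmap, call stress genes.

The filter keeps genes with >= 0.05 FPKM in >= 7 of the 26 tissues; the
heatmap matrix is log2(FPKM + 1); stress responsiveness is a two-fold
change versus the timepoint-matched control after replicate averaging,
with genes under 1 FPKM everywhere flagged as too weak to call.
"""

from pathlib import Path

from bamboocad.expression import (
    expression_filter,
    heatmap_matrix,
    read_design_tsv,
    read_expression_tsv,
    stress_response_table,
)
from bamboocad.simulate import load_ledger

IN = Path("results/synthetic")
OUT = Path("results")

em = read_expression_tsv(IN / "expression.tsv")
filtered = expression_filter(em)
filtered.to_csv(OUT / "filtered_fpkm.tsv", sep="\t")
heatmap_matrix(filtered).to_csv(OUT / "heatmap.tsv", sep="\t")

ledger = load_ledger(IN / "ledger.json")
removed = set(em.index) - set(filtered.index)
print(f"expression filter: kept {filtered.shape[0]}/{em.shape[0]} genes")
print(f"  removed == planted low-expression genes: "
      f"{removed == set(ledger['expression']['low_expression'])}")

sem = read_expression_tsv(IN / "stress_expression.tsv")
design = read_design_tsv(IN / "design.tsv")
table = stress_response_table(sem, design)
table.to_csv(OUT / "fold_changes.tsv", sep="\t", index=False)
up = table[table.direction == "up"]
down = table[table.direction == "down"]
planted = {
    (p["gene"], p["condition"], p["timepoint"]): p["fc"]
    for p in ledger["stress"]["planted_fc"]
}
called = {
    (r.gene, r.condition, r.timepoint)
    for r in table.itertuples()
    if r.direction != "unchanged"
}
print(f"stress calls: {len(up)} up, {len(down)} down -> {OUT}/fold_changes.tsv")
print(f"  calls == planted fold changes: {called == set(planted)}")
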