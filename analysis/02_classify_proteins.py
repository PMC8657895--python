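"""Classify the synthetic protein family by the three CAD signature sites.

Every protein carrying the catalytic Zn, structural Zn and NADP(H) binding
sites within the default mismatch budget (2 per site) is called a CAD;
the verdicts are compared against the generator's ground-truth ledger.
"""

from pathlib import Path

from bamboocad.simulate import load_ledger
from bamboocad.sites import classify_fasta

IN = Path("results/synthetic")
OUT = Path("results")

table = classify_fasta(IN / "proteins.fasta")
table.to_csv(OUT / "classification.tsv", sep="\t", index=False)

truth = {
    p["id"]: p["is_cad"]
    for p in load_ledger(IN / "ledger.json")["proteins"]["proteins"]
}
correct = sum(
    bool(row.is_cad) == truth[row.protein_id] for row in table.itertuples()
)
print(f"classified {len(table)} proteins -> {OUT}/classification.tsv")
print(f"  {int(table['is_cad'].sum())} called CAD")
print(f"  agreement with planting ledger: {correct}/{len(table)}")
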