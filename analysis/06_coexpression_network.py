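"""Build the thresholded Pearson co-expression network.

All pairwise PCCs over the filtered FPKM profiles; pairs with PCC >= 0.7
become positive edges and PCC <= -0.5 negative edges.  The positive
network's connected components are compared with the planted expression
modules.
"""

from pathlib import Path

from bamboocad.expression import read_expression_tsv
from bamboocad.network import (
    NetworkSpec,
    build_network,
    export_network,
    positive_components,
)
from bamboocad.simulate import load_ledger

IN = Path("results/synthetic")
OUT = Path("results")

filtered = read_expression_tsv(OUT / "filtered_fpkm.tsv")
edges = build_network(filtered, NetworkSpec())
export_network(edges, OUT / "network.tsv", "tsv")
export_network(edges, OUT / "network.sif", "sif")

n_pos = sum(e.sign_class == "positive" for e in edges)
modules = {
    frozenset(m["genes"])
    for m in load_ledger(IN / "ledger.json")["expression"]["modules"].values()
}
comps = {
    c
    for c in positive_components(edges, list(filtered.index))
    if len(c) > 1
}
print(f"{n_pos} positive / {len(edges) - n_pos} negative edges "
      f"-> {OUT}/network.tsv, {OUT}/network.sif")
print(f"  non-singleton positive components == planted modules: "
      f"{comps == modules}")
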