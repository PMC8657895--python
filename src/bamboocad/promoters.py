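"""Promoter cis-acting element scanning.

Scans 2 kb upstream promoter sequences for a configured table of named
cis-regulatory elements (ABRE, CGTCA-motif, MBS, ...) on both strands,
reporting exact IUPAC-consensus matches in forward coordinates of the
supplied sequence, and tabulates counts per gene.

The element names come from the stress-responsive set commonly profiled in
plant promoter studies; the shipped consensus strings are PlantCARE-derived
defaults and are configuration, not fixed biology — supply your own table
to change them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

IUPAC_DNA: dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: PlantCARE-derived default consensi for the profiled elements (defaults,
#: not paper facts; override via the element table in the pipeline config).
DEFAULT_ELEMENTS: list[tuple[str, str, str]] = [
    ("ABRE", "ACGTG", "abscisic acid responsiveness"),
    ("CGTCA-motif", "CGTCA", "MeJA responsiveness"),
    ("GARE-motif", "TCTGTTG", "gibberellin responsiveness"),
    ("LTR", "CCGAAA", "low-temperature responsiveness"),
    ("MBS", "CAACTG", "MYB binding site, drought inducibility"),
    ("MRE", "AACCTAA", "MYB binding site, light responsiveness"),
    ("MYB", "CAACAG", "MYB binding site"),
    ("P-box", "CCTTTTG", "gibberellin-responsive element"),
    ("TCA-element", "CCATCTTTTT", "salicylic acid responsiveness"),
    ("TCT-motif", "TCTTAC", "light responsive element"),
    ("TGACG-motif", "TGACG", "MeJA responsiveness"),
]


@dataclass(frozen=True)
class CisElement:
    """A named cis-regulatory element with an IUPAC DNA consensus."""

    name: str
    consensus: str
    note: str = ""

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"element {self.name!r}: empty consensus")
        cons = self.consensus.upper()
        bad = set(cons) - set(IUPAC_DNA)
        if bad:
            raise ValueError(
                f"element {self.name!r}: non-IUPAC character(s) {sorted(bad)!r}"
            )
        object.__setattr__(self, "consensus", cons)

    def __len__(self) -> int:
        return len(self.consensus)


def default_elements() -> list[CisElement]:
    return [CisElement(name=n, consensus=c, note=t) for n, c, t in DEFAULT_ELEMENTS]


def load_element_table(path) -> list[CisElement]:
    """Load elements from a YAML list of {name, consensus, note} entries."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    elements = [
        CisElement(
            name=entry["name"],
            consensus=entry["consensus"],
            note=entry.get("note", ""),
        )
        for entry in raw
    ]
    names = [e.name for e in elements]
    if len(set(names)) != len(names):
        raise ValueError("duplicate element names in element table")
    return elements


@dataclass(frozen=True)
class PromoterHit:
    """One element occurrence; ``start`` is 1-based on the given (forward)
    strand, also for minus-strand hits."""

    gene_id: str
    element: str
    start: int
    strand: str  # "+" or "-"
    matched: str  # forward-strand subsequence at [start, start+len-1]


def _iupac_match(window: str, consensus: str) -> bool:
    # N in the sequence never matches a non-N consensus symbol
    for base, sym in zip(window, consensus):
        if base == "N":
            if sym != "N":
                return False
        elif base not in IUPAC_DNA[sym]:
            return False
    return True


def scan_promoter(
    gene_id: str,
    seq: str,
    elements: Sequence[CisElement],
    strands: str = "both",
) -> list[PromoterHit]:
    """All exact IUPAC matches of each element in ``seq``.

    ``strands='both'`` also scans the reverse complement; minus-strand hits
    are reported at the forward coordinate of the leftmost matched base.
    Overlapping matches are all reported.  Output sorted by (start, element,
    strand).
    """
    if strands not in {"both", "forward"}:
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"{gene_id}: non-DNA character(s) {sorted(bad)!r}")
    names = [e.name for e in elements]
    if len(set(names)) != len(names):
        raise ValueError("duplicate element names")
    hits: list[PromoterHit] = []
    for elem in elements:
        cons = elem.consensus
        L = len(cons)
        rc = str(Seq(cons).reverse_complement()) if strands == "both" else None
        for start0 in range(len(seq) - L + 1):
            window = seq[start0 : start0 + L]
            if _iupac_match(window, cons):
                hits.append(
                    PromoterHit(gene_id, elem.name, start0 + 1, "+", window)
                )
            if rc is not None and _iupac_match(window, rc):
                hits.append(
                    PromoterHit(gene_id, elem.name, start0 + 1, "-", window)
                )
    hits.sort(key=lambda h: (h.start, h.element, h.strand))
    return hits


def scan_promoter_fasta(
    path, elements: Sequence[CisElement], strands: str = "both"
) -> list[PromoterHit]:
    """Scan every record of a promoter FASTA (one record per gene)."""
    hits: list[PromoterHit] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate promoter ID {rec.id!r} in {path}")
        seen.add(rec.id)
        hits.extend(scan_promoter(rec.id, str(rec.seq), elements, strands))
    return hits


def element_count_matrix(
    hits: Iterable[PromoterHit],
    gene_ids: Sequence[str],
    elements: Sequence[CisElement],
) -> pd.DataFrame:
    """Gene x element occurrence counts; genes with no hits keep a zero row."""
    counts = pd.DataFrame(
        0, index=list(gene_ids), columns=[e.name for e in elements], dtype=int
    )
    for h in hits:
        counts.loc[h.gene_id, h.element] += 1
    counts.index.name = "gene_id"
    return counts


def hits_table(hits: Iterable[PromoterHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "element": h.element,
                "start": h.start,
                "strand": h.strand,
                "matched": h.matched,
            }
            for h in hits
        ],
        columns=["gene_id", "element", "start", "strand", "matched"],
    )
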