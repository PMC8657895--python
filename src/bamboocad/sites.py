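"""Signature-site classification of CAD-family proteins.

Cinnamyl alcohol dehydrogenases (CADs) are identified by the joint presence
of three short signature sites: the catalytic Zn-binding site, the
structural Zn-binding site and the NADP(H) binding site.  Each site is a
degenerate pattern of literal residues interleaved with fixed-length
wildcard runs, written in the conventional ``(X)n`` notation, e.g.
``GHE(X)2G(X)5V``.  A protein is called a CAD when every site matches
somewhere in its sequence with at most a configurable number of mismatches
at literal positions ("minor mutations" in the family literature).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}

#: The three CAD signature sites (degenerate patterns; hyphens typographic).
DEFAULT_PATTERN_STRINGS: dict[str, str] = {
    "catalytic_zn": "GHE(X)2G(X)5V",
    "structural_zn": "GD(X)10C(X)2C(X)7C",
    "nadph": "G(X)3G(X)2GLGG(X)GH(X)2VK(X)2K(X)2G-(X)VTV(X)S(X)S(X)2K",
}

#: Default mismatch budget per site ("minor mutations" is not quantified;
#: 2 per site is the package default and is configurable per site).
DEFAULT_TOLERANCE: dict[str, int] = {
    "catalytic_zn": 2,
    "structural_zn": 2,
    "nadph": 2,
}


class PatternParseError(ValueError):
    """Raised when a signature-pattern string cannot be parsed."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier.

    Sequences are normalized to upper case; the alphabet is the 20 standard
    amino acids plus ``X`` for unknown residues.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: invalid residue(s) {sorted(bad)!r}; "
                "allowed: 20 standard amino acids plus X"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


# A token is either a literal residue (single letter) or a wildcard run
# of exact length n, represented ("literal", "G") / ("wildcard", n).
Token = tuple[str, Union[str, int]]

_GROUP_RE = re.compile(r"\(X\)(\d*)")


@dataclass(frozen=True)
class SitePattern:
    """A parsed degenerate signature pattern.

    ``tokens`` alternates literal residues with exact-length wildcard runs;
    ``span`` is the total window length; ``literals`` maps 1-based positions
    within the window to the required residue.
    """

    name: str
    raw: str
    tokens: tuple[Token, ...]
    span: int = field(init=False)
    literals: Mapping[int, str] = field(init=False)

    def __post_init__(self) -> None:
        pos = 1
        literals: dict[int, str] = {}
        for kind, value in self.tokens:
            if kind == "literal":
                literals[pos] = value  # type: ignore[assignment]
                pos += 1
            else:
                pos += int(value)
        object.__setattr__(self, "span", pos - 1)
        object.__setattr__(self, "literals", literals)

    @property
    def n_literals(self) -> int:
        return len(self.literals)

    def normalized(self) -> str:
        """Re-emit the pattern in canonical form (hyphens stripped,
        wildcard runs as ``(X)n`` with ``X`` for runs of one)."""
        parts = []
        for kind, value in self.tokens:
            if kind == "literal":
                parts.append(value)
            elif value == 1:
                parts.append("X")
            else:
                parts.append(f"(X){value}")
        return "".join(parts)


def parse_site_pattern(raw: str, name: str = "") -> SitePattern:
    """Parse a pattern string like ``GHE(X)2G(X)5V`` into a :class:`SitePattern`.

    Grammar: residue letters are literals; ``(X)n`` is a wildcard run of
    exactly ``n`` positions; ``(X)`` with no count and a bare ``X`` are runs
    of one; hyphens are typographic and ignored.
    """
    if not raw:
        raise PatternParseError("empty pattern string")
    tokens: list[Token] = []
    i = 0
    while i < len(raw):
        ch = raw[i]
        if ch == "-":
            i += 1
            continue
        if ch == "(":
            m = _GROUP_RE.match(raw, i)
            if not m:
                raise PatternParseError(
                    f"malformed wildcard group at position {i + 1} in {raw!r}"
                )
            count = int(m.group(1)) if m.group(1) else 1
            if count < 1:
                raise PatternParseError(
                    f"wildcard run of length {count} at position {i + 1} in {raw!r}"
                )
            tokens.append(("wildcard", count))
            i = m.end()
        elif ch == "X":
            tokens.append(("wildcard", 1))
            i += 1
        elif ch.upper() in AMINO_ACIDS:
            tokens.append(("literal", ch.upper()))
            i += 1
        else:
            raise PatternParseError(
                f"unexpected character {ch!r} at position {i + 1} in {raw!r}"
            )
    if not tokens:
        raise PatternParseError(f"pattern {raw!r} contains no tokens")
    return SitePattern(name=name, raw=raw, tokens=tuple(tokens))


def default_patterns(
    overrides: Optional[Mapping[str, str]] = None,
) -> dict[str, SitePattern]:
    """The three CAD signature patterns, optionally overridden per name."""
    strings = dict(DEFAULT_PATTERN_STRINGS)
    if overrides:
        strings.update(overrides)
    return {name: parse_site_pattern(raw, name=name) for name, raw in strings.items()}


@dataclass(frozen=True)
class SiteMatch:
    """One window of a protein matching a signature pattern.

    ``start`` is 1-based on the protein; ``mismatches`` counts literal
    positions whose residue differs (wildcard positions never mismatch;
    an unknown residue ``X`` in the protein always counts as a mismatch
    at a literal position).
    """

    pattern_name: str
    start: int
    mismatches: int
    matched_subsequence: str


def scan_sites(
    protein: ProteinRecord, pattern: SitePattern, max_mismatch: int = 0
) -> list[SiteMatch]:
    """All windows of ``protein`` matching ``pattern`` with at most
    ``max_mismatch`` literal mismatches, sorted by (mismatches, start).

    A protein shorter than the pattern span yields an empty list.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if max_mismatch >= pattern.n_literals:
        raise ValueError(
            f"max_mismatch={max_mismatch} must be < number of literal "
            f"positions ({pattern.n_literals}) in pattern {pattern.name!r}"
        )
    seq = protein.sequence
    span = pattern.span
    hits: list[SiteMatch] = []
    # offsets/residues as parallel tuples; X in the protein never matches.
    offsets = tuple(p - 1 for p in pattern.literals)
    residues = tuple(pattern.literals[p] for p in pattern.literals)
    for start0 in range(len(seq) - span + 1):
        mm = 0
        for off, res in zip(offsets, residues):
            if seq[start0 + off] != res:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            hits.append(
                SiteMatch(
                    pattern_name=pattern.name,
                    start=start0 + 1,
                    mismatches=mm,
                    matched_subsequence=seq[start0 : start0 + span],
                )
            )
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


@dataclass(frozen=True)
class ClassificationResult:
    """Per-protein verdict: CAD iff all three sites matched within budget.

    ``site_matches`` holds, per pattern, the best match (fewest mismatches,
    ties to the smallest start) or ``None``.
    """

    protein_id: str
    is_cad: bool
    site_matches: Mapping[str, Optional[SiteMatch]]
    tolerance_used: Mapping[str, int]


def classify(
    protein: ProteinRecord,
    patterns: Optional[Mapping[str, SitePattern]] = None,
    tolerance: Optional[Mapping[str, int]] = None,
) -> ClassificationResult:
    """Classify one protein by joint presence of the three signature sites."""
    if patterns is None:
        patterns = default_patterns()
    names = list(patterns)
    if len(set(names)) != len(names):
        raise ValueError("duplicate pattern names in configuration")
    if set(names) != set(DEFAULT_PATTERN_STRINGS):
        raise ValueError(
            f"expected exactly the patterns {sorted(DEFAULT_PATTERN_STRINGS)}, "
            f"got {sorted(names)}"
        )
    tol = dict(DEFAULT_TOLERANCE)
    if tolerance:
        tol.update(tolerance)
    best: dict[str, Optional[SiteMatch]] = {}
    for name, pattern in patterns.items():
        hits = scan_sites(protein, pattern, max_mismatch=tol[name])
        best[name] = hits[0] if hits else None
    return ClassificationResult(
        protein_id=protein.id,
        is_cad=all(m is not None for m in best.values()),
        site_matches=best,
        tolerance_used={name: tol[name] for name in patterns},
    )


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Read a multi-FASTA of protein sequences; duplicate IDs are an error."""
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate protein IDs in {path}: {dups}")
    return records


def classify_fasta(
    path,
    patterns: Optional[Mapping[str, SitePattern]] = None,
    tolerance: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Classify every record of a FASTA file.

    Returns one row per record, input order preserved, with per-site start
    and mismatch columns (``<NA>`` where a site did not match).
    """
    results = [
        classify(rec, patterns=patterns, tolerance=tolerance)
        for rec in read_protein_fasta(path)
    ]
    return classification_table(results)


def classification_table(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        row: dict[str, object] = {"protein_id": res.protein_id, "is_cad": res.is_cad}
        for name in sorted(res.site_matches):
            m = res.site_matches[name]
            row[f"{name}_start"] = m.start if m else pd.NA
            row[f"{name}_mismatches"] = m.mismatches if m else pd.NA
        rows.append(row)
    if not rows:
        cols = ["protein_id", "is_cad"]
        for name in sorted(DEFAULT_PATTERN_STRINGS):
            cols += [f"{name}_start", f"{name}_mismatches"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def write_accepted_fasta(
    records: Sequence[ProteinRecord], table: pd.DataFrame, path
) -> int:
    """Write the FASTA of proteins classified as CAD; returns the count."""
    accepted = set(table.loc[table["is_cad"].astype(bool), "protein_id"])
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            if rec.id in accepted:
                fh.write(f">{rec.id}\n{rec.sequence}\n")
                n += 1
    return n
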