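"""Signature-pattern parsing and CAD classification."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bamboocad.sites import (
    DEFAULT_PATTERN_STRINGS,
    PatternParseError,
    ProteinRecord,
    classification_table,
    classify,
    classify_fasta,
    default_patterns,
    parse_site_pattern,
    scan_sites,
)
from bamboocad.simulate import make_protein_family, write_fasta

from helpers import brute_force_site_scan

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestParseSitePattern:
    @pytest.mark.parametrize(
        "raw, span, literals",
        [
            ("GHE(X)2G(X)5V", 12, {1: "G", 2: "H", 3: "E", 6: "G", 12: "V"}),
            ("GD(X)10C(X)2C(X)7C", 24, {1: "G", 2: "D", 13: "C", 16: "C", 24: "C"}),
            ("A", 1, {1: "A"}),
            ("G-(X)V", 3, {1: "G", 3: "V"}),  # hyphen typographic, (X) = run of 1
            ("GXV", 3, {1: "G", 3: "V"}),  # bare X = run of 1
        ],
    )
    def test_span_and_literal_map(self, raw, span, literals):
        pat = parse_site_pattern(raw)
        assert pat.span == span
        assert dict(pat.literals) == literals

    def test_nadph_site_hand_counted(self):
        # G (X)3 G (X)2 G L G G (X) G H (X)2 V K (X)2 K (X)2 G (X) V T V (X) S (X) S (X)2 K
        pat = parse_site_pattern(DEFAULT_PATTERN_STRINGS["nadph"])
        assert pat.span == 35
        assert pat.n_literals == 18
        expected = {
            1: "G", 5: "G", 8: "G", 9: "L", 10: "G", 11: "G", 13: "G",
            14: "H", 17: "V", 18: "K", 21: "K", 24: "G", 26: "V", 27: "T",
            28: "V", 30: "S", 32: "S", 35: "K",
        }
        assert dict(pat.literals) == expected

    def test_round_trip_to_normalized_string(self):
        for raw in DEFAULT_PATTERN_STRINGS.values():
            pat = parse_site_pattern(raw)
            again = parse_site_pattern(pat.normalized())
            assert again.tokens == pat.tokens
            assert again.normalized() == pat.normalized()

    @pytest.mark.parametrize("raw", ["", "(Y)2A", "G(X", "G?V", "(X)0A"])
    def test_malformed_patterns_raise(self, raw):
        with pytest.raises(PatternParseError):
            parse_site_pattern(raw)


class TestScanSites:
    def test_exact_planted_match(self, patterns):
        rec = ProteinRecord("p", "GHEKLGSTACDV")
        hits = scan_sites(rec, patterns["catalytic_zn"], 0)
        assert [(h.start, h.mismatches) for h in hits] == [(1, 0)]
        assert hits[0].matched_subsequence == "GHEKLGSTACDV"

    def test_single_substitution_needs_budget(self, patterns):
        rec = ProteinRecord("p", "GQEKLGSTACDV")  # H -> Q
        assert scan_sites(rec, patterns["catalytic_zn"], 0) == []
        hits = scan_sites(rec, patterns["catalytic_zn"], 1)
        assert [(h.start, h.mismatches) for h in hits] == [(1, 1)]

    def test_all_literals_wrong_is_no_hit(self, patterns):
        rec = ProteinRecord("p", "A" * 12)
        assert scan_sites(rec, patterns["catalytic_zn"], 1) == []

    def test_protein_shorter_than_span_is_empty(self, patterns):
        rec = ProteinRecord("p", "GHEKL")
        assert scan_sites(rec, patterns["catalytic_zn"], 2) == []

    def test_unknown_residue_x_counts_as_mismatch(self, patterns):
        rec = ProteinRecord("p", "XHEKLGSTACDV")  # X at literal position 1
        assert scan_sites(rec, patterns["catalytic_zn"], 0) == []
        hits = scan_sites(rec, patterns["catalytic_zn"], 1)
        assert hits and hits[0].mismatches == 1

    def test_x_at_wildcard_position_never_mismatches(self, patterns):
        rec = ProteinRecord("p", "GHEXXGXXXXXV")
        hits = scan_sites(rec, patterns["catalytic_zn"], 0)
        assert [(h.start, h.mismatches) for h in hits] == [(1, 0)]

    def test_budget_must_be_below_literal_count(self, patterns):
        rec = ProteinRecord("p", "GHEKLGSTACDV")
        with pytest.raises(ValueError):
            scan_sites(rec, patterns["catalytic_zn"], 5)

    @given(
        seq=st.text(alphabet=AA20, min_size=12, max_size=60),
        budget=st.integers(min_value=0, max_value=4),
    )
    def test_agrees_with_exhaustive_window_oracle(self, patterns, seq, budget):
        rec = ProteinRecord("p", seq)
        pat = patterns["catalytic_zn"]
        got = [(h.start, h.mismatches) for h in scan_sites(rec, pat, budget)]
        expected = brute_force_site_scan(seq, dict(pat.literals), pat.span, budget)
        assert got == expected


def _plant_all_sites(patterns):
    """One protein carrying each site exactly, padded with A runs."""
    parts = []
    for name in ("catalytic_zn", "structural_zn", "nadph"):
        pat = patterns[name]
        window = ["A"] * pat.span
        for pos, res in pat.literals.items():
            window[pos - 1] = res
        parts.append("".join(window))
    return "AAAA".join(parts)


class TestClassify:
    def test_planted_positive_has_zero_mismatches(self, patterns):
        rec = ProteinRecord("pos", _plant_all_sites(patterns))
        res = classify(rec, patterns)
        assert res.is_cad
        assert all(m.mismatches == 0 for m in res.site_matches.values())

    def test_missing_nadph_site_is_negative(self, patterns):
        seq = _plant_all_sites(patterns)
        truncated = seq[: -patterns["nadph"].span]
        res = classify(ProteinRecord("neg", truncated), patterns)
        assert not res.is_cad
        assert res.site_matches["nadph"] is None
        assert res.site_matches["catalytic_zn"] is not None

    def test_monotone_in_tolerance(self, patterns):
        recs, _ = make_protein_family(5, 5, seed=42)
        for rec in recs:
            was_cad = False
            for tol in range(4):
                t = {name: tol for name in patterns}
                is_cad = classify(rec, patterns, t).is_cad
                assert not (was_cad and not is_cad), "tolerance monotonicity"
                was_cad = is_cad

    def test_pure_function_of_inputs(self, patterns):
        rec = ProteinRecord("p", _plant_all_sites(patterns))
        assert classify(rec, patterns) == classify(rec, patterns)

    def test_wrong_pattern_set_rejected(self, patterns):
        rec = ProteinRecord("p", "GHEKLGSTACDV")
        with pytest.raises(ValueError):
            classify(rec, {"catalytic_zn": patterns["catalytic_zn"]})

    def test_planted_family_recovered_exactly(self, patterns):
        recs, ledger = make_protein_family(20, 20, seed=7)
        truth = {p["id"]: p["is_cad"] for p in ledger["proteins"]}
        for rec in recs:
            res = classify(rec, patterns)
            assert res.is_cad == truth[rec.id], rec.id
            if res.is_cad:
                planted = next(
                    p for p in ledger["proteins"] if p["id"] == rec.id
                )
                for name, site in planted["sites"].items():
                    best = res.site_matches[name]
                    assert best is not None
                    assert best.mismatches <= site["mismatches"]


class TestClassifyFasta:
    def test_three_record_fixture(self, tmp_path, patterns):
        recs, ledger = make_protein_family(1, 2, seed=3)
        path = tmp_path / "family.fasta"
        write_fasta(recs, path)
        table = classify_fasta(path)
        assert list(table["protein_id"]) == [r.id for r in recs]
        assert int(table["is_cad"].sum()) == 1

    def test_empty_fasta_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        table = classify_fasta(path)
        assert len(table) == 0
        assert "protein_id" in table.columns

    def test_lowercase_sequences_normalized(self, tmp_path, patterns):
        seq = _plant_all_sites(patterns)
        path = tmp_path / "lc.fasta"
        path.write_text(f">a\n{seq.lower()}\n>b\n{seq}\n")
        table = classify_fasta(path)
        assert list(table["is_cad"]) == [True, True]

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nMKV\n>a\nMKL\n")
        with pytest.raises(ValueError, match="duplicate"):
            classify_fasta(path)


def test_classification_table_columns_stable():
    table = classification_table([])
    assert list(table.columns[:2]) == ["protein_id", "is_cad"]
    assert "nadph_start" in table.columns
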