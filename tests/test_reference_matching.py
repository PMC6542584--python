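import numpy as np
import pytest

from peptaxon.formats_io import ReferenceEntry, ReferenceSet
from peptaxon.reference_matching import (
    Placement,
    alignment_report,
    call_proteins,
    call_substitutions,
    canonicalize_references,
    compute_coverage,
    place_peptides,
)

from _oracles import brute_place


def refset(*pairs):
    return ReferenceSet([ReferenceEntry(i, s) for i, s in pairs])


class TestPlacePeptides:
    def test_exact_substring(self):
        refs = refset(("r1", "AAGAGAA"))
        (p,) = place_peptides(["GAGA"], refs)
        assert (p.entry_id, p.start, p.end, p.n_subst, p.unique) == ("r1", 3, 6, 0, True)

    def test_single_mismatch_placement(self):
        refs = refset(("r1", "AAGAGAA"))
        (p,) = place_peptides(["GASA"], refs, max_subst=1, min_subst_len=4)
        assert (p.start, p.end, p.n_subst) == (3, 6, 1)
        assert (p.subst.ref_pos, p.subst.ref_res, p.subst.obs_res) == (5, "G", "S")

    def test_short_peptides_get_no_mismatch_tolerance(self):
        refs = refset(("r1", "AAGAGAA"))
        assert place_peptides(["GASA"], refs, max_subst=1, min_subst_len=6) == []

    def test_terminal_mismatch_forbidden(self):
        refs = refset(("r1", "WWWCCCCCCWWW"))
        # mismatch at first residue of the peptide: rejected
        assert place_peptides(["ACCCCC"], refs, min_subst_len=6) == []
        # same mismatch moved inside: accepted
        (p,) = place_peptides(["CCACCC"], refs, min_subst_len=6)
        assert p.subst.obs_res == "A"

    def test_multi_entry_not_unique(self):
        refs = refset(("r1", "WWPEPTLDEWW"), ("r2", "GGPEPTLDEGG"))
        hits = place_peptides(["PEPTLDE"], refs)
        assert len(hits) == 2
        assert all(not p.unique for p in hits)
        assert [p.entry_id for p in hits] == ["r1", "r2"]  # entry input order

    def test_exact_suppresses_mismatch_placements(self):
        # exact hit in r1 means the 1-mismatch candidate in r2 is not reported
        refs = refset(("r1", "AACCCCCCAA"), ("r2", "AACCCWCCAA"))
        hits = place_peptides(["CCCCCC"], refs)
        assert [p.entry_id for p in hits] == ["r1"]
        assert hits[0].unique

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            place_peptides(["AAAAAA"], ReferenceSet([]))

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(42)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for trial in range(60):
            entries = [
                (f"e{k}", "".join(rng.choice(aa, size=rng.integers(20, 120))))
                for k in range(rng.integers(1, 4))
            ]
            refs = refset(*entries)
            # probe peptides: random, and mutated fragments of the references
            peps = ["".join(rng.choice(aa, size=rng.integers(4, 15)))]
            src = entries[0][1]
            if len(src) > 12:
                start = int(rng.integers(0, len(src) - 10))
                frag = list(src[start : start + 9])
                frag[4] = rng.choice(aa)
                peps.append("".join(frag))
            for pep in peps:
                got = {
                    (p.entry_id, p.start, None if p.subst is None else p.subst.ref_pos - p.start)
                    for p in place_peptides([pep], refs)
                }
                assert got == brute_place(pep, entries), (trial, pep)


class TestCoverage:
    def test_ninety_percent(self):
        refs = refset(("r1", "ACDEFGHKLM"))
        placements = [
            Placement("ACDEF", "r1", 1, 5, unique=True),
            Placement("HKLM", "r1", 7, 10, unique=True),
        ]
        (prof,) = compute_coverage(placements, refs, "S1")
        assert prof.coverage_pct == pytest.approx(90.0)
        assert prof.n_unique_peptides == 2

    def test_no_placements_zero(self):
        refs = refset(("r1", "ACDEFGHKLM"))
        (prof,) = compute_coverage([], refs, "S1")
        assert prof.coverage_pct == 0.0
        assert prof.n_peptides == 0

    def test_depth_two_coverage_half(self):
        refs = refset(("r1", "ACDEFGHKLM"))
        placements = [
            Placement("ACDEF", "r1", 1, 5, unique=True),
            Placement("ACDEF", "r1", 1, 5, unique=True),
        ]
        (prof,) = compute_coverage(placements, refs, "S1")
        assert prof.coverage_pct == pytest.approx(50.0)
        assert list(prof.depth[:5]) == [2] * 5

    def test_out_of_bounds_rejected(self):
        refs = refset(("r1", "ACDEF"))
        with pytest.raises(ValueError, match="outside"):
            compute_coverage([Placement("ACDEFG", "r1", 1, 6)], refs, "S1")

    def test_multimapper_covers_but_not_unique(self):
        refs = refset(("r1", "WWPEPTLDEWW"), ("r2", "GGPEPTLDEGG"))
        placements = place_peptides(["PEPTLDE"], refs)
        profs = compute_coverage(placements, refs, "S1")
        for prof in profs:
            assert prof.coverage_pct > 0
            assert prof.n_unique_peptides == 0
            assert prof.n_peptides == 1

    def test_coverage_pct_exact_formula(self):
        rng = np.random.default_rng(3)
        refs = refset(("r1", "".join(rng.choice(list("ACDEFG"), size=50))))
        seq = refs.get("r1").sequence
        placements = [
            Placement(seq[s : s + 6], "r1", s + 1, s + 6)
            for s in rng.integers(0, 44, size=8)
        ]
        (prof,) = compute_coverage(placements, refs, "S1")
        assert prof.coverage_pct == 100.0 * np.count_nonzero(prof.depth) / 50


class TestProteinCalls:
    def make_profile(self, n_unique):
        refs = refset(("r1", "A" * 10))
        (prof,) = compute_coverage([], refs, "S1")
        prof.n_unique_peptides = n_unique
        return prof

    @pytest.mark.parametrize("n,tier", [(0, "absent"), (1, "relaxed"), (2, "stringent"), (5, "stringent")])
    def test_tiers(self, n, tier):
        (call,) = call_proteins([self.make_profile(n)])
        assert call.tier == tier

    def test_relaxed_flagged_with_asterisk(self):
        (call,) = call_proteins([self.make_profile(1)])
        assert call.flag == "*"
        (call,) = call_proteins([self.make_profile(2)])
        assert call.flag == ""


class TestSubstitutions:
    def profiles_for(self, refs, peptides, min_subst_len=6):
        placements = place_peptides(peptides, refs, min_subst_len=min_subst_len)
        return compute_coverage(placements, refs, "S1")

    def test_concordant_alternative_called(self):
        refs = refset(("r1", "WWWCACCCCWWW"))
        # two peptides observe S where the reference has A at position 5
        profs = self.profiles_for(refs, ["CSCCCC", "WCSCCC"])
        table = call_substitutions(profs, refs, min_support=2)
        assert table.symbol("r1", "S1", 5) == "S"
        assert table.support_at("r1", "S1", 5) == 2

    def test_single_support_is_ambiguous(self):
        refs = refset(("r1", "WWWCACCCCWWW"))
        profs = self.profiles_for(refs, ["CSCCCC"])
        table = call_substitutions(profs, refs, min_support=2)
        assert table.symbol("r1", "S1", 5) == "?"

    def test_uncovered_renders_dash(self):
        refs = refset(("r1", "WWWCACCCCWWW"))
        profs = self.profiles_for(refs, ["CSCCCC"])
        table = call_substitutions(profs, refs)
        assert table.symbol("r1", "S1", 1) == "-"
        assert table.symbol("r1", "S1", 12) == "-"

    def test_conflicting_alternatives_ambiguous(self):
        refs = refset(("r1", "WWWCACCCCWWW"))
        profs = self.profiles_for(refs, ["CSCCCC", "CTCCCC", "WCSCCC"])
        table = call_substitutions(profs, refs, min_support=2)
        assert table.symbol("r1", "S1", 5) == "?"

    def test_reference_agreement_keeps_reference_residue(self):
        refs = refset(("r1", "WWWCACCCCWWW"))
        profs = self.profiles_for(refs, ["CACCCC"])
        table = call_substitutions(profs, refs)
        assert table.symbol("r1", "S1", 5) == "A"

    def test_min_support_monotonicity(self):
        refs = refset(("r1", "WWWCACCCCWWW"))
        profs = self.profiles_for(refs, ["CSCCCC", "WCSCCC"])
        counts = [
            call_substitutions(profs, refs, min_support=k).n_residue_calls()
            for k in (1, 2, 3)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAlignmentReport:
    def test_grid_shape_and_symbols(self):
        refs = refset(("r1", "WWWCACCCCWWW"))
        placements = place_peptides(["CSCCCC", "WCSCCC"], refs)
        profs_a = compute_coverage(placements, refs, "SA")
        profs_b = compute_coverage([], refs, "SB")
        table = call_substitutions([*profs_a, *profs_b], refs, min_support=2)
        grid = alignment_report(table, "r1", ["SA", "SB"], [1, 5, 6])
        assert grid.shape == (2, 3)
        assert list(grid.loc["SA"]) == ["-", "S", "C"]
        assert list(grid.loc["SB"]) == ["-", "-", "-"]  # all-uncovered sample

    def test_unknown_position_rejected(self):
        refs = refset(("r1", "WWWCACCCCWWW"))
        profs = compute_coverage([], refs, "SA")
        table = call_substitutions(profs, refs)
        with pytest.raises(ValueError, match="position"):
            alignment_report(table, "r1", ["SA"], [99])

    def test_tsv_round_trip(self, tmp_path):
        refs = refset(("r1", "WWWCACCCCWWW"))
        placements = place_peptides(["CSCCCC", "WCSCCC"], refs)
        profs = compute_coverage(placements, refs, "SA")
        table = call_substitutions(profs, refs, min_support=2)
        grid = alignment_report(table, "r1", ["SA"], list(range(1, 13)))
        path = tmp_path / "grid.tsv"
        grid.to_csv(path, sep="\t")
        import pandas as pd

        back = pd.read_csv(path, sep="\t", index_col=0).astype(str)
        back.columns = list(grid.columns)
        assert back.equals(grid)


class TestCanonicalizeReferences:
    def test_mapping_applied(self, tiny_refs):
        canon = canonicalize_references(tiny_refs)
        assert "I" not in canon.get("p2").sequence
        assert canon.get("p1").taxon == "tax_a"

    def test_deamidation_monotonic_placement(self):
        refs = refset(("r1", "WWWANQTTTKWWW"))
        pep_deam = "ADETTTK"  # fully deamidated form of ANQTTTK
        canon_on = canonicalize_references(refs, deam_tolerant=True)
        canon_off = canonicalize_references(refs, deam_tolerant=False)
        on = place_peptides([pep_deam.replace("N", "D").replace("Q", "E")], canon_on)
        off = place_peptides([pep_deam], canon_off)
        assert len(on) >= len(off)
        assert len(on) == 1 and len(off) == 0  # two deamidations: only ON places
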