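from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diagnostax.diagnostics import (
    COORDINATE_MISSING,
    SPAN_LENGTH_MISMATCH,
    Diagnosis,
    DiagnosisFormatError,
    Region,
    assemble_diagnosis,
    compute_focal_invariant_columns,
    compute_strict_diagnostic_columns,
    format_diagnosis_block,
    minimal_combination,
    parse_diagnosis_block,
    profiles_from_yaml,
    profiles_to_yaml,
    verify_combination,
)
from diagnostax.msa_io import IUPAC_EXPANSION, SpeciesMapError

from conftest import make_alignment, make_map


# ---------------------------------------------------------------------------
# Independent brute-force oracle: per-column scans + run assembly, written
# without reference to the implementation under test.


def oracle_invariant(rows: list[str]) -> dict[int, str]:
    out = {}
    for col in range(1, len(rows[0]) + 1):
        states = {r[col - 1] for r in rows}
        if len(states) == 1 and states <= set("ACGT"):
            out[col] = rows[0][col - 1]
    return out


def oracle_strict(focal: list[str], background: list[str]) -> dict[int, str]:
    invariant = oracle_invariant(focal)
    out = {}
    for col, state in invariant.items():
        hit = False
        for row in background:
            symbol = row[col - 1]
            if state in IUPAC_EXPANSION.get(symbol, frozenset()):
                hit = True
        if not hit:
            out[col] = state
    return out


def oracle_regions(focal: list[str], background: list[str]) -> list[tuple[int, int, str, frozenset]]:
    invariant = oracle_invariant(focal)
    strict = oracle_strict(focal, background)
    regions = []
    cols = sorted(invariant)
    i = 0
    while i < len(cols):
        j = i
        while j + 1 < len(cols) and cols[j + 1] == cols[j] + 1:
            j += 1
        run = cols[i : j + 1]
        diag = frozenset(c for c in run if c in strict)
        if diag:
            motif = "".join(invariant[c] for c in run)
            regions.append((run[0], run[-1], motif, diag))
        i = j + 1
    return regions


# ---------------------------------------------------------------------------


class TestFocalInvariant:
    def test_forced_by_definition(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGA"})
        smap = make_map({"a": "X", "b": "X"})
        assert compute_focal_invariant_columns(aln, smap, "X") == {1: "A", 2: "C", 3: "G"}

    def test_gap_disqualifies(self):
        aln = make_alignment({"a": "AC-T", "b": "ACAT"})
        smap = make_map({"a": "X", "b": "X"})
        assert compute_focal_invariant_columns(aln, smap, "X") == {1: "A", 2: "C", 4: "T"}

    def test_ambiguity_disqualifies(self):
        aln = make_alignment({"a": "AR", "b": "AR"})
        smap = make_map({"a": "X", "b": "X"})
        assert compute_focal_invariant_columns(aln, smap, "X") == {1: "A"}

    def test_planted_variable_column(self):
        # 10 columns, one planted variable column (4); frozen from the
        # per-column oracle
        rows = {
            "a": "ACGTACGTAC",
            "b": "ACGAACGTAC",
            "c": "ACGCACGTAC",
        }
        aln = make_alignment(rows)
        smap = make_map({k: "X" for k in rows})
        got = compute_focal_invariant_columns(aln, smap, "X")
        assert got == oracle_invariant(list(rows.values()))
        assert set(got) == {1, 2, 3, 5, 6, 7, 8, 9, 10}

    def test_absent_species_errors(self):
        aln = make_alignment({"a": "AC"})
        smap = make_map({"a": "X"})
        with pytest.raises(SpeciesMapError):
            compute_focal_invariant_columns(aln, smap, "Y")


class TestStrictDiagnostic:
    def test_background_differs(self):
        aln = make_alignment({"a": "AA", "b": "AA", "c": "CA", "d": "GA"})
        smap = make_map({"a": "X", "b": "X", "c": "Y", "d": "Z"})
        assert compute_strict_diagnostic_columns(aln, smap, "X") == {1: "A"}

    def test_compatible_ambiguity_disqualifies(self):
        # R = A/G could hide an A
        aln = make_alignment({"a": "A", "b": "A", "c": "R"})
        smap = make_map({"a": "X", "b": "X", "c": "Y"})
        assert compute_strict_diagnostic_columns(aln, smap, "X") == {}

    def test_background_gap_does_not_disqualify(self):
        aln = make_alignment({"a": "A", "b": "A", "c": "-"})
        smap = make_map({"a": "X", "b": "X", "c": "Y"})
        assert compute_strict_diagnostic_columns(aln, smap, "X") == {1: "A"}

    def test_no_background_errors(self):
        aln = make_alignment({"a": "AC"})
        smap = make_map({"a": "X"})
        with pytest.raises(SpeciesMapError):
            compute_strict_diagnostic_columns(aln, smap, "X")

    def test_planted_autapomorphies_recovered(self):
        # 12 columns, 3 species x 2 sequences, 2 planted autapomorphies per
        # species; expectation computed by brute-force enumeration
        rows = {
            "x1": "TACGTACGTACG",
            "x2": "TACGTACGTACG",
            "y1": "AACGTGCGTACG",
            "y2": "AACGTGCGTACG",
            "z1": "AACGTACGTCCG",
            "z2": "AACGTACGTCCG",
        }
        aln = make_alignment(rows)
        smap = make_map({"x1": "X", "x2": "X", "y1": "Y", "y2": "Y", "z1": "Z", "z2": "Z"})
        for species, members in (("X", ["x1", "x2"]), ("Y", ["y1", "y2"]), ("Z", ["z1", "z2"])):
            focal = [rows[m] for m in members]
            background = [rows[m] for m in rows if m not in members]
            assert compute_strict_diagnostic_columns(aln, smap, species) == oracle_strict(
                focal, background
            )


class TestAssembleDiagnosis:
    def test_run_rule(self):
        # invariant columns 5-9 with diagnostic column 7; column 4 variable
        rows = {
            "a": "ACGAGGTCCA",
            "b": "ACGTGGTCCT",
            "y": "ACGTGGACCA",
        }
        aln = make_alignment(rows)
        smap = make_map({"a": "X", "b": "X", "y": "Y"})
        d = assemble_diagnosis(aln, smap, "X")
        assert len(d.regions) == 1
        region = d.regions[0]
        assert (region.start, region.end) == (5, 9)
        assert len(region.motif) == 5
        assert region.diagnostic_positions == frozenset({7})

    def test_single_column_region(self):
        # diagnostic column with variable flanks yields a width-1 region,
        # the shape of a printed single-position entry
        rows = {
            "a": "AATAA",
            "b": "ACTGA",
            "y": "AACAA",
            "z": "AAGAA",
        }
        aln = make_alignment(rows)
        smap = make_map({"a": "X", "b": "X", "y": "Y", "z": "Z"})
        d = assemble_diagnosis(aln, smap, "X")
        assert any(
            r.start == r.end == 3 and r.motif == "T" for r in d.regions
        )

    def test_empty_strict_set_yields_empty_diagnosis(self, caplog):
        aln = make_alignment({"a": "AC", "b": "AC"})
        smap = make_map({"a": "X", "b": "Y"})
        d = assemble_diagnosis(aln, smap, "X")
        assert d.regions == ()

    def test_matches_oracle_on_random_small_alignments(self):
        rng = np.random.default_rng(17)
        for _ in range(150):
            n = int(rng.integers(2, 9))
            L = int(rng.integers(2, 31))
            labels = [f"S{rng.integers(0, 3)}" for _ in range(n)]
            if len(set(labels)) < 2:
                labels[0] = "S0"
                labels[-1] = "S1"
            rows = {
                f"s{i}": "".join(rng.choice(list("ACGT-RN"), p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.03, 0.03], size=L))
                for i in range(n)
            }
            aln = make_alignment(rows)
            smap = make_map({f"s{i}": labels[i] for i in range(n)})
            for species in set(labels):
                focal = [rows[f"s{i}"] for i in range(n) if labels[i] == species]
                background = [rows[f"s{i}"] for i in range(n) if labels[i] != species]
                expected = oracle_regions(focal, background)
                got = [
                    (r.start, r.end, r.motif, r.diagnostic_positions)
                    for r in assemble_diagnosis(aln, smap, species).regions
                ]
                assert got == expected


class TestVerify:
    def _computed(self):
        rows = {
            "a": "ACGTAGGTCA",
            "b": "ACGTAGGTCA",
            "y1": "ACCTAGATCA",
            "y2": "ACCTAGATCA",
        }
        aln = make_alignment(rows)
        smap = make_map({"a": "X", "b": "X", "y1": "Y", "y2": "Y"})
        return aln, smap, assemble_diagnosis(aln, smap, "X")

    def test_computed_diagnosis_passes(self):
        aln, smap, d = self._computed()
        assert verify_combination(d, aln, smap).verdict == "pass"

    def test_mutated_background_fails_with_id(self):
        aln, smap, d = self._computed()
        rows = {s.id: s.residues for s in aln}
        rows["y1"] = rows["a"]  # background copies a focal sequence
        mutated = make_alignment(rows)
        report = verify_combination(d, mutated, smap)
        assert report.verdict == "fail"
        assert "y1" in report.unexcluded

    def test_out_of_range_region_is_malformed(self):
        aln, smap, _ = self._computed()
        rogue = Diagnosis(
            species="X",
            regions=(Region(5, 99, "A" * 95, frozenset({9})),),
        )
        assert verify_combination(rogue, aln, smap).verdict == "malformed"

    def test_single_sequence_species_flagged_low_support(self):
        aln = make_alignment({"a": "AAAA", "y": "CAAA"})
        smap = make_map({"a": "X", "y": "Y"})
        d = assemble_diagnosis(aln, smap, "X")
        report = verify_combination(d, aln, smap)
        assert report.verdict == "pass"
        assert any("low support" in note for note in report.notes)

    def test_printed_style_planted_regions_pass(self):
        # plant the first printed regions of the new species' block on a
        # synthetic backbone; background differs at all diagnostic columns
        block = "11-14: TCAA, 21-23: GTT"
        d, rep = parse_diagnosis_block(block, species="X")
        assert rep.verdict == "pass"
        L = 30
        focal = ["A"] * L
        for region in d.regions:
            for col in region.columns:
                focal[col - 1] = region.motif_at(col)
        background = list(focal)
        for col in (11, 21):  # one diagnostic column per region flipped
            background[col - 1] = "G" if focal[col - 1] != "G" else "C"
        aln = make_alignment({"f1": "".join(focal), "f2": "".join(focal), "b1": "".join(background)})
        smap = make_map({"f1": "X", "f2": "X", "b1": "Y"})
        assert verify_combination(d, aln, smap).verdict == "pass"


class TestMinimal:
    def test_tie_broken_by_smaller_start(self):
        # two regions, each excluding the whole background; the middle
        # column varies within the focal species to split the runs
        rows = {
            "a": "TTAGG",
            "b": "TTCGG",
            "y": "CCACC",
        }
        aln = make_alignment(rows)
        smap = make_map({"a": "X", "b": "X", "y": "Y"})
        d = assemble_diagnosis(aln, smap, "X")
        assert len(d.regions) == 2
        reduced = minimal_combination(d, aln, smap)
        assert len(reduced.regions) == 1
        assert reduced.regions[0].start == d.regions[0].start
        assert verify_combination(reduced, aln, smap).verdict == "pass"

    def test_greedy_cover_matches_brute_force(self):
        # exclusion sets {s1,s2}, {s2,s3}, {s3}: brute force over all
        # subsets confirms the minimum cover has size 2
        import itertools

        exclusion = [{"s1", "s2"}, {"s2", "s3"}, {"s3"}]
        background = {"s1", "s2", "s3"}
        brute_best = min(
            (
                subset
                for r in range(1, 4)
                for subset in itertools.combinations(range(3), r)
                if set().union(*(exclusion[i] for i in subset)) == background
            ),
            key=len,
        )
        assert len(brute_best) == 2

        # a computed diagnosis always has every region excluding the whole
        # background (strict columns exclude everyone), so this partial
        # exclusion structure only arises for externally supplied regions
        diagnosis = Diagnosis(
            "X",
            regions=(
                Region(1, 1, "A", frozenset({1})),
                Region(3, 3, "C", frozenset({3})),
                Region(5, 5, "G", frozenset({5})),
            ),
            source="parsed",
        )
        rows = {
            "f1": "ATCTG",
            "f2": "AACAG",
            "s1": "GTCTG",  # excluded by region 1 only
            "s2": "GTTTG",  # excluded by regions 1 and 2
            "s3": "ATTTA",  # excluded by regions 2 and 3
        }
        aln = make_alignment(rows)
        smap = make_map({"f1": "X", "f2": "X", "s1": "B", "s2": "B", "s3": "B"})
        assert verify_combination(diagnosis, aln, smap).verdict == "pass"
        reduced = minimal_combination(diagnosis, aln, smap)
        assert [r.start for r in reduced.regions] == [1, 3]
        assert verify_combination(reduced, aln, smap).verdict == "pass"

    def test_single_region_unchanged(self):
        aln = make_alignment({"a": "AT", "b": "AT", "y": "CT"})
        smap = make_map({"a": "X", "b": "X", "y": "Y"})
        d = assemble_diagnosis(aln, smap, "X")
        assert minimal_combination(d, aln, smap).regions == d.regions

    def test_unverified_input_rejected(self):
        aln = make_alignment({"a": "AT", "b": "AT", "y": "AT"})
        smap = make_map({"a": "X", "b": "X", "y": "Y"})
        d = assemble_diagnosis(aln, smap, "X")  # empty: nothing diagnostic
        with pytest.raises(ValueError):
            minimal_combination(d, aln, smap)


class TestParse:
    def test_plain_entry(self):
        d, rep = parse_diagnosis_block("78–99: TCAACCCGGTGCTTACCTCGGT")
        assert (d.regions[0].start, d.regions[0].end) == (78, 99)
        assert len(d.regions[0].motif) == 22
        assert rep.region_flags == [[]]
        assert rep.verdict == "pass"

    def test_span_length_mismatch_flagged_not_fatal(self):
        d, rep = parse_diagnosis_block("558–591: CCGT")
        assert len(d.regions) == 1
        assert SPAN_LENGTH_MISMATCH in rep.region_flags[0]
        assert rep.verdict == "malformed"

    def test_single_position(self):
        d, rep = parse_diagnosis_block("306: C")
        region = d.regions[0]
        assert (region.start, region.end, region.motif) == (306, 306, "C")
        assert rep.region_flags == [[]]

    def test_spaces_inside_range(self):
        d, _ = parse_diagnosis_block("288– 292: CGTT, 306: C")
        assert (d.regions[0].start, d.regions[0].end) == (288, 292)

    def test_hyphen_accepted(self):
        d, _ = parse_diagnosis_block("10-13: ACGT")
        assert (d.regions[0].start, d.regions[0].end) == (10, 13)

    def test_missing_end_coordinate_flagged(self):
        d, rep = parse_diagnosis_block("426: CCTAGGTTCT")
        assert COORDINATE_MISSING in rep.region_flags[0]

    def test_unparseable_is_error(self):
        with pytest.raises(DiagnosisFormatError):
            parse_diagnosis_block("no entries here")
        with pytest.raises(DiagnosisFormatError):
            parse_diagnosis_block("   ")

    def test_full_span_candidate_diagnostic(self):
        d, _ = parse_diagnosis_block("10-12: ACG")
        assert d.regions[0].diagnostic_positions == frozenset({10, 11, 12})


class TestFormat:
    def test_single_column_dialect(self):
        d = Diagnosis("X", (Region(306, 306, "C", frozenset({306})),))
        assert format_diagnosis_block(d) == "306: C"

    def test_round_trip_computed(self):
        rows = {
            "a": "ACGTAGGTCAATT",
            "b": "ACGTAGGTCAATT",
            "y": "TCGAAGATCTATT",
        }
        aln = make_alignment(rows)
        smap = make_map({"a": "X", "b": "X", "y": "Y"})
        d = assemble_diagnosis(aln, smap, "X")
        parsed, rep = parse_diagnosis_block(format_diagnosis_block(d), species="X")
        assert rep.verdict == "pass"
        assert [(r.start, r.end, r.motif) for r in parsed.regions] == [
            (r.start, r.end, r.motif) for r in d.regions
        ]

    def test_empty_diagnosis(self):
        d = Diagnosis("X", ())
        assert format_diagnosis_block(d) == ""


# ---------------------------------------------------------------------------
# Properties


@st.composite
def flagless_diagnoses(draw):
    n = draw(st.integers(1, 5))
    regions = []
    cursor = 1
    for _ in range(n):
        start = cursor + draw(st.integers(0, 10))
        length = draw(st.integers(1, 8))
        motif = draw(
            st.text(alphabet="ACGT", min_size=length, max_size=length)
        )
        end = start + length - 1
        regions.append(Region(start, end, motif, frozenset(range(start, end + 1))))
        cursor = end + 2
    return Diagnosis("X", tuple(regions))


@given(flagless_diagnoses())
@settings(max_examples=60, deadline=None)
def test_parse_format_identity(diagnosis):
    text = format_diagnosis_block(diagnosis)
    parsed, rep = parse_diagnosis_block(text, species="X")
    assert rep.verdict == "pass"
    assert [(r.start, r.end, r.motif) for r in parsed.regions] == [
        (r.start, r.end, r.motif) for r in diagnosis.regions
    ]
    assert format_diagnosis_block(parsed) == text


@given(st.data())
@settings(max_examples=40, deadline=None)
def test_strict_set_monotone_in_background(data):
    L = data.draw(st.integers(2, 12))
    row = lambda: data.draw(st.text(alphabet="ACGT-", min_size=L, max_size=L))
    rows = {"f1": row(), "f2": row(), "b1": row()}
    extra = row()
    aln = make_alignment(rows)
    smap = make_map({"f1": "X", "f2": "X", "b1": "Y"})
    before = compute_strict_diagnostic_columns(aln, smap, "X")
    bigger = make_alignment({**rows, "b2": extra})
    bigger_map = make_map({**smap.assignments, "b2": "Y"})
    after = compute_strict_diagnostic_columns(bigger, bigger_map, "X")
    assert set(after) <= set(before)


def test_profiles_yaml_round_trip():
    d = Diagnosis("X", (Region(5, 8, "ACGT", frozenset({6, 7})),))
    back = profiles_from_yaml(profiles_to_yaml([d]))
    assert back[0].species == "X"
    assert back[0].regions == d.regions
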