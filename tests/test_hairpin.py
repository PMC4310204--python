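"""Sequence/structure model: parsing, annotation, interception."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from miplantpremat.hairpin import (
    DotBracketError,
    HairpinRecord,
    InvalidSequenceError,
    MatureAnnotation,
    RnaSequence,
    SecondaryStructure,
    annotate,
    fold,
    intercept,
    is_single_stem_loop,
    parse_dotbracket,
    read_dotbracket_file,
    read_fasta,
    read_mature_tsv,
    render_dotbracket,
    shift_annotation,
    window_mismatches,
    write_dotbracket_file,
    write_fasta,
    write_mature_tsv,
)


class TestRnaSequence:
    def test_transcribes_dna_on_read(self):
        assert RnaSequence.from_string("x", "acgt").residues == "ACGU"

    @pytest.mark.parametrize("bad", ["ACGN", "", "ACGX"])
    def test_rejects_invalid_residues(self, bad):
        with pytest.raises(InvalidSequenceError):
            RnaSequence(id="x", residues=bad)


class TestParseDotbracket:
    @pytest.mark.parametrize(
        "db,expected",
        [
            ("((..))", {(0, 5), (1, 4)}),
            ("((((....))))", {(0, 11), (1, 10), (2, 9), (3, 8)}),
            ("....", set()),
        ],
    )
    def test_examples(self, db, expected):
        assert parse_dotbracket(db) == expected

    def test_unclosed_bracket_reports_index(self):
        with pytest.raises(DotBracketError) as err:
            parse_dotbracket("(()")
        assert err.value.index == 0

    def test_unmatched_close_reports_index(self):
        with pytest.raises(DotBracketError) as err:
            parse_dotbracket(".))")
        assert err.value.index == 1

    @given(st.integers(0, 400))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_random_balanced(self, seed):
        """parse(render(pairs)) recovers any nested pair set."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        # build a random nested pair set by recursive interval splitting
        pairs = set()

        def build(lo, hi):
            while hi - lo >= 2 and rng.random() < 0.7:
                j = int(rng.integers(lo + 1, hi))
                pairs.add((lo, j))
                build(lo + 1, j)
                lo = j + 1

        build(0, n)
        db = render_dotbracket(pairs, n)
        assert parse_dotbracket(db) == pairs


class TestAnnotate:
    def test_perfect_stem(self):
        ann = annotate(SecondaryStructure("((((....))))", -5.0))
        assert (ann.n_stems, ann.n_loops, ann.tot_base_pairs) == (1, 1, 4)

    def test_bulge_breaks_stack(self):
        ann = annotate(SecondaryStructure("((.((...)).))", -3.0))
        assert (ann.n_stems, ann.n_loops, ann.tot_base_pairs) == (2, 1, 4)

    def test_unpaired_structure(self):
        ann = annotate(SecondaryStructure("........", 0.0))
        assert (ann.n_stems, ann.n_loops) == (0, 0)

    def test_stem_lengths_sum_to_pairs(self, bulged_hairpin):
        ann = bulged_hairpin.annotation
        assert sum(len(s) for s in ann.stems) == ann.tot_base_pairs

    def test_loops_present_whenever_paired(self):
        for db in ["(...)", "((..))..", "((...))((...))", "((.((...)).))"]:
            ann = annotate(SecondaryStructure(db, -1.0))
            assert ann.n_loops >= 1
            assert sum(len(s) for s in ann.stems) == ann.tot_base_pairs

    def test_stem_positions_exclude_loop(self, perfect_hairpin):
        stem = perfect_hairpin.annotation.stem_positions()
        loop = perfect_hairpin.annotation.loop_spans[0]
        assert all(not (loop[0] <= p < loop[1]) for p in stem)


class TestSingleStemLoop:
    @pytest.mark.parametrize(
        "db,expected",
        [
            ("((((...))))", True),
            ("((...))((...))", False),
            ("......", False),
            ("((.((...)).))", True),
        ],
    )
    def test_examples(self, db, expected):
        assert is_single_stem_loop(annotate(SecondaryStructure(db, -1.0))) is expected


class TestFold:
    def test_homopolymer_folds_open(self):
        st_ = fold(RnaSequence("a", "AAAAAAAA"))
        assert st_.dotbracket == "........"
        assert st_.mfe == 0.0

    def test_gc_hairpin_pairs(self):
        st_ = fold(RnaSequence("h", "GGGGGAAAACCCCC"))
        assert len(parse_dotbracket(st_.dotbracket)) >= 4
        assert st_.mfe < 0

    def test_deterministic(self):
        seq = RnaSequence("d", "GCGCGAUAGCUAGCUAGCUACGCGC")
        a = fold(seq, with_partition=True)
        b = fold(seq, with_partition=True)
        assert a.dotbracket == b.dotbracket
        assert a.mfe == b.mfe
        assert a.ensemble_free_energy == b.ensemble_free_energy

    def test_partition_quantities_present(self):
        st_ = fold(RnaSequence("p", "GGGGGAAAACCCCC"), with_partition=True)
        assert st_.ensemble_free_energy is not None
        assert 0 < st_.mfe_frequency <= 1
        assert st_.ensemble_free_energy <= st_.mfe + 1e-6


class TestIntercept:
    def _record(self, L=100):
        # long perfect inverted repeat folds reliably into one stem-loop
        arm = "GCGAUCGAUGGCAUCGAUCGGAUCGAUGCAUGCAUCGAUGCCGAUA"[: (L - 8) // 2]
        from miplantpremat.hairpin import reverse_complement

        seq = arm + "GAAAAAAC"[: L - 2 * len(arm)] + reverse_complement(arm)
        return HairpinRecord.from_sequence(RnaSequence("r", seq))

    def test_interval_arithmetic(self):
        rec = self._record(100)
        ann = MatureAnnotation("r", mir_interval=(70, 90), star_interval=(5, 25))
        out = intercept(rec, ann)
        assert len(out) == 85
        assert out.sequence.residues == rec.sequence.residues[5:90]

    def test_idempotent(self):
        rec = self._record(100)
        ann = MatureAnnotation("r", mir_interval=(70, 90), star_interval=(5, 25))
        once = intercept(rec, ann)
        twice = intercept(once, shift_annotation(ann))
        assert twice.sequence.residues == once.sequence.residues

    def test_never_lengthens(self):
        rec = self._record(100)
        ann = MatureAnnotation("r", mir_interval=(70, 90), star_interval=(5, 25))
        assert len(intercept(rec, ann)) <= len(rec)

    def test_requires_star(self):
        rec = self._record(100)
        ann = MatureAnnotation("r", mir_interval=(70, 90))
        with pytest.raises(ValueError, match="miRNA\\*"):
            intercept(rec, ann)

    def test_same_arm_rejected(self):
        rec = self._record(100)
        ann = MatureAnnotation("r", mir_interval=(60, 80), star_interval=(82, 98))
        with pytest.raises(ValueError, match="opposite arms"):
            intercept(rec, ann)

    def test_overlap_rejected_at_construction(self):
        with pytest.raises(ValueError, match="overlap"):
            MatureAnnotation("r", mir_interval=(10, 30), star_interval=(25, 45))


class TestWindowMismatches:
    def test_fully_paired_window(self, perfect_hairpin):
        assert window_mismatches(perfect_hairpin, (0, 5)) == 0

    def test_bulge_counted(self):
        rec = HairpinRecord.from_structure(
            RnaSequence("b", "GGCGGAAACCACC"), SecondaryStructure("((.((...)).))", -3.0)
        )
        assert window_mismatches(rec, (0, 5)) == 1

    def test_loop_window_all_unpaired(self, perfect_hairpin):
        loop = perfect_hairpin.annotation.loop_spans[0]
        assert window_mismatches(perfect_hairpin, loop) == loop[1] - loop[0]

    def test_out_of_bounds(self, perfect_hairpin):
        with pytest.raises(IndexError):
            window_mismatches(perfect_hairpin, (0, len(perfect_hairpin) + 1))


class TestIO:
    def test_fasta_round_trip(self, tmp_path):
        records = [RnaSequence("a", "ACGU"), RnaSequence("b", "GGCC" * 30)]
        path = tmp_path / "x.fasta"
        write_fasta(records, str(path))
        back = read_fasta(str(path))
        assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in records]

    def test_fasta_transcribes_t(self, tmp_path):
        path = tmp_path / "t.fasta"
        path.write_text(">d\nACGT\n")
        assert read_fasta(str(path))[0].residues == "ACGU"

    def test_dotbracket_round_trip(self, tmp_path, perfect_hairpin):
        path = tmp_path / "x.db"
        write_dotbracket_file([perfect_hairpin], path)
        back = read_dotbracket_file(path)
        assert back[0].structure.dotbracket == perfect_hairpin.structure.dotbracket
        assert back[0].structure.mfe == perfect_hairpin.structure.mfe

    def test_mature_tsv_converts_coordinates(self, tmp_path):
        ann = MatureAnnotation("p1", mir_interval=(70, 90), star_interval=(5, 25), arm="3p")
        path = tmp_path / "m.tsv"
        write_mature_tsv([ann], path)
        back = read_mature_tsv(path)
        assert back[0].mir_interval == (70, 90)
        assert back[0].star_interval == (5, 25)
        # external representation is 1-based inclusive
        text = path.read_text().splitlines()
        assert text[1].split("\t")[1] == "71"
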