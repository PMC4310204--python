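"""Feature catalog structure, per-group values, scaling, shuffles."""

import math

import numpy as np
import pandas as pd
import pytest
import random

from miplantpremat.features import (
    FEATURE_CATALOG,
    FEATURE_NAMES,
    GROUP_SIZES,
    FeatureConfig,
    FeatureScaler,
    apply_scaler,
    basepair_features,
    dinucleotide_shuffle,
    extract_all,
    fit_scaler,
    mfe_indices,
    rnafold_features,
    sequence_features,
    thermo_features,
    triplet_features,
)
from miplantpremat.hairpin import (
    HairpinRecord,
    RnaSequence,
    SecondaryStructure,
    reverse_complement,
)


class TestCatalog:
    def test_total_and_group_sizes(self):
        assert len(FEATURE_CATALOG) == 152
        for group, size in GROUP_SIZES.items():
            assert sum(1 for e in FEATURE_CATALOG if e.group == group) == size

    def test_novel_flags(self):
        novel = [e.name for e in FEATURE_CATALOG if e.novel]
        assert len(novel) == 69
        for name in ("MFEI7", "MFEI8", "MFEI9", "Mis_num_begin", "Mis_num_end"):
            assert name in novel
        assert sum(1 for n in novel if "_begin_S" in n or "_end_S" in n) == 64

    def test_names_unique_and_ordered(self):
        assert len(set(FEATURE_NAMES)) == 152
        groups = [e.group for e in FEATURE_CATALOG]
        # catalog keeps the six groups contiguous, in table order
        seen = []
        for g in groups:
            if not seen or seen[-1] != g:
                seen.append(g)
        assert seen == [
            "MFE-related", "Sequence-related", "Mfold-related",
            "BasePair-related", "Triple-related", "RNAfold-related",
        ]


class TestTripletFeatures:
    def test_manual_enumeration(self):
        rec = HairpinRecord.from_structure(
            RnaSequence("x", "GGGAAACCC"), SecondaryStructure("(((...)))", -1.0)
        )
        block = triplet_features(rec, "whole_stem")
        names = [f"{x}{p}" for x in "ACGU" for p in (
            "(((", "((.", "(.(", "(..", ".((", ".(.", "..(", "...")]
        nz = {n: v for n, v in zip(names, block) if v}
        assert nz == {"G(((": 0.5, "C(((": 0.5}

    def test_unpaired_record_zero_block(self, unpaired_record):
        assert triplet_features(unpaired_record, "whole_stem").sum() == 0

    def test_normalisation(self, perfect_hairpin, bulged_hairpin):
        for rec in (perfect_hairpin, bulged_hairpin):
            for region in ("whole_stem", "begin21", "end21"):
                s = triplet_features(rec, region).sum()
                assert s == 0 or abs(s - 1) < 1e-12

    def test_whole_stem_invariant_under_mirroring(self, perfect_hairpin):
        """Swapping which arm is 5' leaves whole-stem triplets unchanged."""
        seq = perfect_hairpin.sequence.residues
        db = perfect_hairpin.structure.dotbracket
        mirrored = HairpinRecord.from_structure(
            RnaSequence("m", seq[::-1]),
            SecondaryStructure(db[::-1].translate(str.maketrans("()", ")(")), -15.0),
        )
        a = triplet_features(perfect_hairpin, "whole_stem")
        b = triplet_features(mirrored, "whole_stem")
        # same multiset of (center nt, pattern) categories up to window reversal;
        # pattern reversal maps each category onto another fixed category, so
        # total mass and the per-nucleotide marginals must agree
        assert a.sum() == b.sum()
        assert np.allclose(a.reshape(4, 8).sum(axis=1), b.reshape(4, 8).sum(axis=1))


class TestSequenceFeatures:
    def test_homopolymer_dinucleotides(self, unpaired_record):
        out = sequence_features(unpaired_record)
        assert out["%AA"] == 1.0
        assert sum(out[f"%{x}{y}"] for x in "ACGU" for y in "ACGU") == 1.0

    def test_dinucleotide_normalisation(self, bulged_hairpin):
        out = sequence_features(bulged_hairpin)
        total = sum(out[f"%{x}{y}"] for x in "ACGU" for y in "ACGU")
        assert abs(total - 1) < 1e-12

    def test_mismatch_counts(self):
        rec = HairpinRecord.from_structure(
            RnaSequence("b", "GGCGGAAACCACC"), SecondaryStructure("((.((...)).))", -3.0)
        )
        out = sequence_features(rec)
        # stem region has 13 - 3 (loop) = 10 positions, 2 unpaired (bulges)
        assert out["Mis_num_begin"] == 2  # whole stem is shorter than 21
        assert out["Avg_mis_num"] == 2  # one 21-nt window tiles the stem

    def test_mirroring_swaps_begin_end(self, bulged_hairpin):
        seq = bulged_hairpin.sequence.residues
        db = bulged_hairpin.structure.dotbracket
        mirrored = HairpinRecord.from_structure(
            RnaSequence("m", seq[::-1]),
            SecondaryStructure(db[::-1].translate(str.maketrans("()", ")(")), -6.0),
        )
        a = sequence_features(bulged_hairpin)
        b = sequence_features(mirrored)
        assert a["Mis_num_begin"] == b["Mis_num_end"]
        assert a["Mis_num_end"] == b["Mis_num_begin"]


class TestMfeIndices:
    def test_mfei1_arithmetic(self):
        # MFE -30, L 100, GC fraction 0.5 -> MFEI1 = -0.6
        seq = "GC" * 25 + "AU" * 25
        rec = HairpinRecord.from_structure(
            RnaSequence("m", seq), SecondaryStructure("." * 100, 0.0)
        )
        out = mfe_indices(rec)
        assert out["MFEI1"] == 0.0  # no pairs: mfe 0
        rec2 = HairpinRecord.from_structure(
            RnaSequence("m", seq[:48] + "GAAA" + reverse_complement(seq[:48])),
            SecondaryStructure("(" * 48 + "...." + ")" * 48, -30.0),
        )
        gc = sum(1 for c in rec2.sequence.residues if c in "GC") / 100
        assert math.isclose(out["MFEI1"], 0.0)
        assert math.isclose(mfe_indices(rec2)["MFEI1"], (-30.0 / 100) / gc)

    def test_guards_on_degenerate_input(self, unpaired_record):
        out = mfe_indices(unpaired_record)
        # zero stems/loops/pairs and zero mismatch rate all guard to 0
        for key in ("MFEI2", "MFEI3", "MFEI4", "MFEI5", "MFEI6", "MFEI9"):
            assert out[key] == 0.0

    def test_mfei9_zero_for_perfect_stem(self, perfect_hairpin):
        assert mfe_indices(perfect_hairpin)["MFEI9"] == 0.0


class TestBasepairFeatures:
    def test_constructed_fixture(self):
        # 3 A-U pairs + 2 G-C pairs, one stem, L = 16
        arm = "AAAGC"
        seq = arm + "AAAAAA" + reverse_complement(arm)
        db = "(((((......)))))"
        rec = HairpinRecord.from_structure(RnaSequence("f", seq), SecondaryStructure(db, -4.0))
        out = basepair_features(rec)
        assert out["|A-U|/L"] == 3 / 16 == 0.1875
        assert out["|G-C|/L"] == 2 / 16
        assert out["|G-U|/L"] == 0.0
        assert out["Avg_BP_Stem"] == 5.0
        assert out["%(A-U)/n_stems"] == 3 / 5

    def test_unpaired_all_zero(self, unpaired_record):
        assert all(v == 0 for v in basepair_features(unpaired_record).values())


class TestThermoFeatures:
    def test_identities_and_stability(self, folded_hairpin):
        rec, _ = folded_hairpin
        out = thermo_features(rec)
        assert math.isclose(out["dS/L"], out["dS"] / len(rec))
        assert math.isclose(out["dH/L"], out["dH"] / len(rec))
        assert out["Tm"] > 37.0  # a stable hairpin melts above folding temp

    def test_unpaired_guard(self, unpaired_record):
        out = thermo_features(unpaired_record)
        assert out == {"dS": 0.0, "dS/L": 0.0, "dH": 0.0, "dH/L": 0.0, "Tm": 0.0, "Tm/L": 0.0}


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self):
        rng = random.Random(0)
        seq = "GGGAUCCAUGCAUGGAUCGAUCGGGCAUCGAUGCAUCGAUCC"
        from collections import Counter

        orig = Counter(zip(seq, seq[1:]))
        for _ in range(20):
            shuf = dinucleotide_shuffle(seq, rng)
            assert Counter(zip(shuf, shuf[1:])) == orig
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_actually_shuffles(self):
        rng = random.Random(1)
        seq = "GGGAUCCAUGCAUGGAUCGAUCGGGCAUCGAUGCAUCGAUCC"
        assert any(dinucleotide_shuffle(seq, rng) != seq for _ in range(10))


class TestRnafoldFeatures:
    def test_d_values(self, folded_hairpin):
        rec, _ = folded_hairpin
        out = rnafold_features(rec, shuffles=5, seed=0)
        ann = rec.annotation
        assert math.isclose(out["dP"], ann.tot_base_pairs / len(rec))
        assert math.isclose(out["dG"], rec.structure.mfe / len(rec))
        assert out["Diff"] >= 0
        # a designed inverted repeat folds much more stably than its shuffles
        assert out["zG"] < 0

    def test_shuffle_count_validated(self, folded_hairpin):
        rec, _ = folded_hairpin
        with pytest.raises(ValueError, match="at least 2 shuffles"):
            rnafold_features(rec, shuffles=1)

    def test_zero_variance_guard_on_homopolymer(self):
        rec = HairpinRecord.from_sequence(
            RnaSequence("homo", "A" * 40), with_partition=True
        )
        out = rnafold_features(rec, shuffles=4, seed=0)
        for k in ("zP", "zG", "zD", "zQ", "zF"):
            assert out[k] == 0.0


class TestExtractAll:
    def test_full_vector(self, folded_hairpin):
        rec, _ = folded_hairpin
        vec = extract_all(rec, FeatureConfig(shuffles=4, seed=0))
        assert vec.values.shape == (152,)
        assert np.all(np.isfinite(vec.values))

    def test_deterministic(self, folded_hairpin):
        rec, _ = folded_hairpin
        cfg = FeatureConfig(shuffles=4, seed=7)
        a = extract_all(rec, cfg)
        b = extract_all(rec, cfg)
        assert np.array_equal(a.values, b.values)


class TestScaler:
    def test_basic_mapping(self):
        M = np.array([[0.0], [5.0], [10.0]])
        sc = fit_scaler(M)
        assert np.allclose(sc.transform(M).ravel(), [-1, 0, 1])

    def test_constant_column_maps_to_zero(self):
        M = np.array([[3.0, 1.0], [3.0, 2.0]])
        out = fit_scaler(M).transform(M)
        assert np.all(out[:, 0] == 0)

    def test_train_extrema_hit_bounds(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(20, 5))
        out = fit_scaler(M).transform(M)
        assert np.allclose(out.min(axis=0), -1)
        assert np.allclose(out.max(axis=0), 1)

    def test_no_clipping_outside_train_range(self):
        sc = fit_scaler(np.array([[0.0], [1.0]]))
        assert sc.transform(np.array([[2.0]]))[0, 0] == 3.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_scaler(np.empty((0, 3)))

    def test_json_round_trip(self, tmp_path):
        M = pd.DataFrame({"a": [0.0, 2.0], "b": [1.0, 5.0]})
        sc = fit_scaler(M)
        sc.to_json(tmp_path / "s.json")
        back = FeatureScaler.from_json(tmp_path / "s.json")
        assert np.allclose(back.min_, sc.min_) and np.allclose(back.max_, sc.max_)
        assert np.allclose(
            apply_scaler(back, M).to_numpy(), apply_scaler(sc, M).to_numpy()
        )
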