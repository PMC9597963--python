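"""Sequence feature extraction: k-mers, poly-T, positional encodings, schema."""

import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crisprboost as cb
from crisprboost.features import DI_LABELS, MONO_LABELS, SCHEMA
from crisprboost.targets import ExpandedTarget
from tests.conftest import SEQ_A, SEQ_B


def _target(seq):
    """Bypass PAM validation for synthetic unit-test sequences."""
    return ExpandedTarget(seq)


def _stub_thermo():
    return cb.ThermoFeatures(50.0, 10.0, 30.0, 20.0, -1.0, -20.0)


random_targets = st.integers(0, 2**31 - 1).map(
    lambda s: cb.random_target(np.random.default_rng(s))
)


class TestKmerCounts:
    def test_homopolymer(self):
        counts = cb.kmer_counts(_target("A" * 30), 1)
        assert counts.tolist() == [30, 0, 0, 0]

    def test_worked_sequence_direct_count(self):
        t = cb.validate_target(SEQ_A)
        c1 = dict(zip("ACGT", cb.kmer_counts(t, 1)))
        assert c1["T"] == 9
        assert c1["G"] + c1["C"] == 16

    def test_overlapping_windows(self):
        t = _target("TTTAAA" + "C" * 24)
        di = dict(zip(cb.features.DINUCLEOTIDES, cb.kmer_counts(t, 2)))
        assert di["TT"] == 2  # TTT holds two overlapping TT windows

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            cb.kmer_counts(_target("A" * 30), 4)

    @given(random_targets)
    @settings(max_examples=200, deadline=None)
    def test_counts_sum_to_window_count(self, t):
        for k in (1, 2, 3):
            assert cb.kmer_counts(t, k).sum() == 30 - k + 1

    @given(random_targets)
    @settings(max_examples=100, deadline=None)
    def test_proportions_flag_normalises(self, t):
        assert cb.kmer_counts(t, 2, proportions=True).sum() == pytest.approx(1.0)

    @given(random_targets)
    @settings(max_examples=100, deadline=None)
    def test_reversal_keeps_k1_multiset(self, t):
        rev = _target(t.sequence[::-1])
        assert np.array_equal(cb.kmer_counts(t, 1), cb.kmer_counts(rev, 1))


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("G" * 30, 1.0), ("A" * 30, 0.0), (SEQ_A, 16 / 30)]
    )
    def test_examples(self, seq, expected):
        assert cb.gc_content(_target(seq)) == pytest.approx(expected)

    @given(random_targets)
    @settings(max_examples=100, deadline=None)
    def test_consistent_with_k1_counts(self, t):
        c = dict(zip("ACGT", cb.kmer_counts(t, 1)))
        assert cb.gc_content(t) * 30 == pytest.approx(c["G"] + c["C"])


class TestPolyT:
    def test_worked_sequence(self):
        assert cb.polyt_features(cb.validate_target(SEQ_A)) == (0, 1)

    def test_single_run_of_four(self):
        assert cb.polyt_features(_target("GTTTTG" + "A" * 24)) == (1, 4)

    def test_two_disjoint_runs(self):
        assert cb.polyt_features(_target("TTTATTTA" + "C" * 22)) == (2, 3)

    def test_min_run_flag_zeroes_short_runs(self):
        t = _target("GTGC" + "A" * 26)
        assert cb.polyt_features(t) == (0, 1)
        assert cb.polyt_features(t, min_run_for_max=3) == (0, 0)

    def test_exhaustive_length8_against_regex_oracle(self):
        # All 4^8 sequences of length 8, padded to 30 with C (never T,
        # so the pad cannot create or extend a run).
        for combo in itertools.product("ACGT", repeat=8):
            seq = "".join(combo) + "C" * 22
            runs = [len(m.group()) for m in re.finditer(r"T+", seq)]
            expected = (sum(1 for r in runs if r >= 3), max(runs, default=0))
            assert cb.polyt_features(_target(seq)) == expected


class TestPositionalFeatures:
    def test_mono_worked_sequence(self):
        mono = cb.positional_mononucleotides(cb.validate_target(SEQ_A))
        assert mono["-4"] == "G"
        assert mono["1"] == "G"
        assert mono["21"] == "T"

    def test_mono_second_worked_sequence(self):
        mono = cb.positional_mononucleotides(cb.validate_target(SEQ_B))
        assert mono["+1"] == "G"

    def test_static_pam_positions_absent(self):
        mono = cb.positional_mononucleotides(cb.validate_target(SEQ_A))
        assert "22" not in mono and "23" not in mono
        assert len(mono) == 28
        di = cb.positional_dinucleotides(cb.validate_target(SEQ_A))
        assert "22" not in di
        assert len(di) == 28

    def test_di_worked_sequences(self):
        di_a = cb.positional_dinucleotides(cb.validate_target(SEQ_A))
        di_b = cb.positional_dinucleotides(cb.validate_target(SEQ_B))
        assert (di_a["19"], di_b["19"]) == ("GA", "AT")
        assert (di_a["18"], di_b["18"]) == ("TG", "AA")
        assert di_a["20"] == "AT"  # spacer end + PAM 'N'

    @given(random_targets)
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_substring_oracle(self, t):
        from crisprboost.targets import LABEL_TO_OFFSET

        mono = cb.positional_mononucleotides(t)
        di = cb.positional_dinucleotides(t)
        for lab, base in mono.items():
            assert base == t.sequence[LABEL_TO_OFFSET[lab]]
        for lab, pair in di.items():
            i = LABEL_TO_OFFSET[lab]
            assert pair == t.sequence[i : i + 2]

    @given(random_targets)
    @settings(max_examples=50, deadline=None)
    def test_reversal_changes_positions_not_k1_counts(self, t):
        rev = _target(t.sequence[::-1])
        if t.sequence != rev.sequence:
            assert cb.positional_mononucleotides(t) != cb.positional_mononucleotides(rev) or \
                cb.positional_dinucleotides(t) != cb.positional_dinucleotides(rev)
        assert np.array_equal(cb.kmer_counts(t, 1), cb.kmer_counts(rev, 1))


class TestFeaturize:
    def test_width_and_split(self):
        row = cb.featurize(cb.validate_target(SEQ_A), _stub_thermo())
        assert len(row) == 149
        assert len(SCHEMA.numeric) == 93
        assert len(SCHEMA.categorical) == 56
        assert len(MONO_LABELS) == 28 and len(DI_LABELS) == 28

    def test_kmer_block_widths(self):
        names = set(SCHEMA.numeric)
        for k, width in ((1, 4), (2, 16), (3, 64)):
            kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
            assert len(kmers) == width
            assert names.issuperset(kmers)

    def test_deterministic(self):
        a = cb.featurize(cb.validate_target(SEQ_A), _stub_thermo())
        b = cb.featurize(cb.validate_target(SEQ_A), _stub_thermo())
        assert a == b

    def test_frame_has_fixed_categorical_vocabularies(self):
        t = cb.validate_target(SEQ_A)
        frame = cb.featurize_frame([t], [_stub_thermo()])
        assert frame.shape == (1, 149)
        assert list(frame["di19"].cat.categories) == list(cb.features.DINUCLEOTIDES)
        assert frame["di19"].iloc[0] == "GA"

    def test_schema_json_round_trip(self):
        restored = cb.FeatureSchema.from_json(SCHEMA.to_json())
        assert restored == SCHEMA
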