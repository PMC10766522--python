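"""Incorporation/extraction, screening metrics and segment pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yycodec.rules import BASES, REFERENCE_SCHEME, scheme_by_id
from yycodec.transcode import (
    ScreenPolicy,
    extract_segments,
    gc_content,
    incorporate_segments,
    max_homopolymer_run,
    pair_and_encode_pool,
    screen_sequence,
    stem_energy_estimate,
)

A_SEG, B_SEG = "10110011", "01011101"


def _incorporate_oracle(a: str, b: str, scheme) -> str:
    """Stepwise set-intersection oracle, independent of the encode LUT."""
    out = []
    prev = scheme.virtual_prev
    for ai, bi in zip(a, b):
        hits = [
            base
            for base in BASES
            if scheme.yang.bit_of(base) == int(ai)
            and scheme.yin.bit_of(prev, base) == int(bi)
        ]
        assert len(hits) == 1
        out.append(hits[0])
        prev = hits[0]
    return "".join(out)


class TestIncorporation:
    def test_worked_example_first_base_is_G(self):
        assert incorporate_segments(A_SEG, B_SEG, REFERENCE_SCHEME)[0] == "G"

    def test_worked_example_full_sequence(self):
        """Regression fixture computed once with the stepwise oracle."""
        seq = incorporate_segments(A_SEG, B_SEG, REFERENCE_SCHEME)
        assert seq == "GTGCTTGC"
        assert seq == _incorporate_oracle(A_SEG, B_SEG, REFERENCE_SCHEME)

    def test_oracle_agreement_across_schemes(self, rng):
        for scheme_id in (1, 100, 598, 888, 1536):
            scheme = scheme_by_id(scheme_id)
            a = "".join(rng.choice(["0", "1"], size=24))
            b = "".join(rng.choice(["0", "1"], size=24))
            assert incorporate_segments(a, b, scheme) == _incorporate_oracle(
                a, b, scheme
            )

    def test_swapping_segments_changes_the_sequence(self):
        assert incorporate_segments(
            A_SEG, B_SEG, REFERENCE_SCHEME
        ) != incorporate_segments(B_SEG, A_SEG, REFERENCE_SCHEME)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            incorporate_segments("101", "01", REFERENCE_SCHEME)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            extract_segments("", REFERENCE_SCHEME)
        with pytest.raises(ValueError):
            incorporate_segments("", "", REFERENCE_SCHEME)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            extract_segments("ACGN", REFERENCE_SCHEME)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        data=st.data(),
        scheme_id=st.integers(min_value=1, max_value=1536),
        length=st.integers(min_value=1, max_value=160),
    )
    def test_roundtrip_property(self, data, scheme_id, length):
        """extract(incorporate(a, b)) == (a, b) for any scheme and segments."""
        bits = st.text(alphabet="01", min_size=length, max_size=length)
        a = data.draw(bits)
        b = data.draw(bits)
        scheme = scheme_by_id(scheme_id)
        assert extract_segments(incorporate_segments(a, b, scheme), scheme) == (a, b)

    def test_roundtrip_all_schemes_short(self, rng):
        a = "".join(rng.choice(["0", "1"], size=8))
        b = "".join(rng.choice(["0", "1"], size=8))
        for scheme_id in range(1, 1537):
            scheme = scheme_by_id(scheme_id)
            assert extract_segments(
                incorporate_segments(a, b, scheme), scheme
            ) == (a, b)

    def test_single_substitution_damages_at_most_three_bits(self, rng):
        """A substitution at position i corrupts bit i of both segments and
        possibly bit i+1 of the yin segment, nothing else."""
        a = "".join(rng.choice(["0", "1"], size=16))
        b = "".join(rng.choice(["0", "1"], size=16))
        seq = incorporate_segments(a, b, REFERENCE_SCHEME)
        for i in range(len(seq)):
            for repl in BASES:
                if repl == seq[i]:
                    continue
                mutated = seq[:i] + repl + seq[i + 1:]
                a2, b2 = extract_segments(mutated, REFERENCE_SCHEME)
                diff_a = [j for j in range(16) if a2[j] != a[j]]
                diff_b = [j for j in range(16) if b2[j] != b[j]]
                assert set(diff_a) <= {i}
                assert set(diff_b) <= {i, i + 1}
                assert diff_a or diff_b  # a real substitution corrupts something


class TestMetrics:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 50.0), ("GGCC", 100.0), ("ATAT", 0.0)]
    )
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == expected

    @pytest.mark.parametrize(
        "seq,expected", [("AAAAT", 4), ("ACGT", 1), ("TTTTTT", 6)]
    )
    def test_max_homopolymer_run(self, seq, expected):
        assert max_homopolymer_run(seq) == expected

    def test_metrics_reject_empty(self):
        with pytest.raises(ValueError):
            gc_content("")
        with pytest.raises(ValueError):
            max_homopolymer_run("")

    def test_stem_energy_flags_self_complementary(self):
        """A long inverted repeat folds into a stable hairpin; the estimate
        must fall below the -30 kcal/mol screen threshold."""
        stem = "ACGTACGGTCAGGCTATCAGCATGCAGG"
        rc = stem.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        hairpin = stem + "AAAA" + rc
        assert stem_energy_estimate(hairpin) < -30
        assert stem_energy_estimate("ATCGATGGCTACGTACGATC") > -30


class TestScreening:
    def test_homopolymer_rejection(self):
        seq = "ATGC" * 20 + "CCCCC" + "ATGC" * 18 + "ATG"
        ok, reason = screen_sequence(seq, ScreenPolicy(energy_estimator=None))
        assert not ok and reason == "homopolymer"

    def test_gc_rejection(self):
        seq = ("AT" * 56 + "GC" * 24)  # GC 30%
        ok, reason = screen_sequence(seq, ScreenPolicy(energy_estimator=None))
        assert not ok and reason == "gc"

    def test_accept_conforming_sequence(self):
        seq = "ATGC" * 40  # GC 50%, max run 1
        ok, reason = screen_sequence(seq, ScreenPolicy(energy_estimator=None))
        assert ok and reason is None

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            ScreenPolicy(gc_min=70, gc_max=60)
        with pytest.raises(ValueError):
            ScreenPolicy(max_homopolymer=0)


class TestPairing:
    def test_imbalanced_segment_routed_and_screened(self, rng):
        """A 90%-ones segment never takes a role that breaks the screen; the
        emitted sequences all pass the policy."""
        segs = [rng.integers(0, 2, size=160, dtype=np.uint8) for _ in range(9)]
        segs.append((rng.random(160) < 0.9).astype(np.uint8))
        policy = ScreenPolicy(energy_estimator=None)
        result = pair_and_encode_pool(segs, REFERENCE_SCHEME, policy, rng=3)
        for seq in result.sequences:
            ok, reason = screen_sequence(seq, policy)
            assert ok, reason
        # every input segment appears exactly once
        used = [p for pair in result.pairs for p in pair if p < result.n_input]
        assert sorted(used) == list(range(10))

    def test_sequence_count_without_fillers(self, rng):
        """n balanced segments, all pairings passing -> ceil(n/2) sequences."""
        segs = [rng.integers(0, 2, size=160, dtype=np.uint8) for _ in range(20)]
        result = pair_and_encode_pool(
            segs, REFERENCE_SCHEME, ScreenPolicy(energy_estimator=None), rng=5
        )
        used_fillers = sum(1 for pair in result.pairs for p in pair if p >= 20)
        assert len(result.sequences) == (20 + used_fillers) // 2
        assert len(result.sequences) >= 10

    def test_determinism_under_fixed_seed(self, rng):
        segs = [rng.integers(0, 2, size=160, dtype=np.uint8) for _ in range(15)]
        r1 = pair_and_encode_pool(segs, REFERENCE_SCHEME, rng=11)
        r2 = pair_and_encode_pool(segs, REFERENCE_SCHEME, rng=11)
        assert r1.sequences == r2.sequences
        assert r1.pairs == r2.pairs

    def test_output_length_equals_segment_length(self, rng):
        segs = [rng.integers(0, 2, size=64, dtype=np.uint8) for _ in range(4)]
        result = pair_and_encode_pool(
            segs, REFERENCE_SCHEME, ScreenPolicy(energy_estimator=None), rng=2
        )
        assert all(len(s) == 64 for s in result.sequences)
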