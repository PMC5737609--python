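"""Motif parsing, similarity scoring, scanning and enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpramars import (
    MotifParseError,
    PWMatrix,
    calibrate_minfn_cutoff,
    copy_number_range,
    enrichment_score,
    match_score,
    parse_motifs,
    scan,
    write_motifs,
)
from mpramars.motifs import ConfigurationError, enrichment_matrix, hits_to_bed

from _oracles import brute_force_scan, brute_force_window_score, revcomp

TRANSFAC_ONE = """\
ID ONEPOS
XX
P0      A      C      G      T
01     10      0      0      0      A
XX
//
"""


class TestParsing:
    def test_count_block_normalised_without_pseudocount(self):
        (m,) = parse_motifs(TRANSFAC_ONE, "transfac", pseudocount=0.0)
        assert m.matrix_id == "ONEPOS"
        assert m.length == 1
        np.testing.assert_allclose(m.freqs[0], [1, 0, 0, 0])

    def test_count_block_with_pseudocount_one(self):
        (m,) = parse_motifs(TRANSFAC_ONE, "transfac", pseudocount=1.0)
        np.testing.assert_allclose(m.freqs[0], [11 / 14, 1 / 14, 1 / 14, 1 / 14])

    def test_empty_input_gives_empty_list(self):
        assert parse_motifs("", "transfac") == []
        assert parse_motifs("", "jaspar") == []

    def test_malformed_row_names_line(self):
        bad = TRANSFAC_ONE.replace("01     10      0      0      0      A",
                                   "01     ten     0      0      0      A")
        with pytest.raises(MotifParseError, match="line 4"):
            parse_motifs(bad, "transfac")

    def test_short_row_names_line(self):
        bad = TRANSFAC_ONE.replace("01     10      0      0      0      A", "01  10  0")
        with pytest.raises(MotifParseError, match="line 4"):
            parse_motifs(bad, "transfac")

    @pytest.mark.parametrize("fmt", ["transfac", "jaspar"])
    def test_write_then_parse_round_trip(self, fmt):
        rng = np.random.default_rng(3)
        motifs = []
        for i in range(3):
            raw = rng.random((6, 4)) + 0.05
            motifs.append(PWMatrix(f"RT{i}", raw / raw.sum(axis=1, keepdims=True)))
        back = parse_motifs(write_motifs(motifs, fmt), fmt, pseudocount=0.0)
        assert [m.matrix_id for m in back] == [m.matrix_id for m in motifs]
        for a, b in zip(motifs, back):
            np.testing.assert_allclose(a.freqs, b.freqs, atol=1e-5)


class TestMatchScore:
    def test_consensus_scores_one_anticonsensus_zero(self, ac_pwm):
        assert match_score(ac_pwm, "AC") == pytest.approx(1.0)
        assert match_score(ac_pwm, "TG") == pytest.approx(0.0)

    def test_hand_computed_mixed_window(self, mixed_pwm):
        # independent position-by-position arithmetic
        expected = brute_force_window_score(mixed_pwm.freqs, mixed_pwm.info, "AGT")
        assert match_score(mixed_pwm, "AGT") == pytest.approx(expected, abs=1e-12)
        assert 0.0 < expected < 1.0

    def test_wrong_window_length_rejected(self, ac_pwm):
        with pytest.raises(ValueError, match="length"):
            match_score(ac_pwm, "ACG")

    def test_invariant_to_info_rescaling(self, mixed_pwm):
        scaled = PWMatrix("MIX2", mixed_pwm.freqs, info=mixed_pwm.info * 7.3)
        for window in ("AAA", "AGT", "CGT", "TCA"):
            assert match_score(mixed_pwm, window) == pytest.approx(
                match_score(scaled, window), abs=1e-12
            )

    def test_ambiguous_base_uses_mean_frequency(self, mixed_pwm):
        # an N at the uniform position changes nothing there
        assert match_score(mixed_pwm, "ANT") == pytest.approx(
            match_score(mixed_pwm, "AAT"), abs=1e-12
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_scores_bounded_on_random_windows(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.random((3, 4)) + 0.02
        pwm = PWMatrix("R", raw / raw.sum(axis=1, keepdims=True))
        window = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
        assert 0.0 <= match_score(pwm, window) <= 1.0


class TestScan:
    def test_planted_consensus_offsets(self, ac_pwm):
        hits = scan(ac_pwm, "ACGGACGGAC", 0.9)
        assert [(h.offset, h.strand) for h in hits] == [(0, "+"), (4, "+"), (8, "+")]

    def test_reverse_complement_hit(self, ac_pwm):
        hits = scan(ac_pwm, "GT", 0.9)
        assert [(h.offset, h.strand) for h in hits] == [(0, "-")]

    def test_no_hits_and_short_sequence(self, ac_pwm):
        assert scan(ac_pwm, "TTTT", 0.9) == []
        assert scan(ac_pwm, "A", 0.9) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_enumeration(self, seed, mixed_pwm):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=rng.integers(20, 200)))
        got = [(h.offset, h.strand, round(h.score, 9)) for h in scan(mixed_pwm, seq, 0.6)]
        expected = [
            (o, s, round(v, 9))
            for o, s, v in brute_force_scan(mixed_pwm.freqs, mixed_pwm.info, seq, 0.6)
        ]
        assert got == expected


class TestEnrichment:
    def test_zero_without_motif(self, ac_pwm):
        assert enrichment_score(ac_pwm, "TTTTTTTT") == 0.0

    def test_additive_over_planted_sites(self, ac_pwm):
        # four exact sites separated by anti-consensus spacers
        seq = "AC" + "TT" + "AC" + "TT" + "AC" + "TT" + "AC"
        # the spacers also create reverse-strand GT windows? no: revcomp(TT)=AA
        assert enrichment_score(ac_pwm, seq) == pytest.approx(4.0)

    def test_additive_over_nonmatching_spacer(self, mixed_pwm):
        pwm = PWMatrix("MIX", mixed_pwm.freqs, cutoff=0.8)
        rng = np.random.default_rng(0)
        s1 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40))
        s2 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40))
        spacer = "TCA"[0] * 0 + "TCT" * 2  # low-score filler longer than the motif
        joined = enrichment_score(pwm, s1 + spacer + s2)
        if all(
            brute_force_window_score(pwm.freqs, pwm.info, w) < 0.8
            and brute_force_window_score(pwm.freqs, pwm.info, revcomp(w)) < 0.8
            for w in [
                (s1 + spacer + s2)[i : i + 3]
                for i in range(len(s1) - 2, len(s1) + len(spacer))
            ]
        ):
            assert joined == pytest.approx(
                enrichment_score(pwm, s1) + enrichment_score(pwm, s2), abs=1e-9
            )

    @pytest.mark.parametrize("seed", range(4))
    def test_reverse_complement_symmetry(self, seed, mixed_pwm):
        pwm = PWMatrix("MIX", mixed_pwm.freqs, cutoff=0.7)
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
        assert enrichment_score(pwm, seq) == pytest.approx(
            enrichment_score(pwm, revcomp(seq)), abs=1e-9
        )

    def test_unset_cutoff_is_a_configuration_error(self, mixed_pwm):
        with pytest.raises(ConfigurationError):
            enrichment_score(mixed_pwm, "ACGTACGT")

    def test_matrix_agrees_with_scalar_path(self, ac_pwm, mixed_pwm):
        mixed = PWMatrix("MIX", mixed_pwm.freqs, cutoff=0.7)
        seqs = {"a": "ACGTACACGT", "b": "TTTTTTT", "c": "GTGTGT"}
        table = enrichment_matrix([ac_pwm, mixed], seqs)
        for sid, seq in seqs.items():
            assert table.loc[sid, "AC"] == pytest.approx(enrichment_score(ac_pwm, seq))
            assert table.loc[sid, "MIX"] == pytest.approx(enrichment_score(mixed, seq))

    def test_hits_to_bed_layout(self, ac_pwm):
        bed = hits_to_bed(scan(ac_pwm, "ACGGAC", 0.9, sequence_id="s"), {"AC": 2})
        assert list(bed.columns) == ["seq_id", "start", "end", "matrix_id", "score", "strand"]
        assert bed["end"].tolist() == [2, 6]


class TestMinFnCutoff:
    def test_deterministic_pwm_returns_one_minus_epsilon(self, ac_pwm):
        cutoff = calibrate_minfn_cutoff(ac_pwm, 0.05, 1000, seed=1)
        assert cutoff == pytest.approx(1.0, abs=1e-6)
        assert cutoff < 1.0

    def test_reproducible_for_same_seed(self, mixed_pwm):
        a = calibrate_minfn_cutoff(mixed_pwm, 0.05, 2000, seed=5)
        b = calibrate_minfn_cutoff(mixed_pwm, 0.05, 2000, seed=5)
        assert a == b

    def test_matches_independent_monte_carlo_quantile(self, mixed_pwm):
        # oracle: sample sites with an independent sampler, score one by one
        rng = np.random.default_rng(123)
        scores = []
        for _ in range(4000):
            window = "".join(
                "ACGT"[rng.choice(4, p=row)] for row in mixed_pwm.freqs
            )
            scores.append(brute_force_window_score(mixed_pwm.freqs, mixed_pwm.info, window))
        expected = float(np.quantile(scores, 0.05))
        got = calibrate_minfn_cutoff(mixed_pwm, 0.05, 10000, seed=9)
        assert got == pytest.approx(expected, abs=0.05)

    def test_fnr_bound_holds_on_model_sites(self, mixed_pwm):
        cutoff = calibrate_minfn_cutoff(mixed_pwm, 0.10, 10000, seed=2)
        rng = np.random.default_rng(77)
        passed = 0
        n = 2000
        for _ in range(n):
            window = "".join("ACGT"[rng.choice(4, p=row)] for row in mixed_pwm.freqs)
            if brute_force_window_score(mixed_pwm.freqs, mixed_pwm.info, window) >= cutoff:
                passed += 1
        assert passed / n >= 0.85  # >= 1 - target_fnr, with sampling slack


class TestCopyNumber:
    def test_total_39_at_stringent_cutoff_pins_four_sites(self):
        assert copy_number_range(3.9, 0.866) == [4]
        # three sites cannot reach 3.9; four sites span [3.464, 4.0]
        assert 3 * 1.0 < 3.9
        assert 4 * 0.866 <= 3.9 <= 4.0

    def test_zero_total_means_zero_sites(self):
        assert copy_number_range(0.0, 0.85) == [0]

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.integers(1, 6),
        st.floats(0.7, 0.99),
        st.integers(0, 10_000),
    )
    def test_any_realisable_total_is_declared_feasible(self, k, cutoff, seed):
        rng = np.random.default_rng(seed)
        total = float(rng.uniform(cutoff, 1.0, size=k).sum())
        assert k in copy_number_range(total, cutoff)
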