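"""Affinity-model unit and property tests: PWM loading, window scoring,
and the sliding-window maximum against a brute-force oracle."""

import math

import numpy as np
import pytest

import tatasel as ts
from tatasel.affinity import AffinityInputError, PwmFormatError

from conftest import brute_force_affinity, random_promoter


class TestLoadPwm:
    def test_uniform_counts_give_flat_rows(self, tmp_path):
        path = tmp_path / "uniform.tsv"
        path.write_text("\n".join("10\t10\t10\t10" for _ in range(15)) + "\n")
        pwm = ts.load_pwm(path)
        assert pwm.length == 15
        for row in pwm.weights:
            assert np.allclose(row, row[0])

    def test_packaged_matrix_argmax_spells_tata_consensus(self, model):
        pwm, _, _ = model
        allowed = ["T", "A", "T", "A", "AT", "A", "AT", "AG"]
        consensus = pwm.consensus()
        for i, bases in enumerate(allowed):
            assert consensus[i] in bases, f"core row {i + 1}"

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("10\t10\t10\t10\n5\t5\t5\n10\t10\t10\t10\n")
        with pytest.raises(PwmFormatError, match="line 2"):
            ts.load_pwm(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("\n".join(["10\t10\t10\t10"] * 4)
                        + "\n10\tx\t10\t10\n")
        with pytest.raises(PwmFormatError, match="non-numeric"):
            ts.load_pwm(path)

    def test_too_short_matrix_rejected(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("10\t10\t10\t10\n" * 3)
        with pytest.raises(PwmFormatError):
            ts.load_pwm(path)


class TestWindowScore:
    def test_zero_weights_reduce_to_baseline(self, model):
        pwm, scales, _ = model
        params = ts.AffinityModelParams(w0=7.5, w_pwm=0, w_ta=0, w_mg=0,
                                        w_melt=0)
        assert ts.window_score("TATAAAAGGCGGGGC", pwm, scales,
                               params) == pytest.approx(7.5)

    def test_consensus_beats_its_shuffle(self, model):
        pwm, scales, params = model
        good = ts.window_score("TATAAAAGGCGGGGC", pwm, scales, params)
        shuffled = ts.window_score("GGTGAGAACGATGCA", pwm, scales, params)
        assert good > shuffled

    def test_explain_terms_sum_to_total(self, model):
        pwm, scales, params = model
        total, terms = ts.window_score("TATAAAAGGCGGGGC", pwm, scales,
                                       params, explain=True)
        assert total == pytest.approx(sum(terms.values()))

    def test_wrong_length_and_alphabet_rejected(self, model):
        pwm, scales, params = model
        with pytest.raises(AffinityInputError):
            ts.window_score("TATA", pwm, scales, params)
        with pytest.raises(AffinityInputError):
            ts.window_score("TATAAAAGGCGGGGN", pwm, scales, params)


class TestEstimateAffinity:
    def test_homopolymer_scan_is_flat(self, model):
        pwm, scales, params = model
        seq = ts.PromoterSequence("POLYA", "A" * 70)
        est = ts.estimate_affinity(seq, pwm, scales, params)
        assert est.stderr == 0.0
        assert est.best_offset == -70
        assert est.best_strand == "+"

    def test_too_short_sequence_rejected(self, model):
        pwm, scales, params = model
        with pytest.raises(AffinityInputError):
            ts.estimate_affinity(ts.PromoterSequence("X", "ACGT" * 3),
                                 pwm, scales, params)

    def test_matches_brute_force_oracle(self, model, rng):
        pwm, scales, params = model
        for _ in range(100):
            seq = random_promoter(rng)
            est = ts.estimate_affinity(ts.PromoterSequence("R", seq),
                                       pwm, scales, params)
            value, start, strand = brute_force_affinity(seq, pwm, scales,
                                                        params)
            assert est.value == pytest.approx(value, abs=1e-12)
            assert est.best_offset == start - 70
            assert est.best_strand == strand

    def test_strand_symmetry(self, model, rng):
        pwm, scales, params = model
        for _ in range(20):
            seq = random_promoter(rng)
            fwd = ts.estimate_affinity(ts.PromoterSequence("F", seq),
                                       pwm, scales, params)
            rev = ts.estimate_affinity(
                ts.PromoterSequence("R", ts.reverse_complement(seq)),
                pwm, scales, params)
            assert fwd.value == pytest.approx(rev.value, abs=1e-12)

    def test_consensus_substitution_in_best_window_never_lowers_value(
            self, model, rng):
        pwm, scales, params = model
        argmax = pwm.consensus()
        for _ in range(20):
            seq = random_promoter(rng)
            prom = ts.PromoterSequence("M", seq)
            est = ts.estimate_affinity(prom, pwm, scales, params)
            start = est.best_offset + 70
            window = (seq[start:start + params.L] if est.best_strand == "+"
                      else ts.reverse_complement(seq)[70 - params.L - start:
                                                      70 - start])
            for j in range(params.L):
                if window[j] == argmax[j]:
                    continue
                improved = window[:j] + argmax[j] + window[j + 1:]
                if est.best_strand == "-":
                    improved_seq = (seq[:start]
                                    + ts.reverse_complement(improved)
                                    + seq[start + params.L:])
                else:
                    improved_seq = (seq[:start] + improved
                                    + seq[start + params.L:])
                est2 = ts.estimate_affinity(
                    ts.PromoterSequence("M", improved_seq), pwm, scales,
                    params)
                assert est2.value >= est.value - 1e-12

    def test_planting_consensus_raises_value(self, model):
        """Planting the consensus box overwhelmingly raises the affinity
        estimate over the same bare background (it can lose only when the
        overwritten stretch happened to carry an even stronger chance
        site)."""
        pwm, scales, params = model
        box = ts.affinity.TATA_CONSENSUS
        wins, diffs = 0, []
        for seed in range(50):
            r = np.random.default_rng(seed)
            seq = random_promoter(r)
            planted = seq[:40] + box + seq[48:]
            bare = ts.estimate_affinity(ts.PromoterSequence("B", seq),
                                        pwm, scales, params)
            with_box = ts.estimate_affinity(
                ts.PromoterSequence("P", planted), pwm, scales, params)
            wins += with_box.value > bare.value
            diffs.append(with_box.value - bare.value)
        assert wins >= 45
        assert np.mean(diffs) > 3.0

    def test_determinism(self, model):
        pwm, scales, params = model
        seq = ts.PromoterSequence("D", random_promoter(
            np.random.default_rng(3)))
        a = ts.estimate_affinity(seq, pwm, scales, params)
        b = ts.estimate_affinity(seq, pwm, scales, params)
        assert a == b

    def test_stderr_positive_on_nondegenerate_promoter(self, model, rng):
        pwm, scales, params = model
        seq = ts.PromoterSequence("S", random_promoter(rng))
        est = ts.estimate_affinity(seq, pwm, scales, params)
        assert est.stderr > 0


def test_offset_index_round_trip():
    seq = ts.PromoterSequence("G", "A" * 70)
    assert seq.offset_to_index(-70) == 0
    assert seq.offset_to_index(-1) == 69
    assert seq.index_to_offset(40) == -30
    with pytest.raises(AffinityInputError):
        seq.offset_to_index(0)


def test_ambiguity_codes_rejected():
    with pytest.raises(AffinityInputError):
        ts.PromoterSequence("N", "ACGTN" * 14)
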