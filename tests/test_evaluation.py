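"""Integer codes, edit-script coding, bitscore, matching, and P/R/F."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoflow.evaluation import (
    MatchPair,
    MatchReport,
    Transcript,
    bitscore,
    edit_code_length,
    edit_script,
    edits_encoded_bits,
    f_bij,
    gamma,
    gamma_len,
    match,
    pair_cost,
    prf,
    read_transcripts,
    write_transcripts,
)

from oracles import brute_force_matching_cost, reference_edit_distance

dna = st.text(alphabet="ACGT", max_size=40)


class TestGamma:
    @pytest.mark.parametrize("x,code", [(1, "1"), (2, "010"), (5, "00101")])
    def test_known_codes(self, x, code):
        assert gamma(x) == code

    def test_length_formula(self):
        for x in range(1, 1001):
            assert len(gamma(x)) == gamma_len(x) == 2 * int(np.log2(x)) + 1

    def test_prefix_free_up_to_1000(self):
        codes = sorted(gamma(x) for x in range(1, 1001))
        assert not any(
            b.startswith(a) for a, b in zip(codes, codes[1:])
        )

    def test_rejects_nonpositive(self):
        for bad in (0, -3):
            with pytest.raises(ValueError):
                gamma(bad)
            with pytest.raises(ValueError):
                gamma_len(bad)


class TestFBij:
    @pytest.mark.parametrize("x,y", [(0, 1), (3, 6), (-2, 5), (1, 2), (-1, 3)])
    def test_known_values(self, x, y):
        assert f_bij(x) == y

    def test_bijection_on_range(self):
        image = {f_bij(x) for x in range(-500, 501)}
        assert image == set(range(1, 1002))


class TestEditCoding:
    def test_identical_sequences_cost_one_bit(self):
        t = Transcript("ACGTACGT", 1)
        assert edit_code_length(t, t) == (0, 1)

    def test_single_symbol_against_empty(self):
        d, bits = edit_code_length(Transcript("A", 1), Transcript("", 0))
        assert (d, bits) == (1, 8)  # gamma(2)=3 bits, then gap+type+symbol=5

    def test_script_is_minimal_and_deterministic(self):
        ops = edit_script("ACGT", "AGGT")
        assert sum(op != "match" for op, _ in ops) == 1
        assert ops == edit_script("ACGT", "AGGT")

    def test_deletions_carry_no_symbol_bits(self):
        # truth shorter than prediction: pure deletions, 3 bits each (gap+type)
        bits = edits_encoded_bits("AC", "ACGG")
        assert bits == gamma_len(3) + 2 + gamma_len(1) + 2  # gap=2 then gap=0

    @given(dna, dna)
    @settings(deadline=None, derandomize=True, max_examples=150)
    def test_distance_matches_reference(self, a, b):
        d, _ = edit_code_length(Transcript(a, 0), Transcript(b, 0))
        assert d == reference_edit_distance(a, b)

    @given(dna, dna, dna)
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_distance_symmetric_triangle(self, a, b, c):
        def dist(x, y):
            return edit_code_length(Transcript(x, 0), Transcript(y, 0))[0]

        assert dist(a, b) == dist(b, a)
        assert dist(a, c) <= dist(a, b) + dist(b, c)

    def test_script_reconstructs_target(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            src = "".join(rng.choice(list("ACGT"), rng.integers(0, 25)))
            dst = "".join(rng.choice(list("ACGT"), rng.integers(0, 25)))
            out, i = [], 0
            for op, sym in edit_script(src, dst):
                if op == "match":
                    out.append(src[i]); i += 1
                elif op == "sub":
                    out.append(sym); i += 1
                elif op == "ins":
                    out.append(sym)
                else:
                    i += 1
            assert "".join(out) == dst and i == len(src)


class TestBitscore:
    def test_perfect_prediction_is_small(self):
        for n in (1, 5, 40):
            t = Transcript("A" * n, 3)
            assert bitscore(t, t) == 1 / (gamma_len(n + 1) + 5 * n) < 0.2

    def test_empty_prediction_scores_one(self):
        t = Transcript("ACGTACGTA", 2)
        assert bitscore(t, Transcript("", 0)) == 1.0

    def test_undefined_for_empty_truth(self):
        with pytest.raises(ValueError):
            bitscore(Transcript("", 0), Transcript("ACGT", 1))

    def test_degrades_with_mutations(self):
        """More point mutations in the prediction -> larger mean bitscore."""
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 200))
        t = Transcript(seq, 1)

        def mutated(k):
            s = list(seq)
            for pos in rng.choice(len(s), size=k, replace=False):
                s[pos] = rng.choice([c for c in "ACGT" if c != s[pos]])
            return "".join(s)

        lo = np.mean([bitscore(t, Transcript(mutated(2), 1)) for _ in range(40)])
        hi = np.mean([bitscore(t, Transcript(mutated(60), 1)) for _ in range(40)])
        assert lo < hi


class TestMatch:
    def test_identity_match(self):
        t = [Transcript("ACGT", 10)]
        report = match(t, t)
        assert len(report.pairs) == 1
        pair = report.pairs[0]
        assert pair.distance == 0 and pair.rel_expr_diff == 0

    def test_missing_prediction_becomes_fn(self):
        report = match([Transcript("ACGT", 10)], [])
        m = prf(report, 0.1, 0.2)
        assert (m.tp, m.fn) == (0, 1) and m.recall == 0

    def test_padding_keeps_sides_square(self):
        report = match([Transcript("ACGT", 5)] * 2, [Transcript("ACGT", 5)] * 4)
        assert len(report.pairs) == 4
        assert sum(p.truth_real for p in report.pairs) == 2

    @pytest.mark.parametrize("seed", range(12))
    def test_total_cost_matches_permutation_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_t, n_p = rng.integers(1, 6), rng.integers(1, 6)

        def rand_tx():
            seq = "".join(rng.choice(list("ACGT"), rng.integers(1, 15)))
            return Transcript(seq, int(rng.integers(0, 50)))

        truth = [rand_tx() for _ in range(n_t)]
        pred = [rand_tx() for _ in range(n_p)]
        report = match(truth, pred)
        n = max(n_t, n_p)
        pad = Transcript("", 0)
        ts = truth + [pad] * (n - n_t)
        ps = pred + [pad] * (n - n_p)
        cost = np.array([[pair_cost(t, p) for p in ps] for t in ts])
        assert report.total_cost == brute_force_matching_cost(cost)
        identity = sum(cost[i, i] for i in range(n))
        assert report.total_cost <= identity


class TestPRF:
    def test_perfect_prediction(self):
        t = [Transcript("ACGT" * 5, 7), Transcript("GGTT" * 6, 3)]
        m = prf(match(t, t), 0.0, 0.2)
        assert (m.precision, m.recall, m.f_measure) == (1, 1, 1)

    def test_direct_arithmetic(self):
        """TP=3, FP=1, FN=2 gives precision .75, recall .6, F=2/3."""
        def pair(i, good):
            return MatchPair(i, i, True, True, 0, 1, 1,
                             0.01 if good else 0.9, 0.0)

        report = MatchReport(
            pairs=[pair(0, True), pair(1, True), pair(2, True), pair(3, False)],
            n_truth=5, n_pred=4, total_cost=0,
        )
        m = prf(report, 0.1, 0.2)
        assert (m.tp, m.fp, m.fn) == (3, 1, 2)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f_measure == pytest.approx(2 / 3)

    def test_f_zero_when_nothing_matches(self):
        report = match([Transcript("ACGT", 1)], [Transcript("TTTT", 99)])
        m = prf(report, 0.0, 0.0)
        assert m.f_measure == 0.0

    def test_expression_thresholding_can_be_disabled(self):
        truth = [Transcript("ACGTACGTAC", 100)]
        pred = [Transcript("ACGTACGTAC", 1)]  # sequence perfect, expression wild
        report = match(truth, pred)
        assert prf(report, 0.1, 0.2).tp == 0
        assert prf(report, None, 0.2).tp == 1

    def test_rejects_negative_thresholds(self):
        with pytest.raises(ValueError):
            prf(match([], []), -0.1, 0.2)


def test_fasta_tsv_round_trip(tmp_path):
    txs = [Transcript("ACGT", 12.5, name="a"), Transcript("GGG", 3, name="b")]
    write_transcripts(txs, tmp_path / "t.fasta", tmp_path / "t.tsv")
    back = read_transcripts(tmp_path / "t.fasta", tmp_path / "t.tsv")
    assert back == txs
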