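"""PWM machinery against brute-force oracles, plus EM and refinement."""

import itertools

import numpy as np
import pytest

from vdrcohort.motif import (
    PWM,
    UNIFORM,
    em_motif_discovery,
    encode,
    iterative_refinement,
    motif_count_curve,
    partition_by_motif,
    pwm_from_counts,
    read_jaspar,
    scan_sequences,
    score_pvalue_table,
    write_jaspar,
)
from vdrcohort.synth import dr3_like_seed_pwm, simulate_motif_sequences


def one_hot_pwm(consensus, strength=1.0, pseudocount=0.25):
    counts = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 100 * strength
    return pwm_from_counts(counts, pseudocount=pseudocount)


def brute_force_hits(seq, pwm, table, p_max, both_strands=True):
    """Score every window on both strands explicitly."""
    ints = table.int_scores
    hits = set()
    w = pwm.width
    codes = encode(seq)
    mats = {"+": ints, "-": ints[::-1, ::-1]}
    if not both_strands:
        mats.pop("-")
    for o in range(len(seq) - w + 1):
        window = codes[o:o + w]
        if (window < 0).any():
            continue
        for strand, mat in mats.items():
            k = int(sum(mat[b, j] for j, b in enumerate(window)))
            if table.pvalue_int(k) <= p_max:
                hits.add((o, strand))
    return hits


class TestPwmConstruction:
    def test_zero_pseudocount_one_hot(self):
        counts = np.array([[10.0], [0.0], [0.0], [0.0]])
        pwm = pwm_from_counts(counts, pseudocount=0)
        assert pwm.probs[:, 0].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_uniform_counts_zero_log_odds(self):
        pwm = pwm_from_counts(np.full((4, 3), 5.0), pseudocount=0)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_jaspar_style_matrix_normalizes(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(4, 15)).astype(float)
        pwm = pwm_from_counts(counts)
        assert np.allclose(pwm.probs.sum(axis=0), 1.0)

    def test_all_zero_column_without_pseudocount(self):
        counts = np.zeros((4, 2))
        counts[0, 0] = 5
        with pytest.raises(ValueError, match="pseudocount"):
            pwm_from_counts(counts, pseudocount=0)

    def test_information_content_limits(self):
        assert one_hot_pwm("ACGT", pseudocount=0).information_content == pytest.approx(
            [2, 2, 2, 2], abs=1e-9)
        flat = PWM(np.full((4, 3), 0.25))
        assert np.allclose(flat.information_content, 0.0)


class TestScoreTable:
    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_exceedance_matches_word_enumeration(self, width):
        rng = np.random.default_rng(width)
        pwm = pwm_from_counts(rng.integers(0, 30, size=(4, width)).astype(float),
                              background=np.array([0.3, 0.2, 0.2, 0.3]))
        table = score_pvalue_table(pwm)
        ints = table.int_scores
        word_scores = {}
        for word in itertools.product(range(4), repeat=width):
            k = int(sum(ints[b, j] for j, b in enumerate(word)))
            pr = float(np.prod([pwm.background[b] for b in word]))
            word_scores[k] = word_scores.get(k, 0.0) + pr
        for k in sorted(word_scores):
            exact = sum(v for kk, v in word_scores.items() if kk >= k)
            assert table.pvalue_int(k) == pytest.approx(exact, abs=1e-12)

    def test_background_pwm_scores_zero(self):
        pwm = PWM(np.full((4, 4), 0.25))
        table = score_pvalue_table(pwm)
        assert table.offset == 0
        assert table.pvalue_int(0) == pytest.approx(1.0)

    def test_exceedance_monotone(self):
        pwm = dr3_like_seed_pwm()
        table = score_pvalue_table(pwm)
        assert (np.diff(table.exceedance) <= 1e-15).all()


class TestScanning:
    def test_planted_consensus_found_at_offset(self):
        pwm = one_hot_pwm("ACGTAC")
        seq = "T" * 17 + "ACGTAC" + "T" * 17
        hits = scan_sequences({"s": seq}, pwm, p_max=1e-3)
        best = [h for h in hits if h.best_in_sequence]
        assert len(best) == 1
        assert (best[0].offset, best[0].strand) == (17, "+")

    def test_reverse_complement_mirrored(self):
        pwm = one_hot_pwm("ACGTCC")
        seq = "T" * 10 + "ACGTCC" + "A" * 10
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = {(h.offset, h.strand) for h in scan_sequences({"s": seq}, pwm, 1e-3)}
        rev = {(h.offset, h.strand) for h in scan_sequences({"s": rc}, pwm, 1e-3)}
        assert (10, "+") in fwd
        assert (len(seq) - 10 - pwm.width, "-") in rev

    def test_no_hits_in_hostile_sequence(self):
        pwm = one_hot_pwm("GCGCGC")
        assert scan_sequences({"s": "A" * 50}, pwm, p_max=1e-4) == []

    def test_short_sequence_no_hits(self):
        pwm = one_hot_pwm("ACGTAC")
        assert scan_sequences({"s": "ACG"}, pwm, p_max=1.0) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        for trial in range(5):
            width = int(rng.integers(3, 9))
            pwm = pwm_from_counts(rng.integers(0, 25, size=(4, width)).astype(float))
            table = score_pvalue_table(pwm)
            seq = "".join(bases[rng.integers(0, 4, size=60)])
            if trial == 0:
                seq = seq[:20] + "N" + seq[21:]  # N windows must be skipped
            p_max = 0.05
            got = {(h.offset, h.strand) for h in
                   scan_sequences({"s": seq}, pwm, p_max, table=table)}
            assert got == brute_force_hits(seq, pwm, table, p_max)


class TestPartition:
    def test_all_consensus_sequences(self):
        pwm = one_hot_pwm("ACGTACGT")
        seqs = {f"s{i}": "TT" + "ACGTACGT" + "TT" for i in range(10)}
        _, _, frac = partition_by_motif(seqs, pwm, p_max=1e-3)
        assert frac == 100.0

    def test_vanishing_threshold_empty(self):
        pwm = one_hot_pwm("ACGTACGT")
        seqs = {f"s{i}": "TTACGTACGTTT" for i in range(5)}
        pos, neg, frac = partition_by_motif(seqs, pwm, p_max=1e-12)
        assert pos == [] and frac == 0.0

    def test_planted_fraction_recovered(self):
        pwm = one_hot_pwm("ACGTACGTAC", strength=1.0)
        seqs = simulate_motif_sequences(pwm, 300, 50, 0.3, seed=5)
        _, _, frac = partition_by_motif(seqs, pwm, p_max=1e-4)
        # ~0.3 planted plus a small false-positive rate (~80 tests/seq * 1e-4)
        assert 24.0 < frac < 38.0


class TestEM:
    def test_consensus_sequences_one_hot(self):
        seqs = {f"s{i}": "ACGTACGT" for i in range(20)}
        em = em_motif_discovery(seqs, width=8, n_starts=2, seed=0)
        assert em.pwm.consensus == "ACGTACGT"
        assert em.pwm.probs.max(axis=0).min() > 0.9

    def test_log_likelihood_nondecreasing(self):
        pwm = one_hot_pwm("ACGTACGTAC")
        seqs = simulate_motif_sequences(pwm, 80, 40, 0.6, seed=1)
        em = em_motif_discovery(seqs, width=10, n_starts=2, seed=2)
        diffs = np.diff(em.ll_trace)
        assert (diffs >= -1e-6).all()

    def test_planted_motif_recovery(self):
        pwm = one_hot_pwm("TGACGTCATT", strength=0.98)
        seqs = simulate_motif_sequences(pwm, 200, 50, 0.8, seed=3)
        em = em_motif_discovery(seqs, width=10, n_starts=3, seed=4)
        cons = em.pwm.consensus
        rc = cons.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        matches = max(sum(a == b for a, b in zip(c, "TGACGTCATT")) for c in (cons, rc))
        assert matches >= 9
        assert em.gamma == pytest.approx(0.8, abs=0.12)

    def test_width_longer_than_sequences_rejected(self):
        with pytest.raises(ValueError, match="width"):
            em_motif_discovery({"a": "ACGT", "b": "ACGT"}, width=10)


class TestRefinement:
    def test_zero_rounds_returns_seed(self):
        pwm = dr3_like_seed_pwm()
        seqs = simulate_motif_sequences(pwm, 30, 40, 0.5, seed=0)
        res = iterative_refinement(seqs, pwm, rounds=0, seed=0)
        assert res.pwm is pwm
        assert res.history == []

    def test_empty_positives_returns_seed(self):
        pwm = one_hot_pwm("GCGCGCGCGC")
        seqs = {f"s{i}": "A" * 40 for i in range(10)}
        res = iterative_refinement(seqs, pwm, rounds=3, seed=0)
        assert res.history[-1].n_positive == 0
        assert res.pwm is pwm

    def test_moves_toward_planted_variant(self):
        # sequences carry a 1-column variant of the seed; refinement should
        # end closer to the variant than the seed is (per-column JSD)
        from scipy.spatial.distance import jensenshannon

        seed = one_hot_pwm("TGACGTCATT", strength=0.9)
        variant = one_hot_pwm("TGACGACATT", strength=0.95)  # T->A at column 5
        seqs = simulate_motif_sequences(variant, 250, 50, 0.7, seed=7)
        res = iterative_refinement(seqs, seed, p_scan=1e-4, rounds=2, seed=8)
        assert not res.degenerate

        def mean_jsd(a, b):
            # best alignment over small phase shifts and both orientations,
            # as motif comparison tools do
            best = np.inf
            for probs in (a.probs, a.probs[::-1, ::-1]):
                for shift in (-1, 0, 1):
                    cols = [
                        jensenshannon(probs[:, j + shift], b.probs[:, j]) ** 2
                        for j in range(b.width)
                        if 0 <= j + shift < probs.shape[1]
                    ]
                    best = min(best, float(np.mean(cols)))
            return best

        d_refined = mean_jsd(res.pwm, variant)
        d_seed = mean_jsd(seed, variant)
        assert d_refined < d_seed


class TestCountCurve:
    def test_counts_monotone_and_saturating(self):
        pwm = one_hot_pwm("ACGTAC")
        seqs = simulate_motif_sequences(pwm, 40, 30, 0.5, seed=2)
        df = motif_count_curve(seqs, pwm, [1e-6, 1e-4, 1e-2, 1.0])
        assert (np.diff(df["count"]) >= 0).all()
        assert df["count"].iloc[-1] == 40
        assert (df["corrected_p"] <= 1.0).all()

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        pwm = pwm_from_counts(rng.integers(0, 20, size=(4, 5)).astype(float))
        table = score_pvalue_table(pwm)
        bases = np.array(list("ACGT"))
        seqs = [(f"s{i}", "".join(bases[rng.integers(0, 4, size=25)])) for i in range(10)]
        grid = [1e-4, 1e-2, 0.1, 0.5]
        df = motif_count_curve(seqs, pwm, grid)
        for p, expected_count in zip(grid, df["count"]):
            manual = sum(
                1 for _, seq in seqs
                if brute_force_hits(seq, pwm, table, p))
            assert expected_count == manual


class TestJasparIO:
    def test_roundtrip(self, tmp_path):
        counts = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]], dtype=float)
        p = tmp_path / "m.jaspar"
        write_jaspar(counts, p, name="toy")
        back = read_jaspar(p)
        assert np.allclose(back, counts)
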