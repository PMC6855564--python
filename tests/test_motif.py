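import itertools

import numpy as np
import pytest

from linksom.io_formats import PWM, GenomicInterval
from linksom.linker import LinkedMetaclusters
from linksom.motif import (MotifHit, bh_qvalues, enrichment_zscores,
                           genome_background, pwm_logodds, scan_regions,
                           scan_sequences, score_pvalue_distribution)
from linksom.synthetic import make_pwms

UNIFORM = np.full(4, 0.25)


class TestPwmLogodds:
    def test_uniform_row_uniform_bg_is_zero(self):
        pwm = PWM("u", np.full((3, 4), 0.25))
        assert np.allclose(pwm_logodds(pwm, UNIFORM, pseudocount=0.0), 0.0)

    def test_certain_base_scores_log2_4(self):
        pwm = PWM("a", np.array([[1.0, 0, 0, 0]]))
        s = pwm_logodds(pwm, UNIFORM, pseudocount=0.0)
        assert s[0, 0] == pytest.approx(2.0)
        assert np.all(np.isneginf(s[0, 1:]))

    def test_pseudocount_regularizes(self):
        pwm = PWM("a", np.array([[1.0, 0, 0, 0]]))
        s = pwm_logodds(pwm, UNIFORM, pseudocount=0.1)
        assert np.all(np.isfinite(s))


class TestScorePvalueDistribution:
    def test_length_one_certain_motif(self):
        pwm = PWM("a", np.array([[1.0, 0, 0, 0]]))
        s = pwm_logodds(pwm, UNIFORM, pseudocount=0.0)
        table = score_pvalue_distribution(s, UNIFORM)
        # the max score is reached only by "A": p = 0.25
        assert table.site_pvalue(int(table.int_scores.max())) == pytest.approx(0.25)

    @pytest.mark.parametrize("L", [1, 2, 3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, L):
        """Exact DP agrees with brute-force enumeration over all 4^L words."""
        rng = np.random.default_rng(L)
        bg = rng.dirichlet([5, 5, 5, 5])
        probs = rng.dirichlet([1, 1, 1, 1], size=L)
        pwm = PWM(f"m{L}", probs)
        s = pwm_logodds(pwm, bg, pseudocount=0.1)
        table = score_pvalue_distribution(s, bg)
        q = table.int_scores
        # enumeration: quantized score and background probability per word
        word_scores = {}
        for word in itertools.product(range(4), repeat=L):
            total = int(sum(q[i, b] for i, b in enumerate(word)))
            p_word = float(np.prod([bg[b] for b in word]))
            word_scores[total] = word_scores.get(total, 0.0) + p_word
        for total in sorted(word_scores):
            expected = sum(p for t, p in word_scores.items() if t >= total)
            assert table.site_pvalue(total) == pytest.approx(expected, abs=1e-6)

    def test_p_non_increasing_in_score(self):
        rng = np.random.default_rng(9)
        pwm = PWM("m", rng.dirichlet([1, 1, 1, 1], size=5))
        s = pwm_logodds(pwm, UNIFORM, pseudocount=0.1)
        table = score_pvalue_distribution(s, UNIFORM)
        assert np.all(np.diff(table.sf) <= 1e-15)


class TestBH:
    def test_known_example(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        q = bh_qvalues(p)
        # sorted p: .01,.03,.04,.5 -> raw .04,.06,.053+,.5 -> monotone .04,.053,.053,.5
        assert q[0] == pytest.approx(0.04)
        assert q[3] == pytest.approx(0.5)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)


def _rc(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


class TestScanSequences:
    @pytest.fixture
    def sharp_pwm(self):
        return make_pwms(1, 8, seed=42)[0]

    def test_planted_consensus_recovered(self, sharp_pwm):
        rng = np.random.default_rng(0)
        seqs = {}
        offsets = {}
        for i in range(10):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 200))
            off = int(rng.integers(0, 192))
            seq = seq[:off] + sharp_pwm.consensus + seq[off + 8:]
            seqs[f"r{i}"] = seq
            offsets[f"r{i}"] = off
        hits = scan_sequences(seqs, sharp_pwm, UNIFORM)
        found = {(h.region_id, h.offset) for h in hits}
        recovered = sum((rid, off) in found for rid, off in offsets.items())
        assert recovered >= 9

    def test_null_sequences_rarely_hit(self, sharp_pwm):
        trials_with_hits = 0
        for t in range(20):
            rng = np.random.default_rng(1000 + t)
            seqs = {f"r{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, 200))
                    for i in range(10)}
            if scan_sequences(seqs, sharp_pwm, UNIFORM):
                trials_with_hits += 1
        assert trials_with_hits <= 1  # >= 95% of null trials produce no hit

    def test_strand_symmetry(self, sharp_pwm):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 150))
        seq = seq[:40] + sharp_pwm.consensus + seq[48:]
        fwd = scan_sequences({"r": seq}, sharp_pwm, UNIFORM)
        rev = scan_sequences({"r": _rc(seq)}, sharp_pwm, UNIFORM)
        # mirrored offsets: site at o maps to len - 8 - o on the reverse
        assert {(len(seq) - 8 - h.offset) for h in rev} == \
            {h.offset for h in fwd}

    def test_palindrome_dedup_to_one_site(self):
        # perfectly palindromic motif: hits both strands at the same offset
        cons = "ACGTACGT"  # its own reverse complement
        mat = np.full((8, 4), 0.01)
        mat[np.arange(8), [{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in cons]] = 0.97
        pal = PWM("pal", mat)
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 100))
        seq = seq[:30] + cons + seq[38:]
        hits = [h for h in scan_sequences({"r": seq}, pal, UNIFORM)
                if h.offset == 30]
        assert len(hits) == 1

    def test_n_windows_skipped(self, sharp_pwm):
        seqs = {"r": "N" * 50}
        assert scan_sequences(seqs, sharp_pwm, UNIFORM) == []

    def test_lowercase_uppercased(self, sharp_pwm):
        rng = np.random.default_rng(7)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 120))
        seq = seq[:50] + sharp_pwm.consensus + seq[58:]
        hits_lower = scan_sequences({"r": seq.lower()}, sharp_pwm, UNIFORM)
        assert any(h.offset == 50 for h in hits_lower)


class TestScanRegions:
    def test_region_beyond_contig_end_rejected(self):
        genome = {"chr1": "ACGT" * 10}
        pwm = make_pwms(1, 4, seed=0)[0]
        with pytest.raises(ValueError, match="past end"):
            scan_regions([GenomicInterval("chr1", 30, 100, "r")], genome,
                         [pwm], background=UNIFORM)

    def test_background_from_genome(self):
        genome = {"chr1": "AAAACCGT", "chr2": "NNNN"}
        bg = genome_background(genome)
        np.testing.assert_allclose(bg, [0.5, 0.25, 0.125, 0.125])


def _lms_with_regions(counts):
    """LinkedMetaclusters with one row of cells holding `counts` regions."""
    lms = LinkedMetaclusters(len(counts), 1)
    rid = 0
    for i, n in enumerate(counts):
        for _ in range(n):
            lms.cells[(i, 0)].append((f"r{rid}", f"g{rid}"))
            rid += 1
    return lms


class TestEnrichmentZscores:
    def test_equal_fractions_sd_zero_none_enriched(self):
        lms = _lms_with_regions([10, 10, 10])
        hits = [MotifHit("m", f"r{i * 10}", 0, "+", 5.0, 1e-6, 1e-3, (i, 0))
                for i in range(3)]  # one hit region per LM: f = 0.1 everywhere
        res = enrichment_zscores(hits, lms, min_regions=5)
        assert all(not r.enriched for r in res)
        assert all(r.p == 1.0 for r in res)

    def test_single_outlier_matches_hand_z(self):
        # 20 LMs of 10 regions; motif hits 9 regions in LM0, 1 in each other
        lms = _lms_with_regions([10] * 20)
        hits = []
        for i in range(20):
            n_hit = 9 if i == 0 else 1
            for j in range(n_hit):
                hits.append(MotifHit("m", f"r{i * 10 + j}", 0, "+", 5.0,
                                     1e-6, 1e-3, (i, 0)))
        res = enrichment_zscores(hits, lms, min_regions=5)
        f = np.array([0.9] + [0.1] * 19)
        z_expected = (0.9 - f.mean()) / f.std(ddof=1)
        r0 = next(r for r in res if r.lm_id == (0, 0))
        assert r0.z == pytest.approx(z_expected)
        from scipy.stats import norm
        assert r0.p == pytest.approx(norm.sf(z_expected))
        assert r0.enriched
        assert sum(r.enriched for r in res) == 1

    def test_small_lms_excluded_from_baseline(self):
        lms = _lms_with_regions([10, 10, 10, 2])
        res = enrichment_zscores([], lms, min_regions=5, motif_ids=["m"])
        assert {r.lm_id for r in res} == {(0, 0), (1, 0), (2, 0)}
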