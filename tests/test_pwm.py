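"""MATCH-style PWM construction, similarity scores, calibration, scanning."""

import math

import numpy as np
import pytest

from mycnet.pwm import (PWM, PromoterRegion, background_probs, build_pwm,
                        calibrate_threshold, core_similarity, hits_to_bed,
                        matrix_similarity, read_pwms, scan_promoters,
                        scan_region, score_pvalue, write_jaspar)
from mycnet.simulate import DEFAULT_MYC_MAX_COUNTS, default_myc_max_pwm

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


def nonpalindromic_pwm():
    """AP-1-like TGACTCAG matrix whose reverse complement shares no match,
    so planted sites hit exactly one strand (unlike the palindromic E-box)."""
    strong = {"A": [17, 1, 1, 1], "C": [1, 17, 1, 1],
              "G": [1, 1, 17, 1], "T": [1, 1, 1, 17]}
    return build_pwm([strong[b] for b in "TGACTCAG"], id="ap1_test")


def oracle_mss(pwm, word, positions=None):
    """Direct formula evaluation, independent of the scanning code path."""
    positions = range(len(pwm)) if positions is None else positions
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    cur = lo = hi = 0.0
    for i in positions:
        info = sum(
            pwm.freqs[i, b] * math.log(4 * pwm.freqs[i, b])
            for b in range(4) if pwm.freqs[i, b] > 0
        )
        cur += info * (pwm.freqs[i].min() if word[i] == "N"
                       else pwm.freqs[i, idx[word[i]]])
        lo += info * pwm.freqs[i].min()
        hi += info * pwm.freqs[i].max()
    return (cur - lo) / (hi - lo)


class TestBuildPwm:
    def test_uniform_column_has_zero_information(self):
        pwm = build_pwm([[5, 5, 5, 5], [20, 0, 0, 0]], pseudocount=0)
        assert pwm.info[0] == pytest.approx(0.0)

    def test_single_base_column_information_ln4(self):
        pwm = build_pwm([[20, 0, 0, 0]] * 5, pseudocount=0)
        assert pwm.info[0] == pytest.approx(math.log(4))

    def test_zero_column_requires_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            build_pwm([[0, 0, 0, 0]], pseudocount=0)
        assert build_pwm([[0, 0, 0, 0]]).freqs[0].tolist() == [0.25] * 4

    def test_columns_sum_to_one(self):
        pwm = default_myc_max_pwm()
        np.testing.assert_allclose(pwm.freqs.sum(axis=1), 1.0, atol=1e-12)

    def test_core_equals_brute_force_window_max(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 30, size=(10, 4))
        pwm = build_pwm(counts)
        sums = [pwm.info[i:i + 5].sum() for i in range(6)]
        assert pwm.core_start == int(np.argmax(sums))
        assert len(pwm.core_positions) == 5


class TestSimilarity:
    def test_consensus_scores_one(self):
        pwm = default_myc_max_pwm()
        assert matrix_similarity(pwm, pwm.consensus) == pytest.approx(1.0)
        assert core_similarity(pwm, pwm.consensus) == pytest.approx(1.0)

    def test_anti_consensus_scores_zero(self):
        pwm = default_myc_max_pwm()
        anti = "".join("ACGT"[b] for b in pwm.freqs.argmin(axis=1))
        assert matrix_similarity(pwm, anti) == pytest.approx(0.0)

    def test_hand_built_three_position_matrix(self):
        pwm = build_pwm([[8, 0, 0, 0], [0, 6, 2, 0], [1, 1, 1, 5]],
                        pseudocount=0.25)
        for word in ("ACG", "ACT", "TGA", "NNN"):
            assert matrix_similarity(pwm, word) == pytest.approx(
                oracle_mss(pwm, word), rel=1e-12)

    def test_core_restricted_sum_oracle(self):
        pwm = default_myc_max_pwm()
        rng = np.random.default_rng(8)
        for _ in range(20):
            word = "".join(rng.choice(list("ACGT"), len(pwm)))
            assert core_similarity(pwm, word) == pytest.approx(
                oracle_mss(pwm, word, pwm.core_positions), rel=1e-12)

    def test_core_only_match(self):
        pwm = default_myc_max_pwm()
        word = list("".join("ACGT"[b] for b in pwm.freqs.argmin(axis=1)))
        for i in pwm.core_positions:
            word[i] = pwm.consensus[i]
        word = "".join(word)
        assert core_similarity(pwm, word) == pytest.approx(1.0)
        assert matrix_similarity(pwm, word) < 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            matrix_similarity(default_myc_max_pwm(), "ACGT")

    def test_scores_bounded(self):
        pwm = default_myc_max_pwm()
        rng = np.random.default_rng(2)
        for _ in range(200):
            word = "".join(rng.choice(list("ACGTN"), len(pwm)))
            assert 0.0 <= matrix_similarity(pwm, word) <= 1.0


class TestCalibration:
    def test_alpha_one_admits_everything(self):
        assert calibrate_threshold(default_myc_max_pwm(), alpha=1.0) == 0.0

    def test_exact_exceedance_within_alpha(self):
        pwm = default_myc_max_pwm()
        probs = background_probs(0.42)
        for alpha in (0.05, 0.01, 0.001):
            cutoff = calibrate_threshold(pwm, probs=probs, alpha=alpha)
            assert score_pvalue(pwm, cutoff, probs) <= alpha + 1e-9

    def test_monte_carlo_within_one_grid_step_of_exact(self):
        counts = np.random.default_rng(6).integers(0, 20, size=(4, 4))
        pwm = build_pwm(counts)
        probs = background_probs(0.5)
        exact = calibrate_threshold(pwm, probs=probs, alpha=0.05, method="exact")
        mc = calibrate_threshold(pwm, probs=probs, alpha=0.05,
                                 method="monte_carlo", n_samples=200_000, seed=3)
        # grid = distinct achievable scores of the 256-word enumeration
        grid = sorted({matrix_similarity(pwm, "".join(w))
                       for w in __import__("itertools").product("ACGT", repeat=4)})
        i = grid.index(pytest.approx(exact))
        neighborhood = grid[max(0, i - 1):i + 2]
        assert any(mc == pytest.approx(g) for g in neighborhood)

    def test_cutoff_monotone_in_alpha(self):
        pwm = default_myc_max_pwm()
        cuts = [calibrate_threshold(pwm, alpha=a) for a in (0.001, 0.01, 0.1, 1.0)]
        assert cuts == sorted(cuts, reverse=True)

    def test_insufficient_samples_guidance(self):
        with pytest.raises(ValueError, match="n_samples"):
            calibrate_threshold(default_myc_max_pwm(), alpha=0.0001,
                                n_samples=1000, method="monte_carlo", seed=0)


def brute_force_scan(pwm, region, mss_cut, css_cut):
    """All-window, both-strand oracle using the independent score formula."""
    seq = region.seq[: region.exon_end]
    L = len(pwm)
    mirror_core = range(len(pwm) - pwm.core_start - 5,
                        len(pwm) - pwm.core_start)
    hits = []
    for i in range(len(seq) - L + 1):
        w = seq[i:i + L]
        for strand in "+-":
            word = w if strand == "+" else revcomp(w)
            mss = oracle_mss(pwm, word)
            core = pwm.core_positions
            css = oracle_mss(pwm, word, core)
            if mss >= mss_cut and css >= css_cut:
                hits.append((i - region.tss_offset, strand,
                             round(mss, 9), round(css, 9)))
    return sorted(hits)


class TestScanning:
    def test_planted_consensus_found_at_minus_150(self):
        pwm = nonpalindromic_pwm()
        rng = np.random.default_rng(1)
        chars = list("".join(rng.choice(list("ACGT"), 400)))
        tss = 300
        pos = tss - 150
        chars[pos:pos + len(pwm)] = pwm.consensus
        region = PromoterRegion("g", "".join(chars), tss, 400)
        hits = scan_region(pwm, region, mss_cutoff=0.95, css_cutoff=0.95)
        assert [(h.start, h.strand) for h in hits] == [(-150, "+")]
        assert hits[0].matrix_score == pytest.approx(1.0)

    def test_reverse_complement_plant_hits_minus_strand(self):
        pwm = nonpalindromic_pwm()
        rng = np.random.default_rng(1)
        chars = list("".join(rng.choice(list("ACGT"), 400)))
        chars[150:150 + len(pwm)] = revcomp(pwm.consensus)
        region = PromoterRegion("g", "".join(chars), 300, 400)
        hits = scan_region(pwm, region, mss_cutoff=0.95, css_cutoff=0.95)
        assert [(h.start, h.strand) for h in hits] == [(150 - 300, "-")]

    def test_strand_mirror_symmetry(self):
        pwm = default_myc_max_pwm()
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), 300))
        fwd = scan_region(pwm, PromoterRegion("g", seq, 0, 300), 0.6, 0.6)
        rev = scan_region(pwm, PromoterRegion("g", revcomp(seq), 0, 300), 0.6, 0.6)
        n, L = 300, len(pwm)
        mirrored = sorted((n - h.start - L, "-" if h.strand == "+" else "+",
                           round(h.matrix_score, 9)) for h in fwd)
        assert mirrored == sorted((h.start, h.strand, round(h.matrix_score, 9))
                                  for h in rev)

    def test_oracle_equivalence_on_random_sequences(self):
        pwm = default_myc_max_pwm()
        rng = np.random.default_rng(13)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), 500))
            region = PromoterRegion("g", seq, 200, 500)
            hits = scan_region(pwm, region, 0.65, 0.65)
            got = sorted((h.start, h.strand, round(h.matrix_score, 9),
                          round(h.core_score, 9)) for h in hits)
            assert got == brute_force_scan(pwm, region, 0.65, 0.65)

    def test_short_region_yields_empty(self):
        region = PromoterRegion("g", "ACGTA", 1, 5)
        assert scan_region(default_myc_max_pwm(), region, 0.5) == []

    def test_region_validation(self):
        with pytest.raises(ValueError):
            PromoterRegion("g", "ACGT", 4, 4)   # tss beyond exon end
        with pytest.raises(ValueError):
            PromoterRegion("g", "A" * 3000, 2500, 3000)  # >2 kb upstream


class TestScanPromoters:
    def regions(self, planted_in):
        pwm = nonpalindromic_pwm()
        rng = np.random.default_rng(3)
        out = []
        for i in range(3):
            chars = list("".join(rng.choice(list("ACGT"), 300)))
            if i in planted_in:
                chars[40:40 + len(pwm)] = pwm.consensus
            out.append(PromoterRegion(f"g{i}", "".join(chars), 200, 300))
        return pwm, out

    def test_summary_counts(self):
        pwm, regions = self.regions({0, 2})
        hits, summary = scan_promoters(pwm, regions, 0.95, 0.95)
        assert summary.n_sites == 2
        assert summary.n_genes_with_site == 2
        assert summary.genes_with_site == ["g0", "g2"]

    def test_gene_with_two_sites_counted_once_in_gene_tally(self):
        pwm = nonpalindromic_pwm()
        chars = list("C" * 300)
        chars[10:10 + len(pwm)] = pwm.consensus
        chars[100:100 + len(pwm)] = pwm.consensus
        region = PromoterRegion("g", "".join(chars), 200, 300)
        hits, summary = scan_promoters(pwm, [region], 0.95, 0.95)
        assert summary.n_sites == 2 and summary.n_genes_with_site == 1

    def test_summary_consistent_with_hit_table(self):
        pwm, regions = self.regions({0, 1, 2})
        hits, summary = scan_promoters(pwm, regions, 0.7, 0.7)
        assert summary.n_sites == len(hits)
        assert summary.n_genes_with_site == len({h.gene_id for h in hits})

    def test_duplicate_gene_ids_rejected(self):
        pwm, regions = self.regions(set())
        regions.append(regions[0])
        with pytest.raises(ValueError, match="duplicate"):
            scan_promoters(pwm, regions, 0.9)


class TestPwmIO:
    def test_jaspar_round_trip_bit_exact(self, tmp_path):
        pwm = default_myc_max_pwm()
        path = tmp_path / "m.jaspar"
        write_jaspar([pwm], path)
        back = read_pwms(path)[0]
        np.testing.assert_array_equal(back.counts, DEFAULT_MYC_MAX_COUNTS)
        np.testing.assert_allclose(back.freqs, pwm.freqs, atol=1e-12)

    def test_transfac_parsing(self, tmp_path):
        text = (
            "ID  ebox_test\nXX\n"
            "P0      A      C      G      T\n"
            "01      2     14      2      2      C\n"
            "02      1     16      2      1      C\n"
            "03     18      0      1      1      A\n"
            "04      0     19      1      0      C\n"
            "05      0      1     19      0      G\n"
            "XX\n//\n"
        )
        path = tmp_path / "m.transfac"
        path.write_text(text)
        pwm = read_pwms(path)[0]
        assert pwm.id == "ebox_test"
        np.testing.assert_array_equal(pwm.counts, DEFAULT_MYC_MAX_COUNTS[:5])

    def test_bed_export(self):
        pwm = nonpalindromic_pwm()
        hits, _ = scan_promoters(
            pwm, [PromoterRegion("g", "C" * 100 + pwm.consensus + "C" * 100,
                                 150, 208)], 0.95, 0.95)
        bed = hits_to_bed(hits, len(pwm))
        assert len(bed.strip().splitlines()) == len(hits) == 1
        fields = bed.strip().split("\t")
        assert fields[0] == "g" and fields[5] == "+"
        assert int(fields[4]) == 1000
        assert int(fields[2]) - int(fields[1]) == len(pwm)
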