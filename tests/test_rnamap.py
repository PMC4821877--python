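"""Positional motif profiles, background band, peaks and k-mer enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qremap import rnamap
from qremap.io import AnnotationRecord
from qremap.qre import reverse_complement
from qremap.simulate import gen_rna_map_set


def brute_window_count(seq, lo, hi, motif):
    """Independent per-window count: motif fully inside [lo, hi)."""
    window = seq[lo:hi]
    return sum(
        1 for i in range(len(window) - len(motif) + 1) if window[i : i + len(motif)] == motif
    )


class TestExtractFlanks:
    def _locus(self, strand="+"):
        ann = [
            AnnotationRecord("c", 0, 100, strand, "g", "t", 0),
            AnnotationRecord("c", 600, 720, strand, "g", "t", 1),
            AnnotationRecord("c", 1220, 1320, strand, "g", "t", 2),
        ]
        rng = np.random.default_rng(4)
        genome = {"c": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1320)])}
        exon_sets = pd.DataFrame(
            [{"chrom": "c", "start": 600, "end": 720, "strand": strand,
              "transcript_id": "t", "set": "background"}]
        )
        return exon_sets, ann, genome

    def test_internal_exon_full_flanks(self):
        es, ann, genome = self._locus()
        (pair,) = rnamap.extract_flanks(es, ann, genome, flank_nt=250)
        assert pair.upstream == genome["c"][350:600]
        assert pair.downstream == genome["c"][720:970]

    def test_short_intron_truncated_at_neighbour(self):
        es, ann, genome = self._locus()
        (pair,) = rnamap.extract_flanks(es, ann, genome, flank_nt=800)
        assert pair.upstream == genome["c"][100:600]  # 500-nt intron, not 800
        assert pair.downstream == genome["c"][720:1220]

    def test_minus_strand_flanks_are_reverse_complements(self):
        es, ann, genome = self._locus(strand="-")
        (pair,) = rnamap.extract_flanks(es, ann, genome, flank_nt=250)
        assert pair.upstream == reverse_complement(genome["c"][720:970])
        assert pair.downstream == reverse_complement(genome["c"][350:600])

    def test_unknown_exon_rejected(self):
        es, ann, genome = self._locus()
        es.loc[0, "start"] = 601
        with pytest.raises(ValueError, match="601"):
            rnamap.extract_flanks(es, ann, genome, flank_nt=250)


class TestWindowGrid:
    def test_grid_size_arithmetic(self):
        up = rnamap.grid_offsets("up", flank=500, window=50, step=5)
        down = rnamap.grid_offsets("down", flank=500, window=50, step=5)
        assert len(up) == len(down) == 91
        assert up[-1] == -25.0 and down[0] == 25.0  # window centers nearest the exon

    def test_counts_match_brute_force(self, rng, dna):
        motif = "ACTAA"
        seqs = [dna(rng, int(rng.integers(40, 500))) for _ in range(30)]
        for side in ("up", "down"):
            counts = rnamap.window_counts(seqs, side, motif, flank=400, window=50, step=5)
            offsets = rnamap.grid_offsets(side, 400, 50, 5)
            assert counts.shape == (30, len(offsets))
            for i, seq in enumerate(seqs):
                L = min(len(seq), 400)
                s = seq[len(seq) - L:] if side == "up" else seq[:L]
                for j, off in enumerate(offsets):
                    if side == "up":
                        hi = L + int(off + 25)
                        lo = hi - 50
                    else:
                        lo = int(off - 25)
                        hi = lo + 50
                    if lo < 0 or hi > L:
                        assert np.isnan(counts[i, j])
                    else:
                        assert counts[i, j] == brute_window_count(s, lo, hi, motif)

    def test_doubling_flank_leaves_shared_positions_unchanged(self, rng, dna):
        seqs = [dna(rng, 600) for _ in range(10)]
        short = rnamap.window_counts(seqs, "up", "ACTAA", flank=250, window=50, step=5)
        long = rnamap.window_counts(seqs, "up", "ACTAA", flank=500, window=50, step=5)
        np.testing.assert_array_equal(short, long[:, -short.shape[1]:])


class TestBackgroundBand:
    def test_degenerate_bootstrap_on_identical_exons(self):
        counts = np.tile([[0.0, 1.0, 2.0]], (30, 1))
        lo, hi = rnamap.background_confidence(counts, B=200, seed=1)
        np.testing.assert_allclose(lo, [0, 1, 2])
        np.testing.assert_allclose(hi, [0, 1, 2])

    def test_band_covers_true_mean(self, rng, dna):
        """The bootstrap band contains the analytic chance rate at ~95% of positions."""
        seqs = [dna(rng, 500) for _ in range(150)]
        counts = rnamap.window_counts(seqs, "down", "ACTAA", flank=500, window=50, step=5)
        lo, hi = rnamap.background_confidence(counts, B=400, seed=2)
        true_mean = 46 * 4.0**-5  # motif start positions per window x uniform rate
        frac = np.mean((lo <= true_mean) & (true_mean <= hi))
        assert frac >= 0.85

    def test_band_widens_as_background_shrinks(self, rng, dna):
        seqs = [dna(rng, 500) for _ in range(1000)]
        counts = rnamap.window_counts(seqs, "down", "ACTAA", flank=500, window=50, step=5)
        lo_b, hi_b = rnamap.background_confidence(counts, B=300, seed=3)
        lo_s, hi_s = rnamap.background_confidence(counts[:50], B=300, seed=3)
        assert np.mean(hi_s - lo_s) > np.mean(hi_b - lo_b)

    def test_zero_bootstrap_rejected(self):
        with pytest.raises(ValueError):
            rnamap.background_confidence(np.zeros((5, 3)), B=0, seed=1)


class TestPeaks:
    def test_profile_inside_band_gives_no_peaks(self):
        offsets = np.arange(5.0)
        peaks = rnamap.find_peaks(np.full(5, 0.5), np.zeros(5), np.ones(5), offsets, "up")
        assert peaks == []

    def test_isolated_point_and_gap_break_runs(self):
        offsets = np.arange(30) * 5.0
        fg = np.zeros(30)
        fg[10:15] = 2.0
        fg[20] = 2.0
        peaks = rnamap.find_peaks(fg, np.full(30, -1.0), np.ones(30), offsets, "down")
        assert [(p.start_pos, p.end_pos, p.n_points) for p in peaks] == [
            (50.0, 70.0, 5),
            (100.0, 100.0, 1),
        ]

    def test_band_edge_is_inside(self):
        offsets = np.arange(3.0)
        peaks = rnamap.find_peaks(np.ones(3), np.zeros(3), np.ones(3), offsets, "up")
        assert peaks == []

    def test_depletion_reported_separately(self):
        offsets = np.arange(4.0)
        fg = np.array([0.5, -1.0, 0.5, 2.0])
        peaks = rnamap.find_peaks(fg, np.zeros(4), np.ones(4), offsets, "up")
        kinds = {p.kind for p in peaks}
        assert kinds == {"enriched", "depleted"}

    def test_double_bonferroni_arithmetic(self, rng):
        offsets = np.arange(91) * 5.0
        fg = rng.poisson(3.0, size=(40, 91)).astype(float)
        bg = rng.poisson(0.2, size=(60, 91)).astype(float)
        pk = rnamap.Peak("down", "enriched", offsets[10], offsets[12], 3)
        (out,) = rnamap.peak_qvalues([pk], fg, bg, offsets)
        pvals = [
            stats.mannwhitneyu(fg[:, k], bg[:, k], alternative="greater").pvalue
            for k in (10, 11, 12)
        ]
        assert out.p_min == pytest.approx(min(pvals))
        assert out.q == pytest.approx(min(1.0, min(pvals) * 3 * 91))

    def test_q_capped_at_one(self, rng):
        offsets = np.arange(91) * 5.0
        fg = rng.poisson(1.0, size=(10, 91)).astype(float)
        bg = rng.poisson(1.0, size=(10, 91)).astype(float)
        pk = rnamap.Peak("down", "enriched", offsets[0], offsets[9], 10)
        (out,) = rnamap.peak_qvalues([pk], fg, bg, offsets)
        assert out.q == 1.0

    def test_point_mww_matches_permutation_oracle(self, rng):
        fg = rng.poisson(1.0, 30).astype(float) + rng.poisson(0.5, 30)
        bg = rng.poisson(1.0, 40).astype(float)
        p = stats.mannwhitneyu(fg, bg, alternative="greater").pvalue
        pooled = np.concatenate([fg, bg])
        u_obs = stats.mannwhitneyu(fg, bg, alternative="greater").statistic
        count = 0
        n_perm = 5000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            count += stats.mannwhitneyu(perm[:30], perm[30:], alternative="greater").statistic >= u_obs - 1e-12
        assert p == pytest.approx(count / n_perm, abs=0.04)


class TestKmerEnrichment:
    def test_identical_sets_show_no_enrichment(self, rng, dna):
        seqs = [dna(rng, 200) for _ in range(5)]
        table = rnamap.kmer_fisher_enrichment(seqs, seqs, k=5)
        present = table[table["count_fg"] > 0]
        np.testing.assert_allclose(present["odds"], 1.0)
        np.testing.assert_allclose(present["p"], 1.0)

    def test_planted_word_is_top_enriched(self, rng, dna):
        bg = [dna(rng, 300) for _ in range(50)]
        fg = [dna(rng, 120) + "ACTAA" * 4 + dna(rng, 120) for _ in range(50)]
        table = rnamap.kmer_fisher_enrichment(fg, bg, k=5)
        row = table.set_index("kmer").loc["ACTAA"]
        assert row["p_adj"] < 0.01
        assert row["odds"] > 1
        assert table.iloc[0].name == 0 and "ACTAA" in table.head(3)["kmer"].tolist()

    def test_fisher_p_matches_hypergeometric_summation(self):
        """Two-sided Fisher p recomputed by summing hypergeometric point masses."""
        a, b, c, d = 10, 990, 1, 999
        table = [[a, b], [c, d]]
        p_fisher = stats.fisher_exact(table, alternative="two-sided")[1]
        n, K, N = a + b + c + d, a + c, a + b
        support = np.arange(max(0, K + N - n), min(K, N) + 1)
        pmf = stats.hypergeom.pmf(support, n, K, N)
        p_oracle = pmf[pmf <= pmf[support == a] * (1 + 1e-7)].sum()
        assert p_fisher == pytest.approx(p_oracle, abs=1e-10)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            rnamap.kmer_fisher_enrichment(["ACG"], ["ACGTACGT"], k=5)


class TestGeometryRecovery:
    def test_planted_offsets_recovered_with_mirrored_sides(self):
        """Repressed exons peak upstream at the planted offset, activated downstream."""
        es, ann, genome, truth = gen_rna_map_set(120, 120, 150, -100, 500, seed=42)
        flanks = rnamap.extract_flanks(es, ann, genome, flank_nt=500)
        _, peaks = rnamap.rna_map(flanks, B=300, seed=43)
        top_rep = (
            peaks[(peaks["set"] == "repressed") & (peaks["kind"] == "enriched")]
            .sort_values("q").iloc[0]
        )
        top_act = (
            peaks[(peaks["set"] == "activated") & (peaks["kind"] == "enriched")]
            .sort_values("q").iloc[0]
        )
        assert top_rep["side"] == "up" and abs(top_rep["center"] - (-100)) <= 5
        assert top_act["side"] == "down" and abs(top_act["center"] - 100) <= 5
        assert top_rep["q"] < 0.05 and top_act["q"] < 0.05

    def test_peak_mean_matches_single_planted_motif(self):
        """Windows fully covering a once-planted motif average ~1 motif per exon."""
        es, ann, genome, _ = gen_rna_map_set(0, 100, 50, -100, 500, seed=44)
        flanks = rnamap.extract_flanks(es, ann, genome, flank_nt=500)
        seqs = [f.upstream for f in flanks if f.set_label == "repressed"]
        counts = rnamap.window_counts(seqs, "up", "ACTAA", 500, 50, 5)
        offsets = rnamap.grid_offsets("up", 500, 50, 5)
        covering = (offsets >= -120) & (offsets <= -75)
        assert np.nanmean(counts[:, covering]) >= 1.0
        background_rate = np.nanmean(counts[:, offsets < -150])
        assert background_rate < 0.2

    def test_no_signal_no_peaks_called_significant(self):
        es, ann, genome, _ = gen_rna_map_set(40, 40, 80, -100, 400, seed=45)
        # strip the planted motifs by regenerating the background only
        es = es[es["set"] == "background"].reset_index(drop=True)
        flanks = rnamap.extract_flanks(es, ann, genome, flank_nt=400)
        with pytest.raises(ValueError):
            # peaks cannot be called without any foreground set vs background
            rnamap.rna_map([f for f in flanks if f.set_label != "background"], B=100, seed=1)
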