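"""Synthetic-genome generator: seeded determinism, composition, planted
truth round-trips."""

import numpy as np
import pytest
from scipy import stats

from tssbind.motifs import MotifSpec, scan_motif
from tssbind.simulate import (
    ExpressionDesign,
    GenomeConfig,
    PeakMixtureConfig,
    generate_expression,
    generate_genome,
    generate_methylation,
    generate_peaks,
    plant_motifs,
)


class TestGenome:
    def test_same_seed_identical(self):
        cfg = GenomeConfig(n_chroms=1, chrom_length=100_000, n_genes=10, seed=3)
        a = generate_genome(cfg)
        b = generate_genome(cfg)
        assert a[0] == b[0]  # sequences byte-identical
        assert a[1] == b[1]  # transcripts
        assert a[2] == b[2]  # CGI intervals

    def test_island_gc_matches_config(self, small_genome):
        """Realized GC inside islands close to the configured 0.65; the
        99% binomial interval at >=10 kb of island sequence is +/-0.015."""
        seqs, transcripts, cgi, truth = small_genome
        bases = "".join(seqs[iv.chrom][iv.start:iv.end] for iv in cgi)
        assert len(bases) >= 10_000
        gc = sum(c in "GC" for c in bases) / len(bases)
        assert abs(gc - 0.65) < 0.015

    def test_background_composition_chi2(self, small_genome):
        """Chi-square GoF of background base frequencies vs the configured
        i.i.d. composition, non-significant at alpha=0.001 on 10 kb."""
        seqs, transcripts, cgi, truth = small_genome
        island_mask = set()
        for iv in cgi:
            if iv.chrom == "chr1":
                island_mask.update(range(iv.start, iv.end))
        bg = [seqs["chr1"][i] for i in range(10_000, 30_000)
              if i not in island_mask][:10_000]
        counts = [bg.count(b) for b in "ACGT"]
        gc = 0.40
        expected = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        chi2, p = stats.chisquare(counts, expected * len(bg))
        assert p > 0.001

    def test_island_cpg_depletion_matches_oe(self, small_genome):
        """CpG dinucleotide frequency inside islands ~ oe * pC * pG."""
        seqs, transcripts, cgi, truth = small_genome
        n_cpg = total = 0
        for iv in cgi:
            s = seqs[iv.chrom][iv.start:iv.end]
            n_cpg += s.count("CG")
            total += len(s) - 1
        observed_oe = (n_cpg / total) / (0.325 * 0.325)
        assert abs(observed_oe - 0.75) < 0.08

    def test_cgi_fraction_zero(self):
        cfg = GenomeConfig(n_chroms=1, chrom_length=100_000, n_genes=10,
                           cgi_fraction=0.0, seed=1)
        _, _, cgi, truth = generate_genome(cfg)
        assert cgi == [] and truth["cgi_genes"] == []

    def test_overfull_genome_errors_with_count(self):
        cfg = GenomeConfig(n_chroms=1, chrom_length=50_000, n_genes=50, seed=1)
        with pytest.raises(ValueError, match="cannot place"):
            generate_genome(cfg)

    def test_gene_anatomy(self, small_genome):
        _, transcripts, _, _ = small_genome
        for t in transcripts[:20]:
            assert len(t.utr5) >= 1
            assert len(t.cds_exons) >= 2
            assert len(t.introns) >= 1
            # first intron follows the first coding exon in transcription order
            if t.strand == "+":
                assert t.introns[0].start == t.cds_exons[0].end
            else:
                assert t.introns[0].end == t.cds_exons[0].start


class TestPlantMotifs:
    def test_roundtrip_recovers_all_sites(self, small_genome):
        seqs, _, cgi, _ = small_genome
        planted, manifest = plant_motifs(seqs, cgi[:30], "AGGCCTAG", 2, seed=5)
        assert len(manifest) == 60
        motif = MotifSpec("m", "AGGCCTAG", scan_strands="forward")
        for row in manifest.itertuples():
            window = planted[row.chrom][row.pos:row.pos + 8]
            assert window == "AGGCCTAG"
        # every planted region now scans positive
        for iv in cgi[:30]:
            hits = scan_motif(planted[iv.chrom][iv.start:iv.end], motif)
            assert len(hits) >= 2

    def test_zero_count_is_identity(self, small_genome):
        seqs, _, cgi, _ = small_genome
        out, manifest = plant_motifs(seqs, cgi[:5], "GGCCT", 0, seed=1)
        assert out == seqs and len(manifest) == 0

    def test_too_small_region_errors(self):
        from tssbind.core import GenomicInterval
        seqs = {"chr1": "A" * 100}
        with pytest.raises(ValueError, match="too small"):
            plant_motifs(seqs, [GenomicInterval("chr1", 0, 9)], "AGGCCTAG", 2)


class TestPeaks:
    def test_degenerate_mixture_exact_offsets(self, small_genome):
        _, transcripts, _, truth = small_genome
        mix = PeakMixtureConfig(weights=(1, 0, 0, 0, 0), down_near=(240, 0),
                                seed=2)
        peaks, track, ptruth = generate_peaks(transcripts, mix, 50,
                                              truth["chrom_sizes"])
        by_id = {t.transcript_id: t for t in transcripts}
        for p, row in zip(peaks, ptruth.itertuples()):
            t = by_id[row.transcript_id]
            expected = t.tss + 240 if t.strand == "+" else t.tss - 240
            assert p.summit == expected

    def test_component_counts_binomial(self, small_genome):
        """Two-component 50/50 mixture: counts within 3 sigma of n/2."""
        _, transcripts, _, truth = small_genome
        mix = PeakMixtureConfig(weights=(0.5, 0.5, 0, 0, 0), seed=7)
        n = 5000
        _, _, ptruth = generate_peaks(transcripts, mix, n, truth["chrom_sizes"])
        k = (ptruth["component"] == "down_near").sum()
        assert abs(k - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_same_seed_identical(self, small_genome):
        _, transcripts, _, truth = small_genome
        mix = PeakMixtureConfig(seed=9)
        a = generate_peaks(transcripts, mix, 100, truth["chrom_sizes"])
        b = generate_peaks(transcripts, mix, 100, truth["chrom_sizes"])
        assert a[0] == b[0]
        assert a[2].equals(b[2])

    def test_exo_mode_width_contract(self, small_genome):
        """Exo-mode peak widths are >= 5x narrower on average."""
        _, transcripts, _, truth = small_genome
        seq_p, _, _ = generate_peaks(transcripts, PeakMixtureConfig(seed=1),
                                     2000, truth["chrom_sizes"])
        exo_p, _, _ = generate_peaks(transcripts,
                                     PeakMixtureConfig.exo_mode(seed=1),
                                     2000, truth["chrom_sizes"])
        mean_seq = np.mean([p.width for p in seq_p])
        mean_exo = np.mean([p.width for p in exo_p])
        assert mean_seq / mean_exo >= 5


class TestExpression:
    def test_null_design_low_discovery(self):
        """No planted effects: the moderated caller's discoveries stay near
        its nominal false-positive rate."""
        from tssbind.degs import call_degs
        design = ExpressionDesign(direct_down_effect=0.0,
                                  indirect_up_effect=0.0, seed=4)
        genes = [f"g{i}" for i in range(2000)]
        counts = generate_expression(design, genes, [], [])
        groups = {c: c.rsplit("_rep", 1)[0] for c in counts.columns}
        table = call_degs(counts, groups, ("DKO_1", "control"))
        assert (table["direction"] != "unchanged").mean() < 0.01

    def test_planted_fourfold_recovered_in_all_clones(self):
        """4-fold direct targets at mean 500 / dispersion 0.05 / 3 reps are
        recovered as down in every DKO clone >= 95% of the time."""
        from tssbind.degs import call_degs, consensus_sets
        design = ExpressionDesign(seed=12)
        genes = [f"g{i}" for i in range(3000)]
        direct = genes[:300]
        counts = generate_expression(design, genes, direct, [])
        groups = {c: c.rsplit("_rep", 1)[0] for c in counts.columns}
        tables = [call_degs(counts, groups, (c, "control"))
                  for c in ("DKO_1", "DKO_2", "DKO_3")]
        cons = consensus_sets(tables, "down")
        assert len(cons.all_clones & set(direct)) / len(direct) >= 0.95

    def test_same_seed_identical(self):
        design = ExpressionDesign(seed=8)
        genes = [f"g{i}" for i in range(50)]
        a = generate_expression(design, genes, genes[:5], genes[10:15])
        b = generate_expression(design, genes, genes[:5], genes[10:15])
        assert a.equals(b)

    def test_overlapping_target_sets_rejected(self):
        design = ExpressionDesign()
        with pytest.raises(ValueError, match="disjoint"):
            generate_expression(design, ["a", "b"], ["a"], ["a"])


class TestMethylation:
    def test_noiseless_beta_exact(self, small_genome):
        _, transcripts, _, _ = small_genome
        table, _ = generate_methylation(transcripts, n_probes=50,
                                        base_beta=0.5, planted_delta=0.0,
                                        n_planted=0, noise_sd=0.0,
                                        flagged_fraction=0.0, seed=1)
        # beta drawn around 0.5 but noiseless: M/(M+U) equals the drawn beta
        M, U = table["M_wt_1"], table["U_wt_1"]
        beta = M / (M + U)
        assert np.allclose(M + U, 1000, atol=1)
        assert ((beta > 0) & (beta < 1)).all()

    def test_flagged_probes_counted(self, small_genome):
        from tssbind.methylation import filter_detection
        _, transcripts, _, _ = small_genome
        table, _ = generate_methylation(transcripts, n_probes=400,
                                        flagged_fraction=0.25, seed=2)
        flagged = (table["detp_wt_1"] > 0.05).sum()
        filtered = filter_detection(table)
        assert filtered["M_wt_1"].isna().sum() == flagged
        assert flagged > 0
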