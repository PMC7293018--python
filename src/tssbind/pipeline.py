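"""End-to-end synthetic demonstration pipeline and its configuration.

One call generates a toy genome, plants motifs, draws peaks from the
positional mixture, clusters TSS-anchored signal, runs the width-matched
motif null, calls per-clone DEGs and their consensus, integrates binding,
computes methylation deltas, and returns a JSON-serializable summary with
every headline statistic alongside the planted truth.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, asdict

import numpy as np

from . import core, degs, methylation, motifs, signal
from .simulate import (
    ExpressionDesign,
    GenomeConfig,
    PeakMixtureConfig,
    generate_expression,
    generate_genome,
    generate_methylation,
    generate_peaks,
    plant_motifs,
)

__all__ = ["PipelineConfig", "run_synthetic_demo"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the synthetic demo; unknown keys are rejected on load."""

    seed: int = 0
    run_id: str = "demo"
    # genome
    n_chroms: int = 4
    chrom_length: int = 20_000_000
    n_genes: int = 10_000
    cgi_fraction: float = 0.7
    gc_cgi: float = 0.65
    gc_bg: float = 0.40
    cpg_oe_cgi: float = 0.75
    # peaks / signal
    n_peaks: int = 10_000
    window: int = 3000
    binsize: int = 20
    k: int = 4
    promoter_window: tuple = (1000, 1000)
    # motifs
    motif_long: str = "AGGCCTAG"
    motif_short: str = "GGCCT"
    null_widths: tuple = (20, 200, 2000)
    n_random: int = 5000
    n_top_peaks: int = 5000
    chexmix_flank: int = 10
    # expression
    fc_threshold: float = 1.5
    alpha: float = 0.05
    n_indirect: int = 800
    # methylation
    n_probes: int = 2000
    dm_cutoff: float = 0.2
    detection_p: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("promoter_window", "null_widths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["promoter_window"] = list(d["promoter_window"])
        d["null_widths"] = list(d["null_widths"])
        return d

    def stage_seed(self, stage: str) -> int:
        """Deterministic sub-seed per pipeline stage."""
        return (self.seed * 2_654_435_761 + zlib.crc32(stage.encode())) % (2 ** 31)


def run_synthetic_demo(config: PipelineConfig | None = None) -> dict:
    """Run every stage on generated data; returns the summary report."""
    cfg = config or PipelineConfig()
    report: dict = {"run_id": cfg.run_id, "seed": cfg.seed,
                    "config": cfg.to_dict(), "stages": {}}

    # --- genome + planted motifs -------------------------------------------
    gconf = GenomeConfig(
        n_chroms=cfg.n_chroms, chrom_length=cfg.chrom_length,
        n_genes=cfg.n_genes, cgi_fraction=cfg.cgi_fraction,
        gc_cgi=cfg.gc_cgi, gc_bg=cfg.gc_bg, cpg_oe_cgi=cfg.cpg_oe_cgi,
        seed=cfg.stage_seed("genome"),
    )
    sequences, transcripts, cgi, genome_truth = generate_genome(gconf)
    chrom_sizes = genome_truth["chrom_sizes"]
    sequences, motif_manifest = plant_motifs(
        sequences, cgi, cfg.motif_long, 1, seed=cfg.stage_seed("motifs")
    )
    report["stages"]["genome"] = {
        "n_transcripts": len(transcripts),
        "n_cgi_promoters": len(cgi),
        "planted_motifs": int(len(motif_manifest)),
    }

    # --- peaks, annotation, clustering -------------------------------------
    mix_seq = PeakMixtureConfig.seq_mode(seed=cfg.stage_seed("peaks_seq"))
    peaks, track, peak_truth = generate_peaks(
        transcripts, mix_seq, cfg.n_peaks, chrom_sizes, cfg.binsize
    )
    mix_exo = PeakMixtureConfig.exo_mode(seed=cfg.stage_seed("peaks_exo"))
    exo_peaks, _, _ = generate_peaks(
        transcripts, mix_exo, cfg.n_peaks, chrom_sizes, cfg.binsize
    )
    index = core.TssIndex(transcripts)
    annotations = [
        core.assign_nearest_tss(p, index, cfg.promoter_window, cgi)
        for p in peaks
    ]
    hist = signal.summit_histogram(
        annotations, window=cfg.window, binsize=cfg.binsize
    )
    cgi_bound = {
        a.gene_id for a in annotations
        if a.location_class == "promoter" and a.promoter_class == "CGI"
    }
    report["stages"]["genome"]["n_cgi_bound_promoters"] = len(cgi_bound)
    matrix = signal.build_signal_matrix(
        track, annotations, window=cfg.window, binsize=cfg.binsize
    )
    assignment = signal.kmeans_positional(
        matrix, cfg.k, seed=cfg.stage_seed("kmeans")
    )
    ari_localized = _ari_against_truth(assignment, peak_truth)
    combo = _combination_clusters(assignment, matrix)
    sub = signal.subcluster(matrix, assignment, combo,
                            k=4, seed=cfg.stage_seed("subcluster"))
    sub_modes = {
        f"sub_{i + 1}": float(matrix.bin_centers[int(np.argmax(c))])
        for i, c in enumerate(sub.centroids)
    }
    mean_seq, med_seq, _ = signal.peak_width_stats(peaks)
    mean_exo, med_exo, _ = signal.peak_width_stats(exo_peaks)
    report["stages"]["positional"] = {
        "summit_mode_bp": hist.primary_mode,
        "summit_mode_refined_bp": hist.primary_mode_refined,
        "summit_shoulder_bp": hist.shoulder,
        "cluster_sizes": assignment.sizes,
        "ari_localized_components": ari_localized,
        "combination_clusters": combo,
        "subcluster_semantics": sub.notes,
        "subcluster_modes_bp": sub_modes,
        "mean_width_seq_bp": mean_seq,
        "median_width_seq_bp": med_seq,
        "mean_width_exo_bp": mean_exo,
        "median_width_exo_bp": med_exo,
        "seq_to_exo_width_ratio": mean_seq / mean_exo,
    }

    # --- genome-wide correlation + bound/unbound group signal --------------
    # a second family member binds the same sites with jittered summits and
    # scores; an unrelated noise track provides the null contrast
    rng_rep = np.random.default_rng(cfg.stage_seed("peaks_rep"))
    track2 = signal.BinnedTrack(chrom_sizes, cfg.binsize)
    for p in peaks:
        jitter = int(rng_rep.normal(0, 50))
        summit2 = int(np.clip(p.summit + jitter, 0,
                              chrom_sizes[p.interval.chrom] - 1))
        score2 = p.score * float(np.exp(rng_rep.normal(0, 0.3)))
        track2.add_triangle(p.interval.chrom, summit2, p.width, score2)
    rng_noise = np.random.default_rng(cfg.stage_seed("noise_track"))
    noise = signal.BinnedTrack(chrom_sizes, cfg.binsize)
    for c in noise.values:
        noise.values[c] = rng_noise.exponential(1.0, len(noise.values[c]))
    names, corr = signal.sample_correlation(
        {"factor_a": track, "factor_b": track2, "noise": noise}
    )
    report["stages"]["correlation"] = {
        "samples": names,
        "factor_a_vs_factor_b": float(corr[0, 1]),
        "factor_a_vs_noise": float(corr[0, 2]),
    }

    binding = core.gene_level_binding(
        annotations,
        {i: int(lab) for i, lab in _peak_labels(annotations, assignment)},
        cfg.promoter_window,
    )
    body_track = _gene_body_track(transcripts, binding, chrom_sizes, cfg.binsize)
    prom_matrix = signal.build_signal_matrix(
        body_track, transcripts, window=cfg.window, binsize=cfg.binsize
    )
    bound_genes = [t.transcript_id for t in transcripts if t.gene_id in binding]
    unbound_genes = [t.transcript_id for t in transcripts
                     if t.gene_id not in binding]
    grp = signal.compare_group_signal(prom_matrix, bound_genes, unbound_genes)
    report["stages"]["group_signal"] = {
        "bound_to_unbound_ratio": grp["ratio"], "flagged": grp["flagged"],
    }

    # --- motif null ---------------------------------------------------------
    m_long = motifs.MotifSpec("known_motif", cfg.motif_long)
    m_short = motifs.MotifSpec("short_motif", cfg.motif_short)
    if not cgi:
        report["stages"]["motif_null"] = {"skipped": "no CGI promoters"}
        curve = None
    else:
        curve = motifs.width_coverage_curve(
            cgi, sequences, [m_long, m_short], cfg.null_widths,
            n=cfg.n_random, seed=cfg.stage_seed("motif_null"),
        )
        top, _ = motifs.select_top_peaks(peaks, cfg.n_top_peaks)
        top_cov = motifs.motif_coverage(
            [p.interval for p in top], sequences, [m_long, m_short], "top_peaks"
        )
        exo_top, _ = motifs.select_top_peaks(exo_peaks, cfg.n_top_peaks)
        chex = motifs.chexmix_window_coverage(
            [(p.interval.chrom, p.summit) for p in exo_top], sequences,
            [m_long, m_short], flank=cfg.chexmix_flank,
        )
        report["stages"]["motif_null"] = {
            "random_cgi_coverage": {
                str(w): rep.fractions for w, rep in curve.items()
            },
            "top_peak_coverage": top_cov.fractions,
            "chexmix_window_coverage": chex.fractions,
        }

    # --- expression, consensus, binding integration ------------------------
    direct = sorted({
        row.gene_id for row in peak_truth.itertuples()
        if row.component == "down_near"
        and binding.get(row.gene_id) is not None
    })
    rng_ind = np.random.default_rng(cfg.stage_seed("indirect"))
    unbound_pool = sorted({t.gene_id for t in transcripts} - set(binding))
    indirect = sorted(
        rng_ind.choice(unbound_pool,
                       size=min(cfg.n_indirect, len(unbound_pool)),
                       replace=False)
    )
    design = ExpressionDesign(seed=cfg.stage_seed("expression"))
    gene_ids = sorted({t.gene_id for t in transcripts})
    counts = generate_expression(design, gene_ids, direct, indirect)
    groups = {c: c.rsplit("_rep", 1)[0] for c in counts.columns}
    tables = {
        clone: degs.call_degs(counts, groups, (clone, "control"),
                              cfg.fc_threshold, cfg.alpha)
        for clone in ("DKO_1", "DKO_2", "DKO_3")
    }
    down = degs.consensus_sets(list(tables.values()), "down")
    up = degs.consensus_sets(list(tables.values()), "up")
    direct_set = set(direct)
    called_down_any = down.union
    sens = (len(down.all_clones & direct_set) / len(direct_set)
            if direct_set else float("nan"))
    false_down = {g for g in called_down_any if g not in direct_set}
    fdr = len(false_down) / max(len(called_down_any), 1)
    down_bf = degs.bound_fraction_by_cluster(down.all_clones, binding,
                                             "consensus_down")
    up_bf = degs.bound_fraction_by_cluster(up.all_clones, binding,
                                           "consensus_up")
    report["stages"]["expression"] = {
        "n_direct_planted": len(direct),
        "n_indirect_planted": len(indirect),
        "consensus_down_all": len(down.all_clones),
        "consensus_down_two": len(down.at_least_two),
        "consensus_up_all": len(up.all_clones),
        "consensus_up_two": len(up.at_least_two),
        "deg_sensitivity": sens,
        "deg_fdr": fdr,
        "down_bound_fraction": down_bf.bound_fraction,
        "down_cluster_fractions": {str(k): v for k, v
                                   in down_bf.cluster_fractions.items()},
        "up_bound_fraction": up_bf.bound_fraction,
    }

    # --- rescue / responding promoters -------------------------------------
    rescue_design = ExpressionDesign(
        conditions=("control", "rescue"),
        direct_down_effect=-2.0,  # re-expression turns direct targets up
        indirect_up_effect=0.0,
        affected_prefix="rescue",
        seed=cfg.stage_seed("rescue"),
    )
    rescue_counts = generate_expression(rescue_design, gene_ids, direct, [])
    rescue_groups = {c: c.rsplit("_rep", 1)[0] for c in rescue_counts.columns}
    rescue_table = degs.call_degs(rescue_counts, rescue_groups,
                                  ("rescue", "control"),
                                  cfg.fc_threshold, cfg.alpha)
    rescued_up = set(rescue_table.index[rescue_table["direction"] == "up"])
    bound_down = {g for g in down.all_clones if g in binding}
    responders = degs.responding_promoters(bound_down, rescued_up)
    resp_frac = (len(responders & direct_set) / len(direct_set)
                 if direct_set else float("nan"))
    # motif coverage at responder promoters (2 kb windows around the TSS)
    resp_tx = [t for t in transcripts if t.gene_id in responders]
    resp_regions = [core._promoter_interval(t, (500, 1500)) for t in resp_tx]
    resp_cov = (motifs.motif_coverage(resp_regions, sequences,
                                      [m_long, m_short], "responders")
                if resp_regions else None)
    report["stages"]["rescue"] = {
        "n_rescued_up": len(rescued_up),
        "n_responding_promoters": len(responders),
        "responder_recovery_of_direct": resp_frac,
        "responder_motif_coverage":
            resp_cov.fractions if resp_cov else {},
    }

    # --- methylation --------------------------------------------------------
    probes, probe_truth = generate_methylation(
        transcripts, n_probes=cfg.n_probes, seed=cfg.stage_seed("methylation"),
    )
    prom_probes = methylation.select_promoter_probes(probes, transcripts)
    delta = methylation.delta_beta_table(
        prom_probes, p_cut=cfg.detection_p, cutoff=cfg.dm_cutoff
    )
    planted = set(probe_truth["planted_probes"]) & set(delta.index)
    hypo = set(delta.index[delta["call"] == "hypomethylated"])
    report["stages"]["methylation"] = {
        "n_probes": int(len(probes)),
        "n_promoter_probes": int(len(prom_probes)),
        "n_hypomethylated": int(len(hypo)),
        "n_hypermethylated": int((delta["call"] == "hypermethylated").sum()),
        "planted_hypo_recovery": (len(hypo & planted) / len(planted)
                                  if planted else float("nan")),
    }
    return report


def _peak_labels(annotations, assignment):
    """Yield (annotation index, cluster label) for rows kept by clustering."""
    lab_by_id = dict(zip(assignment.row_ids, assignment.labels))
    for i, ann in enumerate(annotations):
        lab = lab_by_id.get(ann.peak.sample_id)
        if lab is not None:
            yield i, lab


def _ari_against_truth(assignment, peak_truth) -> float:
    """ARI of cluster labels vs planted components, scored over the four
    localized components; diffuse rows carry no positional identity a
    k=4 shape clustering could recover, so they are excluded from the
    truth comparison."""
    from sklearn.metrics import adjusted_rand_score

    comp = dict(zip(peak_truth["peak_id"], peak_truth["component"]))
    pairs = [
        (comp[rid], lab)
        for rid, lab in zip(assignment.row_ids, assignment.labels)
        if comp.get(rid) not in (None, "diffuse")
    ]
    truth, labels = zip(*pairs)
    return float(adjusted_rand_score(truth, labels))


def _combination_clusters(assignment, matrix) -> list[int]:
    """Clusters playing the 'combination' role: centroid modes beyond
    +/-1 kb of the TSS (the far/diffuse material). Falls back to the
    single farthest-mode cluster when none pass the cutoff."""
    centers = matrix.bin_centers
    modes = [abs(float(centers[int(np.argmax(c))]))
             for c in assignment.centroids]
    far = [i + 1 for i, m in enumerate(modes) if m > 1000]
    return far or [int(np.argmax(modes)) + 1]


def _gene_body_track(transcripts, binding, chrom_sizes, binsize):
    """Elongation-mark-like coverage: flat signal over each gene body,
    3x higher at genes with a bound promoter."""
    track = signal.BinnedTrack(chrom_sizes, binsize)
    for t in transcripts:
        height = 3.0 if t.gene_id in binding else 1.0
        vals = track.values[t.chrom]
        lo = t.interval.start // binsize
        hi = min(len(vals), -(-t.interval.end // binsize))
        vals[lo:hi] += height
    return track
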