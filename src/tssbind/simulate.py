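"""Synthetic toy genome, binding peaks, expression counts and methylation.

Everything here is driven by a seed and emulates the statistical structure
the downstream analyses assume: CpG-island promoters with elevated GC and
CpG density on an otherwise uniform background, stranded gene models with
5'UTR / first coding exon / first intron, peaks drawn from a TSS-relative
positional mixture (near modes at +/-240 bp, far modes at +/-2 kb, a
diffuse component), negative-binomial counts with planted direct
(down-in-DKO, bound downstream) and indirect (up-in-DKO, unbound) targets,
and paired methylated/unmethylated probe intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, PeakCall, TranscriptModel

__all__ = [
    "GenomeConfig",
    "PeakMixtureConfig",
    "ExpressionDesign",
    "generate_genome",
    "plant_motifs",
    "generate_peaks",
    "generate_expression",
    "generate_methylation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed toy gene anatomy (bp, transcription order):
# 5'UTR 200 | CDS exon 300 | intron 800 | CDS exon 400 | intron 600 | CDS exon 700
_UTR5_LEN = 200
_STRUCT = [("utr5", 200), ("cds", 300), ("intron", 800), ("cds", 400),
           ("intron", 600), ("cds", 700)]
_BODY_LEN = sum(n for _, n in _STRUCT)


@dataclass(frozen=True)
class GenomeConfig:
    """Toy genome layout and composition.

    ``cgi_fraction`` of promoters carry a CpG island spanning [-500, +1500)
    around the TSS with GC fraction ``gc_cgi`` and CpG observed/expected
    ``cpg_oe_cgi``; elsewhere bases are i.i.d. at ``gc_bg``.
    """

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 400
    cgi_fraction: float = 0.7
    gc_cgi: float = 0.65
    gc_bg: float = 0.40
    cpg_oe_cgi: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc_bg < self.gc_cgi < 1):
            raise ValueError("require 0 < gc_bg < gc_cgi < 1")
        if not (0 <= self.cgi_fraction <= 1):
            raise ValueError("cgi_fraction in [0,1]")
        if self.chrom_length <= 0 or self.n_genes <= 0 or self.n_chroms <= 0:
            raise ValueError("sizes must be positive")


def _stationary(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def _cgi_transition(gc: float, oe: float) -> np.ndarray:
    """First-order transition matrix with stationary distribution exactly
    the configured base frequencies and P(CpG) = oe * pi_C * pi_G.

    The joint dinucleotide law is the independent product reweighted at
    (C,G) with compensating mass shifted along the C row and G column so
    both marginals stay at pi; the chain is then Q normalized by rows.
    """
    pi = _stationary(gc)
    C, G = 1, 2
    q = np.outer(pi, pi)
    d = (1 - oe)
    q[C, G] = oe * pi[C] * pi[G]
    for j in range(4):
        if j != G:
            q[C, j] = pi[C] * pi[j] * (1 + d * pi[G] / (1 - pi[G]))
    for i in range(4):
        if i != C:
            q[i, G] = pi[i] * pi[G] * (1 + d * pi[C] / (1 - pi[C]))
            for j in range(4):
                if j != G:
                    q[i, j] = pi[i] * pi[j] * (
                        1 - d * pi[C] * pi[G] / ((1 - pi[C]) * (1 - pi[G]))
                    )
    if (q < 0).any():
        raise ValueError("CpG o/e incompatible with base composition")
    return q / q.sum(axis=1, keepdims=True)


def _sample_markov(rng, P: np.ndarray, pi: np.ndarray, n_seq: int, length: int) -> np.ndarray:
    """n_seq Markov chains of the given length, vectorized across chains."""
    cum = np.cumsum(P, axis=1)
    out = np.empty((n_seq, length), dtype=np.uint8)
    out[:, 0] = rng.choice(4, size=n_seq, p=pi)
    u = rng.random((n_seq, length))
    for j in range(1, length):
        rows = cum[out[:, j - 1]]
        out[:, j] = (u[:, j, None] > rows).sum(axis=1)
    return out


def _promoter_region(tss: int, strand: str, up: int, down: int, chrom_len: int,
                     chrom: str) -> GenomicInterval:
    if strand == "+":
        start, end = tss - up, tss + down
    else:
        start, end = tss - down + 1, tss + up + 1
    return GenomicInterval(chrom, max(0, start), min(chrom_len, end), strand)


def generate_genome(config: GenomeConfig):
    """Build sequences, transcript models and CpG-island intervals.

    Returns ``(sequences, transcripts, cgi, truth)`` where ``sequences`` is
    a chrom -> str dict and ``truth`` records which genes got a CGI
    promoter. Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    margin = 4000  # keeps +/-3 kb windows and CGI intervals inside bounds
    transcripts, cgi, cgi_genes = [], [], []
    gid = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        n = per_chrom[ci]
        if n == 0:
            continue
        spacing = (config.chrom_length - 2 * margin) // n
        if spacing < _BODY_LEN + margin:
            need = n - (config.chrom_length - 2 * margin) // (_BODY_LEN + margin)
            raise ValueError(
                f"cannot place {n} non-overlapping genes on {chrom}: "
                f"{max(need, 1)} too many for length {config.chrom_length}"
            )
        for k in range(n):
            start = margin + k * spacing
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            transcripts.append(_make_transcript(chrom, start, strand, gid))
    is_cgi = rng.random(len(transcripts)) < config.cgi_fraction
    for t, flag in zip(transcripts, is_cgi):
        if flag:
            cgi_genes.append(t.gene_id)
            cgi.append(
                _promoter_region(t.tss, t.strand, 500, 1500,
                                 config.chrom_length, t.chrom)
            )
    # sequence: i.i.d. background, then Markov-resampled islands
    pi_bg = _stationary(config.gc_bg)
    pi_cgi = _stationary(config.gc_cgi)
    P_cgi = _cgi_transition(config.gc_cgi, config.cpg_oe_cgi)
    seqs = {}
    arrs = {}
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        arrs[chrom] = rng.choice(4, size=config.chrom_length, p=pi_bg).astype(np.uint8)
    islands_by_len: dict[int, list[GenomicInterval]] = {}
    for iv in cgi:
        islands_by_len.setdefault(len(iv), []).append(iv)
    for length, ivs in sorted(islands_by_len.items()):
        block = _sample_markov(rng, P_cgi, pi_cgi, len(ivs), length)
        for row, iv in zip(block, ivs):
            arrs[iv.chrom][iv.start:iv.end] = row
    for chrom, arr in arrs.items():
        seqs[chrom] = np.take(_BASES, arr).tobytes().decode()
    truth = {"cgi_genes": cgi_genes,
             "chrom_sizes": {c: config.chrom_length for c in seqs}}
    return seqs, transcripts, cgi, truth


def _make_transcript(chrom: str, start: int, strand: str, gid: int) -> TranscriptModel:
    parts = []
    pos = start
    for kind, length in _STRUCT:
        parts.append((kind, pos, pos + length))
        pos += length
    end = pos
    if strand == "-":
        parts = [(kind, start + (end - e), start + (end - s)) for kind, s, e in parts]
    def ivs(kind):
        sel = [GenomicInterval(chrom, s, e, strand) for k, s, e in parts if k == kind]
        return tuple(sorted(sel, key=lambda x: x.start if strand == "+" else -x.end))
    return TranscriptModel(
        gene_id=f"gene_{gid:05d}",
        transcript_id=f"tx_{gid:05d}",
        interval=GenomicInterval(chrom, start, end, strand),
        utr5=ivs("utr5"),
        cds_exons=ivs("cds"),
        introns=ivs("intron"),
    )


def plant_motifs(sequences: dict[str, str], regions, motif: str,
                 count_per_region: int = 1, seed: int = 0):
    """Overwrite ``count_per_region`` non-overlapping sites per region with
    the motif (forward strand). Returns (sequences, manifest DataFrame)."""
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over A/C/G/T")
    rng = np.random.default_rng(seed)
    m = len(motif)
    muts: dict[str, bytearray] = {}
    rows = []
    for iv in regions:
        if count_per_region == 0:
            continue
        width = len(iv)
        if width < count_per_region * m:
            raise ValueError(
                f"region {iv.chrom}:{iv.start}-{iv.end} too small for "
                f"{count_per_region} x {m} nt motif"
            )
        placed: list[int] = []
        attempts = 0
        while len(placed) < count_per_region:
            attempts += 1
            if attempts > 1000 * count_per_region:
                raise ValueError("cannot place non-overlapping motifs")
            p = iv.start + int(rng.integers(0, width - m + 1))
            if all(abs(p - q) >= m for q in placed):
                placed.append(p)
        if iv.chrom not in muts:
            muts[iv.chrom] = bytearray(sequences[iv.chrom], "ascii")
        for p in sorted(placed):
            muts[iv.chrom][p:p + m] = motif.encode()
            rows.append({"chrom": iv.chrom, "pos": p, "motif": motif, "strand": "+"})
    out = dict(sequences)
    for chrom, buf in muts.items():
        out[chrom] = buf.decode()
    manifest = pd.DataFrame(rows, columns=["chrom", "pos", "motif", "strand"])
    return out, manifest


# ---------------------------------------------------------------------------
# peaks

_COMPONENTS = ("down_near", "up_near", "down_far", "up_far", "diffuse")


@dataclass(frozen=True)
class PeakMixtureConfig:
    """TSS-relative positional mixture and peak shape parameters.

    Near modes sit at +/-240 bp, far modes at +/-2 kb, plus a diffuse
    uniform component; weights echo the relative sizes of the four
    positional peak classes seen in TF ChIP data at CpG-island promoters.
    Widths are log-normal: median ~1800 bp for ChIP-seq-like peaks and
    ~300 bp in exo mode. Scores are gamma with the downstream-near
    component strongest so amplitude ordering is part of the truth.
    """

    weights: tuple = (0.25, 0.15, 0.10, 0.10, 0.40)
    down_near: tuple = (240.0, 120.0)
    up_near: tuple = (-240.0, 120.0)
    down_far: tuple = (2000.0, 300.0)
    up_far: tuple = (-2000.0, 300.0)
    diffuse_range: tuple = (-3000.0, 3000.0)
    width_median: float = 1800.0
    width_sigma: float = 0.25
    score_scale: tuple = (30.0, 12.0, 8.0, 8.0, 5.0)
    score_shape: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if (w < 0).any() or abs(w.sum() - 1) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")
        for name in ("down_near", "up_near", "down_far", "up_far"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sd must be >= 0")

    @classmethod
    def seq_mode(cls, **kw) -> "PeakMixtureConfig":
        return cls(**kw)

    @classmethod
    def exo_mode(cls, **kw) -> "PeakMixtureConfig":
        kw.setdefault("width_median", 300.0)
        return cls(**kw)


class BinnedTrack:
    """Genome-wide coverage held as fixed-width bins per chromosome."""

    def __init__(self, chrom_sizes: dict[str, int], binsize: int = 20):
        self.binsize = binsize
        self.values = {
            c: np.zeros(-(-size // binsize)) for c, size in chrom_sizes.items()
        }

    def add_triangle(self, chrom: str, summit: int, width: float, height: float) -> None:
        """Deposit a triangular kernel of the peak's width, centered on the summit."""
        vals = self.values[chrom]
        b = self.binsize
        half = width / 2
        lo = max(0, int((summit - half) // b))
        hi = min(len(vals) - 1, int((summit + half) // b))
        centers = (np.arange(lo, hi + 1) + 0.5) * b
        vals[lo:hi + 1] += height * np.maximum(0.0, 1 - np.abs(centers - summit) / half)

    def value_at(self, chrom: str, pos: int) -> float:
        vals = self.values.get(chrom)
        if vals is None:
            return 0.0
        i = pos // self.binsize
        return float(vals[i]) if 0 <= i < len(vals) else 0.0


def generate_peaks(transcripts, mixture: PeakMixtureConfig, n_peaks: int,
                   chrom_sizes: dict[str, int], coverage_binsize: int = 20):
    """Draw peaks from the positional mixture anchored at transcript TSSs.

    Each peak gets a latent component label (kept in the returned truth
    table for evaluation) and a summit drawn TSS-relative then mapped
    through the anchor's strand. When ``n_peaks`` does not exceed the
    transcript count, anchors are sampled without replacement so every
    peak interrogates a distinct promoter, as in an IDR-deduplicated peak
    list; otherwise anchors repeat. Coverage is the sum of score-scaled
    triangular kernels on the summits.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks >= 1")
    transcripts = list(transcripts)
    rng = np.random.default_rng(mixture.seed)
    if n_peaks <= len(transcripts):
        anchor_idx = rng.permutation(len(transcripts))[:n_peaks]
    else:
        anchor_idx = rng.integers(0, len(transcripts), size=n_peaks)
    comp = rng.choice(len(_COMPONENTS), size=n_peaks, p=mixture.weights)
    offsets = np.empty(n_peaks)
    for k, name in enumerate(_COMPONENTS):
        sel = comp == k
        if name == "diffuse":
            offsets[sel] = rng.uniform(*mixture.diffuse_range, size=sel.sum())
        else:
            mu, sd = getattr(mixture, name)
            offsets[sel] = rng.normal(mu, sd, size=sel.sum())
    widths = rng.lognormal(np.log(mixture.width_median), mixture.width_sigma, n_peaks)
    scores = rng.gamma(mixture.score_shape,
                       np.asarray(mixture.score_scale)[comp] / mixture.score_shape)
    peaks, rows = [], []
    track = BinnedTrack(chrom_sizes, coverage_binsize)
    for i in range(n_peaks):
        t = transcripts[anchor_idx[i]]
        size = chrom_sizes[t.chrom]
        off = offsets[i]
        for attempt in range(100):
            summit = int(round(t.tss + off if t.strand == "+" else t.tss - off))
            if 0 <= summit < size:
                break
            off = _redraw_offset(rng, mixture, int(comp[i]))
        else:
            raise RuntimeError("summit redraw cap exceeded")
        w = max(2, int(round(widths[i])))
        start = max(0, summit - w // 2)
        end = min(size, start + w)
        start = min(start, summit)  # keep summit inside after clipping
        iv = GenomicInterval(t.chrom, start, max(end, summit + 1))
        peak = PeakCall(iv, summit, float(scores[i]), sample_id=f"peak_{i:05d}")
        peaks.append(peak)
        track.add_triangle(t.chrom, summit, w, float(scores[i]))
        rows.append({
            "peak_id": peak.sample_id, "component": _COMPONENTS[comp[i]],
            "transcript_id": t.transcript_id, "gene_id": t.gene_id,
            "offset": float(off), "width": w, "score": float(scores[i]),
        })
    return peaks, track, pd.DataFrame(rows)


def _redraw_offset(rng, mixture, k: int) -> float:
    name = _COMPONENTS[k]
    if name == "diffuse":
        return float(rng.uniform(*mixture.diffuse_range))
    mu, sd = getattr(mixture, name)
    return float(rng.normal(mu, sd))


# ---------------------------------------------------------------------------
# expression

@dataclass(frozen=True)
class ExpressionDesign:
    """Replicated count design: control, two single-KO clones, three DKO clones.

    Direct targets (downstream-bound promoters) are scaled down by
    2**direct_down_effect in the DKO clones; a disjoint unbound indirect
    set is scaled up by 2**indirect_up_effect. Everything else is
    exchangeable across conditions.
    """

    conditions: tuple = ("control", "KO_A", "KO_B", "DKO_1", "DKO_2", "DKO_3")
    replicates: int = 3
    baseline_mean: float = 500.0
    baseline_log2_sd: float = 0.8
    dispersion: float = 0.05
    direct_down_effect: float = 2.0
    indirect_up_effect: float = 1.0
    affected_prefix: str = "DKO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion > 0")


def generate_expression(design: ExpressionDesign, gene_ids,
                        direct_genes, indirect_genes) -> pd.DataFrame:
    """Negative-binomial counts (genes x samples) with planted DKO effects."""
    direct = set(direct_genes)
    indirect = set(indirect_genes)
    if direct & indirect:
        raise ValueError("direct and indirect target sets must be disjoint")
    gene_ids = list(gene_ids)
    rng = np.random.default_rng(design.seed)
    base = design.baseline_mean * 2 ** rng.normal(
        0, design.baseline_log2_sd, len(gene_ids)
    )
    cols, names = [], []
    is_direct = np.array([g in direct for g in gene_ids])
    is_indirect = np.array([g in indirect for g in gene_ids])
    r = 1.0 / design.dispersion
    for cond in design.conditions:
        mu = base.copy()
        if cond.startswith(design.affected_prefix):
            mu[is_direct] *= 2.0 ** (-design.direct_down_effect)
            mu[is_indirect] *= 2.0 ** (design.indirect_up_effect)
        for rep in range(1, design.replicates + 1):
            p = r / (r + mu)
            cols.append(rng.negative_binomial(r, p))
            names.append(f"{cond}_rep{rep}")
    return pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=names)


# ---------------------------------------------------------------------------
# methylation

def generate_methylation(transcripts, n_probes: int = 2000, base_beta: float = 0.75,
                         planted_delta: float = -0.3, n_planted: int = 100,
                         noise_sd: float = 0.02, intensity: float = 1000.0,
                         flagged_fraction: float = 0.01, n_reps: int = 2,
                         seed: int = 0):
    """Paired M/U probe intensities for wt and DKO with planted beta shifts.

    Probes are placed uniformly in promoter windows ([-1500, end of first
    coding exon]) of random transcripts. The first ``n_planted`` probes
    get ``planted_delta`` added to their DKO beta; a ``flagged_fraction``
    of probe/sample entries receive detection p-values above 0.05.
    M = round(I * beta * e) and U = round(I * (1 - beta) * e') with
    independent log-normal multiplicative noise e, e'.
    Returns (table, truth) where truth lists planted probe ids.
    """
    transcripts = list(transcripts)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(transcripts), size=n_probes)
    pos = np.empty(n_probes, dtype=int)
    for i, ti in enumerate(idx):
        t = transcripts[ti]
        if t.strand == "+":
            lo, hi = t.tss - 1500, t.cds_exons[0].end - 1
        else:
            lo, hi = t.cds_exons[0].start, t.tss + 1500
        pos[i] = rng.integers(lo, hi + 1)
    beta_wt = np.clip(rng.normal(base_beta, 0.05, n_probes), 0.02, 0.98)
    beta_ko = beta_wt.copy()
    planted = np.arange(min(n_planted, n_probes))
    beta_ko[planted] = np.clip(beta_ko[planted] + planted_delta, 0.0, 1.0)
    probe_ids = [f"cg{i:06d}" for i in range(n_probes)]
    data = {"probe": probe_ids,
            "chrom": [transcripts[ti].chrom for ti in idx],
            "pos": pos}
    for cond, beta in (("wt", beta_wt), ("dko", beta_ko)):
        for rep in range(1, n_reps + 1):
            e1 = np.exp(rng.normal(0, noise_sd, n_probes)) if noise_sd > 0 else 1.0
            e2 = np.exp(rng.normal(0, noise_sd, n_probes)) if noise_sd > 0 else 1.0
            M = np.round(intensity * beta * e1)
            U = np.round(intensity * (1 - beta) * e2)
            detp = rng.uniform(0.0001, 0.01, n_probes)
            flagged = rng.random(n_probes) < flagged_fraction
            detp[flagged] = rng.uniform(0.051, 0.5, flagged.sum())
            s = f"{cond}_{rep}"
            data[f"M_{s}"], data[f"U_{s}"], data[f"detp_{s}"] = M, U, detp
    table = pd.DataFrame(data)
    truth = {"planted_probes": [probe_ids[i] for i in planted],
             "planted_delta": planted_delta}
    return table, truth
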