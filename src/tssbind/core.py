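"""Coordinate conventions, gene models, and TSS-relative peak geometry.

All coordinates are 0-based, half-open (BED convention). Distances to a
transcription start site (TSS) are signed in the transcription direction:
positive means downstream of the TSS, so a summit 240 bp into the
transcribed region of a minus-strand gene has distance +240.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnnotationError",
    "GenomicInterval",
    "TranscriptModel",
    "PeakCall",
    "TssAnnotation",
    "TssIndex",
    "tss_distance",
    "assign_nearest_tss",
    "classify_peak_location",
    "classify_cgi_promoter",
    "classify_gene_region",
    "gene_level_binding",
]


class AnnotationError(ValueError):
    """Raised for impossible annotation requests (wrong chromosome, empty inputs)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.': {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share >= 1 bp (half-open algebra)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with resolved 5'UTR / CDS-exon / intron structure.

    ``utr5``, ``cds_exons`` and ``introns`` are ordered in the transcription
    direction, so ``cds_exons[0]`` is the first coding exon and
    ``introns[0]`` the first intron regardless of strand.
    """

    gene_id: str
    transcript_id: str
    interval: GenomicInterval
    utr5: tuple = ()
    cds_exons: tuple = ()
    introns: tuple = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("transcripts must be stranded")
        object.__setattr__(self, "utr5", tuple(self.utr5))
        object.__setattr__(self, "cds_exons", tuple(self.cds_exons))
        object.__setattr__(self, "introns", tuple(self.introns))

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Strand-aware 5' end: interval.start on '+', interval.end - 1 on '-'."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class PeakCall:
    """A called binding site: interval, point of maximal enrichment, score."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside {self.interval.chrom}:"
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def width(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class TssAnnotation:
    """A peak annotated against its nearest TSS."""

    peak: PeakCall
    nearest_tss: str  # transcript_id
    gene_id: str
    distance: int  # signed, downstream-positive
    tss_pos: int
    tss_strand: str
    location_class: str = ""  # 'promoter' | 'non-promoter'
    promoter_class: str = ""  # 'CGI' | 'non-CGI' (only when promoter)


def tss_distance(summit: int, transcript: TranscriptModel, chrom: str | None = None) -> int:
    """Signed distance from a TSS to a summit, positive downstream.

    ``chrom``, when given, is checked against the transcript's chromosome;
    a mismatch is an annotation error rather than a silently wrong number.
    """
    if chrom is not None and chrom != transcript.chrom:
        raise AnnotationError(
            f"summit on {chrom} but transcript {transcript.transcript_id} "
            f"on {transcript.chrom}"
        )
    if transcript.strand == "+":
        return summit - transcript.tss
    return transcript.tss - summit


class TssIndex:
    """Sorted per-chromosome TSS positions for O(log n) nearest lookups.

    Ties on |distance| are broken toward the lexicographically smallest
    transcript_id so annotation is deterministic.
    """

    def __init__(self, transcripts) -> None:
        transcripts = list(transcripts)
        if not transcripts:
            raise AnnotationError("empty transcript set")
        self.transcripts = {t.transcript_id: t for t in transcripts}
        by_chrom: dict[str, list] = {}
        for t in transcripts:
            by_chrom.setdefault(t.chrom, []).append(t)
        self._pos: dict[str, list[int]] = {}
        self._tx: dict[str, list[TranscriptModel]] = {}
        for chrom, txs in by_chrom.items():
            txs.sort(key=lambda t: (t.tss, t.transcript_id))
            self._pos[chrom] = [t.tss for t in txs]
            self._tx[chrom] = txs

    def chromosomes(self):
        return set(self._pos)

    def nearest(self, chrom: str, pos: int) -> TranscriptModel | None:
        """Transcript whose TSS minimizes |pos - tss|; None if chrom unknown."""
        positions = self._pos.get(chrom)
        if positions is None:
            return None
        txs = self._tx[chrom]
        i = bisect_left(positions, pos)
        # candidates straddle the insertion point; widen to absorb duplicate
        # TSS positions so the transcript_id tie-break sees all of them
        lo, hi = max(0, i - 1), min(len(txs), i + 1)
        while lo > 0 and positions[lo - 1] == positions[lo]:
            lo -= 1
        while hi < len(txs) and positions[hi - 1] == positions[hi]:
            hi += 1
        best = min(
            txs[lo:hi],
            key=lambda t: (abs(pos - t.tss), t.transcript_id),
        )
        return best


def assign_nearest_tss(
    peak: PeakCall,
    transcripts,
    promoter_window: tuple[int, int] = (1000, 1000),
    cgi=None,
    cgi_window: tuple[int, int] | None = None,
) -> TssAnnotation:
    """Annotate a peak with its nearest TSS, signed distance, and classes.

    ``transcripts`` may be a TssIndex or any iterable of TranscriptModel.
    When ``cgi`` intervals are supplied, promoter peaks are further classed
    CGI / non-CGI using ``cgi_window`` (default: the promoter window).
    """
    index = transcripts if isinstance(transcripts, TssIndex) else TssIndex(transcripts)
    chrom = peak.interval.chrom
    t = index.nearest(chrom, peak.summit)
    if t is None:
        raise AnnotationError(f"no transcript on chromosome {chrom}")
    dist = tss_distance(peak.summit, t, chrom=chrom)
    loc = classify_peak_location(dist, promoter_window)
    promoter_class = ""
    if loc == "promoter" and cgi is not None:
        promoter_class = classify_cgi_promoter(t, cgi, cgi_window or promoter_window)
    return TssAnnotation(
        peak=peak,
        nearest_tss=t.transcript_id,
        gene_id=t.gene_id,
        distance=dist,
        tss_pos=t.tss,
        tss_strand=t.strand,
        location_class=loc,
        promoter_class=promoter_class,
    )


def classify_peak_location(
    distance: int | TssAnnotation, promoter_window: tuple[int, int] = (1000, 1000)
) -> str:
    """'promoter' iff -upstream <= distance <= +downstream (inclusive)."""
    if isinstance(distance, TssAnnotation):
        distance = distance.distance
    up, down = promoter_window
    if up <= 0 or down <= 0:
        raise ValueError("promoter window extents must be > 0")
    return "promoter" if -up <= distance <= down else "non-promoter"


def _promoter_interval(
    transcript: TranscriptModel, window: tuple[int, int]
) -> GenomicInterval:
    """Genomic interval of (upstream, downstream) around the TSS, strand-aware."""
    up, down = window
    tss = transcript.tss
    if transcript.strand == "+":
        start, end = tss - up, tss + down
    else:
        start, end = tss - down + 1, tss + up + 1
    start = max(0, start)
    return GenomicInterval(transcript.chrom, start, end, transcript.strand)


def classify_cgi_promoter(
    transcript: TranscriptModel, cgi, window: tuple[int, int] = (1000, 1000)
) -> str:
    """'CGI' iff the promoter window overlaps >= 1 bp of a CpG island."""
    prom = _promoter_interval(transcript, window)
    for island in cgi:
        if prom.overlaps(island):
            return "CGI"
    return "non-CGI"


def classify_gene_region(summit: int, transcript: TranscriptModel) -> str:
    """Place a summit within gene structure.

    Categories: 5'UTR, first_coding_exon, first_intron, other_transcribed,
    upstream, intergenic. When sub-features overlap (unusual in clean
    models) the priority is 5'UTR > first_coding_exon > first_intron.
    Transcripts without CDS collapse to 5'-exonic / first_intron /
    other_transcribed.
    """
    for iv in transcript.utr5:
        if iv.contains(summit):
            return "5'UTR" if transcript.cds_exons else "5'-exonic"
    if transcript.cds_exons and transcript.cds_exons[0].contains(summit):
        return "first_coding_exon"
    if transcript.introns and transcript.introns[0].contains(summit):
        return "first_intron"
    if transcript.interval.contains(summit):
        return "other_transcribed"
    d = tss_distance(summit, transcript)
    if d < 0:
        return "upstream"
    return "intergenic"


def gene_level_binding(
    annotations,
    cluster_labels: dict | None = None,
    promoter_window: tuple[int, int] = (1000, 1000),
) -> dict[str, int]:
    """Reduce peak annotations to a gene -> cluster-label binding table.

    A gene is bound when any of its transcripts' promoter windows contains
    a peak summit. With per-peak ``cluster_labels`` (peak index -> label,
    1 = strongest), a multiply-bound gene takes the label of its
    highest-scoring promoter peak; without labels, bound genes map to 1.
    """
    bound: dict[str, tuple[float, int]] = {}
    for i, ann in enumerate(annotations):
        if classify_peak_location(ann.distance, promoter_window) != "promoter":
            continue
        label = 1 if cluster_labels is None else cluster_labels.get(i, 0)
        if label == 0:
            continue
        score = ann.peak.score
        prev = bound.get(ann.gene_id)
        if prev is None or score > prev[0]:
            bound[ann.gene_id] = (score, label)
    return {g: lab for g, (_, lab) in bound.items()}
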