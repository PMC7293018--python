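"""Readers and writers for the text formats the pipeline consumes and emits.

BED-family files are 0-based half-open as on disk; GTF is 1-based closed
on disk and converted on read (start - 1). Malformed lines raise
``FormatError`` naming the line; out-of-range coordinates are rejected,
never coerced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomicInterval, PeakCall, TranscriptModel

__all__ = [
    "FormatError",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_counts_tsv",
    "write_tsv",
    "write_annotations_tsv",
    "write_json",
]


class FormatError(ValueError):
    pass


def _fail(path, lineno, msg):
    raise FormatError(f"{path}:{lineno}: {msg}")


def read_bed(path) -> list[GenomicInterval]:
    """BED3/BED6; strand taken from column 6 when present."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                _fail(path, lineno, "fewer than 3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(f[0], start, end, strand))
            except ValueError as e:
                _fail(path, lineno, str(e))
    return out


def write_bed(path, intervals, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_narrowpeak(path) -> list[PeakCall]:
    """ENCODE narrowPeak (10 columns). Summit = start + column-10 offset;
    an offset of -1 (not called) falls back to the interval midpoint."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                _fail(path, lineno, "narrowPeak requires 10 columns")
            try:
                start, end = int(f[1]), int(f[2])
                score = float(f[6])  # signalValue
                offset = int(f[9])
            except ValueError:
                _fail(path, lineno, "bad numeric field")
            summit = start + offset if offset >= 0 else (start + end) // 2
            try:
                iv = GenomicInterval(f[0], start, end, ".")
                peaks.append(PeakCall(iv, summit, score, sample_id=f[3]))
            except ValueError as e:
                _fail(path, lineno, str(e))
    return peaks


def write_narrowpeak(path, peaks) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.sample_id or '.'}\t0\t.\t"
                f"{p.score:g}\t-1\t-1\t{p.summit - iv.start}\n"
            )


def _gtf_attrs(s: str) -> dict:
    attrs = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip('"')
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """GENCODE-dialect GTF -> transcript models with resolved structure.

    Uses transcript / exon / CDS / five_prime_utr features; introns are the
    gaps between exons. Lists are ordered in the transcription direction.
    """
    tx_iv: dict[str, GenomicInterval] = {}
    tx_gene: dict[str, str] = {}
    feats: dict[str, dict[str, list]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                _fail(path, lineno, "GTF requires 9 columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attr_s = f
            try:
                start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            if start < 0 or start >= end:
                _fail(path, lineno, f"bad coordinates [{start_s}, {end_s}]")
            attrs = _gtf_attrs(attr_s)
            tid = attrs.get("transcript_id")
            if ftype == "gene" or tid is None:
                continue
            iv = GenomicInterval(chrom, start, end, strand)
            if ftype == "transcript":
                tx_iv[tid] = iv
                tx_gene[tid] = attrs.get("gene_id", tid)
            elif ftype in ("exon", "CDS", "five_prime_utr"):
                feats.setdefault(tid, {}).setdefault(ftype, []).append(iv)
                tx_gene.setdefault(tid, attrs.get("gene_id", tid))
    out = []
    for tid, iv in tx_iv.items():
        fwd = iv.strand == "+"
        def orient(ivs):
            return tuple(sorted(ivs, key=lambda x: x.start if fwd else -x.end))
        sub = feats.get(tid, {})
        exons = sorted(sub.get("exon", []), key=lambda x: x.start)
        introns = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                introns.append(GenomicInterval(iv.chrom, a.end, b.start, iv.strand))
        out.append(
            TranscriptModel(
                gene_id=tx_gene[tid],
                transcript_id=tid,
                interval=iv,
                utr5=orient(sub.get("five_prime_utr", [])),
                cds_exons=orient(sub.get("CDS", [])),
                introns=orient(introns),
            )
        )
    out.sort(key=lambda t: (t.chrom, t.interval.start, t.transcript_id))
    return out


def write_gtf(path, transcripts, source="tssbind") -> None:
    def line(iv, ftype, t):
        return (
            f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\tgene_id \"{t.gene_id}\"; transcript_id \"{t.transcript_id}\";\n"
        )
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(line(t.interval, "transcript", t))
            # exons = 5'UTR + CDS merged per contiguity; written piecewise is
            # enough for round-trip since introns come from exon gaps
            exonic = sorted(
                [*t.utr5, *t.cds_exons], key=lambda x: x.start
            )
            merged = []
            for iv in exonic:
                if merged and iv.start <= merged[-1].end:
                    last = merged.pop()
                    iv = GenomicInterval(
                        iv.chrom, last.start, max(last.end, iv.end), iv.strand
                    )
                merged.append(iv)
            for iv in merged:
                fh.write(line(iv, "exon", t))
            for iv in t.cds_exons:
                fh.write(line(iv, "CDS", t))
            for iv in t.utr5:
                fh.write(line(iv, "five_prime_utr", t))


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                _fail(path, lineno, "bedGraph requires 4 columns")
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError:
                _fail(path, lineno, "bad numeric field")
            if start < 0 or start >= end:
                _fail(path, lineno, "bad coordinates")
            out.append((f[0], start, end, value))
    return out


def write_bedgraph(path, track) -> None:
    """Write a BinnedTrack (see tssbind.signal); zero runs are compacted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            b = track.binsize
            start = 0
            for i, v in enumerate(vals):
                if i + 1 < len(vals) and vals[i + 1] == v:
                    continue
                if v != 0:
                    fh.write(f"{chrom}\t{start}\t{(i + 1) * b}\t{v:g}\n")
                start = (i + 1) * b
    # runs of equal value are emitted as single records; zeros are dropped


def read_counts_tsv(path) -> pd.DataFrame:
    """Genes x samples count table: first column gene id, header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_tsv(path, df: pd.DataFrame, index=True) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_annotations_tsv(path, annotations) -> None:
    rows = [
        {
            "chrom": a.peak.interval.chrom,
            "start": a.peak.interval.start,
            "end": a.peak.interval.end,
            "summit": a.peak.summit,
            "score": a.peak.score,
            "nearest_tss": a.nearest_tss,
            "gene_id": a.gene_id,
            "distance": a.distance,
            "tss_pos": a.tss_pos,
            "tss_strand": a.tss_strand,
            "location_class": a.location_class,
            "promoter_class": a.promoter_class,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
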