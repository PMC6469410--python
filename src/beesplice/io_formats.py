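"""Readers and writers for the external file formats.

Every coordinate handed to the rest of the package is 0-based, half-open
(``[start, end)``).  GFF3 on disk is 1-based, fully closed; the conversion
happens here and nowhere else.  Splice junctions are stored as *intron*
intervals: ``start`` is the first intronic base, ``end`` is one past the
last intronic base, so a junction's ``start`` coincides with the end of the
upstream exon and its ``end`` with the start of the downstream exon.

Formats handled:

* genome FASTA (via Biopython),
* gene models GFF3 (gene/mRNA/exon hierarchy with ID/Parent links),
* splice-junction TSV (``#chrom start end strand score support``),
* per-base coverage as bedGraph,
* BS-seq methylation calls as TSV (``#chrom pos strand context meth total``),
* ortholog tables as TSV (``#gene_id ortholog_id ortholog_as_events``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "SpliceJunction",
    "CoverageTrack",
    "MethylationRecord",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_junctions",
    "write_junctions",
    "read_coverage",
    "write_coverage",
    "read_methylation",
    "write_methylation",
    "read_orthologs",
]

JUNCTION_HEADER = "#chrom\tstart\tend\tstrand\tscore\tsupport"
METHYLATION_HEADER = "#chrom\tpos\tstrand\tcontext\tmethylated\ttotal"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class SpliceJunction:
    """One intron call: interval, strand, confidence score and read support.

    ``support`` is the number of reads mapped across the junction (the
    N(x~y) quantity used by the inclusion/splicing ratio formulas).
    """

    intron: GenomicInterval
    score: float
    support: int

    def __post_init__(self) -> None:
        if len(self.intron) < 4:
            raise ValueError(f"intron shorter than 4 nt: {self.intron}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"junction score {self.score} outside [0, 1]")
        if self.support < 0:
            raise ValueError(f"negative junction support {self.support}")

    @property
    def chrom(self) -> str:
        return self.intron.chrom

    @property
    def start(self) -> int:
        return self.intron.start

    @property
    def end(self) -> int:
        return self.intron.end

    @property
    def strand(self) -> str:
        return self.intron.strand

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


class CoverageTrack:
    """Per-base read depth, one non-negative integer array per chromosome.

    Positions outside any stored array are depth 0, so tracks built from a
    bedGraph that omits trailing uncovered bases behave correctly.
    """

    def __init__(self, depths: dict[str, np.ndarray] | None = None):
        self.depths: dict[str, np.ndarray] = {}
        if depths:
            for chrom, arr in depths.items():
                self.set_chrom(chrom, arr)

    def set_chrom(self, chrom: str, arr: np.ndarray) -> None:
        arr = np.asarray(arr)
        if arr.size and arr.min() < 0:
            raise ValueError(f"negative depth on {chrom}")
        self.depths[chrom] = arr.astype(np.int64)

    def depth_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depth at each base of [start, end); out-of-range bases are 0."""
        if start < 0 or end < start:
            raise ValueError(f"bad range {start}-{end}")
        out = np.zeros(end - start, dtype=np.int64)
        arr = self.depths.get(chrom)
        if arr is not None and start < arr.size:
            hi = min(end, arr.size)
            out[: hi - start] = arr[start:hi]
        return out

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Cov(x, y): reads summed over [x, y) divided by y - x."""
        if end <= start:
            raise ValueError(f"empty range {start}-{end}")
        return float(self.depth_array(chrom, start, end).mean())

    def min_depth(self, chrom: str, start: int, end: int) -> int:
        return int(self.depth_array(chrom, start, end).min())

    def chroms(self) -> list[str]:
        return sorted(self.depths)


@dataclass(frozen=True)
class MethylationRecord:
    """One cytosine from a BS-seq call set (0-based position)."""

    chrom: str
    pos: int
    strand: str
    context: str
    methylated: int
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.methylated <= self.total):
            raise ValueError(
                f"methylated count {self.methylated} outside [0, {self.total}] "
                f"at {self.chrom}:{self.pos}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().rstrip(";").split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path):
    """Parse a GFF3 file with gene/mRNA/exon features into a GeneModel.

    1-based closed exon coordinates become 0-based half-open.  Exons of each
    transcript are sorted; an exon line whose Parent is unknown, or whose
    start exceeds its end, is an error.
    """
    from .gene_model import Gene, GeneModel, Transcript

    model = GeneModel()
    pending_exons: list[tuple[str, GenomicInterval, str]] = []
    transcripts: dict[str, Transcript] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: expected 9 columns")
            chrom, source, ftype, start, end, _score, strand, _phase, attr_text = fields
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"line {lineno}: start {start_i} > end {end_i}")
            attrs = _parse_attributes(attr_text)
            interval = GenomicInterval(chrom, start_i - 1, end_i, strand)
            provenance = "novel" if source == "beesplice" else "annotated"
            if ftype == "gene":
                gene_id = attrs.get("ID")
                if gene_id is None:
                    raise ValueError(f"line {lineno}: gene without ID")
                model.genes[gene_id] = Gene(
                    id=gene_id, chrom=chrom, strand=strand, provenance=provenance
                )
            elif ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid is None or parent is None:
                    raise ValueError(f"line {lineno}: transcript missing ID/Parent")
                transcripts[tid] = Transcript(
                    id=tid, gene_id=parent, provenance=provenance
                )
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"line {lineno}: exon without Parent")
                for tid in parent.split(","):
                    pending_exons.append((tid, interval, provenance))
    for tid, transcript in transcripts.items():
        gene = model.genes.get(transcript.gene_id)
        if gene is None:
            raise ValueError(
                f"transcript {tid} has unknown Parent {transcript.gene_id}"
            )
        gene.transcripts[tid] = transcript
    by_tid = {tid: t for tid, t in transcripts.items()}
    for tid, interval, provenance in pending_exons:
        transcript = by_tid.get(tid)
        if transcript is None:
            raise ValueError(f"exon has unknown Parent {tid}")
        transcript.exons.append(interval)
        transcript.exon_provenance.append(provenance)
    for transcript in transcripts.values():
        order = sorted(
            range(len(transcript.exons)), key=lambda i: transcript.exons[i].start
        )
        transcript.exons = [transcript.exons[i] for i in order]
        transcript.exon_provenance = [transcript.exon_provenance[i] for i in order]
        for left, right in zip(transcript.exons, transcript.exons[1:]):
            if left.end > right.start:
                raise ValueError(
                    f"overlapping exons in transcript {transcript.id}: "
                    f"{left} and {right}"
                )
    model.rebuild_indexes()
    return model


def write_gff3(model, path) -> None:
    """Write a GeneModel as GFF3, deterministically ordered.

    Features are sorted by (chrom, start, ID); novel features (added by the
    augmentation step) carry the source tag ``beesplice`` so they can be
    told apart from the input annotation.
    """
    lines = ["##gff-version 3"]
    for gene in sorted(
        model.genes.values(), key=lambda g: (g.chrom, g.span()[0], g.id)
    ):
        g_start, g_end = gene.span()
        g_source = "beesplice" if gene.provenance == "novel" else "annotation"
        lines.append(
            "\t".join(
                [
                    gene.chrom,
                    g_source,
                    "gene",
                    str(g_start + 1),
                    str(g_end),
                    ".",
                    gene.strand,
                    ".",
                    f"ID={gene.id}",
                ]
            )
        )
        for tid in sorted(gene.transcripts):
            transcript = gene.transcripts[tid]
            t_source = "beesplice" if transcript.provenance == "novel" else "annotation"
            t_start = transcript.exons[0].start
            t_end = transcript.exons[-1].end
            lines.append(
                "\t".join(
                    [
                        gene.chrom,
                        t_source,
                        "mRNA",
                        str(t_start + 1),
                        str(t_end),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={tid};Parent={gene.id}",
                    ]
                )
            )
            for i, exon in enumerate(transcript.exons):
                e_source = (
                    "beesplice"
                    if transcript.exon_provenance[i] == "novel"
                    else "annotation"
                )
                lines.append(
                    "\t".join(
                        [
                            gene.chrom,
                            e_source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            gene.strand,
                            ".",
                            f"ID={tid}.exon{i + 1};Parent={tid}",
                        ]
                    )
                )
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Splice junctions


def read_junctions(path) -> list[SpliceJunction]:
    """Read a junction TSV; duplicates merge (support summed, score maxed).

    Junction callers run per sample; junction lists from several samples are
    concatenated and clustered here by exact intron coordinates.
    """
    merged: dict[tuple, list] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"line {lineno}: expected 6 columns")
            chrom, start, end, strand, score, support = fields
            key = (chrom, int(start), int(end), strand)
            score_f = float(score)
            support_i = int(support)
            if not (0.0 <= score_f <= 1.0):
                raise ValueError(f"line {lineno}: score {score_f} outside [0, 1]")
            if support_i < 0:
                raise ValueError(f"line {lineno}: negative support {support_i}")
            if key in merged:
                merged[key][0] = max(merged[key][0], score_f)
                merged[key][1] += support_i
            else:
                merged[key] = [score_f, support_i]
    junctions = [
        SpliceJunction(
            intron=GenomicInterval(chrom, start, end, strand),
            score=score,
            support=support,
        )
        for (chrom, start, end, strand), (score, support) in merged.items()
    ]
    junctions.sort(key=lambda j: (j.chrom, j.start, j.end, j.strand))
    return junctions


def write_junctions(junctions, path) -> None:
    rows = sorted(junctions, key=lambda j: (j.chrom, j.start, j.end, j.strand))
    with open(path, "w") as handle:
        handle.write(JUNCTION_HEADER + "\n")
        for j in rows:
            handle.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t"
                f"{j.score:g}\t{j.support}\n"
            )


# ---------------------------------------------------------------------------
# Coverage (bedGraph)


def read_coverage(path, chrom_lengths: dict[str, int] | None = None) -> CoverageTrack:
    """Expand a bedGraph into per-base depths.

    Unlisted bases have depth 0.  Overlapping intervals that disagree on
    depth are an error (same-value overlaps are tolerated as redundant).
    """
    intervals: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            start_i, end_i, value_i = int(start), int(end), int(float(value))
            if value_i < 0:
                raise ValueError(f"line {lineno}: negative depth")
            intervals.setdefault(chrom, []).append((start_i, end_i, value_i))
    track = CoverageTrack()
    for chrom, ivs in intervals.items():
        length = max(end for _s, end, _v in ivs)
        if chrom_lengths and chrom in chrom_lengths:
            length = max(length, chrom_lengths[chrom])
        arr = np.zeros(length, dtype=np.int64)
        seen = np.zeros(length, dtype=bool)
        for start, end, value in ivs:
            window = arr[start:end]
            conflict = seen[start:end] & (window != value)
            if conflict.any():
                pos = start + int(np.argmax(conflict))
                raise ValueError(
                    f"conflicting bedGraph depths at {chrom}:{pos} "
                    f"({window[pos - start]} vs {value})"
                )
            arr[start:end] = value
            seen[start:end] = True
        track.set_chrom(chrom, arr)
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            if chrom not in track.depths:
                track.set_chrom(chrom, np.zeros(length, dtype=np.int64))
    return track


def write_coverage(track: CoverageTrack, path) -> None:
    """Write a track as a bedGraph, run-length encoding each chromosome.

    Zero-depth runs are omitted, matching the usual sparse convention."""
    with open(path, "w") as handle:
        for chrom in track.chroms():
            arr = track.depths[chrom]
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    handle.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# Methylation


def read_methylation(path) -> list[MethylationRecord]:
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"line {lineno}: expected 6 columns")
            chrom, pos, strand, context, methylated, total = fields
            records.append(
                MethylationRecord(
                    chrom=chrom,
                    pos=int(pos),
                    strand=strand,
                    context=context,
                    methylated=int(methylated),
                    total=int(total),
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos, r.strand))
    return records


def write_methylation(records, path) -> None:
    rows = sorted(records, key=lambda r: (r.chrom, r.pos, r.strand))
    with open(path, "w") as handle:
        handle.write(METHYLATION_HEADER + "\n")
        for r in rows:
            handle.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.context}\t"
                f"{r.methylated}\t{r.total}\n"
            )


# ---------------------------------------------------------------------------
# Orthologs


def read_orthologs(path) -> pd.DataFrame:
    """Read a gene/ortholog table with the ortholog's AS-event count."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment=None,
        names=["gene_id", "ortholog_id", "ortholog_as_events"],
        header=0,
        dtype={"gene_id": str, "ortholog_id": str, "ortholog_as_events": np.int64},
    )
    if (df["ortholog_as_events"] < 0).any():
        raise ValueError("negative ortholog AS-event count")
    return df
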