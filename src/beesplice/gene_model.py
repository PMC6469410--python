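"""Gene models and their augmentation from splice junctions and coverage.

A :class:`GeneModel` is a genes → transcripts → exons hierarchy over 0-based
half-open intervals.  Introns are derived as the gaps between consecutive
exons of a transcript.  The augmentation step adds novel exons and novel
intergenic transcripts inferred from high-confidence splice junctions whose
unannotated end lands in a "transcribed island" — a contiguous block of
read coverage outside every annotated exon.  Annotated features are never
modified or removed; every addition carries provenance ``novel``.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CoverageTrack, GenomicInterval, SpliceJunction

logger = logging.getLogger(__name__)

SJ_SCORE_THRESHOLD = 0.5

__all__ = [
    "Gene",
    "Transcript",
    "GeneModel",
    "JunctionPartition",
    "filter_junctions",
    "find_transcribed_islands",
    "augment_model",
]


@dataclass
class Transcript:
    id: str
    gene_id: str
    exons: list[GenomicInterval] = field(default_factory=list)
    exon_provenance: list[str] = field(default_factory=list)
    provenance: str = "annotated"

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            out.append(
                GenomicInterval(left.chrom, left.end, right.start, left.strand)
            )
        return out


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    provenance: str = "annotated"

    def span(self) -> tuple[int, int]:
        starts = [t.exons[0].start for t in self.transcripts.values() if t.exons]
        ends = [t.exons[-1].end for t in self.transcripts.values() if t.exons]
        if not starts:
            raise ValueError(f"gene {self.id} has no exons")
        return min(starts), max(ends)

    def all_exons(self) -> list[GenomicInterval]:
        seen = set()
        out = []
        for tid in sorted(self.transcripts):
            for exon in self.transcripts[tid].exons:
                key = (exon.start, exon.end)
                if key not in seen:
                    seen.add(key)
                    out.append(exon)
        out.sort(key=lambda e: (e.start, e.end))
        return out

    def constitutive_exons(self) -> set[tuple[int, int]]:
        """Exon intervals present in every transcript of the gene."""
        per_transcript = [
            {(e.start, e.end) for e in t.exons} for t in self.transcripts.values()
        ]
        if not per_transcript:
            return set()
        return set.intersection(*per_transcript)


class GeneModel:
    """Container for genes with coordinate indexes used by the detectors."""

    def __init__(self) -> None:
        self.genes: dict[str, Gene] = {}
        self.genome: dict[str, str] | None = None
        # indexes (rebuilt after mutation)
        self._exon_starts: set[tuple[str, int]] = set()
        self._exon_ends: set[tuple[str, int]] = set()
        self._exons_by_chrom: dict[str, tuple[list[int], list[tuple[int, int, str, str]]]] = {}
        self._gene_spans: dict[str, list[tuple[int, int, str]]] = {}
        self._intron_keys: set[tuple[str, int, int]] = set()

    # -- construction -----------------------------------------------------

    def copy(self) -> "GeneModel":
        """Structural copy (genes/transcripts); the genome is shared."""
        model = GeneModel()
        for gid, gene in self.genes.items():
            new_gene = Gene(id=gene.id, chrom=gene.chrom, strand=gene.strand,
                            provenance=gene.provenance)
            for tid, t in gene.transcripts.items():
                new_gene.transcripts[tid] = Transcript(
                    id=t.id, gene_id=t.gene_id, exons=list(t.exons),
                    exon_provenance=list(t.exon_provenance),
                    provenance=t.provenance,
                )
            model.genes[gid] = new_gene
        model.genome = self.genome
        model.rebuild_indexes()
        return model

    def attach_genome(self, genome: dict[str, str]) -> None:
        for gene in self.genes.values():
            if gene.chrom not in genome:
                raise ValueError(f"gene {gene.id} on unknown chromosome {gene.chrom}")
        self.genome = genome

    def add_gene(self, gene: Gene) -> None:
        if gene.id in self.genes:
            raise ValueError(f"duplicate gene id {gene.id}")
        self.genes[gene.id] = gene

    def rebuild_indexes(self) -> None:
        self._exon_starts.clear()
        self._exon_ends.clear()
        self._intron_keys.clear()
        by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
        spans: dict[str, list[tuple[int, int, str]]] = {}
        for gene in self.genes.values():
            for transcript in gene.transcripts.values():
                for exon in transcript.exons:
                    self._exon_starts.add((exon.chrom, exon.start))
                    self._exon_ends.add((exon.chrom, exon.end))
                    by_chrom.setdefault(exon.chrom, []).append(
                        (exon.start, exon.end, gene.strand, gene.id)
                    )
                for intron in transcript.introns():
                    self._intron_keys.add((intron.chrom, intron.start, intron.end))
            start, end = gene.span()
            spans.setdefault(gene.chrom, []).append((start, end, gene.id))
        self._exons_by_chrom = {}
        for chrom, exons in by_chrom.items():
            exons = sorted(set(exons))
            self._exons_by_chrom[chrom] = ([e[0] for e in exons], exons)
        self._gene_spans = {c: sorted(v) for c, v in spans.items()}

    # -- queries ----------------------------------------------------------

    def is_exon_start(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._exon_starts

    def is_exon_end(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._exon_ends

    def is_known_intron(self, chrom: str, start: int, end: int) -> bool:
        return (chrom, start, end) in self._intron_keys

    def n_introns(self) -> int:
        return len(self._intron_keys)

    def exons_overlapping(self, chrom: str, start: int, end: int):
        """All distinct (start, end, strand, gene_id) exons hitting [start, end)."""
        if chrom not in self._exons_by_chrom:
            return []
        starts, exons = self._exons_by_chrom[chrom]
        hi = bisect.bisect_left(starts, end)
        return [e for e in exons[:hi] if e[1] > start]

    def exons_with_end(self, chrom: str, pos: int):
        """Distinct exons whose right boundary is pos."""
        if chrom not in self._exons_by_chrom:
            return []
        return [e for e in self._exons_by_chrom[chrom][1] if e[1] == pos]

    def exons_with_start(self, chrom: str, pos: int):
        if chrom not in self._exons_by_chrom:
            return []
        starts, exons = self._exons_by_chrom[chrom]
        lo = bisect.bisect_left(starts, pos)
        hi = bisect.bisect_right(starts, pos)
        return exons[lo:hi]

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        out = []
        for g_start, g_end, gid in self._gene_spans.get(chrom, []):
            if g_start < end and start < g_end:
                out.append(gid)
        return out

    def iter_transcripts(self):
        for gid in sorted(self.genes):
            gene = self.genes[gid]
            for tid in sorted(gene.transcripts):
                yield gene, gene.transcripts[tid]

    def annotated_introns(self):
        """Distinct introns as (gene, transcript, index, intron interval).

        An intron shared by several transcripts of a gene is reported once,
        for the first transcript (sorted by id) that contains it.
        """
        seen: set[tuple[str, int, int]] = set()
        for gene, transcript in self.iter_transcripts():
            for i, intron in enumerate(transcript.introns()):
                key = (gene.id, intron.start, intron.end)
                if key not in seen:
                    seen.add(key)
                    yield gene, transcript, i, intron


# ---------------------------------------------------------------------------
# Junction filtering


@dataclass
class JunctionPartition:
    """Score-filtered junctions split by how many splice sites are annotated."""

    known: list[SpliceJunction] = field(default_factory=list)
    half_known: list[SpliceJunction] = field(default_factory=list)
    both_novel: list[SpliceJunction] = field(default_factory=list)
    n_discarded: int = 0

    def retained(self) -> list[SpliceJunction]:
        return self.known + self.half_known + self.both_novel


def filter_junctions(
    junctions,
    model: GeneModel,
    score_threshold: float = SJ_SCORE_THRESHOLD,
) -> JunctionPartition:
    """Discard low-confidence junctions and classify the survivors.

    Only junctions with score strictly greater than ``score_threshold``
    (default 0.5) are retained.  A junction's left site is "known" when it
    coincides exactly with an annotated exon end, its right site when it
    coincides with an annotated exon start; junctions are then partitioned
    into both-known / half-known / both-novel.
    """
    partition = JunctionPartition()
    for j in junctions:
        if not j.score > score_threshold:
            partition.n_discarded += 1
            continue
        left_known = model.is_exon_end(j.chrom, j.start)
        right_known = model.is_exon_start(j.chrom, j.end)
        if left_known and right_known:
            partition.known.append(j)
        elif left_known or right_known:
            partition.half_known.append(j)
        else:
            partition.both_novel.append(j)
    if partition.n_discarded:
        logger.debug("discarded %d junctions at score <= %g",
                     partition.n_discarded, score_threshold)
    return partition


# ---------------------------------------------------------------------------
# Transcribed islands


def find_transcribed_islands(
    coverage: CoverageTrack,
    model: GeneModel,
    min_depth: int = 5,
    min_len: int = 50,
    max_gap: int = 10,
) -> list[GenomicInterval]:
    """Maximal covered blocks outside annotated exons.

    A block is a run of bases with depth >= ``min_depth``; runs separated by
    at most ``max_gap`` uncovered bases are merged; merged blocks shorter
    than ``min_len`` are dropped, as is any block overlapping an exon
    already in the model (annotated or previously added).
    """
    islands = []
    for chrom in coverage.chroms():
        arr = coverage.depths[chrom]
        mask = arr >= min_depth
        if not mask.any():
            continue
        padded = np.concatenate([[0], mask.view(np.int8), [0]])
        d = np.diff(padded)
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        merged: list[list[int]] = []
        for s, e in zip(run_starts, run_ends):
            if merged and s - merged[-1][1] <= max_gap:
                merged[-1][1] = e
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            if e - s < min_len:
                continue
            if model.exons_overlapping(chrom, s, e):
                continue
            islands.append(GenomicInterval(chrom, s, e))
    islands.sort(key=lambda iv: (iv.chrom, iv.start))
    return islands


# ---------------------------------------------------------------------------
# Augmentation


def _infer_strand(model: GeneModel, chrom: str, start: int, end: int) -> str:
    """Orient a junction from its terminal dinucleotides (GT..AG)."""
    if model.genome is None:
        return "+"
    seq = model.genome.get(chrom, "")
    if end > len(seq):
        return "+"
    if seq[start : start + 2] == "GT" and seq[end - 2 : end] == "AG":
        return "+"
    if seq[start : start + 2] == "CT" and seq[end - 2 : end] == "AC":
        return "-"
    return "+"


def augment_model(
    model: GeneModel,
    partition: JunctionPartition,
    islands,
) -> GeneModel:
    """Add novel exons and intergenic transcripts to the model, in place.

    * A half-known junction whose unannotated end lands in a transcribed
      island gains a novel exon spanning from the junction end to the far
      island edge, attached to the anchoring gene as a new two-exon
      transcript (anchor exon + novel exon).
    * A both-novel junction linking two islands in intergenic space creates
      a novel two-exon gene.

    Additions are skipped when the novel exon would overlap an existing
    same-strand exon, or when an identical novel feature is already present
    — so a second pass with the same inputs adds nothing.
    """
    island_index: dict[str, list[GenomicInterval]] = {}
    for island in islands:
        island_index.setdefault(island.chrom, []).append(island)

    def island_at(chrom: str, pos: int) -> GenomicInterval | None:
        for island in island_index.get(chrom, []):
            if island.start <= pos < island.end:
                return island
        return None

    def transcript_exists(gene: Gene, exon_pairs) -> bool:
        target = [tuple(p) for p in exon_pairs]
        return any(
            [(e.start, e.end) for e in t.exons] == target
            for t in gene.transcripts.values()
        )

    n_added_exons = 0
    n_added_transcripts = 0
    n_skipped = 0

    # (ii) half-known junctions into islands -> novel terminal/internal exons
    for j in sorted(partition.half_known, key=lambda x: (x.chrom, x.start, x.end)):
        left_known = model.is_exon_end(j.chrom, j.start)
        right_known = model.is_exon_start(j.chrom, j.end)
        if left_known:
            novel_pos = j.end
            island = island_at(j.chrom, novel_pos)
            if island is None:
                continue  # in-exon novel ends are AEB candidates, not exons
            novel_exon = (novel_pos, island.end)
            anchors = model.exons_with_end(j.chrom, j.start)
        elif right_known:
            novel_pos = j.start
            island = island_at(j.chrom, novel_pos - 1)
            if island is None:
                continue
            novel_exon = (island.start, novel_pos)
            anchors = model.exons_with_start(j.chrom, j.end)
        else:  # pragma: no cover - partition contract
            continue
        if not anchors:
            continue
        anchor = sorted(anchors, key=lambda e: e[3])[0]
        gene = model.genes[anchor[3]]
        if j.strand != "." and j.strand != gene.strand:
            n_skipped += 1
            continue
        clash = [
            e
            for e in model.exons_overlapping(j.chrom, *novel_exon)
            if e[2] == gene.strand
        ]
        if clash:
            n_skipped += 1
            logger.debug("novel exon %s:%s overlaps existing exon; skipped",
                         j.chrom, novel_exon)
            continue
        anchor_iv = GenomicInterval(j.chrom, anchor[0], anchor[1], gene.strand)
        novel_iv = GenomicInterval(j.chrom, novel_exon[0], novel_exon[1], gene.strand)
        exons = sorted([anchor_iv, novel_iv], key=lambda e: e.start)
        if transcript_exists(gene, [(e.start, e.end) for e in exons]):
            continue
        tid = f"{gene.id}.novel{len(gene.transcripts) + 1}"
        prov = ["novel" if (e.start, e.end) == novel_exon else "annotated" for e in exons]
        gene.transcripts[tid] = Transcript(
            id=tid, gene_id=gene.id, exons=exons, exon_provenance=prov,
            provenance="novel",
        )
        n_added_exons += 1
        n_added_transcripts += 1
        model.rebuild_indexes()

    # (iii) both-novel junctions bridging two islands -> intergenic transcripts
    for j in sorted(partition.both_novel, key=lambda x: (x.chrom, x.start, x.end)):
        left_island = island_at(j.chrom, j.start - 1)
        right_island = island_at(j.chrom, j.end)
        if left_island is None or right_island is None or left_island is right_island:
            continue
        exon1 = (left_island.start, j.start)
        exon2 = (j.end, right_island.end)
        if exon1[1] <= exon1[0] or exon2[1] <= exon2[0]:
            continue
        if model.genes_overlapping(j.chrom, exon1[0], exon2[1]):
            n_skipped += 1
            continue
        strand = j.strand if j.strand != "." else _infer_strand(
            model, j.chrom, j.start, j.end
        )
        gid = f"novel_gene_{j.chrom}_{exon1[0]}_{exon2[1]}"
        if gid in model.genes:
            continue
        tid = gid + ".t1"
        exons = [
            GenomicInterval(j.chrom, exon1[0], exon1[1], strand),
            GenomicInterval(j.chrom, exon2[0], exon2[1], strand),
        ]
        gene = Gene(id=gid, chrom=j.chrom, strand=strand, provenance="novel")
        gene.transcripts[tid] = Transcript(
            id=tid, gene_id=gid, exons=exons,
            exon_provenance=["novel", "novel"], provenance="novel",
        )
        model.genes[gid] = gene
        n_added_exons += 2
        n_added_transcripts += 1
        model.rebuild_indexes()

    model.rebuild_indexes()
    logger.debug(
        "augmentation: %d novel exons, %d novel transcripts, %d skipped",
        n_added_exons, n_added_transcripts, n_skipped,
    )
    return model
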