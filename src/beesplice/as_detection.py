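"""Detection and quantification of alternative-splicing events.

Four event classes are recognized against a gene model:

* **IR** — intron retention: an annotated intron covered at every base above
  a depth floor whose inclusion ratio exceeds a multiple of the genome-wide
  baseline.
* **CE** — cassette exon: an annotated internal exon skipped by a junction
  that joins the boundaries of two non-adjacent exons of one transcript.
* **ALT_DONOR / ALT_ACCEPTOR** — alternative exon boundary (AEB): a
  half-known junction sharing one splice site with an annotated intron and
  displacing the other by fewer than 200 nt without crossing the far exon
  boundary.
* **AFE / ALE** — alternative terminal exons (ATE): distinct first (last)
  exons of one gene splicing to the same acceptor (donor) site of a
  constitutive exon.

Coordinate symbols on an event follow genomic order: the upstream exon is
``a..b``, the event region ``p..q`` (with alternatives ``p2``/``q2``), the
downstream exon ``c..d``; all 0-based half-open.

Quantification uses two read-derived quantities: junction support
``N(x~y)`` (reads mapped across the intron ``x..y``) and mean per-base
coverage ``Cov(x, y)``.  The ratio formulas are:

* IR inclusion ratio = ``2 * Cov(p, q) / (Cov(a, p) + Cov(q, d))`` — may
  exceed 1 and is deliberately not clamped;
* CE inclusion ratio = ``((N(b~p) + N(q~c)) / 2) / ((N(b~p) + N(q~c)) / 2 + N(b~c))``;
* AEB/ATE splicing ratio = minor junction support over major,
  ``min(N, N') / max(N, N')``;
* AEB inclusion ratio = support of the junction that includes the disputed
  boundary region over the summed support of both competitors.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .gene_model import GeneModel, JunctionPartition
from .io_formats import CoverageTrack, SpliceJunction

logger = logging.getLogger(__name__)

AEB_MAX_DISPLACEMENT = 200
IR_MIN_DEPTH = 5
IR_BASELINE = 0.017
IR_BASELINE_MULTIPLIER = 3.0

EVENT_KINDS = ("IR", "CE", "ALT_DONOR", "ALT_ACCEPTOR", "AFE", "ALE")

__all__ = [
    "ASEvent",
    "JunctionIndex",
    "detect_ce",
    "compute_ce_ratio",
    "detect_ir",
    "compute_ir_ratio",
    "detect_aeb",
    "compute_aeb_ratios",
    "detect_ate",
    "detect_all",
    "displacement_spectrum",
    "events_to_table",
]


@dataclass
class ASEvent:
    kind: str
    gene_id: str
    chrom: str
    strand: str
    a: int | None = None
    b: int | None = None
    p: int | None = None
    q: int | None = None
    p2: int | None = None
    q2: int | None = None
    c: int | None = None
    d: int | None = None
    inclusion_ratio: float | None = None
    splicing_ratio: float | None = None
    displacement: int | None = None
    supports: dict = field(default_factory=dict)

    def key(self) -> tuple:
        return (self.kind, self.chrom, self.a, self.b, self.p, self.q,
                self.p2, self.q2, self.c, self.d)


class JunctionIndex:
    """Support lookup by intron coordinates; absent junctions count 0."""

    def __init__(self, junctions):
        self._support: dict[tuple[str, int, int], int] = {}
        for j in junctions:
            key = (j.chrom, j.start, j.end)
            self._support[key] = self._support.get(key, 0) + j.support

    def support(self, chrom: str, start: int, end: int) -> int:
        return self._support.get((chrom, start, end), 0)

    def __len__(self) -> int:
        return len(self._support)


# ---------------------------------------------------------------------------
# Cassette exons


def detect_ce(model: GeneModel, junctions) -> list[ASEvent]:
    """Find annotated internal exons skipped by a both-known junction.

    For every retained junction joining the end of one exon to the start of
    a non-adjacent downstream exon within a single transcript, each exon
    strictly between the two is emitted as a cassette exon.  Duplicates
    across transcripts of a gene are collapsed.
    """
    jindex = JunctionIndex(junctions)
    junction_keys = {(j.chrom, j.start, j.end) for j in junctions}
    events: dict[tuple, ASEvent] = {}
    for gene, transcript in model.iter_transcripts():
        exons = transcript.exons
        for i in range(len(exons)):
            for j in range(i + 2, len(exons)):
                key = (gene.chrom, exons[i].end, exons[j].start)
                if key not in junction_keys:
                    continue
                for mid in range(i + 1, j):
                    ce = exons[mid]
                    up, down = exons[mid - 1], exons[mid + 1]
                    event = ASEvent(
                        kind="CE",
                        gene_id=gene.id,
                        chrom=gene.chrom,
                        strand=gene.strand,
                        a=up.start, b=up.end,
                        p=ce.start, q=ce.end,
                        c=down.start, d=down.end,
                    )
                    event.inclusion_ratio = compute_ce_ratio(event, jindex)
                    events.setdefault((gene.id,) + event.key(), event)
    return sorted(events.values(), key=lambda e: (e.chrom, e.p, e.q, e.gene_id))


def compute_ce_ratio(event: ASEvent, junctions) -> float | None:
    """CE inclusion ratio from the two inclusion junctions and the skip
    junction; ``None`` (NA) when all three supports are zero."""
    jindex = junctions if isinstance(junctions, JunctionIndex) else JunctionIndex(junctions)
    n_bp = jindex.support(event.chrom, event.b, event.p)
    n_qc = jindex.support(event.chrom, event.q, event.c)
    n_bc = jindex.support(event.chrom, event.b, event.c)
    event.supports = {"N(b~p)": n_bp, "N(q~c)": n_qc, "N(b~c)": n_bc}
    inclusion = (n_bp + n_qc) / 2.0
    if inclusion + n_bc == 0:
        return None
    return inclusion / (inclusion + n_bc)


# ---------------------------------------------------------------------------
# Intron retention


def detect_ir(
    model: GeneModel,
    coverage: CoverageTrack,
    baseline: float = IR_BASELINE,
    min_depth: int = IR_MIN_DEPTH,
) -> list[ASEvent]:
    """Find retained introns.

    An annotated intron ``p..q`` with flanking exons ``a..p`` and ``q..d``
    is retained iff (i) every intronic base has depth strictly greater than
    ``min_depth`` (default 5), and (ii) its inclusion ratio is at least
    three times ``baseline`` (default 0.017, the genome-wide average intron
    inclusion ratio).  Both flanking exons count as involved exons.
    """
    events: dict[tuple, ASEvent] = {}
    for gene, transcript in model.iter_transcripts():
        exons = transcript.exons
        for i in range(len(exons) - 1):
            up, down = exons[i], exons[i + 1]
            p, q = up.end, down.start
            dedup = (gene.id, p, q)
            if dedup in events:
                continue
            if not coverage.min_depth(gene.chrom, p, q) > min_depth:
                continue
            event = ASEvent(
                kind="IR",
                gene_id=gene.id,
                chrom=gene.chrom,
                strand=gene.strand,
                a=up.start, b=p, p=p, q=q, c=q, d=down.end,
            )
            ratio = compute_ir_ratio(event, coverage)
            # 1e-12 guard: a ratio exactly at the documented threshold
            # (e.g. 0.051 = 3 x 0.017) must pass despite binary float dust
            if ratio is None or ratio < IR_BASELINE_MULTIPLIER * baseline - 1e-12:
                continue
            event.inclusion_ratio = ratio
            events[dedup] = event
    return sorted(events.values(), key=lambda e: (e.chrom, e.p, e.q, e.gene_id))


def compute_ir_ratio(event: ASEvent, coverage: CoverageTrack) -> float | None:
    """IR inclusion ratio ``2*Cov(p,q) / (Cov(a,p) + Cov(q,d))``.

    Not clamped to 1; ``None`` (NA) when both flank coverages are zero."""
    cov_intron = coverage.mean_depth(event.chrom, event.p, event.q)
    cov_up = coverage.mean_depth(event.chrom, event.a, event.p)
    cov_down = coverage.mean_depth(event.chrom, event.q, event.d)
    denom = cov_up + cov_down
    if denom == 0:
        return None
    return 2.0 * cov_intron / denom


# ---------------------------------------------------------------------------
# Alternative exon boundaries


def detect_aeb(
    model: GeneModel,
    partition: JunctionPartition,
    max_displacement: int = AEB_MAX_DISPLACEMENT,
) -> list[ASEvent]:
    """Find alternative donor/acceptor usage from half-known junctions.

    A half-known junction that shares one splice site with an annotated
    intron and whose free end sits strictly within ``max_displacement`` nt
    of the annotated site — without crossing the far boundary of the
    affected exon — shifts that exon's boundary.  The moved intron end is
    the donor side when it is 5' of the intron in transcription
    orientation (genomic left on ``+``, right on ``-``), otherwise the
    acceptor side.
    """
    introns_by_start: dict[tuple[str, int], list] = {}
    introns_by_end: dict[tuple[str, int], list] = {}
    for gene, transcript, i, intron in model.annotated_introns():
        up = transcript.exons[i]
        down = transcript.exons[i + 1]
        rec = (gene, up, down, intron)
        introns_by_start.setdefault((intron.chrom, intron.start), []).append(rec)
        introns_by_end.setdefault((intron.chrom, intron.end), []).append(rec)

    events: dict[tuple, ASEvent] = {}
    for j in partition.half_known:
        left_known = model.is_exon_end(j.chrom, j.start)
        right_known = model.is_exon_start(j.chrom, j.end)
        if right_known and not left_known:
            # shared acceptor-side coordinate: annotated intron b..c with the
            # same end; the intron start moved from b to b' = j.start
            for gene, up, down, intron in introns_by_end.get((j.chrom, j.end), []):
                if j.strand != "." and j.strand != gene.strand:
                    continue
                b, b2 = intron.start, j.start
                if b2 == b or abs(b2 - b) >= max_displacement:
                    continue
                if not (b2 > up.start):
                    continue  # crossed the far boundary: novel-exon candidate
                moved_is_donor = gene.strand == "+"
                kind = "ALT_DONOR" if moved_is_donor else "ALT_ACCEPTOR"
                event = ASEvent(
                    kind=kind, gene_id=gene.id, chrom=gene.chrom,
                    strand=gene.strand,
                    a=up.start, b=b, p=b, p2=b2, q=intron.end,
                    c=intron.end, d=down.end,
                    displacement=abs(b2 - b),
                )
                events.setdefault((gene.id,) + event.key(), event)
        elif left_known and not right_known:
            # shared donor-side coordinate: intron end moved from c to c'
            for gene, up, down, intron in introns_by_start.get((j.chrom, j.start), []):
                if j.strand != "." and j.strand != gene.strand:
                    continue
                c, c2 = intron.end, j.end
                if c2 == c or abs(c2 - c) >= max_displacement:
                    continue
                if not (c2 < down.end):
                    continue
                moved_is_donor = gene.strand == "-"
                kind = "ALT_DONOR" if moved_is_donor else "ALT_ACCEPTOR"
                event = ASEvent(
                    kind=kind, gene_id=gene.id, chrom=gene.chrom,
                    strand=gene.strand,
                    a=up.start, b=intron.start, p=intron.start,
                    q=c, q2=c2, c=c, d=down.end,
                    displacement=abs(c2 - c),
                )
                events.setdefault((gene.id,) + event.key(), event)
    out = sorted(events.values(), key=lambda e: (e.chrom, e.p, e.q, e.p2 or -1,
                                                 e.q2 or -1, e.gene_id))
    jindex = JunctionIndex(partition.retained())
    for event in out:
        ratios = compute_aeb_ratios(event, jindex)
        event.splicing_ratio = ratios["splicing_ratio"]
        event.inclusion_ratio = ratios["inclusion_ratio"]
    return out


def compute_aeb_ratios(event: ASEvent, junctions) -> dict:
    """Splicing ratio (minor/major) and boundary-region inclusion ratio.

    The inclusion ratio counts the junction whose shorter intron leaves the
    disputed region ``min..max`` inside the exon, over both competitors.
    NA (``None``) when both supports are zero.
    """
    jindex = junctions if isinstance(junctions, JunctionIndex) else JunctionIndex(junctions)
    if event.p2 is not None:  # moved intron start: introns p..c and p2..c
        n = jindex.support(event.chrom, event.p, event.c)
        n2 = jindex.support(event.chrom, event.p2, event.c)
        n_inc = n if event.p > event.p2 else n2
        if event.p == event.p2:
            n_inc = n
    else:  # moved intron end: introns b..q and b..q2
        n = jindex.support(event.chrom, event.b, event.q)
        n2 = jindex.support(event.chrom, event.b, event.q2)
        n_inc = n if event.q < event.q2 else n2
        if event.q == event.q2:
            n_inc = n
    event.supports = {"N": n, "N'": n2}
    total = n + n2
    major = max(n, n2)
    return {
        "splicing_ratio": (min(n, n2) / major) if major > 0 else None,
        "inclusion_ratio": (n_inc / total) if total > 0 else None,
    }


# ---------------------------------------------------------------------------
# Alternative terminal exons


def detect_ate(model: GeneModel, junctions) -> list[ASEvent]:
    """Find alternative first/last exons sharing a constitutive splice site.

    Distinct first exons of a gene whose initial introns splice to the same
    acceptor form AFE events (mirrored for last exons and a shared donor).
    The shared site must belong to an exon present in every transcript of
    the gene.  The splicing ratio is minor over major junction support;
    ties resolve with the higher-support transcript's exon as major (and,
    on equal support, the genomically first exon).
    """
    jindex = junctions if isinstance(junctions, JunctionIndex) else JunctionIndex(junctions)
    events: list[ASEvent] = []
    for gid in sorted(model.genes):
        gene = model.genes[gid]
        multi = [
            t for _, t in sorted(gene.transcripts.items()) if len(t.exons) >= 2
        ]
        if len(multi) < 2:
            continue
        constitutive = gene.constitutive_exons()
        cons_starts = {s for s, _ in constitutive}
        cons_ends = {e for _, e in constitutive}
        plus = gene.strand != "-"

        # ---- alternative first exons: shared downstream acceptor
        groups: dict[int, dict] = {}
        for t in multi:
            if plus:
                first, intron = t.exons[0], t.introns()[0]
                shared = intron.end  # acceptor side on +
                shared_ok = shared in cons_starts
            else:
                first, intron = t.exons[-1], t.introns()[-1]
                shared = intron.start
                shared_ok = shared in cons_ends
            if not shared_ok:
                continue
            support = jindex.support(gene.chrom, intron.start, intron.end)
            groups.setdefault(shared, {})[(first.start, first.end)] = (
                first, intron, support
            )
        events.extend(_emit_ate(gene, groups, kind="AFE"))

        # ---- alternative last exons: shared upstream donor
        groups = {}
        for t in multi:
            if plus:
                last, intron = t.exons[-1], t.introns()[-1]
                shared = intron.start  # donor side on +
                shared_ok = shared in cons_ends
            else:
                last, intron = t.exons[0], t.introns()[0]
                shared = intron.end
                shared_ok = shared in cons_starts
            if not shared_ok:
                continue
            support = jindex.support(gene.chrom, intron.start, intron.end)
            groups.setdefault(shared, {})[(last.start, last.end)] = (
                last, intron, support
            )
        events.extend(_emit_ate(gene, groups, kind="ALE"))
    events.sort(key=lambda e: (e.chrom, e.p, e.q, e.gene_id, e.kind))
    return events


def _emit_ate(gene, groups, kind: str) -> list[ASEvent]:
    out = []
    for shared in sorted(groups):
        variants = groups[shared]
        if len(variants) < 2:
            continue
        ranked = sorted(
            variants.values(), key=lambda v: (-v[2], v[0].start, v[0].end)
        )
        major_exon, major_intron, major_n = ranked[0]
        for minor_exon, minor_intron, minor_n in ranked[1:]:
            splicing = (minor_n / major_n) if major_n > 0 else None
            out.append(
                ASEvent(
                    kind=kind,
                    gene_id=gene.id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    p=major_exon.start, q=major_exon.end,
                    p2=minor_exon.start, q2=minor_exon.end,
                    c=shared, d=shared,
                    splicing_ratio=splicing,
                    supports={"N": major_n, "N'": minor_n},
                )
            )
    return out


# ---------------------------------------------------------------------------
# Composite detection and the displacement spectrum


def detect_all(
    model: GeneModel,
    partition: JunctionPartition,
    coverage: CoverageTrack,
    baseline: float = IR_BASELINE,
    min_depth: int = IR_MIN_DEPTH,
    max_displacement: int = AEB_MAX_DISPLACEMENT,
) -> dict[str, list[ASEvent]]:
    retained = partition.retained()
    ce = detect_ce(model, retained)
    ir = detect_ir(model, coverage, baseline=baseline, min_depth=min_depth)
    aeb = detect_aeb(model, partition, max_displacement=max_displacement)
    ate = detect_ate(model, retained)
    return {
        "IR": ir,
        "CE": ce,
        "ALT_DONOR": [e for e in aeb if e.kind == "ALT_DONOR"],
        "ALT_ACCEPTOR": [e for e in aeb if e.kind == "ALT_ACCEPTOR"],
        "AFE": [e for e in ate if e.kind == "AFE"],
        "ALE": [e for e in ate if e.kind == "ALE"],
    }


def displacement_spectrum(events) -> dict:
    """Histogram of AEB boundary displacements and frame-preservation stats.

    Reports per-side displacement counts, the fraction of displacements
    divisible by 3, and the fraction of cassette exons whose length is a
    multiple of 3 (frame-preserving events).
    """
    donor = Counter()
    acceptor = Counter()
    ce_lengths = []
    for event in events:
        if event.kind == "ALT_DONOR" and event.displacement is not None:
            donor[event.displacement] += 1
        elif event.kind == "ALT_ACCEPTOR" and event.displacement is not None:
            acceptor[event.displacement] += 1
        elif event.kind == "CE":
            ce_lengths.append(event.q - event.p)

    def mod3_fraction(counts: Counter) -> float | None:
        total = sum(counts.values())
        if total == 0:
            return None
        return sum(n for d, n in counts.items() if d % 3 == 0) / total

    both = donor + acceptor
    return {
        "donor": dict(sorted(donor.items())),
        "acceptor": dict(sorted(acceptor.items())),
        "donor_mod3_fraction": mod3_fraction(donor),
        "acceptor_mod3_fraction": mod3_fraction(acceptor),
        "aeb_mod3_fraction": mod3_fraction(both),
        "ce_mod3_fraction": (
            sum(1 for L in ce_lengths if L % 3 == 0) / len(ce_lengths)
            if ce_lengths
            else None
        ),
        "n_ce": len(ce_lengths),
    }


def events_to_table(events_by_kind: dict[str, list[ASEvent]]):
    """Flatten detected events into a DataFrame (one row per event)."""
    import pandas as pd

    rows = []
    for kind in EVENT_KINDS:
        for e in events_by_kind.get(kind, []):
            rows.append(
                {
                    "kind": e.kind,
                    "gene": e.gene_id,
                    "chrom": e.chrom,
                    "strand": e.strand,
                    "a": e.a, "b": e.b, "p": e.p, "q": e.q,
                    "p2": e.p2, "q2": e.q2, "c": e.c, "d": e.d,
                    "inclusion_ratio": e.inclusion_ratio,
                    "splicing_ratio": e.splicing_ratio,
                    "displacement": e.displacement,
                }
            )
    columns = ["kind", "gene", "chrom", "strand", "a", "b", "p", "q",
               "p2", "q2", "c", "d", "inclusion_ratio", "splicing_ratio",
               "displacement"]
    return pd.DataFrame(rows, columns=columns)
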