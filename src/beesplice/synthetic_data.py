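"""Synthetic genomes with planted alternative-splicing events.

The generator emits a coherent file set — genome FASTA, gene-model GFF3,
junction TSV, coverage bedGraph, BS-seq methylation TSV and a truth table —
in which every downstream quantity is known by construction:

* gene geometry mimics the honey bee transcriptome (exons averaging 320 nt,
  introns 1,390 nt, cassette exons shorter at ~178 nt);
* every intron boundary carries canonical GT/AG dinucleotides in
  transcription orientation;
* junction support counts are binomial draws at the locus read depth, so
  recomputing an event's inclusion or splicing ratio from the emitted files
  recovers the planted target up to binomial sampling error;
* background intron coverage is block-Poisson noise at 0.017x the exonic
  depth, mirroring the genome-wide baseline intron inclusion ratio;
* "methylated" exons are CpG-depleted by a configurable factor and receive
  methylation records with non-zero methylated counts;
* transcribed islands (covered blocks outside the annotation) plus novel
  junctions are planted to exercise gene-model augmentation.

Optional couplings plant the strength and methylation effects that the
figure-level analyses look for: strong splice sites at highly included
cassette exons, weak sites at highly retained introns, weak major sites
where the minor/major expression ratio is high, and CpG-rich displaced
regions for highly included alternative boundaries.  With couplings off the
same analyses see pure noise, giving a null control.

Everything is driven by one :class:`numpy.random.Generator`; a fixed seed
yields a byte-identical file set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gene_model import Gene, GeneModel, Transcript
from .io_formats import (
    CoverageTrack,
    GenomicInterval,
    MethylationRecord,
    SpliceJunction,
    write_coverage,
    write_fasta,
    write_gff3,
    write_junctions,
    write_methylation,
)
from .splice_strength import reverse_complement

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "plant_splice_site_strength",
    "simulate_ortholog_table",
    "reverse_complement_dataset",
    "TRUTH_HEADER",
]

TRUTH_HEADER = ["event_id", "kind", "gene", "chrom", "coords", "target_ratio"]

BASES = np.array(list("ACGT"))

# Donor site: 3 exonic + 6 intronic; GT fixed at intronic positions 0-1.
STRONG_DONOR_PWM = np.array(
    [
        [0.35, 0.35, 0.18, 0.12],
        [0.60, 0.12, 0.15, 0.13],
        [0.10, 0.05, 0.80, 0.05],
        [0.00, 0.00, 1.00, 0.00],  # G
        [0.00, 0.00, 0.00, 1.00],  # T
        [0.55, 0.03, 0.40, 0.02],
        [0.70, 0.08, 0.12, 0.10],
        [0.07, 0.06, 0.82, 0.05],
        [0.15, 0.15, 0.20, 0.50],
    ]
)
WEAK_DONOR_PWM = np.array(
    [[0.25, 0.25, 0.25, 0.25]] * 3
    + [[0.0, 0.0, 1.0, 0.0], [0.0, 0.0, 0.0, 1.0]]
    + [[0.25, 0.25, 0.25, 0.25]] * 4
)

# Acceptor site: 20 intronic + 3 exonic; AG fixed at intronic positions 18-19.
_PYRIMIDINE = [0.08, 0.38, 0.08, 0.46]
STRONG_ACCEPTOR_PWM = np.array(
    [_PYRIMIDINE] * 17
    + [[0.25, 0.35, 0.05, 0.35]]
    + [[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]]  # A, G
    + [[0.25, 0.15, 0.50, 0.10]]
    + [[0.25, 0.25, 0.25, 0.25]] * 2
)
WEAK_ACCEPTOR_PWM = np.array(
    [[0.25, 0.25, 0.25, 0.25]] * 18
    + [[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]]
    + [[0.25, 0.25, 0.25, 0.25]] * 3
)

PWM_POOLS = {
    ("donor", "strong"): STRONG_DONOR_PWM,
    ("donor", "weak"): WEAK_DONOR_PWM,
    ("acceptor", "strong"): STRONG_ACCEPTOR_PWM,
    ("acceptor", "weak"): WEAK_ACCEPTOR_PWM,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    chrom: str = "chr1"
    n_genes: int = 60
    exons_per_gene: tuple = (4, 7)
    exon_len_mean: float = 320.0
    exon_len_min: int = 80
    ce_exon_len_mean: float = 178.0
    intron_len_mean: float = 1390.0
    intron_len_min: int = 300
    intergenic_gap: int = 1000
    read_depth: int = 100
    intron_noise_factor: float = 0.017
    noise_block: int = 25
    # planted event counts
    n_ir: int = 0
    n_ce: int = 0
    n_alt_donor: int = 0
    n_alt_acceptor: int = 0
    n_afe: int = 0
    n_ale: int = 0
    n_novel_exon: int = 0
    n_novel_transcript: int = 0
    n_decoy_junctions: int = 0
    ratio_range: tuple = (0.1, 0.9)
    aeb_displacements: tuple = (3, 4, 5, 6, 7, 9, 12)
    coupled_displacement_range: tuple = (30, 120)
    # couplings: "none" (null), "coupled" (planted effect), "all_strong" (control)
    strength_coupling: str = "none"
    methylation_coupling: str = "none"
    methylated_fraction: float = 0.5
    cpg_depletion: float = 0.25
    base_freqs: tuple = (0.33, 0.17, 0.17, 0.33)  # A, C, G, T
    junction_score_range: tuple = (0.8, 1.0)
    max_layout_retries: int = 20

    def total_gene_events(self) -> int:
        return (self.n_ir + self.n_ce + self.n_alt_donor + self.n_alt_acceptor
                + self.n_afe + self.n_ale + self.n_novel_exon)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    model: GeneModel
    junctions: list[SpliceJunction]
    coverage: CoverageTrack
    methylation: list[MethylationRecord]
    truth: pd.DataFrame
    exon_states: list[tuple[GenomicInterval, str]]
    paths: dict | None = None


def plant_splice_site_strength(kind: str, target_ratio: float, coupling: str) -> dict:
    """Motif pool assignment for the splice sites of one planted event.

    Returns a mapping of site roles to pools (``"strong"``/``"weak"``).
    Under ``"coupled"`` planting: cassette exons with inclusion above 0.8
    get strong sites and weak otherwise; retained introns the reverse
    (high inclusion — weak sites); for boundary/terminal competition the
    major site is weak exactly when the minor/major expression ratio is
    high.  ``"all_strong"`` is the no-contrast control and ``"none"``
    plants bare GT/AG dinucleotides only.
    """
    if coupling == "all_strong":
        return {"site": "strong", "major": "strong", "minor": "strong"}
    if coupling != "coupled":
        return {}
    if kind == "CE":
        pool = "strong" if target_ratio > 0.8 else "weak"
        return {"site": pool}
    if kind == "IR":
        pool = "weak" if target_ratio > 0.5 else "strong"
        return {"site": pool}
    if kind in ("ALT_DONOR", "ALT_ACCEPTOR", "AFE", "ALE"):
        if target_ratio >= 0.5:
            return {"major": "weak", "minor": "strong"}
        return {"major": "strong", "minor": "weak"}
    return {}


def _sample_motif(rng, pwm: np.ndarray) -> str:
    idx = [rng.choice(4, p=row) for row in pwm]
    return "".join(BASES[idx])


def _length(rng, mean: float, minimum: int) -> int:
    return int(max(minimum, round(rng.gamma(4.0, mean / 4.0))))


class _Builder:
    """Accumulates the dataset while genes are laid out left to right."""

    def __init__(self, cfg: SimulationConfig, rng):
        self.cfg = cfg
        self.rng = rng
        self.cursor = 0
        self.model = GeneModel()
        self.junction_rows: dict[tuple, list] = {}  # key -> [score, support]
        self.coverage_writes: list[tuple[int, int, int]] = []
        self.islands: list[tuple[int, int]] = []
        self.truth_rows: list[dict] = []
        self.site_pools: dict[tuple, str] = {}  # (site_type, pos, strand) -> pool
        self.cpg_fills: list[tuple[int, int]] = []
        self.exon_states: list[tuple[tuple[int, int], str]] = []
        self.n_events = 0

    # -- helpers ---------------------------------------------------------

    def _score(self) -> float:
        lo, hi = self.cfg.junction_score_range
        return round(float(self.rng.uniform(lo, hi)), 3)

    def add_junction(self, start: int, end: int, strand: str,
                     support: int, score: float | None = None) -> None:
        key = (self.cfg.chrom, start, end, strand)
        if key in self.junction_rows:
            return
        self.junction_rows[key] = [self._score() if score is None else score,
                                   int(support)]

    def register_site(self, site_type: str, pos: int, strand: str,
                      pool: str | None) -> None:
        key = (site_type, pos, strand)
        if pool is not None:
            self.site_pools[key] = pool
        else:
            self.site_pools.setdefault(key, "dinuc")

    def target_ratio(self) -> float:
        lo, hi = self.cfg.ratio_range
        return round(float(self.rng.uniform(lo, hi)), 3)

    def truth(self, kind: str, gene: str, coords, ratio) -> None:
        self.truth_rows.append(
            {
                "event_id": f"ev{len(self.truth_rows):04d}",
                "kind": kind,
                "gene": gene,
                "chrom": self.cfg.chrom,
                "coords": ",".join(str(c) for c in coords),
                "target_ratio": "NA" if ratio is None else ratio,
            }
        )

    # -- gene construction ----------------------------------------------

    def build_gene(self, index: int, kind: str | None) -> None:
        cfg, rng = self.cfg, self.rng
        gid = f"g{index:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))

        exon_lens = [_length(rng, cfg.exon_len_mean, cfg.exon_len_min)
                     for _ in range(k)]
        intron_lens = [_length(rng, cfg.intron_len_mean, cfg.intron_len_min)
                       for _ in range(k - 1)]

        coupled = (cfg.strength_coupling != "none"
                   or cfg.methylation_coupling != "none")
        ratio = self.target_ratio() if kind else None
        plan: dict = {"kind": kind, "ratio": ratio}

        if kind == "CE":
            plan["ce_index"] = int(rng.integers(1, k - 1))
            exon_lens[plan["ce_index"]] = _length(
                rng, cfg.ce_exon_len_mean, max(50, cfg.exon_len_min // 2)
            )
        elif kind == "IR":
            plan["ir_index"] = int(rng.integers(0, k - 1))
        elif kind in ("ALT_DONOR", "ALT_ACCEPTOR"):
            plan["intron_index"] = int(rng.integers(0, k - 1))
            if coupled:
                lo, hi = cfg.coupled_displacement_range
                plan["displacement"] = int(rng.integers(lo, hi + 1))
            else:
                plan["displacement"] = int(rng.choice(cfg.aeb_displacements))
            plan["major_is_annotated"] = bool(rng.random() < 0.5)

        # genomic segment layout (plus-orientation transcription order,
        # reversed wholesale for minus-strand genes)
        segments: list[tuple[str, int]] = []
        if kind == "AFE":
            alt_len = _length(rng, cfg.exon_len_mean, cfg.exon_len_min)
            segments += [("exon_first_major", exon_lens[0]),
                         ("gap", _length(rng, 600, 250)),
                         ("exon_first_minor", alt_len),
                         ("gap", intron_lens[0])]
            body = list(range(1, k))
        elif kind == "ALE":
            body = list(range(0, k - 1))
        else:
            body = list(range(k))
        for pos, i in enumerate(body):
            segments.append((f"exon{i}", exon_lens[i]))
            if pos < len(body) - 1:
                segments.append((f"intron{i}", intron_lens[i]))
        if kind == "ALE":
            alt_len = _length(rng, cfg.exon_len_mean, cfg.exon_len_min)
            segments += [("gap", intron_lens[k - 2]),
                         ("exon_last_major", exon_lens[k - 1]),
                         ("gap", _length(rng, 600, 250)),
                         ("exon_last_minor", alt_len)]
        if kind == "NOVEL_EXON":
            island_len = int(rng.integers(120, 220))
            segments += [("gap", int(rng.integers(350, 550))),
                         ("island", island_len)]

        if strand == "-":
            segments = segments[::-1]

        gap = cfg.intergenic_gap + int(rng.integers(0, 400))
        self.cursor += gap
        coords: dict[str, tuple[int, int]] = {}
        for tag, length in segments:
            coords[tag] = (self.cursor, self.cursor + length)
            self.cursor += length

        self._emit_gene(gid, strand, k, kind, plan, coords)

    def _emit_gene(self, gid, strand, k, kind, plan, coords) -> None:
        cfg, rng = self.cfg, self.rng
        chrom = cfg.chrom
        depth = cfg.read_depth

        def iv(tag):
            s, e = coords[tag]
            return GenomicInterval(chrom, s, e, strand)

        gene = Gene(id=gid, chrom=chrom, strand=strand)

        def add_transcript(tid, tags):
            exons = sorted((iv(t) for t in tags), key=lambda x: x.start)
            gene.transcripts[tid] = Transcript(
                id=tid, gene_id=gid, exons=exons,
                exon_provenance=["annotated"] * len(exons),
            )
            return gene.transcripts[tid]

        body_tags = [f"exon{i}" for i in range(k) if f"exon{i}" in coords]
        if kind == "AFE":
            t1 = add_transcript(f"{gid}.t1", ["exon_first_major"] + body_tags)
            t2 = add_transcript(f"{gid}.t2", ["exon_first_minor"] + body_tags)
        elif kind == "ALE":
            t1 = add_transcript(f"{gid}.t1", body_tags + ["exon_last_major"])
            t2 = add_transcript(f"{gid}.t2", body_tags + ["exon_last_minor"])
        else:
            t1 = add_transcript(f"{gid}.t1", body_tags)
            t2 = None
        self.model.genes[gid] = gene

        # coverage for exons
        ratio = plan.get("ratio")
        for t in gene.transcripts.values():
            for exon in t.exons:
                self.coverage_writes.append((exon.start, exon.end, depth))

        # introns of all transcripts -> junctions with default support
        all_introns = []
        for t in gene.transcripts.values():
            all_introns.extend(t.introns())
        seen = set()
        introns = []
        for intron in sorted(all_introns, key=lambda x: (x.start, x.end)):
            if (intron.start, intron.end) in seen:
                continue
            seen.add((intron.start, intron.end))
            introns.append(intron)

        support_override: dict[tuple[int, int], int] = {}
        extra_junctions: list[tuple[int, int, int]] = []

        pools = plant_splice_site_strength(kind, ratio, cfg.strength_coupling) if kind else {}

        if kind == "CE":
            ce_iv = iv(f"exon{plan['ce_index']}")
            idx = next(i for i, e in enumerate(t1.exons) if e.start == ce_iv.start)
            ce = t1.exons[idx]
            up = t1.exons[idx - 1]
            down = t1.exons[idx + 1]
            r = ratio
            support_override[(up.end, ce.start)] = int(rng.binomial(depth, r))
            support_override[(ce.end, down.start)] = int(rng.binomial(depth, r))
            extra_junctions.append((up.end, down.start, int(rng.binomial(depth, 1 - r))))
            self.coverage_writes.append((ce.start, ce.end, max(1, round(r * depth))))
            self.truth("CE", gid, (ce.start, ce.end), r)
            pool = pools.get("site")
            if strand == "+":
                self.register_site("acceptor", ce.start, strand, pool)
                self.register_site("donor", ce.end, strand, pool)
            else:
                self.register_site("donor", ce.start, strand, pool)
                self.register_site("acceptor", ce.end, strand, pool)
            if cfg.methylation_coupling == "coupled":
                self.exon_states.append(
                    ((ce.start, ce.end), "methylated" if r > 0.5 else "unmethylated")
                )
        elif kind == "IR":
            intron = t1.introns()[plan["ir_index"]]
            r = ratio
            self.coverage_writes.append(
                (intron.start, intron.end, max(1, round(r * depth)))
            )
            self.truth("IR", gid, (intron.start, intron.end), r)
            pool = pools.get("site")
            if pool:
                if strand == "+":
                    self.register_site("donor", intron.start, strand, pool)
                    self.register_site("acceptor", intron.end, strand, pool)
                else:
                    self.register_site("acceptor", intron.start, strand, pool)
                    self.register_site("donor", intron.end, strand, pool)
        elif kind in ("ALT_DONOR", "ALT_ACCEPTOR"):
            intron = t1.introns()[plan["intron_index"]]
            d = plan["displacement"]
            r = ratio
            # which genomic end of the intron is the moved (donor/acceptor) side
            moved_start = (kind == "ALT_DONOR") == (strand == "+")
            if moved_start:
                alt = (intron.start + d, intron.end)
                moved_pair = (intron.start, alt[0])
                site_type = "donor" if strand == "+" else "acceptor"
                annot_pos, alt_pos = intron.start, alt[0]
            else:
                alt = (intron.start, intron.end - d)
                moved_pair = (intron.end, alt[1])
                site_type = "acceptor" if strand == "+" else "donor"
                annot_pos, alt_pos = intron.end, alt[1]
            major_annot = plan["major_is_annotated"]
            minor_support = int(rng.binomial(depth, r))
            if major_annot:
                support_override[(intron.start, intron.end)] = depth
                extra_junctions.append((alt[0], alt[1], minor_support))
            else:
                support_override[(intron.start, intron.end)] = minor_support
                extra_junctions.append((alt[0], alt[1], depth))
            self.truth(kind, gid, moved_pair, r)
            major_pos = annot_pos if major_annot else alt_pos
            minor_pos = alt_pos if major_annot else annot_pos
            self.register_site(site_type, major_pos, strand, pools.get("major"))
            self.register_site(site_type, minor_pos, strand, pools.get("minor"))
            if cfg.methylation_coupling == "coupled":
                # region between the boundary variants is included in the
                # exon by the higher-support junction iff the shorter intron
                # is the major one; CG-rich fill marks high-inclusion events
                minor_r = r
                shorter_is_major = major_annot == (
                    (moved_start and annot_pos > alt_pos)
                    or (not moved_start and annot_pos < alt_pos)
                )
                inclusion = (1.0 if shorter_is_major else minor_r) / (1.0 + minor_r)
                if inclusion > 0.5:
                    lo, hi = min(annot_pos, alt_pos), max(annot_pos, alt_pos)
                    self.cpg_fills.append((lo, hi))
        elif kind in ("AFE", "ALE"):
            r = ratio
            if kind == "AFE":
                major_exon = iv("exon_first_major")
                minor_exon = iv("exon_first_minor")
                major_intron = (t1.introns()[0] if strand == "+"
                                else t1.introns()[-1])
                minor_intron = (t2.introns()[0] if strand == "+"
                                else t2.introns()[-1])
                site_type = "donor"
                major_pos = major_exon.end if strand == "+" else major_exon.start
                minor_pos = minor_exon.end if strand == "+" else minor_exon.start
            else:
                major_exon = iv("exon_last_major")
                minor_exon = iv("exon_last_minor")
                major_intron = (t1.introns()[-1] if strand == "+"
                                else t1.introns()[0])
                minor_intron = (t2.introns()[-1] if strand == "+"
                                else t2.introns()[0])
                site_type = "acceptor"
                major_pos = major_exon.start if strand == "+" else major_exon.end
                minor_pos = minor_exon.start if strand == "+" else minor_exon.end
            support_override[(major_intron.start, major_intron.end)] = depth
            support_override[(minor_intron.start, minor_intron.end)] = int(
                rng.binomial(depth, r)
            )
            self.coverage_writes.append(
                (minor_exon.start, minor_exon.end, max(1, round(r * depth)))
            )
            self.truth(
                kind, gid,
                (major_exon.start, major_exon.end,
                 minor_exon.start, minor_exon.end),
                r,
            )
            self.register_site(site_type, major_pos, strand, pools.get("major"))
            self.register_site(site_type, minor_pos, strand, pools.get("minor"))
        elif kind == "NOVEL_EXON":
            s, e = coords["island"]
            self.islands.append((s, e))
            self.coverage_writes.append((s, e, depth))
            if strand == "+":
                last = t1.exons[-1]
                extra_junctions.append((last.end, s, depth))
                self.register_site("donor", last.end, strand, None)
                self.register_site("acceptor", s, strand, None)
                self.truth("NOVEL_EXON", gid, (s, e), None)
            else:
                first = t1.exons[0]
                extra_junctions.append((e, first.start, depth))
                self.register_site("donor", first.start, strand, None)
                self.register_site("acceptor", e, strand, None)
                self.truth("NOVEL_EXON", gid, (s, e), None)

        if kind:
            self.n_events += 1

        # default sites + junction emission for every annotated intron
        train_pool = "strong" if cfg.strength_coupling != "none" else None
        for intron in introns:
            if strand == "+":
                self.register_site("donor", intron.start, strand,
                                   None if train_pool is None else
                                   self.site_pools.get(("donor", intron.start, strand),
                                                        train_pool))
                self.register_site("acceptor", intron.end, strand,
                                   None if train_pool is None else
                                   self.site_pools.get(("acceptor", intron.end, strand),
                                                        train_pool))
            else:
                self.register_site("acceptor", intron.start, strand,
                                   None if train_pool is None else
                                   self.site_pools.get(("acceptor", intron.start, strand),
                                                        train_pool))
                self.register_site("donor", intron.end, strand,
                                   None if train_pool is None else
                                   self.site_pools.get(("donor", intron.end, strand),
                                                        train_pool))
            support = support_override.get((intron.start, intron.end), depth)
            self.add_junction(intron.start, intron.end, strand, support)
        for s, e, support in extra_junctions:
            self.add_junction(s, e, strand, support)
            if strand == "+":
                self.register_site("donor", s, strand, None)
                self.register_site("acceptor", e, strand, None)
            else:
                self.register_site("acceptor", s, strand, None)
                self.register_site("donor", e, strand, None)

        # methylation states for ordinary exons
        for t in gene.transcripts.values():
            for exon in t.exons:
                key = (exon.start, exon.end)
                if any(k == key for k, _ in self.exon_states):
                    continue
                if cfg.methylation_coupling in ("coupled", "random"):
                    state = ("methylated"
                             if rng.random() < cfg.methylated_fraction
                             else "unmethylated")
                    self.exon_states.append((key, state))

    def build_intergenic_transcript(self, index: int) -> None:
        cfg, rng = self.cfg, self.rng
        gap = cfg.intergenic_gap + 1200 + int(rng.integers(0, 400))
        self.cursor += gap
        len1 = int(rng.integers(150, 260))
        intron = int(rng.integers(400, 700))
        len2 = int(rng.integers(150, 260))
        s1 = self.cursor
        e1 = s1 + len1
        s2 = e1 + intron
        e2 = s2 + len2
        self.cursor = e2
        strand = "+" if rng.random() < 0.5 else "-"
        self.islands += [(s1, e1), (s2, e2)]
        self.coverage_writes += [(s1, e1, cfg.read_depth), (s2, e2, cfg.read_depth)]
        self.add_junction(e1, s2, strand, cfg.read_depth)
        if strand == "+":
            self.register_site("donor", e1, strand, None)
            self.register_site("acceptor", s2, strand, None)
        else:
            self.register_site("acceptor", e1, strand, None)
            self.register_site("donor", s2, strand, None)
        self.truth("NOVEL_TRANSCRIPT", f"intergenic{index}",
                   (s1, e1, s2, e2), None)

    def add_decoys(self) -> None:
        """Low-confidence junctions that must be removed by score filtering."""
        cfg, rng = self.cfg, self.rng
        gene_ids = sorted(self.model.genes)
        if not gene_ids:
            return
        for i in range(cfg.n_decoy_junctions):
            gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
            gene = self.model.genes[gid]
            t = gene.transcripts[sorted(gene.transcripts)[0]]
            score = round(float(rng.uniform(0.05, 0.5)), 3)
            support = int(rng.poisson(3))
            if i % 2 == 0 and len(t.exons) >= 3:
                # would look like exon skipping if the filter failed
                j = int(rng.integers(0, len(t.exons) - 2))
                self.add_junction(t.exons[j].end, t.exons[j + 2].start,
                                  gene.strand, support, score=score)
            else:
                introns = t.introns()
                intron = introns[int(rng.integers(0, len(introns)))]
                if len(intron) < 60:
                    continue
                self.add_junction(intron.start + 17, intron.end - 17,
                                  gene.strand, support, score=score)


def _write_dinucleotides(seq: np.ndarray, site_type: str, pos: int, strand: str):
    if site_type == "donor":
        if strand == "+":
            seq[pos], seq[pos + 1] = "G", "T"
        else:
            seq[pos - 2], seq[pos - 1] = "A", "C"
    else:
        if strand == "+":
            seq[pos - 2], seq[pos - 1] = "A", "G"
        else:
            seq[pos], seq[pos + 1] = "C", "T"


def _write_motif(seq: np.ndarray, site_type: str, pos: int, strand: str,
                 motif: str) -> None:
    if site_type == "donor":
        window = (pos - 3, pos + 6) if strand == "+" else (pos - 6, pos + 3)
    else:
        window = (pos - 20, pos + 3) if strand == "+" else (pos - 3, pos + 20)
    text = motif if strand == "+" else reverse_complement(motif)
    s, e = window
    if s < 0 or e > seq.size:
        return
    seq[s:e] = list(text)


def simulate(config: SimulationConfig, out_dir=None) -> SimulatedDataset:
    """Generate one dataset; write its file set when ``out_dir`` is given."""
    cfg = config
    if cfg.total_gene_events() > cfg.n_genes:
        raise ValueError(
            f"{cfg.total_gene_events()} planted events exceed {cfg.n_genes} genes"
        )
    rng = np.random.default_rng(cfg.seed)
    builder = _Builder(cfg, rng)

    kinds = (
        ["IR"] * cfg.n_ir + ["CE"] * cfg.n_ce
        + ["ALT_DONOR"] * cfg.n_alt_donor + ["ALT_ACCEPTOR"] * cfg.n_alt_acceptor
        + ["AFE"] * cfg.n_afe + ["ALE"] * cfg.n_ale
        + ["NOVEL_EXON"] * cfg.n_novel_exon
    )
    kinds += [None] * (cfg.n_genes - len(kinds))
    order = rng.permutation(len(kinds))
    assignment = [kinds[i] for i in order]

    for index, kind in enumerate(assignment):
        builder.build_gene(index, kind)
    for index in range(cfg.n_novel_transcript):
        builder.build_intergenic_transcript(index)
    builder.add_decoys()

    length = builder.cursor + cfg.intergenic_gap
    # base sequence
    seq = BASES[rng.choice(4, size=length, p=np.asarray(cfg.base_freqs))]

    # CpG depletion of methylated exons (germline hyper-methylation proxy)
    for (s, e), state in builder.exon_states:
        if state != "methylated":
            continue
        window = seq[s:e]
        cg = np.flatnonzero((window[:-1] == "C") & (window[1:] == "G"))
        for off in cg:
            if rng.random() > cfg.cpg_depletion:
                window[off + 1] = "T"
        seq[s:e] = window

    # CG-rich fills for methylation-coupled boundary regions
    for s, e in builder.cpg_fills:
        fill = np.tile(np.array(["C", "G"]), (e - s) // 2 + 1)[: e - s]
        seq[s:e] = fill

    # splice-site motifs last so GT/AG dinucleotides always survive
    for (site_type, pos, strand) in sorted(builder.site_pools):
        pool = builder.site_pools[(site_type, pos, strand)]
        if pool == "dinuc":
            _write_dinucleotides(seq, site_type, pos, strand)
        else:
            motif = _sample_motif(rng, PWM_POOLS[(site_type, pool)])
            _write_motif(seq, site_type, pos, strand, motif)
            _write_dinucleotides(seq, site_type, pos, strand)

    genome = {cfg.chrom: "".join(seq)}

    # coverage: block-Poisson intron/intergenic noise, exact exon depths
    arr = np.zeros(length, dtype=np.int64)
    if cfg.intron_noise_factor > 0:
        n_blocks = length // cfg.noise_block + 1
        noise = rng.poisson(cfg.intron_noise_factor * cfg.read_depth, n_blocks)
        arr[:] = np.repeat(noise, cfg.noise_block)[:length]
    for s, e, depth in builder.coverage_writes:
        arr[s:e] = depth
    coverage = CoverageTrack({cfg.chrom: arr})

    # methylation records from the final sequence
    records = []
    for (s, e), state in sorted(builder.exon_states):
        window = seq[s:e]
        cg = np.flatnonzero((window[:-1] == "C") & (window[1:] == "G"))
        for off in cg:
            total = 20
            meth = (max(1, int(rng.binomial(total, 0.8)))
                    if state == "methylated" else 0)
            records.append(
                MethylationRecord(chrom=cfg.chrom, pos=int(s + off), strand="+",
                                  context="CG", methylated=meth, total=total)
            )

    junctions = [
        SpliceJunction(
            intron=GenomicInterval(chrom, s, e, strand),
            score=score, support=support,
        )
        for (chrom, s, e, strand), (score, support) in sorted(builder.junction_rows.items())
    ]

    builder.model.rebuild_indexes()
    builder.model.attach_genome(genome)
    truth = pd.DataFrame(builder.truth_rows, columns=TRUTH_HEADER)

    dataset = SimulatedDataset(
        config=cfg,
        genome=genome,
        model=builder.model,
        junctions=junctions,
        coverage=coverage,
        methylation=records,
        truth=truth,
        exon_states=[
            (GenomicInterval(cfg.chrom, s, e), state)
            for (s, e), state in builder.exon_states
        ],
    )
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fa",
            "gff3": out / "annotation.gff3",
            "junctions": out / "junctions.tsv",
            "coverage": out / "coverage.bedgraph",
            "methylation": out / "methylation.tsv",
            "truth": out / "truth.tsv",
        }
        write_fasta(genome, paths["fasta"])
        write_gff3(dataset.model, paths["gff3"])
        write_junctions(junctions, paths["junctions"])
        write_coverage(coverage, paths["coverage"])
        write_methylation(records, paths["methylation"])
        with open(paths["truth"], "w") as handle:
            handle.write("#" + "\t".join(TRUTH_HEADER) + "\n")
            truth.to_csv(handle, sep="\t", header=False, index=False)
        dataset.paths = {k: str(v) for k, v in paths.items()}
    return dataset


def simulate_ortholog_table(
    truth: pd.DataFrame,
    seed: int = 0,
    fraction_with_ortholog: float = 0.6,
    fraction_as_ortholog: float = 0.5,
    fraction_equal: float = 0.5,
) -> pd.DataFrame:
    """An ortholog table consistent with a truth table's per-gene AS counts."""
    rng = np.random.default_rng(seed)
    counts = truth[~truth["kind"].isin(["NOVEL_EXON", "NOVEL_TRANSCRIPT"])]
    per_gene = counts.groupby("gene").size()
    rows = []
    for i, (gene, n) in enumerate(sorted(per_gene.items())):
        if rng.random() >= fraction_with_ortholog:
            continue
        if rng.random() < fraction_as_ortholog:
            if rng.random() < fraction_equal:
                ortholog_n = int(n)
            else:
                ortholog_n = int(n) + 1 + int(rng.integers(0, 3))
        else:
            ortholog_n = 0
        rows.append(
            {"gene_id": gene, "ortholog_id": f"FBgn{i:07d}",
             "ortholog_as_events": ortholog_n}
        )
    return pd.DataFrame(rows, columns=["gene_id", "ortholog_id",
                                       "ortholog_as_events"])


def reverse_complement_dataset(dataset: SimulatedDataset) -> SimulatedDataset:
    """Mirror a dataset: reverse-complement the genome and remap all records.

    Detection on the mirrored dataset must yield the same events with
    coordinates mapped through ``x -> L - x`` and strands flipped.
    """
    cfg = dataset.config
    chrom = cfg.chrom
    L = len(dataset.genome[chrom])

    def flip(strand: str) -> str:
        return {"+": "-", "-": "+", ".": "."}[strand]

    genome = {chrom: reverse_complement(dataset.genome[chrom])}

    model = GeneModel()
    for gid, gene in dataset.model.genes.items():
        new_gene = Gene(id=gid, chrom=chrom, strand=flip(gene.strand),
                        provenance=gene.provenance)
        for tid, t in gene.transcripts.items():
            exons = sorted(
                (GenomicInterval(chrom, L - e.end, L - e.start, flip(e.strand))
                 for e in t.exons),
                key=lambda x: x.start,
            )
            new_gene.transcripts[tid] = Transcript(
                id=tid, gene_id=gid, exons=exons,
                exon_provenance=list(t.exon_provenance[::-1]),
                provenance=t.provenance,
            )
        model.genes[gid] = new_gene
    model.rebuild_indexes()
    model.attach_genome(genome)

    junctions = sorted(
        (
            SpliceJunction(
                intron=GenomicInterval(chrom, L - j.end, L - j.start,
                                       flip(j.strand)),
                score=j.score, support=j.support,
            )
            for j in dataset.junctions
        ),
        key=lambda j: (j.start, j.end),
    )
    coverage = CoverageTrack({chrom: dataset.coverage.depths[chrom][::-1].copy()})
    methylation = [
        MethylationRecord(chrom=chrom, pos=L - r.pos - 2, strand=flip(r.strand),
                          context=r.context, methylated=r.methylated,
                          total=r.total)
        for r in dataset.methylation
    ]

    truth = dataset.truth.copy()
    truth["coords"] = truth["coords"].map(
        lambda text: ",".join(
            str(c) for c in _flip_coords([int(x) for x in text.split(",")], L)
        )
    )
    exon_states = [
        (GenomicInterval(chrom, L - iv.end, L - iv.start), state)
        for iv, state in dataset.exon_states
    ]
    return SimulatedDataset(
        config=replace(cfg),
        genome=genome,
        model=model,
        junctions=junctions,
        coverage=coverage,
        methylation=methylation,
        truth=truth,
        exon_states=exon_states,
    )


def _flip_coords(coords: list[int], L: int) -> list[int]:
    return [L - c for c in coords]
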