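"""Pipeline orchestration: junctions → model augmentation → event detection
→ quantitative comparisons → report bundle.

The report layer only composes operations that the other modules expose;
every number it emits can be re-derived from the event tables it writes.
Raw (uncorrected) Mann-Whitney p-values are reported throughout — no
multiple-testing correction is applied, which should be kept in mind when
many bin comparisons are read together.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import mannwhitneyu

from . import __version__
from . import as_detection, gene_model, io_formats, methylation, splice_strength
from .as_detection import EVENT_KINDS
from .io_formats import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "mann_whitney",
           "table1_counts", "training_sites"]


@dataclass
class PipelineConfig:
    genome_fasta: str | None = None
    gff3: str | None = None
    junctions: str | None = None
    coverage: str | None = None
    methylation: str | None = None
    orthologs: str | None = None
    out_dir: str | None = None
    sj_score_threshold: float = 0.5
    ir_min_depth: int = 5
    ir_baseline: float = 0.017
    aeb_max_displacement: int = 200
    island_min_depth: int = 5
    island_min_len: int = 50
    island_max_gap: int = 10
    ratio_bins: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    constraint_order: int = 2
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.sj_score_threshold < 0 or self.ir_min_depth <= 0:
            raise ValueError("thresholds must be positive")
        edges = list(self.ratio_bins)
        if edges != sorted(edges) or len(set(edges)) != len(edges):
            raise ValueError("ratio bin edges must be strictly increasing")


@dataclass
class ReportBundle:
    config: PipelineConfig
    model: object
    events: dict
    events_table: object
    table1: object
    displacement: dict
    strength: dict | None
    relative_strength: dict | None
    methylation: dict | None
    conservation: dict | None
    manifest: dict = field(default_factory=dict)


def mann_whitney(group_a, group_b) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value.

    Exact null distribution when the combined sample size is at most 20 and
    there are no ties; tie-corrected normal approximation otherwise.
    Identical constant groups give p = 1.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 1.0
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    return float(
        mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def table1_counts(events_by_kind: dict):
    """Per-kind event / involved-exon / gene counts.

    For retained introns the two flanking exons count as involved exons;
    other kinds involve the event (or alternative terminal) exon itself.
    """
    import pandas as pd

    rows = []
    for kind in EVENT_KINDS:
        events = events_by_kind.get(kind, [])
        exons = set()
        genes = set()
        for e in events:
            genes.add(e.gene_id)
            if kind == "IR":
                exons.add((e.chrom, e.a, e.b))
                exons.add((e.chrom, e.c, e.d))
            elif kind == "CE":
                exons.add((e.chrom, e.p, e.q))
            elif kind in ("ALT_DONOR", "ALT_ACCEPTOR"):
                if e.p2 is not None:
                    exons.add((e.chrom, e.a, e.p))
                else:
                    exons.add((e.chrom, e.q, e.d))
            else:  # AFE/ALE: both terminal exons are involved
                exons.add((e.chrom, e.p, e.q))
                exons.add((e.chrom, e.p2, e.q2))
        rows.append(
            {
                "kind": kind,
                "number": len(events),
                "exons_involved": len(exons),
                "genes": len(genes),
            }
        )
    return pd.DataFrame(rows)


def training_sites(model, genome):
    """Donor/acceptor motif windows of the annotated introns, for model
    training.  Introns of novel (augmented) transcripts are excluded."""
    donors, acceptors = [], []
    for gene, transcript in model.iter_transcripts():
        if transcript.provenance == "novel":
            continue
        for intron in transcript.introns():
            plus = gene.strand != "-"
            dpos = intron.start if plus else intron.end
            apos = intron.end if plus else intron.start
            d = splice_strength.donor_window(genome, gene.chrom, dpos, gene.strand)
            a = splice_strength.acceptor_window(genome, gene.chrom, apos, gene.strand)
            if d and all(ch in "ACGT" for ch in d):
                donors.append(d)
            if a and all(ch in "ACGT" for ch in a):
                acceptors.append(a)
    return donors, acceptors


def _check_chrom_namespace(genome, model, junctions, coverage) -> None:
    known = set(genome)
    offenders = set()
    for gene in model.genes.values():
        if gene.chrom not in known:
            offenders.add(gene.chrom)
    for j in junctions:
        if j.chrom not in known:
            offenders.add(j.chrom)
    for chrom in coverage.chroms():
        if chrom not in known:
            offenders.add(chrom)
    if offenders:
        raise ValueError(
            "chromosome names absent from the genome: "
            + ", ".join(sorted(offenders))
        )


def run_pipeline(config: PipelineConfig, dataset=None) -> ReportBundle:
    """Run the full analysis, from files or from an in-memory dataset.

    ``dataset`` (a :class:`~beesplice.synthetic_data.SimulatedDataset` or
    any object with the same attributes) short-circuits file reading; with
    ``config.out_dir`` set, the augmented GFF3, event table, per-kind count
    table and a JSON manifest are written there deterministically.
    """
    import pandas as pd

    if dataset is not None:
        genome = dataset.genome
        model = dataset.model.copy()  # augmentation must not touch the input
        junctions = dataset.junctions
        coverage = dataset.coverage
        meth_records = dataset.methylation
        ortholog_table = None
    else:
        genome = io_formats.read_fasta(config.genome_fasta)
        model = io_formats.read_gff3(config.gff3)
        junctions = io_formats.read_junctions(config.junctions)
        coverage = io_formats.read_coverage(
            config.coverage, {c: len(s) for c, s in genome.items()}
        )
        meth_records = (
            io_formats.read_methylation(config.methylation)
            if config.methylation
            else []
        )
        ortholog_table = (
            io_formats.read_orthologs(config.orthologs)
            if config.orthologs
            else None
        )
        model.attach_genome(genome)
    _check_chrom_namespace(genome, model, junctions, coverage)

    # 1. score filtering + partition against the input annotation
    partition = gene_model.filter_junctions(
        junctions, model, score_threshold=config.sj_score_threshold
    )

    # 2. transcribed islands and model augmentation
    islands = gene_model.find_transcribed_islands(
        coverage, model,
        min_depth=config.island_min_depth,
        min_len=config.island_min_len,
        max_gap=config.island_max_gap,
    )
    model = gene_model.augment_model(model, partition, islands)

    # 3. re-partition against the augmented model, then detect events
    partition = gene_model.filter_junctions(
        junctions, model, score_threshold=config.sj_score_threshold
    )
    events = as_detection.detect_all(
        model, partition, coverage,
        baseline=config.ir_baseline,
        min_depth=config.ir_min_depth,
        max_displacement=config.aeb_max_displacement,
    )
    flat = [e for kind in EVENT_KINDS for e in events[kind]]
    events_table = as_detection.events_to_table(events)
    table1 = table1_counts(events)
    displacement = as_detection.displacement_spectrum(flat)

    # 4. splice-site strength comparisons
    strength = relative = None
    donors, acceptors = training_sites(model, genome)
    if len(donors) >= 100 and len(acceptors) >= 100:
        base_counts = np.zeros(4)
        for i, base in enumerate("ACGT"):
            base_counts[i] = sum(seq.count(base) for seq in genome.values())
        model_d = splice_strength.train(
            donors, "donor", constraint_order=config.constraint_order,
            background=base_counts,
        )
        model_a = splice_strength.train(
            acceptors, "acceptor", constraint_order=config.constraint_order,
            background=base_counts,
        )
        strength = splice_strength.strength_vs_inclusion(
            flat, model_d, model_a, genome, bins=config.ratio_bins
        )
        relative = splice_strength.relative_strength_vs_splicing_ratio(
            flat, model_d, model_a, genome, bins=config.ratio_bins
        )

    # 5. methylation / CpG comparisons
    all_intron_oe = []
    for _gene, transcript in model.iter_transcripts():
        for intron in transcript.introns():
            s = methylation.cpg_oe(genome, intron)
            if s.oe is not None:
                all_intron_oe.append(s.oe)
    meth = methylation.methylation_vs_inclusion(
        flat, genome, bins=config.ratio_bins, all_intron_oe=all_intron_oe
    )
    if meth_records:
        index = methylation.MethylationIndex(meth_records)
        statuses = {"methylated": 0, "unmethylated": 0, "no_data": 0}
        for e in flat:
            region = _event_region(e)
            if region is not None:
                statuses[methylation.region_methylation_status(region, index)] += 1
        meth["event_region_status_counts"] = statuses

    # 6. conservation
    conservation_summary = None
    if ortholog_table is not None:
        from .conservation import conservation_summary as summarize

        conservation_summary = summarize(events, ortholog_table)

    manifest = {
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if not k.startswith("_")
        },
        "n_junctions_input": len(junctions),
        "n_junctions_discarded": partition.n_discarded,
        "n_islands": len(islands),
        "n_genes": len(model.genes),
        "event_counts": {kind: len(events[kind]) for kind in EVENT_KINDS},
    }

    bundle = ReportBundle(
        config=config,
        model=model,
        events=events,
        events_table=events_table,
        table1=table1,
        displacement=displacement,
        strength=strength,
        relative_strength=relative,
        methylation=meth,
        conservation=conservation_summary,
        manifest=manifest,
    )
    if config.out_dir:
        _write_bundle(bundle, genome)
    return bundle


def _event_region(e) -> GenomicInterval | None:
    if e.kind in ("IR", "CE"):
        return GenomicInterval(e.chrom, e.p, e.q, e.strand)
    if e.kind in ("ALT_DONOR", "ALT_ACCEPTOR"):
        lo, hi = ((e.p2, e.p) if e.p2 is not None else (e.q, e.q2))
        lo, hi = min(lo, hi), max(lo, hi)
        if lo == hi:
            return None
        return GenomicInterval(e.chrom, lo, hi, e.strand)
    return GenomicInterval(e.chrom, min(e.p, e.p2), max(e.q, e.q2), e.strand)


def _write_bundle(bundle: ReportBundle, genome) -> None:
    out = Path(bundle.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_gff3(bundle.model, out / "augmented.gff3")
    bundle.events_table.to_csv(out / "events.tsv", sep="\t", index=False)
    bundle.table1.to_csv(out / "event_counts.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as handle:
        json.dump(bundle.manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    spectrum = {
        k: v for k, v in bundle.displacement.items()
    }
    with open(out / "displacement_spectrum.json", "w") as handle:
        json.dump(spectrum, handle, indent=2, sort_keys=True)
        handle.write("\n")
    if bundle.config.make_plots:
        _plot_spectrum(bundle, out)


def _plot_spectrum(bundle: ReportBundle, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    for ax, side in zip(axes, ("donor", "acceptor")):
        hist = bundle.displacement[side]
        if hist:
            ax.bar(list(hist.keys()), list(hist.values()), color="#4477aa")
        ax.set_title(f"alternative {side} sites")
        ax.set_xlabel("displacement (nt)")
    axes[0].set_ylabel("events")
    fig.tight_layout()
    fig.savefig(out / "displacement_spectrum.png", dpi=120)
    plt.close(fig)
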