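"""CpG depletion metrics and BS-seq region methylation calls.

CpG(o/e) — observed over expected CpG dinucleotide frequency,
``P_CpG / (P_C * P_G)`` — is an evolutionary proxy for germline DNA
methylation: methylated cytosines deaminate to thymine over time, so a
low o/e marks a historically hyper-methylated region, a high o/e a
hypo-methylated one.  Dinucleotides are counted overlapping, with
denominator ``L - 1``; base frequencies use the full length ``L``.  All
counting is done on the plus-strand sequence: a CpG is its own reverse
complement, so the statistic is strand-symmetric.

BS-seq records classify a region as *methylated* as soon as one CpG
cytosine in it carries a non-zero methylated count (on either strand),
*unmethylated* when it has covered CpGs but none methylated, and
*no_data* otherwise.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, ttest_ind

from .io_formats import GenomicInterval, MethylationRecord

__all__ = [
    "CpGScore",
    "cpg_oe",
    "cpg_oe_seq",
    "relative_cpg_for_aeb",
    "MethylationIndex",
    "region_methylation_status",
    "methylation_vs_inclusion",
]


@dataclass(frozen=True)
class CpGScore:
    region: GenomicInterval | None
    p_cpg: float
    p_c: float
    p_g: float
    oe: float | None  # None (NA) when p_c * p_g == 0


def cpg_oe_seq(seq: str, region: GenomicInterval | None = None) -> CpGScore:
    """CpG(o/e) of a raw sequence (must be at least 2 nt)."""
    seq = seq.upper()
    L = len(seq)
    if L < 2:
        raise ValueError("region shorter than 2 nt")
    informative = sum(1 for b in seq if b in "ACGT")
    if informative == 0:
        return CpGScore(region, np.nan, np.nan, np.nan, None)
    n_cpg = seq.count("CG")
    p_cpg = n_cpg / (L - 1)
    p_c = seq.count("C") / L
    p_g = seq.count("G") / L
    denom = p_c * p_g
    oe = p_cpg / denom if denom > 0 else None
    return CpGScore(region, p_cpg, p_c, p_g, oe)


def cpg_oe(genome: dict[str, str], region: GenomicInterval) -> CpGScore:
    """CpG(o/e) of a genomic region, computed on the plus strand."""
    seq = genome[region.chrom][region.start : region.end]
    return cpg_oe_seq(seq, region)


def relative_cpg_for_aeb(event, genome: dict[str, str]) -> float | None:
    """|CpG(o/e) difference| between the two boundary variants of an AEB exon.

    The affected exon is taken once with its annotated boundary and once
    with the displaced one; a zero displacement gives 0 by construction.
    Returns ``None`` when either variant's o/e is undefined.
    """
    if event.p2 is not None:
        # moved exon start: upstream? no — p is the intron start = end of the
        # upstream exon a..p, so the variants are a..p and a..p2
        iv1 = (event.a, event.p)
        iv2 = (event.a, event.p2)
    elif event.q2 is not None:
        # moved intron end = start of the downstream exon q..d
        iv1 = (event.q, event.d)
        iv2 = (event.q2, event.d)
    else:
        raise ValueError("event has no alternative boundary")
    if iv1 == iv2:
        return 0.0
    s1 = cpg_oe(genome, GenomicInterval(event.chrom, *iv1, event.strand))
    s2 = cpg_oe(genome, GenomicInterval(event.chrom, *iv2, event.strand))
    if s1.oe is None or s2.oe is None:
        return None
    return abs(s1.oe - s2.oe)


class MethylationIndex:
    """Per-chromosome position-sorted index over CpG methylation records."""

    def __init__(self, records, min_total: int = 1):
        self.min_total = min_total
        self._by_chrom: dict[str, tuple[list[int], list[MethylationRecord]]] = {}
        grouped: dict[str, list[MethylationRecord]] = {}
        for r in records:
            grouped.setdefault(r.chrom, []).append(r)
        for chrom, recs in grouped.items():
            recs.sort(key=lambda r: r.pos)
            self._by_chrom[chrom] = ([r.pos for r in recs], recs)

    def in_region(self, region: GenomicInterval) -> list[MethylationRecord]:
        if region.chrom not in self._by_chrom:
            return []
        positions, recs = self._by_chrom[region.chrom]
        lo = bisect.bisect_left(positions, region.start)
        hi = bisect.bisect_left(positions, region.end)
        return recs[lo:hi]


def region_methylation_status(region: GenomicInterval, records) -> str:
    """Classify a region from its covered CpG cytosines.

    A methylated C on either strand of a CG pair marks the pair as
    methylated.  Returns ``"methylated"``, ``"unmethylated"`` or
    ``"no_data"``.
    """
    index = records if isinstance(records, MethylationIndex) else MethylationIndex(records)
    covered = 0
    for r in index.in_region(region):
        if r.context != "CG" or r.total < index.min_total:
            continue
        covered += 1
        if r.methylated > 0:
            return "methylated"
    return "unmethylated" if covered else "no_data"


# ---------------------------------------------------------------------------
# Figure-level comparison


def _bin_values(pairs, bins):
    groups: dict[int, list[float]] = {i: [] for i in range(len(bins) - 1)}
    for ratio, value in pairs:
        if ratio is None or value is None:
            continue
        for i in range(len(bins) - 1):
            if bins[i] <= ratio < bins[i + 1] or (
                i == len(bins) - 2 and ratio >= bins[-1]
            ):
                groups[i].append(value)
                break
    return groups


def _extreme_bins(groups):
    occupied = sorted(i for i, v in groups.items() if len(v) > 1)
    if len(occupied) < 2:
        return None, None
    low, high = groups[occupied[0]], groups[occupied[-1]]
    combined = np.concatenate([low, high])
    if np.all(combined == combined[0]):
        return 1.0, 0.0
    p = float(mannwhitneyu(low, high, alternative="two-sided").pvalue)
    return p, float(np.median(high) - np.median(low))


def methylation_vs_inclusion(
    events,
    genome: dict[str, str],
    bins=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    all_intron_oe=None,
) -> dict:
    """CpG metrics across inclusion-ratio bins, per event family.

    * CE: CpG(o/e) of the cassette exon per inclusion bin;
    * IR: CpG(o/e) of the retained intron per inclusion bin, plus — when
      ``all_intron_oe`` (the o/e values of every annotated intron) is
      supplied — a two-tailed t-test of retained-intron o/e against it;
    * AEB: relative CpG score (|o/e difference| of the two boundary
      variants) per inclusion bin.

    Each family reports bin medians and a Mann-Whitney p-value between the
    lowest and highest occupied bins (``None`` when under two bins have
    more than one observation).
    """
    import pandas as pd

    out = {}

    ce_pairs = []
    for e in events:
        if e.kind == "CE" and e.inclusion_ratio is not None:
            s = cpg_oe(genome, GenomicInterval(e.chrom, e.p, e.q, e.strand))
            if s.oe is not None:
                ce_pairs.append((e.inclusion_ratio, s.oe))
    ir_pairs = []
    ir_oes = []
    for e in events:
        if e.kind == "IR" and e.inclusion_ratio is not None:
            s = cpg_oe(genome, GenomicInterval(e.chrom, e.p, e.q, e.strand))
            if s.oe is not None:
                ir_pairs.append((e.inclusion_ratio, s.oe))
                ir_oes.append(s.oe)
    aeb_pairs = []
    for e in events:
        if e.kind in ("ALT_DONOR", "ALT_ACCEPTOR") and e.inclusion_ratio is not None:
            rel = relative_cpg_for_aeb(e, genome)
            if rel is not None:
                aeb_pairs.append((e.inclusion_ratio, rel))

    for family, pairs in (("CE", ce_pairs), ("IR", ir_pairs), ("AEB", aeb_pairs)):
        groups = _bin_values(pairs, bins)
        rows = [
            {
                "bin_low": bins[i],
                "bin_high": bins[i + 1],
                "n": len(groups[i]),
                "median": float(np.median(groups[i])) if groups[i] else np.nan,
            }
            for i in range(len(bins) - 1)
        ]
        p, shift = _extreme_bins(groups)
        out[family] = {
            "table": pd.DataFrame(rows),
            "p_extreme_bins": p,
            "median_shift": shift,
        }

    if all_intron_oe is not None and len(ir_oes) > 1 and len(all_intron_oe) > 1:
        t = ttest_ind(ir_oes, list(all_intron_oe), equal_var=False)
        out["IR"]["t_test_vs_all_introns"] = float(t.pvalue)
        out["IR"]["median_ir_oe"] = float(np.median(ir_oes))
        out["IR"]["median_all_intron_oe"] = float(np.median(all_intron_oe))
    return out
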