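"""Junction filtering, transcribed islands, and gene-model augmentation."""

import numpy as np

from beesplice.gene_model import (
    augment_model,
    filter_junctions,
    find_transcribed_islands,
)
from beesplice.io_formats import CoverageTrack, GenomicInterval, SpliceJunction
from beesplice.synthetic_data import SimulationConfig, simulate
from conftest import build_model


def junction(start, end, strand="+", score=0.9, support=10, chrom="chr1"):
    return SpliceJunction(GenomicInterval(chrom, start, end, strand),
                          score, support)


class TestFilterJunctions:
    def test_score_exactly_half_is_discarded(self, three_exon_model):
        part = filter_junctions([junction(200, 300, score=0.5)], three_exon_model)
        assert part.n_discarded == 1 and part.retained() == []

    def test_score_just_above_half_is_kept(self, three_exon_model):
        part = filter_junctions([junction(200, 300, score=0.51)], three_exon_model)
        assert len(part.known) == 1

    def test_partition_classes(self, three_exon_model):
        part = filter_junctions(
            [
                junction(200, 300),  # both ends annotated boundaries
                junction(207, 300),  # right end only
                junction(1207, 1300),  # neither
            ],
            three_exon_model,
        )
        assert (len(part.known), len(part.half_known), len(part.both_novel)) == (1, 1, 1)

    def test_partition_matches_brute_force_on_random_junctions(self, three_exon_model):
        rng = np.random.default_rng(2)
        model = three_exon_model
        ends = {200, 400, 600}
        starts = {100, 300, 500}
        junctions = [
            junction(int(s), int(s) + int(rng.integers(10, 300)),
                     score=float(rng.uniform(0, 1)))
            for s in rng.integers(50, 900, size=1000)
        ]
        part = filter_junctions(junctions, model)
        expect = {"known": 0, "half": 0, "novel": 0}
        for j in junctions:
            if not j.score > 0.5:
                continue
            left = j.start in ends
            right = j.end in starts
            key = "known" if left and right else ("half" if left or right else "novel")
            expect[key] += 1
        assert (len(part.known), len(part.half_known), len(part.both_novel)) == (
            expect["known"], expect["half"], expect["novel"],
        )


class TestTranscribedIslands:
    def test_zero_coverage_gives_no_islands(self, three_exon_model):
        track = CoverageTrack({"chr1": np.zeros(1000, dtype=int)})
        assert find_transcribed_islands(track, three_exon_model) == []

    def test_single_intergenic_block_is_returned_exactly(self, three_exon_model):
        arr = np.zeros(3000, dtype=int)
        arr[2000:2300] = 20
        track = CoverageTrack({"chr1": arr})
        islands = find_transcribed_islands(track, three_exon_model)
        assert [(i.start, i.end) for i in islands] == [(2000, 2300)]

    def test_block_overlapping_an_exon_is_dropped(self, three_exon_model):
        arr = np.zeros(1000, dtype=int)
        arr[150:450] = 20  # overlaps exons (100,200) and (300,400)
        track = CoverageTrack({"chr1": arr})
        assert find_transcribed_islands(track, three_exon_model) == []

    def test_matches_brute_force_scan(self, three_exon_model):
        rng = np.random.default_rng(3)
        arr = rng.poisson(3, size=4000)
        arr[rng.random(4000) < 0.5] = 0
        track = CoverageTrack({"chr1": arr})
        min_depth, min_len, max_gap = 5, 50, 10
        got = find_transcribed_islands(track, three_exon_model,
                                       min_depth, min_len, max_gap)

        # independent linear scan
        runs = []
        start = None
        for pos, depth in enumerate(arr):
            if depth >= min_depth and start is None:
                start = pos
            elif depth < min_depth and start is not None:
                runs.append([start, pos])
                start = None
        if start is not None:
            runs.append([start, len(arr)])
        merged = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= max_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        exons = [(100, 200), (300, 400), (500, 600)]
        expected = [
            (s, e) for s, e in merged
            if e - s >= min_len and not any(s < xe and xs < e for xs, xe in exons)
        ]
        assert [(i.start, i.end) for i in got] == expected


class TestAugmentation:
    def _setup(self):
        model = build_model(
            {"g1": ("chr1", "+", {"g1.t1": [(100, 200), (300, 400)]})}
        )
        island = GenomicInterval("chr1", 700, 900)
        half = junction(400, 760)  # known donor at exon end, novel end in island
        return model, island, half

    def test_half_known_junction_into_island_creates_novel_exon(self):
        model, island, half = self._setup()
        part = filter_junctions([half], model)
        augment_model(model, part, [island])
        novel = [
            (e.start, e.end)
            for _, t in model.iter_transcripts()
            for e, prov in zip(t.exons, t.exon_provenance)
            if prov == "novel"
        ]
        assert novel == [(760, 900)]
        # the junction is now both-known
        part2 = filter_junctions([half], model)
        assert len(part2.known) == 1

    def test_augmentation_is_idempotent(self):
        model, island, half = self._setup()
        part = filter_junctions([half], model)
        augment_model(model, part, [island])
        n_transcripts = sum(1 for _ in model.iter_transcripts())
        augment_model(model, part, [island])
        assert sum(1 for _ in model.iter_transcripts()) == n_transcripts

    def test_annotated_features_are_never_modified(self):
        model, island, half = self._setup()
        before = {
            (gid, tid): [(e.start, e.end) for e in t.exons]
            for gid, gene in model.genes.items()
            for tid, t in gene.transcripts.items()
        }
        augment_model(model, filter_junctions([half], model), [island])
        for key, exons in before.items():
            gid, tid = key
            assert [(e.start, e.end)
                    for e in model.genes[gid].transcripts[tid].exons] == exons

    def test_bridged_islands_create_intergenic_transcript(self):
        model = build_model(
            {"g1": ("chr1", "+", {"g1.t1": [(100, 200), (300, 400)]})}
        )
        islands = [GenomicInterval("chr1", 5000, 5200),
                   GenomicInterval("chr1", 5800, 6000)]
        bridge = junction(5200, 5800)
        augment_model(model, filter_junctions([bridge], model), islands)
        novel_genes = [g for g in model.genes.values() if g.provenance == "novel"]
        assert len(novel_genes) == 1
        (t,) = novel_genes[0].transcripts.values()
        assert [(e.start, e.end) for e in t.exons] == [(5000, 5200), (5800, 6000)]

    def test_overlap_with_annotated_exon_is_skipped(self):
        model = build_model(
            {"g1": ("chr1", "+", {"g1.t1": [(100, 200), (300, 400)]}),
             "g2": ("chr1", "+", {"g2.t1": [(800, 1000), (1200, 1300)]})}
        )
        island = GenomicInterval("chr1", 1400, 1600)  # fine island, unused
        # novel end falls inside g2's annotated exon region via an island that
        # overlaps it -> no island survives there, junction stays half-known
        half = junction(400, 850)
        augment_model(model, filter_junctions([half], model), [island])
        assert all(
            prov == "annotated"
            for _, t in model.iter_transcripts()
            for prov in t.exon_provenance
        )

    def test_planted_novel_exons_are_recovered(self):
        cfg = SimulationConfig(seed=13, n_genes=12, n_novel_exon=10,
                               intron_len_mean=500, intron_len_min=250)
        dataset = simulate(cfg)
        model = dataset.model
        part = filter_junctions(dataset.junctions, model)
        islands = find_transcribed_islands(dataset.coverage, model)
        augment_model(model, part, islands)
        recovered = {
            (e.start, e.end)
            for _, t in model.iter_transcripts()
            for e, prov in zip(t.exons, t.exon_provenance)
            if prov == "novel"
        }
        truth = {
            tuple(map(int, row.coords.split(",")))
            for row in dataset.truth.itertuples()
            if row.kind == "NOVEL_EXON"
        }
        exact = truth & recovered
        assert len(exact) >= 9
        # junction-side boundary is exact for every recovered exon by
        # construction; island-side boundaries match planted truth here
        assert len(recovered) == len(exact)
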