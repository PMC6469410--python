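"""Event detection and ratio formulas against independent oracles."""

from fractions import Fraction

import numpy as np
import pytest

from beesplice import as_detection as det
from beesplice.as_detection import (
    ASEvent,
    JunctionIndex,
    compute_aeb_ratios,
    compute_ce_ratio,
    compute_ir_ratio,
    detect_aeb,
    detect_all,
    detect_ate,
    detect_ce,
    detect_ir,
    displacement_spectrum,
)
from beesplice.gene_model import filter_junctions
from beesplice.io_formats import CoverageTrack, GenomicInterval, SpliceJunction
from beesplice.synthetic_data import reverse_complement_dataset
from conftest import build_model


def junction(start, end, strand="+", score=0.9, support=10, chrom="chr1"):
    return SpliceJunction(GenomicInterval(chrom, start, end, strand),
                          score, support)


def ce_event(**kw):
    base = dict(kind="CE", gene_id="g1", chrom="chr1", strand="+",
                a=100, b=200, p=300, q=400, c=500, d=600)
    base.update(kw)
    return ASEvent(**base)


class TestCassetteExons:
    def test_skip_junction_marks_middle_exon(self, three_exon_model):
        events = detect_ce(three_exon_model, [junction(200, 500)])
        assert [(e.kind, e.p, e.q) for e in events] == [("CE", 300, 400)]
        assert (e.a, e.b, e.c, e.d) == (100, 200, 500, 600) if (e := events[0]) else False

    def test_junction_between_adjacent_exons_is_not_skipping(self, three_exon_model):
        assert detect_ce(three_exon_model, [junction(200, 300)]) == []

    def test_ratio_symmetric_case(self):
        jx = [junction(200, 300, support=10), junction(400, 500, support=10),
              junction(200, 500, support=10)]
        assert compute_ce_ratio(ce_event(), JunctionIndex(jx)) == 0.5

    def test_ratio_one_when_no_skipping_reads(self):
        jx = [junction(200, 300, support=8), junction(400, 500, support=12)]
        assert compute_ce_ratio(ce_event(), JunctionIndex(jx)) == 1.0

    def test_all_zero_supports_flagged_na(self):
        assert compute_ce_ratio(ce_event(), JunctionIndex([])) is None

    def test_random_supports_match_formula_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n_bp, n_qc, n_bc = (int(x) for x in rng.integers(0, 500, size=3))
            jx = [junction(200, 300, support=n_bp),
                  junction(400, 500, support=n_qc),
                  junction(200, 500, support=n_bc)]
            got = compute_ce_ratio(ce_event(), JunctionIndex(jx))
            inc = Fraction(n_bp + n_qc, 2)
            if inc + n_bc == 0:
                assert got is None
            else:
                assert got == pytest.approx(float(inc / (inc + n_bc)), abs=0)


class TestIntronRetention:
    def _track(self, intron_depth, flank_depth=100, length=700):
        arr = np.zeros(length, dtype=int)
        arr[100:200] = flank_depth
        arr[500:600] = flank_depth
        arr[200:500] = intron_depth
        return CoverageTrack({"chr1": arr})

    def test_depth_floor_is_strict(self, three_exon_model):
        # the gene's first intron is (200, 300)
        model = build_model({"g1": ("chr1", "+", {"t": [(100, 200), (500, 600)]})})
        assert detect_ir(model, self._track(5)) == []
        assert len(detect_ir(model, self._track(6))) == 1

    def test_high_uniform_depth_is_retained(self):
        model = build_model({"g1": ("chr1", "+", {"t": [(100, 200), (500, 600)]})})
        (event,) = detect_ir(model, self._track(100))
        assert event.inclusion_ratio == 1.0
        assert (event.a, event.p, event.q, event.d) == (100, 200, 500, 600)

    def test_ratio_arithmetic(self):
        event = ASEvent(kind="IR", gene_id="g", chrom="chr1", strand="+",
                        a=100, b=200, p=200, q=500, c=500, d=600)
        arr = np.zeros(700, dtype=int)
        arr[100:200] = 20
        arr[200:500] = 10
        arr[500:600] = 20
        assert compute_ir_ratio(event, CoverageTrack({"chr1": arr})) == 0.5

    def test_ratio_may_exceed_one_unclamped(self):
        event = ASEvent(kind="IR", gene_id="g", chrom="chr1", strand="+",
                        a=100, b=200, p=200, q=500, c=500, d=600)
        arr = np.zeros(700, dtype=int)
        arr[100:200] = 10
        arr[200:500] = 40
        arr[500:600] = 10
        assert compute_ir_ratio(event, CoverageTrack({"chr1": arr})) == 4.0

    def test_zero_flanks_flagged_na(self):
        event = ASEvent(kind="IR", gene_id="g", chrom="chr1", strand="+",
                        a=100, b=200, p=200, q=500, c=500, d=600)
        assert compute_ir_ratio(event, CoverageTrack({"chr1": np.zeros(700, int)})) is None

    def test_random_tracks_match_per_base_mean_oracle(self):
        rng = np.random.default_rng(5)
        event = ASEvent(kind="IR", gene_id="g", chrom="chr1", strand="+",
                        a=0, b=50, p=50, q=150, c=150, d=230)
        for _ in range(100):
            arr = rng.integers(0, 30, size=230)
            got = compute_ir_ratio(event, CoverageTrack({"chr1": arr}))
            cov = lambda s, e: sum(int(x) for x in arr[s:e]) / (e - s)
            denom = cov(0, 50) + cov(150, 230)
            expect = 2 * cov(50, 150) / denom if denom else None
            assert got == pytest.approx(expect, abs=1e-12)


class TestAlternativeBoundaries:
    def _model(self, strand="+"):
        return build_model(
            {"g1": ("chr1", strand, {"t": [(100, 200), (500, 600)]})}
        )

    def _detect(self, model, alt_junction):
        part = filter_junctions([junction(200, 500), alt_junction], model)
        return detect_aeb(model, part)

    def test_moved_intron_start_on_plus_is_alt_donor(self):
        (event,) = self._detect(self._model("+"), junction(203, 500))
        assert event.kind == "ALT_DONOR" and event.displacement == 3
        assert (event.p, event.p2) == (200, 203)

    def test_moved_intron_start_on_minus_is_alt_acceptor(self):
        (event,) = self._detect(self._model("-"), junction(203, 500, strand="-"))
        assert event.kind == "ALT_ACCEPTOR" and event.displacement == 3

    def test_moved_intron_end_on_plus_is_alt_acceptor(self):
        (event,) = self._detect(self._model("+"), junction(200, 496))
        assert event.kind == "ALT_ACCEPTOR" and event.displacement == 4
        assert (event.q, event.q2) == (500, 496)

    def test_displacement_of_exactly_200_is_rejected(self):
        assert self._detect(self._model("+"), junction(400, 500)) == []
        assert len(self._detect(self._model("+"), junction(399, 500))) == 1

    def test_novel_end_crossing_far_exon_boundary_is_rejected(self):
        # b' must stay beyond the exon's other boundary (b' > a = 100)
        model = build_model({"g1": ("chr1", "+", {"t": [(150, 200), (260, 600)]})})
        part = filter_junctions([junction(200, 260), junction(140, 260)], model)
        assert detect_aeb(model, part) == []

    def test_splicing_ratio_minor_over_major(self):
        event = ASEvent(kind="ALT_DONOR", gene_id="g", chrom="chr1", strand="+",
                        a=100, b=200, p=200, p2=203, q=500, c=500, d=600)
        jx = JunctionIndex([junction(200, 500, support=5),
                            junction(203, 500, support=10)])
        ratios = compute_aeb_ratios(event, jx)
        assert ratios["splicing_ratio"] == 0.5
        # region (200,203) is included by the shorter intron (203,500)
        assert ratios["inclusion_ratio"] == pytest.approx(10 / 15)

    def test_tie_gives_splicing_ratio_one(self):
        event = ASEvent(kind="ALT_DONOR", gene_id="g", chrom="chr1", strand="+",
                        a=100, b=200, p=200, p2=203, q=500, c=500, d=600)
        jx = JunctionIndex([junction(200, 500, support=7),
                            junction(203, 500, support=7)])
        assert compute_aeb_ratios(event, jx)["splicing_ratio"] == 1.0

    def test_zero_supports_flagged_na(self):
        event = ASEvent(kind="ALT_DONOR", gene_id="g", chrom="chr1", strand="+",
                        a=100, b=200, p=200, p2=203, q=500, c=500, d=600)
        ratios = compute_aeb_ratios(event, JunctionIndex([]))
        assert ratios["splicing_ratio"] is None
        assert ratios["inclusion_ratio"] is None

    def test_random_support_pairs_match_formula_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n, n2 = (int(x) for x in rng.integers(0, 300, size=2))
            event = ASEvent(kind="ALT_DONOR", gene_id="g", chrom="chr1",
                            strand="+", a=100, b=200, p=200, p2=207,
                            q=500, c=500, d=600)
            jx = JunctionIndex([junction(200, 500, support=n),
                                junction(207, 500, support=n2)])
            ratios = compute_aeb_ratios(event, jx)
            if max(n, n2) == 0:
                assert ratios["splicing_ratio"] is None
            else:
                assert ratios["splicing_ratio"] == pytest.approx(
                    float(Fraction(min(n, n2), max(n, n2))), abs=0
                )
                # p2 > p: the alternative (shorter) intron includes the region
                assert ratios["inclusion_ratio"] == pytest.approx(
                    float(Fraction(n2, n + n2)), abs=0
                )


class TestAlternativeTerminalExons:
    def test_shared_acceptor_gives_one_afe(self):
        model = build_model(
            {"g1": ("chr1", "+", {
                "t1": [(100, 200), (400, 500)],
                "t2": [(250, 330), (400, 500)],
            })}
        )
        jx = [junction(200, 400, support=30), junction(330, 400, support=10)]
        events = detect_ate(model, jx)
        assert [e.kind for e in events] == ["AFE"]
        assert events[0].splicing_ratio == pytest.approx(1 / 3)
        assert {(events[0].p, events[0].q), (events[0].p2, events[0].q2)} == {
            (100, 200), (250, 330)
        }

    def test_different_acceptors_give_no_afe(self):
        model = build_model(
            {"g1": ("chr1", "+", {
                "t1": [(100, 200), (400, 500), (700, 800)],
                "t2": [(250, 330), (600, 650), (700, 800)],
            })}
        )
        events = detect_ate(model, [junction(200, 400), junction(330, 600)])
        assert [e for e in events if e.kind == "AFE"] == []

    def test_single_exon_transcripts_are_skipped(self):
        model = build_model(
            {"g1": ("chr1", "+", {"t1": [(100, 200)], "t2": [(250, 330)]})}
        )
        assert detect_ate(model, []) == []

    def test_shared_donor_gives_ale_on_plus(self):
        model = build_model(
            {"g1": ("chr1", "+", {
                "t1": [(100, 200), (400, 500)],
                "t2": [(100, 200), (600, 700)],
            })}
        )
        jx = [junction(200, 400, support=40), junction(200, 600, support=8)]
        events = detect_ate(model, jx)
        assert [e.kind for e in events] == ["ALE"]
        assert events[0].splicing_ratio == pytest.approx(0.2)


class TestDisplacementSpectrum:
    def _aeb(self, kind, disp):
        return ASEvent(kind=kind, gene_id="g", chrom="chr1", strand="+",
                       displacement=disp)

    def test_all_threes_give_mod3_fraction_one(self):
        spectrum = displacement_spectrum(
            [self._aeb("ALT_DONOR", 3) for _ in range(5)]
        )
        assert spectrum["donor_mod3_fraction"] == 1.0
        assert spectrum["donor"] == {3: 5}

    def test_empty_event_list(self):
        spectrum = displacement_spectrum([])
        assert spectrum["donor"] == {} and spectrum["aeb_mod3_fraction"] is None

    def test_mixture_fractions(self):
        events = [self._aeb("ALT_ACCEPTOR", 3)] * 6 + [self._aeb("ALT_ACCEPTOR", 4)] * 6
        spectrum = displacement_spectrum(events)
        assert spectrum["acceptor_mod3_fraction"] == 0.5
        assert spectrum["acceptor"] == {3: 6, 4: 6}

    def test_ce_length_mod3_fraction(self):
        events = [ce_event(p=300, q=399), ce_event(p=300, q=400)]
        assert displacement_spectrum(events)["ce_mod3_fraction"] == 0.5


class TestDatasetLevelProperties:
    def _detect(self, dataset):
        part = filter_junctions(dataset.junctions, dataset.model)
        return detect_all(dataset.model, part, dataset.coverage)

    def test_planted_events_recovered_without_false_positives(self, event_dataset):
        events = self._detect(event_dataset)
        truth = event_dataset.truth
        for kind in ("CE", "ALT_DONOR", "ALT_ACCEPTOR", "AFE", "ALE"):
            assert len(events[kind]) == (truth.kind == kind).sum()
        planted_ir = (truth.kind == "IR").sum()
        assert len(events["IR"]) >= planted_ir
        # every planted IR found; false IRs bounded by the noise criterion
        ir_coords = {(e.p, e.q) for e in events["IR"]}
        for row in truth[truth.kind == "IR"].itertuples():
            assert tuple(map(int, row.coords.split(","))) in ir_coords
        n_clean = event_dataset.model.n_introns() - planted_ir
        assert len(events["IR"]) - planted_ir <= max(1, 0.02 * n_clean)

    def test_no_duplicate_events_per_gene(self, event_dataset):
        events = self._detect(event_dataset)
        for kind, evs in events.items():
            keys = [(e.gene_id,) + e.key() for e in evs]
            assert len(keys) == len(set(keys))

    def test_strand_reversal_invariance(self, event_dataset):
        L = len(event_dataset.genome["chr1"])
        forward = self._detect(event_dataset)
        mirrored = self._detect(reverse_complement_dataset(event_dataset))

        def signature(events):
            out = set()
            for e in events:
                coords = frozenset(
                    c for c in (e.a, e.b, e.p, e.q, e.p2, e.q2, e.c, e.d)
                    if c is not None
                )
                out.add((e.kind, coords))
            return out

        for kind in forward:
            mapped = {
                (k, frozenset(L - c for c in coords))
                for k, coords in signature(mirrored[kind])
            }
            assert signature(forward[kind]) == mapped, kind

    def test_detection_is_monotone_in_depth(self, event_dataset):
        # halving coverage can only lose IR events, never create planted-kind
        # junction events (which do not depend on coverage)
        half = CoverageTrack(
            {c: a // 2 for c, a in event_dataset.coverage.depths.items()}
        )
        part = filter_junctions(event_dataset.junctions, event_dataset.model)
        full_ir = {(e.p, e.q) for e in detect_ir(event_dataset.model,
                                                 event_dataset.coverage)}
        half_ir = {(e.p, e.q) for e in detect_ir(event_dataset.model, half)}
        assert half_ir <= full_ir
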