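"""Generator invariants: determinism, ratio recovery, CpG structure."""

import numpy as np
import pytest

from beesplice.as_detection import detect_all
from beesplice.gene_model import filter_junctions
from beesplice.methylation import cpg_oe
from beesplice.synthetic_data import (
    SimulationConfig,
    plant_splice_site_strength,
    simulate,
    simulate_ortholog_table,
)


class TestDeterminism:
    def test_fixed_seed_gives_byte_identical_file_set(self, tmp_path):
        cfg = SimulationConfig(seed=17, n_genes=8, n_ce=2, n_ir=2,
                               n_alt_donor=1, intron_len_mean=450,
                               intron_len_min=250,
                               methylation_coupling="random")
        blobs = []
        for run in range(2):
            out = tmp_path / f"run{run}"
            simulate(cfg, out_dir=out)
            blobs.append(
                b"".join((out / p.name).read_bytes()
                         for p in sorted(out.iterdir()))
            )
        assert blobs[0] == blobs[1]

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(seed=1, n_genes=4, intron_len_mean=400,
                               intron_len_min=250)
        other = SimulationConfig(seed=2, n_genes=4, intron_len_mean=400,
                                 intron_len_min=250)
        assert simulate(cfg).genome != simulate(other).genome


class TestRatioRecovery:
    def test_deep_coverage_recovers_planted_ratios_closely(self):
        cfg = SimulationConfig(seed=19, n_genes=36, n_ce=12, n_ir=12,
                               n_alt_donor=6, n_alt_acceptor=6,
                               read_depth=1000, intron_len_mean=500,
                               intron_len_min=250)
        dataset = simulate(cfg)
        part = filter_junctions(dataset.junctions, dataset.model)
        events = detect_all(dataset.model, part, dataset.coverage)
        errors = []
        table = {}
        for e in events["CE"]:
            table[("CE", e.p, e.q)] = e.inclusion_ratio
        for e in events["IR"]:
            table[("IR", e.p, e.q)] = e.inclusion_ratio
        for e in events["ALT_DONOR"] + events["ALT_ACCEPTOR"]:
            pair = (e.p, e.p2) if e.p2 is not None else (e.q, e.q2)
            table[(e.kind,) + pair] = e.splicing_ratio
        for row in dataset.truth.itertuples():
            if row.kind in ("NOVEL_EXON", "NOVEL_TRANSCRIPT"):
                continue
            if row.kind in ("AFE", "ALE"):
                continue
            key = (row.kind,) + tuple(map(int, row.coords.split(",")))
            assert key in table, key
            errors.append(abs(table[key] - float(row.target_ratio)))
        assert np.mean(errors) < 0.02

    def test_planted_ir_with_full_inclusion_matches_flank_depth(self):
        cfg = SimulationConfig(seed=23, n_genes=4, n_ir=1, ratio_range=(1.0, 1.0),
                               intron_len_mean=400, intron_len_min=250)
        dataset = simulate(cfg)
        (row,) = dataset.truth[dataset.truth.kind == "IR"].itertuples()
        p, q = map(int, row.coords.split(","))
        arr = dataset.coverage.depths["chr1"]
        assert set(arr[p:q]) == {cfg.read_depth}


class TestNullCase:
    def test_zero_event_config_plants_nothing(self, null_dataset):
        assert len(null_dataset.truth) == 0
        part = filter_junctions(null_dataset.junctions, null_dataset.model)
        events = detect_all(null_dataset.model, part, null_dataset.coverage)
        for kind in ("CE", "ALT_DONOR", "ALT_ACCEPTOR", "AFE", "ALE"):
            assert events[kind] == []

    def test_annotation_junctions_exactly_match_introns(self, null_dataset):
        intron_keys = set()
        for _, t in null_dataset.model.iter_transcripts():
            for intron in t.introns():
                intron_keys.add((intron.start, intron.end))
        junction_keys = {(j.start, j.end) for j in null_dataset.junctions}
        assert intron_keys == junction_keys

    def test_over_planting_raises(self):
        with pytest.raises(ValueError, match="exceed"):
            simulate(SimulationConfig(n_genes=3, n_ce=4))


class TestCpGStructure:
    def test_methylated_exons_are_cpg_depleted(self):
        cfg = SimulationConfig(seed=29, n_genes=40, intron_len_mean=400,
                               intron_len_min=250,
                               methylation_coupling="random")
        dataset = simulate(cfg)
        meth, unmeth = [], []
        for region, state in dataset.exon_states:
            score = cpg_oe(dataset.genome, region)
            if score.oe is None:
                continue
            (meth if state == "methylated" else unmeth).append(score.oe)
        assert len(meth) + len(unmeth) >= 200
        assert np.mean(meth) < np.mean(unmeth)
        # depletion factor is roughly recovered in the group means
        assert np.mean(meth) / np.mean(unmeth) < 0.6

    def test_methylation_records_consistent_with_states(self):
        cfg = SimulationConfig(seed=31, n_genes=6, intron_len_mean=400,
                               intron_len_min=250,
                               methylation_coupling="random")
        dataset = simulate(cfg)
        from beesplice.methylation import MethylationIndex, region_methylation_status

        index = MethylationIndex(dataset.methylation)
        for region, state in dataset.exon_states:
            got = region_methylation_status(region, index)
            assert got in (state, "no_data")


class TestMotifPools:
    def test_coupled_assignment_follows_ratio(self):
        assert plant_splice_site_strength("CE", 0.9, "coupled") == {"site": "strong"}
        assert plant_splice_site_strength("CE", 0.5, "coupled") == {"site": "weak"}
        assert plant_splice_site_strength("IR", 0.9, "coupled") == {"site": "weak"}
        aeb = plant_splice_site_strength("ALT_DONOR", 0.9, "coupled")
        assert aeb == {"major": "weak", "minor": "strong"}

    def test_all_strong_control(self):
        pools = plant_splice_site_strength("CE", 0.1, "all_strong")
        assert pools["site"] == "strong"

    def test_uncoupled_plants_nothing(self):
        assert plant_splice_site_strength("CE", 0.9, "none") == {}


class TestOrthologTable:
    def test_table_is_consistent_with_truth(self, event_dataset):
        table = simulate_ortholog_table(event_dataset.truth, seed=3,
                                        fraction_with_ortholog=1.0,
                                        fraction_as_ortholog=1.0,
                                        fraction_equal=1.0)
        per_gene = event_dataset.truth[
            ~event_dataset.truth.kind.isin(["NOVEL_EXON", "NOVEL_TRANSCRIPT"])
        ].groupby("gene").size()
        assert set(table.gene_id) == set(per_gene.index)
        for row in table.itertuples():
            assert row.ortholog_as_events == per_gene[row.gene_id]
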