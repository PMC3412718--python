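"""Selection criteria, divergon-aware target assignment, conservation, reports."""

import numpy as np
import pytest

from regulonscan import (PipelineConfig, RegulonEntry, RegulonPrediction, SiteHit,
                         SimulationSpec, assign_targets, conserved_associations,
                         infer_operons, classify_divergons, predict_regulon,
                         read_regulon_tsv, simulate_genome, sms_score,
                         write_conservation_tsv, write_regulon_tsv)
from regulonscan.motif_builder import BASES
from regulonscan.regulon_predict import _rank
from regulonscan.synthetic_data import default_planting_pfm

from conftest import make_genome, random_dna

CONSENSUS_PFM = default_planting_pfm(defined_fraction=1.0, spacer_fraction=1.0)
CONSENSUS_SITE = "".join(BASES[int(k)] for k in CONSENSUS_PFM.freqs.argmax(axis=0))


def plant_in_contig(contig, gene_start, site, distance):
    """Overwrite so the site's 3' edge sits `distance` nt before gene_start."""
    lo = gene_start - distance - len(site) + 1
    return contig[:lo] + site + contig[lo + len(site):]


class TestPredictRegulon:
    def test_planted_consensus_operons_are_recovered_exactly(self):
        # tandem layout: no shared divergon windows, so the prediction must
        # equal the planted operon set exactly
        spec = SimulationSpec(seed=5, genes_per_genome=12, anchor=False,
                              planted_targets=[1, 3, 5, 7, 9],
                              planting_pfm=CONSENSUS_PFM,
                              strand_pattern="forward",
                              intergenic_length=(200, 400))
        genome, truth = simulate_genome(spec, genome_id="one")
        pred = predict_regulon(genome, CONSENSUS_PFM)
        assert {e.operon_id for e in pred.entries} == \
               {f"opn_{g}" for g in truth.gene_id}
        assert all(e.best_hit.relative == pytest.approx(1.0) for e in pred.entries)
        assert all(e.rank == 1 for e in pred.entries)

    def test_sub_threshold_site_is_not_predicted(self):
        # three defined-position mismatches: relative 14/17, below 0.87
        weak = "CCA" + CONSENSUS_SITE[3:]
        assert sms_score(CONSENSUS_PFM, weak)[2] == pytest.approx(14 / 17)
        rng = np.random.default_rng(6)
        contig = random_dna(rng, 1500)
        contig = plant_in_contig(contig, 600, weak, distance=50)
        genome = make_genome(contig, [("g", 600, 1400, "+")])
        pred = predict_regulon(genome, CONSENSUS_PFM)
        assert pred.entries == []

    def test_whitelist_relaxes_distance_but_not_score(self):
        rng = np.random.default_rng(7)
        contig = random_dna(rng, 1800)
        contig = plant_in_contig(contig, 700, CONSENSUS_SITE, distance=400)
        genome = make_genome(contig, [("g", 700, 1600, "+")], genome_id="wl")
        assert predict_regulon(genome, CONSENSUS_PFM).entries == []
        config = PipelineConfig(whitelist=[("wl", "g")])
        pred = predict_regulon(genome, CONSENSUS_PFM, config)
        (entry,) = pred.entries
        assert entry.divergon_note == "whitelist"
        assert entry.best_hit.distance_to_start == 400

    @pytest.mark.parametrize("seed", range(5))
    def test_raising_the_threshold_never_adds_entries(self, seed):
        spec = SimulationSpec(seed=30 + seed, genes_per_genome=20, anchor=True,
                              planted_fraction=0.4)
        genome, _ = simulate_genome(spec)
        pfm = default_planting_pfm()
        loose = {e.operon_id for e in predict_regulon(
            genome, pfm, PipelineConfig(threshold=0.87)).entries}
        strict = {e.operon_id for e in predict_regulon(
            genome, pfm, PipelineConfig.high_confidence()).entries}
        assert strict <= loose


class TestAssignTargets:
    def divergon_genome(self, interval):
        contig = "A" * (500 + interval + 500)
        return make_genome(contig, [("a", 0, 500, "-"),
                                    ("b", 500 + interval, 1000 + interval, "+")])

    def hit(self, leader, offset, strand="+"):
        return SiteHit("T" * 17, 15.0, 0.9, 0.95, offset, 250 - offset - 17 + 1,
                       strand, leader)

    def test_plain_leader_site_maps_to_one_operon(self):
        genome = make_genome("A" * 1300, [("g", 600, 1200, "+")])
        ops = infer_operons(genome)
        out = assign_targets(self.hit("g", offset=100), genome, ops, {})
        assert out == [("opn_g", "")]

    def test_shared_interval_site_maps_to_both_partners_flagged(self):
        genome = self.divergon_genome(interval=200)
        ops = infer_operons(genome)
        div = classify_divergons(genome, ops)
        # b's window is [450,700); offset 100 puts the site at [550,567),
        # inside a's window [500,750) as well
        out = assign_targets(self.hit("b", offset=100), genome, ops, div)
        assert sorted(out) == [("opn_a", "divergon"), ("opn_b", "divergon")]

    def test_distant_partner_window_excludes_the_site(self):
        genome = self.divergon_genome(interval=500)
        ops = infer_operons(genome)
        div = classify_divergons(genome, ops)
        # site close to a (window [500,750)) but ~460 nt from b's start
        out = assign_targets(self.hit("a", offset=14), genome, ops, div)
        assert out == [("opn_a", "")]


class TestConservation:
    def prediction(self, genome_id, gene_ids, score=0.95):
        entries = []
        for g in gene_ids:
            hit = SiteHit("T" * 17, 15.0, 0.9, score, 10, 40, "+", g, genome_id)
            entries.append(RegulonEntry(f"opn_{g}", [g], hit, 1))
        return RegulonPrediction(genome_id, entries)

    def panel(self, fam_support):
        """fam_support: family -> number of supporting genomes (of 10)."""
        genomes = [f"sp{k:02d}" for k in range(10)]
        predictions, families = {}, {}
        for k, gid in enumerate(genomes):
            genes = []
            for fam, support in fam_support.items():
                gene = f"{gid}_{fam}"
                families[(gid, gene)] = fam
                if k < support:
                    genes.append(gene)
            predictions[gid] = self.prediction(gid, genes)
        return predictions, families

    def test_support_counting_and_conservation_flag(self):
        predictions, families = self.panel({"anchor": 10, "famA": 6, "famB": 2})
        report = conserved_associations(predictions, families)
        by_family = report.set_index("family")
        assert by_family.loc["famA", "n_support"] == 6
        assert bool(by_family.loc["famA", "conserved"])
        assert by_family.loc["famB", "n_support"] == 2
        assert not bool(by_family.loc["famB", "conserved"])

    def test_anchor_family_ranks_first_with_full_support(self):
        predictions, families = self.panel({"anchor": 10, "famA": 6, "famB": 2})
        report = conserved_associations(predictions, families)
        assert report.iloc[0]["family"] == "anchor"
        assert report.iloc[0]["n_support"] == 10

    def test_unmapped_targets_fall_into_unassigned(self):
        predictions, _ = self.panel({"famA": 4})
        report = conserved_associations(predictions, families={})
        assert set(report["family"]) == {"unassigned"}


class TestRankingAndReports:
    def entry(self, operon, relative):
        hit = SiteHit("T" * 17, 15.0, 0.9, relative, 10, 40, "+", operon)
        return RegulonEntry(f"opn_{operon}", [operon], hit, 0)

    def test_printed_score_ties_share_the_lower_rank(self):
        entries = [self.entry("a", 0.952), self.entry("b", 0.949),
                   self.entry("c", 0.91), self.entry("d", 0.905)]
        _rank(entries)
        ranks = {e.operon_id.removeprefix("opn_"): e.rank for e in entries}
        assert ranks == {"a": 1, "b": 1, "c": 3, "d": 3}

    def test_regulon_report_round_trips_and_is_deterministic(self, tmp_path):
        spec = SimulationSpec(seed=9, genes_per_genome=15, planted_fraction=0.3)
        genome, _ = simulate_genome(spec, genome_id="det")
        pred = predict_regulon(genome, default_planting_pfm())
        assert pred.entries  # anchor at least
        write_regulon_tsv(pred, tmp_path / "r1.tsv")
        write_regulon_tsv(pred, tmp_path / "r2.tsv")
        assert (tmp_path / "r1.tsv").read_bytes() == (tmp_path / "r2.tsv").read_bytes()
        back = read_regulon_tsv(tmp_path / "r1.tsv")
        assert back.genome_id == pred.genome_id
        assert [(e.operon_id, e.rank, e.target_gene_ids, e.best_hit.relative,
                 e.best_hit.distance_to_start, e.divergon_note)
                for e in back.entries] == \
               [(e.operon_id, e.rank, e.target_gene_ids, e.best_hit.relative,
                 e.best_hit.distance_to_start, e.divergon_note)
                for e in sorted(pred.entries,
                                key=lambda e: (e.rank, -e.best_hit.relative,
                                               e.operon_id))]

    def test_empty_prediction_writes_header_only(self, tmp_path):
        write_regulon_tsv(RegulonPrediction("empty", []), tmp_path / "r.tsv")
        lines = (tmp_path / "r.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("genome\t")

    def test_conservation_report_is_deterministic(self, tmp_path):
        predictions, families = TestConservation().panel({"famA": 5, "famB": 3})
        report = conserved_associations(predictions, families)
        write_conservation_tsv(report, tmp_path / "c1.tsv")
        write_conservation_tsv(report, tmp_path / "c2.tsv")
        assert (tmp_path / "c1.tsv").read_bytes() == (tmp_path / "c2.tsv").read_bytes()
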