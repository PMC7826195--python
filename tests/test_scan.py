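"""LoF mutation calling: classification, filtering, sharing, counting."""

import numpy as np
import pytest

from genedecay import (
    Completeness,
    GeneModel,
    GeneScanReport,
    GeneSequencePair,
    LoFCategory,
    LoFEvent,
    Regime,
    SimulationScenario,
    evolve_sequences,
    generate_gene_set,
    lof_count_distribution,
    scan_cds,
    scan_gene,
    scan_splice_sites,
    shared_lof,
)

from conftest import DENTATA_COUNTS, GIBARENSIS_COUNTS


def _pair(ref, query, **kw):
    return GeneSequencePair(gene_id="g", reference_cds=ref, query_cds=query, **kw)


REF_300 = "ATG" + "GAA" * 98 + "TAA"  # 300 bp, clean CDS


class TestScanCds:
    def test_identical_sequences_yield_no_events(self):
        assert scan_cds(_pair(REF_300, REF_300)).n_lof == 0

    def test_11bp_deletion_is_one_frameshift(self):
        # an 11-bp gap: 11 mod 3 = 2, the frame is shifted
        query = REF_300[:90] + "-" * 11 + REF_300[101:]
        report = scan_cds(_pair(REF_300, query))
        assert [e.category for e in report.lof_events] == [LoFCategory.FRAMESHIFT_INDEL]
        assert report.lof_events[0].indel_length == -11
        assert report.lof_events[0].cds_position == 90

    def test_trp_to_stop_is_premature_stop(self):
        ref = "ATG" + "AAA" + "TGG" + "TAA"
        query = "ATG" + "AAA" + "TGA" + "TAA"
        events = scan_cds(_pair(ref, query)).lof_events
        assert [e.category for e in events] == [LoFCategory.PREMATURE_STOP]
        assert events[0].cds_position == 6
        assert (events[0].ref_allele, events[0].alt_allele) == ("TGG", "TGA")

    def test_start_codon_change_is_start_loss(self):
        query = "GTG" + REF_300[3:]
        events = scan_cds(_pair(REF_300, query)).lof_events
        assert [e.category for e in events] == [LoFCategory.START_LOSS]

    def test_terminal_stop_change_is_stop_loss(self):
        query = REF_300[:-3] + "TAC"
        events = scan_cds(_pair(REF_300, query)).lof_events
        assert [e.category for e in events] == [LoFCategory.STOP_LOSS]

    def test_stop_to_stop_is_not_an_event(self):
        query = REF_300[:-3] + "TGA"
        assert scan_cds(_pair(REF_300, query)).n_lof == 0

    def test_in_frame_indel_is_not_lof(self):
        query = REF_300[:90] + "-" * 9 + REF_300[99:]
        report = scan_cds(_pair(REF_300, query))
        assert report.n_lof == 0
        assert report.in_frame_indels == 1

    def test_stops_downstream_of_first_frameshift_not_counted(self):
        # frameshift at 30, then a stop-gain at codon 20 (position 60)
        query = REF_300[:30] + "-" + REF_300[31:60] + "TAA" + REF_300[63:]
        cats = [e.category for e in scan_cds(_pair(REF_300, query)).lof_events]
        assert cats == [LoFCategory.FRAMESHIFT_INDEL]

    def test_stop_upstream_of_frameshift_is_counted(self):
        query = REF_300[:60] + "TAA" + REF_300[63:90] + "-" + REF_300[91:]
        cats = sorted(e.category for e in scan_cds(_pair(REF_300, query)).lof_events)
        assert cats == sorted([LoFCategory.PREMATURE_STOP, LoFCategory.FRAMESHIFT_INDEL])

    def test_incomplete_pair_reports_no_events(self):
        pair = _pair(REF_300, "GTG" + REF_300[3:], missing_exons=[1])
        report = scan_cds(pair)
        assert report.completeness is Completeness.INCOMPLETE
        assert report.n_lof == 0

    def test_heavily_gapped_query_flagged_incomplete(self):
        query = "-" * 60 + REF_300[60:]
        assert scan_cds(_pair(REF_300, query)).completeness is Completeness.INCOMPLETE

    def test_unequal_lengths_fatal(self):
        with pytest.raises(ValueError):
            _pair(REF_300, REF_300[:-3])


class TestSpliceSites:
    MODEL = GeneModel("g", [60, 60, 60, 60, 60, 39],
                      splice_dinucleotides=[("GT", "AG")] * 5)

    def test_canonical_sites_yield_nothing(self):
        assert scan_splice_sites(self.MODEL, [("GT", "AG")] * 5) == []

    def test_intron4_donor_mutation(self):
        # the donor of intron 4 (index 3) mutated GT -> AT
        query = [("GT", "AG")] * 5
        query[3] = ("AT", "AG")
        events = scan_splice_sites(self.MODEL, query)
        assert len(events) == 1
        ev = events[0]
        assert (ev.category, ev.cds_position, ev.splice_side) == (
            LoFCategory.SPLICE_SITE, 3, "donor",
        )

    def test_donor_and_acceptor_in_same_intron_are_two_events(self):
        query = [("GT", "AG")] * 5
        query[1] = ("GA", "AA")
        events = scan_splice_sites(self.MODEL, query)
        assert len(events) == 2
        assert {e.splice_side for e in events} == {"donor", "acceptor"}

    def test_gc_donor_not_called(self, caplog):
        query = [("GT", "AG")] * 5
        query[0] = ("GC", "AG")
        assert scan_splice_sites(self.MODEL, query) == []

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            scan_splice_sites(self.MODEL, [("GT", "AG")] * 4)


class TestSharedLof:
    SPLICE = LoFEvent("rgr1", LoFCategory.SPLICE_SITE, 3, "GT", "AT",
                      splice_side="donor")

    def _report(self, events):
        return GeneScanReport("rgr1", Completeness.COMPLETE, list(events))

    def test_identical_event_in_two_species_is_shared(self):
        table = shared_lof({
            "sp1": [self._report([self.SPLICE])],
            "sp2": [self._report([self.SPLICE])],
        })
        assert len(table) == 1
        assert table.iloc[0]["species_list"] == ["sp1", "sp2"]

    def test_different_positions_not_shared(self):
        other = LoFEvent("rgr1", LoFCategory.PREMATURE_STOP, 42, "TGG", "TGA")
        table = shared_lof({
            "sp1": [self._report([self.SPLICE])],
            "sp2": [self._report([other])],
        })
        assert len(table) == 0

    def test_single_species_gives_empty_table(self):
        assert len(shared_lof({"sp1": [self._report([self.SPLICE])]})) == 0


class TestCountDistribution:
    def _reports(self, n_x):
        reports = []
        g = 0
        for x, n in enumerate(n_x):
            for _ in range(n):
                events = [
                    LoFEvent(f"g{g}", LoFCategory.PREMATURE_STOP, 3 * (k + 1),
                             "TGG", "TGA")
                    for k in range(x)
                ]
                reports.append(GeneScanReport(f"g{g}", Completeness.COMPLETE, events))
                g += 1
        return reports

    @pytest.mark.parametrize(
        "n_x, T, D, m",
        [(DENTATA_COUNTS, 76, 19, 22), (GIBARENSIS_COUNTS, 76, 5, 7)],
    )
    def test_printed_vectors(self, n_x, T, D, m):
        dist = lof_count_distribution(self._reports(n_x))
        assert (dist.T, dist.D, dist.m) == (T, D, m)

    def test_all_clean_genes(self):
        dist = lof_count_distribution(self._reports([10]))
        assert (dist.D, dist.m) == (0, 0)

    def test_incomplete_genes_excluded(self):
        reports = self._reports([3])
        reports.append(GeneScanReport("bad", Completeness.INCOMPLETE))
        assert lof_count_distribution(reports).T == 3


class TestAgainstSimulationTruth:
    def test_reference_scans_clean_against_itself(self, vision_gene_set):
        gs = vision_gene_set
        for g in gs.gene_ids:
            pair = GeneSequencePair(
                gene_id=g, reference_cds=gs.cds[g], query_cds=gs.cds[g],
                query_splice_dinucleotides=gs.models[g].splice_dinucleotides,
            )
            assert scan_gene(pair, gs.models[g]).n_lof == 0

    def test_indel_free_evolution_events_match_truth_exactly(self):
        scen = SimulationScenario(n_genes=40, seed=23, generations=600_000)
        gs = generate_gene_set(scen)
        pairs, truth = evolve_sequences(gs, Regime.NEUTRAL, scen)
        called = sorted(
            (e.gene_id, e.category.value, e.cds_position)
            for p in pairs
            for e in scan_gene(p, gs.models[p.gene_id]).lof_events
        )
        expected = sorted(
            (r.gene_id, r.category, r.position) for r in truth.lof_events()
        )
        assert called == expected
        assert len(called) > 10  # the check exercised real events

    def test_with_indels_counts_agree(self):
        scen = SimulationScenario(
            n_genes=40, seed=29, generations=600_000, indel_rate_ratio=0.05
        )
        gs = generate_gene_set(scen)
        pairs, truth = evolve_sequences(gs, Regime.NEUTRAL, scen)
        called = {
            p.gene_id: scan_gene(p, gs.models[p.gene_id]).n_lof for p in pairs
        }
        assert called == truth.lof_count_by_gene(gs.gene_ids)
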