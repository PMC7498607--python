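import numpy as np
import pytest

from ssrmine.insilico_pcr import Amplicon, BindingSite
from ssrmine.io_core import SequenceRecord
from ssrmine.marker_pipeline import (
    EMM_COLUMNS,
    MarkerRecord,
    call_transfer_polymorphism,
    cluster_across_genomes,
    comparative_map,
    export_emm,
    filter_redundant,
    query_markers,
    transferable_to_clade,
)
from ssrmine.primer_design import (
    FlankedLocus,
    PrimerPair,
    design_for_locus,
    extract_flanks,
)
from ssrmine.repeat_scan import RepeatLocus, canonical_motif

BASES = np.array(list("ACGT"))


def _pair(forward="ACGTACGTACGTACGTAC", reverse="TGCATGCATGCATGCATG", product=200):
    return PrimerPair(forward, reverse, 60.0, 60.0, 50.0, 50.0, product, 1.0, 1, 0, product)


def _marker(mid, genome="gA", start=100, pair=None, seq_id="c1"):
    locus = RepeatLocus(seq_id, start, start + 24, "AG", "AG", 12)
    fl = FlankedLocus(locus, "A" * 10, "C" * 10, "AG" * 12, True, True)
    return MarkerRecord(
        marker_id=mid,
        source_genome=genome,
        locus=locus,
        primer_pairs=(pair or _pair(),),
        flanks=fl,
        source_genomes=(genome,),
    )


def _amp(seq_id, start, length, taxon_mm=0):
    f = BindingSite(seq_id, "+", start, start + 18, taxon_mm, 0)
    r = BindingSite(seq_id, "-", start + length - 18, start + length, 0, 0)
    return Amplicon(seq_id, start, start + length, f, r, "FR")


class TestFilterRedundant:
    def test_duplicate_primer_pairs_first_by_coordinate_kept(self):
        a = _marker("m1", start=100)
        b = _marker("m2", start=500)  # identical pair
        kept, pct = filter_redundant([a, b], [], drop_multihit=False)
        assert [m.marker_id for m in kept] == ["m1"]
        assert pct == pytest.approx(50.0)

    def test_multi_hit_marker_removed(self, rng):
        bg = "".join(rng.choice(BASES, 6000))
        tract = "AAT" * 8
        seq = bg[:900] + tract + bg[900 + len(tract) :]
        cassette = seq[600:1300]
        seq = seq[:4000] + cassette + seq[4000 + len(cassette) :]
        rec = SequenceRecord("c", seq)
        locus = RepeatLocus("c", 900, 924, "AAT", canonical_motif("AAT"), 8)
        pair = design_for_locus(extract_flanks(locus, [rec], 200))[0]
        m = _marker("m1", pair=pair, seq_id="c", start=900)
        kept, pct = filter_redundant([m], [rec], drop_duplicates=False)
        assert kept == [] and pct == pytest.approx(100.0)

    def test_unique_specific_marker_survives(self, rng):
        bg = "".join(rng.choice(BASES, 4000))
        tract = "AG" * 12
        seq = bg[:900] + tract + bg[924:]
        rec = SequenceRecord("c", seq)
        locus = RepeatLocus("c", 900, 924, "AG", "AG", 12)
        pair = design_for_locus(extract_flanks(locus, [rec], 200))[0]
        m = _marker("m1", pair=pair, seq_id="c", start=900)
        kept, pct = filter_redundant([m], [rec])
        assert kept == [m] and pct == 0.0


class TestClusterAcrossGenomes:
    def test_shared_pair_collapses_with_sources_recorded(self):
        shared = _pair()
        per = {
            "gA": [_marker("EMM-gA-1", "gA", pair=shared)],
            "gB": [_marker("EMM-gB-1", "gB", pair=shared)],
            "gC": [_marker("EMM-gC-1", "gC", pair=_pair(forward="GGGGCCCCGGGGCCCCGG"))],
            "gD": [],
        }
        merged, venn = cluster_across_genomes(per)
        assert len(merged) == 2
        two_set = next(m for m in merged if len(m.source_genomes) == 2)
        assert two_set.source_genomes == ("gA", "gB")
        assert venn[frozenset({"gA", "gB"})] == 1
        assert venn[frozenset({"gC"})] == 1

    def test_all_distinct_pairs_concatenate(self):
        per = {
            "gA": [_marker("EMM-gA-1", "gA", pair=_pair(forward="AACCGGTTAACCGGTTAA"))],
            "gB": [_marker("EMM-gB-1", "gB", pair=_pair(forward="TTGGCCAATTGGCCAATT"))],
        }
        merged, venn = cluster_across_genomes(per)
        assert len(merged) == 2
        assert sum(venn.values()) == 2

    def test_venn_cells_sum_to_marker_total(self, small_result):
        assert sum(small_result.venn.values()) == len(small_result.markers)


class TestCallTransferPolymorphism:
    def _matrix(self, sizes_by_taxon):
        return {
            ("m1", taxon): ([_amp("c", 10, size)] if size else [])
            for taxon, size in sizes_by_taxon.items()
        }

    def test_six_bp_boundary_is_polymorphic(self):
        calls = call_transfer_polymorphism(
            self._matrix({"src": 200, "tgt": 206}), {"m1": 200}
        )
        assert calls[0].polymorphic and calls[0].size_range == (200, 206)

    def test_five_bp_is_monomorphic(self):
        calls = call_transfer_polymorphism(
            self._matrix({"src": 200, "tgt": 205}), {"m1": 200}
        )
        assert not calls[0].polymorphic

    def test_negative_differences_count_symmetrically(self):
        calls = call_transfer_polymorphism(
            self._matrix({"src": 200, "tgt": 194}), {"m1": 200}
        )
        assert calls[0].polymorphic

    def test_presence_and_clade_predicate(self):
        calls = call_transfer_polymorphism(
            self._matrix({"a": 200, "b": 0, "c": 203}), {"m1": 200}
        )
        assert calls[0].taxa_present == frozenset({"a", "c"})
        assert transferable_to_clade(calls[0], {"a", "c"})
        assert not transferable_to_clade(calls[0], {"a", "b"})


class TestComparativeMap:
    def test_counts_mean_and_unplaced(self):
        matrix = {
            ("m1", "musa"): [_amp("chr1", 10, 200)],
            ("m2", "musa"): [_amp("chr1", 500, 200)],
            ("m3", "musa"): [_amp("chr1", 900, 200)],
            ("m4", "musa"): [_amp("chr2", 10, 200)],
            ("m5", "musa"): [_amp("chr1", 10, 200), _amp("chr3", 10, 200)],
            ("m6", "other"): [_amp("chrX", 10, 200)],
        }
        cmap = comparative_map(matrix, "musa")
        assert cmap.counts == {"chr1": 3, "chr2": 1}
        assert cmap.unplaced == 1
        assert cmap.mean == pytest.approx(2.0)
        assert cmap.std == pytest.approx(1.0)


class TestExportEmm:
    def test_rows_and_header(self, tmp_path):
        markers = [_marker("m1"), _marker("m2", pair=_pair(forward="GGCCGGCCAATTGGCCAA"))]
        out = tmp_path / "emm.tsv"
        export_emm(markers, out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == EMM_COLUMNS
        assert len(lines) == 3

    def test_export_is_byte_deterministic(self, tmp_path, small_result):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_emm(small_result.markers, p1)
        export_emm(small_result.markers, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_sqlite_queries_match_manifest_filters(self, tmp_path, small_result):
        tsv, db = tmp_path / "emm.tsv", tmp_path / "emm.sqlite"
        export_emm(small_result.markers, tsv, db)
        rows = query_markers(db)
        assert len(rows) == len(small_result.markers)
        class1_poly = [
            m
            for m in small_result.markers
            if m.locus.length_class == "I" and m.polymorphic
        ]
        got = query_markers(db, length_class="I", polymorphic=True)
        assert len(got) == len(class1_poly)
        by_id = query_markers(db, marker_id=small_result.markers[0].marker_id)
        assert len(by_id) == 1


class TestPipelineInvariants:
    def test_every_marker_amplifies_its_source_uniquely(self, small_panel, small_result):
        from ssrmine.insilico_pcr import amplify

        for m in small_result.markers[:4]:
            genome = small_panel.genomes[m.source_genome]
            amps = amplify(m.primer_pairs[0], genome)
            assert len(amps) == 1
            assert amps[0].length == m.expected_size

    def test_success_rate_between_0_and_100(self, small_result):
        for report in small_result.per_genome_reports.values():
            assert 0.0 <= report.success_rate_pct <= 100.0
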