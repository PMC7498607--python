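import numpy as np
import pytest

from oracle_utils import brute_force_binding_sites, rc
from ssrmine.insilico_pcr import (
    EPCRConfig,
    _raw_sites,
    amplify,
    epcr_matrix,
    find_binding_sites,
    suppress_dominated,
)
from ssrmine.io_core import SequenceRecord
from ssrmine.primer_design import design_for_locus, extract_flanks
from ssrmine.repeat_scan import RepeatLocus, canonical_motif

BASES = np.array(list("ACGT"))
CFG = EPCRConfig()


def _sites(primer, text, cfg=CFG):
    return suppress_dominated(_raw_sites(primer, text, cfg), cfg.max_gaps)


def _sub(ch):
    return "A" if ch != "A" else "C"


def _plant(text, primer, pos):
    return text[:pos] + primer + text[pos + len(primer) :]


@pytest.fixture
def text(rng):
    return "".join(rng.choice(BASES, 3000))


@pytest.fixture
def primer(rng):
    return "".join(rng.choice(BASES, 22))


class TestFindBindingSites:
    def test_verbatim_plant_found_exactly(self, text, primer):
        t = _plant(text, primer, 1000)
        assert (1000, 1022, 0, 0) in _sites(primer, t)

    def test_four_substitutions_exceed_mismatch_budget(self, text, primer):
        mut = list(primer)
        for i in (0, 3, 6, 9):  # spaced, all 5' of the seed
            mut[i] = _sub(mut[i])
        t = _plant(text, "".join(mut), 1000)
        cfg = EPCRConfig(max_gaps=0)
        assert not any(
            abs(s[0] - 1000) <= 5 for s in _sites(primer, t, cfg)
        )
        # at default caps no reported site may breach either budget
        for s in _sites(primer, t):
            assert s[2] <= 3 and s[3] <= 3

    def test_three_substitutions_accepted(self, text, primer):
        mut = list(primer)
        for i in (0, 4, 8):
            mut[i] = _sub(mut[i])
        t = _plant(text, "".join(mut), 1000)
        hit = [s for s in _sites(primer, t) if abs(s[0] - 1000) <= 5]
        assert hit and hit[0][2] == 3 and hit[0][3] == 0

    def test_three_gaps_accepted_four_rejected(self, text, primer):
        mut = list(primer)
        for i in (2, 6, 10):
            mut[i] = None  # deletions
        t3 = _plant(text, "".join(c for c in mut if c), 1000)[: len(text)]
        hit = [s for s in _sites(primer, t3) if abs(s[0] - 1000) <= 5]
        assert hit and hit[0][3] <= 3
        mut[13] = None
        t4 = text[:1000] + "".join(c for c in mut if c) + text[1018:]
        assert not any(
            s[2] == 0 and abs(s[0] - 1000) <= 5 for s in _sites(primer, t4)
        )

    def test_two_subs_one_deletion_found(self, text, primer):
        mut = list(primer)
        mut[1] = _sub(mut[1])
        mut[7] = _sub(mut[7])
        del mut[4]
        t = _plant(text, "".join(mut), 1000)[: len(text)]
        hit = [s for s in _sites(primer, t) if abs(s[0] - 1000) <= 5]
        assert hit
        assert hit[0][2] <= 2 and hit[0][3] <= 1

    def test_mismatch_inside_seed_word_rejected(self, text, primer):
        mut = list(primer)
        mut[-3] = _sub(mut[-3])  # inside the 3'-anchored 7-mer
        t = _plant(text, "".join(mut), 1000)
        assert not any(abs(s[0] - 1000) <= 5 for s in _sites(primer, t))

    def test_strand_symmetry(self, text, primer):
        t = _plant(text, primer, 1000)
        rec_fwd = [SequenceRecord("c", t)]
        rec_rev = [SequenceRecord("c", rc(t))]
        fwd = find_binding_sites(primer, rec_fwd)
        rev = find_binding_sites(primer, rec_rev)
        L = len(t)
        mirrored = {
            ("-" if s.strand == "+" else "+", L - s.end, L - s.start, s.mismatches, s.gaps)
            for s in rev
        }
        assert {
            (s.strand, s.start, s.end, s.mismatches, s.gaps) for s in fwd
        } == mirrored

    def test_matches_bruteforce_aligner_on_planted_instance(self, rng):
        t = "".join(rng.choice(BASES, 800))
        p = "".join(rng.choice(BASES, 20))
        mut = list(p)
        mut[2] = _sub(mut[2])
        del mut[8]
        t = t[:300] + p + t[322:]
        t = t[:600] + "".join(mut) + t[619:]
        assert sorted(_sites(p, t)) == brute_force_binding_sites(p, t)


class TestAmplify:
    def _marker(self, rng, n=6000):
        bg = "".join(rng.choice(BASES, n))
        tract = "AAT" * 8
        seq = bg[:900] + tract + bg[900 + len(tract) :]
        rec = SequenceRecord("c", seq)
        locus = RepeatLocus("c", 900, 924, "AAT", canonical_motif("AAT"), 8)
        pairs = design_for_locus(extract_flanks(locus, [rec], 200))
        return rec, pairs[0]

    def test_self_template_single_exact_amplicon(self, rng):
        rec, pair = self._marker(rng)
        (amp,) = amplify(pair, [rec])
        assert amp.length == pair.product_size
        assert amp.orientation == "FR"

    def test_duplicated_cassette_gives_two_amplicons(self, rng):
        rec, pair = self._marker(rng)
        seq = rec.sequence
        cassette = seq[600:1300]
        dup = seq[:4000] + cassette + seq[4000 + len(cassette) :]
        amps = amplify(pair, [SequenceRecord("c", dup)])
        assert len(amps) == 2
        assert {a.length for a in amps} == {pair.product_size}

    def test_product_size_bound_enforced(self, rng):
        rec, pair = self._marker(rng)
        seq = rec.sequence
        # move the reverse-site region 5 kb downstream of the forward site
        left = seq[: 900 + 24]
        right = seq[900 + 24 :]
        stretched = left + "".join(rng.choice(BASES, 5000)) + right
        amps = amplify(pair, [SequenceRecord("c", stretched)], EPCRConfig(max_product=2000))
        assert all(a.length <= 2000 for a in amps)
        assert not any(a.length > 2000 for a in amps)


class TestEpcrMatrix:
    def test_complete_matrix_with_empty_cells(self, rng, small_panel, small_result):
        markers = small_result.markers[:2]
        genomes = {
            "a": small_panel.genomes["landrace_a"],
            "b": small_panel.genomes["landrace_b"],
        }
        matrix = epcr_matrix(markers, genomes)
        assert set(matrix) == {
            (m.marker_id, t) for m in markers for t in ("a", "b")
        }
        assert list(matrix) == sorted(matrix)

    def test_destroyed_site_yields_empty_cell(self, rng):
        bg = "".join(rng.choice(BASES, 4000))
        tract = "AG" * 12
        seq = bg[:900] + tract + bg[924:]
        rec = SequenceRecord("c", seq)
        locus = RepeatLocus("c", 900, 924, "AG", "AG", 12)
        pair = design_for_locus(extract_flanks(locus, [rec], 200))[0]
        # destroy the forward site: substitutions over its 3'-anchored seed
        f_end = 900 - 200 + pair.forward_start + len(pair.forward)
        broken = list(seq)
        for i in range(f_end - 10, f_end, 2):
            broken[i] = _sub(broken[i])
        class M:
            marker_id = "m1"
            primer_pairs = (pair,)
        matrix = epcr_matrix([M()], {"ok": [rec], "broken": [SequenceRecord("c", "".join(broken))]})
        assert matrix[("m1", "ok")] and not matrix[("m1", "broken")]
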