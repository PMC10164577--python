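"""Assembly-sequencing pipeline: demultiplexing, mapping, fragment statistics."""

import numpy as np
import pytest

from strandfold import naqseq, synthgen
from strandfold.core import Fragment, ReadPair
from strandfold.util import revcomp

IDX_A = "ACGTACGT"
IDX_B = "TGCATGCA"


@pytest.fixture(scope="module")
def mapper(refs):
    return naqseq.PlasmidMapper(refs)


@pytest.fixture()
def table():
    return naqseq.IndexTable({"A": IDX_A, "B": IDX_B})


def _find_all(haystack, needle, limit):
    i = haystack.find(needle)
    while 0 <= i < limit:
        yield i
        i = haystack.find(needle, i + 1)


def brute_force_map_read(read, refs):
    """All-positions, all-strands exact scan; returns set of (ref, strand, start)."""
    hits = set()
    for ref in refs:
        L = len(ref)
        ext = ref.sequence * 2 if ref.circular else ref.sequence
        n_starts = L if ref.circular else L - len(read) + 1
        for i in _find_all(ext, read, max(n_starts, 0)):
            hits.add((ref.name, +1, i % L))
        rc = revcomp(ext)
        for i in _find_all(rc, read, max(n_starts, 0)):
            start = (len(ext) - i - len(read)) % L if ref.circular else len(ext) - i - len(read)
            hits.add((ref.name, -1, start))
    return hits


class TestIndexTable:
    def test_near_identical_indices_rejected(self):
        with pytest.raises(ValueError):
            naqseq.IndexTable({"A": "ACGTACGT", "B": "ACGTACGA"})

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            naqseq.IndexTable({})


class TestDemultiplex:
    def _pair(self, i1, i2):
        return ReadPair(name="p", r1=i1 + "A" * 40, r2=i2 + "C" * 40)

    def test_matching_indices_on_both_ends_assigned(self, table):
        assigned, discarded = naqseq.demultiplex([self._pair(IDX_A, IDX_A)], table)
        assert len(assigned["A"]) == 1 and not discarded

    def test_conflicting_mate_indices_discarded(self, table):
        assigned, discarded = naqseq.demultiplex([self._pair(IDX_A, IDX_B)], table)
        assert not assigned and len(discarded) == 1

    def test_partitions_input_exactly(self, table):
        rng = np.random.default_rng(5)
        pairs = []
        for i in range(60):
            i1 = [IDX_A, IDX_B, "GGGGGGGG"][rng.integers(3)]
            i2 = [IDX_A, IDX_B][rng.integers(2)]
            pairs.append(ReadPair(name=f"p{i}", r1=i1 + "A" * 30, r2=i2 + "C" * 30))
        assigned, discarded = naqseq.demultiplex(pairs, table)
        n_assigned = sum(len(v) for v in assigned.values())
        assert n_assigned + len(discarded) == len(pairs)
        names = [p.name for v in assigned.values() for p in v] + [p.name for p in discarded]
        assert sorted(names) == sorted(p.name for p in pairs)

    def test_empty_input(self, table):
        assigned, discarded = naqseq.demultiplex([], table)
        assert not assigned and not discarded


class TestTrimIndex:
    def test_prefix_removed_from_both_mates(self):
        pair = ReadPair(name="p", r1=IDX_A + "G" * 67, r2=IDX_A + "T" * 67)
        out = naqseq.trim_index(pair, 8)
        assert len(out.r1) == 67 and out.r1 == "G" * 67

    def test_read_no_longer_than_index_rejected(self):
        with pytest.raises(ValueError):
            naqseq.trim_index(ReadPair(name="p", r1=IDX_A, r2=IDX_A + "T"), 8)


class TestMapPair:
    def _sim_pairs(self, refs, n, seed, p_nicked=0.5):
        truth = synthgen.NaqSimTruth(p_nicked=p_nicked, n_pairs=n, seed=seed)
        pairs = synthgen.sim_naq_readpairs(truth, refs)
        return [naqseq.trim_index(p, 8) for p in pairs]

    def test_simulated_pairs_recover_generator_coordinates(self, refs, mapper):
        for pair in self._sim_pairs(refs, 200, seed=17):
            frag = naqseq.map_pair(pair, mapper)
            assert frag is not None
            assert frag.reference == pair.true_ref
            assert frag.start == pair.true_start
            assert frag.length == pair.true_length

    def test_origin_spanning_fragment_resolved(self, refs, mapper):
        nicked = refs.by_role("nicked")
        L = len(nicked)
        start, flen = L - 60, 140  # wraps the circular origin
        insert = (nicked.sequence * 2)[start : start + flen]
        pair = ReadPair(name="wrap", r1=insert[:75], r2=revcomp(insert)[:75])
        frag = naqseq.map_pair(pair, mapper)
        assert frag is not None
        assert (frag.start, frag.length) == (start, flen)
        assert frag.end > L  # wrap encoded as end beyond the reference length

    def test_mates_from_different_references_unmapped(self, refs, mapper):
        a = refs.by_role("nicked").sequence
        b = refs.by_role("supercoiled").sequence
        pair = ReadPair(name="x", r1=a[:75], r2=revcomp(b[:140])[:75])
        assert naqseq.map_pair(pair, mapper) is None

    def test_agrees_with_brute_force_scan(self, refs, mapper):
        for pair in self._sim_pairs(refs, 500, seed=23):
            for read in (pair.r1, pair.r2):
                hits = brute_force_map_read(read, refs)
                got = mapper.map_read(read)
                if len(hits) == 1:
                    ref, strand, start = next(iter(hits))
                    assert got is not None
                    assert (got.ref, got.strand, got.start) == (ref, strand, start)
                else:
                    assert got is None


class TestLengthSelect:
    def test_closed_interval_boundaries(self):
        frags = [Fragment("p", 0, n) for n in (120, 125, 160, 161)]
        kept = naqseq.length_select(frags)
        assert [f.length for f in kept] == [125, 160]

    def test_composition_is_window_intersection(self):
        rng = np.random.default_rng(3)
        frags = [Fragment("p", 0, int(n)) for n in rng.integers(80, 220, 200)]
        twice = naqseq.length_select(naqseq.length_select(frags, 100, 180), 125, 160)
        assert twice == naqseq.length_select(frags, 125, 160)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            naqseq.length_select([], 160, 125)


class TestPercentNicked:
    def test_arithmetic_and_control_exclusion(self, refs):
        nicked = refs.by_role("nicked").name
        sc = refs.by_role("supercoiled").name
        ctrl = refs.by_role("loading_control").name
        frags = (
            [Fragment(nicked, 0, 150)] * 50
            + [Fragment(sc, 0, 150)] * 50
            + [Fragment(ctrl, 0, 150)] * 30
        )
        assert naqseq.percent_nicked(frags, refs) == pytest.approx(50.0)

    def test_no_nicked_fragments(self, refs):
        frags = [Fragment(refs.by_role("supercoiled").name, 0, 150)] * 10
        assert naqseq.percent_nicked(frags, refs) == 0.0

    def test_empty_denominator_rejected(self, refs):
        with pytest.raises(ValueError):
            naqseq.percent_nicked([], refs)


class TestControlNormalizedCoverage:
    def test_scale_invariance(self, refs):
        nicked = refs.by_role("nicked").name
        frags = [Fragment(nicked, i * 10, i * 10 + 150) for i in range(20)]
        cov1 = naqseq.control_normalized_coverage(frags, refs, control_count=10)
        cov2 = naqseq.control_normalized_coverage(frags * 2, refs, control_count=20)
        assert np.allclose(cov1[nicked], cov2[nicked])

    def test_wrap_around_coverage(self, refs):
        nicked = refs.by_role("nicked")
        L = len(nicked)
        frags = [Fragment(nicked.name, L - 50, L + 100)]  # wraps
        cov = naqseq.control_normalized_coverage(frags, refs, control_count=1)
        assert cov[nicked.name][L - 1] == 1.0 and cov[nicked.name][0] == 1.0
        assert cov[nicked.name].sum() == 150

    def test_zero_control_rejected(self, refs):
        with pytest.raises(ValueError):
            naqseq.control_normalized_coverage([], refs, control_count=0)


class TestGelLevelQuants:
    @pytest.mark.parametrize("nuc,ctrl,expected", [(30.0, 60.0, 0.5), (5.0, 5.0, 1.0)])
    def test_band_ratio(self, nuc, ctrl, expected):
        assert naqseq.gel_band_quant(nuc, ctrl) == pytest.approx(expected)

    def test_band_ratio_zero_control_rejected(self):
        with pytest.raises(ValueError):
            naqseq.gel_band_quant(1.0, 0.0)

    @pytest.mark.parametrize(
        "nicked,sc,expected", [(1.0, 1.0, 50.0), (1.0, 4.0, 20.0), (0.0, 3.0, 0.0)]
    )
    def test_fluorescence_fraction(self, nicked, sc, expected):
        assert naqseq.fluorescence_fraction_nicked(nicked, sc) == pytest.approx(expected)


class TestFullPipelineRecovery:
    def test_percent_nicked_recovered_within_binomial_error(self, refs):
        n = 20000
        truth = synthgen.NaqSimTruth(p_nicked=0.5, n_pairs=n, adapter_index=IDX_A, seed=31)
        pairs = synthgen.sim_naq_readpairs(truth, refs)
        table = naqseq.IndexTable({"A": IDX_A})
        summary = naqseq.run_naq_pipeline(pairs, table, refs)["A"]
        se_pct = 100.0 * np.sqrt(0.25 / n)
        assert summary.percent_nicked == pytest.approx(50.0, abs=3 * se_pct)
        assert summary.n_assigned == n
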