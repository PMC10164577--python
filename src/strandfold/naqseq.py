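"""Plasmid nucleosome-assembly sequencing (NAQ-seq) analysis.

The assay mixes a nicked plasmid (where the PCNA clamp can be loaded) with a
supercoiled competitor of different sequence, assembles nucleosomes, digests
with MNase and sequences the protected fragments together with a linear
loading-control amplicon. This module implements the read-level pipeline:

demultiplexing by the ligated adapter index present at the 5' end of BOTH
mates, index trimming, unique-best mapping of read pairs onto the (circular)
plasmid references, selection of nucleosomal fragment lengths (125-160 bp),
the percent-nicked statistic, and loading-control-normalized coverage.

Mapping uses an exact k-mer seed (default 31) with full ungapped verification
against the doubled circular sequence and its reverse complement; a pair is
reported only when both mates place at a unique best location on the same
reference in proper orientation. Uniqueness of the best placement stands in
for a mapping-quality cutoff, which is appropriate for error-free reads on
kilobase-scale references with disjoint k-mer content.

Gel-level quantifications of the same assay (band ratios, fluorescence
fractions) live here as well.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from strandfold.core import Fragment, PlasmidReference, ReadPair, ReferenceSet
from strandfold.util import hamming, revcomp

DEFAULT_SEED_K = 31
NUCLEOSOMAL_LO = 125
NUCLEOSOMAL_HI = 160


# ---------------------------------------------------------------------------
# demultiplexing


class IndexTable:
    """Sample -> adapter-index table; indices must be equal-length and
    pairwise distinct at >= 2 mismatches so single-mismatch assignment stays
    unambiguous."""

    def __init__(self, indices: dict[str, str]):
        if not indices:
            raise ValueError("index table must be non-empty")
        lengths = {len(v) for v in indices.values()}
        if len(lengths) != 1:
            raise ValueError("all indices must have the same length")
        self.index_length = lengths.pop()
        if self.index_length == 0:
            raise ValueError("indices must be non-empty")
        items = list(indices.items())
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if hamming(items[i][1], items[j][1]) < 2:
                    raise ValueError(
                        f"indices for {items[i][0]!r} and {items[j][0]!r} differ at < 2 positions"
                    )
        self.indices = dict(indices)

    def items(self):
        return self.indices.items()


def _match_index(read: str, table: IndexTable, max_mismatch: int) -> str | None:
    prefix = read[: table.index_length]
    if len(prefix) < table.index_length:
        return None
    best: str | None = None
    for sample, idx in table.items():
        if hamming(prefix, idx) <= max_mismatch:
            if best is not None:
                return None  # ambiguous (cannot happen for valid tables, mm=0)
            best = sample
    return best


def demultiplex(
    pairs: list[ReadPair], table: IndexTable, max_mismatch: int = 0
) -> tuple[dict[str, list[ReadPair]], list[ReadPair]]:
    """Assign pairs to samples by the adapter index on BOTH read ends.

    A pair goes to sample ``s`` only when both mates begin with s's index
    (within ``max_mismatch``); pairs with absent, mismatched or conflicting
    indices are discarded. Returns (per-sample pairs, discard pile); every
    input pair lands in exactly one of the two.
    """
    assigned: dict[str, list[ReadPair]] = defaultdict(list)
    discarded: list[ReadPair] = []
    for pair in pairs:
        s1 = _match_index(pair.r1, table, max_mismatch)
        s2 = _match_index(pair.r2, table, max_mismatch)
        if s1 is not None and s1 == s2:
            assigned[s1].append(pair)
        else:
            discarded.append(pair)
    return dict(assigned), discarded


def trim_index(pair: ReadPair, index_length: int) -> ReadPair:
    """Remove the 5' adapter index from both mates of an assigned pair."""
    if len(pair.r1) <= index_length or len(pair.r2) <= index_length:
        raise ValueError(f"pair {pair.name!r}: read not longer than the index")
    return ReadPair(
        name=pair.name,
        r1=pair.r1[index_length:],
        r2=pair.r2[index_length:],
        true_ref=pair.true_ref,
        true_start=pair.true_start,
        true_length=pair.true_length,
    )


# ---------------------------------------------------------------------------
# mapping


@dataclass(frozen=True)
class _Hit:
    ref: str
    strand: int  # +1 read matches forward strand, -1 matches reverse
    start: int  # leftmost forward-strand coordinate, in [0, L)


class PlasmidMapper:
    """Exact-seed unique-best mapper for short reads on small references.

    Indexes every k-mer start position of each reference (doubled when
    circular, so reads crossing the origin are found) on both strands. A read
    is placed by looking up its first k-mer and verifying the full read
    ungapped; the placement must be unique after collapsing circular
    rotations, otherwise the read is treated as unmapped.
    """

    def __init__(self, refs: ReferenceSet, k: int = DEFAULT_SEED_K):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.refs = refs
        self.k = k
        self._seqs: dict[str, tuple[str, bool]] = {}
        self._index: dict[str, list[tuple[str, int, int]]] = {}
        for ref in refs:
            L = len(ref)
            ext = ref.sequence * 2 if ref.circular else ref.sequence
            self._seqs[ref.name] = (ref.sequence, ref.circular)
            n_starts = L if ref.circular else max(L - k + 1, 0)
            for strand, seq in ((+1, ext), (-1, revcomp(ext))):
                for i in range(n_starts):
                    self._index.setdefault(seq[i : i + k], []).append((ref.name, strand, i))

    def _verify(self, read: str, ref_name: str, strand: int, seed_pos: int) -> _Hit | None:
        seq, circular = self._seqs[ref_name]
        L = len(seq)
        ext = seq * 2 if circular else seq
        target = ext if strand == +1 else revcomp(ext)
        if seed_pos + len(read) > len(target):
            return None
        if target[seed_pos : seed_pos + len(read)] != read:
            return None
        if strand == +1:
            start = seed_pos % L if circular else seed_pos
        else:
            # position in reverse-complement coords -> forward-strand leftmost
            end_fwd = len(target) - seed_pos
            start = (end_fwd - len(read)) % L if circular else end_fwd - len(read)
            if start < 0:
                return None
        return _Hit(ref=ref_name, strand=strand, start=start)

    def map_read(self, read: str) -> _Hit | None:
        """Unique-best placement of a single read, or None."""
        if len(read) < self.k:
            return None
        candidates = self._index.get(read[: self.k], [])
        hits: set[_Hit] = set()
        for ref_name, strand, seed_pos in candidates:
            hit = self._verify(read, ref_name, strand, seed_pos)
            if hit is not None:
                hits.add(hit)
        if len(hits) != 1:
            return None
        return hits.pop()


def map_pair(pair: ReadPair, mapper: PlasmidMapper) -> Fragment | None:
    """Map a trimmed read pair to a Fragment, or None when unmapped.

    Requires both mates uniquely placed on the same reference on opposite
    strands in proper (inward-facing) orientation. The fragment is the outer
    span of the two mate alignments; on circular references a span crossing
    the origin is resolved so that ``end - start`` is the true insert length
    (``end`` then exceeds the reference length).
    """
    h1 = mapper.map_read(pair.r1)
    h2 = mapper.map_read(pair.r2)
    if h1 is None or h2 is None or h1.ref != h2.ref or h1.strand == h2.strand:
        return None
    fwd, rev, fwd_len, rev_len = (
        (h1, h2, len(pair.r1), len(pair.r2))
        if h1.strand == +1
        else (h2, h1, len(pair.r2), len(pair.r1))
    )
    seq, circular = mapper._seqs[fwd.ref]
    L = len(seq)
    frag_end = rev.start + rev_len  # rightmost coordinate of the reverse mate
    if circular:
        length = (frag_end - fwd.start - 1) % L + 1
    else:
        length = frag_end - fwd.start
    if length < max(fwd_len, rev_len) or length <= 0 or length > L:
        return None  # outward-facing or inconsistent pair
    return Fragment(reference=fwd.ref, start=fwd.start, end=fwd.start + length, unique=True)


# ---------------------------------------------------------------------------
# fragment-level statistics


def length_select(
    fragments: list[Fragment], lo: int = NUCLEOSOMAL_LO, hi: int = NUCLEOSOMAL_HI
) -> list[Fragment]:
    """Keep fragments with lo <= length <= hi (closed interval), stable order."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    return [f for f in fragments if lo <= f.length <= hi]


def percent_nicked(fragments: list[Fragment], refs: ReferenceSet) -> float:
    """Percent of plasmid fragments on the nicked reference.

    100 * n_nicked / (n_nicked + n_supercoiled); loading-control fragments
    are excluded from both numerator and denominator.
    """
    nicked_name = refs.by_role("nicked").name
    sc_name = refs.by_role("supercoiled").name
    n_nicked = sum(1 for f in fragments if f.reference == nicked_name)
    n_sc = sum(1 for f in fragments if f.reference == sc_name)
    if n_nicked + n_sc == 0:
        raise ValueError("no fragments on the nicked or supercoiled plasmid")
    return 100.0 * n_nicked / (n_nicked + n_sc)


def control_normalized_coverage(
    fragments: list[Fragment], refs: ReferenceSet, control_count: int | None = None
) -> dict[str, np.ndarray]:
    """Per-bp fragment coverage of each plasmid, divided by the loading-control
    fragment count (retrieval normalization).

    ``control_count`` defaults to the number of fragments on the
    loading-control reference among ``fragments``.
    """
    control_name = refs.by_role("loading_control").name
    if control_count is None:
        control_count = sum(1 for f in fragments if f.reference == control_name)
    if control_count <= 0:
        raise ValueError("loading-control fragment count must be positive")
    out: dict[str, np.ndarray] = {}
    for role in ("nicked", "supercoiled"):
        ref = refs.by_role(role)
        L = len(ref)
        cov = np.zeros(L)
        for f in fragments:
            if f.reference != ref.name:
                continue
            if f.end <= L:
                cov[f.start : f.end] += 1
            else:  # wraps the circular origin
                cov[f.start :] += 1
                cov[: f.end - L] += 1
        out[ref.name] = cov / control_count
    return out


# ---------------------------------------------------------------------------
# gel-level quantifications of the same assay


def gel_band_quant(nucleosome_band_intensity: float, control_band_intensity: float) -> float:
    """Nucleosome band (140-160 bp) normalized to the 621 bp loading-control
    band within the same lane."""
    if control_band_intensity <= 0:
        raise ValueError("control band intensity must be positive")
    return nucleosome_band_intensity / control_band_intensity


def fluorescence_fraction_nicked(nicked_intensity: float, supercoiled_intensity: float) -> float:
    """Percent of histone fluorescence on the nicked plasmid relative to the
    total on both plasmids — the clamp-dependent assembly readout."""
    if nicked_intensity < 0 or supercoiled_intensity < 0:
        raise ValueError("intensities must be nonnegative")
    total = nicked_intensity + supercoiled_intensity
    if total <= 0:
        raise ValueError("total intensity must be positive")
    return 100.0 * nicked_intensity / total


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class NaqSampleSummary:
    sample: str
    n_assigned: int
    n_mapped: int
    n_selected: int
    percent_nicked: float


def run_naq_pipeline(
    pairs: list[ReadPair],
    table: IndexTable,
    refs: ReferenceSet,
    lo: int = NUCLEOSOMAL_LO,
    hi: int = NUCLEOSOMAL_HI,
    max_mismatch: int = 0,
    seed_k: int = DEFAULT_SEED_K,
) -> dict[str, NaqSampleSummary]:
    """Demultiplex -> trim -> map -> length-select -> percent-nicked, per sample."""
    mapper = PlasmidMapper(refs, k=seed_k)
    assigned, _ = demultiplex(pairs, table, max_mismatch)
    out: dict[str, NaqSampleSummary] = {}
    for sample, sample_pairs in assigned.items():
        fragments = []
        for pair in sample_pairs:
            frag = map_pair(trim_index(pair, table.index_length), mapper)
            if frag is not None:
                fragments.append(frag)
        selected = length_select(fragments, lo, hi)
        out[sample] = NaqSampleSummary(
            sample=sample,
            n_assigned=len(sample_pairs),
            n_mapped=len(fragments),
            n_selected=len(selected),
            percent_nicked=percent_nicked(selected, refs),
        )
    return out
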