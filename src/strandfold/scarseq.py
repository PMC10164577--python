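"""Strand-partition analysis of stranded sequencing tracks.

Implements the partition / replication-fork-directionality (RFD) computation
on per-bin forward/reverse count tracks: counts-per-million scaling, uniform
blur smoothing, input subtraction with zero clipping, joint low-coverage
filtering, the partition score (F - R)/(F + R), meta-profiles around oriented
replication initiation zones, and spike-in normalization of library totals.

Conventions: 1 kb bins by default, smoothing over the 30 neighbouring bins on
each side, bins where both strands fall below 0.3 CPM after input correction
are masked. A positive partition score marks enrichment on the nascent
forward strand; RFD is the same ratio with the sign reversed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from strandfold.core import InitiationZone, PartitionTrack, StrandedBinTrack

DEFAULT_BLUR_HALFWIDTH = 30
DEFAULT_MIN_CPM = 0.3


def cpm_normalize(track: StrandedBinTrack, library_total: float) -> StrandedBinTrack:
    """Scale raw counts to counts-per-million of the library total.

    The denominator is the total mapped target-genome reads of the sample
    across both strands (a single library is strand-split after sequencing).
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if track.units != "counts":
        raise ValueError("track must be in counts")
    scale = 1e6 / library_total
    return replace(track, F=track.F * scale, R=track.R * scale, units="CPM")


def _window_mean(x: np.ndarray, halfwidth: int) -> np.ndarray:
    # truncated-window mean: edge windows renormalized by their actual size
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.maximum(np.arange(n) - halfwidth, 0)
    hi = np.minimum(np.arange(n) + halfwidth + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def uniform_blur(track: StrandedBinTrack, halfwidth: int = DEFAULT_BLUR_HALFWIDTH) -> StrandedBinTrack:
    """Smooth each strand with a uniform blur over ``halfwidth`` bins per side.

    Each bin becomes the mean of the window [i - h, i + h] intersected with
    the track; truncated edge windows are renormalized by their actual size,
    so no signal is fabricated at the ends. ``halfwidth=0`` is the identity.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be nonnegative")
    if halfwidth == 0:
        return replace(track)
    return replace(
        track,
        F=_window_mean(track.F, halfwidth),
        R=_window_mean(track.R, halfwidth),
    )


def input_correct(pulldown: StrandedBinTrack, input_track: StrandedBinTrack) -> StrandedBinTrack:
    """Subtract the matched input per strand and clip negatives at zero."""
    if pulldown.F.shape != input_track.F.shape:
        raise ValueError("pulldown and input tracks must have the same shape")
    if pulldown.units != input_track.units:
        raise ValueError("pulldown and input tracks must share units")
    return replace(
        pulldown,
        F=np.maximum(pulldown.F - input_track.F, 0.0),
        R=np.maximum(pulldown.R - input_track.R, 0.0),
    )


def coverage_filter(track: StrandedBinTrack, threshold_cpm: float = DEFAULT_MIN_CPM) -> np.ndarray:
    """Validity mask for an input-corrected CPM track.

    A bin is masked out when BOTH strands fall strictly below the threshold
    (jointly low coverage), or when F + R = 0 (the partition ratio would be
    undefined). Returns a boolean array, True = keep.
    """
    low_both = (track.F < threshold_cpm) & (track.R < threshold_cpm)
    empty = (track.F + track.R) == 0
    return ~(low_both | empty)


def partition(track: StrandedBinTrack, mask: np.ndarray | None = None) -> PartitionTrack:
    """Partition score (F - R)/(F + R) per kept bin; masked bins are NaN.

    Scores of +1 / -1 mark signal confined to the nascent forward / reverse
    strand respectively.
    """
    if mask is None:
        mask = np.ones(track.n_bins, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != track.F.shape:
        raise ValueError("mask length must equal track length")
    total = track.F + track.R
    valid = mask & (total > 0)
    value = np.full(track.n_bins, np.nan)
    value[valid] = (track.F[valid] - track.R[valid]) / total[valid]
    return PartitionTrack(
        reference=track.reference, bin_width=track.bin_width, value=value, mask=valid
    )


def rfd(track: StrandedBinTrack, mask: np.ndarray | None = None) -> PartitionTrack:
    """Replication fork directionality (R - F)/(F + R): minus the partition."""
    p = partition(track, mask)
    return PartitionTrack(
        reference=p.reference, bin_width=p.bin_width, value=-p.value, mask=p.mask
    )


@dataclass(frozen=True)
class MetaProfile:
    """Mean partition by signed bin offset from oriented initiation zones."""

    offsets_bins: np.ndarray
    mean: np.ndarray
    n: np.ndarray
    bin_width: int

    @property
    def offsets_bp(self) -> np.ndarray:
        return self.offsets_bins * self.bin_width

    def extremum(self) -> float:
        """The profile value of largest magnitude (signed)."""
        finite = np.isfinite(self.mean)
        if not finite.any():
            raise ValueError("profile has no defined offsets")
        vals = self.mean[finite]
        return float(vals[np.argmax(np.abs(vals))])


def iz_metaprofile(
    ptrack: PartitionTrack, izs: list[InitiationZone], window: int
) -> MetaProfile:
    """Average the partition track across initiation zones.

    For each signed offset in [-window, +window], the mean of the defined
    partition values over all zones. Zones with orientation -1 are mirrored
    (offset negated) AND sign-flipped, so leading-strand bias always appears
    on positive offsets; per-offset counts are reported.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not izs:
        raise ValueError("empty initiation-zone list")
    n_bins = ptrack.value.size
    offsets = np.arange(-window, window + 1)
    total = np.zeros(offsets.size)
    count = np.zeros(offsets.size, dtype=int)
    for iz in izs:
        if not 0 <= iz.center_bin < n_bins:
            raise ValueError(f"initiation zone at bin {iz.center_bin} outside track")
        idx = iz.center_bin + iz.strand_orientation * offsets
        ok = (idx >= 0) & (idx < n_bins)
        vals = np.full(offsets.size, np.nan)
        vals[ok] = ptrack.value[idx[ok]] * iz.strand_orientation
        defined = np.isfinite(vals)
        total[defined] += vals[defined]
        count[defined] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return MetaProfile(offsets_bins=offsets, mean=mean, n=count, bin_width=ptrack.bin_width)


def spikein_normalize(
    sample_totals: dict[str, tuple[float, float]], reference_sample: str
) -> dict[str, float]:
    """Spike-in-normalized relative abundance per sample.

    ``sample_totals`` maps sample -> (target-genome reads, spike-in reads).
    Each sample's target/spike-in ratio is divided by the reference sample's
    ratio, so the reference maps to 1.0. Because the spike-in is added in
    constant amount, the result compares absolute material across samples.
    """
    if reference_sample not in sample_totals:
        raise KeyError(f"reference sample {reference_sample!r} not in totals")
    for sample, (target, spike) in sample_totals.items():
        if spike <= 0:
            raise ValueError(f"sample {sample!r}: spike-in count must be positive")
        if target <= 0:
            raise ValueError(f"sample {sample!r}: target count must be positive")
    ref_target, ref_spike = sample_totals[reference_sample]
    ref_ratio = ref_target / ref_spike
    return {s: (t / sp) / ref_ratio for s, (t, sp) in sample_totals.items()}


def compute_partition(
    pulldown: StrandedBinTrack,
    input_track: StrandedBinTrack,
    pulldown_total: float | None = None,
    input_total: float | None = None,
    blur_halfwidth: int = DEFAULT_BLUR_HALFWIDTH,
    min_cpm: float = DEFAULT_MIN_CPM,
) -> PartitionTrack:
    """Full per-sample pipeline: CPM -> blur -> input subtraction -> filter -> partition.

    Library totals default to the track sums (appropriate when the tracks
    cover the whole mapped library).
    """
    if pulldown_total is None:
        pulldown_total = float(pulldown.F.sum() + pulldown.R.sum())
    if input_total is None:
        input_total = float(input_track.F.sum() + input_track.R.sum())
    pd = uniform_blur(cpm_normalize(pulldown, pulldown_total), blur_halfwidth)
    inp = uniform_blur(cpm_normalize(input_track, input_total), blur_halfwidth)
    corrected = input_correct(pd, inp)
    mask = coverage_filter(corrected, min_cpm)
    return partition(corrected, mask)
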