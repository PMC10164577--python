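"""Synthetic-data generators with known ground truth.

Every analysis stage in this package has a matching generator here, so the
whole pipeline can be validated by parameter recovery: plasmid references and
paired nucleosomal reads for the assembly-sequencing pipeline, stranded bin
tracks with injected partition asymmetry for the strand-partition pipeline,
1-D gel lanes on a log-linear migration calibration, titration curves from the
one-site Hill model, and mass-photometry event lists from Gaussian mixtures.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from strandfold.core import (
    LaneProfile,
    PlasmidReference,
    ReadPair,
    ReferenceSet,
    StrandedBinTrack,
    TitrationCurve,
    hill_response,
)
from strandfold.util import revcomp

# Lambda DNA / HindIII digest product sizes (bp), the standard sizing ladder.
LAMBDA_HINDIII_BP = (23130, 9416, 6557, 4361, 2322, 2027, 564, 125)

# Default log-linear gel calibration: log10(size_bp) = slope * Rf + intercept.
DEFAULT_GEL_CALIBRATION = (-1.7, 4.3)

READ_LENGTH = 75  # nt of insert sequence carried per mate, after the index


# ---------------------------------------------------------------------------
# references


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _kmers(seq: str, k: int, circular: bool) -> list[str]:
    s = seq + seq[: k - 1] if circular else seq
    return [s[i : i + k] for i in range(len(s) - k + 1)]


def gen_references(
    seed: int,
    lengths: tuple[int, int, int] = (3000, 3000, 207),
    k: int = 31,
    max_retries: int = 25,
) -> ReferenceSet:
    """Generate a nicked plasmid, a supercoiled plasmid and a loading-control
    amplicon with mutually disjoint ``k``-mer content.

    Disjointness is checked over both strands (and across the circular origin),
    which guarantees that any error-free read of >= k nt maps to a unique
    reference; uniqueness of the position within a reference is checked too.
    Lengths below 500 bp are rejected for the two plasmids.
    """
    if len(lengths) != 3:
        raise ValueError("expected three lengths (nicked, supercoiled, loading_control)")
    if lengths[0] < 500 or lengths[1] < 500:
        raise ValueError("plasmid lengths must be >= 500 bp")
    if lengths[2] < k:
        raise ValueError(f"loading-control length must be >= k ({k})")
    rng = np.random.default_rng(seed)
    specs = [
        ("pNick", lengths[0], True, "nicked"),
        ("pSC", lengths[1], True, "supercoiled"),
        ("ctrl207", lengths[2], False, "loading_control"),
    ]
    for _ in range(max_retries):
        refs = [
            PlasmidReference(name, _random_dna(rng, n), circ, role)
            for name, n, circ, role in specs
        ]
        kmer_sets = []
        ok = True
        for r in refs:
            fwd = _kmers(r.sequence, k, r.circular)
            rev = _kmers(revcomp(r.sequence), k, r.circular)
            both = fwd + rev
            if len(set(both)) != len(both):  # repeated k-mer within a reference
                ok = False
                break
            kmer_sets.append(set(both))
        if ok and all(
            not (kmer_sets[i] & kmer_sets[j])
            for i in range(3)
            for j in range(i + 1, 3)
        ):
            return ReferenceSet(tuple(refs))
    raise RuntimeError(f"could not generate {k}-mer-disjoint references in {max_retries} tries")


# ---------------------------------------------------------------------------
# nucleosome-assembly sequencing reads


@dataclass(frozen=True)
class NaqSimTruth:
    """Ground truth for a simulated assembly-sequencing library.

    ``p_nicked`` is the probability that a (non-control) nucleosomal fragment
    derives from the nicked plasmid; fragment lengths are Normal(mean, sd)
    truncated to [50, 250] bp, emulating an MNase digest around the ~147 bp
    nucleosome footprint.
    """

    p_nicked: float
    n_pairs: int
    fraglen_mean: float = 145.0
    fraglen_sd: float = 10.0
    adapter_index: str = "ACGTACGT"
    control_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_nicked <= 1.0:
            raise ValueError("p_nicked must lie in [0, 1]")
        if not 100 <= self.fraglen_mean <= 200:
            raise ValueError("fraglen_mean outside plausible nucleosomal range (100-200 bp)")
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if not 0.0 <= self.control_fraction < 1.0:
            raise ValueError("control_fraction must lie in [0, 1)")


def _truncated_normal_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int = 50, hi: int = 250
) -> np.ndarray:
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = np.rint(rng.normal(mean, sd, size=2 * (n - filled))).astype(int)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def sim_naq_readpairs(
    truth: NaqSimTruth, refs: ReferenceSet, read_length: int = READ_LENGTH
) -> list[ReadPair]:
    """Simulate error-free paired reads from an assembly-sequencing library.

    Each pair derives from a fragment on the nicked plasmid with probability
    ``p_nicked`` (else the supercoiled one); a ``control_fraction`` of pairs
    comes from the linear loading-control amplicon instead. Both mates carry
    the sample's adapter index at their 5' end followed by up to
    ``read_length`` nt of insert sequence (mate 2 reverse-complemented).
    Fragments on circular references wrap the origin.
    """
    if not refs.references:
        raise ValueError("empty reference set")
    rng = np.random.default_rng(truth.seed)
    nicked = refs.by_role("nicked")
    supercoiled = refs.by_role("supercoiled")
    control = refs.by_role("loading_control")

    is_control = rng.random(truth.n_pairs) < truth.control_fraction
    is_nicked = rng.random(truth.n_pairs) < truth.p_nicked
    lengths = _truncated_normal_lengths(
        rng, truth.n_pairs, truth.fraglen_mean, truth.fraglen_sd
    )
    pairs: list[ReadPair] = []
    for i in range(truth.n_pairs):
        if is_control[i]:
            ref = control
        elif is_nicked[i]:
            ref = nicked
        else:
            ref = supercoiled
        L = len(ref)
        flen = int(min(lengths[i], L))
        if ref.circular:
            start = int(rng.integers(0, L))
            insert = (ref.sequence * 2)[start : start + flen]
        else:
            start = int(rng.integers(0, L - flen + 1))
            insert = ref.sequence[start : start + flen]
        r1 = truth.adapter_index + insert[:read_length]
        r2 = truth.adapter_index + revcomp(insert)[:read_length]
        pairs.append(
            ReadPair(
                name=f"frag{i}:{ref.name}:{start}:{flen}",
                r1=r1,
                r2=r2,
                true_ref=ref.name,
                true_start=start,
                true_length=flen,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# stranded bin tracks with injected partition asymmetry


@dataclass(frozen=True)
class ScarSimTruth:
    """Ground truth for simulated strand-partition samples.

    The injected forward-strand fraction at signed bin offset ``d`` from the
    nearest initiation zone is ``0.5 * (1 + a * s(d))`` with
    ``s(d) = sign(d) * exp(-|d| / decay_bins)``: bins downstream of an
    initiation zone are enriched on the forward strand for positive amplitude
    ``a``, mirroring the odd-symmetric average profile around origins.

    ``depth_per_bin`` is the expected pulldown read count per bin (F + R)
    for a sample with scale factor 1; ``spikein_fraction`` sets a constant
    exogenous-genome read count ``round(spikein_fraction * depth_per_bin *
    n_bins)`` shared by all samples.

    ``decay_bins`` defaults to 300 (300 kb at 1 kb bins): fork-directionality
    bias around initiation zones extends over hundreds of kilobases, so the
    injected profile must be broad relative to the +/-30-bin smoothing
    window of the analysis pipeline.

    ``pulldown_enrichment`` is the ratio of pulldown to input CPM inside the
    simulated window: the pulldown library concentrates its reads on marked
    nascent chromatin while the input spreads genome-wide, so within covered
    regions the input sits well below the pulldown after CPM scaling. The
    generator reports matching library totals on each sample.
    """

    n_bins: int
    iz_positions: tuple[int, ...]
    partition_amplitude: float
    decay_bins: float = 300.0
    depth_per_bin: float = 50.0
    bin_width: int = 1000
    spikein_fraction: float = 0.05
    pulldown_enrichment: float = 20.0
    sample_scale_factors: dict[str, float] = field(default_factory=lambda: {"sample": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.partition_amplitude) > 1:
            raise ValueError("|partition_amplitude| must be <= 1")
        if self.depth_per_bin <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 < self.spikein_fraction < 1.0:
            raise ValueError("spikein_fraction must lie in (0, 1)")
        if self.pulldown_enrichment <= 1.0:
            raise ValueError("pulldown_enrichment must exceed 1")
        if any(s <= 0 for s in self.sample_scale_factors.values()):
            raise ValueError("scale factors must be positive")
        if any(not 0 <= p < self.n_bins for p in self.iz_positions):
            raise ValueError("iz_positions must lie within [0, n_bins)")


@dataclass(frozen=True)
class ScarSample:
    """One simulated sample: pulldown and input tracks, their library totals
    (the CPM denominators), and the spike-in read count."""

    pulldown: StrandedBinTrack
    input: StrandedBinTrack
    spikein_reads: int
    pulldown_library_total: float
    input_library_total: float

    @property
    def target_reads(self) -> int:
        return int(self.pulldown.F.sum() + self.pulldown.R.sum())


def forward_fraction_profile(truth: ScarSimTruth) -> np.ndarray:
    """Expected forward-strand fraction per bin under the injected asymmetry."""
    bins = np.arange(truth.n_bins)
    if not truth.iz_positions:
        return np.full(truth.n_bins, 0.5)
    izs = np.asarray(truth.iz_positions)
    d = bins[:, None] - izs[None, :]
    nearest = np.argmin(np.abs(d), axis=1)
    d_near = d[np.arange(truth.n_bins), nearest].astype(float)
    s = np.sign(d_near) * np.exp(-np.abs(d_near) / truth.decay_bins)
    return 0.5 * (1.0 + truth.partition_amplitude * s)


def sim_scar_samples(truth: ScarSimTruth) -> dict[str, ScarSample]:
    """Simulate pulldown/input stranded tracks for each sample.

    Per-bin counts are Poisson with means ``scale * depth * f`` (forward) and
    ``scale * depth * (1 - f)`` (reverse) for the pulldown, and symmetric
    ``scale * depth / 2`` for the input. Spike-in counts are constant across
    samples — only the target-genome totals scale.

    The pulldown library total equals the window sum (its reads concentrate
    on nascent chromatin); the input library total is inflated by
    ``pulldown_enrichment`` so that the input CPM inside the window sits at
    ``1 / pulldown_enrichment`` of the pulldown CPM, as in genome-wide input
    libraries.
    """
    rng = np.random.default_rng(truth.seed)
    f = forward_fraction_profile(truth)
    spikein = int(round(truth.spikein_fraction * truth.depth_per_bin * truth.n_bins))
    out: dict[str, ScarSample] = {}
    for sample, scale in truth.sample_scale_factors.items():
        lam = truth.depth_per_bin * scale
        pd = StrandedBinTrack(
            reference="chrSim",
            bin_width=truth.bin_width,
            F=rng.poisson(lam * f).astype(float),
            R=rng.poisson(lam * (1.0 - f)).astype(float),
            units="counts",
        )
        inp = StrandedBinTrack(
            reference="chrSim",
            bin_width=truth.bin_width,
            F=rng.poisson(np.full(truth.n_bins, lam / 2.0)).astype(float),
            R=rng.poisson(np.full(truth.n_bins, lam / 2.0)).astype(float),
            units="counts",
        )
        window_pd = float(pd.F.sum() + pd.R.sum())
        window_inp = float(inp.F.sum() + inp.R.sum())
        out[sample] = ScarSample(
            pulldown=pd,
            input=inp,
            spikein_reads=spikein,
            pulldown_library_total=window_pd,
            input_library_total=window_inp * truth.pulldown_enrichment,
        )
    return out


# ---------------------------------------------------------------------------
# gel lanes


def ladder_lane(
    calib_truth: tuple[float, float] = DEFAULT_GEL_CALIBRATION,
    lane_length: float = 100.0,
    sizes: tuple[int, ...] = LAMBDA_HINDIII_BP,
) -> tuple[np.ndarray, np.ndarray]:
    """Band positions for a sizing ladder under a log-linear calibration.

    Returns (positions, sizes) for the ladder products whose retardation
    factor falls on the lane (Rf in [0, 1]); off-gel bands are dropped.
    """
    slope, intercept = calib_truth
    sizes_arr = np.asarray(sizes, dtype=float)
    rf = (np.log10(sizes_arr) - intercept) / slope
    keep = (rf >= 0.0) & (rf <= 1.0)
    return rf[keep] * lane_length, sizes_arr[keep]


def sim_gel_lane(
    front_bp: float,
    calib_truth: tuple[float, float] = DEFAULT_GEL_CALIBRATION,
    noise_sd: float = 0.0,
    seed: int = 0,
    lane_length: float = 100.0,
    n_samples: int = 1001,
    ramp_width: float = 2.0,
    plateau_width: float = 1.0,
    decay_width: float = 12.0,
    peak_height: float = 1000.0,
    front_fraction: float = 0.05,
) -> LaneProfile:
    """Simulate a 1-D lane of smeared replication products.

    The high-molecular-weight edge ("front") of the product smear sits at the
    migration position implied by the log-linear calibration for ``front_bp``.
    The edge is a linear ramp constructed so that, in the noiseless case, the
    relative-threshold front detector (threshold ``front_fraction`` of the
    peak maximum) crosses exactly at the analytic front position. A ladder
    lane from the same calibration is attached as annotations.
    """
    if front_bp <= 0:
        raise ValueError("front_bp must be positive")
    slope, intercept = calib_truth
    rf_front = (np.log10(front_bp) - intercept) / slope
    p_front = rf_front * lane_length
    if not 0.0 < p_front < lane_length:
        raise ValueError(f"front for {front_bp} bp falls off the lane")

    pos = np.linspace(0.0, lane_length, n_samples)
    # ramp start placed so the front_fraction crossing is exactly at p_front
    p0 = p_front - front_fraction * ramp_width
    p1 = p0 + ramp_width  # top of ramp
    p2 = p1 + plateau_width  # end of flat peak plateau
    intensity = np.zeros_like(pos)
    on_ramp = (pos >= p0) & (pos < p1)
    intensity[on_ramp] = peak_height * (pos[on_ramp] - p0) / ramp_width
    intensity[(pos >= p1) & (pos <= p2)] = peak_height
    tail = pos > p2
    intensity[tail] = peak_height * np.exp(-(((pos[tail] - p2) / decay_width) ** 2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(intensity + rng.normal(0.0, noise_sd, size=pos.size), 0.0, None)
    lad_pos, lad_sizes = ladder_lane(calib_truth, lane_length)
    return LaneProfile(
        position=pos,
        intensity=intensity,
        lane_length=lane_length,
        ladder_positions=lad_pos,
        ladder_sizes=lad_sizes,
    )


# ---------------------------------------------------------------------------
# titrations and mass events


def sim_titration(
    model: str,
    params: tuple[float, float, float, float],
    concentrations: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_mode: str = "absolute",
) -> TitrationCurve:
    """Simulate a titration from the one-site Hill model.

    ``params`` is (Kd, hill, amplitude, baseline); ``model`` selects the
    response semantics: ``one_site_hill`` (percent bound, EMSA-style) or
    ``fp_one_site`` (polarization units, hill fixed at 1 by the caller).

    ``noise_mode='absolute'`` adds Gaussian noise of SD ``noise_sd`` in
    response units; ``'relative'`` scales the SD by the noiseless response at
    each point (``noise_sd`` then is a fraction, e.g. 0.05 for 5%), the usual
    error model for band-intensity measurements.
    """
    if model not in ("one_site_hill", "fp_one_site"):
        raise ValueError(f"unknown model {model!r}")
    if noise_mode not in ("absolute", "relative"):
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    kd, hill, amplitude, baseline = params
    if kd <= 0 or hill <= 0:
        raise ValueError("Kd and hill must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    resp = np.asarray(hill_response(conc, kd, hill, amplitude, baseline), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sd * np.abs(resp) if noise_mode == "relative" else noise_sd
        resp = resp + rng.normal(0.0, 1.0, size=conc.size) * sd
    kind = "percent_bound" if model == "one_site_hill" else "polarization"
    return TitrationCurve(concentration=conc, response=resp, response_kind=kind)


def sim_mass_events(
    components: list[tuple[float, float]],
    sigma_kda: float,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw single-molecule landing-event masses from a Gaussian mixture.

    ``components`` is a list of (mean_kDa, weight); weights must sum to 1.
    """
    if sigma_kda <= 0:
        raise ValueError("sigma must be positive")
    means = np.array([m for m, _ in components], dtype=float)
    weights = np.array([w for _, w in components], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("component weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(means.size, size=n, p=weights)
    return rng.normal(means[comp], sigma_kda)
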