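# Methods

## Strand-partition analysis

The partition score of a 1 kb window is `(F − R)/(F + R)` computed on
normalized, input-corrected forward/reverse signal; replication fork
directionality (RFD) is its negation. The processing order is fixed:
counts-per-million scaling (denominator: total mapped target-genome reads of
the sample across both strands, since one library is strand-split after
sequencing), uniform blur over the 30 neighbouring bins on each side, input
subtraction with negatives clipped to zero, then a coverage filter that
removes windows where **both** strands fall strictly below 0.3 CPM. The
input track receives the same CPM + blur treatment before subtraction;
subtracting an unsmoothed input would mix scales. We read the coverage rule
as "both strands below threshold" rather than "either": the filter's purpose
is to drop jointly low-coverage windows, and an either-strand rule would
delete exactly the one-sided windows that carry the strongest asymmetry.
Windows with `F + R = 0` are undefined and always masked.

Edge windows of the blur are truncated and renormalized by their actual
size — no padding, so no signal is fabricated at track ends. Bins are
0-based half-open: bin *i* covers `[i·w, (i+1)·w)`.

Meta-profiles average the partition across replication initiation zones over
signed offsets; zones oriented by a negative RFD transition are mirrored
*and* sign-flipped so leading-strand bias always appears at positive
offsets. Spike-in normalization divides each sample's target/spike-in read
ratio by the reference sample's ratio; because the exogenous material is
added in constant amount, this compares absolute recovered material across
samples.

## Assembly-sequencing (NAQ) pipeline

Read pairs are assigned to a sample only when **both** mates begin with that
sample's adapter index (default 8 nt, 0 mismatches allowed; the index table
requires pairwise Hamming distance ≥ 2 so single-mismatch assignment can
never be ambiguous). After trimming, pairs are mapped with an exact 31-mer
seed followed by full ungapped verification against the doubled circular
sequence and its reverse complement; a fragment is emitted only when both
mates place at a *unique* best location on the same reference in proper
inward orientation. Unique-best placement plays the role a mapping-quality
cutoff plays with a general-purpose aligner; for error-free reads on
kilobase references with disjoint k-mer content the two are equivalent, and
the test suite pins the mapper against a brute-force all-positions scan.
Fragment-length selection keeps the closed interval 125–160 bp (nucleosomal
core protection). Percent-nicked is `100·n_nicked/(n_nicked +
n_supercoiled)` on length-selected fragments, loading-control fragments
excluded from both terms. Which plasmid is "nicked" is experiment metadata
carried on the reference, never inferred from the data.

## Gel densitometry

Background subtraction removes the running-minimum lower envelope (window:
1/10 of lane length, configurable) and clamps at zero. Size calibration fits
`log10(size_bp) = slope·Rf + intercept` by least squares on ≥ 3 ladder
bands, with the retardation factor Rf defined as migration position over
the full lane span (the reference point of the original instrument software
is not documented; the full span is the natural choice and cancels in
relative comparisons). The product front is the smallest migration position
where intensity first reaches 5% of the lane maximum, linearly interpolated
between samples. The 5% relative threshold is this package's
operationalization of "the upper boundary of the product smear": a relative
threshold makes the front invariant to exposure scaling, and the threshold
is a parameter (`fraction_of_max`) so its sensitivity can be examined
directly — on the synthetic lanes used here, fronts move by under 1% of
lane length as the threshold varies across 2–10%. Maximum replication rate
is the OLS slope of front size against chase time over the earliest three
timepoints (later points saturate as forks terminate), reported in kb/min;
rates are optionally normalized to a designated reference condition.

EMSA percent-bound is `100 − 100·(unbound/unbound_reference)` clamped to
[0, 100], with the no-protein lane as reference.

## Binding fits

The one-site Hill model `y = baseline + amplitude·cʰ/(Kdʰ + cʰ)` is fit by
nonlinear least squares with multi-start initialization: Kd starts at the
concentration nearest half-maximal response plus geometric quartiles of the
concentration range, h starts at {0.5, 1, 2} when free; the lowest residual
sum of squares wins. The fit is covariant under joint rescaling of
concentrations and Kd, so units are free as long as they are consistent.
A flat titration leaves Kd unidentifiable; such fits are flagged
`converged=False` rather than returning an arbitrary number.

Fluorescence-polarization curves use the hyperbolic (h = 1) form by
default, even in regimes where the fitted Kd approaches the labeled-probe
concentration — matching common practice — but a ligand-depletion
(quadratic isotherm) variant is available via `probe_concentration` and is
the better model when Kd ≲ probe; the difference matters for the tightest
binders (single-nM Kd measured against a 10 nM probe).

Mass-photometry histograms are fit as k-component Gaussian mixtures with a
shared standard deviation (EM, deterministic under a fixed seed; k chosen by
the caller from the visible peaks). Peak masses are assigned to
`a·M(CAF-1) + b·M(PCNA trimer)` by exhaustive search over `a ≤ 3, b ≤ 1`
(one clamp per assembly), ties broken toward fewer subunits, with a generous
default tolerance of 50 kDa because instrument-fitted masses of large
assemblies deviate from naive subunit sums (a 430 kDa peak vs a 470 kDa
naive 2:1 sum). Component masses default to 190 kDa (CAF-1 heterotrimer,
matching the free-CAF-1 peak) and 90 kDa (PCNA homotrimer) and are
configurable.

## What the generators emulate — and what they do not

* **References and reads.** Three random-sequence references (two 3 kb
  circular plasmids, one 207 bp linear amplicon) with mutually disjoint
  31-mer content on both strands, so every error-free ≥ 31 nt read maps
  uniquely. Fragments are position-uniform with Normal(145, 10) lengths
  truncated to [50, 250] bp — a stand-in for an MNase digest, since the true
  library length distribution inside the selection window is not known.
  Reads are error-free with constant quality: no sequencing-error or PCR
  duplicate model, and no nucleosome-positioning signal. Passing recovery
  tests therefore demonstrates the pipeline logic (demultiplexing, circular
  mapping, length selection, counting), not robustness to base errors.
* **Stranded tracks.** The injected forward fraction at signed offset *d*
  from the nearest initiation zone is `0.5·(1 + a·sign(d)·exp(−|d|/τ))` — an
  odd-symmetric, exponentially decaying profile; the field's data constrain
  the qualitative shape but not a functional form. τ defaults to 300 bins
  (300 kb), matching the scale over which fork-directionality bias extends
  around mammalian initiation zones and keeping the profile broad relative
  to the ±30-bin blur (a profile narrower than the blur window cannot be
  recovered at full amplitude by construction). Counts are Poisson. The
  input is symmetric and flat; its library total is inflated by a
  pulldown-enrichment factor (default 20) reflecting that pulldown reads
  concentrate on marked nascent chromatin while input reads spread
  genome-wide — without this, input subtraction at matched CPM would
  saturate the partition to ±1. The residual bias from subtraction is
  `a/(enrichment − 1)` ≈ 0.02 at the default. Spike-in material is
  represented as a scalar read count (constant across samples), not
  simulated sequence.
* **Gel lanes.** A product smear whose high-molecular-weight edge is a
  linear ramp placed so the 5% relative-threshold crossing sits exactly at
  the migration position the log-linear calibration implies — making the
  noiseless round trip exact by construction — with a plateau and Gaussian
  tail toward smaller sizes, plus optional additive Gaussian noise. Ladder
  bands are generated from the same calibration (λ/HindIII sizes; off-lane
  bands dropped). No 2-D image structure, lane warping or autoradiography
  nonlinearity.
* **Titrations.** Exact one-site Hill responses plus Gaussian noise, either
  absolute or relative (SD proportional to the response — the usual error
  model for band intensities, and the model used in the noisy-recovery
  suite at 5%).
* **Mass events.** Gaussian-mixture draws; no contrast-to-mass nonlinearity
  or binding-unbinding kinetics.

## Problem sizes and numerical choices

Recovery suites run at desk scale: 20,000 read pairs for the percent-nicked
checks (3× binomial SE ≈ 1.1 points at 50%), 2,000–6,000 bins at a mean
50 reads/bin for the partition checks, 100 seeds for noisy-fit medians,
3,000 events for mixture fits. Generators derive all randomness from
`numpy.random.default_rng(seed)`; every generator is bit-reproducible for a
fixed seed. Degenerate inputs raise rather than return silent defaults:
zero library totals, empty reference sets, ladders with < 3 bands, flat
lanes, titrations with < 5 points, inverted length windows.

## Known limitations

The mapper assumes error-free reads (exact seed and verification); the blur
and filter defaults are tuned to 1 kb bins; the front detector presumes a
single dominant product peak per lane; the Gaussian-mixture fitter requires
the caller to choose k; and the null-profile statistical test must account
for blur-induced autocorrelation (the suite subsamples at the blur width
before computing standard errors).
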