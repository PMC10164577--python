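# strandfold

Quantitative analysis of replication-coupled chromatin assembly, built around
four measurement families and the synthetic-data generators that validate
them by parameter recovery:

* **Strand-partition sequencing (`strandfold.scarseq`).** Strand-resolved
  sequencing of nascent chromatin yields forward/reverse read counts per
  genomic window. The partition score per 1 kb bin,
  `partition = (F − R)/(F + R)`, measures whether a histone mark segregates
  to the nascent forward (`> 0`) or reverse (`< 0`) strand; replication fork
  directionality is the sign-reversed ratio, `RFD = (R − F)/(F + R)`. The
  pipeline applies CPM scaling, a uniform blur over ±30 bins, input
  subtraction with zero clipping, joint low-coverage filtering (< 0.3 CPM on
  both strands), meta-profiles around oriented replication initiation zones,
  and spike-in normalization of library totals against an exogenous genome.
* **Plasmid nucleosome-assembly sequencing (`strandfold.naqseq`).** An assay
  that mixes a nicked plasmid (where the PCNA clamp loads) with a supercoiled
  competitor, assembles nucleosomes, MNase-digests and sequences the
  protected fragments. The pipeline demultiplexes by the adapter index on
  both read ends, trims, maps pairs to the circular references with an
  exact-seed unique-best mapper, selects nucleosomal fragment lengths
  (125–160 bp) and reports the percent of fragments on the nicked plasmid —
  the clamp-dependent assembly readout.
* **Gel densitometry (`strandfold.gelquant`).** 1-D lane profiles:
  minimum-profile background subtraction, log-linear size calibration
  `log10(bp) = a·Rf + b` against a λ/HindIII ladder, detection of the
  high-molecular-weight front of the leading-strand product smear, maximum
  replication rates from a 3-point linear fit of front size vs chase time,
  EMSA percent-bound, and full-length-product fractions.
* **Equilibrium binding and mass photometry (`strandfold.bindfit`).**
  One-site binding with Hill slope,
  `y = baseline + amplitude·cʰ/(Kdʰ + cʰ)`, fit by multi-start nonlinear
  least squares; simple one-site fluorescence-polarization fits (with an
  optional ligand-depletion variant for tight binders); contrast-to-mass
  calibration; Gaussian-mixture fits of mass histograms; and assignment of
  peak masses to CAF-1 : PCNA-trimer stoichiometries.

Every generator in `strandfold.synthgen` is seeded and bit-reproducible, so
each stage of each pipeline is tested by recovering known ground truth.

## Worked example

```python
import numpy as np
from strandfold import bindfit, gelquant, naqseq, scarseq, synthgen
from strandfold.core import InitiationZone

# 1. Percent-nicked from 20,000 simulated read pairs at p_nicked = 0.5
refs = synthgen.gen_references(seed=1)
truth = synthgen.NaqSimTruth(p_nicked=0.5, n_pairs=20000, seed=42)
pairs = synthgen.sim_naq_readpairs(truth, refs)
table = naqseq.IndexTable({"S": "ACGTACGT"})
print(naqseq.run_naq_pipeline(pairs, table, refs)["S"].percent_nicked)
# 49.47416552354824

# 2. Max replication rate from three chase timepoints advancing at 1.09 kb/min
fronts, calib = {}, None
for t in (4.0, 5.0, 6.0):
    lane = synthgen.sim_gel_lane(front_bp=1090.0 * t)
    calib = calib or gelquant.fit_ladder(lane.ladder_positions, lane.ladder_sizes,
                                         lane.lane_length)
    fronts[t] = gelquant.position_to_bp(calib, gelquant.detect_front(lane))
print(gelquant.max_replication_rate(fronts).rate_kb_per_min)
# 1.0900000000000005

# 3. Kd from a noiseless percent-bound titration generated at 0.33 uM
conc = np.geomspace(0.01, 5.0, 10)
curve = synthgen.sim_titration("one_site_hill", (0.33, 1.0, 100.0, 0.0), conc)
print(bindfit.fit_one_site_hill(curve).kd)
# 0.33000000000000007

# 4. Injected strand asymmetry (a = 0.4) recovered at the meta-profile extremum
st = synthgen.ScarSimTruth(n_bins=6000, iz_positions=(1000, 3000, 5000),
                           partition_amplitude=0.4, seed=21)
s = synthgen.sim_scar_samples(st)["sample"]
ptrack = scarseq.compute_partition(s.pulldown, s.input,
                                   pulldown_total=s.pulldown_library_total,
                                   input_total=s.input_library_total)
izs = [InitiationZone("chrSim", c) for c in (1000, 3000, 5000)]
print(scarseq.iz_metaprofile(ptrack, izs, 600).extremum())
# -0.387  (odd-symmetric profile; the magnitude is the recovered amplitude)
```

The percent-nicked lands within binomial sampling error of the injected 50%,
the gel pipeline returns the construction rate exactly on noiseless lanes,
the refit Kd matches the generating value, and the meta-profile extremum
recovers the injected partition amplitude to ±0.05.

A command-line interface mirrors the library:
`strandfold simulate {naq|scar|gel|titration|mass}`, `strandfold scar`,
`strandfold naq`, `strandfold gel {calibrate|rate|emsa}` and
`strandfold fit {hill|fp|mass}`.

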