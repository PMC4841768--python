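# Methods

This note documents the models, parameter choices and numerical decisions
behind each `ptmkit` stage, what the synthetic generators do and do not
emulate, and the package's known limitations.

## PTM proteoform stoichiometry (`ptm_quant`)

**Model.** A peptide's modification states (proteoforms) are resolved in
MS1 either by mass (each HexNAc adds 203.079373 Da, each phosphate
79.966331 Da, monoisotopic) or, for positional isomers of identical mass,
by chromatography. The theoretical m/z of a proteoform at charge *z* is
(Σ residue monoisotopic masses + water 18.010565 + Σ modification deltas +
*z* × 1.007276466) / *z*; residue masses come from pyteomics. For each
proteoform an XIC is built per scan by summing centroid intensities within
a relative tolerance (default 10 ppm) of the target m/z, inside a
caller-supplied retention-time window. Windows are mandatory rather than
inferred: isobaric positional isomers are only distinguishable by elution
time, so the package refuses isobaric isoforms whose windows overlap
instead of silently splitting their signal.

**Integration.** Vendor chromatographic peak-area algorithms are
proprietary; the package integrates the baseline-subtracted trapezoid,
with baseline equal to the minimum intensity in the window and the
integrand clipped at zero. For well-formed peaks this agrees with a dense
Riemann sum to well under 0.1% (tested), and it is shape-agnostic, so the
Gaussian elution assumption of the generator is not load-bearing.

**Stoichiometry and LOQ.** Fractions are areas over the summed area; they
always sum to 1. Charge states of the same isoform are summed before
normalisation. Rows whose fraction falls below `loq_fraction` (default
0.01, i.e. 1% of total) are flagged below the limit of quantitation but
never dropped — a flagged row still participates in the normalisation, so
the reported composition remains a true partition of signal. The 1%
default is a package choice; the concept mirrors compositions in which a
doubly modified form is reported only as "below LOQ". When replicate runs
are quantified separately, `mean_stoichiometry` averages per-replicate
fractions (rather than pooling areas), matching how mean percentages over
n replicates are usually reported.

**Reference compositions.** `ptmkit.reference` carries two TAD
compositions used by tests and the acceptance script. Wild type:
unmodified 33.2%, GlcNAc-S248 44.1%, phospho-S253 10.9%, with the
remaining 11.8% assigned to the co-modified GlcNAc-S248 + phospho-S253
form, completing the four main TAD populations. S248A mutant: only the
phospho-S253 slice (18.7%) is externally anchored; the remainder is split
unmodified 69.5% / GlcNAc-T258 11.8% as this package's own choice — the
recovery checks only score the anchored slices, so the split is a
modelling convenience, not a claim. The TAD peptide itself is represented
by a synthetic stand-in 16-mer with S/S/T at the relative offsets of
S248/S253/T258; every computation depends only on residue composition and
site chemistry, not on the true sequence.

## AP-MS interactome scoring (`interactome`)

**Specificity.** Per protein, *r* = log2(mean FLAG intensity / mean HA
intensity); the ratio of replicate means is the default ("average ratio"
is ambiguous between ratio-of-means and mean-of-ratios, so a
`mode="mean_of_ratios"` switch is provided). Ratios are centred on the
global median — enforcing the invariant that the median normalised ratio
is exactly zero — and a protein is called specific when its centred ratio
is at least `sd_threshold` (default 2) sample standard deviations above
the mean of the centred ratios. The call is one-sided: proteins depleted
in FLAG purifications are not "interactors". For the stricter
two-line rule, `specific_interactors` requires the 2-SD call in the
FLAG-WT and FLAG-S248A lines independently.

**Missing values.** A protein absent from every HA sample would have an
infinite ratio; it instead receives a floor equal to the 1st percentile of
observed HA intensities — standard AP-MS practice that keeps bait-specific
preys scoreable. Proteins absent from every FLAG sample are not scored at
all (missing, not zero).

**Differential interaction.** The statistic is the log2 ratio-of-ratios
(S248A/HA over WT/HA), in which the HA term cancels; after median
centring, the z-score uses the sample SD over scored proteins (the z
denominator is otherwise undefined). |z| > 1.5 classifies a protein as
S248A- or WT-preferring. Fold change is reported alongside rather than
used as a second gate, because the mapping between a fold threshold and a
z threshold is dataset-dependent. Under a pure null the |z| > 1.5 call
rate is 2(1 − Φ(1.5)) ≈ 13.4%, which the test suite verifies on a
1000-protein no-effect simulation.

**Rollup and targeted quantitation.** Protein intensity is the sum of
non-homologous peptide intensities; homologous peptides (shared across
proteins) count for no protein, and bait peptides overlapping the
modified-region interval are excluded so the bait's own modification state
cannot bias its quantitation. Targeted mode picks each listed protein's
two most intense non-homologous peptides, computes per-replicate
log2(FLAG-S248A / FLAG-WT) of their summed intensity, and reports the
median across replicates.

## ChIP-seq signal (`chip_signal`)

**Tags and density.** A tag is the 5′ position of an aligned fragment;
uniqueness is (chromosome, position, strand), both strands counted
identically, no fragment shift by default (a `--shift` option exists in
the CLI). After deduplication, exactly *n* tags are sampled uniformly
without replacement (seeded). The density of bin [s, s+B) is the count of
tags in [s − F, s + B + F) — the bin dilated by the flank F (default 75 bp
around 20 bp bins, a 170 bp window); an alternative "within F of the bin
centre" mode is available. Counts are scaled by `normalize_to`/total
(default 10⁷) so libraries are comparable; the toy-genome tests use
smaller values of the same parameter. Input subtraction is element-wise on
identically binned, identically normalised tracks, and negative values are
retained.

**Peak calling and overlap.** The caller is deliberately simple plumbing —
maximal runs of bins at or above a threshold, merged across gaps shorter
than `merge_gap`, filtered by `min_width`; externally called peak BEDs are
accepted everywhere. When no threshold is given, mean + 5 SD of the track
is used: on a mostly-background, input-subtracted track (mean ≈ 0) this
sits far above counting noise yet well below the planted enrichment.
Overlap partitioning uses half-open intervals and any-overlap (≥ 1 bp);
an all-pairs brute-force oracle verifies it exactly on random sets.
"Present in both replicates" is expressed as the shared set of a
replicate-pair overlap.

**Motif scanning.** PWMs are log2-odds against an explicit background
(uniform by default), built from count matrices (JASPAR text via
Bio.motifs) or sharp consensus matrices. Every window on both strands is
scored (reverse strand on the reverse complement); windows containing N
are skipped. The default hit threshold is 80% of the maximum achievable
score — the matching threshold behind published motif-fraction figures is
tool-specific, so it is exposed as a parameter; the exactness test uses
90% of max, which a sharp consensus matrix only reaches without
mismatches. The motif fraction of a peak set is the share of peaks with at
least one hit.

## Expression filters (`expression`)

The paired t-test runs on log2 values (the scale is a package choice;
linear-scale vendor pipelines differ), as a one-sample two-sided t on
per-pair differences, and fold change is the geometric mean of per-pair
ratios (arithmetic mean behind a flag). Classification follows the joint
gate: up iff FC ≥ 1.5 and p < 0.05, down for the reciprocal. No
multiple-testing correction is applied by default, mirroring a raw-p gate;
BH q-values are an optional column. Zero-variance differences with a
nonzero mean are reported as the p → 0 limit with a `degenerate` flag;
all-identical pairs are unchanged with p = 1. The 2^−ΔCq helper is exact
arithmetic and satisfies ΔCq reciprocity.

## Synthetic data (`synthetic`)

Each generator is bit-reproducible for a fixed seed and returns ground
truth sufficient to score recovery.

* `gen_ms1_run`: Gaussian elution profiles (sd 0.1 min) at theoretical
  m/z, scan spacing 0.02 min, centroid m/z jitter uniform ±3 ppm (inside
  the 10 ppm window), multiplicative intensity noise with the stated CV
  (default 1%), Poisson background centroids kept ≥ 50 ppm from all
  targets. Truth windows are ±6 elution sd: at ±5 sd, window-edge
  truncation and baseline subtraction would perturb noiseless recovery at
  the ~10⁻⁵ level, while ±6 sd keeps the round trip below 10⁻⁶. Real
  peaks tail and carry isotope envelopes; neither matters to a
  shape-agnostic integrator reading the monoisotopic trace.
* `gen_apms`: log-normal intensities (base abundance 2^N(20, 2), sample
  noise 0.5 in log2 units), two replicates per line by default (duplicate
  co-IPs), spiked interactors at a stated fold over HA with an optional
  differential fold between FLAG lines, 5% missing values (never on
  spikes, so planted effects stay scoreable). Peptide tables split protein
  intensity by Dirichlet shares, plus flagged homologous peptides whose
  extra intensity must not reach protein level — which the rollup tests
  exploit. With duplicate replicates and 0.5 log2 noise, a 4-fold
  differential spike has a miss probability of roughly 5%; recovery tests
  therefore assert the recovery rate over a fixed panel of ten seeds
  rather than a single draw.
* `gen_chip`: uniform background tags, enriched regions at a stated
  rate multiple (default 10× over 20 regions of 300 bp on 2 × 100 kb),
  uniform input, a consensus motif embedded in a stated fraction of
  regions on a random strand. No mappability, GC bias or fragment-length
  model — sufficient for density/subtraction/caller semantics, not for
  benchmarking real peak callers.
* `gen_expression`: planted up/down genes at a stated fold, paired
  structure induced by a shared per-gene, per-pair batch effect
  (sd 0.25 log2) plus residual noise (default 0.25 log2), defaults shaped
  like a genome-scale array experiment (12 000 genes, 320 up / 344 down,
  three pairs).

Passing tests on these generators demonstrates correctness of the
computations and calibration of the statistics under the stated noise
models; they do not demonstrate robustness to real-data pathologies
(chimeric spectra, ratio compression, mapping artefacts, batch effects
beyond the pairing structure).

## Problem sizes

The test suite and acceptance script run at desk scale by design: MS1 runs
of ~400 scans, AP-MS tables of 200–1000 proteins, toy genomes of 2 × 100 kb
with 20 000 tags, and expression matrices of 2000–12 000 genes. These sizes
keep every stage's statistical behaviour observable (null calibrations,
recovery rates) while the full run completes in seconds. Dataset-scale
headline counts from genome-wide experiments depend on the underlying raw
data volumes and are out of scope for the synthetic checks.

## Known limitations

* No isotope-envelope or charge-state-deconvolution model; quantitation
  reads the monoisotopic trace the caller specifies.
* The missing-value floor (1st percentile of HA) is a pragmatic rule; very
  sparse HA channels make specificity scores sensitive to it.
* The peak caller is a threshold/merge rule, not a statistical model; use
  external callers for real data and import their BED output.
* PWM scanning assumes independence between motif positions, as PWMs do.
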