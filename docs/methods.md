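# Methods

This note documents the models, conventions and design choices behind
`mutaccum`, and what its synthetic-data generator does and does not
emulate.

## Experimental design being modeled

The package targets mutation-accumulation (MA) experiments in bacteria:
replicate lines founded from a single clone are propagated by streaking a
single colony to a fresh plate once per incubation round ("bottleneck"),
so that each passage restarts the population from one cell and selection
is largely powerless against the mutations that fix. The reference design
is 20 lines per temperature group at 25, 28 and 37 °C, incubated 72, 48
and 24 h respectively (chosen so colonies reach similar sizes, ~2²⁷
cells), through 30 bottlenecks, with endpoint whole-genome sequencing of
each line against the ancestor's assembled genome.

## Generation accounting

A colony grown from one cell to $N$ cells has undergone $\log_2 N$
doublings, so generations per passage $= \log_2(\text{colony cells})$
(27.0 for $2^{27}$ cells). Colony sizes are measured at a subset of
bottlenecks (default 1, 11, 21) and each measurement is applied to a
window of passages (1–10, 11–20, 21–30 for the default 30-bottleneck
design); the per-line total is the window-weighted sum, ~810 generations
at the reference size. Generations are kept real-valued throughout; the
"27" is a display convention. Growth rate is generations per hour,
$\log_2(N)/\text{incubation hours}$.

## Mutation-rate estimator

$\mu = m/(G \cdot L)$ per line, with $m$ the retained mutation count
(substitutions plus 1–4 bp indels), $G$ the line's total generations and
$L$ the denominator site count. **$L$ defaults to the genome length**; a
depth-qualified ("callable sites") denominator can be substituted via the
pipeline configuration, since published analyses are often ambiguous on
this point. Per-category rates use the same $G$ and $L$, so category
rates add up exactly to the rate of their union. Group summaries report
mean ± 95% CL with CL = SEM × t₀.₉₇₅(df = n−1).

Calls with read depth below 20× are excluded (strict less-than; a DP=20
call is retained). Calls with no depth value are conservatively excluded
but tallied separately, and can be kept by configuration. An optional
ancestor VCF subtracts variants present before the experiment.

## Spectrum classification

- **Six types.** Substitutions are strand-collapsed into A:T>G:C,
  G:C>A:T (transitions) and A:T>C:G, G:C>T:A, A:T>T:A, G:C>C:G
  (transversions); a mutation and its reverse complement share a label.
- **Coding consequence.** For a site inside a CDS the codon is
  reconstructed on the gene's sense strand (minus-strand genes
  reverse-complemented), mutated, and translated with NCBI table 11.
  Initiator codons are translated by the plain table (GTG → Val), which
  only affects the first codon of a gene and keeps the synonymous /
  nonsynonymous call purely sequence-based.
- **Conservation.** Nonsynonymous changes with BLOSUM62 score ≥ 0 are
  conservative. BLOSUM62 has no meaningful stop row, so any change
  creating or destroying a stop codon is counted nonsynonymous and
  non-conservative. The matrix comes from Biopython's
  `substitution_matrices`; the unit tests pin the specific scores the
  classifier depends on so results cannot drift silently.
- **Overlapping genes** are classified against the gene first in
  coordinate order, with a warning (configurable to reject).
- **Indels.** Direction is gain/loss by net length change (1–4 bp); 1 bp
  events carry an A:T or G:C pair label from the inserted/deleted base.
  An event is "in a run" when a homopolymer of ≥ `run_min_len`
  (default 3, configurable — the literature rarely defines "runs")
  matching the indel base lies at or adjacent to the site (1 bp), or the
  site sits inside any such run (2–4 bp). Indel region is assigned by the
  leftmost affected base; frameshift-consequence analysis is out of
  scope.

## Monte Carlo placement null

The null asks what spectrum ratios would look like if the observed
mutations were placed at random. Per trial, each six-type class's
observed count is placed uniformly **without replacement** on the sites
whose strand-collapsed pair matches the class source pair (A/T for
A:T>·); every placement is classified, and coding/noncoding,
nonsynonymous/synonymous and conservative/non-conservative tallies are
accumulated over `n_trials` (default 1000). Counts are fixed exactly per
trial — the strongest reading of conditioning on the observed numbers —
rather than resampled multinomially. Observed ratios are tested two
ways: a Pearson χ² against the trial-mean proportions (df = 1 per
contrast) and the empirical upper-tail fraction of trials at least as
coding-biased as observed.

Respecting base identity matters: composition-blind placement would bias
coding/noncoding expectations whenever coding DNA is GC-shifted relative
to noncoding. A `composition_blind` switch exists for sensitivity
analysis; in that mode only the coding/noncoding contrast is defined,
because the alternate base is unconstrained on non-matching sites.

Classification inside the MC loop uses a precomputed per-site effect
table (site × alt-base → noncoding/synonymous/conservative/
non-conservative), verified against the call-level classifier in the test
suite; 1000 trials of 10⁴ mutations run in seconds.

## Group comparisons

Welch's unequal-variance t with Welch–Satterthwaite df is the default
flavor: in this kind of study the printed fractional df for rate
contrasts (e.g. 29, 32, 33 from two n=20 groups) indicate unequal
variances, while a pooled option is provided for df=38-style analyses.
Tests are one-tailed with the default alternative "warmer group has the
higher value"; direction is configurable. When both samples are constant
and equal the test is degenerate and p = 0.5 by convention.
Benjamini–Hochberg step-up correction (via statsmodels, checked against
a brute-force implementation of the definition) is applied within each
category — each "data set" is its own family of 3 contrasts. Letters are
assigned by the insert-and-absorb procedure; intransitive significance
patterns produce multi-letter labels and a warning.

## Metabolic normalization

Headspace O₂ volume fractions measured before and after incubation are
converted to moles by the ideal gas law,
$n = PV\,\Delta f / (RT)$ with $R = 0.0820574$ L·atm·K⁻¹·mol⁻¹, at the
assay's incubation temperature and 1 atm (instrument-specific
calibrations are outside scope; both constants are explicit parameters).
A colony of $N$ cells represents $N - 1$ divisions, so
OUR = mol O₂ / (colonies × (cells per colony − 1)). Assays flagged as
QC-discarded (e.g. poorly isolated colonies) are excluded before
averaging. Dividing $\mu$ (per nt per generation) by OUR (mol per
division) gives mutations · nt⁻¹ · mol O₂⁻¹, using the identification
one generation ≡ one division per cell.

## Synthetic-data generator

The generator defines the conditions under which the package is tested.

- **Genome.** Default 50.77% GC and 85% coding, emulating a typical
  enterobacterial chromosome at configurable scale. Genes are tiled
  non-overlapping with alternating strands (so reverse-complement
  handling is always exercised), each a valid CDS: ATG start, stop
  codon, no internal stops, length divisible by 3. Because rejecting
  internal stops (AT-rich codons) would push coding GC up, the coding
  base composition is pre-compensated analytically so realized GC stays
  within ±1 point of target. Requested homopolymer runs are planted in
  intergenic sequence. Genes wrapping a circular origin are never
  emitted (and the parser rejects them); multi-contig genomes are out of
  scope.
- **Mutation supply.** Per line, each six-type class contributes a
  Poisson count with mean rate × effective eligible sites × G, placed
  uniformly over eligible sites (weighted by `coding_bias`, default 1 =
  unbiased) without replacement within a line — recurrent mutation at
  one site over a 30-passage line is negligible and skipping collisions
  avoids ref/alt bookkeeping conflicts. Indels are placed with
  `in_run_multiplier` (default 8) weighting inside runs; insertions in a
  run extend the run's base. No selection is modeled (MA designs are
  chosen precisely because selection is negligible) and no lethal-class
  rejection is applied.
- **Default rates** are synthetic but sized like a mismatch-repair
  deficient (mutS) mutator: total ~8.1 × 10⁻⁹ per nt per generation at
  37 °C (≈30 mutations per line at 4.6 Mb × 810 generations), 0.63× and
  0.62× of that at 25 and 28 °C, transitions 87% of BPSs at 25 °C and
  96% at 28/37 °C with G:C>A:T slightly exceeding A:T>G:C, and indels at
  ~1/5 of the BPS rate with gains more frequent than losses. The indel
  base rates are normalized by the expected run inflation
  (1 + 7 × 0.15625 on an iid genome) so the in-run multiplier
  concentrates rather than inflates the indel supply.
- **Colony sizes** are lognormal around 2²⁷ cells with CV 0.1 (single
  colonies picked at matched growth phase vary little). The simulation's
  true generation count is the same window-weighted log₂ sum the
  estimator uses, so rate-recovery tests are self-consistent by
  construction — they test estimator calibration, not growth modeling.
- **Assays.** Each simulated plate draws a Poisson colony census
  (mean 150) and lognormal cells per colony, consumes
  truth × divisions × lognormal noise (CV default 0.08) mol O₂, and
  reports headspace fractions through the same ideal-gas relation the
  analysis inverts; noiseless assays therefore round-trip exactly. The
  rig constants (0.5 L headspace, 0.2095 starting O₂ fraction, 1 atm)
  are fixed module constants. Default OUR truths (4.80, 4.95, 7.50 ×
  10⁻¹⁵ mol/division at 25/28/37 °C) are sized so mutations-per-mol-O₂
  lands near 10⁶ per nt per mol.
- **Depth** is Poisson around the design mean (default 163×).

What the generator does **not** emulate: read-level errors (no FASTQ, no
miscalls — depth is attached, not simulated from reads), structural
variants, selection or fitness effects, context-dependent mutation
beyond homopolymer indel hotspots, and expression-stratified mutation
bias. Passing tests therefore certify the statistical pipeline —
estimator calibration, classifier correctness, null-model conditioning —
not robustness to upstream variant-calling artifacts.

## Numerical and interface conventions

- External coordinates are 1-based inclusive (FASTA/GFF3/VCF); the
  0-based conversion is confined to the I/O module. Indels are stored
  normalized (inserted/deleted bases plus position) and re-anchored on
  VCF output.
- Every stochastic operation takes an explicit seed and is a pure
  function of (inputs, seed); the pipeline derives module seeds from one
  run seed.
- Without-replacement sampling uses rejection sampling when the draw is
  small relative to the pool and permutation otherwise; weighted draws
  use Gumbel top-k (Plackett–Luce), equivalent to sequential weighted
  sampling without replacement.
- χ² tests require strictly positive expected proportions and use
  df = categories − 1; empty categories are a caller error, not silently
  dropped.

## Problem sizes in the shipped checks

The test suite runs on genomes of 20–48 kb with rates scaled up so
per-line counts match the real design's ~10–40 mutations; calibration
checks use 200 replicate experiments of 20 lines (rate-estimator
coverage), 2000 simulated category-sets (null false-positive rate), 400
replicates (1.6× power), and 1000 MC trials of 10⁴ mutations (analytic
limit). `scripts/acceptance.py` simulates the full 3 × 20-line study on
a 2 Mb genome — the package's chosen compromise between fidelity to the
4.6 Mb reference design and quick, exactly reproducible runs.

## Known limitations

- Single-contig genomes only; origin-spanning genes rejected.
- The MC null covers substitutions only (indel placement nulls are not
  defined here).
- Growth-rate and metabolic measurements share the simulator's colony
  model; instrument error models are not included.
- The per-site effect table resolves overlapping genes by coordinate
  order, matching the classifier, but overlap-aware dual annotation is
  not attempted.
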