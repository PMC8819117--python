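# Methods

## Coverage model

A cell's gene-body coverage profile is the read depth observed at 100
percentile positions of each transcript, summed over transcripts and scaled
to unit maximum. Percentile k of a transcript with spliced length L is the
genomic coordinate of spliced nucleotide ⌊kL/100⌋, walked 5'→3' in transcript
orientation (reverse genomic order on the minus strand). All coordinates are
0-based half-open (the BED convention) and conversions happen only at I/O
boundaries. The mapping is deterministic and total for L ≥ 100; transcripts
shorter than 100 nt are excluded (below that, percentile sampling
double-counts bases), as are transcripts matching rRNA/tRNA name patterns
(defaults: `rRNA`, `tRNA`, `Mt_rRNA`, `Mt_tRNA`), since their extreme
expression would dominate every cell's profile.

Depth is per-base: an alignment covers a percentile coordinate when one of
its reference-consuming CIGAR segments (M/=/X) spans it; N (splice) and D
(deletion) gaps do not cover. Default alignment filters are primary records
only, not QC-fail, not duplicate-flagged, MAPQ ≥ 0; all are configurable.
UMI deduplication is available but off by default. Reads overlapping several
transcripts contribute to each — the profile is a shape, not a
quantification, so no assignment disambiguation is done. A cell with no
passing reads gets an all-zero profile (never NaN) and is flagged; flagged
cells bypass clustering and are labeled skewed with reason `zero_coverage`,
because a cell with no coverage signal is by definition not typical.

Implementation: percentile coordinates of all transcripts are pooled into one
sorted array per chromosome, so each alignment is processed with two binary
searches per CIGAR block in a single streaming pass — no pileup over the full
genome, no index required, and runtime is linear in read count and hence in
cell count for fixed per-cell depth. 10x-style barcoded BAMs are
demultiplexed in the same pass by the CB tag (tag name and `-1`-suffix policy
configurable) without materializing per-cell files, though a materializing
mode exists for workflow parity.

## Bin reduction

The cells × 100 matrix is mean-reduced to cells × 10: entry (i, j) is the
arithmetic mean of positions 10j..10j+9. Values are not re-normalized after
reduction; re-scaling each row back to unit maximum would distort the
relative amplitudes that separate profile shapes. Reduction is linear and
preserves row means, which the tests assert.

## Trimmed Gaussian classification

Cells are classified by fitting one multivariate Gaussian to the reduced
profiles while trimming a fraction α: maximize the trimmed log-likelihood
Σ_{i∈H} log φ(x_i; μ, Σ) over retained sets H of size h = n − ⌊nα⌋.
Estimation is by concentration steps: given (μ, Σ), retain the h densest
points, refit moments on them, repeat until the retained set is stable. Each
step cannot decrease the objective, so every start converges; the code
asserts the monotone trace. Ties in density are broken by row index for
determinism.

Starts: (1) full-sample moments — deterministic, so single-start runs are
reproducible without a seed; (2) the moments of the h points nearest the
MAD-scaled coordinate-wise median — a robust deterministic start that is
immune to far contamination; (3) `n_starts − 1` random elemental starts
(moments of d+1 random points; default `n_starts` = 20, `max_iter` = 100,
objective tolerance 1e−8). The scatter estimate is regularized as
Σ + ε·tr(Σ)/d·I with ε = 1e−6 plus an absolute eigenvalue floor of 1e−12:
coverage bins are strongly correlated and near-singular scatters would
otherwise break the density evaluation. The fit requires h ≥ d + 1 so the
scatter is estimable on the retained set.

## CTL curve and automatic α

One fit per grid α (default 0.01–0.45 in steps of 0.01; trimming beyond 50%
would invert the majority/minority semantics of "typical") yields the
classification trimmed likelihood curve: mean trimmed log-likelihood
(objective / h) versus α. Each α's fit is additionally warm-started from its
neighbor's solution, and backward/forward warm-start sweeps run until no fit
improves: a good solution found at any α rescues neighboring α stuck in
local optima, and at convergence the chaining guarantees the curve is
non-decreasing in α (asserted on every curve). The sweeps add little cost —
warm starts converge in a few concentration steps.

Selection: the gain of each grid interval is expressed as the fraction of the
curve's total range gained per grid step; because ⌊nα⌋ is integer, adjacent
intervals can trim unequal numbers of points, so each gain is rescaled to the
mean per-step trimming increment before thresholding (at n a multiple of the
grid step's reciprocal this rescaling is exactly 1). The selected α is the
smallest grid point from which every subsequent normalized gain stays below
`flatness_tol` (default 0.02): below the contamination fraction each step
still expels genuine outliers and gains are large; beyond it the curve
settles into the slow drift of trimming a clean Gaussian's own tail. If no
point qualifies the grid minimum is returned with a low-confidence flag
rather than an error. The flatness tolerance is an exposed tunable, not a
hidden constant: automatic and manual α can legitimately disagree, and the
CTL-curve export (TSV and optional plot with the selected α marked) is
provided so the user can inspect the choice. The heuristic is validated by
parameter recovery on simulations — selected α within one grid step of the
planted fraction and trimmed-vs-planted Jaccard ≥ 0.9 in ≥ 18/20 seeded
replicates at contamination 0.05/0.1/0.2 — not by fidelity to any particular
elbow convention.

## Synthetic data

The generator emulates the coverage-profile families of the major scRNA-seq
chemistries with scaled beta-density shapes on the unit gene body, chosen for
smooth two-parameter control of peak location and concentration:
`five_prime_tag` (mode 0.08, concentration 8), `three_prime_tag` (mode 0.92),
`full_length` (concentration 2.6, max/min ≤ 2 across the mid-body). A typical
cell is the archetype curve plus per-bin Gaussian noise (default sd 0.05),
clipped at 0 and re-normalized. Skewed cells are declared multiplicative
distortions, not claims about biology: `opposite_end_bias` (the mirrored
curve — e.g. 3' bias under a 5'-tag protocol), `mid_body_dropout` (a Gaussian
notch of depth 0.9, width 0.15 at mid-body), `degradation_3prime` (an
exponential ramp `exp(−4(1−x))` concentrating signal 3'-ward). Defaults are
200 cells, 10% skewed, one seeded generator per call.

What the simulations do not model: per-transcript heterogeneity and
transcript-length effects, sequencing-error and mapping artifacts, UMI
duplication structure, correlated (non-independent) bin noise, and
contamination that is *not* well separated from the typical profile. Passing
recovery tests therefore show that the estimator and the α heuristic behave
correctly in the separable regime they define, not that every real dataset's
contamination fraction is identifiable; on real data the CTL curve should be
inspected, and the manual-α mode exists precisely for ambiguous curves.

The read-level generator writes miniature BED12 models (plain, spliced, and
minus-strand transcripts), sorted+indexed BAMs whose read placement follows a
stated positional density (uniform or end-concentrated), optionally barcoded,
and a truth table of expected depth counts computed by brute-force per-base
pileup — the independent oracle for the streaming engine.

## Numerical and design choices

- Trimmed-fit oracle equivalence is tested by exhaustive subset enumeration
  on n ≤ 10, d = 2 instances (objective agreement within 1e−9, identical
  retained sets).
- Problem sizes in the test and acceptance harnesses — 200-cell simulations,
  20 replicates per contamination level, 60-cell toy BAM batches for the
  runtime-scaling fit — keep the full suite around a minute while leaving the
  statistical assertions well-powered.
- Row order of the coverage matrix is input order; parallel per-cell
  computation merges by cell id, so results are identical for any worker
  count. Duplicate cell ids are a hard error everywhere.
- Output artifacts are plain TSV (including the annotation table, rather than
  a language-specific serialized object) so downstream toolkits in any
  language can consume them; id lists are one id per line, and ids containing
  whitespace are rejected at write time.
- The general K > 1 trimmed clustering problem (eigenvalue-ratio constraints
  across clusters) is out of scope: the classifier is the K = 1 special case,
  where the only constraint needed is the scatter regularization above.

## Known limitations

- The α grid floor (0.01) means contamination below 1% is not separable from
  the no-contamination case; the flat-curve answer is the grid minimum.
- Coverage profiles are aggregated over all transcripts of the gene model;
  one transcript per gene vs all isoforms is delegated to the supplied BED
  (each record contributes one profile).
- The linear-runtime guarantee is per fixed per-cell read depth; cells with
  wildly different read counts scale with total reads, not cell count.
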