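# Methods

## Model

The score rests on a first-order consequence of single-causal-variant
association: if the index SNP tags the causal signal and LD estimates are
correct, the expected chi-square statistic of a member SNP scales with its r²
to the index, so on the −log₁₀P scale the expected significance of a member
is approximated by the origin-anchored line `p̂ = r² · p_index`. This is a
deliberate simplification — the exact relationship holds for non-centrality
parameters, not −log₁₀P — but it is monotone, parameter-free, anchored in
the observed index statistic, and deviations large enough to matter for
quality control dwarf the approximation error.

Per member SNP the residual `e = p − p̂` and ratio `S = e/p̂` are computed;
`loss = max(0, −S)` lies in [0, 1] because observed −log₁₀P is non-negative.
Gains (S > 0) are excluded from all outlier logic: under a single causal
variant a large gain indicates a second independent signal, not bad data, and
is surfaced separately as a secondary-signal advisory (default trigger:
S > 1 at r² > 0.4) with `rescore_with_index` as the follow-up tool.

## Drop threshold and distances

Empirically, low-LD SNPs scatter widely around the line, so loss alone
over-flags them. The outlier boundary is therefore linear in the (r², loss)
plane: loss 1.0 at r² = 0.4 decreasing to 0.4 at r² = 1.0 (`loss = 1.4 − r²`
by default), with SNPs at r² ≤ 0.4 never eligible. Both boundary losses and
the floor are configurable (`DropThreshold`); strict inequalities are used
throughout, so a point exactly on the line or exactly at the floor is not an
outlier.

Outlier severity is the perpendicular Euclidean distance from (r², loss) to
the boundary line, `|loss − thr(r²)|/√(1+m²)` with line slope `m` (−1 by
default). The region score divides the largest outlier distance by the
worst-case distance — from the total-loss-at-complete-LD corner (1, 1) —
which for the default line is 0.6/√2 ≈ 0.42426. Because loss ≤ 1 and r² ≤ 1,
no outlier can exceed the worst case, so the ratio is in (0, 1] and
GQS ∈ [0, 1) whenever outliers exist. Perpendicular (not vertical) distance
is the geometry under which the default worst case is 0.424; the reference
worked example 1 − 0.342/0.424 = 0.193 takes
both distances at that 3-decimal precision, and the acceptance script
reproduces it that way, while the library always computes exact geometry.

Sentinels: a region with no non-index member above the r² floor scores −1
(nothing supports the LD pattern; the region needs manual scrutiny), and a
supported region with no outliers scores exactly 1. The index SNP is
excluded from its own scored set — its r² = 1 with itself would otherwise
make −1 unreachable. Ties in maximal outlier distance do not affect the
score; the reported "strongest outlier" is the lexicographically smallest ID.

## Inputs and numerical choices

* −log₁₀P: P = 0 (underflow in large meta-analyses) is clamped to the
  smallest positive double (≈ 5×10⁻³²⁴, −log₁₀P ≈ 323.3) and counted, never
  dropped; P outside (0, 1] is dropped and counted.
* Duplicate variant IDs keep the smallest-P record (mirroring index
  selection) with a warning.
* r² is the squared Pearson correlation of unphased alt-allele dosages
  (composite LD) over pairwise-complete individuals, with a minimum of 10
  complete pairs (configurable); zero-variance variants are omitted. This
  estimator needs no phasing and is invariant to allele relabelling
  (d ↔ 2−d). Variants at r² < 0.01 are discarded as linkage-equilibrium
  noise before scoring.
* Panel↔summary variant matching is by ID first, then (chrom, pos, allele
  set); summary variants with no LD estimate are left unscored with a
  warning — incomplete overlap is a finding the score should reflect, not
  an error.
* Region discovery is greedy distance clumping (take the globally smallest
  P < 5×10⁻⁸, open ±500 kb, assign, repeat; overlapping regions merged
  keeping the smaller-P index). Distance rather than LD clumping keeps
  region discovery independent of LD-reference completeness. P ties break
  by position then ID, for determinism. Targeted regions are gene ± 50 kb
  by default, indexed by the regional minimum P regardless of significance.
* The 68/95/99 % bands reported in tables and plots are fixed |S| cut
  points (0.68/0.95/0.99), not empirical quantiles; they annotate only and
  never enter the score. The naive single-SNP screen flags loss > 0.75.

## Synthetic data

The simulator exists so the whole pipeline is testable without external
data. It emulates, at a small-cohort scale (defaults: 464 cases, 516
controls, 60 SNPs at 1 kb spacing):

* **LD structure** — haplotypes from a first-order Markov copy model: site j
  copies site j−1's allele with probability ρ (default 0.95), else draws at
  its own MAF (uniform in 0.2–0.5). Adjacent-site correlation ≈ ρ and decays
  geometrically, so a 60-SNP region spans r² from ~1 down through the 0.4
  floor. The analytic per-site r² with the causal variant (covariance
  c^d·Var(earlier site), marginals by the copy recursion) is stored as
  ground truth and checked against empirical LD in tests.
* **Association** — binary phenotype from a logistic model on the causal
  dosage (default OR 2; intercept solved so the expected case fraction
  matches the design), tested per SNP with the 1-df allele-count chi-square;
  effect/SE are the allele log-OR with Woolf SE (Haldane correction on empty
  cells) so cohorts can be meta-analyzed by fixed-effects inverse-variance
  weighting.
* **Artifacts**, with ground-truth labels: *differential missingness*
  emulates a failing calling cluster in the case batch — alt-carrying case
  genotypes go missing at the severity rate, deflating the case allele
  frequency (informative missingness; missing-at-random within cases would
  only shrink effective N and produces losses too small to cross the
  threshold); *allele flip* recodes d → 2−d within a fixed random half of
  samples (a mis-coded batch — flipping all samples would be a harmless
  relabelling); *cohort dropout* removes a SNP from a fraction of
  meta-analyzed cohorts, deflating its significance relative to fully
  covered LD neighbours.

Everything is deterministic given the seed, to the byte, including emitted
files.

What the simulator does **not** model: population structure and demography
(no coalescent realism), imputation quality, X-chromosome dosage, covariates,
polygenic background, or multiple causal variants per region (two-signal
regions can be composed manually by summing simulations). Passing tests
therefore demonstrate that the scorer detects the modelled artifact classes
under clean single-signal LD decay — not that it detects every real-world
failure mode, nor calibrate its false-positive rate on real consortium data.

## Problem sizes in tests

Property checks run the scorer against an independent brute-force
recomputation on hundreds of random ≤30-SNP regions; calibration and
detection are estimated over 100 seeded replicates of the default-scale
simulation (clean runs score 1 in ≥90 %, an informatively-missing SNP at
true r² ≈ 0.9 is flagged in ≥80 %); the score-range invariant is exercised
over 10,000 random regions. These sizes make the suite a few tens of
seconds while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* The score depends entirely on the index SNP: an index that itself lost
  power yields GQS = 1 even in a problematic region.
* Regions without any r² > 0.4 member are undecidable (−1), not scored.
* The drop threshold is a fixed heuristic, not a calibrated statistical
  test; no per-SNP chi-square heterogeneity test is attempted.
* One score per region: multiple independent signals require manual
  re-indexing to assess separately.
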