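# Methods

## Occupancy model

A window is scanned on both strands at every offset. The reverse strand is
scored by applying the reverse-complemented PWM to the forward sequence,
which is algebraically identical to scoring the reverse complement of each
site against the original PWM; the strand-symmetry property
`X(S) = X(revcomp(S))` is enforced by test. Unknown bases (`N`) contribute
zero log-likelihood at their position, i.e. they are treated as draws from
the background.

Site affinities are expressed relative to the consensus:
`K = exp(llr − llr_max) ∈ (0, 1]`, so the single concentration parameter τ
absorbs the consensus binding constant and is the only scale parameter.
Predicted occupancy is the sum of independent fractional occupancies
`τK/(1+τK)` over sites within eT natural-log units of the consensus. This
is the non-cooperative, no-overlap-exclusion form: for ≤ 12 sites it equals
the expected bound count from exhaustive enumeration of all 2^n
bound/unbound configurations with factorized Boltzmann weights (asserted to
1e-9 in the tests). Cooperative binding, overlap exclusion and secondary-TF
motifs are deliberately out of scope.

**Fitting.** τ is searched on a log grid of 13 points spanning 1e-3…1e3;
eT on {2, 3, 4, 6, 8, ∞} (natural-log units below consensus). Both grids
are configurable. For each eT, τ maximizes Pearson correlation between
occupancy and ChIP signal on an 80% split; eT is chosen by correlation on
the held-out 20%; τ is then re-optimized on all windows at the chosen eT
(the only free parameters being the pair itself, "refitting on all data"
reduces to this re-optimization). Exact ties resolve to the smallest τ,
then the largest (most permissive) eT, making the search deterministic.
Because Pearson correlation is scale-free, no slope/intercept is fit during
training; the final linear calibration — reference-set minimum to 0,
maximum to 1, never clipped for novel sequences — supplies the output
scale. Exact recovery of τ is not expected or asserted: occupancy curves at
neighboring grid points are nearly affinely related across windows, so
recovery is measured as held-out correlation.

Degenerate inputs fail loudly: fewer than 20 training windows, constant
ChIP signal, constant calibration reference, and sequences shorter than the
motif are all errors.

## Multi-motif fusion

Features are each submodel's *calibrated* score (not raw occupancy), so
motifs sit on a common scale before fusion. Features are standardized with
stored center/scale; a constant feature gets unit scale and drops out of
the RBF distance. The regression is ε-SVR (C = 1, ε = 0.1, kernel width
γ = 1/(d·Var(Z)) computed explicitly on the standardized matrix and stored)
— the ε-flavored SVR with library-default constants, chosen for
determinism. The fitted model is stored as explicit support vectors, dual
coefficients, intercept and γ; prediction is an explicit kernel sum, making
it JSON-serializable and bitwise-reproducible (verified against the
library's own predict to ~1e-15).

## Variant scoring

Allele windows are 501 bp centered on the SNP, built from the major-allele
reference genome (every SNP position set to its major allele first); the
two windows differ only at the central base. SNPs within 250 bp of a
chromosome end are errors, never padded — padding would distort occupancy.
Delta-PWM restricts to motif placements overlapping the SNP: non-overlapping
placements are identical between alleles and cancel exactly, so this is an
optimization, not an approximation (verified against full enumeration).
All delta scores are symmetric under allele swap by construction.

## Training-set construction

Positive windows are 500 bp centered on peak midpoints (the midpoint is the
conventional summit proxy; the upstream-50-kbp eligibility rule is
strand-aware relative to the TSS). HOT exclusion counts distinct other TFs
with any peak overlapping ≥ 50% of the candidate peak's length; six or more
excludes it. One window per peak avoids near-duplicate leakage between
train and test. Negatives are other TFs' positive windows with zero overlap
(even 1 bp) with any test-TF peak. The 80/20 split is balanced per class
and seeded.

## Statistics

* **eQTL test**: simple linear regression of expression on additive
  minor-allele dosage, two-sided t-test on the slope with df = m − 2 over
  complete pairs; missing dosages are dropped pairwise, never imputed.
  Constant dosage returns p = 1 with a degenerate flag.
* **Thresholds**: the eQTL threshold is strict (p < 0.05); the
  drug-response-gene threshold is inclusive (p ≤ 0.05); both follow the
  respective rule literally and are parameters.
* **Regulatory regions**: all Hi-C domains overlapping the gene, plus the
  partner anchor of any loop touching the gene (both anchors when both
  touch). Coordinates: BED intervals are 0-based half-open, SNPs 1-based;
  the only conversion point is the overlap predicate
  `start ≤ pos−1 < end`.
* **Binding-change SNPs**: top-k (default 300) by each available impact
  scorer among within-peak SNPs, union across scorers; missing scores rank
  last; exact ties break lexicographically by SNP id. Ranking happens
  within peak SNPs and sets are intersected with the universe at test time.
* **Enrichment**: hypergeometric upper tail P(X ≥ k) evaluated in log
  space; both tested sets are intersected with the accessible-SNP universe
  first, which the hypergeometric model requires for well-formedness.
  Verified against exact rational enumeration for every (N, K, n, k) with
  N ≤ 15.
* **FDR**: Benjamini-Hochberg step-up across all TF-drug pairs jointly
  (verified against a direct step-up implementation); ties in p share a q.
  The implied per-test nominal cutoff for j discoveries among m tests is
  α·j/m.
* **Utility p score**: 100 seeded size-matched subsets of the TF's
  within-peak SNPs, fraction with control p strictly below the observed p.
  Controls can alternatively be drawn from the whole accessible universe
  (the second control experiment); both modes are exposed.
* **Quality filters**: SNPs with minor-allele frequency < 5% or a
  Hardy-Weinberg chi-square (1 df) goodness-of-fit p < 0.05 are flagged and
  excluded by `passing_snps`. The HWE rule is implemented as a p < 0.05
  exclusion — the conventional reading of an equilibrium-deviation filter.

## Synthetic studies: what they emulate and what they do not

`gen_chip_windows` plants 1–3 sites per positive window, sampled per
position (consensus with probability = site strength, else a draw from the
motif column), and emits ChIP signal as analytic occupancy under a known
(τ = 2, eT = 3) plus Gaussian noise (σ = 0.05 for the standard fixtures).
Negatives are motif-free background or carry decoy-motif sites. Truth
sidecars record planted site offsets; recovery tests read only these.

`simulate_study` (tiny preset) is a scaled-down analogue of a real cohort
study (which would have ~284 samples, 24 drugs, 37 TFs, ~1.3M SNPs): one
400-kb chromosome at GC 0.41, 20 chromatin domains of 20 kb, 40 genes,
2 TFs × 3 drugs, 120 samples, ~400 accessible SNPs, top-k = 40. The causal
chain: 31 site-destroying SNPs (consensus → least-preferred base at the
most informative motif column) inside the causal TF's peaks, three per
causal-gene domain plus one reached through a chromatin loop; each causal
gene's expression is 0.8 × (summed causal dosages, centered) + N(0, 1); the
causal drug's EC50 is 0.4 × (summed causal-gene expression) + N(0, 1).
Causal SNPs have MAF 0.3, background SNPs MAF ~ U(0.1, 0.45); genotypes are
Hardy-Weinberg binomial draws. The second TF has its own site-destroying
SNPs that are *not* wired to expression, so it controls for "high impact
score without phenotype linkage". Problem sizes were chosen once as the
smallest panel in which the planted effect is unambiguous while every
pipeline component (loops, domains, utility controls, FDR) is exercised.

Deliberately not emulated: linkage disequilibrium (dosages are independent
across SNPs; an optional block-LD mode is a natural extension),
population structure, read-level ChIP noise, probe-to-gene mapping noise,
and dosage missingness (supported by the pipeline, not generated by
default). Passing recovery tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not performance on
real cohorts, where LD alone guarantees that associated SNPs are not
necessarily causal.

## Known limitations

* The occupancy model ignores site overlap, so a palindromic consensus is
  counted on both strands; τ compensates in fitting but absolute
  occupancies can double-count.
* The SVR fusion extrapolates poorly outside the feature range seen in
  training (an RBF property); calibrated scores outside [0, 1] are passed
  through unclipped by design.
* The association engine tests marginal enrichment; it does not model
  correlated SNP sets or gene-level dependence, and q-values are only as
  calibrated as the independence assumptions allow.
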