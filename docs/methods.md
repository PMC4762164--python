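# Methods

## Problem setting

A tumor's somatic single-nucleotide variants are summarized as a fraction
profile `t` over the 96 trinucleotide substitution classes (six
pyrimidine-referenced substitutions × 16 flank combinations; purine-reference
mutations are reverse-complemented, which halves the 192 raw encodings).
Given a reference catalog `S` — `k` known signatures, each a probability
distribution over the 96 classes — the refitting problem is to estimate
non-negative exposures `w` such that `wᵀS` reconstructs `t` with minimal
sum of squared errors (SSE). Exposures cannot be negative: a mutational
process adds mutations, it cannot remove them. This is a per-sample
analysis; no information is shared between tumors.

## Catalog construction

`catalog.build_context_matrix` looks each SNV up in an indexed FASTA
(pyfaidx), checks the reference allele against the genome, uppercases
soft-masked bases, strand-collapses the triplet, and tallies per sample.
Records that cannot be resolved (reference mismatch, ambiguous N in the
triplet, position without both flanks) are dropped with a logged per-sample
count; a sample losing *all* its records is an error rather than a silent
zero row. Coordinates are 1-based fully closed; VCF input (also 1-based) is
split per alternate allele, with non-SNV alleles dropped.

When profiles are counts from a restricted territory (e.g. exome capture),
`normalize_context_matrix` multiplies each class count by
`target[tri] / source[tri]` — the ratio of trinucleotide occurrences in the
target vs. source territory — and then renormalizes rows to fractions.
The bundled territory tables are **synthetic** (generated by
`scripts/make_tri_count_tables.py` from independent-base composition with
CpG suppression, GC 0.41 genome-like / 0.50 exome-like, CpG factors 0.22 /
0.70); they demonstrate the mechanism and carry realistic gross structure,
but real analyses should derive tables from their reference build with
`catalog.tri_counts_from_fasta`, which counts both strands collapsed to
pyrimidine-centered triplets.

## The refit algorithm

1. **Candidate filter.** A signature is excluded when any single context
   holds strictly more than `context_filter_threshold` (default 0.20) of
   its mass while the tumor has exactly zero mutations there. A process
   defined by a peak it never produced is implausible; this also removes
   most of the search space for sparse tumors. "Zero" means exactly 0.0 —
   the filter acts on observed absence, not on small fractions.
2. **Seed.** The single candidate with lowest SSE against `t` (ties: lowest
   index) starts with raw weight 1.
3. **Forward selection.** For every candidate `i`, the SSE is exactly
   quadratic in `w_i` with the others held fixed; its non-negative
   minimizer is the clamped closed form
   `max(0, ⟨S_i, t − Σ_{j≠i} w_j S_j⟩ / ⟨S_i, S_i⟩)`. The single
   reassignment with the globally lowest resulting SSE is applied (ties:
   lowest index). The closed form is verified against a bounded numeric
   search in the test suite; using it removes a line-search tolerance from
   the core. The seed's own weight is re-optimizable like any other — the
   only reading under which the SSE can keep decreasing on that coordinate.
4. **Stopping rule.** Iteration stops when one step improves the SSE by
   less than `error_threshold` (default 0.001) *of the current SSE*. The
   threshold is relative by design: each step updates a single coordinate,
   so on broad mixtures the per-step improvement is a small fraction of the
   total SSE long before the fit is good, and an absolute 1e-3 cutoff would
   freeze the fit at the seed plus a handful of corrections (measured:
   ~40 % of truly contributing signatures would be missed; the relative
   rule reaches the non-negative least-squares optimum to within 1e-3 on
   every tested instance).
5. **Normalization and cutoff.** Raw weights are normalized to sum to 1
   (because `t` itself sums to 1, they converge near unit sum anyway), and
   every normalized weight strictly below `weight_cutoff` (default 0.06)
   is zeroed **without renormalizing**: the removed mass is reported as the
   `unknown` fraction, preserving `Σ weights + unknown = 1` as an exact
   contract. The cutoff separates genuine small exposures from fitting
   noise; its default is supported by the calibration simulation below.
6. A warning is logged when the sample has fewer than
   `min_mutation_warning` (default 50) mutations — 96-bin fractions from so
   few draws are noisy and exposures correspondingly unreliable.

### Numerical choices

- Exact mixtures make the SSE decay geometrically (coordinate descent
  converges linearly), so the relative improvement never falls below the
  threshold; the iteration additionally stops when the SSE is below 1e-15
  or the absolute improvement falls below 1e-14 — both far outside any
  scientifically meaningful regime.
- Near-collinear signature pairs (cosine ≥ 0.95) slow the linear rate to
  ~0.97–0.99 per step; the iteration cap is therefore 10 000 (an error is
  raised if hit, guarding true non-termination). Perturbed or noisy
  profiles stop via the relative rule after tens of steps.
- Tie-breaks everywhere take the lowest signature index, making results
  order-deterministic.
- Degenerate inputs raise: profiles not summing to 1 within 1e-6, empty
  candidate sets after filtering, all-zero weight vectors.

## Calibration simulation

`simulate.run_calibration` generates a cohort of in-silico tumors, each a
convex combination of up to `max_sigs` (default 10) reference signatures
(the count uniform on {1..10}, the subset uniform), perturbs each profile,
refits it with the cutoff disabled, and scores every candidate cutoff
against ground truth. A **false positive** is a signature with true weight
0 assigned positive weight; a **false negative** is a truly contributing
signature whose weight the cutoff zeroes. By construction the FN count is
non-decreasing and the FP count non-increasing in the cutoff.

Two choices are deliberately documented because they shape the headline
rates:

- **Perturbation** (default ±5 %, relative): each context value is
  multiplied by `1 + u`, `u ~ Uniform(−0.05, 0.05)`, then the profile is
  renormalized. Relative jitter keeps zero contexts at zero, which is the
  only mode consistent with the candidate filter's exact-zero semantics.
  An absolute mode (add `u`, clip at 0) is available.
- **Weight drawing** defaults to `equal` (1/m per chosen signature) in
  calibration runs. Under simplex-uniform (Dirichlet(1)) weights, a large
  share of true exposures lies below the 6 % cutoff and is unrecoverable
  *by design* — the measured FN rate then reflects the weight prior, not
  the method. With equal weights every true exposure is ≥ 0.1 and an FN is
  a genuine fitting failure. `generate_tumor` keeps Dirichlet(1) as its
  general-purpose default; both expose `weight_scheme`.

Under the defaults (27-signature synthetic catalog, 100 tumors, ±5 %
relative perturbation, 6 % cutoff) the FN rate lands in the low single-digit
percents and the 95th percentile of FP weights is well below 6 % — the
regime in which the 6 % default is justified. These numbers are computed,
not asserted: `scripts/acceptance.py` re-measures them on every run.

## Synthetic data generators

`synthetic_signature_set` emulates the *structure* of published catalogs
rather than drawing featureless random distributions: each signature
concentrates its mass on one or two substitution-class blocks with
separable 5'/3' flank preferences over a low uniform background
(mutational processes have chemical specificity); ~12 % of signatures are
background-dominated and nearly flat (the hard-to-fit analogue of the
clock-like and HR-deficiency signatures); and a few signatures are
near-duplicate *variants* of earlier ones (pairwise cosine ~0.94–0.99),
mirroring the split sub-signatures and low-confidence entries that
published catalogs carry. The variant pairs are what make calibration FN
rates nonzero — without them weight recovery is essentially perfect and a
cutoff calibration would be uninformative. Parameters were chosen to match
the similarity structure of the real catalog (median pairwise cosine
~0.05, peak context fractions ~0.05–0.6).

`separated_signature_set` greedily enforces a pairwise-cosine bound
(default 0.8) and is used for recovery studies whose guarantees only hold
on well-separated references. `random_genome` and `mutations_from_profile`
produce FASTA-backed mutation tables realizing a given context profile,
exercising the full catalog path including strand collapsing.

What the generators do **not** emulate: real signatures' specific
biochemical profiles (no signature here *is* the UV or APOBEC signature);
mutation-count noise in calibration profiles (perturbation is applied to
exact fractions, not multinomial draws); inter-context correlation
structure beyond block/flank separability; and genome-wide sequence
context biases beyond GC content and CpG depletion. Passing tests
therefore demonstrate the correctness and calibration of the *method*
under realistic-in-structure conditions, not performance figures for any
particular real catalog or cancer type.

## Problem sizes

The shipped studies use the sizes at which their quantities stabilize
while remaining quick to re-run: calibration at 100 tumors × 27
signatures, oracle comparison on 200 instances (k ≤ 8, mixtures of ≤ 4
with exposures ≥ 0.1), recovery over 500 trials on a 10-signature
separated set, and catalog checks on a 7 kb two-chromosome synthetic
genome. All are seeded and bit-reproducible; per-tumor RNG streams are
derived from the master seed by fixed arithmetic, so cohorts parallelize
deterministically.

## Known limitations

- Forward selection is greedy; it is not guaranteed to reach the global
  non-negative least-squares optimum, though on all tested instance
  families it does to within 1e-3 SSE (and the NNLS solution itself is the
  package's test oracle, never its implementation).
- Exposures of near-collinear signatures are fundamentally poorly
  identified; the method reports one allocation among near-equivalent ones.
- The 6 % cutoff trades sensitivity for specificity; genuine exposures
  below 6 % are invisible by design, and `unknown` aggregates both their
  mass and fitting residue.
- Catalog-level choices (merging split signature variants, exome vs.
  genome normalization) change fitted exposures; both are exposed as
  explicit options (`merge_signatures`, `normalize_context_matrix`) and
  default to off.
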