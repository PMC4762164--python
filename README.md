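# sigrefit

Mutational signature refitting for **single tumor samples**.

Cohort-level methods (non-negative matrix factorization over hundreds of
genomes) discover mutational signatures de novo but cannot say anything
about one patient's tumor in isolation. `sigrefit` solves the complementary
problem: given the somatic SNVs of a single tumor and a catalog of *known*
signatures, it estimates how much each signature contributed to that
tumor's mutations. It is aimed at cancer genomics analysts working
downstream of somatic variant calling — per-patient signature exposures for
DNA-repair-deficiency screening, mutagen attribution, or clonal-evolution
analyses.

## The model

Every somatic SNV is classified into one of the 96 trinucleotide
substitution classes: the six pyrimidine-referenced substitutions
(C>A, C>G, C>T, T>A, T>C, T>G) by the 16 combinations of immediate 5' and
3' flanking bases. Mutations at purine reference bases are
reverse-complemented first, so `...TGC...` with G>A becomes `G[C>T]A`.
A tumor is summarized as a fraction profile **t** ∈ Δ⁹⁵ over these classes;
a reference catalog is a row-stochastic matrix **S** (k signatures × 96).

`sigrefit` infers non-negative exposures **w** minimizing the sum of
squared errors

&nbsp;&nbsp;&nbsp;&nbsp;SSE(w) = ‖ t − wᵀS ‖² ,  w ≥ 0,

by iterative forward selection: signatures whose defining context (> 20 %
of the signature's mass in a single class) is absent from the tumor are
filtered out; the best single signature seeds the fit with weight 1; then,
repeatedly, the one weight whose closed-form non-negative re-optimization
most reduces the SSE is updated, until a full step improves the SSE by
less than 0.1 % of its current value. Final weights are normalized to sum
to 1 and any exposure below 6 % is zeroed — its mass is reported as the
*unknown* fraction rather than redistributed, so reported weights plus
unknown always sum to 1. The 6 % cutoff is calibrated by simulation
(`sigrefit.simulate`): on perturbed in-silico tumors, spurious exposures
fall below it while true exposures above it are almost never lost.

## Worked example

```python
from sigrefit import synthetic_signature_set, which_signatures

# a 27-signature synthetic reference catalog and a tumor mixing three of them
S = synthetic_signature_set(k=27, seed=0)
t = 0.55 * S.row("Signature.4") + 0.35 * S.row("Signature.11") \
    + 0.10 * S.row("Signature.19")

result = which_signatures(t, S, n_mutations=180, sample_id="TUMOR-1")
for name, w in sorted(result.nonzero_weights.items(), key=lambda kv: -kv[1]):
    print(f"{name}\t{w:.3f}")
print(f"unknown\t{result.unknown:.3f}")
print(f"SSE\t{result.sse:.2e}")
```

prints

```
Signature.4	0.550
Signature.11	0.350
Signature.19	0.100
unknown	0.000
SSE	6.05e-15
```

i.e. the three contributing processes are recovered at their true
exposures (55 %, 35 %, 10 % of mutations), nothing is attributed to the
other 24 signatures, and the reconstruction error is at machine precision
because the input was an exact mixture. Real profiles carry sampling
noise; with fewer than 50 mutations a warning is logged because 96-bin
fractions become unreliable.

The same pipeline runs from the shell on raw mutation tables
(`sample, chr, pos, ref, alt` TSV, or single-sample VCF) plus an indexed
FASTA:

```bash
sigrefit catalog --mutations muts.tsv --genome genome.fa --mode fractions --out-dir out/
sigrefit refit   --context-matrix out/context_matrix.tsv --signatures sigs.tsv \
                 --plots --out-dir out/
sigrefit simulate --n-tumors 500 --seed 7 --out-dir calib/
```

`refit --plots` writes the three-panel profile figure (tumor /
reconstruction / residual with SSE annotated) and the exposure pie chart
for every sample. Reference catalogs are plain TSV with `A[C>A]A`-style
column headers, so published signature tables load directly; exposures of
exome-sequenced tumors can be re-weighted to whole-genome trinucleotide
frequencies via `--tri-counts-source/--tri-counts-target`.

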