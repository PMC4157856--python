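# Methods

## Reference tag model

A reference tag is the 17 bases immediately 3' of a `CATG` (NlaIII) site on
the sense strand. Every qualifying site of a gene contributes one tag to the
index (so a 2 kb transcript contributes ~8 tags on average at uniform base
composition), but only the tag at the 3'-most site — the one the
library-preparation chemistry actually captures — is the gene's *canonical*
tag, and it is the only tag the simulator sequences. Sites within 17 bp of
the 3' end contribute nothing (the tag would be truncated), and a window
containing `N` is disqualified because it could never match under the
0/1-mismatch rule. "Genes with CATG site" in the reference summary counts
genes with at least one *qualifying* site; a gene whose only `CATG` sits too
close to the 3' end is tag-less and is not counted. Antisense tags are not
indexed; the summary table records the strand policy in its metadata so
alternative policies remain comparable.

## Cleaning and mapping

Raw distinct-tag tables pass three filters: tags containing any non-ACGT
character are dropped ("low-quality"); tags whose sequence begins with the
configured adaptor prefix are dropped; then tags with a single copy are
dropped, since a one-copy tag is indistinguishable from a sequencing error
at typical error rates. Mapping resolves each remaining tag by exact lookup
first; failing that, all 51 single-base variants are looked up. A tag whose
hit set (exact preferred) contains exactly one gene contributes its full
count to that gene as an *unambiguous* mapping — the analysis-grade
quantity used for TPM and differential testing. Tags resolving to several
genes are retained as mapped-but-ambiguous and are credited to each
candidate gene only in a separate detection column (used by the saturation
analysis); no fractional allocation is attempted. Tags with no hit are
*unknown*, unless an optional genome decoy tag set is supplied, in which
case decoy hits fill a separate "genome" bucket. TPM uses the library's
clean-tag total (not the mapped total) as denominator: count / N × 10⁶.

## The two-library test

With one library per condition, a gene's count is Poisson: its expression
occupies a small fraction of a large library. Conditioned on count x in
library 1 (total N1), the count y in library 2 (total N2) under equal
underlying expression follows

    p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

which is NB(x+1, N1/(N1+N2)) in y. Both tails are computed through the
regularized incomplete beta function (scipy), which keeps relative accuracy
to ~1e-13 for counts up to 10⁶; tails below 1e-250, where that route
degrades, are recomputed by log-space direct summation. The two-sided
P-value doubles the smaller tail, includes the observed point, and is capped
at 1 — the conservative standard choice. Note the tails condition on x, so
the P-value is not exactly invariant under swapping the libraries (the
conditional pmf itself is exchange-symmetric at equal depths); significance
verdicts are stable under the swap.

Multiple testing uses Benjamini–Hochberg step-up adjustment
(statsmodels). Genes with x + y = 0 are untestable and are excluded from
the results and from the BH family, which would otherwise be artificially
deflated. A gene is called differentially expressed only when all three
gates pass: P < 0.005, FDR < 0.001, and |log2 ratio| ≥ 1 (the boundary is
inclusive). The log2 ratio is computed on the TPM scale with zero counts
floored at 1 before normalization, so genes observed in only one library
get large finite ratios rather than infinities; a (0,0) gene is assigned
ratio 0 by convention but never reaches the caller.

## Enrichment

For N annotated background genes, n annotated DEGs, M background genes
carrying a term, and m DEGs carrying it, the enrichment P-value is the
upper hypergeometric tail P(X ≥ m) = 1 − Σ_{i<m} C(M,i)C(N−M,n−i)/C(N,n).
N and n count annotated genes only. Significance is assessed on raw
P-values at α = 0.05, matching common practice for this assay generation;
a BH-adjusted mode exists but is off by default. GO terms and pathways are
mathematically identical and share one engine; a namespace label keeps them
separable in reports. The default background is the set of genes detected
in either library; the full annotated reference can be supplied instead.
No ontology-graph propagation is performed — annotation tables are taken
as given.

## qPCR validation

The comparative-CT method: replicates are averaged on the Ct scale, ΔCt =
mean Ct(target) − mean Ct(reference gene) per sample, ΔΔCt = ΔCt(case) −
ΔCt(control), fold change = 2^−ΔΔCt. Group comparisons run Student's
t-test on per-sample ΔCt values (equivalent to testing log2 fold changes,
and the more standard scale); this choice is recorded in the result
metadata. Concordance with the sequencing analysis is assessed by sign
agreement of log2 fold changes, not magnitude correlation — tag counting
and qPCR have different dynamic ranges and efficiencies. No
amplification-efficiency correction is applied.

## Synthetic study generator

The generator emulates a two-condition experiment at realistic scale.
Defaults: 10,000 reference genes of 200–4000 bp, 92.28% guaranteed a
qualifying CATG site (the remainder scrubbed of CATG entirely, so the
realized count is binomial); two libraries of 2,000,000 raw tags; gene
abundances log-normal with σ = 1.5 (a realistic dispersion for tag
libraries: a heavy tail of highly expressed genes and a soft floor of
barely detectable ones), normalized to sum 1. Five percent of expressed
genes are differentially expressed at |log2 fold| = 2, injected into
library 1 symmetrically (half up, half down) and restricted to genes of at
least 50 true TPM; library-1 abundances are renormalized afterwards.
Non-DE genes carry an effect of exactly 0.

Corruption is applied per sampled tag copy, as sequencing operates on
reads: each copy of a gene's canonical tag mutates per base with
probability 0.001 (so ~1.7% of copies carry ≥1 substitution, producing the
1-mismatch tags the mapper must rescue). On top of the signal, 1.5% of raw
tags are replaced by a fixed adaptor 17-mer, 1.2% receive an `N` at a
random position, and 25% are random non-reference 17-mers ("unknown
tags") — fractions chosen to mirror typical raw-vs-clean and unknown-tag
accounting in real tag libraries. Distinct-tag counts sum exactly to the
configured library size, and all randomness flows from one root seed
through per-stage streams, so identical configurations are byte-identical.

What the simulator does **not** model: read-level quality strings, partial
NlaIII digestion (every transcript yields its canonical tag only),
antisense tags, genome-derived (non-transcript) tags as a distinct class,
and correlated (batch) noise between libraries. Passing the recovery tests
therefore demonstrates correctness of the pipeline's accounting and
statistics under the stated sampling model, not robustness to every
artefact of real sequencing.

## Numerical and design choices

- **Tie-breaks**: DE results sort by (P, FDR) with a stable sort;
  enrichment results and top-k reports break P ties by term id, so all
  outputs are deterministic.
- **1-mismatch search** enumerates the 3×17 variants of each query against
  a hash index — exact, and faster than all-pairs scanning at these sizes;
  tests verify equivalence against a brute-force Hamming oracle.
- **Saturation curves** use nested prefixes of one seeded shuffle of the
  raw tag stream (sampling without replacement), which makes both
  detected-gene columns non-decreasing by construction. Cleaned tags are
  mapped without the >1-copy filter, whose depth-dependence would break
  monotonicity.
- **Degenerate inputs**: empty references, empty annotation tables, empty
  count tables, all-singleton libraries, zero-variance qPCR groups and
  k ≤ 0 report requests all either return well-formed empty results or
  raise typed errors naming the offending field/file/line.
- **Problem sizes**: the validation suite exercises the full study scale
  (2M tags per library, 10k genes, five seeds) for parameter recovery and
  saturation; unit tests run scaled-down studies (~400 genes, ~80k tags)
  where binomial/multinomial interval checks are sharp enough to catch
  rate errors.

## Known limitations

- One library per condition: no replicates, hence no dispersion
  estimation; the Poisson-conditional test understates biological
  variability and its calls should be read as candidates for validation.
- Ambiguous tags are segregated, never allocated, so genes whose canonical
  tag is shared are systematically under-counted.
- The P-value's library-swap asymmetry (above) is a property of the
  conditional tail definition, not of the implementation.
- Enrichment treats annotation terms as flat sets; nested GO terms will
  co-fire.
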