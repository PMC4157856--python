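# dgetag

Digital gene expression (DGE) tag-profiling analysis for two-library
comparisons, with a fully ground-truthed synthetic study generator.

## The problem

Before full-length RNA-seq became routine, transcriptomes were compared by
counting short cDNA *tags*: each transcript is cut at its NlaIII restriction
sites (the motif `CATG`) and the 17 bases immediately 3' of a site are
sequenced as that transcript's tag. Differential expression between two
conditions — e.g. a diseased versus a normal tissue, each sequenced as one
library of millions of tags — is then a comparison of per-gene tag counts
between two multinomial samples. `dgetag` implements the complete analysis
chain for such experiments:

1. **Reference tag index** — locate every `CATG` site in a reference gene
   set, derive the 17 bp tags, flag tags shared by several genes as
   *ambiguous*, and report the standard accounting (genes with a CATG site,
   unambiguous/ambiguous tag percentages).
2. **Tag cleaning and mapping** — drop adaptor-contaminated and
   ambiguous-base (`N`) raw tags, drop single-copy tags, and assign the rest
   to genes under a perfect-or-1-mismatch rule; expression is normalized as
   TPM (transcripts per million clean tags).
3. **Differential expression** — the Audic–Claverie exact test. Conditioned
   on a gene's count x in library 1 (depth N1), its count y in library 2
   (depth N2) under equal expression follows

       p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

   a negative binomial NB(x+1, N1/(N1+N2)) in y. The two-sided P-value
   doubles the smaller tail; genes are called up/down when P < 0.005,
   Benjamini–Hochberg FDR < 0.001, and |log2(TPM1/TPM2)| ≥ 1 jointly.
4. **Enrichment** — upper-tail hypergeometric enrichment of the DEG set
   against GO-term / pathway annotation tables (raw P ≤ 0.05).
5. **qPCR validation** — comparative-CT (2^−ΔΔCt) fold changes against a
   housekeeping control, with t-tests on per-sample ΔCt and sign-concordance
   against the sequencing-based calls.
6. **Saturation analysis** — detected-gene counts on nested subsamples of
   the raw tag stream, to verify sequencing depth suffices.

Because real tag libraries are rarely at hand, the `simulate` module
generates complete studies — reference, annotations, and corrupted raw tag
libraries — from a known ground truth (log-normal abundances, injected log2
effects, per-base sequencing errors, adaptor/`N`/non-reference
contamination), so every stage of the pipeline is quantitatively testable.

## Worked example

```python
import dgetag as d

cfg = d.SimConfig(n_genes=2000, n1=400_000, n2=400_000, seed=42,
                  frac_de=0.05, de_min_tpm=100.0)
genes, annotations, truth, lib1, lib2 = d.simulate_study(cfg)

index = d.extract_reference_tags(genes)
print(d.reference_summary(index).to_string(index=False))

clean1 = d.clean_tags(lib1, d.ADAPTOR)
clean2 = d.clean_tags(lib2, d.ADAPTOR)
expr1, rep1 = d.map_tags(d.drop_singletons(clean1), index, clean_total=clean1.total)
expr2, _ = d.map_tags(d.drop_singletons(clean2), index, clean_total=clean2.total)

res = d.TwoLibraryDE(d.combine_libraries(expr1, expr2)).fit()
print(res.summary())
called, true = set(res.degs.index), set(truth.de_genes)
print(f"recovered {len(called & true)} of {len(true)} injected DEGs, "
      f"{len(called - true)} false positives")
```

prints

```
            category  count  percentage
     Reference genes   2000         NaN
Genes with CATG site   1876        93.8
Total reference tags  15182         NaN
    Unambiguous tags  15182       100.0
      Ambiguous tags      0         0.0
Two-library differential expression (Audic-Claverie test)
==========================================================
Libraries: deformed (N1=389,251) vs normal (N2=389,155)
Genes tested: 1,853
Thresholds: P<0.005, FDR<0.001, |log2 ratio|>=1.0
Significant DEGs: 90 (47 up [52.2%], 43 down [47.8%])
Ratios within 5-fold: 99.14%
recovered 90 of 94 injected DEGs, 0 false positives
```

93.8% of the simulated genes carry a usable CATG site; with 2,000 short
genes every reference tag happens to be gene-unique. Of the 94 genes
injected at 4-fold differential expression, 90 pass all three gates
(4 fall below the detection depth), with no false calls, and ~99% of tested
genes show less than 5-fold difference — the expected picture for two
libraries drawn from mostly-identical abundances.

The same analysis is scriptable from the shell:

```sh
dgetag simulate --seed 42 --outdir study/
dgetag run --fasta study/reference.fasta \
           --tags1 study/tags_deformed.tsv --tags2 study/tags_normal.tsv \
           --annot study/annotations.tsv --outdir study/run
```

Subcommands `build-ref`, `clean`, `map`, `saturation`, `test`, `enrich`,
and `qpcr` expose the individual stages.

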