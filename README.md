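# epinoia

Two-stage genome-wide search for pairwise epistasis on expression traits in
recombinant inbred line (RIL) populations.

eQTL epistasis scans face a brutal multiplicity problem: with *m* markers and
*G* expression traits, a direct two-locus scan performs `G * C(m, 2)` tests
(~879 million at the scale of a typical RIL transcriptome study with 493
markers and 7,244 expressed traits). `epinoia` attacks this on two fronts:

1. **Multi-trait complexes.** Traits are clustered by weighted co-expression
   network analysis (soft-thresholded `|r|^beta` adjacency, topological-overlap
   dissimilarity, top-down branch cutting) and each module is summarized by its
   first-principal-component **meta-trait**. Traits sharing an epistatic pair
   pool their signal, so small interaction effects that are invisible per trait
   become detectable per module.
2. **Hierarchical search with tree FDR control.** A coarse screen tests every
   (meta-trait, framework-marker-pair) combination on a sparse ~10 cM marker
   skeleton; only rejected combinations are followed up densely with the
   secondary markers inside the two framework regions. Both levels are tested
   with the Benjamini–Hochberg step-up procedure at a within-family level
   `q* = q / (2 delta)`, which bounds the FDR over the whole two-level tree of
   hypotheses by `2 * delta * pi * q*` (the family factor satisfies
   `delta <= 1.44`; it can also be estimated by permutation).

## The model

For a RIL population (homozygous lines, two genotype classes per marker) the
expression of trait *g* at loci *A*, *B* follows the NOIA
(natural-and-orthogonal-interactions) statistical model

    y = R + a_A x_A + a_B x_B + i_AB x_A x_B + e

where the genotype codes `x = -2 p2` (parent-1 allele) or `2 p1` (parent-2
allele) are centered at the observed allele frequencies. The codes make the
design columns orthogonal regardless of segregation distortion, so the
ordinary-least-squares estimates of the main effects `a_A`, `a_B` and the
epistasis coefficient `i_AB` are independent, `H0: i_AB = 0` is a plain t-test
on the interaction column, and each effect's **heritability** (its share of
the phenotypic variance, `SS_effect / SS_total`) is individually
interpretable and sums to the model R².

A simulation engine generates RIL genotypes along a genetic map (Haldane map
function with the RIL switch probability `R = 2r / (1 + 2r)`) and
cluster-correlated traits with implanted NOIA effects, and estimates the
power, FDR and heritability of the full pipeline over replicate simulations.

## Worked example

`examples/03_hierarchical_scan.py` simulates the study design (4 clusters of
15 traits, 211 lines x 2 replicates, 12 framework regions of 6 markers on 3
chromosomes) with a strong implanted interaction, builds meta-traits and runs
the two-stage scan:

```
implanted pairs: {1: ('c1r2m1', 'c2r2m1'), 2: ('c1r1m1', 'c1r3m1')}
level 1: 264 tests, 22 rejected at q* = 0.0347
level 2: 770 tests in 22 families, 744 rejected
total discoveries: 766; full-tree FDR bound 0.100
 level trait marker_a marker_b       pvalue    h2_ab
     2    M1   c1r2m2   c2r2m1 9.224912e-38 0.237927
     1    M1   c1r2m1   c2r2m1 9.224912e-38 0.237927
     2    M1   c1r2m1   c2r2m2 2.066852e-36 0.232906
```

The screen rejects the framework pair carrying each implanted interaction
(e.g. `c1r2m1 x c2r2m1` for meta-trait M1), the dense follow-up confirms the
surrounding secondary pairs, and the full-tree FDR stays bounded at the
requested q = 0.1. The other examples cover the expression filter and
clustering (`01`), a single NOIA fit with its heritability decomposition
(`02`), and a small power experiment (`04`). The same steps are scriptable
via the thin CLI: `epinoia cluster`, `epinoia scan`, `epinoia simulate`,
`epinoia qq`.

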