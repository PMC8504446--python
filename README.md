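# plastdeg

Comparative analysis of plastid-genome (plastome) degradation in
hemiparasitic plants: quadripartite structure detection, inverted-repeat
(IR) junction typing, four-state pseudogene calling, codon/GC and
rank-based statistics, and ancestral reconstruction of gene functional
loss on a phylogeny.

Plastomes of parasitic plants degrade as photosynthesis becomes
dispensable: genes — the NAD(P)H dehydrogenase-like (NDH) complex first —
pick up premature stop codons, truncate, and disappear, while the
boundaries between the inverted repeats (IRa/IRb) and the single-copy
regions (LSC/SSC) shift and capture genes into the repeat. `plastdeg`
packages the full desk analysis of such a dataset for a clade of
*Pedicularis* hemiparasites and its autotrophic relatives: it ships the
published 22-sample state/size tables and tree topology as fixtures, and
generates fully annotated synthetic plastomes with known ground truth to
validate every stage.

## Core models

* **Quadripartite detection** — the maximal pair of disjoint, exactly
  reverse-complementary arcs ≥ 1 kb on the circle (seeded k-mer match,
  maximal extension); junction types I–IV are called from the placement
  of the landmark genes *ycf1*, *ndhF*, *ndhH*, *ndhA*.
* **Degradation states** — per gene and taxon, a state in {0, 1, 2, 3}:
  functional / full-length with premature stop / truncated / lost, called
  from coverage, frameshifts and in-frame stops of the best alignment
  against an intact reference CDS.
* **Mk-ER likelihood** — k-state equal-rates Markov model,
  P_ii(t) = 1/k + (k−1)/k·e^(−kμt), Felsenstein pruning, uniform root
  prior, marginal (inside/outside) ancestral probabilities, μ fitted by
  bounded ML.
* **Dollo parsimony** — the derived state arises once, on the branch
  subtending the MRCA of the derived tips; reversals are allowed and
  minimized (each maximal all-ancestral subtree inside the origin clade
  reverts on its stem).
* **Rank statistics** — Spearman's ρ and the Mann–Whitney U (reported for
  the first sample, the R `wilcox.test` W convention).
* **NG86 screen** — pairwise Nei–Gojobori dN/dS with pathway averaging
  and Jukes–Cantor correction, as a light selection screen.

See `docs/methods.md` for assumptions, tunables and limitations.

## Worked example

```python
>>> from plastdeg import (binarize, dollo_reconstruct, fixture_table1,
...                       fixture_tree, mann_whitney_u, summarize_losses)
>>> from plastdeg.fixtures import NDH_GENES, SECT_CYATHOPHORA, OTHER_PEDICULARIS
>>> matrix, regions = fixture_table1()
>>> tree = fixture_tree()

# IR size: the 13 section-Cyathophora samples vs the 5 other Pedicularis
>>> mann_whitney_u(regions.loc[list(SECT_CYATHOPHORA), "ir_bp"],
...                regions.loc[list(OTHER_PEDICULARIS), "ir_bp"]).u
65.0

# Dollo reconstruction of functional loss: how many NDH genes were already
# non-functional in the ancestor of the section?
>>> b = binarize(matrix, "functional")
>>> results = {g: dollo_reconstruct(tree, b.column(g)) for g in NDH_GENES}
>>> summarize_losses(results, tree, SECT_CYATHOPHORA)
9

# ndhG: one loss, then three reversals within series Reges
>>> [tips for kind, tips in results["ndhG"].event_branches() if kind == "reversal"]
[frozenset({'P_thamnophila', 'P_aff_thamnophila'}), frozenset({'P_rex_var_rex'}),
 frozenset({'P_rex_var_rockii'})]
```

U = 65 is complete separation (13 × 5 pairs): every section-*Cyathophora*
IR is larger than every other *Pedicularis* IR. The Dollo result says
nine of the eleven NDH genes had already lost function in the section's
common ancestor, and that *ndhG* function was regained three times within
series *Reges*.

A command-line interface mirrors the library
(`plastdeg partition | irtype | genestate | rscu | stats | ancestral |
dnds | simulate | all`); `plastdeg all -o out/` with no inputs runs the
statistics and Dollo stages on the packaged study tables and writes TSV
reports plus a run manifest.

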