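# Methods

`plastdeg` re-implements, as a tested library, a comparative analysis of
plastid-genome (plastome) degradation in a clade of hemiparasitic plants
(*Pedicularis* sect. *Cyathophora* and relatives): quadripartite structure
and inverted-repeat (IR) junction architecture, four-state pseudogene
calling, codon/GC statistics, rank-based comparisons, and ancestral
reconstruction of gene functional loss. This note documents the models,
the numerical choices, and what the synthetic data do and do not show.

## Quadripartite structure detection

A plastome is modeled as a circle partitioned into LSC, IRb, SSC and IRa,
with IRa the exact reverse complement of IRb. Detection finds the
maximal-length pair of disjoint, exactly reverse-complementary arcs of
length ≥ `min_len` (default 1,000 bp): non-overlapping 24-mers of the
doubled sequence are matched against a hash of the doubled reverse
complement, and each seed is extended mismatch-free in both directions
(capped at one genome length). Doubling handles origin-crossing repeats;
arcs are reduced mod genome length and deduplicated.

Choices:

* **Exact matching, no mismatch tolerance.** The two IR copies of a single
  plastome are essentially always identical, and exactness keeps the
  detection oracle trivial (the generator knows the planted coordinates).
  A tolerance flag is reserved for future use.
* **Ties** (co-maximal non-nested pairs) break to the pair with the smaller
  canonical start coordinate; this is deterministic and has no effect on
  realistic inputs.
* **Labeling.** The longer single-copy gap is the LSC; IRb is the IR copy
  immediately upstream of the SSC on the forward strand. The canonical
  rotation places the LSC start at offset 0, in the order
  LSC → IRb → SSC → IRa. Detection is rotation-invariant and covariant
  under strand flip (IRa/IRb labels swap; lengths are preserved).

## IR junction typing

Four junction architectures are distinguished by the placement of the
landmark genes *ycf1*, *ndhF*, *ndhH* and *ndhA* relative to the IR:

* **I** — *ycf1* spans the IRb/SSC junction; *ndhF*, *ndhH*, *ndhA* fully
  in the SSC (the widespread angiosperm arrangement).
* **II** — *ycf1*, *ndhF*, *ndhH*, *ndhA* all captured into the IR.
* **III** — *ycf1*, *ndhH*, *ndhA* in the IR; *ndhF* not.
* **IV** — *ycf1*, *ndhH* in the IR; *ndhA* in the SSC with inverted
  orientation.

A gene counts as "inside" a region when ≥ 95% of its span lies there and
as junction-spanning when both sides hold ≥ 5%. The source analysis never
quantifies these cutoffs; the 95/5 split tolerates small annotation jitter
without affecting any genuine case. Pseudogene remnants count as landmarks
as long as they are annotated (the evidence list records every copy
consulted). "Inverted" orientation of *ndhA* is judged relative to the
annotated strand of *ndhF*, which shares a strand with *ndhA* in the
type-I/II arrangement; without an *ndhF* annotation type IV is not called.

## Gene degradation states

Each target gene is scored on the four-state code: 0 functional, 1
full-length with a premature stop codon, 2 truncated, 3 complete loss.
Calling works against an intact reference CDS from a designated
all-functional reference taxon:

1. **Location** — exact 15-mer seeds (step 6) chained on diagonals
   (band 60 bp, tolerating indels), extended exactly at the ends, then
   globally aligned over the chained span with edlib. Coverage is the
   chained fraction of the reference; identity is matches over alignment
   columns; frameshifts are indel runs with length ≢ 0 (mod 3); in-frame
   stops are counted on the coding strand in the reference frame,
   excluding the gene's own terminator. A hit must reach 60% identity
   over ≥ 50 bp, otherwise the gene is absent.
2. **Classification** — no hit → 3; coverage < 0.90 → 2; coverage ≥ 0.90
   with stops or frameshifts → 1; coverage ≥ 0.95 with intact start
   (ATG/GTG/TTG, the plastid convention) and stop codons and no defects
   → 0. Full-length hits with eroded termini are called 2. Coverage in
   [0.90, 0.95) without defects is called 0 with a "borderline" warning.
   The thresholds are configurable; the defaults separate the verbal
   categories (full-length / truncated / lost) cleanly on scripted edits.
3. **IR duplicates** — both copies are called independently and the taxon
   receives the least degraded state: a functional copy anywhere implies
   function.

Translation uses the bacterial/plastid code (table 11).

## Codon and GC statistics

RSCU(c) = count(c) × family size / family total, pooled over all CDS of a
sample (per-gene mode by flag); stop codons are excluded and the
single-codon families (Met, Trp) are fixed at 1 and flagged
uninformative. GC content is (G+C)/(A+C+G+T) with N excluded, optionally
restricted to a codon position. The GC-by-gene-group matrix pools the CDS
of each group (atp, ndh, pet, psa, psb, rpl, rps, rpo, clp, ycf, plus
single-gene groups) and reports deviations from the per-group mean across
samples, which center to zero by construction.

## Rank statistics

Spearman correlation (average ranks, t-approximation with n−2 df) and the
two-sample Mann–Whitney U, reported for the first sample — the convention
of R's `wilcox.test` W, which the study's printed values follow. Ties
contribute ½ per tied pair. The p-value is exact when n₁+n₂ ≤ 20 without
ties and otherwise uses the tie- and continuity-corrected normal
approximation. Both statistics are computed by scipy behind this
contract; the test suite checks them against independent brute-force
oracles (pairwise counting, full permutation enumeration at n₁+n₂ ≤ 8,
rank-then-Pearson).

## Ancestral reconstruction

The four-state matrix is collapsed to binary under three schemes:
functional (0 vs 1/2/3), complete (0/1 vs 2/3), existing (0/1/2 vs 3).

**Mk equal-rates (ER).** All transitions share one rate μ, giving the
closed-form kernel P_ii(t) = 1/k + (k−1)/k·e^(−kμt),
P_ij(t) = (1 − e^(−kμt))/k. Likelihoods use Felsenstein pruning with
per-node rescaling; the root prior is uniform (1/k). The state space is
fixed a priori — k = 4 for multistate runs, k = 2 for binarized runs —
regardless of which states happen to be observed. Marginal (not joint)
reconstruction is reported, from the standard inside/outside two-pass
algorithm; tip marginals recover the observed states. μ is fitted by
bounded scalar search on [10⁻⁸, 10³] (tolerance 10⁻⁸). Because the
likelihood flattens into an independence plateau for large μ, a naive
golden-section over eleven decades can converge onto the plateau; the fit
therefore brackets the optimum on a 45-point log-spaced grid before
refining. Invariant characters drive μ̂ to the lower bound and are
flagged. Branches without lengths are treated as 1.0 with a warning.

**Dollo parsimony.** The derived (non-functional) state arises exactly
once — on the branch subtending the MRCA of all derived tips (the root if
that MRCA is the root) — and reversions to the ancestral state are
allowed and minimized: inside the origin clade, every maximal subtree
whose tips are all ancestral receives one reversal on its stem. This
attains the single-origin minimum event count (verified exhaustively on
random six-taxon cases). Reversions-allowed semantics are required for
internal consistency: the reconstruction's own reversal events (e.g.
three *ndhG* reversals within series *Reges*, one *ndhK* reversal in
clade I) are part of the study's results.

## Nei–Gojobori dN/dS screen

A deliberately lightweight pairwise screen, not a branch-site selection
test: per-codon synonymous/nonsynonymous site fractions (changes to stop
codons count as nonsynonymous), pathway-averaged difference counts for
codons differing at 2–3 positions (pathways through stops excluded, with
an include flag; both substitution directions averaged so the statistic
is symmetric), site counts averaged between the two sequences, and
Jukes–Cantor correction d = −¾·ln(1 − 4p/3). Proportions at or beyond ¾
raise a saturation error; ω is undefined when dS = 0. Raw counts are
available separately for degenerate inputs (e.g. single-codon pairs).

## Synthetic data

The generators define the conditions under which the pipeline is tested.

* **Trees** — Yule (pure-birth), rescaled to height 1, so rates are in
  units of expected changes per tree depth.
* **Mk characters** — simulated with the mixture form of the ER kernel
  (copy parent with probability e^(−kμt), else uniform); node truth
  retained. Rate-recovery checks pool 200 characters on 64-tip trees at
  μ = 0.5.
* **Dollo characters** — at most one origin per character (branch drawn
  proportionally to length), independent per-branch reversals below it;
  the event script is retained.
* **Plastomes** — assembled as LSC + IRb + SSC + revcomp(IRb) from a gene
  table with the canonical junction flanks (…*rps19* | *rpl2*… and
  …*rpl2* | *trnH-GUG*…), one template per junction type. CDS are
  stop-free with ATG start and TAA stop; codon usage is solved so its
  expected GC matches each region's target (0.36/0.43/0.33 for
  LSC/IR/SSC, matching the magnitudes and ordering of real plastomes),
  and spacer composition absorbs the remaining GC budget so each region
  hits its target to within rounding. Gene lengths follow typical plastid
  values scaled into a ~45–55 kb genome — one third of a real plastome —
  which keeps the default suite fast without changing any detection or
  calling logic; lengths are config-exposed. Bases flanking the planted
  IR pair are pinned non-complementary so maximal extension stops exactly
  at the designed junctions. Scripted edits (premature stop, 5'/3'
  truncation, deletion) are applied to the gene sequences before
  assembly; edits to IR genes propagate to both copies.

What the generator does **not** emulate: substitution divergence between
reference and target beyond the scripted edits, intron structure, RNA
editing, intergenic sequence evolution, annotation error, or IR copies
that differ from one another. Passing the recovery tests therefore shows
that the machinery is correct under clean conditions, not that the
thresholds are optimal for noisy real annotations.

## Packaged study fixtures

The published 22-sample × 13-gene state matrix (11 NDH genes + *accD* +
*ccsA*; unlisted genes functional, outgroups fully functional) and the
region size/GC table are transcribed verbatim; a documented errata list
covers the places where the source's table and running text disagree
(`plastdeg.fixtures.FIXTURE_ERRATA`). In particular, *ndhG* of *P. rex*
var. *rex* is analyzed as functional — the running text and the reported
three Dollo reversals in series *Reges* require it — while the printed
table value (2) is stored unchanged. The tree topology is assembled from
the published clade statements, with (*P. insignis*, *P. przewalskii*)
as a sister pair to the section (required for the nine-gene ancestral
count under Dollo) and unit branch lengths throughout, since the original
ML branch lengths were not published. Likelihood-based node supports are
therefore qualitative here: the *ccsA* reversal signal concentrates at
the clade-III ancestor (an order of magnitude more functional probability
than at the section ancestor), but the published numeric support is not
reproducible without the original branch lengths.

## Problem sizes and runtime

The default test suite runs in well under a minute on one CPU: synthetic
plastomes are ~50 kb, the exhaustive oracles use ≤ 6-tip trees, the
rank-statistic oracles use ≤ 30 observations, and rate recovery uses five
replicates of 64 tips × 200 characters. `scripts/acceptance.py` repeats
the headline computations from scratch (four junction types × five seeds,
208 scripted gene-state calls, five rate-recovery replicates) in a few
seconds.

## Known limitations

* Exact IR matching will fragment the repeat if the two copies genuinely
  differ; the caller then sees the longest exact sub-repeat.
* The degradation caller assumes the reference CDS is homologous and
  close to the target (it is a within-genus screen, not a remote-homology
  search); at high divergence the 60%-identity floor makes genes appear
  lost.
* The dN/dS screen is pairwise NG86 with Jukes–Cantor correction only; it
  is not a substitute for codon-model selection tests and none of the
  published relaxation coefficients are reproduced.
* Equal-rates likelihood on a unit-length topology is a coarse stand-in
  for the original ML tree; Dollo counts are robust to this, marginal
  probabilities are not.
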