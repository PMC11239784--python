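# Methods

## Overview

The package implements the sequence–structure evidence chain used to carve
new subfamilies out of the α-amylase family GH13: reduce a homolog set to
representatives, anchor the family's conserved sequence regions (CSRs)
onto an alignment, quantify subfamily-specific motif conservation, check
discriminability with per-subfamily scoring profiles, confirm grouping by
a bootstrapped distance phylogeny of the catalytic-barrel region, and
corroborate relatedness by Cα superposition of representative structures.
This note records the models, parameter choices and their limits.

## The CSR coordinate system

GH13's seven CSRs tile a 52-position logo coordinate system in
N→C-terminal order CSR-VI (1–9), CSR-I (10–15), CSR-V (16–20), CSR-II
(21–29), CSR-III (30–37), CSR-IV (38–43), CSR-VII (44–52). The catalytic
triad sits at fixed coordinates inside it: nucleophile Asp 25, proton
donor Glu 34, transition-state stabilizer Asp 43. One auxiliary anchored
position, `preCSRV`, is the residue immediately N-terminal to logo 16; in
the maltogenic-amylase subfamily it carries the Asp of the non-reducing-end
carbohydrate-binding site. Anchoring takes a reference sequence plus a
logo-position→ungapped-residue map (a config file, because reference
residue numbering is structure-specific), validates D/E/D at the triad
(overridable for aberrant-triad members, which do occur in the family),
and maps each logo position to the reference residue's alignment column.
Anchoring is equivariant under gap-column insertion, so the extracted
52(+aux)-column block is independent of alignment padding.

Gap semantics are uniform: gaps and `X` never satisfy a conservation or
fingerprint constraint, and both are excluded mass in position frequency
tables (frequencies are renormalized over the 20 canonical residues).
Logo tables use IC_p = log₂20 − H_p (bits) with letter heights f·IC; the
small-sample correction is off by default, and all-gap columns carry IC 0
by convention.

## Clustering

Greedy centroid clustering mirrors incremental identity clustering:
sequences ordered by decreasing ungapped length (ties lexicographic),
first-match assignment in centroid creation order (best-match available as
an option). Identity = identical columns of an optimal global alignment ÷
shorter ungapped length, with BLOSUM62, gap open 10, gap extend 0.5 — the
conventional defaults, chosen here because identity-threshold clustering
conventions, not alignment subtleties, dominate the outcome. `X` never
counts as identical, so unknown residues cannot inflate identity. No k-mer
prefilter is implemented; target set sizes are hundreds to low thousands.

## Profile classification

Each subfamily's anchored CSR block yields a position-specific log-odds
profile: score(p,a) = log₂(f′/q) with f′ = (n_{p,a} + βq_a)/(N_p + β),
uniform background q = 1/20, pseudocount mass β = 1. Gap/`X` positions add
a fixed −2-bit penalty; all-gap positions are neutral. A query is assigned
to the top-scoring profile only when the margin over the runner-up is at
least δ = 5 bits and the top score is positive, otherwise "unassigned";
ties break lexicographically. A PSSM rather than a profile HMM is used
deliberately: anchoring fixes the residue-to-position correspondence, which
is the indel problem an HMM's insert/delete states exist to solve, and the
per-position constraint information is the same. β, q, δ and the gap score
are configurable; the defaults are conservative (δ = 5 bits demands a
32-fold likelihood-ratio advantage).

## Phylogeny

The alignment is trimmed to the inclusive column span from logo 1 (start
of CSR-VI, barrel strand β2) to logo 52 (end of CSR-VII, strand β8) — the
catalytic TIM-barrel including domain B — to maximize signal over the
noisy termini. Distances use pairwise deletion (per-pair complete columns;
`X` is comparable but always mismatches) as p-distance or Poisson-corrected
−ln(1−p) with p capped at 0.95 before correction; pairs with no comparable
columns are an error. Tree search is Saitou–Nei neighbor joining with the
Q criterion, deterministic smallest-(i,j) tie-breaking, and negative branch
lengths clamped to zero with the deficit moved to the sibling so the joined
pair's distance is preserved. NJ is exact on additive matrices (tested to
1e-9). Supports come from column-resampling bootstrap: the support of each
internal split of the full-data tree is the percentage of replicate trees
containing it; 100 replicates by default at desk scale, 500 available.
Distance NJ stands in for maximum-likelihood search by design: the
acceptance surface here is group separation, which is method-robust,
whereas an ML engine is a separate engineering domain. Multiple sequence
alignment construction is likewise out of scope — the pipeline consumes
precomputed alignments (synthetic data ships ground-truth ones).

## Superposition

Residue correspondence between two Cα traces comes from a global sequence
alignment of the domain-restricted sequences (the compared proteins are
homologous; structure-based alignment engines are out of scope). Domain
boundaries (the canonical A+B+C domains) are supplied per structure as
residue-number intervals. The rigid fit is the closed-form Kabsch solution
with the determinant correction excluding reflections; iterative pruning
refits after discarding pairs beyond a cutoff (default 2.0 Å, the
conventional default of interactive structure-comparison tools) until the
pair set is stable or ≤3 pairs remain. Retained-pair RMSD is
non-increasing across iterations, and an infinite cutoff reduces to plain
Kabsch. Degenerate (collinear, <3-pair) inputs raise errors.

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes —
and only that. Four classes (GH13_48-like, GH13_49-like, GH13_38-like, an
unlabelled intermediary group) of length-210 sequences carry the 52 CSR
positions (plus `preCSRV`) at fixed scaffold sites; each CSR position emits
a residue from its class's allowed set with its conservation probability
c, else a uniform non-member; non-CSR positions are uniform background;
the triad is emitted deterministically (an aberrant-triad variant flag
exists). Default class sizes are 300/40/3/2. Conservation probabilities in
the shipped config are set from the subfamilies' reported motif
conservation levels; for a k-position motif the per-position probability
is the k-th root of the motif-level fraction, so that independent
per-position emission reproduces the motif-level conservation (e.g. L-[DN]
joint 0.862 → 0.92835 per position; [WY]-[GA] 0.9756; Asp33 and Glu40
0.9512; Cys24 0.81; GQ 0.855; `preCSRV` Asp 0.954). Positions typical of
most GH13 subfamilies (NH 14–15, GXR 21–23, NHD 41–42) are set at 0.95 and
remaining CSR positions default to 0.85. Within an allowed set the first
(consensus) residue has weight 4, alternatives weight 1. All generators
are pure functions of (parameters, seed).

What the generator does **not** emulate: phylogenetic correlation (classes
are i.i.d. around a consensus, so bootstrap supports and classification
margins on synthetic data are optimistic relative to real, tree-structured
sequence sets); realistic background composition; indel structure inside
CSRs; within-class identity levels of real subfamilies (the uniform
background makes non-CSR positions nearly random, so greedy clustering of
synthetic sets at 50 % mostly yields singletons — the clustering tests
therefore check the ClusterSet contract, not cluster counts). Passing
tests demonstrate correctness of the machinery and recoverability of the
configured conservation regime, not performance on real family data.

## Problem sizes and numerics

The default test and acceptance runs use the full 345-sequence benchmark
(LOO classification and a 100-replicate bootstrap NJ over 345 taxa run in
seconds to tens of seconds on one CPU); oracle-based exactness checks use
4–8 taxa, 30-mers and toy point sets. Distance computations are one-hot
matrix products in float32 (exact for the integer match counts involved);
Kabsch uses SVD with a 1e-12 singular-value floor for degeneracy
detection; frequency tables guard all-gap columns; the pipeline report is
written with sorted keys and no timestamps so reruns are bit-identical.

## Known limitations

- Real-data anchoring needs a curated reference logo→residue map; none is
  shipped for experimental structures (deriving one requires the structure
  and literature domain boundaries).
- First-match greedy clustering is input-order dependent by construction
  (as in the tool it mirrors); representative counts are therefore not
  comparable across orderings.
- The margin-based "unassigned" rule has no E-value calibration; δ is a
  bits threshold, not a significance level.
- Sequence-based residue pairing can differ from structure-based pairing
  in regions of low sequence similarity, shifting matched-Cα counts for
  remote homolog pairs.
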