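# Methods

This note records the models, parameter choices and numerical conventions
behind `motifthread`, and what the synthetic test conditions do and do not
demonstrate about real data.

## Model overview and assumptions

The pipeline assumes that a TF's sequence preference is encoded in the
atomic contacts of a single static TF-DNA complex: if the bases of the
bound duplex are replaced by every possible sequence while protein, sugar-
phosphate backbone and interface waters stay fixed, a statistical potential
over protein-DNA atom pairs can rank the threaded models by relative
binding strength. This is a direct-readout model; indirect readout (DNA
shape, bending, sugar pucker) is deliberately out of scope, as is homology
modeling of the complex itself — the package consumes a ready structure and
exposes the curated complex as the hook where an external modeling adapter
could attach.

## Curation

* Resolution filter 2.5 Å (read from `REMARK 2`; structures without a
  recorded resolution pass, since synthetic and model coordinates have
  none).
* Contact rule: any protein-DNA heavy-atom pair at d ≤ 4.5 Å; the boundary
  is inclusive. All DNA atoms count, base and backbone alike, because the
  rule is defined over "any" atom pair; this choice changes k for real
  structures and is therefore isolated in `contacting_positions`.
* A contact to either strand marks the base-pair position; positions are
  counted once on the reference strand (the first DNA chain in the file),
  5′→3′.
* The trimmed stretch is made contiguous: interior non-contacting bases are
  kept, because a duplex with holes cannot be threaded. k is the length of
  that stretch and must be ≤ 9 for enumeration (4⁹ = 262,144 models).
* Strand pairing is antiparallel by residue order, validated by ≥ 60%
  Watson-Crick complementarity; a previously trimmed complex whose mate
  chain is stored pairing-ordered is detected by trying both orientations.
* Interface waters (within 4.5 Å of both protein and DNA) are retained by
  default; they are geometry only and are never scored.
* Hydrogens are ignored everywhere; only heavy atoms enter contacts and
  scoring.
* Protein-chain selection on `curate_complex` covers the obligate-homodimer
  case: by default all protein chains are one TF unit.

## Base templates and threading

Replacement bases are idealized planar heavy-atom templates built
analytically: rings are regular polygons with 1.39 Å sides (hexagon for
pyrimidines; edge-fused pentagon + hexagon for purines) and exocyclic
substituents lie on the radial direction of their ring atom (C-N 1.35 Å,
C=O 1.23 Å, C-CH₃ 1.50 Å). This was a deliberate design choice over
copying a crystallographic geometry table: the analytic construction is
exactly planar (the ring-coplanarity invariant holds by construction), has
well-defined anchor triads, and keeps the fixtures self-consistent, while
agreeing with tabulated base dimensions to ~0.1 Å — well below anything the
binned potential can resolve.

Anchor triads are N9-C8-C4 (purines) and N1-C6-C2 (pyrimidines): the
glycosidic nitrogen and its two bonded ring carbons. Purine↔pyrimidine
swaps map triad atoms positionally (N9↔N1, C8↔C6, C4↔C2), preserving the
glycosidic direction. The triad atoms themselves are retained in place
(renamed when the base class changes); only atoms beyond the triad are
rebuilt, via a proper Kabsch superposition of the template triad onto the
retained one (SVD with reflection correction; collinear triads are
rejected). C1′ is not part of the fit — the triad alone already fixes the
base frame.

The clash relaxer is a simplified stand-in for a force-field minimization:
soft-sphere repulsion Σ max(0, rᵢ + rⱼ − d)² over inter-residue pairs
involving at least one swapped-base atom, minimized by line-searched
gradient descent (≤ 100 steps, step halving up to 25 times), moving base
atoms only. The energy is monotonically non-increasing by construction and
clash-free models are returned untouched. Pairs between two frozen atoms
are excluded from the energy: they are constants the relaxer cannot
change, and including, e.g., covalently bonded backbone neighbors would
make "clash-free" unreachable on real chains.

## The pair potential

Atom typing is (residue name, atom name) on the protein side and (base
letter, atom name) on the DNA side — the finest typing the phrase
"residue-specific" supports; pooling schemes can be swapped behind the
`PairPotential` abstraction. Distances up to 10 Å map to 8 bins (3 Å, then
7 × 1 Å). Energies are

    e = −ln[(N + σ) / (N_exp + σ)],  N_exp = N(tp,td,·) · N(·,·,bin) / N(·,·,·)

with pseudocount σ = 1. The reference state (pair-type marginal × distance
marginal) is a standard choice for distance-dependent statistical
potentials; the exact reference of the original potential is not specified
by its description, so the choice is documented here and isolated in
`train_potential`. Unobserved pair types have N = N_exp = 0 and energy
exactly 0. A `self_swapped` training flag rebuilds each training complex's
bases onto their own backbone before counting, emulating training on
self-modeled rather than raw crystal geometry.

Scoring sums energies over all in-range protein-DNA heavy-atom pairs with
`math.fsum`, so the result is independent of pair enumeration order and
bit-identical to the brute-force double-loop oracle used in tests. The
neighbor search is a k-d tree at the 10 Å cutoff (an off-the-shelf,
deterministic structure; the tests enforce oracle bit-identity, which is
the actual contract). Waters, ions and unknown residues never enter the
sum; unknown DNA residues warn (or raise in strict mode).

## Affinities and PWM construction

S_norm is the min-max normalization of S_RV over the full enumeration
(affine-invariant; a table with all scores equal raises rather than
emitting a flat motif, since the pipeline presumes specificity). K_a =
exp(−A/(k_B T)·S_norm) with A = 4.74 kcal/mol, T = 298 K and k_B fixed at
1.9872041e−3 kcal/(mol·K) so that A/(k_B T) ≈ 8.004 is reproducible.
Sites require K_a ≥ γ = 0.25 — the boundary is inclusive, resolving the
ambiguous "above the cutoff" in the inclusive direction — sorted by K_a
with lexicographic tie-break, capped at 300. PWM columns are K_a-weighted
base frequencies; with fixed-position enumeration all k-mers are already in
register, so no alignment step is needed. Written motifs carry 8-decimal
frequencies (and a large `nsites` in MEME minimal output) so both dialects
round-trip within 1e−6 through count-based readers.

## Motif similarity and clustering

Each sliding alignment (both strands, overlap ≥ 3 columns — short 3-bp
motifs are real and must remain comparable) reduces the aligned columns to
consensus match/mismatch counts m of L, tested one-sided against the 2×2
table [m, L−m; round(L/4), L−round(L/4)]. The consensus-match construction
is the package's choice of how to form a 2×2 table from two PWMs (the
operation only requires something exact, parameter-light and monotone in
similarity); alternates can be swapped behind `fisher_slide_compare`.
P-values come from the hypergeometric tail and are cached by (L, m).

Z-scores: the null is the all-against-all comparison set within the decoy
motifs, restricted to pairs whose best alignment has the same overlap L as
the observed comparison (widened ±1 column at a time until ≥ 8 null points
exist). Both observed and null values are the same best-over-alignments
statistic, which is what makes the calibration honest: with the null drawn
from single fixed-length comparisons instead, the optimized observed
statistic is biased high and the false-positive rate at Z ≥ 2 triples or
worse. Z is computed on −log10 p (approximately normal over the null),
capped at 10. Measured on 1000 random motif pairs against a 36-decoy set,
P(Z ≥ 2) = 0.052 — consistent with the 95%-confidence interpretation of
the Z = 2 cutoff.

Decoy sets are built greedily in input order, rejecting any candidate whose
best p against a retained decoy is < 0.05 (the reject-similar reading of
the redundancy rule — the reading that actually yields non-redundancy).

Distances D = |Z − 10|/11.1 (10 = the Z cap; 11.1 = the fixed observed
range, treated as a constant of the transform, giving D = 1 at Z = −1.1).
UPGMA is implemented directly — deterministic tie-breaking by smallest leaf
label is required for reproducible trees — and cross-checked against an
independent average-linkage implementation in tests. Node height is half
the merge distance, so cutting at D(Z=2)/2 makes "pairwise distance ≤
D(Z=2)" equivalent to "merged below the cut".

## Promoter scanning

Promoters are [TSS−1500, TSS+500) on the + strand and the mirrored,
reverse-complemented window on the − strand; coordinates are 0-based
half-open internally (BED native, GFF3 shifted at the parser). Contig-edge
windows are clipped and flagged. Match scores follow the frequency-sum
description (a log-odds variant would slot in behind the same
`ScoreDistribution` interface); the null is an exact position-wise
convolution on a 1e−4 score grid against an iid background estimated from
the scanned promoter set (overridable). Scanned windows are scored on the
same integer grid, so reported p-values are exactly the tail of the null at
the window's score with no float-rounding mismatch. Windows containing
ambiguous bases are skipped. The per-window threshold p ≤ 1e−4 is applied
with no multiple-testing correction, matching the method's fixed-cutoff
design. Genes with several promoters collapse by best hit.

## Synthetic test conditions

The fixtures emulate exactly the features the pipeline's statistics see:
typed heavy atoms at controlled distances (a straight untwisted duplex,
rise 6 Å, strands 12 Å apart with bases pointing outward, and one small
probe residue of a distinct residue type per contacted position), planted
potentials whose energies live only in the < 5 Å bins so position scores
are exactly additive, Dirichlet-random PWMs, and random genomes with
planted words. They do not emulate real interface geometry, base stacking,
water-mediated readout, correlated promoter composition, or the noise of
trained potentials on small structure sets — so passing tests demonstrate
algorithmic correctness (each stage equals its independent oracle and
recovers planted ground truth), not predictive accuracy on crystal
structures. Problem sizes used by the default suite and the acceptance
script (k = 3–5 pipelines, 8-column motifs, 40-decoy calibrations, 10-gene
genomes, 1e5 Monte-Carlo draws) were chosen as the smallest sizes at which
every statistical property under test is well-resolved.

## Known limitations

* No indirect readout: DNA shape and deformation energetics are absent by
  design.
* The soft-sphere relaxer resolves overlaps but does not re-optimize
  side-chain or base geometry; a real minimizer can be plugged in where
  `relax_clashes` sits.
* The potential's absolute energies depend on the training set; only
  relative rankings within one enumeration are meaningful.
* Redundancy removal for protein sequences is a greedy global-identity
  stand-in for cd-hit, adequate for de-duplication but not a reimplementation
  of its word-filter algorithm.
* GFF3 TSS parsing reads `gene`/`mRNA`/`transcript` features with simple
  `ID=`/`Name=` attributes; richer annotation models belong upstream.
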