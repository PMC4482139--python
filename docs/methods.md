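# Methods

## Peak matching model

Two HSQC spectra of the same construct, acquired independently, show the
same amide cross-peak at slightly different coordinates (temperature,
referencing and shimming differences). We therefore model correspondence as
a hard per-axis tolerance box — a reference peak and a query peak may pair
only if |Δδ_H| ≤ `tol_h` and |Δδ_N| ≤ `tol_n` — and choose among admissible
pairings the one-to-one assignment that first maximises the number of pairs
and then minimises the total combined distance

d(a, b) = sqrt( (δ_H(a) − δ_H(b))² + (w_N · (δ_N(a) − δ_N(b)))² ),

the standard chemical-shift-perturbation metric with nitrogen weighting
w_N = 0.14 (the ¹⁵N shift range is roughly 7× the ¹H range). Defaults
`tol_h` = 0.03 ppm, `tol_n` = 0.3 ppm follow common CSP practice. The
assignment is solved exactly with the Hungarian algorithm on a cost matrix
in which out-of-box pairs carry a cost larger than any feasible total, which
makes "maximise cardinality, then minimise cost" a single minimisation. Peaks
are sorted by id before the solve so ties resolve reproducibly. The test
suite checks the solver against an exhaustive bitmask dynamic program on
lists of up to 12 peaks.

Unmatched query peaks are classified *appearing*, unmatched reference peaks
*disappearing*. A matched pair whose distance is large but inside the box is
still a match; we do not split large shifts into an appear/disappear pair.
This is a deliberate reading: visual superimposition of spectra cannot
distinguish "one peak moved far" from "one vanished and another arose", and
the conservative choice keeps the two categories disjoint.

## Attribution by set subtraction

The analysis assumes *independence*: each substitution perturbs its own
local environment, so the change set of a multi-SNP haplotype versus wild
type is the disjoint union of its members' signatures. Under that
assumption, subtracting the change set of a sub-haplotype (tolerance-matched
peak by peak, min-cost assignment deciding any ambiguity) leaves exactly the
signature of the remaining substitutions. `attribute_all` orders haplotypes
by size and peels to a fixpoint: singles are read off directly; a haplotype
with one unattributed member has its attributed components subtracted and
the remainder credited to that member. Two kinds of redundancy become
consistency checks rather than inputs: a haplotype whose members are all
attributed must subtract to an empty set, and a direct variant-vs-variant
comparison spanning one extra substitution must reproduce that
substitution's signature (we count the symmetric difference under matching
as the residual). `additivity_check` audits the assumption itself: observed
counts minus summed component counts per haplotype, zero iff effects are
disjoint. On deliberately overlapping planted effects the discrepancy is
reported, never raised.

All attribution is anchored at the wild-type reference; variant-vs-variant
comparisons are used only as consistency evidence. Attribution assigns peaks
to substitutions, not to residues — that would require backbone assignments.

## Synthetic families and the identifiability guarantee

The generator exists to make the attribution logic *provably* testable. A
scenario plants, per substitution, `n_disappear` removed base peaks and
`n_appear` new peaks; the reference scenario uses the characteristic counts
of the three MYLK SNPs (S147P 5/5, P21H 1/3, V261A 2/2) on a 200-peak base
spectrum — a plausible peak count for constructs of a few hundred residues —
inside the acquisition window of 14 ppm ¹H (centred 4.7) × 36 ppm ¹⁵N
(centred 118). Two constraints make recovery exact rather than approximate:

* every pair of true peak positions is at least `min_separation` = 0.12
  apart in combined distance, which exceeds twice the combined tolerance
  radius sqrt(0.03² + (0.14·0.3)²) ≈ 0.052, so no peak can be captured by a
  neighbour's box;
* positional jitter is a truncated Gaussian (sd 0.005 ppm ¹H / 0.05 ppm ¹⁵N
  = tolerance/6, clipped at ±2.8 sd), so two independently jittered copies
  of the same peak differ by less than 0.94× the per-axis tolerance and
  always re-match. An unbounded Gaussian would violate this at rare seeds;
  clipping exactly at 3 sd puts the worst case on the tolerance boundary
  where floating-point rounding decides, hence the 2.8.

Each haplotype's list is jittered independently, modelling independently
acquired spectra; the planted effect sets themselves are drawn once per
substitution so that all haplotypes agree on them, and effects of distinct
substitutions touch disjoint peaks. `truncate_to_segment` emulates a shorter
construct: a shared random subset of base peaks (planted peaks of in-segment
substitutions always retained, out-of-segment planted peaks dropped),
rebuilt from the clean coordinates and given one fresh jitter — so a
truncated list is again within a single jitter of truth and matches its
full-length counterpart completely.

What the generator does **not** emulate: line widths and intensities,
chemical-shift physics (appearing peaks are placed anywhere admissible, not
where a real conformational change would put them), peak overlap in crowded
regions (an optional 8.0–8.6 ppm density boost exists, but separation is
still enforced), and spectral artefacts. Passing tests therefore demonstrate
the correctness of the matching/attribution logic under the independence
assumption, not robustness to real spectral crowding or exchange broadening.

## Motif engine

Motifs are position constraints around the phosphoacceptor (S or T — the
acceptor may be threonine throughout, as at T151): mode-1 14-3-3 RXXSXP
(R −3, P +2), mode-2 RXXXSXXP (R −4, P +3), CaMK2 RXXS, AGC RXXXS, GSK3
SXXXS with the +4 serine/threonine as the required pre-existing phosphosite.
Relaxed mode definitions without the proline are available but off by
default; GSK3's reported preference for a +1 proline is annotated on hits
but never required. `propagate_priming` seeds the phosphosite set from the
selected primary-kinase consensus hits plus any supplied sites, then closes
under the GSK3 rule (add any S/T whose +4 position is phosphorylated). Each
iteration adds at least one site, so the fixpoint is reached in at most
len(sequence) iterations, and since the rule is monotone the result is
independent of iteration order; provenance records chains such as
26 → 22 → 18. 14-3-3 hits are *satisfied* only when their acceptor is in
the closed phosphosite set, and every unordered pair of satisfied hits at
distinct acceptors is reported as a candidate bidentate engagement of a
14-3-3 dimer. Variant impact diffs satisfied hits, cascade-derived sites and
bidentate pairs between the reference and each edited sequence; it deals in
motif presence only and claims nothing about in-cell phosphorylation or
site accessibility.

## Superposition

Kabsch superposition: centre both coordinate sets, take the SVD of the
covariance matrix, and correct the sign of the smallest singular axis if the
optimal orthogonal matrix would be a reflection (determinant −1), yielding
the least-squares optimal proper rotation. Atom pairing is positional within
the filtered selection (default backbone N/CA/C/O, CA-only and all-atom
selectable) — the compared structures are models of the identical sequence,
so no alignment is performed. `range_rmsd` measures over a 1-based inclusive
residue range after fitting on the range itself, on the whole structure, or
not at all. Collinear inputs are warned about (the rotation is then not
unique) but the RMSD remains a least-squares optimum. Published RMSD values
for this system derive from homology models that were never deposited, so no
numeric comparison to them is attempted; the module is validated by
invariance, optimality and symmetry properties and against a generic
numerical minimiser over rigid motions.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline on 200-peak spectra
(five haplotypes, ≈ 10 pairwise 200×200 matchings per family), 200 random
small-list matcher-oracle trials, 200 random sequences of length ≤ 500 for
the motif oracle, and 60 Monte-Carlo replicates for the displacement-RMSD
calibration; the whole suite completes in a few seconds. Matching costs are
exact floats; the only tolerance beyond the matching box itself is 1e-9 Å
on rigid-motion RMSD identities. Degenerate inputs (empty lists, empty
haplotypes, zero-peak scenarios) are defined rather than rejected wherever a
sensible identity exists; an empty truncated list in subset recapitulation
returns fraction 1.0 with a warning.

## Known limitations

Attribution requires a haplotype chain that isolates each substitution; a
family like {WT, double} raises rather than guessing. The generator's
guarantees are conditional on its own separation/jitter constraints —
violating them (or real spectra) can produce ambiguous matches that are
resolved by min-cost assignment and surfaced only through consistency
residuals. Motif definitions are the strict consensus strings; weaker or
noncanonical 14-3-3 ligands are invisible unless the relaxed definitions are
passed explicitly.
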