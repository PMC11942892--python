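# Methods

## The problem and the procedure

Karyopherins recognize short linear motifs (nuclear localization
signals, NLSs) on their cargo proteins. Given a receptor structure and
a panel of cargoes known to bind it, the discovery procedure
implemented here is:

1. **Dock** each cargo rigidly onto the receptor and score the complex.
2. **Map the interface**: cargo residues with at least one receptor
   contact form contiguous interacting segments.
3. **Truncation-scan** each segment: remove one residue at a time from
   the N- and, independently, the C-terminus, rebuild the truncated
   peptide as an idealized extended chain, re-dock, and record the
   binding-score series for each terminus.
4. **Call the minimal peptide**: a residue is critical when its removal
   raises the score by more than a jump threshold J; the first such
   jump from each end delimits the minimal binding peptide.
5. **Align** the minimal peptides across cargoes (ungapped center-star)
   and reduce each column to a single residue, a degenerate set
   (`(E/R)`), or a wildcard — the consensus recognition motif.

A motif scanner applies published degenerate motifs (RRKLPVGRS for
importin 8, `EKRKI(E/R)(K/L/R/S/T)` for importin 7, `LPPRS(G/P)P` and
`KP(K/Y)LV` for importins 4/5, KKKRK for importin α) to new sequences.

## The energy model

Physics-based docking scores from third-party programs are not
reproducible primitives, so the pipeline defines its own score and
treats it as the ground truth of its world. Structures are
coarse-grained to one bead per residue at the CA position. Each residue
belongs to one of five classes: POS {R,K,H}, NEG {D,E}, POL
{S,T,N,Q,C,Y}, HPH {A,V,L,I,M,F,W}, SPC {G,P}; histidine is counted
positive because charge clustering is the salient feature of the basic
motifs under study.

The score of a pose is

    ΔG = Σ_pairs  w_r · ε(class_p, class_r) · w(d)  +  clash(d)

over all peptide-bead/receptor-bead pairs, where `w_r` is the receptor
bead weight, `ε` a symmetric 5×5 class-contact table in arbitrary units
(a.u.), `w(d)` a linear switching function (1 for d ≤ 5.0 Å, falling
linearly to 0 at 6.5 Å) and `clash(d)` a flat +10 a.u. penalty for
pairs closer than 3.0 Å. The default table encodes charge
complementarity as dominant (ε(POS,NEG) = −2, like charges +1),
hydrophobic packing secondary (ε(HPH,HPH) = −1), polar contacts weak
(−0.5 / −0.3) and glycine/proline near-neutral (−0.1). All values are
config-overridable. Scores are deliberately labeled a.u., not kcal/mol:
absolute binding energies printed by molecular docking programs are not
reproduction targets here — only the procedure's logic is.

Per-residue decomposition assigns each pair term to its peptide
residue, so the decomposition sums exactly to the total; contacts are
all pairs within 6.5 Å.

## The docking search

The search is exhaustive and deterministic; there is no randomness
anywhere in the pipeline proper:

* **Anchors**: every receptor bead. The anchor point is the bead plus a
  4.0 Å stand-off along its outward normal (unit vector from the
  receptor centroid to the bead; +x when degenerate).
* **Orientations**: 64 Fibonacci-sphere unit vectors, expressed in a
  receptor-intrinsic frame per anchor (normal plus an in-plane
  reference toward the bead farthest from the centroid). Because the
  frame is built from receptor geometry only, the whole search grid
  moves rigidly with the receptor and the docked score is invariant
  under rigid motions of the input.
* **Anchored residue**: each peptide residue in turn is the one placed
  at the anchor point, with the chain axis along the orientation
  vector. Anchoring interior residues is essential: a motif buried
  mid-chain can only sit on the binding groove if its flanks are
  allowed to trail away from the surface.
* **Refinement**: the ten best-scoring grid poses are each refined by
  greedy ±0.5 Å translations along pose-local axes (chain axis, anchor
  normal, their cross product; at most 50 iterations), and the best
  refined pose wins. Refining a shortlist rather than the single grid
  minimum keeps results stable when two basins score within a few a.u.
  at stand-off distance but refine to different depths — with a single
  start, point-mutation ΔΔG values inherited up to ~70 a.u. of basin
  luck. Ties are always broken lexicographically by (energy, anchor,
  orientation, anchored residue).

For peptides built as extended chains, all candidate bead positions at
one (anchor, orientation) lie on a common 3.8 Å-spaced line, so
per-position class energies are precomputed once per receptor and each
pose is a windowed sum; the grid is cached and reused across the many
re-docks of a truncation scan. With refinement disabled the search
reproduces a plain-loop enumeration of the same pose space exactly,
which the tests exploit as an independent oracle. Arbitrary rigid
structures take a direct enumeration with the first-to-last-bead axis
aligned to each orientation; for the (near-)collinear chains this
package builds, both paths coincide.

## Truncation scan and the jump rule

Both termini are scanned independently on the original segment (the
dual-curve presentation: one series per terminus), down to a minimum
length of 3 residues. The jump is measured step-to-step,
ΔG(k) − ΔG(k−1) > J, with J = 50 a.u. by default — numerically
mirroring the >50 kcal/mol criterion used with physics-based scores,
and matched by the synthetic generator's calibration (one charged
groove contact ≈ 60 a.u.). A versus-full-length mode is available as a
config flag. First jump wins on each terminus; a terminus with no jump
stays at the segment edge and is flagged unconverged; if the two
boundaries cross, the full segment is returned with both flags false
and a warning.

## Consensus calling

Alignment is ungapped center-star: minimal peptides are short
near-exact repeats of one motif, so gapped multiple alignment adds
machinery without benefit; the reference is the longest peptide (ties:
lexicographically smallest), others are placed at the identity-
maximizing offset (ties: smallest offset), making the result
independent of input order. Per column over non-gap entries: frequency
> 0.5 → single-residue call; otherwise the smallest most-frequent set
with cumulative frequency ≥ 0.7 → degenerate call; if that set would
exceed 6 residues → wildcard. The 6-residue cap exists because the
cumulative rule as stated always terminates (frequencies sum to 1), so
some bound must separate "degenerate" from "uninformative"; 6 leaves
room for the published 5-letter group `(K/L/R/S/T)`. Leading/trailing
columns supported by fewer than half the peptides are trimmed. All
thresholds are config keys.

## The synthetic cohort

The generator builds the world the procedure assumes, with known
truth:

* **Receptor**: 150 beads on a Fibonacci lattice over a 20 Å sphere,
  classes drawn uniformly from {POL, HPH}, weight 1. A collinear run of
  9 sites at 3.8 Å spacing, tangent to the sphere (a convex patch — a
  rigid straight peptide can reach it, unlike a concave pocket),
  replaces the nearest lattice beads. Site p's class is the complement
  of motif position p's class (POS↔NEG, HPH↔HPH, POL↔POL, SPC→POL),
  with weight 30 so one charged contact contributes ≈ −60 a.u. — the
  calibration that drives the jump rule.
* **Cargoes** (8 by default, 40 residues): flank + motif + flank as
  extended chains, motif start uniform with ≥ 3 flanking residues on
  each side; flanks drawn from POL ∪ HPH with a 2% charged-residue
  rate; optional per-position same-class noise on the motif.
* **Decoys** (3): identical geometry and weights, groove classes
  derangement-shuffled (no position keeps its class).

Everything is a pure function of (spec, seed) via per-purpose RNG
streams, so fixtures are byte-reproducible.

What the generator does **not** emulate: real backbone geometry,
secondary structure, side chains, concave binding pockets, flexible
docking, solvation, and the absolute energy scale of physical scores.
Passing tests therefore demonstrate that the *procedure* — interface
extraction, jump calling, consensus reduction — recovers a planted
signal under its stated assumptions, not that the energy model predicts
real importin–cargo affinities.

A measured property of this geometry worth knowing: with r_on = 5.0 Å
and 3.8 Å site spacing, a peptide residue also reaches the *adjacent*
groove sites at near-full switching weight, so even class-shuffled
decoy grooves bind charged peptides substantially (−360 to −530 a.u.
vs −540 to −570 for the true receptor across seeds). Selectivity for
the true receptor is therefore an ordering property (it ranks first in
10/10 seeds, margins 15–95 a.u.), not a large-gap property.

## Numerical choices and edge cases

* All coordinates in Å; PDB output carries bead weight in the B-factor
  column and the loader restores it (round-trip convention of this
  package's fixtures).
* PDB parsing: CA-only, first-listed alternate conformer, residues
  without CA or with non-canonical names skipped with a warning,
  insertion-coded residues skipped, first model only.
* Kabsch superposition via SVD with the determinant correction, so the
  returned rotation is always proper.
* Problem sizes used by the shipped checks (chosen to exercise every
  stage at full default cohort size): 50 random tiny instances for the
  search-vs-enumeration oracle, 1000 random poses for decomposition
  conservation, 20 cohorts for boundary and consensus recovery, 10 for
  selectivity and alanine contrast.

## Known limitations

* Rigid, extended peptides only; no backbone or side-chain flexibility.
* The pose space cannot reach concave pockets (by design, matching the
  convex synthetic groove).
* Interface definition is distance-based at the energy cutoff, not
  buried-surface-area based.
* The consensus caller assumes ungapped near-repeats; peptides of very
  different lengths or with indels need a gapped aligner, which is
  deliberately out of scope.
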