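# Methods

## Model

`rna2ss` treats a base as being in one of two discrete states — paired or
non-paired — and derives the secondary structure purely from geometry.
The model has four levels:

**Base frames.** Each complete base is assigned a rigid reference frame
by Kabsch superposition (SVD, proper rotation enforced) of a standard
planar base template onto the observed ring atoms (9 atoms for purines,
6 for pyrimidines). The template coordinates are the standard
reference-frame base geometries used throughout nucleic-acid structure
analysis; the frame origin is the observed ring centroid, the normal the
image of the template +z axis. Residues missing ring atoms get no frame
and are left unpaired (logged), never dropped from the residue table.

**Pairing.** Two framed bases are a base pair when all of the following
hold:

| criterion | default | unit |
|---|---|---|
| C1′–C1′ coarse prefilter | 15 | Å |
| frame-origin distance | ≤ 9 | Å |
| inter-plane angle | ≤ 65 | degrees |
| vertical offset along mean normal | ≤ 2.5 | Å |
| donor–acceptor heavy-atom contacts | ≥ 1 within 3.5 | count, Å |

The vertical-offset window is what separates pairing (coplanar, offset
≈ 0) from stacking (offset ≈ one helical rise); with these defaults an
ideal A-form duplex yields exactly its Watson–Crick pairs and nothing
else. The thresholds are conventions, not physical constants — the
established geometric annotators use windows of this order — so all are
exposed in config and on the CLI. Pairs within 10 % of any threshold are
flagged `borderline` as candidates for manual inspection, which is the
package's stand-in for human curation of marginal geometries. Interacting
edges are assigned by counting contacts against per-base edge-atom tables
(ties resolved WC > Hoogsteen > Sugar); orientation is cis when both
glycosidic bonds fall on the same side of the axis through the two
glycosidic nitrogens, in the mean base plane. A residue may participate
in several pairs: base triples are first-class results, not errors (a
residue with more than three partners is logged as a structural anomaly
but kept).

**Stacking.** Ring centroids within 5.5 Å, normals within 30°, and a
strictly positive overlap of the convex ring outlines projected onto the
mean-normal plane (computed with shapely). Overlap > 0 is what excludes
coplanar side-by-side bases that would pass the distance and angle gates.

**Helices and topology.** Helices are maximal chains of pairs with
ascending 5′ indices and descending 3′ indices, gaps of at most the bulge
tolerance *g* (default 3 nt per strand), and an unbroken stack across
every junction — the stacking requirement, not the sequence gap, is the
real gate, so *g* merely bounds the search. In pairing-list-only mode
(no coordinates, e.g. the packaged topology fixtures) strict sequence
adjacency substitutes for stacking. Non-canonical pairs chain exactly
like canonical ones. Unique membership is enforced afterwards: a residue
claimed by pairs of two helices stays with the longer helix (ties: the
helix starting earlier on the 5′ strand, then on the 3′ strand); the
losing pair is demoted, its helix re-validated and split if continuity
broke. Crossing (i < j < q < p at the pair level) partitions helices
into layer 0 — the maximum-weight crossing-free subset, weight = pair
count, solved exactly per connected component of the crossing graph with
branch-and-bound (ties broken toward lexicographically smaller 5′
starts, so results are fully deterministic) — and greedy layers 1, 2, …
of mutually non-crossing leftovers, ordered by descending weight.
Forced-secondary labels constrain helices into layer 0 and exclude
everything that crosses them; two forced helices that cross each other
are an infeasible configuration and raise an error.

## Design choices where the design was open

- **Lone pairs.** An isolated pair is kept as a 1-pair `Helix` object —
  the unique-membership and triple machinery needs it — but a single
  pair does not constitute a helical region, so its pair role is
  *tertiary*, matching the usual annotation convention for lone pairs.
- **Triple slot order.** Per-residue partner lists put the secondary
  (helix) partner in slot 0 and remaining partners in ascending index
  order, so flat writers have a deterministic primary pair.
- **Flat formats and triples.** CT and dot-bracket can carry one partner
  per residue. They serialize the *mutual* slot-0 relation (i's slot-0
  partner j counts only when j's slot-0 partner is i — otherwise the CT
  would be asymmetric and invalid); everything else is counted and
  logged as omitted, and BPSEQ appends `# TRIPLE i j` trailer lines so
  the omitted pairs remain recoverable. JSON is the lossless record.
- **Inter-plane angle** is computed as atan2(|n₁×n₂|, |n₁·n₂|), which is
  numerically exact near 0° where the arccos form loses half the
  mantissa; this is what makes detection metrics stable to 1e-6 under
  rigid motion.
- **Alternate locations** keep the highest-occupancy conformer, ties to
  the first in file; **modified nucleotides** map to their parent base
  through a packaged table (pairing geometry follows the parent);
  unknown residue codes are excluded with a warning.
- **Multi-model files** default to model 1, as crystallographic and
  cryo-EM rRNA depositions are effectively single-model.

## Synthetic data

The fixture generator builds idealized A-form geometry from the standard
base templates: a Watson–Crick partner is the 2-fold rotation of the
template about the pair x-axis, successive pairs are related by 32.7°
twist and 2.81 Å rise (standard A-form constants), bulge and loop
residues are placed far off-axis so they neither pair nor stack. The
construction is its own ground truth: detection must return exactly the
constructed pairing. What these fixtures *do not* emulate: thermal
noise and refinement error in atom positions, sugar pucker and backbone
(only C1′ is placed beyond the base), modified-base geometry, and the
marginal, distorted pairs of real crystal structures. Passing tests
therefore demonstrate correctness of the geometric logic and its exact
thresholds, not robustness to experimental coordinate error — for real
structures the thresholds are the tuning surface. Topology fixtures
(the four-helix nesting example, the central pseudoknot with its forced
"Helix 2", the A915–U15–U20 triple placed at its native residue numbers
in a 920-nt index space, and seeded random interleaved helix sets) carry
hand-derived expected outcomes recorded in the fixture objects.

## Problem sizes and numerics

The test suite and the acceptance script run the worked examples
(≤ 920-nt index spaces, ≤ 16 pairs), a 100-instance random-topology
ensemble at 8 helices (where the exact search is verified against
exhaustive 2⁸ subset enumeration), and duplexes up to 10 bp; everything
completes in seconds. The exact nesting search is exponential only in
the size of a connected crossing-graph component, which stays small in
real rRNA; candidate pruning uses KD-trees, so geometric detection
scales near-linearly with residue count. Degenerate inputs: empty pair
lists yield empty helix lists; empty structures are an error at parse
time; a zero-length overlap polygon or coincident centroids simply fail
the stacking gates.

## Known limitations

- Edge assignment is contact-count based and deliberately coarser than a
  full 12-family Leontis–Westhof classifier; bifurcated and
  water-mediated pairs are out of scope.
- No thermodynamic scoring, co-variation analysis, automatic E. coli
  helix numbering, or 2D layout/drawing.
- Helix labels and domain boundaries are user configuration; the
  packaged domain schemes are illustrative, not curated boundaries.
- The geometric thresholds are global; structures with unusually
  distorted pairing may need per-run tuning.
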