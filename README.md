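# rna2ss

Derive annotated RNA secondary structure directly from 3D coordinates.

Secondary (2°) structures of structured RNAs — above all the ribosomal
RNAs — have traditionally been inferred from sequence co-variation, which
misses non-canonical base pairs and struggles with idiosyncratic regions
such as eukaryotic expansion segments. When a 3D structure is available,
the 2° structure can instead be *read off the coordinates*: every base
pair and every helix observed in the fold, canonical or not, on equal
footing. `rna2ss` implements that structural route for anyone working
with rRNA or other large RNAs deposited as mmCIF/PDB: structural
biologists annotating a new structure, and bioinformaticians who need
machine-readable pairing tables consistent with the 3D model.

## What it computes

Given coordinates, the pipeline:

1. **Fits a reference frame to every base** by least-squares superposition
   of a standard planar base template onto the observed ring atoms.
2. **Detects base pairs geometrically**: two bases pair when their frame
   origins are close (≤ 9 Å), near-coplanar (inter-plane angle ≤ 65°,
   vertical offset ≤ 2.5 Å) and linked by at least one donor–acceptor
   heavy-atom contact (≤ 3.5 Å). Each pair is labelled with its
   interacting edges (Watson–Crick / Hoogsteen / Sugar), cis/trans
   orientation, and a canonical flag (cis WC/WC A–U, G–C, G–U).
3. **Detects base stacking** from ring-centroid distance (≤ 5.5 Å),
   normal–normal angle (≤ 30°) and positive projected ring overlap.
4. **Assembles helices** as *continuous base-paired stacks faithful to
   strand connectivity*: consecutive pairs (i,j), (i′,j′) chain when
   i < i′ and j′ < j within a bulge tolerance **and** a stacking contact
   bridges the junction — so a bulge does not break a helix as long as
   the stack is unbroken. Each nucleotide belongs to at most one helix;
   when base triples span helices the pair in the longer helix wins and
   the other is demoted.
5. **Classifies topology**: pairs inside helical regions are *secondary*,
   all others (lone pairs, demoted triple partners) *tertiary*. Two
   helices with pairs (i,q) and (j,p) are nested when i < j < p < q and
   cross when i < j < q < p. The secondary structure proper is the
   maximum-weight crossing-free helix subset (exact search); crossing
   helices — pseudoknots and kissing loops — are stacked into layers
   1, 2, …  A helix label listed as *forced secondary* (the convention
   used for the SSU central pseudoknot's helix 2) is constrained into
   layer 0 regardless of weight.
6. **Represents base triples as pairs of base pairs** — a hub residue
   carries an ordered partner list, secondary partner first — and writes
   **CT**, **BPSEQ** (with `# TRIPLE i j` trailer lines so no pairing is
   lost), layered **dot-bracket** (`()`, `[]`, `{}`, …) and a lossless
   **JSON** record, plus per-residue domain labels from a user scheme.

## Worked example

Generate an idealized A-form duplex with a known answer, then annotate it:

```sh
$ rna2ss fixtures --kind duplex --sequence GCGCGCGC --out dup.cif
wrote dup.cif (16 residues)
$ rna2ss derive dup.cif --out out
16 residues, 8 pairs (8 canonical), 1 helices, 1 layer(s)
$ cat out/dup.dbn
GCGCGCGCGCGCGCGC
(((((((())))))))
```

All 8 constructed Watson–Crick pairs are recovered as canonical cis WC/WC
pairs, chained into a single layer-0 helix. A bulged hairpin shows the
bulge rule:

```sh
$ rna2ss fixtures --kind hairpin --stem 8 --bulge 2 --loop 4 --out hp.cif
wrote hp.cif (22 residues)
$ rna2ss derive hp.cif --out out
22 residues, 8 pairs (8 canonical), 1 helices, 1 layer(s)
$ cat out/hp.dbn
GCGCAAGCGCUUUUGCGCGCGC
((((..((((....))))))))
```

One helix despite the 2-nt bulge (`has_defect: true` in `out/hp.json`),
because the flanking stacks bridge it. `out/hp.log.json` records every
parameter and count of the run, including the conservation identity
`pairs_detected = pairs_secondary + pairs_tertiary`.

Real structures are annotated the same way, e.g.
`rna2ss derive ribosome.cif --chains A --domains domains_ssu.yaml
--labels helix_labels.yaml --force-secondary "Helix 2" --out out`.
Example domain-scheme configs ship in `src/rna2ss/data/`.

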