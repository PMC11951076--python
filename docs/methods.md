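# Methods

`pufatyper` reimplements, at desk scale, the comparative genomics workflow that
classifies thraustochytrid strains into four PUFA-biosynthesis lineages from
their repertoire of diagnostic genes.  This note documents the models,
defaults, and design decisions; everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## The diagnostic gene panel

Thraustochytrids synthesise long-chain ω3 PUFAs (EPA C20:5 n-3, DHA C22:6 n-3)
through two routes:

* the **ELO/DES pathway** — iterative elongases and oxygen-dependent
  desaturases extending palmitic acid (C16:0) into C16–C22 PUFAs, and
* the **PUFA synthase (PUFA-S) pathway** — a polyketide-synthase-like complex
  of three subunits (PfaA, PfaB, PfaC) that builds C20–C22 PUFAs without
  oxygen-dependent desaturation.

The panel registers 24 genes: the 3 PUFA-S subunits; 10 desaturase families
(Δ4, Δ5, Δ6, Δ8, Δ9A, ω6/Δ9B, ω3 and the uncharacterised U1–U3); 7 elongase
groups (C16, C16-like, C18, C20, Δ9, U1, U2 — six major groups plus the C16L
minor group); and 4 accessory genes: ATP-citrate lyase (ACLY) and cytosolic
carnitine acetyltransferase (cCrAT) for cytosolic acetyl-CoA supply, and the
xanthophyll enzymes β-carotene hydroxylase (CrtZ) and β-carotene ketolase
(CrtO).

## The packaged fixture matrix

`build_fixture_matrix()` returns a 22-strain × 24-gene presence/absence matrix
(19 thraustochytrid strains in six genera plus three labyrinthulomycete
relatives).  Fill policy: a cell is 1/0 **only** when an explicit published
text statement fixes it (per-lineage strain lists, exclusivity statements such
as "Δ9A and U2 occur only in Types I/II", per-gene exceptions such as CrtO
missing from *T. striatum* and the *T. aureum* strains); every other cell is
`?` (unknown).  Each statement is also encoded as a machine-checked predicate
(`validate_fixture`), so the fixture cannot drift from its sources.  Copy
number (the diploid strain, 1–2 cCrAT copies) is kept in the strain note, not
in the cell.  The one deliberate normalisation: the 422-residue truncated ACLY
of *Schizochytrium* sp. CCTCC M209059 lacks the N-terminal ATP/citrate/CoA
binding domains and is recorded **absent** for typing, with the exception
preserved in the note.  Absence in transcriptome-only strains is recorded as
absence, but those rows carry `evidence_source=transcriptome` so reports can
flag the weaker support.

## Motif model

Membrane desaturases carry three short His-rich catalytic boxes; subfamily
shapes are: First = HRLWSH / HRXHH / HNXHH, Front-End = HDXGH / HXXHH (the
variant observed in thraustochytrids; canonically HXXXHH) / QXEHH, Omega =
H[ED]CGH / HXXHH / HVXHH.  The Δ4 group keeps the canonical six-residue second
box (HXXXHH) with relaxed first/third boxes.  Elongases carry one box, HXXHH,
except the C20 group's QXXHH.  Patterns support literals, `X` wildcards and
bracketed alternatives; parsing enforces 5–6 positions and ≥2 literal H/Q.

Only subfamily-level shapes are published, and within a subfamily several
families would be indistinguishable by shape alone.  The default registry
therefore instantiates one wildcard position per family with a distinguishing
residue (e.g. HDAGH/HAXHH/QAEHH for Δ5 vs HDEGH/HEXHH/QEEHH for Δ6).  These
instantiations are *synthetic defaults*: they make the generator ↔ classifier
loop exactly self-consistent and keep the subfamily shape, but they are not
published consensus sequences.  On real data, within-subfamily resolution is
carried by homology (best hit), which always wins a motif/best-hit conflict.
The U1–U3 families get Front-End-shaped placeholder signatures for the same
reason.

Other motif defaults:

* **Box spacing** 15–300 residues between consecutive boxes (no spacing is
  published; the bounds are deliberately loose and configurable per signature).
* **N-terminal domains** are detected by core-motif heuristics, not profile
  HMMs: cytochrome b5 via the standard heme-pocket tetrapeptide HPGG within a
  150-residue N-terminal window; DUF3474/DUF1129 have no default core motif and
  are treated as satisfied unless the user configures one.  The U3 family's
  ~500-residue N-terminal extension ahead of its cytb5 domain is accommodated
  by enlarging its search window to 700 residues.
* **Candidate enumeration** caps at 50 hits per box (error beyond), bounding
  the combinatorial search; among full matches the minimal-span combination
  wins.

## Homology assignment

Candidates are aligned to per-family archetypes with exact Smith–Waterman
local alignment (BLOSUM62; a gap of length L costs 11 + L), the deterministic
stand-in for the original BLASTP searches.  Scores are normalised by archetype
self-score, so 1.0 means identity.  The acceptance threshold
`min_norm_score = 0.3` is a package decision (no cutoff is published): loose
enough to admit ~35–40% diverged members, strict enough that composition-
preserving shuffled decoys score ~0.05–0.15 and are rejected (checked in the
suite).  Desaturase/elongase calls fuse motif and best-hit evidence; elongase
groups other than C20 are resolvable only by homology, so an elongase box
without an acceptable best hit stays unclassified.  The packaged reference
library is synthetic (seeded archetypes per family, labelled as such); the
C16L archetype is derived from C16 at 30% substitution with the box fully
protected, reproducing the published situation of two groups with >50% mutual
identity and an identical box that only homology can separate.  Users replace
the library with a real archetype FASTA for genuine analyses.

## Typing rule

Flags derived per strain row: `pufas_complete` = PfaA ∧ PfaB ∧ PfaC;
`elodes_complete` = Δ9A ∧ Δ4 ∧ Δ5 ∧ ω3 ∧ (Δ6 ∨ Δ8) ∧ C16 ∧ C18 ∧ C20 ∧ Δ9
elongase.  The Δ6 and Δ8 desaturases head alternative routes in the published
pathway diagram, so either satisfies completeness; ω6/Δ9B, the U families and
C16L are not main-route enzymes and sit outside the predicate (`strict=True`
adds ω6/Δ9B as a sensitivity check).  Lineages, evaluated I→IV with first
match winning:

* **I** = complete ELO/DES without PUFA-S,
* **II** = both pathways complete,
* **III** = PUFA-S, no Δ9A, C18/C20 elongases retained,
* **IV** = PUFA-S, no Δ9A, C18/C20 lost;

anything else is unclassified.  On flag vectors realisable from a matrix row
(completeness implies Δ9A and the long elongases) the four predicates are
mutually exclusive — proven by 64-case enumeration in the suite.  Unknown
cells count as absent but are listed in the call's `uncertain` set and
rationale.  Cytosolic acetyl-CoA: ACLY present → citrate route; else cCrAT →
acetyl-carnitine shuttle; else undetermined (the published situation of the
Type IV lineage).  Relatives are typed with an explicit "heuristic only"
caveat and excluded from thraustochytrid aggregates.

## Synteny

Neighborhoods are the ≤4 genes up/downstream of the target locus on its contig
in coordinate order (strand recorded, not normalised).  Flank genes are paired
across strains by reciprocal-best local alignment, score normalised by the
larger self-score (symmetric), threshold 0.3.  Conservation is
membership-based within the corresponding window — upstream pairs with
upstream, downstream with downstream — which is also what makes conserved
counts symmetric under swapping reference and other strain; order and strand
agreement are reported as flags, never required.  "PfaA–PfaB adjacent" means
consecutive gene features on one contig, any strand combination.  GFF-lite
coordinates are 1-based inclusive on disk and converted to 0-based half-open
in memory.

## Phylogenetics

Deliberately transparent desk-scale stack rather than wrappers around MAFFT /
PHYLIP: progressive alignment with a 3-mer-cosine + NJ guide (merge tie-breaks
on sorted member ids make the column set invariant to input order),
profile–profile global alignment under BLOSUM62 column scores with a linear
gap penalty of 4; p-distances over columns ungapped in both rows (a pair with
no comparable columns gets distance 1.0 with a warning), with an optional
Poisson correction −ln(1−p), p capped at 0.95; Saitou–Nei neighbor joining
with ties broken on the smallest index pair and negative branch lengths
clamped to 0 with a warning, so runs are bit-reproducible; classical
Felsenstein column-bootstrap supports (the original study's transfer bootstrap
is a method substitution we do not reproduce).  Monophyly of a tip set means
some edge of the unrooted tree bipartitions exactly that set.  NJ recovers
topology and branch lengths exactly from additive matrices (property-tested
against an independent random-additive-tree generator, and cross-checked
against dendropy's split encoding for monophyly).

## Synthetic data

The generators define the conditions every claim is tested under:

* Background residues uniform over the 20 amino acids — the simplest null
  under which spurious box hits are analytically quantifiable (e.g. a QXXHH
  hit in a 300-residue background occurs with probability ≈ 300/20³ ≈ 4%,
  which is why elongase group calls need homology corroboration).
* Member lengths: desaturases 360–440, elongases 260–320, PUFA-S subunits
  480–560, accessory 380–460 residues; box gaps 20–60 (spacing-legal).  The
  PUFA-S lengths are desk-scale stand-ins, not the ~1000+-residue real
  subunits; only relative homology structure matters here.
* Point mutation substitutes to a *different* residue, so the realised changed
  fraction equals the nominal rate; planted boxes are protected with
  probability 0.9 by default, reflecting that catalytic histidines are
  conserved without claiming a measured rate.
* Strains carry one protein per profile gene (mutated from the family
  archetype) plus 5 composition-preserving shuffled decoys; lineage profiles
  are read off representative fixture strains.
* Contig generators plant conserved flank slots; tree evolution applies
  per-site substitution with probability min(1, rate × branch length) per
  branch.
* All randomness derives from one seed via CRC-labelled `SeedSequence`
  substreams, so every stage is reproducible in isolation.

What the generators do **not** emulate — indels, compositional bias, domain
shuffling, paralogy, fragmented gene models — bounds what green tests show:
they validate the decision logic and its calibration on clean signals, not
performance on real predicted proteomes.

## Problem sizes

The suite and `scripts/acceptance.py` run the synthetic studies at fixed desk
scale chosen as the smallest sizes at which every check is information-rich:
end-to-end recovery over 20 seeds × 4 strains (~100 proteins per replicate),
motif-oracle agreement on 1000 sequences, NJ recovery on 20 random additive
matrices of ≤8 taxa, planted synteny over 50 seeded scenarios, monophyly on
16 tips × 3 seeds, bootstrap at 200 replicates.

## Known limitations

* Real Pfam domain calls (cytb5 PF00173, DUF3474, DUF1129, elongase PF01151)
  are replaced by core-motif heuristics; proteins with degenerate HPGG pockets
  will miss the cytb5 flag (which is advisory, not gating).
* The per-family signature instantiations are synthetic; on real data the
  motif layer only narrows candidates to subfamily level.
* Typing treats unknown as absent; a strain with missing data for a driver
  gene can only be typed optimistically downward (the `uncertain` list makes
  this auditable).
* The NJ/bootstrap stack is quadratic–cubic and intended for ≤ a few hundred
  sequences; it is not a replacement for production aligners/tree builders.
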