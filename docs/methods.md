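# Methods

This note documents the models and numerical choices behind
`segremodel`, what its synthetic data emulates, and what its tests do
and do not establish about real design campaigns.

## Scope and model of the problem

The package formalizes segment-level structure engineering as four
decoupled stages — profile, redesign, sequence design, evaluate — glued
by explicit contracts. The contribution-level pieces (secondary-
structure assignment, torsion-space building and closure, superposition
metrics, Neff, compliance filtering, clustering, composite ranking) are
implemented here; generative and predictive foundation models are
*interfaces*, not dependencies. A production deployment points the
backbone/sequence/prediction contracts at real model outputs via the
directory protocols; this repository ships seeded synthetic backends so
the full cascade is executable and testable offline.

Residue addressing is 1-based author numbering with inclusive ranges
throughout; all lookups go through a residue-number index. Insertion
codes are rejected at parse time rather than renumbered, because
segment specs reference author numbering and silent renumbering would
corrupt targeting. Hetero residues and waters are dropped; common
modified residues map to their standard parent; only backbone atoms
(N, CA, C, O) are required anywhere.

## Geometry

Chains are built by sequential internal-coordinate (NeRF-style)
placement with fixed ideal bonds and angles (N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°),
ω fixed trans at 180° (cis-proline out of scope). The carbonyl O is
placed in the CA–C–N(next) plane anti to the next N (C–O 1.231 Å,
CA–C–O 120.8°); the terminal O applies the same rule using the last
residue's supplied ψ. Build→measure consistency is a tested invariant
(torsions recovered to < 0.5°).

**Loop closure** is cyclic coordinate descent over the segment's φ/ψ
pivots, visited C-terminal-first so adjustments localize near the exit.
The end effectors are the *virtual* next-residue N and CA extended from
the segment with ideal geometry: those two atoms fully determine the
exit C–N junction (bond, both flanking angles, trans ω), while the
downstream residue's own φ is free — targeting a third atom would
impose an arbitrary φ convention and create an irreducible error floor.
Per-pivot rotation uses the closed-form optimal angle; the best iterate
is tracked, so the reported junction distance never increases; sweeps
stop at the tolerance (default 0.5 Å junction RMSD; the synthetic
backend requests 0.08 Å so the junction bond lands inside the boundary
filter's 1.2–1.5 Å window) or after 25 sweeps without ≥ 10⁻³ Å
improvement. Non-convergence is a flag, never an exception.

**Superposition** is the closed-form Kabsch solution (SVD with
reflection correction); degenerate (collinear, < 3-point) fit sets are
rejected. The TM-score is a *fixed-superposition* score: it is
evaluated on an existing residue pairing after one global superposition
and never re-searches the alignment — unlike TM-align-family tools.
The d0 scale is floored at 0.5 Å for region lengths ≤ 21 where the
canonical cube-root formula goes non-positive. Consequence worth
knowing: short fixed regions (tens of residues) yield numerically small
TM values even at ~2 Å RMSD, because d0 is at the floor; the score is
comparable across variants, not across region lengths.

## Secondary structure

The assigner follows the classic Kabsch–Sander scheme: amide H at
1.0 Å from N along the unit sum of unit(N−C_prev) and unit(N−CA)
(prolines and chain starts have no donor); electrostatic bond energy
with a −0.5 kcal/mol cutoff and a −9.9 clamp below 0.5 Å separations;
n-turns (n = 3, 4, 5) and parallel/antiparallel bridges from the bond
table; two consecutive 4-turns → H (analogously G and I, with π given
lowest helix priority per the classic ordering); ladders of consecutive
bridges → E, isolated bridges → B; remaining turn residues → T; a bend
rule (S) at > 70° Cα-direction kink; priority H > E > B > G > I > T > S.
Bridges may pair residues across chains; turns never span chain breaks
(non-consecutive numbering or C–N > 2.5 Å). The SS3 reduction
{H,G,I}→H, {E,B}→E, rest→C treats 3₁₀ helix as a helical design
outcome.

Tests require class-level (H/E/C) agreement with an independent
Kabsch–Sander implementation (mdtraj's DSSP) on packaged fixtures, not
letter-perfect SS8 agreement: boundary-residue conventions differ
legitimately across implementations. Display rounding of composition
fractions is decimal half-up to 2 places (0.3125 → 0.31); full
precision is kept internally.

## Profiling

Neff is the exponentiated weighted Shannon entropy of a column's
amino-acid frequencies, gaps excluded from the normalization so sparse
columns are not inflated; empty columns pin Neff to 1 with a flag.
Sequence weights are 1/(single-linkage cluster size) at 80 % identity;
identity is matches over mutually non-gap columns divided by the
shorter ungapped length. The redundancy filter is a greedy first-wins
pass in input order with the query always kept — idempotent by
construction. Conservation = 1 − ln(Neff)/ln 20 is purely a bounded
reporting transform. Segment nomination is deliberately conservative —
maximal coil-only runs with Neff strictly above the chain-wide median,
minus a user-supplied exclusion set; softening helices or strands is a
user decision, not auto-nominated.

## Synthetic backends: what they emulate, and what they do not

The **backbone backend** rebuilds the segment from ideal class torsions
with seeded Gaussian noise (default σ = 10°) and closes onto the
downstream anchor. Conditioning is soft: each sample realizes the
target class on a contiguous sub-block of the segment (content fraction
uniform in [0.35, 1], random offset) with coil flanks drawn from a
broad left-half Ramachandran rectangle (φ ∈ [−160°, −55°],
ψ ∈ [−60°, 180°]). This mirrors the behavior of real inpainting
models, whose outputs are not guaranteed to satisfy the secondary-
structure objective and typically realize it partially; geometrically,
a full-length ideal helix often cannot bridge the anchors of a loop it
replaces, and the coil flanks absorb the closure. The
helix-versus-strand designability asymmetry emerges from the
annotation physics, not from tuned constants: a rebuilt strand earns E
only if it finds a hydrogen-bonded pairing partner, which an isolated
segment in a helical scaffold essentially never does, while helices are
stabilized by their own local i→i+4 bonds.

The **sequence backend** draws segment residues from class-conditioned
propensity sets (helix-favoring {A,L,E,K,M,Q}, strand-favoring
{V,I,Y,T,F,W}) with a temperature that flattens toward uniform (T → 0
gives the argmax); its score is a backbone-specific base level (seeded
hash) plus Gaussian noise minus a bonus for propensity agreement, so
class-compatible sequences tend to score better. The **prediction
backend** returns the wild-type fixed region plus the variant's parent
backbone segment under small seeded jitter, with per-residue confidence
synthesized as a decreasing function of local geometric irregularity
(Cα–Cα deviation from 3.8 Å; torsion deviation from the class ideal),
scaled into [30, 95].

None of these backends learns anything: passing tests demonstrate that
the *orchestration* — contracts, filters, metrics, determinism,
provenance — behaves correctly, and that the filter cascade's
directionality (helix easier than strand; noise degrades compliance)
matches the physics encoded in the assigner. They say nothing about
the absolute success rates real generative models would achieve on real
proteins.

## Fixtures

Toy proteins concatenate ideal-torsion blocks; sheet fixtures are
explicit two-strand assemblies, because an isolated strand cannot earn
E under bridge-based assignment. The antiparallel partner is placed by
a deterministic registration search: a 180°-rotated copy of the strand
is scanned over placements near the nominal 4.9 Å inter-strand spacing
(spacing ±0.6 Å, slide along the strand axis, pleat offset), keeping
the placement with the most Kabsch–Sander inter-strand bonds (ties by
total bond energy). Synthetic alignments mutate a query at per-column
rates, with optional planted duplicates for redundancy tests. Every
fixture is a pure function of (spec, seed).

## Pipeline determinism, resumability, and scale

A run is a pure function of (inputs, config, seed): stage outputs carry
no timestamps, downstream stages always consume the *serialized* stage
outputs (PDB/FASTA file precision) rather than in-memory values so
fresh and resumed runs are byte-identical, and stage snapshots are
keyed by content digests of the scientific inputs (config minus paths,
plus the structure file's content hash). Deleting a stage directory
recomputes exactly that stage and its dependents.

Default stage parameters follow the production-scale protocol (100
backbones per objective, 1000 sequences per backbone, top 50 % by
score, representative count held to a few hundred by walking the
min-identity grid {0.95 … 0.50}, screening at segment pLDDT ≥ 50,
global pLDDT ≥ 70, predicted compliance ≥ 0.40 with ≥ semantics at the
screening stage versus strict > at the backbone stage). Tests, the
worked example and the acceptance script run the same cascade at
reduced sizes (10–30 backbones, 50–200 sequences per backbone, seed 1
for the demo — a seed at which the small helix run carries candidates
through every stage, so the full path is exercised). The composite
rank uses median/MAD robust z-scores (MAD floor 10⁻⁹) so heavy-tailed
segment RMSD outliers cannot dominate; weights are equal by default
and recorded in provenance. The backbone-stage compliance filter uses
backbone-stage annotation; prediction-stage compliance is computed
separately on predicted structures.

## Open choices made here

- The superposition fit set defaults to all shared Cα atoms ("single
  global superposition" reading), with `fit=fixed` available; both are
  tested.
- Neff's weighting scheme (single-linkage at 80 % identity, 1/cluster
  size) and the entropy definition are documented choices isolated
  behind one operation.
- Multi-chain inputs: a segment spec targets one chain; other chains
  are fixed context (they participate in annotation, e.g. inter-chain
  strand pairing, but are never remodeled).
- The clustering identity grid and target band (100–500
  representatives) are defaults; "several hundred" is not a precise
  prescription.
- The library-level CLI (`segremodel`) is a thin wrapper; the module
  functions are the primary interface.

## Known limitations

- Single static structures only: no ensembles, dynamics, or kinetics.
- The synthetic inpainter samples torsion space without awareness of
  tertiary packing; its steric-clash rate is higher than a learned
  model's, and the geometry filter absorbs this (typically ~10 % of
  helix-target samples survive all three geometric flags at σ = 10°).
- Positional (alignment-free) sequence identity assumes equal-length
  sequences, valid here because remodeling preserves residue count.
- Strand-target campaigns in scaffolds lacking pairing partners retain
  few or no backbones; this is the designability asymmetry the report
  stage quantifies, not a failure mode of the cascade.
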