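# segremodel

Segment-level protein secondary-structure remodeling: a four-stage,
fully deterministic pipeline that takes a protein structure, a
user-chosen segment (chain + inclusive residue range), and a target
three-state secondary-structure class (H = helix, E = strand, C = coil),
and produces a ranked, provenance-complete panel of sequence variants
whose remodeled segment realizes that class while the rest of the fold
is preserved.

It is written for protein engineers who want to harden a flexible loop
into a helix or strand (or soften a rigid element) without redesigning
the whole scaffold, and for method developers who need a desk-scale,
GPU-free harness in which every stage of such a workflow is testable.
The heavy generative models that production pipelines call (backbone
diffusion inpainting, inverse folding, structure prediction) sit behind
file-exchange backend contracts; the package ships seeded synthetic
backends implementing the same contracts, so the entire cascade runs in
seconds and is reproducible bit for bit.

## The method

**Profiling.** Designable segments are nominated from a multiple
sequence alignment and the structure's secondary-structure annotation.
Per-column amino-acid diversity is summarized as the effective number of
amino acids, `Neff = exp(−Σₐ pₐ ln pₐ)` over weighted, gap-excluded
frequencies (1 = fully conserved, 20 = maximum entropy), with
conservation reported as `1 − ln(Neff)/ln 20`. Maximal coil runs with
above-median Neff, minus any user-excluded positions (catalytic
residues), are returned ranked by mean Neff × length.

**Secondary structure.** Assignment is a from-scratch Kabsch–Sander
implementation: amide hydrogens are rebuilt geometrically, hydrogen
bonds scored with the electrostatic model
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol (bond when
E < −0.5), and n-turn and bridge patterns reduced to the 8-letter
alphabet with priority H > E > B > G > I > T > S. The 3-state reduction
maps {H, G, I} → H and {E, B} → E, so 3₁₀ helices count as helical
outcomes. **Compliance** of a segment is the fraction of its residues
assigned the target class.

**Backbone redesign.** Candidate backbones are sampled for the segment
(fixed region preserved to numerical precision — enforced on ingest,
not assumed), annotated, filtered for geometric continuity, steric
plausibility and boundary compatibility, and retained only above a
compliance threshold (default: strictly > 0.40). The synthetic backend
rebuilds the segment in torsion space from ideal class torsions
(H: −57°/−47°, E: −139°/135°) with seeded Gaussian noise and closes it
onto the downstream anchor by cyclic coordinate descent.

**Sequence design and clustering.** Per backbone, sequences are sampled
with the fixed region constrained to wild type, scored (lower is
better), the top fraction retained (default 50 %), then greedily
clustered in score order; the minimum-identity threshold is walked down
a grid until the representative count lands in a target band.

**Evaluation.** Predicted structures (pLDDT in the B-factor column,
0–100 scale) are screened on segment pLDDT, global pLDDT and predicted
compliance; then a *single* global Kabsch superposition is followed by
per-region Cα RMSD and fixed-superposition TM-score
(`Σ 1/(1+(dᵢ/d0)²)/L`, d0 = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å for
L ≤ 21) for the fixed region and the designed segment separately.
Survivors are ranked by an equal-weight robust-z composite of predicted
compliance, segment/global pLDDT, design score and fixed-region RMSD.

## Worked example

Build a toy scaffold (10-residue helix, 12-residue coil, 10-residue
helix), then run matched helix- and strand-targeted campaigns on the
coil segment:

```python
from segremodel.core import write_structure
from segremodel.fixtures import FixtureSpec, make_toy_protein
from segremodel.pipeline import PipelineConfig, run_pipeline

structure, _ = make_toy_protein(
    FixtureSpec(blocks=(("H", 10), ("C", 12), ("H", 10)), seed=3))
write_structure(structure, "scaffold.pdb")

for target in ("H", "E"):
    cfg = PipelineConfig(structure_path="scaffold.pdb", segment="A:11-22",
                         target_ss3=target, seed=1, out_dir=f"run_{target}",
                         n_backbones=10, n_seq_per_backbone=50)
    result = run_pipeline(cfg)
```

which prints:

```
[backbone] sampled 10, retained 2
[sequence] designed 100, top fraction 50, representatives 50
[evaluate] predicted 50, screened 50, panel 50
[backbone] sampled 10, retained 0
[sequence] designed 0, top fraction 0, representatives 0
```

The helix campaign retains 2 of 10 sampled backbones (compliance > 0.40
with clean geometry) and carries 50 clustered representatives through
screening into the ranked panel (`run_H/panel.tsv`, `panel.fasta`).
The strand campaign on the *same* segment retains none: an isolated
strand cannot satisfy bridge-based strand assignment without a pairing
partner, so strand compliance stays near zero — the helix-versus-strand
designability asymmetry that the evaluation stage is designed to
quantify. `segremodel report` tabulates this comparison across run
manifests.

The same pipeline is available from the shell:

```bash
segremodel run --config config.yaml --seed 1 --out run_H
segremodel annotate --structure scaffold.pdb --segment A:11-22 --target H
```

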