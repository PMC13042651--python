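"""Segment backbone inpainting: backend contract, seeded synthetic backend,
and compliance/geometry filtering and ranking of sampled backbones.

Real diffusion-based inpainting backends are driven through a file-exchange
directory contract (request.json + input PDB in, numbered candidate PDBs
out) and never linked in-process.  The synthetic backend rebuilds the
segment in torsion space from target-class ideal angles with seeded
Gaussian noise, closes it onto the downstream anchor by CCD, and keeps the
fixed region bit-identical — it is a deterministic, desk-scale generator of
structurally plausible candidates, not a learned model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (ProvenanceRecord, SegmentSpec, Structure, read_structure,
                   segment_residues, validate_segment, write_structure)
from .geometry import (COIL_PHI_RANGE, COIL_PSI_RANGE, IDEAL_TORSIONS,
                       TorsionTriple, build_backbone_from_torsions, ccd_close,
                       dihedral)
from .ss import assign_ss8, segment_composition

FIXED_REGION_TOL = 1e-3  # A; scaffold preservation is enforced, not assumed

GEOMETRY_TOLERANCES = {
    "ca_ca_range": (2.9, 4.1),      # continuity: consecutive CA-CA (A)
    "min_nonbonded": 2.0,           # steric: closest allowed |i-j|>=2 pair (A)
    "junction_cn_range": (1.2, 1.5),  # boundary: segment-junction C-N bond (A)
}


class BackendError(RuntimeError):
    pass


@dataclass(frozen=True)
class BackboneBackendRequest:
    structure: Structure
    spec: SegmentSpec
    n_samples: int
    steps: int = 50  # carried as backend metadata; the synthetic backend has no diffusion
    ss_conditioning: str | None = None
    seed: int = 0
    noise_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@dataclass
class BackboneCandidate:
    candidate_id: str
    structure: Structure
    spec: SegmentSpec
    compliance: float | None = None
    segment_ss3: str | None = None
    geometry_flags: dict = field(default_factory=dict)
    closure_converged: bool = True
    provenance: ProvenanceRecord | None = None

    @property
    def passes_geometry(self) -> bool:
        return all(self.geometry_flags.get(k, False)
                   for k in ("continuity", "steric", "boundary"))


@dataclass
class RejectionRecord:
    candidate_id: str
    reason: str


def synthetic_inpaint(structure: Structure, spec: SegmentSpec,
                      target_ss3: str, noise_deg: float = 10.0,
                      seed: int = 0,
                      target_block: tuple[int, int] | None = None
                      ) -> BackboneCandidate:
    """Rebuild the design segment in torsion space.

    Target-class ideal torsions (H: -57/-47, E: -139/135; C: uniform coil
    draws) are perturbed by zero-mean Gaussian noise of ``noise_deg``
    standard deviation, the segment is rebuilt from the upstream anchor,
    and CCD-closed onto the downstream anchor frame when one exists.
    ``target_block`` = (offset, length) restricts the target torsions to
    a contiguous sub-block of the segment, with coil draws on the flanks
    (default: the whole segment).  Closure failure flags the candidate
    boundary=false but still returns it.  Deterministic under
    (inputs, seed).
    """
    chain = validate_segment(structure, spec)
    rng = np.random.default_rng(seed)
    length = spec.length
    if target_block is None:
        block = range(length)
    else:
        off, blen = target_block
        if not (0 <= off and off + blen <= length and blen >= 1):
            raise ValueError(f"target_block {target_block} outside segment")
        block = range(off, off + blen)

    torsions = []
    for i in range(length):
        if target_ss3 in IDEAL_TORSIONS and i in block:
            phi, psi = IDEAL_TORSIONS[target_ss3]
        else:
            phi = rng.uniform(*COIL_PHI_RANGE)
            psi = rng.uniform(*COIL_PSI_RANGE)
        phi = _wrap(phi + rng.normal(0.0, noise_deg)) if noise_deg > 0 else phi
        psi = _wrap(psi + rng.normal(0.0, noise_deg)) if noise_deg > 0 else psi
        torsions.append(TorsionTriple(phi, psi, 180.0))

    up = chain[spec.start - 1] if (spec.start - 1) in chain else None
    down = chain[spec.end + 1] if (spec.end + 1) in chain else None

    if up is not None and up.has_backbone():
        anchor = np.array([up.atoms["N"], up.atoms["CA"], up.atoms["C"]])
        if target_ss3 in IDEAL_TORSIONS and 0 in block:
            anchor_psi = IDEAL_TORSIONS[target_ss3][1]
        else:
            anchor_psi = rng.uniform(*COIL_PSI_RANGE)
        coords = build_backbone_from_torsions(torsions, anchor=anchor,
                                              anchor_psi=anchor_psi)
    else:
        coords = build_backbone_from_torsions(torsions)

    converged = True
    if down is not None and down.has_backbone() and length >= 3:
        target_frame = np.array([down.atoms["N"], down.atoms["CA"],
                                 down.atoms["C"]])
        # tighter-than-default closure so the junction C-N bond lands
        # inside the boundary filter's [1.2, 1.5] A window
        coords, converged, _ = ccd_close(coords, target_frame,
                                         max_iters=500, tol=0.08)

    new_structure = structure.copy()
    new_chain = new_structure.chain(spec.chain_id)
    for i, res_num in enumerate(spec.res_nums()):
        res = new_chain[res_num]
        for atom in ("N", "CA", "C", "O"):
            res.atoms[atom] = coords[i][atom].copy()
        # drop side-chain atoms: the remodeled backbone has no side chains
        for extra in [a for a in res.atoms if a not in ("N", "CA", "C", "O")]:
            del res.atoms[extra]

    cid = f"bb_{seed:05d}"
    return BackboneCandidate(
        candidate_id=cid,
        structure=new_structure,
        spec=spec,
        closure_converged=converged,
        provenance=ProvenanceRecord(
            stage="backbone", parent_id=structure.id,
            parameters={"backend": "synthetic", "target_ss3": target_ss3,
                        "noise_deg": noise_deg, "seed": seed},
        ),
    )


def _wrap(angle: float) -> float:
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def geometry_filter(candidate: BackboneCandidate,
                    tolerances: dict | None = None) -> dict:
    """Continuity / steric / boundary flags for a remodeled chain.

    continuity: all consecutive CA-CA distances within [2.9, 4.1] A;
    steric: no backbone atom pair from residues |i-j| >= 2 closer than
    2.0 A; boundary: both segment-junction C-N bonds within [1.2, 1.5] A
    (junctions at chain termini pass vacuously).
    """
    tol = dict(GEOMETRY_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    spec = candidate.spec
    chain = candidate.structure.chain(spec.chain_id)
    residues = chain.residues

    ca = np.array([r.atoms["CA"] for r in residues if "CA" in r.atoms])
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    lo, hi = tol["ca_ca_range"]
    continuity = bool(np.all((d >= lo) & (d <= hi)))

    atoms = []
    owners = []
    for idx, r in enumerate(residues):
        for a in ("N", "CA", "C", "O"):
            if a in r.atoms:
                atoms.append(r.atoms[a])
                owners.append(idx)
    atoms = np.array(atoms)
    owners = np.array(owners)
    dist = np.linalg.norm(atoms[:, None] - atoms[None], axis=-1)
    sep = np.abs(owners[:, None] - owners[None])
    clash = (dist < tol["min_nonbonded"]) & (sep >= 2)
    steric = not bool(np.any(np.triu(clash, k=1)))

    boundary = True
    jlo, jhi = tol["junction_cn_range"]
    for c_num, n_num in ((spec.start - 1, spec.start), (spec.end, spec.end + 1)):
        if c_num in chain and n_num in chain:
            c_res, n_res = chain[c_num], chain[n_num]
            if "C" in c_res.atoms and "N" in n_res.atoms:
                b = float(np.linalg.norm(n_res.atoms["N"] - c_res.atoms["C"]))
                if not (jlo <= b <= jhi):
                    boundary = False
    flags = {"continuity": continuity, "steric": steric, "boundary": boundary}
    candidate.geometry_flags = flags
    return flags


def annotate_candidate(candidate: BackboneCandidate) -> BackboneCandidate:
    """Compute SS3 compliance (backbone-stage annotation) and geometry flags."""
    ann = assign_ss8(candidate.structure)
    comp = segment_composition(ann, candidate.spec, candidate.structure)
    candidate.compliance = comp.compliance
    candidate.segment_ss3 = comp.segment_ss3
    geometry_filter(candidate)
    if not candidate.closure_converged:
        candidate.geometry_flags["boundary"] = False
    return candidate


def check_fixed_region(candidate: Structure, reference: Structure,
                       spec: SegmentSpec, tol: float = FIXED_REGION_TOL) -> bool:
    """True iff fixed-region CA coordinates match the input within tol."""
    ref_chain = reference.chain(spec.chain_id)
    cand_chain = candidate.chain(spec.chain_id)
    seg = set(spec.res_nums())
    for res in ref_chain.residues:
        if res.res_num in seg or "CA" not in res.atoms:
            continue
        if res.res_num not in cand_chain:
            return False
        other = cand_chain[res.res_num]
        if "CA" not in other.atoms:
            return False
        if np.linalg.norm(res.atoms["CA"] - other.atoms["CA"]) > tol:
            return False
    return True


class SyntheticBackboneBackend:
    """In-process synthetic inpainting backend (the tested default).

    Secondary-structure conditioning is soft: each sample realizes the
    target class on a contiguous sub-block of the segment (content
    fraction drawn uniformly from [0.35, 1]) with coil flanks that absorb
    loop closure — emulating the partial-compliance behavior of real
    inpainting models, where generated backbones are not guaranteed to
    satisfy the full secondary-structure objective.
    """

    name = "synthetic"

    def __init__(self, noise_deg: float = 10.0,
                 content_range: tuple[float, float] = (0.35, 1.0)):
        self.noise_deg = noise_deg
        self.content_range = content_range

    def sample(self, request: BackboneBackendRequest) -> list[BackboneCandidate]:
        noise = request.noise_deg if request.noise_deg is not None else self.noise_deg
        target = request.ss_conditioning or request.spec.target_ss3
        seeds = np.random.SeedSequence([request.seed, 0x5eed]).generate_state(
            request.n_samples)
        length = request.spec.length
        out = []
        for i, s in enumerate(seeds):
            child_seed = int(s % (2 ** 31))
            block_rng = np.random.default_rng(
                np.random.SeedSequence([child_seed, 1]))
            frac = block_rng.uniform(*self.content_range)
            blen = max(min(4, length), round(frac * length))
            off = int(block_rng.integers(0, length - blen + 1))
            cand = synthetic_inpaint(request.structure, request.spec, target,
                                     noise_deg=noise, seed=child_seed,
                                     target_block=(off, blen))
            cand.candidate_id = f"bb_{i:04d}"
            out.append(cand)
        return out


class DirectoryBackboneBackend:
    """File-exchange adapter: request.json + input.pdb in, numbered
    candidate PDBs out of ``out_dir``.  Used to ingest externally produced
    backbones (e.g. from a diffusion model run elsewhere)."""

    name = "directory"

    def __init__(self, out_dir):
        self.out_dir = Path(out_dir)

    def sample(self, request: BackboneBackendRequest) -> list[BackboneCandidate]:
        paths = sorted(self.out_dir.glob("*.pdb"))
        out = []
        for i, p in enumerate(paths[: request.n_samples]):
            try:
                st = read_structure(p)
            except Exception:
                st = None
            cand = BackboneCandidate(
                candidate_id=f"bb_{i:04d}",
                structure=st, spec=request.spec,
                provenance=ProvenanceRecord(
                    stage="backbone", parent_id=request.structure.id,
                    parameters={"backend": self.name, "file": p.name,
                                "steps": request.steps}),
            )
            if st is None:
                cand.geometry_flags = {"continuity": False, "steric": False,
                                       "boundary": False}
            out.append(cand)
        return out


def sample_backbones(backend, request: BackboneBackendRequest
                     ) -> tuple[list[BackboneCandidate], list[RejectionRecord]]:
    """Run a backbone backend and ingest its candidates.

    Fixed-region preservation is verified on ingest; violating or
    malformed candidates become rejection records, never a crash.
    Surviving candidates get backbone-stage compliance and geometry flags.
    """
    raw = backend.sample(request)
    kept: list[BackboneCandidate] = []
    rejected: list[RejectionRecord] = []
    for cand in raw:
        if cand.structure is None:
            rejected.append(RejectionRecord(cand.candidate_id, "unparseable output"))
            continue
        try:
            segment_residues(cand.structure, request.spec)
        except Exception as exc:
            rejected.append(RejectionRecord(cand.candidate_id,
                                            f"segment missing: {exc}"))
            continue
        if not check_fixed_region(cand.structure, request.structure, request.spec):
            rejected.append(RejectionRecord(cand.candidate_id,
                                            "fixed-region coordinates altered"))
            continue
        if cand.provenance is None:
            cand.provenance = ProvenanceRecord(
                stage="backbone", parent_id=request.structure.id,
                parameters={"backend": getattr(backend, "name", "?"),
                            "steps": request.steps, "seed": request.seed})
        cand.provenance.parameters.setdefault("steps", request.steps)
        cand.provenance.parameters.setdefault("seed", request.seed)
        annotate_candidate(cand)
        kept.append(cand)
    return kept, rejected


def rank_and_filter_backbones(
    candidates: list[BackboneCandidate],
    min_compliance: float = 0.40,
) -> list[BackboneCandidate]:
    """Drop geometry failures and candidates at or below the compliance
    threshold (strict >), then sort by compliance descending with ties
    broken by candidate id."""
    survivors = [c for c in candidates
                 if c.passes_geometry and c.compliance is not None
                 and c.compliance > min_compliance]
    survivors.sort(key=lambda c: (-c.compliance, c.candidate_id))
    return survivors


def write_backend_request(request: BackboneBackendRequest, work_dir) -> Path:
    """Materialize the directory-contract inputs for an external backend."""
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    pdb = work_dir / "input.pdb"
    write_structure(request.structure, pdb)
    meta = {
        "segment": f"{request.spec.chain_id}:{request.spec.start}-{request.spec.end}",
        "target_ss3": request.spec.target_ss3,
        "n_samples": request.n_samples,
        "steps": request.steps,
        "ss_conditioning": request.ss_conditioning,
        "seed": request.seed,
        "input": pdb.name,
    }
    path = work_dir / "request.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path
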