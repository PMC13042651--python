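"""Deterministic synthetic proteins, MSAs, and backend outputs.

Everything here is a pure function of its spec and seed, so tests and
pipeline demos regenerate identical inputs with no downloads.  Sheet
fixtures are built as explicit two-strand assemblies: an isolated strand
cannot earn E under bridge-based assignment, because strand formation
relies on directional backbone hydrogen bonding with a pairing partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Chain, Residue, Structure, write_structure
from .geometry import (COIL_PHI_RANGE, COIL_PSI_RANGE, IDEAL_TORSIONS,
                       TorsionTriple, build_backbone_from_torsions)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: inter-strand spacing used when placing a beta partner strand (Angstrom)
SHEET_SPACING = 4.9


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a toy protein: ordered (ss3_class, length) blocks."""

    blocks: tuple[tuple[str, int], ...]
    chain_id: str = "A"
    start_num: int = 1
    seed: int = 0
    noise_deg: float = 0.0
    pair_strands: bool = True

    def __post_init__(self) -> None:
        for cls, length in self.blocks:
            if cls not in "HEC" or length < 1:
                raise ValueError(f"bad block ({cls}, {length})")

    @property
    def length(self) -> int:
        return sum(n for _, n in self.blocks)

    @property
    def ground_truth_ss3(self) -> str:
        return "".join(cls * n for cls, n in self.blocks)


def _block_torsions(spec: FixtureSpec, rng: np.random.Generator
                    ) -> list[TorsionTriple]:
    out = []
    for cls, length in spec.blocks:
        for _ in range(length):
            if cls in IDEAL_TORSIONS:
                phi, psi = IDEAL_TORSIONS[cls]
            else:
                phi = rng.uniform(*COIL_PHI_RANGE)
                psi = rng.uniform(*COIL_PSI_RANGE)
            if spec.noise_deg > 0:
                phi += rng.normal(0.0, spec.noise_deg)
                psi += rng.normal(0.0, spec.noise_deg)
            out.append(TorsionTriple(_clamp(phi), _clamp(psi), 180.0))
    return out


def _clamp(angle: float) -> float:
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _coords_to_residues(coords, chain_id: str, start_num: int,
                        res_name: str = "ALA") -> list[Residue]:
    return [
        Residue(chain_id, start_num + i, res_name,
                {k: v.copy() for k, v in res.items()})
        for i, res in enumerate(coords)
    ]


def make_toy_protein(spec: FixtureSpec) -> tuple[Structure, str]:
    """Build a toy protein from ideal-torsion blocks.

    Returns the structure and the intended (ground-truth) SS3 string for
    the main chain.  When ``pair_strands`` is set, every E block also gets
    a detached antiparallel partner strand as an extra chain, placed at
    ~4.9 A spacing by a deterministic registration search that maximizes
    the number of Kabsch-Sander inter-strand hydrogen bonds.
    """
    rng = np.random.default_rng(spec.seed)
    torsions = _block_torsions(spec, rng)
    coords = build_backbone_from_torsions(torsions)
    main = Chain(spec.chain_id, _coords_to_residues(coords, spec.chain_id,
                                                    spec.start_num))
    chains = [main]
    if spec.pair_strands:
        offset = 0
        partner_id = iter(c for c in "BCDEFGH" if c != spec.chain_id)
        for cls, length in spec.blocks:
            if cls == "E" and length >= 4:
                block = coords[offset:offset + length]
                partner = _place_partner_strand(block)
                chains.append(Chain(next(partner_id),
                                    _coords_to_residues(partner, "?", 1)))
                for i, res in enumerate(chains[-1].residues):
                    res.chain_id = chains[-1].chain_id
            offset += length
    # re-tag partner residues with their chain id (Chain ctor copies refs)
    for chain in chains:
        for res in chain.residues:
            res.chain_id = chain.chain_id
    return Structure(f"toy_{spec.seed}", chains), spec.ground_truth_ss3


def make_paired_sheet(n_per_strand: int = 8, seed: int = 0,
                      noise_deg: float = 0.0) -> tuple[Structure, str]:
    """Two antiparallel ideal strands as chains A and B."""
    spec = FixtureSpec(blocks=(("E", n_per_strand),), seed=seed,
                       noise_deg=noise_deg, pair_strands=True)
    return make_toy_protein(spec)


def _strand_arrays(block: list[dict[str, np.ndarray]]):
    """(C, O, N, H) coordinate arrays for a strand; H by the bisector rule,
    NaN where no donor exists (first residue)."""
    n = len(block)
    c = np.array([r["C"] for r in block])
    o = np.array([r["O"] for r in block])
    nn = np.array([r["N"] for r in block])
    h = np.full((n, 3), np.nan)
    for i in range(1, n):
        d1 = nn[i] - c[i - 1]
        d2 = nn[i] - np.asarray(block[i]["CA"])
        u = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
        h[i] = nn[i] + u / np.linalg.norm(u)
    return c, o, nn, h


def _interchain_bond_score(a_arrays, b_arrays) -> tuple[int, float]:
    """(bond count, total energy) of Kabsch-Sander bonds between strands."""
    from .ss import HBOND_CUTOFF, _KS_Q

    count = 0
    total = 0.0
    for (c, o, _, _), (_, _, nn, h) in ((a_arrays, b_arrays),
                                        (b_arrays, a_arrays)):
        valid = ~np.isnan(h[:, 0])
        r_on = np.linalg.norm(o[:, None] - nn[None], axis=-1)
        r_ch = np.linalg.norm(c[:, None] - h[None], axis=-1)
        r_oh = np.linalg.norm(o[:, None] - h[None], axis=-1)
        r_cn = np.linalg.norm(c[:, None] - nn[None], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            e = _KS_Q * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
        e = np.where(np.minimum.reduce([r_on, r_ch, r_oh, r_cn]) < 0.5, -9.9, e)
        e[:, ~valid] = 0.0
        mask = e < HBOND_CUTOFF
        count += int(mask.sum())
        total += float(e[mask].sum())
    return count, total


def _place_partner_strand(block: list[dict[str, np.ndarray]]
                          ) -> list[dict[str, np.ndarray]]:
    """Antiparallel partner for a built strand.

    Candidate placements rotate a copy of the strand by 180 degrees about
    in-plane axes through its centroid, offset it near the nominal sheet
    spacing, and slide it along the strand axis and pleat direction; the
    placement maximizing (inter-strand H-bond count, then total bond
    energy) wins.  The scan is deterministic, so the fixture is a pure
    function of its spec.
    """
    from scipy.spatial.transform import Rotation

    ca = np.array([r["CA"] for r in block])
    centroid = ca.mean(axis=0)
    # principal axes of the CA trace: strand axis, pleat, sheet direction
    _, _, vt = np.linalg.svd(ca - centroid, full_matrices=False)
    axis_d, axis_p = vt[0], vt[1]
    axis_o = np.cross(axis_d, axis_p)
    axis_o /= np.linalg.norm(axis_o)

    flat = np.array([r[a] for r in block for a in ("N", "CA", "C", "O")])
    a_arrays = _strand_arrays(block)
    n = len(block)

    def unflatten(arr):
        return [{a: arr[4 * i + k] for k, a in enumerate(("N", "CA", "C", "O"))}
                for i in range(n)]

    best = None
    best_score = (-1, 0.0)
    for rot_axis in (axis_o, axis_p):
        rotated = Rotation.from_rotvec(np.pi * rot_axis).apply(flat - centroid)
        for sign in (1.0, -1.0):
            for spacing in np.arange(SHEET_SPACING - 0.6, SHEET_SPACING + 0.45, 0.1):
                for shift in np.arange(-3.5, 3.51, 0.25):
                    for poff in (-0.5, 0.0, 0.5):
                        cand = (rotated + centroid + sign * spacing * axis_o
                                + shift * axis_d + poff * axis_p)
                        count, total = _interchain_bond_score(
                            a_arrays, _strand_arrays(unflatten(cand)))
                        score = (count, -total)
                        if score > best_score:
                            best_score = score
                            best = cand.copy()
    return unflatten(best)


# ---------------------------------------------------------------------------
# MSA fixtures
# ---------------------------------------------------------------------------

def make_toy_msa(query: str, n: int, mutation_rates,
                 seed: int = 0, n_duplicates: int = 0):
    """Synthetic alignment: rows mutated from the query at per-column rates.

    Low-rate columns emulate conserved positions, high-rate columns
    variable ones.  ``n_duplicates`` plants exact copies of the first
    mutated row (for redundancy-filter tests).  Returns an MSA.
    """
    from .profiling import MSA

    rng = np.random.default_rng(seed)
    rates = np.broadcast_to(np.asarray(mutation_rates, float), (len(query),))
    rows = [query]
    ids = ["query"]
    for k in range(n):
        row = []
        for col, aa in enumerate(query):
            if rng.random() < rates[col]:
                row.append(AMINO_ACIDS[rng.integers(20)])
            else:
                row.append(aa)
        rows.append("".join(row))
        ids.append(f"hom{k:04d}")
    for d in range(n_duplicates):
        if n >= 1:
            rows.append(rows[1])
            ids.append(f"dup{d:02d}")
    return MSA(ids=ids, rows=rows, query_index=0)


# ---------------------------------------------------------------------------
# Backend-output emulation (file contracts)
# ---------------------------------------------------------------------------

def emulate_backend_outputs(kind: str, request: dict, seed: int,
                            out_dir, corrupt: set[int] | None = None) -> list[Path]:
    """Write files obeying a backend directory contract.

    kind='backbone': numbered candidate PDBs from the synthetic inpainter.
    kind='sequence': a FASTA of designed variants with scores.
    kind='prediction': per-variant PDBs with pLDDT in the B-factor column.
    ``corrupt`` marks output indices to truncate, for adapter fault tests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corrupt = corrupt or set()
    paths: list[Path] = []
    if kind == "backbone":
        from .backbone import synthetic_inpaint

        structure = request["structure"]
        spec = request["spec"]
        n = request["n_samples"]
        noise = request.get("noise_deg", 10.0)
        for i in range(n):
            cand = synthetic_inpaint(structure, spec, spec.target_ss3,
                                     noise_deg=noise, seed=seed + i)
            p = out_dir / f"candidate_{i:04d}.pdb"
            write_structure(cand.structure, p)
            paths.append(p)
    elif kind == "sequence":
        from .seqdesign import mock_design_backend

        variants = mock_design_backend(request["backbone"], request["n"],
                                       request.get("temperature", 0.2), seed)
        p = out_dir / "designs.fasta"
        with open(p, "w") as fh:
            for v in variants:
                fh.write(f">{v.variant_id} score={v.global_score:.4f}\n")
                fh.write(v.sequence + "\n")
        paths.append(p)
    elif kind == "prediction":
        from .evaluation import mock_predictor

        for i, (variant, backbone) in enumerate(request["variants"]):
            rec = mock_predictor(variant, request["wild_type"], backbone,
                                 seed=seed + i)
            p = out_dir / f"{variant.variant_id}.pdb"
            write_structure(rec.structure, p)
            paths.append(p)
    else:
        raise ValueError(f"unknown backend kind {kind!r}")
    for idx in corrupt:
        if idx < len(paths):
            text = paths[idx].read_text().splitlines()
            paths[idx].write_text("\n".join(text[: max(1, len(text) // 4)]))
    return paths
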