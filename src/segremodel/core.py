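"""Structure/sequence data model, PDB/mmCIF I/O, and segment bookkeeping.

Residue addressing throughout the package is 1-based author numbering with
inclusive ranges ("residues 230-245" selects 16 residues).  All lookups go
through an explicit residue-number index, never positional offsets, so that
segment specs survive gaps in author numbering.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: three-letter -> one-letter codes for the 20 standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: common modified residues mapped to their standard parent
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "CSO": "CYS", "CSS": "CYS", "HYP": "PRO", "MLY": "LYS",
    "M3L": "LYS", "FME": "MET", "KCX": "LYS", "SEC": "CYS",
}


class StructureError(ValueError):
    """Raised for unparseable or structurally incomplete inputs."""


class SegmentError(ValueError):
    """Raised when a segment spec does not match the structure."""


@dataclass
class Residue:
    chain_id: str
    res_num: int
    res_name: str
    atoms: dict[str, np.ndarray]
    plddt: float | None = None

    def __post_init__(self) -> None:
        for name, xyz in self.atoms.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise StructureError(
                    f"residue {self.chain_id}:{self.res_num} atom {name}: "
                    "coordinates must be a finite 3-vector"
                )
            self.atoms[name] = arr

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))

    def ca(self) -> np.ndarray:
        try:
            return self.atoms["CA"]
        except KeyError:
            raise StructureError(
                f"residue {self.chain_id}:{self.res_num} has no CA atom"
            ) from None

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id, self.res_num, self.res_name,
            {k: v.copy() for k, v in self.atoms.items()}, self.plddt,
        )


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        nums = [r.res_num for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise StructureError(
                f"chain {self.chain_id}: residue numbers must be strictly increasing"
            )
        self._index = {r.res_num: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, res_num: int) -> Residue:
        return self._index[res_num]

    def __contains__(self, res_num: int) -> bool:
        return res_num in self._index

    @property
    def res_nums(self) -> list[int]:
        return [r.res_num for r in self.residues]

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain]
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(len(c) for c in self.chains):
            raise StructureError("structure has no residues")
        self._by_id = {c.chain_id: c for c in self.chains}

    def chain(self, chain_id: str) -> Chain:
        try:
            return self._by_id[chain_id]
        except KeyError:
            raise SegmentError(
                f"no chain {chain_id!r} in structure {self.id} "
                f"(have {sorted(self._by_id)})"
            ) from None

    def residues(self) -> Iterable[Residue]:
        for c in self.chains:
            yield from c.residues

    def copy(self) -> "Structure":
        return Structure(
            self.id,
            [Chain(c.chain_id, [r.copy() for r in c.residues]) for c in self.chains],
            dict(self.source),
        )


@dataclass(frozen=True)
class SegmentSpec:
    """A design target: chain, inclusive residue range, and target SS3 class."""

    chain_id: str
    start: int
    end: int
    target_ss3: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SegmentError(f"segment start {self.start} > end {self.end}")
        if self.target_ss3 not in ("H", "E", "C"):
            raise SegmentError(f"target_ss3 must be H, E or C, got {self.target_ss3!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def res_nums(self) -> range:
        return range(self.start, self.end + 1)

    @classmethod
    def parse(cls, text: str, target_ss3: str) -> "SegmentSpec":
        """Parse 'A:230-245' style segment strings."""
        chain, _, rng = text.partition(":")
        if not rng:
            raise SegmentError(f"cannot parse segment {text!r}; expected CHAIN:START-END")
        a, _, b = rng.partition("-")
        return cls(chain, int(a), int(b), target_ss3)


@dataclass
class ProvenanceRecord:
    stage: str  # profile | backbone | sequence | screen | evaluate
    parent_id: str | None
    parameters: dict
    timestamp: str | None = None
    digests: dict = field(default_factory=dict)

    STAGES = ("input", "profile", "backbone", "sequence", "screen", "evaluate")

    def __post_init__(self) -> None:
        if self.stage not in self.STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "parent_id": self.parent_id,
            "parameters": self.parameters,
            "digests": self.digests,
        }


def digest_of(obj) -> str:
    """Stable sha256 digest of a JSON-serializable object (12 hex chars)."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# File I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def _best_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken alphabetically by altloc id
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def read_structure(path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the in-memory model.

    First model only; waters and hetero compounds are dropped; common
    modified residues are mapped to their standard parent; altlocs are
    resolved to the highest-occupancy (then alphabetically first) copy.
    Insertion codes are rejected: segment specs use author numbering and
    silently renumbering would corrupt segment targeting.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except StructureError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError with line context
        raise StructureError(f"cannot parse {path} as {fmt}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            name = gres.name
            if name == "HOH":
                continue
            if name not in THREE_TO_ONE:
                if name in NONSTANDARD_PARENT:
                    name = NONSTANDARD_PARENT[name]
                else:
                    info = gemmi.find_tabulated_residue(gres.name)
                    if info is not None and not info.is_amino_acid():
                        continue  # ligand/nucleotide/etc.
                    raise StructureError(
                        f"{path}: unmappable non-standard residue {gres.name} "
                        f"at {gchain.name}:{gres.seqid.num}"
                    )
            if gres.seqid.icode not in ("", " ", "\x00"):
                raise StructureError(
                    f"{path}: insertion code {gres.seqid.icode!r} at "
                    f"{gchain.name}:{gres.seqid.num}; renumber the input — "
                    "segment specs address author numbering"
                )
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in gres:
                by_name.setdefault(atom.name, []).append(atom)
            coords = {}
            bvals = []
            for aname, group in by_name.items():
                best = _best_altloc(group)
                coords[aname] = np.array([best.pos.x, best.pos.y, best.pos.z])
                if aname in BACKBONE_ATOMS:
                    bvals.append(best.b_iso)
            plddt = float(np.mean(bvals)) if bvals else None
            residues.append(
                Residue(gchain.name, gres.seqid.num, name, coords, plddt)
            )
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise StructureError(f"{path}: no protein residues found")
    return Structure(
        id=path.stem,
        chains=chains,
        source={"path": str(path), "format": fmt},
    )


def write_structure(structure: Structure, path, format: str = "auto") -> None:
    """Write the structure as PDB or mmCIF.

    Per-residue confidence values (``Residue.plddt``), when present, are
    stored in the B-factor column, the convention used by structure
    predictors for pLDDT.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if not any(len(c) for c in structure.chains):
        raise StructureError("refusing to write an empty structure")

    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.res_num, " ")
            for aname in sorted(res.atoms, key=_atom_order):
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(aname[0])
                x, y, z = res.atoms[aname]
                atom.pos = gemmi.Position(x, y, z)
                atom.occ = 1.0
                atom.b_iso = round(res.plddt, 2) if res.plddt is not None else 0.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    try:
        if fmt == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except Exception as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def _atom_order(name: str) -> tuple:
    try:
        return (0, BACKBONE_ATOMS.index(name))
    except ValueError:
        return (1, name)


# ---------------------------------------------------------------------------
# Segment bookkeeping
# ---------------------------------------------------------------------------

def validate_segment(structure: Structure, spec: SegmentSpec) -> Chain:
    chain = structure.chain(spec.chain_id)
    nums = set(chain.res_nums)
    missing = [n for n in spec.res_nums() if n not in nums]
    if missing:
        lo, hi = min(chain.res_nums), max(chain.res_nums)
        if spec.start < lo or spec.end > hi:
            raise SegmentError(
                f"segment {spec.start}-{spec.end} outside chain "
                f"{spec.chain_id} range {lo}-{hi}"
            )
        raise SegmentError(
            f"segment {spec.start}-{spec.end}: chain {spec.chain_id} is "
            f"missing residues {missing}"
        )
    return chain


def segment_residues(structure: Structure, spec: SegmentSpec) -> list[Residue]:
    """Residues of the design segment, in order (end - start + 1 of them)."""
    chain = validate_segment(structure, spec)
    return [chain[n] for n in spec.res_nums()]


def fixed_residues(structure: Structure, spec: SegmentSpec) -> list[Residue]:
    """Complement accessor: the fixed-region residues of the segment's chain."""
    chain = validate_segment(structure, spec)
    seg = set(spec.res_nums())
    return [r for r in chain.residues if r.res_num not in seg]
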