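"""Secondary-structure assignment in the Kabsch-Sander style.

Backbone amide hydrogens are reconstructed geometrically, hydrogen bonds are
scored with the classic electrostatic model, and the bond pattern is reduced
to the 8-state alphabet (H, G, I, E, B, T, S, C) with the classic priority
H > E > B > G > I > T > S.  The 3-state reduction maps {H, G, I} -> H,
{E, B} -> E and everything else -> C, so 3-10 helices count toward helical
design outcomes.

Assignment operates on all chains at once: beta bridges may pair residues
across chains (a two-strand sheet built as two chains earns E), while turn
patterns are confined within a chain and never span chain breaks.  A break
is declared where consecutive residues are non-consecutive in numbering or
their C-N distance exceeds 2.5 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .core import SegmentSpec, Structure, validate_segment
from .geometry import bond_angle

#: Kabsch-Sander electrostatic prefactor (q1*q2*f, kcal/mol*A)
_KS_Q = 0.084 * 332.0
HBOND_CUTOFF = -0.5  # kcal/mol
CHAIN_BREAK_CN = 2.5  # A
BEND_ANGLE = 70.0  # degrees

SS8_ALPHABET = "HGIEBTSC"
_SS8_TO_SS3 = {"H": "H", "G": "H", "I": "H",
               "E": "E", "B": "E",
               "T": "C", "S": "C", "C": "C"}


class AnnotationError(ValueError):
    pass


@dataclass
class SSAnnotation:
    """Per-residue SS8/SS3 strings aligned to (chain_id, res_num) keys."""

    res_keys: list[tuple[str, int]]
    ss8: str
    ss3: str
    hbonds: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.res_keys) == len(self.ss8) == len(self.ss3)):
            raise AnnotationError("annotation strings must align with residues")
        self._index = {k: i for i, k in enumerate(self.res_keys)}

    def for_chain(self, chain_id: str) -> str:
        return "".join(s for k, s in zip(self.res_keys, self.ss3) if k[0] == chain_id)

    def ss3_at(self, chain_id: str, res_num: int) -> str:
        return self.ss3[self._index[(chain_id, res_num)]]

    def ss3_for_range(self, chain_id: str, start: int, end: int) -> str:
        return "".join(self.ss3_at(chain_id, n) for n in range(start, end + 1))

    def ss8_for_range(self, chain_id: str, start: int, end: int) -> str:
        return "".join(self.ss8[self._index[(chain_id, n)]]
                       for n in range(start, end + 1))


def place_amide_hydrogens(structure: Structure) -> dict[tuple[str, int], np.ndarray]:
    """Reconstruct backbone amide H positions.

    H sits 1.0 A from N along the unit sum of unit(N - C_prev) and
    unit(N - CA).  Chain-start residues (including residues after a
    numbering gap or broken C-N bond) and prolines carry no donor H.
    """
    out: dict[tuple[str, int], np.ndarray] = {}
    for chain in structure.chains:
        prev = None
        for res in chain.residues:
            is_start = (
                prev is None
                or res.res_num != prev.res_num + 1
                or "C" not in prev.atoms
                or "N" not in res.atoms
                or np.linalg.norm(res.atoms["N"] - prev.atoms["C"]) > CHAIN_BREAK_CN
            )
            if (not is_start and res.res_name != "PRO"
                    and "N" in res.atoms and "CA" in res.atoms):
                n = res.atoms["N"]
                d1 = n - prev.atoms["C"]
                d2 = n - res.atoms["CA"]
                direction = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
                out[(res.chain_id, res.res_num)] = (
                    n + direction / np.linalg.norm(direction)
                )
            prev = res
    return out


def hbond_energy(c: np.ndarray, o: np.ndarray,
                 n: np.ndarray, h: np.ndarray) -> float:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol) for an
    acceptor C=O and donor N-H.  Any interatomic distance below 0.5 A
    clamps the energy to -9.9 (overlapping atoms)."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9
    return float(_KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def _flatten(structure: Structure):
    """Global residue list with chain-start/break bookkeeping."""
    residues = []
    starts = []  # True where residue begins a contiguous stretch
    for chain in structure.chains:
        prev = None
        for res in chain.residues:
            is_start = (
                prev is None
                or res.res_num != prev.res_num + 1
                or "C" not in prev.atoms
                or "N" not in res.atoms
                or np.linalg.norm(res.atoms["N"] - prev.atoms["C"]) > CHAIN_BREAK_CN
            )
            residues.append(res)
            starts.append(is_start)
            prev = res
    return residues, starts


def _contiguous(starts: list[bool], i: int, j: int) -> bool:
    """True if residues i..j (global indices, i < j) are one unbroken stretch."""
    return not any(starts[k] for k in range(i + 1, j + 1))


def compute_hbonds(structure: Structure) -> dict[tuple[int, int], float]:
    """All Kabsch-Sander H-bonds as {(acceptor_idx, donor_idx): energy}
    with energy < -0.5; indices are global residue positions.  Self and
    sequence-adjacent donor-acceptor pairs are excluded."""
    residues, starts = _flatten(structure)
    hydro = place_amide_hydrogens(structure)
    bonds: dict[tuple[int, int], float] = {}
    n_res = len(residues)
    coords_ok = [("C" in r.atoms and "O" in r.atoms) for r in residues]
    for j, donor in enumerate(residues):  # donor NH
        h = hydro.get((donor.chain_id, donor.res_num))
        if h is None or "N" not in donor.atoms:
            continue
        n_at = donor.atoms["N"]
        for i in range(n_res):  # acceptor CO
            if abs(i - j) <= 1 and residues[i].chain_id == donor.chain_id:
                continue
            if i == j or not coords_ok[i]:
                continue
            acc = residues[i]
            e = hbond_energy(acc.atoms["C"], acc.atoms["O"], n_at, h)
            if e < HBOND_CUTOFF:
                bonds[(i, j)] = e
    return bonds


def assign_ss8(structure: Structure) -> SSAnnotation:
    """Assign 8-state secondary structure from backbone H-bond patterns."""
    residues, starts = _flatten(structure)
    n = len(residues)
    bonds = compute_hbonds(structure)
    bondset = set(bonds)
    chain_of = [r.chain_id for r in residues]

    def hb(i: int, j: int) -> bool:  # CO(i) -> NH(j)
        return (i, j) in bondset

    # n-turns: CO(i) -> NH(i+k) within one unbroken stretch
    turns = {3: [False] * n, 4: [False] * n, 5: [False] * n}
    for k in (3, 4, 5):
        for i in range(n - k):
            if chain_of[i] == chain_of[i + k] and _contiguous(starts, i, i + k) \
                    and hb(i, i + k):
                turns[k][i] = True

    helix = {"H": [False] * n, "G": [False] * n, "I": [False] * n}
    for letter, k in (("H", 4), ("G", 3), ("I", 5)):
        for i in range(1, n - k):
            if turns[k][i - 1] and turns[k][i]:
                for m in range(i, i + k):
                    helix[letter][m] = True

    # bridges: i, j each need in-chain neighbors; stretches non-overlapping
    def has_neighbors(i: int) -> bool:
        return (0 < i < n - 1
                and chain_of[i - 1] == chain_of[i] == chain_of[i + 1]
                and _contiguous(starts, i - 1, i + 1))

    bridges: list[tuple[int, int, str]] = []
    for i in range(n):
        if not has_neighbors(i):
            continue
        for j in range(i + 3, n):
            if not has_neighbors(j):
                continue
            parallel = (hb(i - 1, j) and hb(j, i + 1)) or \
                       (hb(j - 1, i) and hb(i, j + 1))
            anti = (hb(i, j) and hb(j, i)) or \
                   (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if parallel:
                bridges.append((i, j, "P"))
            if anti:
                bridges.append((i, j, "A"))

    # ladders: consecutive bridges of the same type extend each other
    in_ladder = [False] * n
    bridged = [False] * n
    bridge_set = set(bridges)
    for (i, j, t) in bridges:
        bridged[i] = bridged[j] = True
        if t == "P":
            ext = ((i + 1, j + 1, "P") in bridge_set
                   or (i - 1, j - 1, "P") in bridge_set)
        else:
            ext = ((i + 1, j - 1, "A") in bridge_set
                   or (i - 1, j + 1, "A") in bridge_set
                   or (j - 1, i + 1, "A") in bridge_set
                   or (j + 1, i - 1, "A") in bridge_set)
        if ext:
            in_ladder[i] = in_ladder[j] = True

    # turn (T) residues: interior of any n-turn span
    in_turn = [False] * n
    for k in (3, 4, 5):
        for i in range(n):
            if turns[k][i]:
                for m in range(i + 1, min(i + k, n)):
                    in_turn[m] = True

    # bend (S): CA-direction kink > 70 degrees over i-2..i+2
    bend = [False] * n
    for i in range(2, n - 2):
        window = [residues[i + d] for d in (-2, -1, 0, 1, 2)]
        if any(chain_of[i + d] != chain_of[i] for d in (-2, -1, 1, 2)):
            continue
        if not _contiguous(starts, i - 2, i + 2):
            continue
        if not all("CA" in r.atoms for r in window):
            continue
        u = window[2].atoms["CA"] - window[0].atoms["CA"]
        v = window[4].atoms["CA"] - window[2].atoms["CA"]
        ang = bond_angle(window[2].atoms["CA"] + u, window[2].atoms["CA"],
                         window[2].atoms["CA"] + v)
        if ang > BEND_ANGLE:
            bend[i] = True

    ss8 = []
    for i in range(n):
        if helix["H"][i]:
            ss8.append("H")
        elif in_ladder[i]:
            ss8.append("E")
        elif bridged[i]:
            ss8.append("B")
        elif helix["G"][i]:
            ss8.append("G")
        elif helix["I"][i]:
            ss8.append("I")
        elif in_turn[i]:
            ss8.append("T")
        elif bend[i]:
            ss8.append("S")
        else:
            ss8.append("C")
    ss8_str = "".join(ss8)
    keys = [(r.chain_id, r.res_num) for r in residues]
    return SSAnnotation(keys, ss8_str, reduce_ss3(ss8_str), dict(bonds))


def reduce_ss3(ss8: str) -> str:
    """Reduce SS8 to SS3: {H,G,I} -> H, {E,B} -> E, {T,S,C} -> C."""
    out = []
    for pos, letter in enumerate(ss8):
        try:
            out.append(_SS8_TO_SS3[letter])
        except KeyError:
            raise AnnotationError(
                f"unknown SS8 letter {letter!r} at position {pos}"
            ) from None
    return "".join(out)


def round_half_up(x: float, places: int = 2) -> float:
    """Decimal half-up rounding for display (0.3125 -> 0.31, 0.625 -> 0.63)."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SegmentComposition:
    """SS3 class fractions over a segment and compliance with its target."""

    segment_ss3: str
    target_ss3: str
    h_frac: float
    e_frac: float
    c_frac: float

    @property
    def compliance(self) -> float:
        return {"H": self.h_frac, "E": self.e_frac, "C": self.c_frac}[self.target_ss3]

    def rounded(self, places: int = 2) -> dict[str, float]:
        return {
            "H": round_half_up(self.h_frac, places),
            "E": round_half_up(self.e_frac, places),
            "C": round_half_up(self.c_frac, places),
            "compliance": round_half_up(self.compliance, places),
        }


def composition_of(segment_ss3: str, target_ss3: str) -> SegmentComposition:
    """Class fractions of an SS3 segment string (full precision)."""
    seg = "".join(segment_ss3.split())
    if not seg:
        raise AnnotationError("empty segment")
    bad = set(seg) - set("HEC")
    if bad:
        raise AnnotationError(f"segment string contains non-SS3 letters {bad}")
    n = len(seg)
    return SegmentComposition(
        seg, target_ss3,
        seg.count("H") / n, seg.count("E") / n, seg.count("C") / n,
    )


def segment_composition(annotation: SSAnnotation, spec: SegmentSpec,
                        structure: Structure | None = None) -> SegmentComposition:
    """Composition/compliance of a design segment under an annotation."""
    if structure is not None:
        validate_segment(structure, spec)
    try:
        seg = annotation.ss3_for_range(spec.chain_id, spec.start, spec.end)
    except KeyError as exc:
        raise AnnotationError(
            f"annotation does not cover segment {spec.chain_id}:"
            f"{spec.start}-{spec.end} (missing {exc})"
        ) from None
    return composition_of(seg, spec.target_ss3)


def compliance_of(structure: Structure, spec: SegmentSpec) -> float:
    """Convenience: fraction of segment residues in the target SS3 class."""
    return segment_composition(assign_ss8(structure), spec, structure).compliance
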