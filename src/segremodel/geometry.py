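"""Coordinate mathematics: torsion-driven chain building, cyclic-coordinate-
descent loop closure, rigid superposition, and distance-based scores.

The backbone builder uses sequential natural-extension (NeRF-style)
internal-to-Cartesian construction with fixed ideal bond lengths and angles;
only the torsions vary.  The TM-score here is a *fixed-superposition* score:
it is evaluated on an existing residue pairing after one rigid superposition
and never re-searches the alignment, unlike TM-align-style tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

# ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8

#: canonical torsions per SS3 class (phi, psi)
IDEAL_TORSIONS = {"H": (-57.0, -47.0), "E": (-139.0, 135.0)}

#: phi/psi rectangle that coil torsions are drawn from (uniform); spans the
#: broad favorable left half of the Ramachandran map so drawn loops stay
#: compact rather than fully extended
COIL_PHI_RANGE = (-160.0, -55.0)
COIL_PSI_RANGE = (-60.0, 180.0)


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class TorsionTriple:
    phi: float
    psi: float
    omega: float = 180.0

    def __post_init__(self) -> None:
        for name in ("phi", "psi", "omega"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise GeometryError(f"{name}={v} outside (-180, 180]")


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, with det(rotation) = +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise GeometryError("rotation must be 3x3 with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length vector in frame construction")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = _unit(np.asarray(p0, float) - np.asarray(p1, float))
    v = _unit(np.asarray(p2, float) - np.asarray(p1, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = _unit(c - b)
    ab = b - a
    n_raw = np.cross(ab, bc)
    if np.linalg.norm(n_raw) < 1e-9:
        raise GeometryError("collinear frame atoms")
    n = n_raw / np.linalg.norm(n_raw)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.cos(tor) * np.sin(ang),
        bond * np.sin(tor) * np.sin(ang),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone_from_torsions(
    torsions: list[TorsionTriple],
    anchor: np.ndarray | None = None,
    anchor_psi: float = 140.0,
) -> list[dict[str, np.ndarray]]:
    """Build N/CA/C/O coordinates for one chain segment from its torsions.

    ``anchor``, when given, is the (N, CA, C) coordinate triple of the
    residue immediately upstream; the first built residue is attached to it
    using ``anchor_psi`` as the upstream residue's psi.  Without an anchor
    the chain starts in a canonical frame at the origin (the first phi and
    omega are then unused).  The carbonyl O of residue i is placed in the
    CA(i)-C(i)-N(i+1) plane anti to N(i+1); the terminal O uses the last
    residue's supplied psi the same way.
    """
    if len(torsions) < 1:
        raise GeometryError("need at least one torsion triple")
    residues: list[dict[str, np.ndarray]] = []
    if anchor is None:
        n0 = np.zeros(3)
        ca0 = np.array([BOND_N_CA, 0.0, 0.0])
        theta = np.radians(180.0 - ANG_N_CA_C)
        c0 = ca0 + BOND_CA_C * np.array([np.cos(theta), np.sin(theta), 0.0])
    else:
        anchor = np.asarray(anchor, float)
        if anchor.shape != (3, 3):
            raise GeometryError("anchor must be three atoms (N, CA, C)")
        p_n, p_ca, p_c = anchor
        if np.linalg.norm(np.cross(p_ca - p_n, p_c - p_ca)) < 1e-6:
            raise GeometryError("anchor atoms are collinear")
        n0 = place_atom(p_n, p_ca, p_c, BOND_C_N, ANG_CA_C_N, anchor_psi)
        ca0 = place_atom(p_ca, p_c, n0, BOND_N_CA, ANG_C_N_CA, torsions[0].omega)
        c0 = place_atom(p_c, n0, ca0, BOND_CA_C, ANG_N_CA_C, torsions[0].phi)
    residues.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, len(torsions)):
        prev = residues[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"],
                       BOND_C_N, ANG_CA_C_N, torsions[i - 1].psi)
        ca = place_atom(prev["CA"], prev["C"], n,
                        BOND_N_CA, ANG_C_N_CA, torsions[i].omega)
        c = place_atom(prev["C"], n, ca,
                       BOND_CA_C, ANG_N_CA_C, torsions[i].phi)
        residues.append({"N": n, "CA": ca, "C": c})

    for i, res in enumerate(residues):
        res["O"] = place_atom(
            res["N"], res["CA"], res["C"],
            BOND_C_O, ANG_CA_C_O, _wrap(torsions[i].psi + 180.0),
        )
    return residues


def _wrap(angle: float) -> float:
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def measure_torsions(residues: list[dict[str, np.ndarray]],
                     anchor: np.ndarray | None = None) -> list[TorsionTriple]:
    """phi/psi/omega measured from built coordinates (inverse of the builder).

    Unmeasurable angles (first phi/omega without anchor, psi of the last
    residue which is recovered from the carbonyl O plane) fall back to the
    builder's conventions.
    """
    out = []
    for i, res in enumerate(residues):
        if i > 0:
            prev_c = residues[i - 1]["C"]
            prev_ca = residues[i - 1]["CA"]
            phi = dihedral(prev_c, res["N"], res["CA"], res["C"])
            omega = dihedral(prev_ca, prev_c, res["N"], res["CA"])
        elif anchor is not None:
            phi = dihedral(anchor[2], res["N"], res["CA"], res["C"])
            omega = dihedral(anchor[1], anchor[2], res["N"], res["CA"])
        else:
            phi, omega = -57.0, 180.0  # undefined at a free N-terminus
        if i + 1 < len(residues):
            psi = dihedral(res["N"], res["CA"], res["C"], residues[i + 1]["N"])
        else:
            psi = _wrap(dihedral(res["N"], res["CA"], res["C"], res["O"]) + 180.0)
        out.append(TorsionTriple(_wrap(phi), _wrap(psi), _wrap(omega)))
    return out


# ---------------------------------------------------------------------------
# Loop closure (cyclic coordinate descent)
# ---------------------------------------------------------------------------

def _virtual_extension(last: dict[str, np.ndarray], psi: float = 140.0
                       ) -> np.ndarray:
    """Ideal-geometry (N, CA) of a virtual residue downstream of `last`.

    These two atoms fully determine the exit C-N junction (bond length,
    both flanking angles, and trans omega are fixed by construction), so
    they are the CCD end effectors; the downstream residue's own phi is
    free and not targeted.
    """
    v_n = place_atom(last["N"], last["CA"], last["C"], BOND_C_N, ANG_CA_C_N, psi)
    v_ca = place_atom(last["CA"], last["C"], v_n, BOND_N_CA, ANG_C_N_CA, 180.0)
    return np.array([v_n, v_ca])


def ccd_close(
    residues: list[dict[str, np.ndarray]],
    target_frame: np.ndarray,
    max_iters: int = 200,
    tol: float = 0.5,
) -> tuple[list[dict[str, np.ndarray]], bool, int]:
    """Close a built segment onto a downstream anchor frame by CCD.

    ``target_frame`` holds the (N, CA, C) coordinates of the first fixed
    residue downstream of the segment.  Each sweep visits every phi and psi
    pivot once (omega stays trans) and rotates all downstream N/CA/C atoms
    by the closed-form optimal angle about the pivot bond.  The junction
    distance is the RMSD between the segment's ideally-extended virtual
    (N, CA, C) and the target frame; the best iterate seen is returned, so
    the reported junction distance never increases.  Non-convergence is
    reported via the flag, never an exception.
    """
    if len(residues) < 3:
        raise GeometryError("CCD closure needs a segment of >= 3 residues")
    target = np.asarray(target_frame, float)
    if target.shape not in ((3, 3), (2, 3)) or not np.all(np.isfinite(target)):
        raise GeometryError("target frame must be the downstream (N, CA[, C]) atoms")
    target = target[:2]  # the junction is determined by N and CA alone

    n_res = len(residues)
    # flat coordinate array: N0 CA0 C0 N1 ... C_{n-1}  then 2 virtual atoms
    coords = np.array([res[a] for res in residues for a in ("N", "CA", "C")])
    coords = np.vstack([coords, _virtual_extension(residues[-1])])
    n_atoms = coords.shape[0]

    def junction_rmsd(xyz: np.ndarray) -> float:
        d = xyz[-2:] - target
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    best = coords.copy()
    best_d = junction_rmsd(coords)
    if best_d <= tol:
        return _unflatten(best, n_res, residues), True, 0

    # pivots: (axis_from_idx, axis_to_idx, first moving atom index),
    # visited C-terminal-first so closure adjustments localize near the exit
    pivots = []
    for i in range(n_res):
        base = 3 * i
        pivots.append((base, base + 1, base + 2))      # phi: N->CA moves C...
        pivots.append((base + 1, base + 2, base + 3))  # psi: CA->C moves next N...
    pivots.reverse()

    converged = False
    iters = 0
    stall = 0
    for sweep in range(max_iters):
        iters = sweep + 1
        for p0, p1, first_moving in pivots:
            axis_origin = coords[p1]
            axis = coords[p1] - coords[p0]
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                continue
            u = axis / norm
            ux, uy, uz = u
            m = coords[n_atoms - 2:]  # the virtual end-effector atoms
            rel = m - axis_origin
            base = axis_origin + (rel @ u)[:, None] * u
            r = m - base
            f = target - base
            a = float(np.sum(r * f))
            # b = sum((u x r) . f), cross product written out for speed
            cx = uy * r[:, 2] - uz * r[:, 1]
            cy = uz * r[:, 0] - ux * r[:, 2]
            cz = ux * r[:, 1] - uy * r[:, 0]
            b = float(np.sum(cx * f[:, 0] + cy * f[:, 1] + cz * f[:, 2]))
            theta = np.arctan2(b, a)
            if abs(theta) < 1e-12:
                continue
            # Rodrigues rotation of all downstream atoms about the pivot bond
            v = coords[first_moving:] - axis_origin
            cos_t, sin_t = np.cos(theta), np.sin(theta)
            uxv = np.empty_like(v)
            uxv[:, 0] = uy * v[:, 2] - uz * v[:, 1]
            uxv[:, 1] = uz * v[:, 0] - ux * v[:, 2]
            uxv[:, 2] = ux * v[:, 1] - uy * v[:, 0]
            coords[first_moving:] = (
                v * cos_t + uxv * sin_t
                + np.outer(v @ u, u) * (1.0 - cos_t) + axis_origin
            )
        d = junction_rmsd(coords)
        if d < best_d - 1e-3:
            best_d = d
            best = coords.copy()
            stall = 0
        else:
            if d < best_d:
                best_d = d
                best = coords.copy()
            stall += 1
        if best_d <= tol:
            converged = True
            break
        if stall >= 25:  # stuck in a local minimum; stop burning sweeps
            break
    return _unflatten(best, n_res, residues), converged, iters


def _unflatten(coords: np.ndarray, n_res: int,
               template: list[dict[str, np.ndarray]]) -> list[dict[str, np.ndarray]]:
    out = []
    for i in range(n_res):
        out.append({
            "N": coords[3 * i].copy(),
            "CA": coords[3 * i + 1].copy(),
            "C": coords[3 * i + 2].copy(),
        })
    # rebuild carbonyl O from final geometry (anti to the next N)
    for i, res in enumerate(out):
        if i + 1 < n_res:
            psi = dihedral(res["N"], res["CA"], res["C"], out[i + 1]["N"])
        else:
            psi = 140.0
        res["O"] = place_atom(res["N"], res["CA"], res["C"],
                              BOND_C_O, ANG_CA_C_O, _wrap(psi + 180.0))
    return out


# ---------------------------------------------------------------------------
# Superposition and scores
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_mask: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid superposition (Kabsch, SVD form).

    Returns the reflection-corrected transform mapping `mobile` onto
    `reference` and the RMSD over the fitted positions.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("mobile and reference must be equal-shape (n, 3) arrays")
    if fit_mask is not None:
        mask = np.asarray(fit_mask, bool)
        if mask.shape[0] != P.shape[0]:
            raise GeometryError("fit_mask length mismatch")
        P, Q = P[mask], Q[mask]
    if P.shape[0] < 3:
        raise GeometryError("superposition needs >= 3 fit points")
    Pc = P.mean(axis=0)
    Qc = Q.mean(axis=0)
    P0 = P - Pc
    Q0 = Q - Qc
    if np.linalg.matrix_rank(Q0, tol=1e-8) < 2 or np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) fit point set")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    tr = RigidTransform(R, t)
    return tr, rmsd_over(tr.apply(P), Q)


def rmsd_over(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation over paired coordinates; no re-fitting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.shape[0] < 1:
        raise GeometryError("rmsd needs >= 1 equal-length coordinate pair")
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale; floored at 0.5 A for l_norm <= 21 where the
    canonical cube-root formula goes non-positive."""
    if l_norm > 21:
        return 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8
    return 0.5


def tm_score_over(a: np.ndarray, b: np.ndarray, l_norm: int) -> float:
    """Fixed-superposition TM-score of paired coordinates, normalized by
    ``l_norm`` (no re-fitting, no alignment search)."""
    if l_norm < 1:
        raise GeometryError("l_norm must be >= 1")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise GeometryError("paired coordinate sets must have equal shape")
    d = np.linalg.norm(a - b, axis=-1)
    d0 = tm_d0(l_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)
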