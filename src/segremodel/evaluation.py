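"""Variant evaluation: prediction backend contract, confidence screening,
single-superposition partitioned metrics, and composite ranking.

pLDDT is carried on the 0-100 scale throughout (adapters must rescale 0-1
outputs).  Partitioned metrics follow the single-global-superposition
protocol: one Kabsch fit (over all shared CA atoms, or fixed-region-only),
then RMSD and fixed-superposition TM-score evaluated separately on the
fixed region and the designed segment with no re-fitting between regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneCandidate
from .core import ProvenanceRecord, SegmentSpec, Structure
from .geometry import dihedral, kabsch_superpose, rmsd_over, tm_score_over
from .seqdesign import SequenceVariant
from .ss import assign_ss8, segment_composition

DEFAULT_THRESHOLDS = {
    "segment_plddt_min": 50.0,
    "global_plddt_min": 70.0,
    "ss_coverage_min": 0.40,
}

#: composite metrics: direction +1 means higher is better
COMPOSITE_METRICS = {
    "compliance_pred": +1,
    "segment_mean_plddt": +1,
    "global_mean_plddt": +1,
    "global_score": -1,
    "fixed_rmsd": -1,
}


class EvaluationError(ValueError):
    pass


@dataclass
class PredictionRecord:
    variant_id: str
    structure: Structure  # per-residue pLDDT carried on Residue.plddt
    spec: SegmentSpec
    global_mean_plddt: float
    segment_mean_plddt: float
    provenance: ProvenanceRecord | None = None


@dataclass
class EvaluationRecord:
    variant_id: str
    backbone_id: str
    compliance_pred: float
    segment_ss3: str
    fixed_rmsd: float
    fixed_tm: float
    segment_rmsd: float
    segment_tm: float
    global_score: float
    segment_mean_plddt: float
    global_mean_plddt: float
    composite: float = float("nan")
    rank: int | None = None
    pass_flags: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "backbone_id": self.backbone_id,
            "compliance_pred": self.compliance_pred,
            "segment_ss3": self.segment_ss3,
            "fixed_rmsd": self.fixed_rmsd,
            "fixed_tm": self.fixed_tm,
            "segment_rmsd": self.segment_rmsd,
            "segment_tm": self.segment_tm,
            "global_score": self.global_score,
            "segment_mean_plddt": self.segment_mean_plddt,
            "global_mean_plddt": self.global_mean_plddt,
            "composite": self.composite,
            "rank": self.rank,
        }


def _plddt_from_geometry(chain_residues, segment_nums: set[int],
                         ideal_torsions: tuple[float, float] | None,
                         rng: np.random.Generator) -> np.ndarray:
    """Synthesize per-residue confidence from local geometric irregularity.

    Irregularity combines the deviation of consecutive CA-CA distances
    from 3.8 A and, inside the segment, the torsion deviation from the
    target class ideal; confidence decreases with irregularity, scaled
    into [30, 95] with small seeded jitter.
    """
    n = len(chain_residues)
    ca = np.array([r.atoms["CA"] for r in chain_residues])
    dev = np.zeros(n)
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    ca_dev = np.abs(d - 3.8)
    for i in range(n):
        local = []
        if i > 0:
            local.append(ca_dev[i - 1])
        if i < n - 1:
            local.append(ca_dev[i])
        dev[i] = np.mean(local) if local else 0.0
    tor_dev = np.zeros(n)
    if ideal_torsions is not None:
        phi0, psi0 = ideal_torsions
        for i, r in enumerate(chain_residues):
            if r.res_num not in segment_nums or i == 0 or i >= n - 1:
                continue
            prev, nxt = chain_residues[i - 1], chain_residues[i + 1]
            try:
                phi = dihedral(prev.atoms["C"], r.atoms["N"], r.atoms["CA"],
                               r.atoms["C"])
                psi = dihedral(r.atoms["N"], r.atoms["CA"], r.atoms["C"],
                               nxt.atoms["N"])
            except KeyError:
                continue
            tor_dev[i] = (_angdiff(phi, phi0) + _angdiff(psi, psi0)) / 360.0
    irregularity = dev / 0.4 + tor_dev
    plddt = 95.0 - 45.0 * np.clip(irregularity, 0.0, 1.4)
    plddt += rng.normal(0.0, 1.5, size=n)
    return np.clip(plddt, 30.0, 95.0)


def _angdiff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def mock_predictor(variant: SequenceVariant, wild_type: Structure,
                   backbone: BackboneCandidate, seed: int = 0,
                   jitter: float = 0.05) -> PredictionRecord:
    """Seeded stand-in for a structure predictor.

    The "prediction" is the wild-type fixed region plus the variant's
    parent remodeled segment, with small seeded coordinate jitter;
    pLDDT is synthesized from local geometric irregularity.
    """
    from .geometry import IDEAL_TORSIONS

    spec = backbone.spec
    rng = np.random.default_rng(np.random.SeedSequence(
        [seed, abs(hash(variant.variant_id)) % (2 ** 31)]))
    predicted = backbone.structure.copy()
    predicted.id = f"pred_{variant.variant_id}"
    chain = predicted.chain(spec.chain_id)
    for res in chain.residues:
        for a in res.atoms:
            res.atoms[a] = res.atoms[a] + rng.normal(0.0, jitter, 3)
    seg_nums = set(spec.res_nums())
    plddt = _plddt_from_geometry(chain.residues, seg_nums,
                                 IDEAL_TORSIONS.get(spec.target_ss3), rng)
    for res, p in zip(chain.residues, plddt):
        res.plddt = float(p)
    for other in predicted.chains:
        if other.chain_id != spec.chain_id:
            for res in other.residues:
                res.plddt = 90.0  # untouched context chains
    seg_vals = [chain[n].plddt for n in spec.res_nums()]
    all_vals = [r.plddt for r in predicted.residues()]
    return PredictionRecord(
        variant_id=variant.variant_id,
        structure=predicted,
        spec=spec,
        global_mean_plddt=float(np.mean(all_vals)),
        segment_mean_plddt=float(np.mean(seg_vals)),
        provenance=ProvenanceRecord(
            stage="screen", parent_id=variant.variant_id,
            parameters={"backend": "mock_predictor", "seed": seed,
                        "jitter": jitter}),
    )


class MockPredictionBackend:
    """In-process mock predictor resolving each variant's parent backbone."""

    name = "mock_predictor"

    def __init__(self, wild_type: Structure,
                 backbones: dict[str, BackboneCandidate],
                 jitter: float = 0.05):
        self.wild_type = wild_type
        self.backbones = backbones
        self.jitter = jitter

    def predict(self, variants, seed):
        out = []
        for v in variants:
            bb = self.backbones.get(v.backbone_id)
            if bb is None:
                out.append((v.variant_id, None, "unknown parent backbone"))
                continue
            rec = mock_predictor(v, self.wild_type, bb, seed=seed,
                                 jitter=self.jitter)
            out.append((v.variant_id, rec, None))
        return out


@dataclass
class PredictionRejection:
    variant_id: str
    reason: str


def predict_structures(backend, variants: list[SequenceVariant], seed: int = 0
                       ) -> tuple[list[PredictionRecord], list[PredictionRejection]]:
    """Run a prediction backend; verify residue-count match and confidence
    presence on ingest.  Malformed predictions are rejected per variant."""
    records, rejections = [], []
    for variant_id, rec, err in backend.predict(variants, seed):
        if rec is None:
            rejections.append(PredictionRejection(variant_id, err or "failed"))
            continue
        chain = rec.structure.chain(rec.spec.chain_id)
        if any(r.plddt is None for r in chain.residues):
            rejections.append(PredictionRejection(
                variant_id, "missing per-residue confidence"))
            continue
        records.append(rec)
    return records, rejections


def screen_predictions(
    evaluations: list[EvaluationRecord],
    thresholds: dict | None = None,
) -> tuple[list[EvaluationRecord], dict[str, int]]:
    """Retain records meeting all three screening thresholds (>= semantics);
    per-filter failure counts support failure-mode analysis."""
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    counts = {"segment_plddt": 0, "global_plddt": 0, "ss_coverage": 0}
    kept = []
    for ev in evaluations:
        ok = True
        if ev.segment_mean_plddt < thr["segment_plddt_min"]:
            counts["segment_plddt"] += 1
            ok = False
        if ev.global_mean_plddt < thr["global_plddt_min"]:
            counts["global_plddt"] += 1
            ok = False
        if ev.compliance_pred < thr["ss_coverage_min"]:
            counts["ss_coverage"] += 1
            ok = False
        ev.pass_flags = {
            "segment_plddt": ev.segment_mean_plddt >= thr["segment_plddt_min"],
            "global_plddt": ev.global_mean_plddt >= thr["global_plddt_min"],
            "ss_coverage": ev.compliance_pred >= thr["ss_coverage_min"],
        }
        if ok:
            kept.append(ev)
    return kept, counts


def partitioned_metrics(wild_type: Structure, prediction: PredictionRecord,
                        spec: SegmentSpec, fit: str = "all"
                        ) -> dict[str, float]:
    """One global superposition, then per-region RMSD / TM-score.

    ``fit`` selects the superposed positions: 'all' (every shared CA) or
    'fixed' (fixed-region CA only).  TM normalization uses the region's
    own length.  No re-fitting between regions.
    """
    if fit not in ("all", "fixed"):
        raise EvaluationError(f"fit must be 'all' or 'fixed', got {fit!r}")
    wchain = wild_type.chain(spec.chain_id)
    pchain = prediction.structure.chain(spec.chain_id)
    shared = [n for n in wchain.res_nums if n in pchain]
    if shared != [n for n in pchain.res_nums if n in wchain]:
        raise EvaluationError("residue numbering mismatch between wild type "
                              "and prediction")
    seg = set(spec.res_nums())
    if not seg.issubset(set(shared)):
        raise EvaluationError("prediction does not cover the design segment")
    wild_ca = np.array([wchain[n].ca() for n in shared])
    pred_ca = np.array([pchain[n].ca() for n in shared])
    in_seg = np.array([n in seg for n in shared])
    mask = None if fit == "all" else ~in_seg
    transform, _ = kabsch_superpose(pred_ca, wild_ca, fit_mask=mask)
    moved = transform.apply(pred_ca)
    fixed_idx = ~in_seg
    out = {}
    out["fixed_rmsd"] = rmsd_over(moved[fixed_idx], wild_ca[fixed_idx])
    out["fixed_tm"] = tm_score_over(moved[fixed_idx], wild_ca[fixed_idx],
                                    int(fixed_idx.sum()))
    out["segment_rmsd"] = rmsd_over(moved[in_seg], wild_ca[in_seg])
    out["segment_tm"] = tm_score_over(moved[in_seg], wild_ca[in_seg],
                                      int(in_seg.sum()))
    return out


def evaluate_variants(
    wild_type: Structure,
    spec: SegmentSpec,
    variants: list[SequenceVariant],
    predictions: list[PredictionRecord],
    fit: str = "all",
) -> list[EvaluationRecord]:
    """Assemble per-variant evaluation records (compliance on the predicted
    structure, partitioned metrics, confidence and score columns)."""
    by_id = {v.variant_id: v for v in variants}
    out = []
    for rec in predictions:
        v = by_id.get(rec.variant_id)
        if v is None:
            continue
        ann = assign_ss8(rec.structure)
        comp = segment_composition(ann, spec, rec.structure)
        metrics = partitioned_metrics(wild_type, rec, spec, fit=fit)
        out.append(EvaluationRecord(
            variant_id=rec.variant_id,
            backbone_id=v.backbone_id,
            compliance_pred=comp.compliance,
            segment_ss3=comp.segment_ss3,
            global_score=v.global_score,
            segment_mean_plddt=rec.segment_mean_plddt,
            global_mean_plddt=rec.global_mean_plddt,
            **metrics,
        ))
    return out


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return (values - med) / max(mad, 1e-9)


def composite_rank(
    evaluations: list[EvaluationRecord],
    weights: dict[str, float] | None = None,
) -> list[EvaluationRecord]:
    """Robust-z composite score and ranking.

    Each metric column is median/MAD-standardized (MAD floor 1e-9),
    direction-aligned so higher is better, and weighted-summed (equal
    weights by default).  Ties break by variant id.  A single-variant
    input gets composite 0 by convention.
    """
    if not evaluations:
        raise EvaluationError("no evaluations to rank")
    w = {m: 1.0 for m in COMPOSITE_METRICS}
    if weights:
        unknown = set(weights) - set(w)
        if unknown:
            raise EvaluationError(f"unknown composite metrics: {sorted(unknown)}")
        w.update(weights)
    if len(evaluations) == 1:
        evaluations[0].composite = 0.0
        evaluations[0].rank = 1
        return list(evaluations)
    cols = {}
    for metric, direction in COMPOSITE_METRICS.items():
        vals = np.array([getattr(ev, metric) for ev in evaluations], float)
        cols[metric] = direction * _robust_z(vals)
    total = sum(w[m] * cols[m] for m in COMPOSITE_METRICS)
    for ev, score in zip(evaluations, total):
        ev.composite = float(score)
    ranked = sorted(evaluations, key=lambda e: (-e.composite, e.variant_id))
    for i, ev in enumerate(ranked):
        ev.rank = i + 1
    return ranked
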