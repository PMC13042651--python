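"""Inverse-folding stage: backend contract, score-based filtering, pairwise
identity, greedy clustering, and adaptive representative-count control.

Sequences are equal-length by construction (segment remodeling preserves
residue count), so identity is positional and no alignment step is needed —
a deliberate restriction relative to general-purpose clustering tools.
Global scores follow the inverse-folding convention: lower is better.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneCandidate
from .core import ProvenanceRecord

#: residue propensity sets per SS3 class used by the mock designer
HELIX_FORMERS = "ALEKMQ"
STRAND_FORMERS = "VIYTFW"
ALL_AA = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_TEMPERATURE = 0.2
DEFAULT_MIN_SEQ_ID_GRID = (0.95, 0.90, 0.85, 0.80, 0.70, 0.60, 0.50)
DEFAULT_TARGET_REPS = (100, 500)


@dataclass
class SequenceVariant:
    variant_id: str
    backbone_id: str
    sequence: str
    global_score: float
    temperature: float
    provenance: ProvenanceRecord | None = None


@dataclass
class VariantRejection:
    variant_id: str
    reason: str


def _stable_hash(*parts) -> int:
    blob = "|".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big")


def _propensity_probs(target_ss3: str, temperature: float) -> np.ndarray:
    """Amino-acid sampling distribution for one designed position.

    Favored residues for the segment's target class carry most of the
    mass; raising the temperature flattens the distribution toward
    uniform (p proportional to base**(1/T)); T -> 0 gives the argmax."""
    favored = {"H": HELIX_FORMERS, "E": STRAND_FORMERS}.get(target_ss3, "")
    base = np.ones(20)
    for rank, aa in enumerate(favored):
        # strictly decreasing weights so the zero-temperature limit is unique
        base[ALL_AA.index(aa)] = 12.0 - rank
    if not favored:  # coil: mildly favor G/P/S/N/D
        for rank, aa in enumerate("GPSND"):
            base[ALL_AA.index(aa)] = 6.0 - rank * 0.5
    base /= base.sum()
    if temperature <= 1e-6:
        out = np.zeros(20)
        out[int(np.argmax(base))] = 1.0
        return out
    p = base ** (1.0 / temperature)
    return p / p.sum()


def mock_design_backend(backbone: BackboneCandidate, n: int,
                        temperature: float = DEFAULT_TEMPERATURE,
                        seed: int = 0,
                        redesign_positions: set[int] | None = None
                        ) -> list[SequenceVariant]:
    """Seeded stand-in for an inverse-folding model.

    Segment residues are drawn from SS-conditioned propensity tables;
    the global score is a backbone-specific base level (seeded hash) plus
    Gaussian noise minus a bonus proportional to propensity agreement, so
    sequences matching the target class tend to score lower (better).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = backbone.spec
    chain = backbone.structure.chain(spec.chain_id)
    wild = chain.sequence()
    nums = chain.res_nums
    positions = redesign_positions if redesign_positions is not None \
        else set(spec.res_nums())
    design_idx = [i for i, num in enumerate(nums) if num in positions]

    probs = _propensity_probs(spec.target_ss3, temperature)
    favored = set({"H": HELIX_FORMERS, "E": STRAND_FORMERS}.get(spec.target_ss3, ""))
    base = 0.8 + (_stable_hash(backbone.candidate_id, seed) % 1000) / 1250.0
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, _stable_hash(backbone.candidate_id)]))

    variants = []
    for k in range(n):
        seq = list(wild)
        for i in design_idx:
            seq[i] = ALL_AA[rng.choice(20, p=probs)]
        seq = "".join(seq)
        agreement = (sum(seq[i] in favored for i in design_idx) / len(design_idx)
                     if design_idx and favored else 0.0)
        score = base + 0.15 * rng.normal() - 0.5 * agreement
        variants.append(SequenceVariant(
            variant_id=f"{backbone.candidate_id}_seq_{k:05d}",
            backbone_id=backbone.candidate_id,
            sequence=seq,
            global_score=float(score),
            temperature=temperature,
            provenance=ProvenanceRecord(
                stage="sequence", parent_id=backbone.candidate_id,
                parameters={"backend": "mock", "temperature": temperature,
                            "seed": seed, "index": k}),
        ))
    return variants


def score_wild_type(backbone: BackboneCandidate, seed: int = 0,
                    temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Score the unmodified wild-type sequence through the mock backend's
    scoring rule; reported alongside design-score distributions."""
    chain = backbone.structure.chain(backbone.spec.chain_id)
    wild = chain.sequence()
    favored = set({"H": HELIX_FORMERS,
                   "E": STRAND_FORMERS}.get(backbone.spec.target_ss3, ""))
    design_idx = [i for i, num in enumerate(chain.res_nums)
                  if num in set(backbone.spec.res_nums())]
    agreement = (sum(wild[i] in favored for i in design_idx) / len(design_idx)
                 if design_idx and favored else 0.0)
    base = 0.8 + (_stable_hash(backbone.candidate_id, seed) % 1000) / 1250.0
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, _stable_hash(backbone.candidate_id), 1]))
    return float(base + 0.15 * rng.normal() - 0.5 * agreement)


class MockSequenceBackend:
    name = "mock"

    def design(self, backbone, n, temperature, redesign_positions, seed):
        return mock_design_backend(backbone, n, temperature, seed,
                                   redesign_positions)


def design_sequences(backend, backbone: BackboneCandidate, n: int,
                     temperature: float = DEFAULT_TEMPERATURE,
                     redesign_positions: set[int] | None = None,
                     seed: int = 0
                     ) -> tuple[list[SequenceVariant], list[VariantRejection]]:
    """Run a sequence-design backend and verify its output on ingest.

    Positions outside ``redesign_positions`` (default: the design segment)
    must equal the wild type; violating or wrong-length sequences are
    rejected with a record.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    chain = backbone.structure.chain(backbone.spec.chain_id)
    wild = chain.sequence()
    nums = chain.res_nums
    positions = redesign_positions if redesign_positions is not None \
        else set(backbone.spec.res_nums())
    unknown = positions - set(nums)
    if unknown:
        raise ValueError(f"redesign positions not in chain: {sorted(unknown)}")

    raw = backend.design(backbone, n, temperature, positions, seed)
    kept, rejected = [], []
    for v in raw:
        if len(v.sequence) != len(wild):
            rejected.append(VariantRejection(
                v.variant_id, f"length {len(v.sequence)} != chain {len(wild)}"))
            continue
        mutated = [num for i, num in enumerate(nums)
                   if num not in positions and v.sequence[i] != wild[i]]
        if mutated:
            rejected.append(VariantRejection(
                v.variant_id, f"constrained positions mutated: {mutated[:5]}"))
            continue
        kept.append(v)
    return kept, rejected


def filter_top_fraction(variants: list[SequenceVariant],
                        fraction: float = 0.5) -> list[SequenceVariant]:
    """Keep the best-scoring ceil(fraction * n) variants (lower score is
    better); ties broken by variant id."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    ordered = sorted(variants, key=lambda v: (v.global_score, v.variant_id))
    return ordered[: math.ceil(fraction * len(variants))]


def pairwise_identity(a: str, b: str) -> float:
    """Positional identity of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def greedy_cluster(variants: list[SequenceVariant], min_seq_id: float
                   ) -> tuple[list[SequenceVariant], dict[str, str]]:
    """Greedy clustering in ascending score order.

    Each variant joins the first existing representative it matches at
    identity >= min_seq_id, else founds a new cluster.  Returns
    representatives in creation order and a member -> representative map.
    """
    ordered = sorted(variants, key=lambda v: (v.global_score, v.variant_id))
    reps: list[SequenceVariant] = []
    membership: dict[str, str] = {}
    for v in ordered:
        for rep in reps:
            if pairwise_identity(v.sequence, rep.sequence) >= min_seq_id:
                membership[v.variant_id] = rep.variant_id
                break
        else:
            reps.append(v)
            membership[v.variant_id] = v.variant_id
    return reps, membership


@dataclass
class ClusteringResult:
    min_seq_id: float
    representatives: list[SequenceVariant]
    membership: dict[str, str]
    in_range: bool
    counts_by_threshold: dict[float, int] = field(default_factory=dict)


def adapt_min_seq_id(
    variants: list[SequenceVariant],
    target_range: tuple[int, int] = DEFAULT_TARGET_REPS,
    grid: tuple[float, ...] = DEFAULT_MIN_SEQ_ID_GRID,
) -> ClusteringResult:
    """Walk the identity grid from strictest down and keep the first
    threshold whose representative count lands in the target range; if
    none does, keep the threshold closest to the range, flagged."""
    if not variants:
        raise ValueError("no variants to cluster")
    low, high = target_range
    counts: dict[float, int] = {}
    results: dict[float, tuple] = {}
    for thr in sorted(grid, reverse=True):
        reps, membership = greedy_cluster(variants, thr)
        counts[thr] = len(reps)
        results[thr] = (reps, membership)
        if low <= len(reps) <= high:
            return ClusteringResult(thr, reps, membership, True, counts)

    def distance(thr):
        c = counts[thr]
        return low - c if c < low else c - high

    best_thr = min(sorted(counts, reverse=True), key=distance)
    reps, membership = results[best_thr]
    return ClusteringResult(best_thr, reps, membership, False, counts)
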