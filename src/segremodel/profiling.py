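"""Evolutionary profiling: MSA handling, redundancy filtering, per-residue
conservation / Neff tracks, and designable-segment nomination.

The library consumes a ready multiple sequence alignment (FASTA/A2M or
Stockholm); running a homology search is an optional external step.  Neff
at a column is the exponentiated weighted Shannon entropy of amino-acid
frequencies (gaps excluded from normalization), bounded in [1, 20];
conservation is the bounded reporting transform 1 - ln(Neff)/ln(20).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .core import Chain, SegmentSpec, Structure

GAP_CHARS = "-."


class MSAError(ValueError):
    pass


@dataclass
class MSA:
    """Aligned sequences with a designated query row and optional weights."""

    ids: list[str]
    rows: list[str]
    query_index: int = 0
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise MSAError("empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise MSAError("alignment rows have unequal lengths")
        if not (0 <= self.query_index < len(self.rows)):
            raise MSAError("query index out of range")
        if self.weights is not None:
            w = np.asarray(self.weights, float)
            if w.shape != (len(self.rows),) or w.sum() <= 0:
                raise MSAError("weights must be per-row with positive sum")
            self.weights = w

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def query(self) -> str:
        return self.rows[self.query_index]

    def query_sequence(self) -> str:
        return "".join(c for c in self.query if c not in GAP_CHARS)


def read_msa(path, format: str = "auto", query_id: str | None = None) -> MSA:
    """Read a FASTA/A2M or Stockholm alignment into query frame.

    A2M lowercase insert states are uppercased and '.' gaps normalized to
    '-' first; then every column gapped in the query row is dropped, so
    profile columns map 1:1 onto query residues.  The query row is the
    named id, or the first row.
    """
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") \
            else "fasta"
    biofmt = {"fasta": "fasta", "a2m": "fasta", "stockholm": "stockholm"}.get(fmt)
    if biofmt is None:
        raise MSAError(f"unknown MSA format {fmt!r}")
    try:
        aln = AlignIO.read(str(path), biofmt)
    except Exception as exc:
        raise MSAError(f"cannot parse {path} as {fmt}: {exc}") from exc

    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).replace(".", "-").upper() for rec in aln]
    qidx = 0
    if query_id is not None:
        try:
            qidx = ids.index(query_id)
        except ValueError:
            raise MSAError(f"query id {query_id!r} not in alignment") from None
    keep = [i for i, c in enumerate(rows[qidx]) if c not in GAP_CHARS]
    rows = ["".join(r[i] for i in keep) for r in rows]
    return MSA(ids=ids, rows=rows, query_index=qidx)


def map_query_to_structure(msa: MSA, structure: Structure,
                           chain_id: str) -> dict[int, int]:
    """Map query-frame columns onto chain residue numbers by exact sequence
    match (with offset).  Raises naming the first mismatching position."""
    chain = structure.chain(chain_id)
    chain_seq = chain.sequence()
    qseq = msa.query_sequence()
    start = chain_seq.find(qseq)
    if start < 0:
        # report first mismatch against the best offset-0 comparison
        for i, (a, b) in enumerate(zip(qseq, chain_seq)):
            if a != b:
                raise MSAError(
                    f"query does not match chain {chain_id}: first mismatch "
                    f"at query position {i + 1} ({a!r} vs {b!r})"
                )
        raise MSAError(
            f"query ({len(qseq)} aa) does not match chain {chain_id} "
            f"({len(chain_seq)} aa)"
        )
    nums = chain.res_nums
    return {col: nums[start + col] for col in range(len(qseq))}


def _pair_identity(a: str, b: str) -> float:
    """Aligned identity: matches over mutually non-gap columns, divided by
    the shorter ungapped length."""
    matches = 0
    len_a = len_b = 0
    for x, y in zip(a, b):
        gx = x in GAP_CHARS
        gy = y in GAP_CHARS
        if not gx:
            len_a += 1
        if not gy:
            len_b += 1
        if not gx and not gy and x == y:
            matches += 1
    denom = min(len_a, len_b)
    return matches / denom if denom else 0.0


def filter_redundancy(msa: MSA, max_identity: float = 0.80) -> MSA:
    """Greedy redundancy filter in input order.

    The query row is always kept first; every other row is kept iff its
    identity to each previously kept row is strictly below the threshold.
    Idempotent by construction.
    """
    order = [msa.query_index] + [i for i in range(msa.n_rows)
                                 if i != msa.query_index]
    kept: list[int] = []
    for i in order:
        if i == msa.query_index or all(
                _pair_identity(msa.rows[i], msa.rows[j]) < max_identity
                for j in kept):
            kept.append(i)
    kept_sorted = sorted(kept)
    return MSA(
        ids=[msa.ids[i] for i in kept_sorted],
        rows=[msa.rows[i] for i in kept_sorted],
        query_index=kept_sorted.index(msa.query_index),
    )


def sequence_weights(msa: MSA, cluster_identity: float = 0.80) -> np.ndarray:
    """Single-linkage cluster rows at the identity threshold; each row's
    weight is 1 / (its cluster size)."""
    n = msa.n_rows
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _pair_identity(msa.rows[i], msa.rows[j]) >= cluster_identity:
                parent[find(i)] = find(j)
    sizes: dict[int, int] = {}
    roots = [find(i) for i in range(n)]
    for r in roots:
        sizes[r] = sizes.get(r, 0) + 1
    return np.array([1.0 / sizes[r] for r in roots])


def column_neff(msa: MSA, weights: np.ndarray, column: int) -> tuple[float, bool]:
    """Effective number of amino acids at a query-frame column.

    Weighted frequencies run over non-gap symbols only; Neff is the
    exponential of the Shannon entropy.  Returns (neff, empty_flag) where
    the flag marks columns with zero non-gap weight (Neff pinned to 1).
    """
    if not (0 <= column < msa.width):
        raise MSAError(f"column {column} out of range")
    freqs: dict[str, float] = {}
    total = 0.0
    for row, w in zip(msa.rows, weights):
        c = row[column]
        if c in GAP_CHARS:
            continue
        freqs[c] = freqs.get(c, 0.0) + w
        total += w
    if total <= 0:
        return 1.0, True
    p = np.array(list(freqs.values())) / total
    p = p[p > 0]
    entropy = -np.sum(p * np.log(p))
    return float(np.exp(entropy)), False


def conservation_from_neff(neff: float) -> float:
    """Bounded conservation track: 1 - ln(Neff)/ln(20)."""
    return 1.0 - np.log(max(neff, 1.0)) / np.log(20.0)


@dataclass(frozen=True)
class ResidueProfile:
    res_num: int
    aa: str
    ss3: str
    neff: float
    conservation: float
    designable: bool = False
    empty_column: bool = False


def build_residue_profiles(msa: MSA, structure: Structure, chain_id: str,
                           ss3: str | None = None,
                           cluster_identity: float = 0.80) -> list[ResidueProfile]:
    """Per-residue Neff/conservation tracks aligned to chain numbering."""
    from .ss import assign_ss8

    mapping = map_query_to_structure(msa, structure, chain_id)
    weights = msa.weights if msa.weights is not None \
        else sequence_weights(msa, cluster_identity)
    chain = structure.chain(chain_id)
    if ss3 is None:
        ann = assign_ss8(structure)
        ss3_by_num = {n: ann.ss3_at(chain_id, n) for n in chain.res_nums}
    else:
        ss3_by_num = dict(zip(chain.res_nums, ss3))
    profiles = []
    for col, res_num in mapping.items():
        neff, empty = column_neff(msa, weights, col)
        profiles.append(ResidueProfile(
            res_num=res_num,
            aa=chain[res_num].one_letter,
            ss3=ss3_by_num.get(res_num, "C"),
            neff=neff,
            conservation=conservation_from_neff(neff),
            empty_column=empty,
        ))
    return profiles


@dataclass(frozen=True)
class SegmentCandidate:
    """A nominated designable run, ranked by mean Neff x length."""

    chain_id: str
    start: int
    end: int
    mean_neff: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def score(self) -> float:
        return self.mean_neff * self.length

    def as_spec(self, target_ss3: str) -> SegmentSpec:
        return SegmentSpec(self.chain_id, self.start, self.end, target_ss3)


def select_designable_segments(
    profiles: list[ResidueProfile],
    chain_id: str,
    min_len: int = 6,
    neff_quantile: float = 0.5,
    exclusions: set[int] | None = None,
) -> list[SegmentCandidate]:
    """Nominate maximal coil runs of low evolutionary constraint.

    A residue qualifies iff it is coil (ss3 == 'C'), its Neff is strictly
    above the chain-wide quantile (low constraint = high Neff), and it is
    not in the exclusion set (user-supplied essential residues, e.g.
    catalytic positions).  Runs of length >= min_len are returned ranked
    by mean Neff x length, descending; terminal runs are eligible.
    """
    exclusions = exclusions or set()
    if not profiles:
        return []
    threshold = float(np.quantile([p.neff for p in profiles], neff_quantile))
    eligible = {
        p.res_num: p.neff for p in profiles
        if p.ss3 == "C" and p.neff > threshold and p.res_num not in exclusions
    }
    runs: list[SegmentCandidate] = []
    nums = sorted(p.res_num for p in profiles)
    run: list[int] = []
    for n in nums + [None]:
        if n is not None and n in eligible and (not run or n == run[-1] + 1):
            run.append(n)
            continue
        if len(run) >= min_len:
            runs.append(SegmentCandidate(
                chain_id, run[0], run[-1],
                float(np.mean([eligible[m] for m in run])),
            ))
        run = [n] if (n is not None and n in eligible) else []
    runs.sort(key=lambda c: (-c.score, c.start))
    return runs


def run_jackhmmer(query_fasta, database_fasta, out_path,
                  evalue: float = 1e-3, max_hits: int = 5000) -> dict:
    """Optional external homology-search adapter.

    Invokes a local ``jackhmmer`` executable (file in, Stockholm
    alignment out) and returns a provenance dict recording the search
    parameters.  Never required by the library: all profiling operations
    consume a ready MSA.
    """
    import shutil
    import subprocess

    exe = shutil.which("jackhmmer")
    if exe is None:
        raise MSAError("jackhmmer executable not found on PATH")
    cmd = [exe, "--incE", str(evalue), "-E", str(evalue),
           "-A", str(out_path), str(query_fasta), str(database_fasta)]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise MSAError(f"jackhmmer failed: {proc.stderr[-500:]}")
    return {"tool": "jackhmmer", "evalue": evalue, "max_hits": max_hits,
            "alignment": str(out_path)}


def write_profile_table(profiles: list[ResidueProfile], path) -> None:
    """Tab-separated per-residue profile export."""
    with open(path, "w") as fh:
        fh.write("res_num\taa\tss3\tneff\tconservation\tdesignable\n")
        for p in profiles:
            fh.write(f"{p.res_num}\t{p.aa}\t{p.ss3}\t{p.neff:.4f}\t"
                     f"{p.conservation:.4f}\t{int(p.designable)}\n")
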