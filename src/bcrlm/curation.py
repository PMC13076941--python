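"""Repertoire curation: QC filtering, identity clustering, splitting.

Deduplication follows the CD-HIT recipe — greedy incremental clustering by
descending length at a 95% identity threshold, keeping one representative
per cluster — but with an exactly defined identity: matches divided by
global-alignment length under match +1 / mismatch 0 / linear gap −1
scoring, ties broken toward fewer gaps.  Running deduplication *before*
the train/validation/test split is what guarantees that no test sequence
is ≥95% identical to any training sequence.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .records import AA_ALPHABET, HEAVY, LIGHT, BCRRecord

_CODE = {c: i for i, c in enumerate(AA_ALPHABET)}

CDR3_MIN_LEN = 6
CDR3_MAX_LEN = 29


def _encode_seq(s: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in s), dtype=np.int8, count=len(s))


@njit(cache=False)
def _nw_matches_alen(a: np.ndarray, b: np.ndarray) -> Tuple[int, int]:  # pragma: no cover
    """Global alignment DP returning (matches, alignment length) of the
    optimal alignment under match +1 / mismatch 0 / gap −1, maximizing
    score first, then fewest gaps, tie-broken diagonal > up > left."""
    la, lb = a.size, b.size
    K = la + lb + 1  # dominates the gap counter in the combined objective
    C = np.empty((la + 1, lb + 1), dtype=np.int64)  # score*K - gaps
    M = np.zeros((la + 1, lb + 1), dtype=np.int64)  # matches on chosen path
    A = np.zeros((la + 1, lb + 1), dtype=np.int64)  # alignment columns
    C[0, 0] = 0
    for i in range(1, la + 1):
        C[i, 0] = -i * K - i
        A[i, 0] = i
    for j in range(1, lb + 1):
        C[0, j] = -j * K - j
        A[0, j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            eq = 1 if a[i - 1] == b[j - 1] else 0
            cd = C[i - 1, j - 1] + eq * K
            cu = C[i - 1, j] - K - 1
            cl = C[i, j - 1] - K - 1
            if cd >= cu and cd >= cl:
                C[i, j] = cd
                M[i, j] = M[i - 1, j - 1] + eq
                A[i, j] = A[i - 1, j - 1] + 1
            elif cu >= cl:
                C[i, j] = cu
                M[i, j] = M[i - 1, j]
                A[i, j] = A[i - 1, j] + 1
            else:
                C[i, j] = cl
                M[i, j] = M[i, j - 1]
                A[i, j] = A[i, j - 1] + 1
    return M[la, lb], A[la, lb]


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions in the optimal global
    alignment of ``a`` and ``b`` (see module docstring for the scoring)."""
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    m, alen = _nw_matches_alen(_encode_seq(a), _encode_seq(b))
    return m / alen


def identity_upper_bound(a: str, b: str) -> float:
    """Cheap upper bound on pairwise_identity: aligned matches cannot
    exceed the residue-multiset intersection, and the alignment is at
    least as long as the longer sequence.  Never underestimates."""
    ca = np.bincount(_encode_seq(a), minlength=20)
    cb = np.bincount(_encode_seq(b), minlength=20)
    return float(np.minimum(ca, cb).sum()) / max(len(a), len(b))


# ---------------------------------------------------------------------------
# QC filtering


def qc_filter(
    records: Sequence[BCRRecord],
    min_cdr3_len: int = CDR3_MIN_LEN,
    max_cdr3_len: int = CDR3_MAX_LEN,
    filter_light_cdr3: bool = True,
) -> Tuple[List[BCRRecord], Dict[str, int]]:
    """Apply the quality-control filters in fixed precedence order.

    A record is rejected for (1) a missing CDR3, then (2) incomplete
    V(D)J annotation (V+D+J for heavy, V+J for light), then (3) CDR3
    length outside [min_cdr3_len, max_cdr3_len].  Returns the kept
    records and a per-rule rejection count whose sum equals the number
    rejected.
    """
    kept: List[BCRRecord] = []
    report = {"missing_cdr3": 0, "incomplete_annotation": 0, "cdr3_length": 0}
    for r in records:
        if not r.hcdr3:
            report["missing_cdr3"] += 1
            continue
        complete = r.v_call and r.j_call and (r.chain == LIGHT or r.d_call)
        if not complete:
            report["incomplete_annotation"] += 1
            continue
        if r.chain == HEAVY or filter_light_cdr3:
            if not (min_cdr3_len <= len(r.hcdr3) <= max_cdr3_len):
                report["cdr3_length"] += 1
                continue
        kept.append(r)
    return kept, report


# ---------------------------------------------------------------------------
# Greedy identity clustering

ClusterAssignment = namedtuple("ClusterAssignment", ["cluster_id", "representative_id", "identity"])


def dedup_cluster(
    records: Sequence[BCRRecord],
    threshold: float = 0.95,
    per_chain: bool = True,
) -> Tuple[List[BCRRecord], Dict[str, ClusterAssignment]]:
    """Greedy incremental identity clustering, one representative each.

    Records are processed by descending sequence length (input order on
    ties); each joins the first existing cluster whose representative has
    identity ≥ threshold, else founds a new cluster.  Heavy and light
    chains are clustered separately by default.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    groups: List[List[BCRRecord]] = (
        [[r for r in records if r.chain == HEAVY], [r for r in records if r.chain == LIGHT]]
        if per_chain
        else [list(records)]
    )
    representatives: List[BCRRecord] = []
    cluster_map: Dict[str, ClusterAssignment] = {}
    cluster_counter = 0
    for group in groups:
        order = sorted(range(len(group)), key=lambda i: (-len(group[i].sequence), i))
        reps: List[Tuple[BCRRecord, str, np.ndarray]] = []  # (record, cluster_id, codes)
        for i in order:
            rec = group[i]
            assigned = False
            for rep, cid, _codes in reps:
                if identity_upper_bound(rec.sequence, rep.sequence) < threshold:
                    continue
                ident = pairwise_identity(rec.sequence, rep.sequence)
                if ident >= threshold:
                    cluster_map[rec.id] = ClusterAssignment(cid, rep.id, ident)
                    assigned = True
                    break
            if not assigned:
                cid = f"c{cluster_counter:06d}"
                cluster_counter += 1
                reps.append((rec, cid, _encode_seq(rec.sequence)))
                representatives.append(rec)
                cluster_map[rec.id] = ClusterAssignment(cid, rec.id, 1.0)
    return representatives, cluster_map


# ---------------------------------------------------------------------------
# Train/validation/test splitting


@dataclass
class SplitResult:
    train: List[BCRRecord]
    validation: List[BCRRecord]
    test: List[BCRRecord]
    ratios: Tuple[float, float, float]
    seed: int


def _allocate(n: int, ratios: Sequence[float]) -> List[int]:
    """Floor-then-distribute rounding of n items to ratio quotas.

    Leftover items go first to still-empty parts with positive ratio,
    then by largest fractional remainder (earlier part on ties), so that
    no part with positive ratio is starved when n is small.
    """
    total = float(sum(ratios))
    quotas = [n * r / total for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    fracs = [q - c for q, c in zip(quotas, counts)]
    # priority: (still empty & positive ratio) first, then fractional part
    order = sorted(
        range(len(ratios)),
        key=lambda k: (not (counts[k] == 0 and ratios[k] > 0), -fracs[k], k),
    )
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def split(
    records: Sequence[BCRRecord],
    ratios: Tuple[float, float, float] = (90, 5, 5),
    seed: int = 0,
) -> SplitResult:
    """Shuffle by seed and partition contiguously by cumulative ratio."""
    if len(ratios) != 3 or any(r < 0 for r in ratios) or sum(ratios) <= 0:
        raise ValueError("ratios must be three non-negative weights with positive sum")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    shuffled = [records[i] for i in perm]
    n_train, n_val, n_test = _allocate(len(records), ratios)
    return SplitResult(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        ratios=tuple(ratios),
        seed=seed,
    )


def max_cross_identity(
    test_set: Sequence[BCRRecord],
    train_set: Sequence[BCRRecord],
    sample: Optional[int] = None,
    seed: int = 0,
) -> float:
    """Maximum pairwise identity between test and train sequences.

    With ``sample`` given, that many random cross pairs are audited
    instead of the full cross product.  The multiset upper bound is used
    to skip alignments that cannot beat the current maximum (exact).
    """
    if not test_set or not train_set:
        raise ValueError("max_cross_identity requires two non-empty sets")
    if sample is not None:
        rng = np.random.default_rng(seed)
        pairs = [
            (int(i), int(j))
            for i, j in zip(
                rng.integers(0, len(test_set), size=sample),
                rng.integers(0, len(train_set), size=sample),
            )
        ]
    else:
        pairs = [(i, j) for i in range(len(test_set)) for j in range(len(train_set))]
    best = 0.0
    for i, j in pairs:
        a, b = test_set[i].sequence, train_set[j].sequence
        if identity_upper_bound(a, b) <= best:
            continue
        best = max(best, pairwise_identity(a, b))
        if best == 1.0:
            break
    return best


def curate_pipeline(
    records: Sequence[BCRRecord],
    threshold: float = 0.95,
    ratios: Tuple[float, float, float] = (90, 5, 5),
    seed: int = 0,
) -> Tuple[SplitResult, Dict[str, int], Dict[str, ClusterAssignment]]:
    """QC filter → dedup (before splitting) → 90:5:5 split."""
    kept, report = qc_filter(records)
    reps, cluster_map = dedup_cluster(kept, threshold=threshold)
    result = split(reps, ratios=ratios, seed=seed)
    return result, report, cluster_map
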