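"""Synthetic BCR repertoire and paratope-set simulation.

The simulator emulates the statistical structure that repertoire language
models assume: V(D)J germline recombination with junctional diversity,
subtype-dependent somatic hypermutation (SHM) load and isotype usage, and
optional subtype-specific k-mers planted inside the heavy-chain CDR3 so
that phenotype supervision carries learnable sequence signal.  It is not a
biophysical model (no AID hotspots, no nucleotide level, no clonal trees).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .records import AA_ALPHABET, AA_SET, HEAVY, ISOTYPES, LIGHT, BCRRecord, ParatopeRecord

_AA = np.array(list(AA_ALPHABET))

#: Default six-subtype label set (configurable; ordered from least to most
#: antigen-experienced).
DEFAULT_SUBTYPES: Tuple[str, ...] = (
    "immature",
    "naive",
    "unswitched_memory",
    "switched_memory",
    "plasmablast",
    "plasma",
)

DEFAULT_PROPORTIONS: Tuple[float, ...] = (0.05, 0.45, 0.10, 0.25, 0.05, 0.10)

#: Per-residue substitution probability by subtype: antigen-inexperienced
#: cells carry near-germline receptors, memory/plasma compartments carry
#: progressively higher SHM load.
DEFAULT_SHM_RATES: Dict[str, float] = {
    "immature": 0.0,
    "naive": 0.005,
    "unswitched_memory": 0.03,
    "switched_memory": 0.06,
    "plasmablast": 0.07,
    "plasma": 0.08,
}

# Isotype usage per subtype, ordered as ISOTYPES = (IgM, IgD, IgG, IgA, IgE):
# surface IgM/IgD dominate antigen-inexperienced cells; class-switched
# compartments shift to IgG/IgA.
DEFAULT_ISOTYPE_DISTRIBUTIONS: Dict[str, Tuple[float, ...]] = {
    "immature": (0.85, 0.12, 0.01, 0.01, 0.01),
    "naive": (0.80, 0.17, 0.01, 0.01, 0.01),
    "unswitched_memory": (0.80, 0.10, 0.05, 0.04, 0.01),
    "switched_memory": (0.05, 0.03, 0.60, 0.30, 0.02),
    "plasmablast": (0.07, 0.01, 0.55, 0.35, 0.02),
    "plasma": (0.07, 0.01, 0.45, 0.45, 0.02),
}

#: Subtype-specific HCDR3 k-mers planted with probability ``motif_strength``.
DEFAULT_MOTIFS: Dict[str, str] = {
    "immature": "ARDYW",
    "naive": "GYSSW",
    "unswitched_memory": "DTAMV",
    "switched_memory": "RGLEW",
    "plasmablast": "KWELP",
    "plasma": "HNYPM",
}


def _motif_for_label(label: str, length: int = 5) -> str:
    """Deterministic pseudo-random k-mer for labels without a preset motif."""
    rng = np.random.default_rng(zlib.crc32(label.encode()) % (2**31))
    return "".join(rng.choice(_AA, size=length))


@dataclass
class GermlinePools:
    """Germline V/D/J segment pools as (symbol, amino-acid string) pairs."""

    v_segments: List[Tuple[str, str]]
    d_segments: List[Tuple[str, str]]
    j_segments: List[Tuple[str, str]]
    light_v_segments: List[Tuple[str, str]]
    light_j_segments: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        for name in ("v_segments", "d_segments", "j_segments", "light_v_segments", "light_j_segments"):
            pool = getattr(self, name)
            if len(pool) < 1:
                raise ValueError(f"{name}: pool must contain at least one segment")
            for sym, seq in pool:
                if not seq or not set(seq) <= AA_SET:
                    raise ValueError(f"{name}: segment {sym!r} is not a 20-letter amino-acid string")
        syms = self.all_symbols()
        if len(syms) != len(set(syms)):
            raise ValueError("germline segment symbols must be unique")

    def all_symbols(self) -> List[str]:
        return [
            sym
            for pool in (
                self.v_segments,
                self.d_segments,
                self.j_segments,
                self.light_v_segments,
                self.light_j_segments,
            )
            for sym, _ in pool
        ]


# Default pool sizes chosen so the combined gene-symbol count is 230,
# matching the vocabulary's gene block at full configuration.
PAPER_POOL_SIZES = dict(n_v=75, n_d=27, n_j=6, n_light_v=110, n_light_j=12)


def _random_segment(rng: np.random.Generator, lo: int, hi: int, suffix: str = "") -> str:
    length = int(rng.integers(lo, hi + 1)) - len(suffix)
    return "".join(rng.choice(_AA, size=length)) + suffix


def build_germline_pools(
    n_v: int = PAPER_POOL_SIZES["n_v"],
    n_d: int = PAPER_POOL_SIZES["n_d"],
    n_j: int = PAPER_POOL_SIZES["n_j"],
    seed: int = 0,
    n_light_v: int = PAPER_POOL_SIZES["n_light_v"],
    n_light_j: int = PAPER_POOL_SIZES["n_light_j"],
) -> GermlinePools:
    """Generate deterministic germline pools.

    Heavy V segments end in the cysteine that anchors the CDR3; the CDR3
    span is defined from that anchor to the start of the J segment.  The
    default sizes give 230 distinct gene symbols in total.
    """
    for name, n in (("n_v", n_v), ("n_d", n_d), ("n_j", n_j), ("n_light_v", n_light_v), ("n_light_j", n_light_j)):
        if n < 1:
            raise ValueError(f"{name} must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    v = [(f"IGHV{i + 1}", _random_segment(rng, 88, 98, suffix="C")) for i in range(n_v)]
    d = [(f"IGHD{i + 1}", _random_segment(rng, 4, 8)) for i in range(n_d)]
    j = [(f"IGHJ{i + 1}", _random_segment(rng, 12, 16)) for i in range(n_j)]
    n_kv = n_light_v // 2
    lv = [(f"IGKV{i + 1}", _random_segment(rng, 85, 95, suffix="C")) for i in range(n_kv)]
    lv += [(f"IGLV{i + 1}", _random_segment(rng, 85, 95, suffix="C")) for i in range(n_light_v - n_kv)]
    n_kj = n_light_j // 2
    lj = [(f"IGKJ{i + 1}", _random_segment(rng, 9, 12)) for i in range(n_kj)]
    lj += [(f"IGLJ{i + 1}", _random_segment(rng, 9, 12)) for i in range(n_light_j - n_kj)]
    return GermlinePools(v, d, j, lv, lj)


@dataclass
class SimConfig:
    """Study conditions for a simulated repertoire.

    ``motif_strength`` is the probability that the subtype's k-mer is
    planted inside the CDR3 of a heavy chain; 1.0 gives a fully planted
    signal (the regime used for learnability checks), 0.0 removes the
    phenotype signal from the sequence entirely.
    """

    n_records: int = 1000
    subtype_labels: Tuple[str, ...] = DEFAULT_SUBTYPES
    subtype_proportions: Tuple[float, ...] = DEFAULT_PROPORTIONS
    shm_rate_per_subtype: Optional[Dict[str, float]] = None
    isotype_distribution_per_subtype: Optional[Dict[str, Tuple[float, ...]]] = None
    motif_strength: float = 0.5
    subtype_motifs: Optional[Dict[str, str]] = None
    heavy_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        labels = tuple(self.subtype_labels)
        self.subtype_labels = labels
        if self.shm_rate_per_subtype is None:
            self.shm_rate_per_subtype = {
                s: DEFAULT_SHM_RATES.get(s, 0.04) for s in labels
            }
        if self.isotype_distribution_per_subtype is None:
            self.isotype_distribution_per_subtype = {
                s: DEFAULT_ISOTYPE_DISTRIBUTIONS.get(s, (0.4, 0.1, 0.3, 0.15, 0.05))
                for s in labels
            }
        if self.subtype_motifs is None:
            self.subtype_motifs = {
                s: DEFAULT_MOTIFS.get(s, _motif_for_label(s)) for s in labels
            }

    def validate(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if len(self.subtype_labels) != len(self.subtype_proportions):
            raise ValueError("subtype_labels and subtype_proportions length mismatch")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must be non-negative and sum to 1")
        for s in self.subtype_labels:
            rate = self.shm_rate_per_subtype[s]
            if not 0.0 <= rate <= 0.25:
                raise ValueError(f"shm rate for {s!r} must lie in [0, 0.25]")
            dist = np.asarray(self.isotype_distribution_per_subtype[s], dtype=float)
            if dist.shape != (len(ISOTYPES),) or (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-9:
                raise ValueError(f"isotype distribution for {s!r} must be a simplex over {len(ISOTYPES)} isotypes")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must lie in [0, 1]")
        if not 0.0 <= self.heavy_fraction <= 1.0:
            raise ValueError("heavy_fraction must lie in [0, 1]")


def _apply_shm(seq: np.ndarray, rate: float, rng: np.random.Generator) -> Tuple[np.ndarray, int]:
    """Independent per-residue substitution to one of the 19 alternatives."""
    if rate <= 0:
        return seq, 0
    hit = rng.random(seq.size) < rate
    n = int(hit.sum())
    if n:
        # draw a uniformly random *different* residue at each hit position
        offsets = rng.integers(1, 20, size=n)
        idx = np.searchsorted(_AA, seq[hit])
        seq = seq.copy()
        seq[hit] = _AA[(idx + offsets) % 20]
    return seq, n


def simulate_record(
    pools: GermlinePools,
    subtype: str,
    config: SimConfig,
    seed: int,
    chain: str = HEAVY,
    record_id: Optional[str] = None,
) -> BCRRecord:
    """Simulate one unpaired chain for a given subtype.

    The sequence is the concatenation V + junction + D + junction + J for
    heavy chains (V + junction + J for light chains); the CDR3 span runs
    from the V-terminal cysteine anchor to the start of the J segment.
    Point substitutions at the subtype's SHM rate are applied first, then
    the subtype motif is planted (with probability ``motif_strength``) so
    that a planted motif is always intact.
    """
    if subtype not in config.subtype_labels:
        raise ValueError(f"unknown subtype {subtype!r}; known: {config.subtype_labels}")
    rng = np.random.default_rng(seed)
    shm_rate = config.shm_rate_per_subtype[subtype]
    motif = config.subtype_motifs[subtype]
    plant = chain == HEAVY and rng.random() < config.motif_strength

    if chain == HEAVY:
        v_sym, v_seq = pools.v_segments[rng.integers(len(pools.v_segments))]
        d_sym, d_seq = pools.d_segments[rng.integers(len(pools.d_segments))]
        j_sym, j_seq = pools.j_segments[rng.integers(len(pools.j_segments))]
        n1 = int(rng.integers(0, 7))
        n2 = int(rng.integers(0, 7))
        if plant:  # widen the junction so the motif fits after the anchor
            deficit = len(motif) - (n1 + len(d_seq) + n2)
            if deficit > 0:
                n2 += deficit
        jx1 = "".join(rng.choice(_AA, size=n1))
        jx2 = "".join(rng.choice(_AA, size=n2))
        germline = v_seq + jx1 + d_seq + jx2 + j_seq
        cys = len(v_seq) - 1
        cdr3_span = (cys, cys + 1 + n1 + len(d_seq) + n2)
        d_call: Optional[str] = d_sym
        isotype = str(rng.choice(ISOTYPES, p=np.asarray(config.isotype_distribution_per_subtype[subtype])))
        v_call, j_call = v_sym, j_sym
    elif chain == LIGHT:
        v_sym, v_seq = pools.light_v_segments[rng.integers(len(pools.light_v_segments))]
        j_sym, j_seq = pools.light_j_segments[rng.integers(len(pools.light_j_segments))]
        n1 = int(rng.integers(4, 11))
        jx1 = "".join(rng.choice(_AA, size=n1))
        germline = v_seq + jx1 + j_seq
        cys = len(v_seq) - 1
        cdr3_span = (cys, cys + 1 + n1)
        d_call = None
        # kappa:lambda usage ~2:1; the locus constant region stands in for
        # the isotype slot (encoded as [UNK] by the tokenizer).
        isotype = "IGK" if rng.random() < 2 / 3 else "IGL"
        v_call, j_call = v_sym, j_sym
    else:
        raise ValueError(f"chain must be 'heavy' or 'light', got {chain!r}")

    arr = np.array(list(germline))
    arr, n_mut = _apply_shm(arr, shm_rate, rng)
    if plant:
        start = cdr3_span[0] + 1
        arr[start : start + len(motif)] = list(motif)
    seq = "".join(arr)
    hcdr3 = seq[cdr3_span[0] : cdr3_span[1]]
    return BCRRecord(
        id=record_id or f"sim-{seed}",
        chain=chain,
        sequence=seq,
        hcdr3=hcdr3,
        v_call=v_call,
        d_call=d_call,
        j_call=j_call,
        isotype=isotype,
        subtype=subtype,
        n_mutations=n_mut,
        hcdr3_span=cdr3_span,
    )


def simulate_repertoire(config: SimConfig, pools: GermlinePools) -> List[BCRRecord]:
    """Simulate ``config.n_records`` chains; deterministic per config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = list(config.subtype_labels)
    props = np.asarray(config.subtype_proportions, dtype=float)
    subtype_idx = rng.choice(len(labels), size=config.n_records, p=props)
    chains = np.where(rng.random(config.n_records) < config.heavy_fraction, HEAVY, LIGHT)
    seeds = rng.integers(0, 2**31 - 1, size=config.n_records)
    width = len(str(config.n_records))
    return [
        simulate_record(
            pools,
            labels[subtype_idx[i]],
            config,
            seed=int(seeds[i]),
            chain=str(chains[i]),
            record_id=f"seq-{i:0{width}d}",
        )
        for i in range(config.n_records)
    ]


def simulate_paratope_set(
    n: int,
    motif: str = "YYGMDV",
    seed: int = 0,
    length_range: Tuple[int, int] = (90, 130),
    extra_contacts: int = 4,
) -> List[ParatopeRecord]:
    """Synthetic stand-in for a structurally annotated paratope benchmark.

    Each record is a random amino-acid sequence with the contact motif
    planted at a random position; the binary label vector marks exactly
    the motif span plus ``extra_contacts`` random non-motif positions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(motif) < 2:
        raise ValueError("motif length must be >= 2")
    if not set(motif) <= AA_SET:
        raise ValueError("motif must use the 20-letter amino-acid alphabet")
    lo, hi = length_range
    if len(motif) > lo:
        raise ValueError(f"motif (len {len(motif)}) longer than minimum sequence length {lo}")
    if extra_contacts < 0:
        raise ValueError("extra_contacts must be >= 0")
    rng = np.random.default_rng(seed)
    out: List[ParatopeRecord] = []
    width = len(str(n))
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        arr = rng.choice(_AA, size=length)
        start = int(rng.integers(0, length - len(motif) + 1))
        arr[start : start + len(motif)] = list(motif)
        labels = np.zeros(length, dtype=np.int64)
        labels[start : start + len(motif)] = 1
        non_motif = np.flatnonzero(labels == 0)
        k = min(extra_contacts, non_motif.size)
        if k:
            labels[rng.choice(non_motif, size=k, replace=False)] = 1
        out.append(ParatopeRecord(id=f"ab-{i:0{width}d}", chain=HEAVY, sequence="".join(arr), labels=labels))
    return out


def plant_near_duplicates(
    records: Sequence[BCRRecord],
    n_pairs: int,
    identity_range: Tuple[float, float] = (0.96, 1.0),
    seed: int = 0,
) -> List[BCRRecord]:
    """Append near-duplicate copies of randomly chosen records.

    Each duplicate substitutes a number of residues drawn so that its
    Hamming identity to the source lies in ``identity_range`` — the
    stress-test input for dedup-before-split pipelines.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    rng = np.random.default_rng(seed)
    out = list(records)
    idx = rng.choice(len(records), size=min(n_pairs, len(records)), replace=False)
    for k, i in enumerate(idx):
        src = records[int(i)]
        arr = np.array(list(src.sequence))
        target_identity = rng.uniform(*identity_range)
        n_sub = int(round((1.0 - target_identity) * arr.size))
        if n_sub:
            pos = rng.choice(arr.size, size=n_sub, replace=False)
            offsets = rng.integers(1, 20, size=n_sub)
            ai = np.searchsorted(_AA, arr[pos])
            arr[pos] = _AA[(ai + offsets) % 20]
        seq = "".join(arr)
        span = src.hcdr3_span
        out.append(
            BCRRecord(
                id=f"{src.id}-dup{k}",
                chain=src.chain,
                sequence=seq,
                hcdr3=seq[span[0] : span[1]] if span else src.hcdr3,
                v_call=src.v_call,
                d_call=src.d_call,
                j_call=src.j_call,
                isotype=src.isotype,
                subtype=src.subtype,
                n_mutations=src.n_mutations,
                hcdr3_span=span,
            )
        )
    return out
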