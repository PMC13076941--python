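"""Composite vocabulary and sequence-pair-style encoding.

A single vocabulary merges four disjoint blocks — 5 special tokens, the
20 amino acids, the germline V(D)J gene symbols, and the isotype labels
(260 tokens at the full 230-gene configuration).  Each chain is encoded
as ``[CLS] residues… [SEP] v (d) j isotype [SEP]`` followed by padding:
the residue segment and the gene/isotype metadata form the two
"sentences" of a sentence-pair input.  The tokenizer is chain-agnostic:
no token identifies heavy versus light; light chains simply omit the D
slot.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .records import AA_ALPHABET, HEAVY, ISOTYPES, BCRRecord

SPECIAL_TOKENS: Tuple[str, ...] = ("[CLS]", "[PAD]", "[MASK]", "[SEP]", "[UNK]")
CLS, PAD, MASK, SEP, UNK = range(5)

MAX_LEN = 148  # default truncation length

# per-position category tags
CAT_SPECIAL = 0
CAT_RESIDUE = 1
CAT_METADATA = 2
CATEGORY_NAMES = {CAT_SPECIAL: "special", CAT_RESIDUE: "residue", CAT_METADATA: "metadata"}

FULL_LENGTH = "full_length"
HCDR3_MODE = "hcdr3"


@dataclass
class Vocabulary:
    """Bidirectional token↔id mapping partitioned into blocks."""

    token_to_id: Dict[str, int]
    id_to_token: List[str]
    blocks: Dict[str, Tuple[int, int]]  # name -> [start, end) id range

    def __len__(self) -> int:
        return len(self.id_to_token)

    def block_size(self, name: str) -> int:
        lo, hi = self.blocks[name]
        return hi - lo

    def in_block(self, token_id: int, name: str) -> bool:
        lo, hi = self.blocks[name]
        return lo <= token_id < hi

    @property
    def amino_acid_ids(self) -> np.ndarray:
        lo, hi = self.blocks["amino_acid"]
        return np.arange(lo, hi)

    def lookup(self, token: str) -> int:
        """Token id, falling back to [UNK] for unknown tokens."""
        return self.token_to_id.get(token, UNK)

    def content_hash(self) -> str:
        return hashlib.sha256("\n".join(self.id_to_token).encode()).hexdigest()

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for i, tok in enumerate(self.id_to_token):
                fh.write(f"{tok}\t{i}\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Vocabulary":
        tokens: List[str] = []
        with open(path) as fh:
            for line in fh:
                tok, idx = line.rstrip("\n").split("\t")
                assert int(idx) == len(tokens), "vocabulary file ids must be dense and ordered"
                tokens.append(tok)
        n_special, n_aa = len(SPECIAL_TOKENS), len(AA_ALPHABET)
        n_iso = sum(1 for t in tokens if t in ISOTYPES and tokens.index(t) >= n_special + n_aa)
        # isotypes occupy the final block; genes sit between amino acids and isotypes
        iso_start = len(tokens) - n_iso
        blocks = {
            "special": (0, n_special),
            "amino_acid": (n_special, n_special + n_aa),
            "gene": (n_special + n_aa, iso_start),
            "isotype": (iso_start, len(tokens)),
        }
        return cls({t: i for i, t in enumerate(tokens)}, tokens, blocks)


def build_vocabulary(
    gene_symbols: Sequence[str],
    isotype_labels: Sequence[str] = ISOTYPES,
) -> Vocabulary:
    """Deterministic vocabulary: specials 0–4, amino acids alphabetical,
    then sorted gene symbols, then sorted isotype labels."""
    genes = sorted(gene_symbols)
    isotypes = sorted(isotype_labels)
    tokens = list(SPECIAL_TOKENS) + list(AA_ALPHABET) + genes + isotypes
    if len(set(tokens)) != len(tokens):
        seen: set = set()
        dup = next(t for t in tokens if t in seen or seen.add(t))
        raise ValueError(f"duplicate token across blocks: {dup!r}")
    n_special, n_aa = len(SPECIAL_TOKENS), len(AA_ALPHABET)
    blocks = {
        "special": (0, n_special),
        "amino_acid": (n_special, n_special + n_aa),
        "gene": (n_special + n_aa, n_special + n_aa + len(genes)),
        "isotype": (n_special + n_aa + len(genes), len(tokens)),
    }
    return Vocabulary({t: i for i, t in enumerate(tokens)}, tokens, blocks)


@dataclass
class EncodedSequence:
    """Fixed-length id vector with padding and per-position categories."""

    ids: np.ndarray  # (max_len,) int64
    pad_mask: np.ndarray  # (max_len,) bool, True = real token
    category: np.ndarray  # (max_len,) int8, CAT_* tags ([PAD] positions are CAT_SPECIAL)
    source_id: str

    @property
    def residue_positions(self) -> np.ndarray:
        return np.flatnonzero((self.category == CAT_RESIDUE) & self.pad_mask)

    @property
    def maskable(self) -> np.ndarray:
        """Positions eligible for MLM corruption: real, non-special tokens."""
        return (self.category != CAT_SPECIAL) & self.pad_mask

    @property
    def length(self) -> int:
        return int(self.pad_mask.sum())


def encode(
    record: BCRRecord,
    vocab: Vocabulary,
    mode: str = FULL_LENGTH,
    max_len: int = MAX_LEN,
) -> EncodedSequence:
    """Encode one record as ``[CLS] residues [SEP] metadata [SEP] [PAD]…``.

    In ``hcdr3`` mode the residue segment is the CDR3 alone.  The residue
    segment is truncated from its C-terminal end so the total length never
    exceeds ``max_len`` while the metadata tail survives intact.  Residues
    outside the 20-letter alphabet and unknown/absent metadata map to
    [UNK] (with a warning for residues).
    """
    if mode not in (FULL_LENGTH, HCDR3_MODE):
        raise ValueError(f"unknown encoding mode {mode!r}")
    if mode == HCDR3_MODE:
        residues = getattr(record, "hcdr3", None) or ""
        if not residues:
            raise ValueError(f"record {record.id!r}: hcdr3 mode requires a CDR3")
    else:
        residues = record.sequence

    # paratope records carry no gene/isotype annotation; their metadata
    # slots all encode as [UNK]
    meta_tokens = [getattr(record, "v_call", None)]
    if record.chain == HEAVY:
        meta_tokens.append(getattr(record, "d_call", None))
    meta_tokens += [getattr(record, "j_call", None), getattr(record, "isotype", None)]
    meta_ids = [vocab.lookup(t) if t is not None else UNK for t in meta_tokens]

    budget = max_len - (3 + len(meta_ids))  # [CLS], two [SEP]s, metadata tail
    if budget < 0:
        raise ValueError(f"max_len={max_len} too small for the metadata tail")
    res_ids = []
    for ch in residues[:budget]:
        tid = vocab.token_to_id.get(ch)
        if tid is None:
            warnings.warn(f"record {record.id!r}: residue {ch!r} outside the amino-acid alphabet, using [UNK]")
            tid = UNK
        res_ids.append(tid)

    ids = np.full(max_len, PAD, dtype=np.int64)
    category = np.full(max_len, CAT_SPECIAL, dtype=np.int8)
    pad_mask = np.zeros(max_len, dtype=bool)
    body = [CLS] + res_ids + [SEP] + meta_ids + [SEP]
    ids[: len(body)] = body
    pad_mask[: len(body)] = True
    category[1 : 1 + len(res_ids)] = CAT_RESIDUE
    category[2 + len(res_ids) : 2 + len(res_ids) + len(meta_ids)] = CAT_METADATA
    return EncodedSequence(ids=ids, pad_mask=pad_mask, category=category, source_id=record.id)


def decode(ids: Sequence[int], vocab: Vocabulary) -> List[str]:
    out = []
    for i in ids:
        i = int(i)
        if not 0 <= i < len(vocab):
            raise ValueError(f"token id {i} outside vocabulary of size {len(vocab)}")
        out.append(vocab.id_to_token[i])
    return out


def encode_batch(
    records: Sequence[BCRRecord],
    vocab: Vocabulary,
    mode: str = FULL_LENGTH,
    max_len: int = MAX_LEN,
) -> List[EncodedSequence]:
    return [encode(r, vocab, mode=mode, max_len=max_len) for r in records]


def stack(encodings: Sequence[EncodedSequence]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack encodings into (ids, pad_mask, maskable) matrices."""
    ids = np.stack([e.ids for e in encodings])
    pad = np.stack([e.pad_mask for e in encodings])
    maskable = np.stack([e.maskable for e in encodings])
    return ids, pad, maskable
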