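"""Core record types for unpaired B-cell receptor chains.

Internally all coordinates are 0-based, half-open; conversion to/from
1-based conventions happens only at file I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

#: The 20 standard amino acids, alphabetical by one-letter code.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

#: Canonical isotype (constant-region class) labels.
ISOTYPES: Tuple[str, ...] = ("IgM", "IgD", "IgG", "IgA", "IgE")

HEAVY = "heavy"
LIGHT = "light"


@dataclass
class BCRRecord:
    """One unpaired heavy- or light-chain amino-acid sequence with metadata.

    ``hcdr3`` holds the CDR3 of whichever chain this is (the heavy-chain
    CDR3 for heavy chains); ``hcdr3_span`` is its 0-based half-open span
    within ``sequence`` when the CDR3 is a substring of it.
    """

    id: str
    chain: str  # HEAVY or LIGHT
    sequence: str
    hcdr3: Optional[str] = None
    v_call: Optional[str] = None
    d_call: Optional[str] = None  # absent for light chains
    j_call: Optional[str] = None
    isotype: Optional[str] = None
    subtype: Optional[str] = None
    n_mutations: Optional[int] = None
    hcdr3_span: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.chain not in (HEAVY, LIGHT):
            raise ValueError(f"record {self.id!r}: chain must be 'heavy' or 'light'")


@dataclass
class ParatopeRecord:
    """Antibody sequence with a per-residue binary antigen-contact label."""

    id: str
    chain: str
    sequence: str
    labels: np.ndarray  # shape (len(sequence),), values in {0, 1}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.sequence),):
            raise ValueError(
                f"record {self.id!r}: label vector length {self.labels.size} "
                f"!= sequence length {len(self.sequence)}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError(f"record {self.id!r}: labels must be binary")
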