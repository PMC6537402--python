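"""Fixed-length physicochemical encoding of CDR amino-acid sequences.

Each residue maps to its 10 Kidera factors — orthogonal factors derived
from a multivariate analysis of 188 physicochemical properties of the 20
amino acids.  CDR1, CDR2 and CDR3 are trimmed or padded to target lengths
(8, 8 and 17, the median CDR lengths in heavy-chain repertoires), giving a
33 x 10 matrix (330 features) per sequence.

Length fixing convention: trimming removes the middle of the sequence
(keeping the first ceil(target/2) and last floor(target/2) residues);
padding inserts zero-vector pseudo residues (sentinel ``-``) after
position ceil(len/2).  When the count to trim or pad is odd the
N-terminal side keeps or receives the extra position.  An ``ends`` mode
trims/pads at the C-terminus instead, for comparing strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

PAD = "-"
#: default target lengths for (CDR1, CDR2, CDR3)
DEFAULT_TARGETS = (8, 8, 17)
N_FACTORS = 10


@lru_cache(maxsize=1)
def kidera_table() -> dict[str, np.ndarray]:
    """The 10-factor table, residue -> length-10 vector."""
    with resources.files("bcrml.data").joinpath("kidera_factors.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="residue")
    return {aa: row.to_numpy(dtype=float) for aa, row in df.iterrows()}


@dataclass(slots=True)
class CdrFeatureMatrix:
    """Fixed-length Kidera encoding of one sequence's three CDRs.

    ``values`` has one row per position (CDR1 then CDR2 then CDR3 after
    length fixing) and one column per Kidera factor; ``pad_mask`` marks
    inserted pseudo residues, whose rows are all zero.
    """

    values: np.ndarray  # (33, 10)
    pad_mask: np.ndarray  # (33,) bool

    def flatten(self) -> np.ndarray:
        return self.values.ravel()


def fix_length(seq: str, target: int, mode: str = "center") -> tuple[str, list[int]]:
    """Trim or pad ``seq`` to exactly ``target`` characters.

    Returns the fixed string and the (0-based) positions of inserted pad
    sentinels.  A sequence already at the target length is unchanged.
    """
    if target < 1:
        raise ValueError(f"target length must be >= 1, got {target}")
    if not seq:
        raise ValueError("sequence must be non-empty")
    if mode not in ("center", "ends"):
        raise ValueError(f"mode must be 'center' or 'ends', got {mode!r}")
    n = len(seq)
    if n == target:
        return seq, []
    if n > target:  # trim
        if mode == "center":
            head = -(-target // 2)  # ceil
            tail = target // 2
            return seq[:head] + seq[n - tail :] if tail else seq[:head], []
        return seq[:target], []
    # pad
    n_pad = target - n
    if mode == "center":
        cut = -(-n // 2)  # insert after position ceil(n/2)
        fixed = seq[:cut] + PAD * n_pad + seq[cut:]
        return fixed, list(range(cut, cut + n_pad))
    return seq + PAD * n_pad, list(range(n, target))


def encode_residues(seq: str) -> np.ndarray:
    """Map a (possibly padded) amino-acid string to a (len, 10) matrix.

    The pad sentinel and the unknown residue ``X`` map to zero rows; any
    other character outside the 20-letter alphabet raises ``ValueError``.
    """
    table = kidera_table()
    out = np.zeros((len(seq), N_FACTORS))
    for i, aa in enumerate(seq):
        if aa in (PAD, "X"):
            continue
        try:
            out[i] = table[aa]
        except KeyError:
            raise ValueError(f"invalid amino acid {aa!r} at position {i}") from None
    return out


def kidera_encode(
    cdr1: str,
    cdr2: str,
    cdr3: str,
    targets: tuple[int, int, int] = DEFAULT_TARGETS,
    mode: str = "center",
) -> CdrFeatureMatrix:
    """Encode one sequence's CDR1/2/3 as a fixed-length factor matrix."""
    blocks = []
    masks = []
    for seq, target in zip((cdr1, cdr2, cdr3), targets):
        fixed, pad_pos = fix_length(seq, target, mode=mode)
        blocks.append(encode_residues(fixed))
        mask = np.zeros(target, dtype=bool)
        mask[pad_pos] = True
        masks.append(mask)
    return CdrFeatureMatrix(values=np.vstack(blocks), pad_mask=np.concatenate(masks))


def encode_records(records, targets=DEFAULT_TARGETS, mode: str = "center") -> np.ndarray:
    """Stack per-record feature matrices into an (n, 33, 10) array."""
    return np.stack(
        [kidera_encode(r.cdr1_aa, r.cdr2_aa, r.cdr3_aa, targets, mode).values for r in records]
    )


def cdr_length_triple(record) -> tuple[int, int, int]:
    """Amino-acid lengths (L1, L2, L3) of a record's CDRs."""
    return (len(record.cdr1_aa), len(record.cdr2_aa), len(record.cdr3_aa))


def shm_feature(record) -> tuple[int, int]:
    """Somatic hypermutation counts (framework, CDR) of a record."""
    return (record.shm_fr, record.shm_cdr)
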