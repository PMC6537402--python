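"""Reading and writing annotated BCR/Ig repertoire records.

The on-disk dialect is an AIRR Rearrangement-style TSV: tab-separated,
UTF-8, one header row, ``\\n`` line endings, no quoting.  Column names
follow the AIRR Rearrangement standard where one exists (``sequence_id``,
``v_call``, ``j_call``, ``cdr1_aa``, ``cdr2_aa``, ``cdr3_aa``, ``cdr3``
for the junction nucleotides, ``duplicate_count``); ``patient_id``,
``tissue``, ``shm_fr``, ``shm_cdr`` and ``clone_id`` are custom columns.
Unknown extra columns are preserved on a round trip but ignored by the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

NORMAL = "normal"
TUMOR = "tumor"
TISSUES = (NORMAL, TUMOR)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET_X = AA_ALPHABET | {"X"}
NT_ALPHABET = set("ACGT")

#: required columns, in canonical order
COLUMNS = [
    "sequence_id",
    "patient_id",
    "tissue",
    "v_call",
    "j_call",
    "cdr1_aa",
    "cdr2_aa",
    "cdr3_aa",
    "cdr3",
    "duplicate_count",
    "shm_fr",
    "shm_cdr",
]
OPTIONAL_COLUMNS = ["clone_id"]


class RepertoireFormatError(ValueError):
    """The file does not conform to the expected TSV dialect."""


class RepertoireValidationError(ValueError):
    """A record violates a field invariant."""


@dataclass(slots=True)
class SequenceRecord:
    """One read-collapsed, annotated BCR/Ig heavy-chain sequence.

    ``duplicate_count`` is the number of reads supporting the collapsed
    sequence; ``shm_fr`` and ``shm_cdr`` count somatic hypermutations in
    the framework regions and the CDRs respectively.
    """

    sequence_id: str
    patient_id: str
    tissue: str
    v_call: str
    j_call: str
    cdr1_aa: str
    cdr2_aa: str
    cdr3_aa: str
    cdr3_nt: str
    duplicate_count: int
    shm_fr: int
    shm_cdr: int
    clone_id: str | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.tissue not in TISSUES:
            raise RepertoireValidationError(
                f"record {self.sequence_id!r}: tissue must be one of "
                f"{TISSUES}, got {self.tissue!r}"
            )
        if self.duplicate_count < 1:
            raise RepertoireValidationError(
                f"record {self.sequence_id!r}: duplicate_count must be >= 1, "
                f"got {self.duplicate_count}"
            )
        if self.shm_fr < 0 or self.shm_cdr < 0:
            raise RepertoireValidationError(
                f"record {self.sequence_id!r}: SHM counts must be >= 0"
            )
        if len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise RepertoireValidationError(
                f"record {self.sequence_id!r}: cdr3 nucleotide length "
                f"{len(self.cdr3_nt)} is not 3x the amino-acid length "
                f"{len(self.cdr3_aa)}"
            )
        for name, seq in (
            ("cdr1_aa", self.cdr1_aa),
            ("cdr2_aa", self.cdr2_aa),
            ("cdr3_aa", self.cdr3_aa),
        ):
            bad = set(seq) - AA_ALPHABET_X
            if bad:
                raise RepertoireValidationError(
                    f"record {self.sequence_id!r}: field {name} contains "
                    f"invalid residues {sorted(bad)}"
                )
        bad_nt = set(self.cdr3_nt) - NT_ALPHABET
        if bad_nt:
            raise RepertoireValidationError(
                f"record {self.sequence_id!r}: cdr3 contains invalid "
                f"nucleotides {sorted(bad_nt)}"
            )


def read_repertoire(path) -> list[SequenceRecord]:
    """Read an annotated repertoire TSV into validated records.

    Row order is preserved.  Raises :class:`RepertoireFormatError` when a
    required column is missing and :class:`RepertoireValidationError` when
    a row violates a record invariant.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise RepertoireFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    extra_cols = [
        c for c in df.columns if c not in COLUMNS and c not in OPTIONAL_COLUMNS
    ]
    records: list[SequenceRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            rec = SequenceRecord(
                sequence_id=row_d["sequence_id"],
                patient_id=row_d["patient_id"],
                tissue=row_d["tissue"],
                v_call=row_d["v_call"],
                j_call=row_d["j_call"],
                cdr1_aa=row_d["cdr1_aa"],
                cdr2_aa=row_d["cdr2_aa"],
                cdr3_aa=row_d["cdr3_aa"],
                cdr3_nt=row_d["cdr3"],
                duplicate_count=_to_int(row_d["duplicate_count"], i, "duplicate_count"),
                shm_fr=_to_int(row_d["shm_fr"], i, "shm_fr"),
                shm_cdr=_to_int(row_d["shm_cdr"], i, "shm_cdr"),
                clone_id=row_d.get("clone_id") or None,
                extra={c: row_d[c] for c in extra_cols},
            )
            rec.validate()
        except RepertoireValidationError as exc:
            raise RepertoireValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    return records


def _to_int(value: str, row: int, field_name: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise RepertoireValidationError(
            f"row {row}: field {field_name} is not an integer: {value!r}"
        ) from None


def write_repertoire(records: list[SequenceRecord], path) -> None:
    """Write records as a TSV that :func:`read_repertoire` inverts exactly."""
    for rec in records:
        rec.validate()
    extra_cols: list[str] = []
    for rec in records:
        for c in rec.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    has_clone = any(r.clone_id is not None for r in records)
    cols = COLUMNS + (["clone_id"] if has_clone else []) + extra_cols
    rows = []
    for rec in records:
        row = {
            "sequence_id": rec.sequence_id,
            "patient_id": rec.patient_id,
            "tissue": rec.tissue,
            "v_call": rec.v_call,
            "j_call": rec.j_call,
            "cdr1_aa": rec.cdr1_aa,
            "cdr2_aa": rec.cdr2_aa,
            "cdr3_aa": rec.cdr3_aa,
            "cdr3": rec.cdr3_nt,
            "duplicate_count": rec.duplicate_count,
            "shm_fr": rec.shm_fr,
            "shm_cdr": rec.shm_cdr,
        }
        if has_clone:
            row["clone_id"] = rec.clone_id if rec.clone_id is not None else ""
        for c in extra_cols:
            row[c] = rec.extra.get(c, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
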