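"""Reading, validation, and normalization of fixed-length nucleotide sets.

Datasets are pairs of plain FASTA files, one per class; labels are never
stored in the FASTA itself. Sequences are uppercased on read, the alphabet
(DNA vs RNA) is inferred per record, and IUPAC ambiguity codes are rejected
outright rather than masked.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import (
    AlphabetError,
    CenterUndefinedError,
    CenterViolationError,
    EmptyInputError,
    HeterogeneousLengthError,
    InvalidCharacterError,
    MissingClassError,
)

DNA = "DNA"
RNA = "RNA"

_CANONICAL = set("ACGTU")


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled fixed-length nucleotide sequence.

    Attributes
    ----------
    id : str
        FASTA header (everything after ``>`` up to end of line).
    sequence : str
        Uppercase canonical nucleotide string.
    label : int
        1 for 6mA-positive, 0 for negative.
    species : str
        Free-text species tag.
    alphabet : str
        ``"DNA"`` or ``"RNA"``.
    """

    id: str
    sequence: str
    label: int
    species: str = ""
    alphabet: str = DNA

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.alphabet not in (DNA, RNA):
            raise ValueError(f"alphabet must be DNA or RNA, got {self.alphabet!r}")


@dataclass(frozen=True)
class DatasetSummary:
    """Class counts and shared geometry of one validated dataset."""

    n_positive: int
    n_negative: int
    length: int
    species: str = ""
    alphabet: str = DNA

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_positive": self.n_positive,
                "n_negative": self.n_negative,
                "length": self.length,
                "species": self.species,
                "alphabet": self.alphabet,
            },
            indent=2,
        )


def _check_sequence(record_id: str, seq: str) -> str:
    """Uppercase, validate characters, and infer the alphabet of one sequence."""
    seq = seq.upper()
    for ch in seq:
        if ch not in _CANONICAL:
            raise InvalidCharacterError(record_id, ch)
    has_t = "T" in seq
    has_u = "U" in seq
    if has_t and has_u:
        raise AlphabetError(f"record {record_id!r} mixes T and U")
    return seq


def read_fasta(path: str | Path, label: int, species: str = "") -> list[SequenceRecord]:
    """Read one class of sequences from a FASTA file.

    Every entry receives the given ``label`` and ``species``. Alphabet is
    inferred per record: presence of U means RNA, otherwise DNA.

    Raises
    ------
    EmptyInputError
        If the file holds no FASTA entries.
    InvalidCharacterError
        On any character outside {A, C, G, T, U} (case-insensitive).
    AlphabetError
        If a single sequence mixes T and U.
    """
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _check_sequence(entry.description, str(entry.seq))
        if not seq:
            raise EmptyInputError(f"record {entry.description!r} has an empty sequence")
        alphabet = RNA if "U" in seq else DNA
        records.append(
            SequenceRecord(
                id=entry.description,
                sequence=seq,
                label=label,
                species=species,
                alphabet=alphabet,
            )
        )
    if not records:
        raise EmptyInputError(f"no FASTA entries found in {path}")
    return records


def normalize_alphabet(
    records: Iterable[SequenceRecord], target: str
) -> list[SequenceRecord]:
    """Convert every record to the target alphabet by T<->U substitution.

    Idempotent; normalizing to RNA then back to DNA restores the input.
    """
    if target not in (DNA, RNA):
        raise ValueError(f"target must be DNA or RNA, got {target!r}")
    src, dst = ("U", "T") if target == DNA else ("T", "U")
    out = []
    for rec in records:
        seq = rec.sequence.replace(src, dst)
        out.append(replace(rec, sequence=seq, alphabet=target))
    return out


def validate_benchmark(
    records: Sequence[SequenceRecord],
    expected_length: int | None = None,
    require_center_A: bool = True,
) -> DatasetSummary:
    """Check dataset geometry and return per-class counts.

    The center position is the 1-based index (L+1)/2, defined only for odd L.

    Raises
    ------
    EmptyInputError, HeterogeneousLengthError, CenterUndefinedError,
    CenterViolationError
    """
    if not records:
        raise EmptyInputError("cannot validate an empty record list")
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        raise HeterogeneousLengthError(
            f"records have mixed lengths {sorted(lengths)}"
        )
    length = lengths.pop()
    if expected_length is not None and length != expected_length:
        raise HeterogeneousLengthError(
            f"expected length {expected_length}, found {length}"
        )
    if require_center_A:
        if length % 2 == 0:
            raise CenterUndefinedError(
                f"center position undefined for even length {length}"
            )
        center = (length - 1) // 2  # 0-based
        bad = [r.id for r in records if r.sequence[center] != "A"]
        if bad:
            raise CenterViolationError(bad)
    labels = Counter(r.label for r in records)
    species = {r.species for r in records}
    alphabets = {r.alphabet for r in records}
    return DatasetSummary(
        n_positive=labels.get(1, 0),
        n_negative=labels.get(0, 0),
        length=length,
        species=species.pop() if len(species) == 1 else "mixed",
        alphabet=alphabets.pop() if len(alphabets) == 1 else "mixed",
    )


def balance_classes(
    records: Sequence[SequenceRecord], seed: int
) -> list[SequenceRecord]:
    """Subsample the majority class to match the minority class size.

    All minority records are kept; the majority class is subsampled uniformly
    without replacement using ``seed``. Input order is preserved.
    """
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    if not pos or not neg:
        raise MissingClassError("both classes must be present to balance")
    if len(pos) == len(neg):
        return list(records)
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    rng = random.Random(seed)
    kept = set(
        id(r) for r in rng.sample(majority, len(minority))
    )
    keep_minority = set(id(r) for r in minority)
    return [r for r in records if id(r) in kept or id(r) in keep_minority]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as plain unwrapped FASTA (``>id`` then one sequence line)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
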