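"""Five nucleotide encoding families and the 15-scheme benchmark grid.

Families
--------
binary : positional one-hot, 4 columns per base (A, C, G, T/U order)
kmer   : normalized overlapping k-mer frequencies, lexicographic order
enac   : per-window base frequencies from a width-w window slid by 1
cksnap : normalized ordered-pair frequencies at every gap g = 0..k
ncp    : per-base chemical-property triple A=(1,1,1) C=(0,1,0) G=(1,0,0) T/U=(0,0,1)

T and U are interchangeable everywhere: encoding a sequence and encoding its
T<->U image give identical vectors, so DNA and RNA datasets mix freely for
composition features.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    HeterogeneousLengthError,
    InvalidCharacterError,
    M6aPredError,
    SequenceTooShortError,
)
from .seqio import SequenceRecord

FAMILIES = ("binary", "kmer", "enac", "cksnap", "ncp")
BASES = "ACGT"

# base -> column index; U shares T's slot
_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# chemical-property triples (ring structure, hydrogen bond, functional group)
_NCP = {
    "A": (1.0, 1.0, 1.0),
    "C": (0.0, 1.0, 0.0),
    "G": (1.0, 0.0, 0.0),
    "T": (0.0, 0.0, 1.0),
    "U": (0.0, 0.0, 1.0),
}


@dataclass(frozen=True)
class EncodingScheme:
    """A named encoder family plus its integer parameter.

    ``param`` is k for kmer, the window width w for enac, and the maximum gap
    for cksnap; it is ignored for binary and ncp.
    """

    family: str
    param: int | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown encoder family {self.family!r}")
        if self.family in ("binary", "ncp"):
            if self.param is not None:
                object.__setattr__(self, "param", None)
        elif self.family in ("kmer", "enac"):
            if self.param is None or self.param < 1:
                raise ValueError(f"{self.family} requires param >= 1")
        elif self.family == "cksnap":
            if self.param is None or self.param < 0:
                raise ValueError("cksnap requires param >= 0")

    @property
    def name(self) -> str:
        if self.param is None:
            return self.family
        return f"{self.family}-{self.param}"

    @classmethod
    def from_name(cls, name: str) -> "EncodingScheme":
        fam, _, p = name.partition("-")
        return cls(fam, int(p) if p else None)

    def n_features(self, length: int) -> int:
        """Closed-form feature count for sequences of the given length."""
        if self.family == "binary":
            return 4 * length
        if self.family == "ncp":
            return 3 * length
        if self.family == "kmer":
            return 4 ** self.param
        if self.family == "enac":
            return 4 * (length - self.param + 1)
        return 16 * (self.param + 1)  # cksnap

    def feature_names(self, length: int) -> list[str]:
        if self.family == "binary":
            return [f"pos{i}_{b}" for i in range(1, length + 1) for b in BASES]
        if self.family == "ncp":
            props = ("ring", "hbond", "func")
            return [f"pos{i}_{p}" for i in range(1, length + 1) for p in props]
        if self.family == "kmer":
            return ["".join(t) for t in itertools.product(BASES, repeat=self.param)]
        if self.family == "enac":
            return [
                f"win{i}_{b}"
                for i in range(1, length - self.param + 2)
                for b in BASES
            ]
        pairs = ["".join(t) for t in itertools.product(BASES, repeat=2)]
        return [f"gap{g}_{p}" for g in range(self.param + 1) for p in pairs]


def enumerate_schemes() -> list[EncodingScheme]:
    """The full 15-scheme benchmark grid, in canonical order.

    binary; kmer k=2..5; enac w=2..5; cksnap k=1..5; ncp.
    """
    grid = [EncodingScheme("binary")]
    grid += [EncodingScheme("kmer", k) for k in (2, 3, 4, 5)]
    grid += [EncodingScheme("enac", w) for w in (2, 3, 4, 5)]
    grid += [EncodingScheme("cksnap", k) for k in (1, 2, 3, 4, 5)]
    grid.append(EncodingScheme("ncp"))
    return grid


def _indices(sequence: str, record_id: str = "<seq>") -> np.ndarray:
    try:
        return np.fromiter(
            (_INDEX[c] for c in sequence), dtype=np.intp, count=len(sequence)
        )
    except KeyError as exc:
        raise InvalidCharacterError(record_id, exc.args[0]) from None


def encode_binary(sequence: str) -> np.ndarray:
    """Positional one-hot vector of length 4L, base order A, C, G, T/U."""
    idx = _indices(sequence)
    L = len(idx)
    out = np.zeros(4 * L)
    out[np.arange(L) * 4 + idx] = 1.0
    return out


def encode_kmer(sequence: str, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies (length 4**k, lexicographic order).

    Each entry is N(t) / (L - k + 1); the vector sums to 1.
    """
    idx = _indices(sequence)
    L = len(idx)
    if L < k:
        raise SequenceTooShortError(f"length {L} < k = {k}")
    # base-4 rolling code of each window
    codes = np.zeros(L - k + 1, dtype=np.intp)
    for j in range(k):
        codes = codes * 4 + idx[j : L - k + 1 + j]
    out = np.bincount(codes, minlength=4**k).astype(float)
    return out / (L - k + 1)


def encode_enac(sequence: str, w: int) -> np.ndarray:
    """Sliding-window base frequencies: one A,C,G,T/U block per window start.

    Windows advance by 1, no partial windows; each 4-block sums to 1.
    """
    idx = _indices(sequence)
    L = len(idx)
    if L < w:
        raise SequenceTooShortError(f"length {L} < window = {w}")
    onehot = np.zeros((L, 4))
    onehot[np.arange(L), idx] = 1.0
    csum = np.vstack([np.zeros(4), np.cumsum(onehot, axis=0)])
    blocks = (csum[w:] - csum[:-w]) / w
    return blocks.ravel()


def encode_cksnap(sequence: str, kmax: int) -> np.ndarray:
    """Spaced-pair composition: a 16-entry block per gap g = 0..kmax.

    Block entry for pair (x, y) at gap g counts positions i with s[i] = x and
    s[i+g+1] = y, divided by the number of such positions (L - g - 1); pairs
    are ordered lexicographically (AA, AC, ..., TT).
    """
    idx = _indices(sequence)
    L = len(idx)
    if L < kmax + 2:
        raise SequenceTooShortError(f"length {L} < kmax + 2 = {kmax + 2}")
    out = np.empty(16 * (kmax + 1))
    for g in range(kmax + 1):
        codes = idx[: L - g - 1] * 4 + idx[g + 1 :]
        counts = np.bincount(codes, minlength=16).astype(float)
        out[16 * g : 16 * (g + 1)] = counts / (L - g - 1)
    return out


def encode_ncp(sequence: str) -> np.ndarray:
    """Chemical-property triples concatenated 5'->3' (length 3L)."""
    out = np.empty(3 * len(sequence))
    for i, c in enumerate(sequence):
        try:
            out[3 * i : 3 * i + 3] = _NCP[c]
        except KeyError:
            raise InvalidCharacterError("<seq>", c) from None
    return out


def encode_sequence(sequence: str, scheme: EncodingScheme) -> np.ndarray:
    """Dispatch one sequence through the scheme's encoder."""
    if scheme.family == "binary":
        return encode_binary(sequence)
    if scheme.family == "kmer":
        return encode_kmer(sequence, scheme.param)
    if scheme.family == "enac":
        return encode_enac(sequence, scheme.param)
    if scheme.family == "cksnap":
        return encode_cksnap(sequence, scheme.param)
    return encode_ncp(sequence)


@dataclass
class FeatureMatrix:
    """Encoded dataset: one row per record, with scheme provenance."""

    values: np.ndarray
    scheme: EncodingScheme
    feature_names: list[str]
    record_ids: list[str]
    labels: np.ndarray

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """CSV with id + label first, then feature columns; JSON sidecar
        at ``<path>.scheme.json`` carries the scheme metadata."""
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.record_ids)
        df.to_csv(path, index=False)
        sidecar = {"family": self.scheme.family, "param": self.scheme.param}
        Path(f"{path}.scheme.json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = json.loads(Path(f"{path}.scheme.json").read_text())
        scheme = EncodingScheme(meta["family"], meta["param"])
        return cls(
            values=df.iloc[:, 2:].to_numpy(dtype=float),
            scheme=scheme,
            feature_names=list(df.columns[2:]),
            record_ids=[str(x) for x in df["id"]],
            labels=df["label"].to_numpy(dtype=int),
        )


def encode_dataset(
    records: Sequence[SequenceRecord],
    scheme: EncodingScheme,
    length: int | None = None,
) -> FeatureMatrix:
    """Encode a dataset of equal-length records into a FeatureMatrix.

    ``length`` must be supplied for the zero-record case so feature metadata
    can still be populated.
    """
    if records:
        lengths = {len(r.sequence) for r in records}
        if len(lengths) > 1:
            raise HeterogeneousLengthError(
                f"records have mixed lengths {sorted(lengths)}"
            )
        length = lengths.pop()
    elif length is None:
        raise ValueError("length is required when encoding zero records")
    names = scheme.feature_names(length)
    values = np.empty((len(records), len(names)))
    for i, rec in enumerate(records):
        try:
            values[i] = encode_sequence(rec.sequence, scheme)
        except InvalidCharacterError as exc:
            raise InvalidCharacterError(rec.id, exc.char) from None
        except M6aPredError as exc:
            raise type(exc)(f"record {rec.id!r}: {exc}") from exc
    return FeatureMatrix(
        values=values,
        scheme=scheme,
        feature_names=names,
        record_ids=[r.id for r in records],
        labels=np.array([r.label for r in records], dtype=int),
    )
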