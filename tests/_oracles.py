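"""Independent brute-force reference implementations used only by tests.

Written directly from the definitions (dictionary counting and explicit
loops), deliberately sharing no code with the package's vectorized encoders
or rank-based AUC.
"""

import itertools

BASES = "ACGT"


def _canon(seq: str) -> str:
    return seq.upper().replace("U", "T")


def oracle_binary(seq: str) -> list[float]:
    out = []
    for ch in _canon(seq):
        out.extend(1.0 if b == ch else 0.0 for b in BASES)
    return out


def oracle_ncp(seq: str) -> list[float]:
    table = {"A": [1, 1, 1], "C": [0, 1, 0], "G": [1, 0, 0], "T": [0, 0, 1]}
    out = []
    for ch in _canon(seq):
        out.extend(float(v) for v in table[ch])
    return out


# lexicographic k-mer and pair orderings, precomputed once
_KMERS = {
    k: ["".join(t) for t in itertools.product(BASES, repeat=k)] for k in range(1, 6)
}
_PAIRS = _KMERS[2]


def oracle_kmer(seq: str, k: int) -> list[float]:
    seq = _canon(seq)
    n_windows = len(seq) - k + 1
    counts = {}
    for i in range(n_windows):
        t = seq[i : i + k]
        counts[t] = counts.get(t, 0) + 1
    return [counts.get(t, 0) / n_windows for t in _KMERS[k]]


def oracle_enac(seq: str, w: int) -> list[float]:
    seq = _canon(seq)
    out = []
    for start in range(len(seq) - w + 1):
        window = seq[start : start + w]
        out.extend(window.count(b) / w for b in BASES)
    return out


def oracle_cksnap(seq: str, kmax: int) -> list[float]:
    seq = _canon(seq)
    out = []
    for gap in range(kmax + 1):
        counts = {}
        n_total = 0
        for i in range(len(seq) - gap - 1):
            p = seq[i] + seq[i + gap + 1]
            counts[p] = counts.get(p, 0) + 1
            n_total += 1
        out.extend(counts.get(p, 0) / n_total for p in _PAIRS)
    return out


def oracle_auc(y_true, scores) -> float:
    """All-pairs count: P(score_pos > score_neg) with ties worth 1/2."""
    pos = [s for y, s in zip(y_true, scores) if y == 1]
    neg = [s for y, s in zip(y_true, scores) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def all_sequences(max_len: int):
    """Every ACGT string of length 1..max_len."""
    for L in range(1, max_len + 1):
        for t in itertools.product(BASES, repeat=L):
            yield "".join(t)
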