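"""Seeded synthetic benchmark generator.

Produces balanced, fixed-length, center-A datasets whose positive class
carries a tunable positional motif around the center. The motif is a PWM
mixture: within +/-``motif_halfwidth`` of the center, positive-class
positions draw from ``signal * consensus + (1 - signal) * background``, so
``signal=0`` makes positives statistically identical to negatives and
``signal=1`` pins the motif positions to the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError
from .seqio import DNA, RNA, SequenceRecord

_BASES_DNA = np.array(list("ACGT"))
_BASES_RNA = np.array(list("ACGU"))

# fixed consensus preference cycled over motif offsets (arbitrary but frozen)
_CONSENSUS_CYCLE = (2, 2, 0, 1, 3, 0)  # G G A C T A as base indices


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of one synthetic dataset."""

    n_pos: int = 100
    n_neg: int = 100
    length: int = 41
    alphabet: str = DNA
    signal: float = 0.8
    motif_halfwidth: int = 3
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    species: str = "synthetic"

    def validate(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ConfigError("n_pos and n_neg must be nonnegative")
        if self.length < 1 or self.length % 2 == 0:
            raise ConfigError("length must be a positive odd number (center-A)")
        if self.alphabet not in (DNA, RNA):
            raise ConfigError(f"alphabet must be DNA or RNA, got {self.alphabet!r}")
        if not 0.0 <= self.signal <= 1.0:
            raise ConfigError("signal must lie in [0, 1]")
        if self.motif_halfwidth < 0:
            raise ConfigError("motif_halfwidth must be nonnegative")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg < 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ConfigError("background must be 4 nonnegative probabilities summing to 1")


def default_motif_pwm(config: FixtureConfig) -> np.ndarray:
    """Consensus preference per motif offset: a (2*halfwidth+1, 4) one-hot
    matrix over the window centered on the (always-A) center position."""
    width = 2 * config.motif_halfwidth + 1
    pwm = np.zeros((width, 4))
    for i in range(width):
        pwm[i, _CONSENSUS_CYCLE[i % len(_CONSENSUS_CYCLE)]] = 1.0
    return pwm


def _position_probs(config: FixtureConfig, motif_pwm: np.ndarray | None) -> np.ndarray:
    """Per-position base probabilities for the positive class; (L, 4)."""
    bg = np.asarray(config.background, dtype=float)
    probs = np.tile(bg, (config.length, 1))
    if motif_pwm is None:
        motif_pwm = default_motif_pwm(config)
    center = (config.length - 1) // 2
    hw = config.motif_halfwidth
    for offset in range(-hw, hw + 1):
        pos = center + offset
        if pos < 0 or pos >= config.length:
            continue
        consensus = motif_pwm[offset + hw]
        probs[pos] = config.signal * consensus + (1.0 - config.signal) * bg
    return probs


def _draw(
    n: int,
    probs: np.ndarray,
    config: FixtureConfig,
    label: int,
    prefix: str,
    rng: np.random.Generator,
) -> list[SequenceRecord]:
    L = config.length
    center = (L - 1) // 2
    bases = _BASES_RNA if config.alphabet == RNA else _BASES_DNA
    records = []
    cum = np.cumsum(probs, axis=1)
    for i in range(n):
        u = rng.random(L)
        idx = (u[:, None] > cum).sum(axis=1)
        idx[center] = 0  # center base is always A, both classes
        seq = "".join(bases[idx])
        records.append(
            SequenceRecord(
                id=f"{prefix}{i}",
                sequence=seq,
                label=label,
                species=config.species,
                alphabet=config.alphabet,
            )
        )
    return records


def generate_benchmark(
    config: FixtureConfig, motif_pwm: np.ndarray | None = None
) -> list[SequenceRecord]:
    """Generate ``n_pos`` motif-carrying positives and ``n_neg`` background
    negatives, all length ``config.length`` with A at the center.

    Deterministic for a fixed config (the seed drives a single RNG stream).
    An explicit ``motif_pwm`` (rows = motif window positions, columns =
    A,C,G,T probabilities) overrides the built-in consensus.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pos_probs = _position_probs(config, motif_pwm)
    bg_probs = np.tile(np.asarray(config.background, dtype=float), (config.length, 1))
    positives = _draw(config.n_pos, pos_probs, config, 1, "pos", rng)
    negatives = _draw(config.n_neg, bg_probs, config, 0, "neg", rng)
    return positives + negatives


def generate_species_pair(
    config_a: FixtureConfig,
    config_b: FixtureConfig,
    divergence: float,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Two datasets whose motif PWMs are interpolated by ``divergence``.

    divergence=0: both species share one randomly drawn motif PWM (only the
    sampling seeds differ). divergence=1: independent PWMs. Sub-seeds are
    derived deterministically from ``config_a.seed``.
    """
    config_a.validate()
    config_b.validate()
    if config_a.length != config_b.length:
        raise ConfigError("species pair requires equal sequence lengths")
    if config_a.motif_halfwidth != config_b.motif_halfwidth:
        raise ConfigError("species pair requires equal motif halfwidths")
    if not 0.0 <= divergence <= 1.0:
        raise ConfigError("divergence must lie in [0, 1]")
    ss = np.random.SeedSequence(config_a.seed)
    seed_pwm_a, seed_pwm_b, seed_data_a, seed_data_b = (
        int(s.generate_state(1)[0]) for s in ss.spawn(4)
    )
    width = 2 * config_a.motif_halfwidth + 1
    pwm_a = np.random.default_rng(seed_pwm_a).dirichlet(np.full(4, 0.3), size=width)
    pwm_ind = np.random.default_rng(seed_pwm_b).dirichlet(np.full(4, 0.3), size=width)
    pwm_b = (1.0 - divergence) * pwm_a + divergence * pwm_ind
    records_a = generate_benchmark(replace(config_a, seed=seed_data_a), motif_pwm=pwm_a)
    records_b = generate_benchmark(replace(config_b, seed=seed_data_b), motif_pwm=pwm_b)
    return records_a, records_b
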