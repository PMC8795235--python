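"""Binary word stimuli driving the network.

A stimulus is N words of 8 letters; each letter lasts ``delta_t_letter``
milliseconds (default 3 ms) and is 1 with probability p (random drive) or laid
out deterministically (periodic drive).  Derived quantities: signal length
``Delta_t = 8 * N * delta_t`` (ms) and sampling frequency ``f = p / delta_t``
(Hz) — e.g. p = 0.4 at delta_t = 3 ms gives f ≈ 133 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulusSpec",
    "BitSequence",
    "random_stimulus",
    "periodic_stimulus",
    "signal_length",
    "signal_frequency",
]

WORD_LENGTH = 8
DEFAULT_DELTA_T = 3.0  # ms per letter
DEFAULT_P = 0.4
DEFAULT_J_OVER_CM = 0.25  # mV per injection event


@dataclass(frozen=True)
class StimulusSpec:
    n_words: int
    p: float = DEFAULT_P
    delta_t_letter: float = DEFAULT_DELTA_T
    word_length: int = WORD_LENGTH
    J_over_Cm: float = DEFAULT_J_OVER_CM

    def __post_init__(self) -> None:
        if self.n_words < 1:
            raise ValueError("n_words must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.delta_t_letter <= 0:
            raise ValueError("delta_t_letter must be positive")

    @property
    def n_letters(self) -> int:
        return self.word_length * self.n_words


@dataclass
class BitSequence:
    """Ordered binary letters with their common duration."""

    bits: np.ndarray
    delta_t_letter: float

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("bits must be one-dimensional")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("letters must be 0 or 1")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def duration(self) -> float:
        """Total duration in ms."""
        return len(self.bits) * self.delta_t_letter


def random_stimulus(spec: StimulusSpec, seed: int | np.random.Generator) -> BitSequence:
    """8N independent Bernoulli(p) letters."""
    rng = np.random.default_rng(seed)
    bits = (rng.random(spec.n_letters) < spec.p).astype(np.uint8)
    return BitSequence(bits=bits, delta_t_letter=spec.delta_t_letter)


def periodic_stimulus(spec: StimulusSpec) -> BitSequence:
    """One fixed word with round(8p) active letters, evenly spaced, repeated N times.

    The activity rate matches the random drive (round(8p)/8 per letter) so the
    random and periodic references differ in structure, not rate.
    """
    k = int(round(spec.word_length * spec.p))
    word = np.zeros(spec.word_length, dtype=np.uint8)
    if k > 0:
        positions = (np.arange(k) * spec.word_length) // k
        word[positions] = 1
    return BitSequence(
        bits=np.tile(word, spec.n_words), delta_t_letter=spec.delta_t_letter
    )


def signal_length(spec: StimulusSpec) -> float:
    """Total stimulus length Delta_t = 8 * N * delta_t, in ms."""
    return spec.word_length * spec.n_words * spec.delta_t_letter


def signal_frequency(spec: StimulusSpec) -> float:
    """Sampling frequency f = p / delta_t, in Hz (delta_t in ms)."""
    return spec.p / (spec.delta_t_letter * 1e-3)
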