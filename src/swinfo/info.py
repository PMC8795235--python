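"""Shannon-entropy decoding of spike trains.

Spike trains are binned into binary letters (one per stimulus letter duration),
cut into non-overlapping 8-letter words (256 possible substates) and summarised
by the plug-in Shannon entropy H = -sum P log2 P, in bits (0 <= H <= 8).  The
information transported through a node is the entropy of its response to a
random drive minus the entropy of its response to a periodic drive of the same
rate, I = T - N; word counts are pooled across trial repetitions before the
entropy is taken (the only variance-reduction step — no bias correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lif import SpikeTrain
from .stimulus import BitSequence, StimulusSpec, periodic_stimulus, random_stimulus

__all__ = [
    "WordDistribution",
    "NodeInformation",
    "bits_from_spikes",
    "word_distribution",
    "entropy",
    "node_information",
    "input_information",
]

WORD_LENGTH = 8
N_STATES = 2**WORD_LENGTH


@dataclass
class WordDistribution:
    """P(s) over the 256 word states, sorted by decreasing frequency."""

    states: np.ndarray  # word codes (0..255), decreasing probability
    probabilities: np.ndarray
    n_words_observed: int

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


@dataclass
class NodeInformation:
    T: float  # entropy under the random drive, bits
    N_noise: float  # entropy under the periodic drive, bits
    I: float  # T - N_noise, bits (may be negative at small samples)


def bits_from_spikes(
    train: SpikeTrain, delta_t_letter: float, duration: float
) -> BitSequence:
    """One letter per delta_t bin; 1 iff >= 1 spike in [k*dt_l, (k+1)*dt_l)."""
    n_bins = int(round(duration / delta_t_letter))
    if abs(n_bins * delta_t_letter - duration) > 1e-9:
        raise ValueError("duration must be a multiple of delta_t_letter")
    bits = np.zeros(n_bins, dtype=np.uint8)
    if len(train.spike_times):
        idx = np.floor(train.spike_times / delta_t_letter).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        bits[idx] = 1
    return BitSequence(bits=bits, delta_t_letter=delta_t_letter)


def _word_codes(bits: np.ndarray) -> np.ndarray:
    if len(bits) % WORD_LENGTH:
        raise ValueError("sequence length must be a multiple of 8")
    words = bits.reshape(-1, WORD_LENGTH)
    return words @ (1 << np.arange(WORD_LENGTH - 1, -1, -1)).astype(np.int64)


def word_distribution(
    bits: BitSequence, pool: Sequence[BitSequence] | None = None
) -> WordDistribution:
    """Cut sequences into consecutive non-overlapping 8-letter words and count.

    ``pool`` adds further sequences (e.g. the trial repetitions) whose word
    counts are pooled before normalisation.
    """
    codes = [_word_codes(bits.bits)]
    for extra in pool or ():
        codes.append(_word_codes(extra.bits))
    all_codes = np.concatenate(codes)
    counts = np.bincount(all_codes, minlength=N_STATES)
    total = counts.sum()
    order = np.argsort(-counts, kind="stable")
    order = order[counts[order] > 0]
    return WordDistribution(
        states=order,
        probabilities=counts[order] / total,
        n_words_observed=int(total),
    )


def entropy(dist: WordDistribution) -> float:
    """Plug-in Shannon entropy, base 2, with 0*log(0) = 0."""
    p = dist.probabilities[dist.probabilities > 0]
    return float(-(p * np.log2(p)).sum())


def node_information(
    random_resp: Sequence[BitSequence], periodic_resp: Sequence[BitSequence]
) -> NodeInformation:
    """I = T - N: pooled word entropy under random minus periodic drive."""
    if not len(random_resp) or not len(periodic_resp):
        raise ValueError("both response sets must be non-empty")
    t = entropy(word_distribution(random_resp[0], random_resp[1:]))
    n = entropy(word_distribution(periodic_resp[0], periodic_resp[1:]))
    return NodeInformation(T=t, N_noise=n, I=t - n)


def input_information(
    spec: StimulusSpec, seed: int | np.random.Generator, n_trials: int = 10
) -> float:
    """Information content of the drive itself (the denominator of I/I_input).

    Applies the node_information formula to the stimulus sequences: pooled word
    entropy of ``n_trials`` random draws minus that of the periodic reference
    (which is a single repeated word, entropy 0).
    """
    rng = np.random.default_rng(seed)
    randoms = [random_stimulus(spec, rng) for _ in range(n_trials)]
    periodic = [periodic_stimulus(spec)] * n_trials
    return node_information(randoms, periodic).I
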