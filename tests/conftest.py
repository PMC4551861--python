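import itertools
import math

import numpy as np
import pytest

import spikeinfo as si


@pytest.fixture(scope="session")
def sig211():
    """The drift-diffusion ISI law with tau=2 ms, unit drift, unit shape."""
    return si.ShiftedInverseGaussian(2.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def sig_machine_coarse(sig211):
    """Small renewal machine (70 states) usable with enumeration oracles."""
    return si.build_renewal_machine(si.discretize_distribution(sig211, 0.5))


def word_probability(m, word, start=None):
    """Probability of a binary word from the machine, brute force."""
    p = 0.0
    start_dist = m.stationary if start is None else start
    for s0, ps in enumerate(start_dist):
        if ps == 0:
            continue
        pr, s = ps, s0
        for x in word:
            e = m.emit1[s]
            pr *= e if x == 1 else (1 - e)
            if pr == 0:
                break
            s = m.next1[s] if x == 1 else m.next0[s]
        p += pr
    return p


def enumerate_block_entropy(m, L):
    """H(L) by explicit enumeration over all 2^L words."""
    tot = 0.0
    for word in itertools.product([0, 1], repeat=L):
        p = word_probability(m, word)
        if p > 0:
            tot -= p * math.log2(p)
    return tot


def enumerate_word_distribution(m, L):
    return {w: word_probability(m, w)
            for w in itertools.product([0, 1], repeat=L)
            if word_probability(m, w) > 0}
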