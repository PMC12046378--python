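"""Shared fixtures: reference simulations and synthetic corpora."""

import numpy as np
import pytest

from gesturedyn import oscillators as osc
from gesturedyn import preprocess as pp
from gesturedyn import synthetic_data as sd

K_REF = 2000.0
B_REF = 2.0 * np.sqrt(K_REF)  # critical damping
T_REF = 0.2


@pytest.fixture(scope="session")
def replication_trajectory():
    """Critically damped oscillator: x0=1, v0=0, k=2000, b=2*sqrt(k), T=0.2."""
    params = osc.GestureParams(k=K_REF, b=B_REF, T=T_REF, x0=1.0, v0=0.0)
    return osc.simulate(params, duration=0.25, dt=0.001)


@pytest.fixture(scope="session")
def clean_corpus():
    """Noise-free 200-token corpus (50 per articulatory variable)."""
    spec = sd.CorpusSpec(n_tokens=50, noise_sd=0.0, orth_jitter_sd=0.0,
                         seed=1)
    rec, ledger = sd.generate_recording(spec)
    return spec, rec, ledger


@pytest.fixture(scope="session")
def clean_corpus_processed(clean_corpus):
    spec, rec, ledger = clean_corpus
    return spec, ledger, pp.preprocess_recording(rec)


@pytest.fixture(scope="session")
def noisy_corpus():
    """200-token corpus with noise sd = 2% of each token's amplitude."""
    spec = sd.CorpusSpec(n_tokens=50, noise_frac=0.02, seed=1)
    rec, ledger = sd.generate_recording(spec)
    return spec, rec, ledger


def match_segments(ledger, results, variables, tol=4):
    """Pair ledger tokens with kept segments by boundary proximity."""
    pairs = []
    for var in variables:
        kept = results[var]["kept"]
        for tok in ledger.tokens_for(var):
            cand = [s for s in kept
                    if abs(s.start - tok.start) <= tol
                    and abs(s.stop - tok.stop) <= tol]
            if cand:
                pairs.append((cand[0], tok))
    return pairs
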