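import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import companion_series, delay_states, identity_mlp_weights  # noqa: E402

from ekatp.koopman import CompanionForward, inverse_companion  # noqa: E402
from ekatp.model import DecoderSpec, EKATPModel, EncoderSpec  # noqa: E402


@pytest.fixture
def stable_companion() -> CompanionForward:
    """L=4 companion operator with two conjugate root pairs on the unit
    circle, so every mode persists and the coefficients are identifiable
    from any segment of the generated series."""
    roots = np.exp(1j * np.array([0.7, -0.7, 2.0, -2.0]))
    poly = np.real(np.poly(roots))  # z^4 + c3 z^3 + ... + c0
    a = -poly[1:][::-1]  # y_{t+4} = a1 y_t + ... + a4 y_{t+3}
    return CompanionForward(a)


@pytest.fixture
def exact_model(stable_companion):
    """Hand-built model that is a global zero of every loss term.

    Ambient states are the delay vectors themselves (identity lift, n = L),
    the encoder/decoder are exact identities, and the operators are the true
    companion pair.
    """
    L = stable_companion.L
    enc = EncoderSpec(L, L, hidden=(L,), activation="identity")
    model = EKATPModel(enc, DecoderSpec.mirror(enc), seed=0)
    identity_mlp_weights(model.encoder, L)
    identity_mlp_weights(model.decoder, L)
    model.a.data = stable_companion.a.copy()
    model.b.data = inverse_companion(stable_companion).b.copy()
    return model


@pytest.fixture
def companion_ambient(stable_companion):
    """Ambient trajectory (n = L = 4 rows over time) generated by the
    companion recurrence, matching `exact_model`."""
    rng = np.random.default_rng(3)
    y = companion_series(stable_companion.a, rng.standard_normal(4), 80)
    return delay_states(y, 4).T  # (n=4, T)
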