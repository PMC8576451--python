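import numpy as np


def companion_series(a: np.ndarray, y_init: np.ndarray, steps: int) -> np.ndarray:
    """Scalar series following the linear recurrence y_{t+L} = a . (y_t..y_{t+L-1})."""
    L = a.size
    y = np.empty(steps + L)
    y[:L] = y_init
    for t in range(steps):
        y[L + t] = a @ y[t: t + L]
    return y


def delay_states(y: np.ndarray, L: int) -> np.ndarray:
    """Stack delay vectors Y_t = (y_t, ..., y_{t+L-1}) as rows."""
    return np.lib.stride_tricks.sliding_window_view(y, L)


def identity_mlp_weights(mlp, dim: int) -> None:
    """Overwrite a 1-hidden-layer identity-activation MLP with the identity map."""
    (w0, b0), (w1, b1) = mlp.layers
    w0.data = np.eye(dim)
    b0.data = np.zeros(dim)
    w1.data = np.eye(dim)
    b1.data = np.zeros(dim)
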