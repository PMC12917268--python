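"""Bidirectional LSTM classifier, forward pass only.

The network is implemented from first principles because its weights
are trained by a gradient-free metaheuristic rather than
backpropagation: input, forget and output gates are sigmoids of an
affine map of the concatenated ``[h_prev, x_t]``, the candidate cell is
a tanh of the same form, the cell state is the gated convex mix
``c_t = f * c_prev + i * c_cand`` and the hidden state ``h_t = o *
tanh(c_t)``.  A forward pass runs the sequence left-to-right, a second
pass right-to-left with its own parameters, and the two final hidden
states are concatenated and mapped by a dense softmax head onto the
two classes (interictal / ictal).

All parameters live in one flat float64 vector with a fixed, versioned
packing order so an optimizer can treat the whole network as a point
in R^k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkConfig",
    "LSTMParams",
    "param_count",
    "pack_params",
    "unpack_params",
    "init_params",
    "lstm_step",
    "bilstm_forward",
    "predict_proba",
    "predict",
    "cross_entropy",
    "PACKING_VERSION",
]

#: bump when the flat packing order changes; serialized alongside params
PACKING_VERSION = "bilstm-flat-1"

_GATES = ("A", "D", "F", "H")  # input, forget, candidate, output


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the classifier.

    input_length is the number of timesteps (2000 in segment mode, 13 in
    feature mode); input_size the values per step (1); hidden_units the
    LSTM state width per direction; n_classes the softmax width.
    ``pooling`` selects how the per-step bidirectional outputs collapse
    to one vector: "last" concatenates the two final hidden states
    (default), "mean" averages the concatenated sequence.
    """

    input_length: int = 13
    input_size: int = 1
    hidden_units: int = 100
    n_classes: int = 2
    pooling: str = "last"

    def __post_init__(self) -> None:
        for name in ("input_length", "input_size", "hidden_units", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pooling not in ("last", "mean"):
            raise ValueError("pooling must be 'last' or 'mean'")


@dataclass
class DirectionParams:
    """Gate weights/biases for one direction.

    Each weight matrix has shape (hidden, hidden + input_size) and acts
    on the concatenation [h_prev, x_t]; each bias has shape (hidden,).
    """

    weights: dict[str, np.ndarray]
    biases: dict[str, np.ndarray]


@dataclass
class LSTMParams:
    """Structured view of all network parameters."""

    config: NetworkConfig
    forward: DirectionParams
    backward: DirectionParams
    head_weight: np.ndarray  # (n_classes, head_in)
    head_bias: np.ndarray  # (n_classes,)

    @property
    def head_in(self) -> int:
        return 2 * self.config.hidden_units


def param_count(config: NetworkConfig) -> int:
    """Length of the flat vector: 2 directions x 4 gates x (W + b) + head."""
    h, n = config.hidden_units, config.input_size
    per_direction = 4 * (h * (h + n) + h)
    head = config.n_classes * (2 * h + 1)
    return 2 * per_direction + head


def unpack_params(vector: np.ndarray, config: NetworkConfig) -> LSTMParams:
    """Flat vector -> structured parameters.

    Packing order: forward gates A, D, F, H weights (row-major), then
    forward biases in the same gate order; backward likewise; head
    weight then head bias.
    """
    vector = np.asarray(vector, dtype=np.float64).ravel()
    expected = param_count(config)
    if vector.size != expected:
        raise ValueError(f"parameter vector has {vector.size} entries, expected {expected}")
    h, n = config.hidden_units, config.input_size
    pos = 0

    def take(shape: tuple[int, ...]) -> np.ndarray:
        nonlocal pos
        size = int(np.prod(shape))
        out = vector[pos : pos + size].reshape(shape)
        pos += size
        return out

    directions = []
    for _ in range(2):
        weights = {g: take((h, h + n)) for g in _GATES}
        biases = {g: take((h,)) for g in _GATES}
        directions.append(DirectionParams(weights=weights, biases=biases))
    head_w = take((config.n_classes, 2 * h))
    head_b = take((config.n_classes,))
    assert pos == expected
    return LSTMParams(
        config=config,
        forward=directions[0],
        backward=directions[1],
        head_weight=head_w,
        head_bias=head_b,
    )


def pack_params(params: LSTMParams) -> np.ndarray:
    """Structured parameters -> flat vector (exact inverse of unpack)."""
    parts = []
    for direction in (params.forward, params.backward):
        for g in _GATES:
            parts.append(direction.weights[g].ravel())
        for g in _GATES:
            parts.append(direction.biases[g].ravel())
    parts.append(params.head_weight.ravel())
    parts.append(params.head_bias.ravel())
    vector = np.concatenate(parts)
    assert vector.size == param_count(params.config)
    return vector


def init_params(config: NetworkConfig, rng: np.random.Generator, scale: float = 0.5) -> np.ndarray:
    """Uniform(-scale, scale) flat initial parameter vector."""
    return rng.uniform(-scale, scale, size=param_count(config))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    direction: DirectionParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update on a batch.

    x_t: (batch, input_size); h_prev/c_prev: (batch, hidden).
    Gates are sigmoid(W . [h_prev, x_t] + b); the candidate uses tanh;
    c_t = forget * c_prev + input * candidate; h_t = output * tanh(c_t).
    """
    x_t = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=np.float64))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=np.float64))
    if h_prev.shape != c_prev.shape:
        raise ValueError("h_prev and c_prev shapes differ")
    hidden = direction.biases["A"].size
    if h_prev.shape[1] != hidden:
        raise ValueError(f"hidden state width {h_prev.shape[1]}, expected {hidden}")
    concat = np.concatenate([h_prev, x_t], axis=1)  # (batch, hidden + input)
    if concat.shape[1] != direction.weights["A"].shape[1]:
        raise ValueError(
            f"input width {x_t.shape[1]} inconsistent with gate weights "
            f"{direction.weights['A'].shape}"
        )
    gate_in = _sigmoid(concat @ direction.weights["A"].T + direction.biases["A"])
    gate_forget = _sigmoid(concat @ direction.weights["D"].T + direction.biases["D"])
    candidate = np.tanh(concat @ direction.weights["F"].T + direction.biases["F"])
    gate_out = _sigmoid(concat @ direction.weights["H"].T + direction.biases["H"])
    c_t = gate_forget * c_prev + gate_in * candidate
    h_t = gate_out * np.tanh(c_t)
    return h_t, c_t


def _run_direction(
    sequences: np.ndarray, direction: DirectionParams, reverse: bool
) -> np.ndarray:
    """All hidden states of one direction; (batch, T, hidden), original time order."""
    batch, timesteps, _ = sequences.shape
    hidden = direction.biases["A"].size
    h = np.zeros((batch, hidden))
    c = np.zeros((batch, hidden))
    order = range(timesteps - 1, -1, -1) if reverse else range(timesteps)
    states = np.empty((batch, timesteps, hidden))
    for t in order:
        h, c = lstm_step(sequences[:, t, :], h, c, direction)
        states[:, t, :] = h
    return states


def bilstm_forward(sequences: np.ndarray, params: LSTMParams) -> tuple[np.ndarray, np.ndarray]:
    """Bidirectional forward pass.

    sequences: (batch, T) or (batch, T, input_size) with T equal to the
    configured input_length.  Returns ``(G, rep)`` where G has shape
    (batch, T, 2*hidden) — forward and backward hidden states
    concatenated per step — and rep is the pooled representation fed to
    the dense head.
    """
    sequences = np.asarray(sequences, dtype=np.float64)
    if sequences.ndim == 1:
        sequences = sequences[None, :]
    if sequences.ndim == 2:
        sequences = sequences[:, :, None]
    if sequences.shape[1] != params.config.input_length:
        raise ValueError(
            f"sequence length {sequences.shape[1]} != configured "
            f"input_length {params.config.input_length}"
        )
    if sequences.shape[2] != params.config.input_size:
        raise ValueError("per-step input size mismatch")
    fwd = _run_direction(sequences, params.forward, reverse=False)
    bwd = _run_direction(sequences, params.backward, reverse=True)
    g = np.concatenate([fwd, bwd], axis=2)
    if params.config.pooling == "mean":
        rep = g.mean(axis=1)
    else:
        # final state of each direction: forward at t = T-1, backward at t = 0
        rep = np.concatenate([fwd[:, -1, :], bwd[:, 0, :]], axis=1)
    return g, rep


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def predict_proba(sequences: np.ndarray, params: LSTMParams) -> np.ndarray:
    """Class probabilities, (batch, n_classes); rows sum to 1."""
    _, rep = bilstm_forward(sequences, params)
    logits = rep @ params.head_weight.T + params.head_bias
    return _softmax(logits)


def predict(sequences: np.ndarray, params: LSTMParams) -> np.ndarray:
    """Hard labels as the argmax class per sequence."""
    return predict_proba(sequences, params).argmax(axis=1)


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean negative log-likelihood of the true class (reporting only)."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    picked = probabilities[np.arange(labels.size), labels]
    return float(-np.mean(np.log(np.clip(picked, eps, 1.0))))
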