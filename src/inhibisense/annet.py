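"""The sensor-array classifier: a 3-12-6 network trained by Levenberg-Marquardt.

The network maps the 3-channel normalized inhibition response to six outputs
in (0, 1) that regress onto a 6-bit binary codeword.  The codebook enumerates
the 60 (pollutant, concentration level) classes sequentially in table order -
code integer = 5*p + c + 1 for pollutant index p and level index c - so a
codeword jointly identifies the pollutant (12 classes) and its quantized
concentration (5 decade levels).  Hidden units use tanh, output units the
logistic (log-sigmoid) function; weights are optimized by damped Gauss-Newton
(Levenberg-Marquardt) on the mean squared error against the 0/1 code bits.

Decoding thresholds each output at 0.5 and, when the resulting bitstring is
not one of the 60 valid codewords, falls back to the nearest valid codeword
in Hamming distance (ties toward the smallest code integer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .errors import DomainError, RegistryError, StructureError, TrainingError
from .registry import LEVELS_UM, POLLUTANTS, group_of, level_index, pollutant_index
from .types import LabeledSample, ResponseVector

__all__ = [
    "Codebook",
    "NetworkConfig",
    "PollutantCall",
    "TrainedNetwork",
    "dataset_to_arrays",
    "decode",
    "forward",
    "init_weights",
    "network_outputs",
    "network_outputs_and_jacobian",
    "predict",
    "quantize_concentration",
    "train_lm",
]

#: Epoch budget of the full-scale reference protocol (not run by default).
FULL_SCALE_EPOCHS = 250_000
#: Epoch budget used for routine desk-scale training.
DESK_SCALE_EPOCHS = 2_000


def quantize_concentration(concentration_uM: float) -> float:
    """Round a concentration to the nearest grid level in log10 distance.

    Grid: 0.1, 1, 10, 100, 1000 uM.  An exact midpoint (sqrt(10) times a
    level) breaks toward the lower level.
    """
    if concentration_uM <= 0:
        raise DomainError("concentration must be positive")
    dist = np.abs(np.log10(concentration_uM) - np.log10(LEVELS_UM))
    return LEVELS_UM[int(np.argmin(dist))]  # argmin takes the first (lower) tie


class Codebook:
    """Bijection between the 60 classes and their 6-bit codewords."""

    def __init__(self) -> None:
        self.pollutants = POLLUTANTS
        self.levels_uM = LEVELS_UM
        self.n_classes = len(POLLUTANTS) * len(LEVELS_UM)
        self._by_code = {self.encode(p, c): (p, c)
                         for p in range(len(POLLUTANTS))
                         for c in range(len(LEVELS_UM))}

    def encode(self, pollutant_idx: int, level_idx: int) -> str:
        """Codeword of class (p, c): the integer 5p + c + 1 as 6 binary digits."""
        if not (0 <= pollutant_idx < len(self.pollutants)):
            raise RegistryError(f"pollutant index {pollutant_idx} out of range")
        if not (0 <= level_idx < len(self.levels_uM)):
            raise RegistryError(f"level index {level_idx} out of range")
        value = 5 * pollutant_idx + level_idx + 1
        return format(value, "06b")

    def encode_class(self, pollutant: str, level_uM: float) -> str:
        return self.encode(pollutant_index(pollutant), level_index(level_uM))

    def is_valid(self, codeword: str) -> bool:
        return codeword in self._by_code

    def class_of(self, codeword: str) -> tuple[int, int]:
        """(pollutant index, level index) of a valid codeword."""
        try:
            return self._by_code[codeword]
        except KeyError:
            raise RegistryError(f"invalid codeword {codeword!r}") from None

    def codewords(self) -> list[str]:
        """All 60 valid codewords in ascending integer order."""
        return sorted(self._by_code, key=lambda s: int(s, 2))

    def bits(self, codeword: str) -> np.ndarray:
        return np.array([int(ch) for ch in codeword], dtype=float)


@dataclass(frozen=True)
class PollutantCall:
    """A decoded network verdict: codeword, identity, quantized level."""

    codeword: str
    pollutant: str
    level_uM: float
    raw_output: tuple[float, ...] | None = None

    @property
    def group(self) -> str:
        return group_of(self.pollutant)


def decode(raw_output: Iterable[float], codebook: Codebook | None = None) -> PollutantCall:
    """Threshold six outputs at 0.5 and map to the nearest valid codeword.

    Total on (0,1)^6: an invalid bitstring is replaced by the valid codeword
    at minimum Hamming distance, ties broken toward the smallest code integer.
    """
    codebook = codebook or _DEFAULT_CODEBOOK
    raw = np.asarray(tuple(raw_output), dtype=float)
    if raw.shape != (6,):
        raise StructureError("decode expects exactly 6 outputs")
    bits = "".join("1" if v >= 0.5 else "0" for v in raw)
    if codebook.is_valid(bits):
        chosen = bits
    else:
        best, best_dist = None, 7
        for cw in codebook.codewords():  # ascending integer order => tie-break
            d = sum(a != b for a, b in zip(cw, bits))
            if d < best_dist:
                best, best_dist = cw, d
        chosen = best
    p, c = codebook.class_of(chosen)
    return PollutantCall(
        codeword=chosen,
        pollutant=codebook.pollutants[p],
        level_uM=codebook.levels_uM[c],
        raw_output=tuple(raw.tolist()),
    )


_DEFAULT_CODEBOOK = Codebook()


# ---------------------------------------------------------------------------
# Network definition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and Levenberg-Marquardt schedule.

    Defaults are the 3-12-6 architecture with a desk-scale epoch budget; the
    full-scale protocol (250 000 epochs, MSE goal 1e-10) is available via
    :meth:`full_scale`.  ``damping_*`` is the standard LM schedule: start at
    ``damping_init``, multiply by ``damping_up`` on a rejected step and by
    ``damping_down`` on an accepted one; training stops at the MSE goal, the
    epoch budget, or when the damping factor overflows ``damping_max``.
    """

    n_input: int = 3
    n_hidden: int = 12
    n_output: int = 6
    max_epochs: int = DESK_SCALE_EPOCHS
    mse_goal: float = 1e-10
    damping_init: float = 1e-3
    damping_up: float = 10.0
    damping_down: float = 0.1
    damping_max: float = 1e12
    damping_min: float = 1e-12
    seed: int = 0

    def __post_init__(self):
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise DomainError("layer sizes must be positive")
        if self.mse_goal <= 0:
            raise DomainError("mse_goal must be positive")
        if min(self.damping_init, self.damping_up, self.damping_down) <= 0:
            raise DomainError("damping factors must be positive")
        if self.max_epochs < 1:
            raise DomainError("max_epochs must be >= 1")

    @property
    def n_params(self) -> int:
        h, i, o = self.n_hidden, self.n_input, self.n_output
        return h * i + h + o * h + o

    @classmethod
    def full_scale(cls, **overrides) -> "NetworkConfig":
        """The full-length reference protocol: 250 000 epochs, goal 1e-10."""
        overrides.setdefault("max_epochs", FULL_SCALE_EPOCHS)
        overrides.setdefault("mse_goal", 1e-10)
        return cls(**overrides)


def init_weights(config: NetworkConfig) -> np.ndarray:
    """Seeded flat parameter vector, uniform in [-0.5, 0.5]."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    return rng.uniform(-0.5, 0.5, config.n_params)


def _unpack(params: np.ndarray, config: NetworkConfig):
    h, i, o = config.n_hidden, config.n_input, config.n_output
    k = 0
    w1 = params[k:k + h * i].reshape(h, i); k += h * i
    b1 = params[k:k + h]; k += h
    w2 = params[k:k + o * h].reshape(o, h); k += o * h
    b2 = params[k:k + o]
    return w1, b1, w2, b2


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def network_outputs(params: np.ndarray, X: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Batch forward pass: tanh hidden layer, logistic output layer."""
    w1, b1, w2, b2 = _unpack(params, config)
    hidden = np.tanh(X @ w1.T + b1)
    return expit(hidden @ w2.T + b2)


def network_outputs_and_jacobian(
    params: np.ndarray, X: np.ndarray, config: NetworkConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Outputs (N, O) and the Jacobian d y / d params of shape (N*O, P).

    The Jacobian is assembled analytically (backpropagation through the two
    layers); parameter order matches :func:`_pack`: W1 rows, b1, W2 rows, b2.
    """
    w1, b1, w2, b2 = _unpack(params, config)
    N = X.shape[0]
    h_dim, i_dim, o_dim = config.n_hidden, config.n_input, config.n_output
    hidden = np.tanh(X @ w1.T + b1)                     # (N, H)
    y = expit(hidden @ w2.T + b2)                       # (N, O)
    s = y * (1.0 - y)                                   # logistic derivative

    P = config.n_params
    J = np.empty((N, o_dim, P))
    # g[n, o, j] = s_no * W2_oj * (1 - h_nj^2): sensitivity wrt hidden pre-act
    g = s[:, :, None] * w2[None, :, :] * (1.0 - hidden ** 2)[:, None, :]
    k = 0
    J[:, :, k:k + h_dim * i_dim] = np.einsum("noj,ni->noji", g, X).reshape(
        N, o_dim, h_dim * i_dim
    )
    k += h_dim * i_dim
    J[:, :, k:k + h_dim] = g
    k += h_dim
    w2_block = np.zeros((N, o_dim, o_dim, h_dim))
    idx = np.arange(o_dim)
    w2_block[:, idx, idx, :] = s[:, :, None] * hidden[:, None, :]
    J[:, :, k:k + o_dim * h_dim] = w2_block.reshape(N, o_dim, o_dim * h_dim)
    k += o_dim * h_dim
    b2_block = np.zeros((N, o_dim, o_dim))
    b2_block[:, idx, idx] = s
    J[:, :, k:] = b2_block
    return y, J.reshape(N * o_dim, P)


@dataclass(frozen=True)
class TrainedNetwork:
    """Weights, biases and the accepted-step MSE history of one training run."""

    config: NetworkConfig
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    history: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        c = self.config
        if self.w1.shape != (c.n_hidden, c.n_input) or self.b1.shape != (c.n_hidden,):
            raise StructureError("hidden-layer shapes inconsistent with config")
        if self.w2.shape != (c.n_output, c.n_hidden) or self.b2.shape != (c.n_output,):
            raise StructureError("output-layer shapes inconsistent with config")

    @property
    def params(self) -> np.ndarray:
        return _pack(self.w1, self.b1, self.w2, self.b2)

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.n_input:
            raise StructureError("input matrix must be (N, n_input)")
        return network_outputs(self.params, X, self.config)

    def save(self, path) -> None:
        """Serialize to JSON; floats round-trip bit-exactly via repr."""
        doc = {
            "config": asdict(self.config),
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "history": self.history.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path) -> "TrainedNetwork":
        doc = json.loads(Path(path).read_text())
        return cls(
            config=NetworkConfig(**doc["config"]),
            w1=np.array(doc["w1"], dtype=float),
            b1=np.array(doc["b1"], dtype=float),
            w2=np.array(doc["w2"], dtype=float),
            b2=np.array(doc["b2"], dtype=float),
            history=np.array(doc["history"], dtype=float),
        )


def forward(net: TrainedNetwork, response: ResponseVector | np.ndarray) -> np.ndarray:
    """Outputs in (0,1)^6 for one response triple."""
    x = response.as_array() if isinstance(response, ResponseVector) else np.asarray(response, float)
    if x.shape != (net.config.n_input,):
        raise StructureError(f"expected {net.config.n_input} inputs, got {x.shape}")
    return net.forward_batch(x[None, :])[0]


def dataset_to_arrays(
    samples: Sequence[LabeledSample], codebook: Codebook | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(X, T): responses and 0/1 codeword targets for a labeled dataset.

    The target class is (pollutant, quantized true concentration).
    """
    codebook = codebook or _DEFAULT_CODEBOOK
    X = np.array([s.response.as_array() for s in samples])
    T = np.array(
        [
            codebook.bits(
                codebook.encode_class(s.pollutant, quantize_concentration(s.concentration_uM))
            )
            for s in samples
        ]
    )
    return X, T


def train_lm(dataset, config: NetworkConfig | None = None) -> TrainedNetwork:
    """Train the network with Levenberg-Marquardt on 0/1 codeword targets.

    ``dataset`` is either a sequence of :class:`LabeledSample` or a pair of
    arrays ``(X, T)`` with X of shape (N, n_input) and T of shape
    (N, n_output) holding codeword bits.

    Each epoch solves the damped normal equations
    ``(J^T J + lambda I) dw = J^T e`` for the full-batch residual
    ``e = T - y``; a step is accepted only if it strictly decreases the MSE
    (so the recorded history is strictly decreasing), otherwise the damping
    factor is raised and the step retried.  Training stops at the MSE goal,
    the epoch budget, or damping overflow, and returns the best weights seen.
    """
    config = config or NetworkConfig()
    if isinstance(dataset, tuple):
        X, T = (np.asarray(a, dtype=float) for a in dataset)
    else:
        if len(dataset) == 0:
            raise DomainError("dataset must be nonempty")
        X, T = dataset_to_arrays(dataset)
    if X.ndim != 2 or X.shape[1] != config.n_input:
        raise StructureError("X must have shape (N, n_input)")
    if T.shape != (X.shape[0], config.n_output):
        raise StructureError("targets must have shape (N, n_output)")
    if X.shape[0] == 0:
        raise DomainError("dataset must be nonempty")

    params = init_weights(config)
    y, J = network_outputs_and_jacobian(params, X, config)
    e = (T - y.reshape(T.shape)).ravel()
    mse = float(np.mean(e ** 2))
    lam = config.damping_init
    history = [mse]
    identity = np.eye(config.n_params)

    epoch = 0
    while epoch < config.max_epochs and mse > config.mse_goal:
        epoch += 1
        A = J.T @ J
        g = J.T @ e
        accepted = False
        singular = False
        while lam <= config.damping_max:
            try:
                step = np.linalg.solve(A + lam * identity, g)
            except np.linalg.LinAlgError:
                # raise damping until the system regularizes
                singular = True
                lam *= config.damping_up
                continue
            trial = params + step
            y_t = network_outputs(trial, X, config)
            e_t = (T - y_t).ravel()
            mse_t = float(np.mean(e_t ** 2))
            if np.isfinite(mse_t) and mse_t < mse:
                params, mse = trial, mse_t
                lam = max(lam * config.damping_down, config.damping_min)
                history.append(mse)
                accepted = True
                break
            lam *= config.damping_up
        if not accepted:
            if singular:
                raise TrainingError(
                    "normal equations singular at every damping level",
                    diagnostics={"lambda": lam, "epoch": epoch, "mse": mse},
                )
            break  # damping overflow: no further descent possible
        y, J = network_outputs_and_jacobian(params, X, config)
        e = (T - y.reshape(T.shape)).ravel()

    w1, b1, w2, b2 = _unpack(params, config)
    return TrainedNetwork(
        config=config, w1=w1.copy(), b1=b1.copy(), w2=w2.copy(), b2=b2.copy(),
        history=np.array(history),
    )


def predict(
    net: TrainedNetwork,
    response: ResponseVector | np.ndarray,
    codebook: Codebook | None = None,
) -> PollutantCall:
    """decode(forward(net, response)): identity plus quantized level."""
    return decode(forward(net, response), codebook)
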