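"""The multimodal glucose forecasting network.

Architecture (per mode):

  unimodal:    window (6 scaled samples) -> BiLSTM -> self-attention ->
               1D CNN (kernel 3, stride 1, no padding) -> flatten ->
               dense regressor -> sigmoid
  multimodal:  ... -> flatten = Z1;  baseline record -> dense encoder = Z2;
               Z3 = G(concat(Z1, Z2)); -> dense regressor -> sigmoid

The LSTM cell follows the standard gated recurrence
  f,i,o = sigmoid(theta_. [h_prev, x] + b_.),  Ctil = tanh(theta_c [.] + b_c),
  C = f*C_prev + i*Ctil,  h = o*tanh(C).
Self-attention is parameter-free: the BiLSTM output sequence acts as its own
query and value, scores are plain dot products, and each output row is the
softmax-weighted (rows sum to 1) combination of the sequence rows.

Weights are Glorot-uniform initialised (U(-limit, limit),
limit = sqrt(6/(fan_in + fan_out))); biases start at zero. Dropout (10%
after the CNN; a separate 20% "stacked" rate after the fusion layer) is
active in training mode only. Training is mini-batch Adam on mean squared
error over scaled targets by default; the listwise log-likelihood objective
(sum_i [Yhat_i - log sum_{j in t_i} exp(Yhat_j)]) is implemented and
selectable, with per-subject within-batch candidate sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, concat, dropout, logsumexp, stack

INPUT_LEN = 6
CONV_POSITIONS_FORMULA = "floor((l_f - m)/d) + 1"


@dataclass
class ModelConfig:
    lstm_hidden: int = 64
    cnn_filters: int = 100
    cnn_kernel: int = 3
    cnn_stride: int = 1
    dropout_after_cnn: float = 0.10
    dropout_stacked: float = 0.20
    baseline_hidden: tuple[int, ...] = (32, 16)
    fusion_hidden: int = 64
    loss: str = "mse"               # "mse" or "listwise"
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    mode: str = "unimodal"          # "unimodal" or "multimodal"
    variable_set: int = 0
    baseline_dim: int = 2           # input width of the baseline encoder

    def __post_init__(self) -> None:
        if min(self.lstm_hidden, self.cnn_filters, self.fusion_hidden) <= 0 \
                or any(w <= 0 for w in self.baseline_hidden):
            raise ValueError("all layer widths must be positive")
        for r in (self.dropout_after_cnn, self.dropout_stacked):
            if not 0.0 <= r < 1.0:
                raise ValueError("dropout rates must lie in [0, 1)")
        if self.mode not in ("unimodal", "multimodal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.loss not in ("mse", "listwise"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.cnn_stride != 1:
            raise ValueError("only stride 1 is supported")

    @property
    def conv_positions(self) -> int:
        return (INPUT_LEN - self.cnn_kernel) // self.cnn_stride + 1

    @property
    def cnn_flat_dim(self) -> int:
        return self.conv_positions * self.cnn_filters


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def _dense_params(rng, fan_in, fan_out, prefix, params):
    params[f"{prefix}.W"] = Tensor(glorot_uniform(rng, fan_in, fan_out),
                                   requires_grad=True)
    params[f"{prefix}.b"] = Tensor(np.zeros(fan_out), requires_grad=True)


def init_params(config: ModelConfig, rng: np.random.Generator
                ) -> dict[str, Tensor]:
    """Glorot-uniform weights, zero biases; deterministic given the rng state."""
    H = config.lstm_hidden
    params: dict[str, Tensor] = {}
    for direction in ("fwd", "bwd"):
        for gate in ("f", "i", "o", "c"):
            _dense_params(rng, H + 1, H, f"lstm_{direction}.{gate}", params)
    d_seq = 2 * H
    k_in = config.cnn_kernel * d_seq
    params["conv.K"] = Tensor(
        glorot_uniform(rng, k_in, config.cnn_filters), requires_grad=True)
    params["conv.b"] = Tensor(np.zeros(config.cnn_filters), requires_grad=True)
    if config.mode == "multimodal":
        widths = [config.baseline_dim, *config.baseline_hidden]
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            _dense_params(rng, a, b, f"baseline.{i}", params)
        _dense_params(rng, config.cnn_flat_dim + config.baseline_hidden[-1],
                      config.fusion_hidden, "fusion", params)
        _dense_params(rng, config.fusion_hidden, 1, "regressor", params)
    else:
        _dense_params(rng, config.cnn_flat_dim, 1, "regressor", params)
    return params


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def lstm_step(x_t, h_prev, c_prev, theta_f, theta_i, theta_o, theta_c,
              b_f, b_i, b_o, b_c):
    """One LSTM cell update on a batch; inputs (B, I), states (B, H).

    Accepts numpy arrays or Tensors; returns (h_t, c_t) as Tensors.
    """
    x_t, h_prev, c_prev = as_tensor(x_t), as_tensor(h_prev), as_tensor(c_prev)
    z = concat([h_prev, x_t], axis=-1)
    f = (z @ as_tensor(theta_f) + as_tensor(b_f)).sigmoid()
    i = (z @ as_tensor(theta_i) + as_tensor(b_i)).sigmoid()
    o = (z @ as_tensor(theta_o) + as_tensor(b_o)).sigmoid()
    c_til = (z @ as_tensor(theta_c) + as_tensor(b_c)).tanh()
    c_t = f * c_prev + i * c_til
    h_t = o * c_t.tanh()
    return h_t, c_t


def _run_direction(xs: list[Tensor], params: dict[str, Tensor],
                   direction: str, hidden: int, batch: int) -> list[Tensor]:
    # One fused (H+1, 4H) gate matmul per step: algebraically identical to
    # four separate lstm_step products, just fewer graph nodes.
    W = concat([params[f"lstm_{direction}.{g}.W"] for g in ("f", "i", "o", "c")],
               axis=1)
    b = concat([params[f"lstm_{direction}.{g}.b"] for g in ("f", "i", "o", "c")],
               axis=0)
    h = as_tensor(np.zeros((batch, hidden)))
    c = as_tensor(np.zeros((batch, hidden)))
    out = []
    H = hidden
    for x in xs:
        z = concat([h, x], axis=-1)
        a = z @ W + b
        f = a[:, 0:H].sigmoid()
        i = a[:, H:2 * H].sigmoid()
        o = a[:, 2 * H:3 * H].sigmoid()
        c_til = a[:, 3 * H:4 * H].tanh()
        c = f * c + i * c_til
        h = o * c.tanh()
        out.append(h)
    return out


def bilstm_forward(window, params: dict[str, Tensor], hidden: int) -> Tensor:
    """Run the window (B, 6) through both LSTM directions.

    Forward stream reads t0 -> t5, backward stream t5 -> t0; per-step outputs
    are concatenated, giving (B, 6, 2H) aligned on the original time axis.
    """
    w = as_tensor(window)
    if w.data.ndim == 1:
        w = w.reshape(1, -1)
    if w.data.shape[1] != INPUT_LEN:
        raise ValueError(f"window must have {INPUT_LEN} samples")
    batch = w.data.shape[0]
    xs = [w[:, t:t + 1] for t in range(INPUT_LEN)]
    fwd = _run_direction(xs, params, "fwd", hidden, batch)
    bwd = _run_direction(xs[::-1], params, "bwd", hidden, batch)[::-1]
    steps = [concat([f, b], axis=-1) for f, b in zip(fwd, bwd)]
    return stack(steps, axis=1)  # (B, 6, 2H)


def self_attention(y_seq, return_weights: bool = False):
    """Parameter-free self-attention over the sequence axis.

    The sequence is its own query and value; scores are dot products, weights
    are row-softmaxed (each row sums to 1), and the output is the weighted sum
    of sequence rows. Accepts (6, d) or (B, 6, d).
    """
    y = as_tensor(y_seq)
    squeeze = y.data.ndim == 2
    if squeeze:
        y = y.reshape(1, *y.data.shape)
    if not np.isfinite(y.data).all():
        raise ValueError("non-finite attention input")
    scores = y @ y.swap_last2()          # (B, 6, 6)
    weights = scores.softmax(axis=-1)
    out = weights @ y
    if squeeze:
        out = out.reshape(*out.data.shape[1:])
        weights = weights.reshape(*weights.data.shape[1:])
    return (out, weights) if return_weights else out


def conv1d_relu(attended, kernel, bias, training: bool = False,
                dropout_rate: float = 0.0,
                rng: np.random.Generator | None = None) -> Tensor:
    """1D convolution along time (kernel 3, stride 1, no padding) + ReLU.

    ``kernel`` is the flattened (kernel_len * d_in, filters) weight; output is
    (B, positions, filters) with positions = floor((6 - m)/1) + 1 = 4.
    """
    x = as_tensor(attended)
    squeeze = x.data.ndim == 2
    if squeeze:
        x = x.reshape(1, *x.data.shape)
    kernel = as_tensor(kernel)
    bias = as_tensor(bias)
    l_f, d_in = x.data.shape[1], x.data.shape[2]
    m = kernel.data.shape[0] // d_in
    if m > l_f:
        raise ValueError("kernel longer than the input sequence")
    positions = l_f - m + 1
    batch = x.data.shape[0]
    feats = []
    for i in range(positions):
        window = x[:, i:i + m, :].reshape(batch, m * d_in)
        feats.append((window @ kernel + bias).relu())
    out = stack(feats, axis=1)          # (B, positions, filters)
    if training and dropout_rate > 0:
        out = dropout(out, dropout_rate, rng, training)
    if squeeze:
        out = out.reshape(*out.data.shape[1:])
    return out


def _dense_stack(x: Tensor, params: dict[str, Tensor], prefix: str,
                 n_layers: int) -> Tensor:
    for i in range(n_layers):
        x = (x @ params[f"{prefix}.{i}.W"] + params[f"{prefix}.{i}.b"]).relu()
    return x


def baseline_encoder(record, params: dict[str, Tensor],
                     n_layers: int) -> Tensor:
    """Dense+ReLU stack over the (unscaled) baseline variable vector."""
    x = as_tensor(record)
    if x.data.ndim == 1:
        x = x.reshape(1, -1)
    if np.isnan(x.data).any():
        raise ValueError("baseline record contains absent variables")
    return _dense_stack(x, params, "baseline", n_layers)


def fuse(z1, z2, params: dict[str, Tensor]) -> Tensor:
    """Z3 = G(concat(Z1, Z2)): feature-axis concatenation into one
    fully-connected ReLU layer of width fusion_hidden."""
    z = concat([as_tensor(z1), as_tensor(z2)], axis=-1)
    return (z @ params["fusion.W"] + params["fusion.b"]).relu()


def forward(window, record, params: dict[str, Tensor], config: ModelConfig,
            training: bool = False,
            rng: np.random.Generator | None = None) -> Tensor:
    """Full pipeline; returns sigmoid outputs in (0, 1), shape (B,).

    In unimodal mode ``record`` is ignored and the regressor reads the
    flattened CNN features directly.
    """
    if training and rng is None:
        rng = np.random.default_rng(config.seed)
    seq = bilstm_forward(window, params, config.lstm_hidden)
    att = self_attention(seq)
    feats = conv1d_relu(att, params["conv.K"], params["conv.b"],
                        training=training, dropout_rate=config.dropout_after_cnn,
                        rng=rng)
    batch = feats.data.shape[0]
    z1 = feats.reshape(batch, config.cnn_flat_dim)
    if config.mode == "multimodal":
        if record is None:
            raise ValueError("multimodal mode requires a baseline record")
        z2 = baseline_encoder(record, params, len(config.baseline_hidden))
        z3 = fuse(z1, z2, params)
        if training and config.dropout_stacked > 0:
            z3 = dropout(z3, config.dropout_stacked, rng, training)
        head = z3
    else:
        head = z1
    y = (head @ params["regressor.W"] + params["regressor.b"]).sigmoid()
    return y.reshape(batch)


# ---------------------------------------------------------------------------
# objectives and training
# ---------------------------------------------------------------------------

def loss_mse(pred: Tensor, target) -> Tensor:
    diff = pred - as_tensor(np.asarray(target, dtype=float))
    return (diff * diff).mean()


def loss_listwise_loglik(pred, sets) -> Tensor:
    """Listwise log-likelihood: sum_i pred[i] - logsumexp(pred[sets[i]]).

    ``sets[i]`` is the candidate index set attached to prediction i (the
    horizon set); a singleton {i} contributes exactly 0. Uses a stable
    log-sum-exp.
    """
    p = as_tensor(pred)
    if p.data.size == 0 or len(sets) == 0:
        raise ValueError("empty prediction set")
    total = None
    for i, s in enumerate(sets):
        s = np.asarray(s, dtype=int)
        if s.size == 0:
            raise ValueError("empty candidate set")
        term = p[int(i)] - logsumexp(p[s])
        total = term if total is None else total + term
    return total


def _batch_listwise_objective(pred: Tensor, patient_codes: np.ndarray) -> Tensor:
    """Training surrogate for the listwise objective: the candidate set of a
    window is all windows of the same subject in the mini-batch. Returns the
    negated likelihood (to minimise)."""
    sets = []
    for i in range(pred.data.size):
        sets.append(np.flatnonzero(patient_codes == patient_codes[i]))
    return -1.0 * loss_listwise_loglik(pred, sets) * (1.0 / pred.data.size)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(X: np.ndarray, y: np.ndarray, records: np.ndarray | None,
          config: ModelConfig, patient_ids: np.ndarray | None = None
          ) -> tuple[dict[str, Tensor], list[float]]:
    """Mini-batch gradient training; deterministic given config.seed.

    X: (n, 6) scaled inputs; y: (n,) scaled targets; records: (n, p) raw
    baseline vectors (multimodal only). Returns final parameters and the
    per-epoch mean training loss trace.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if config.mode == "multimodal" and records is None:
        raise ValueError("multimodal training requires baseline records")
    rng = np.random.default_rng(config.seed)
    params = init_params(config, rng)
    opt = Adam(params, lr=config.learning_rate)
    if config.loss == "listwise":
        if patient_ids is None:
            patient_ids = np.zeros(X.shape[0], dtype=int)
        _, codes = np.unique(np.asarray(patient_ids), return_inverse=True)

    n = X.shape[0]
    trace: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            rec = records[idx] if records is not None else None
            pred = forward(X[idx], rec, params, config, training=True, rng=rng)
            if config.loss == "listwise":
                loss = _batch_listwise_objective(pred, codes[idx])
            else:
                loss = loss_mse(pred, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}")
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        trace.append(float(np.mean(epoch_losses)))
    return params, trace


def predict(X: np.ndarray, records: np.ndarray | None,
            params: dict[str, Tensor], config: ModelConfig) -> np.ndarray:
    """Deterministic (dropout-off) predictions on the scaled output scale."""
    out = forward(np.asarray(X, dtype=float), records, params, config,
                  training=False)
    return out.data.copy()
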