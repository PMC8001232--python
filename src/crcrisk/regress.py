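"""Feedforward-network regression trained with Levenberg–Marquardt.

The continuous risk score (0–100) is regressed on the continuous cohort
features (raw analyte values plus binary-encoded qualitative variables).
Networks are fully connected tanh-hidden / linear-output perceptrons; training
is damped Gauss–Newton: each accepted update solves

    (J^T J + mu I) delta = J^T e

where J is the Jacobian of the network output w.r.t. all weights and biases
on the training set and e the vector of training errors.  The damping mu
grows on rejected steps and shrinks on accepted ones.  One accepted pass over
the training set is one epoch.  Training stops after a run of epochs without
validation-MSE improvement (default patience 6), on a vanishing gradient
norm ||J^T e||, at the epoch cap, or when no step is accepted before mu
reaches its ceiling.

When the network has more parameters than training samples the update is
solved in the equivalent dual form delta = J^T (J J^T + mu I)^{-1} e, which
turns an O(P^3) solve into O(N^3).

The ten-architecture sweep trains nets of 1/5/10 hidden layers with 3–40
neurons per layer on a fixed seeded 60/20/20 split and reports epochs, MSE,
gradient and wall time per architecture.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .labeling import label_cohort
from .schema import CohortTable

STOP_VALIDATION = "validation_failures"
STOP_GRADIENT = "min_gradient"
STOP_EPOCHS = "max_epochs"
STOP_DAMPING = "damping_limit"

#: The ten (hidden_layers, neurons_per_layer) sweep architectures.
SWEEP_ARCHITECTURES: tuple[tuple[int, int], ...] = (
    (1, 3), (1, 10), (1, 20),
    (5, 3), (5, 10), (5, 20), (5, 40),
    (10, 3), (10, 10), (10, 20),
)


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class NetArchitecture:
    hidden_layers: int
    neurons_per_layer: int

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.neurons_per_layer < 1:
            raise ValueError("hidden_layers and neurons_per_layer must be >= 1")

    def n_parameters(self, n_inputs: int) -> int:
        m, L = self.neurons_per_layer, self.hidden_layers
        return (n_inputs * m + m) + (L - 1) * (m * m + m) + (m + 1)


@dataclass(frozen=True)
class TrainingConfig:
    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    max_validation_failures: int = 6
    max_epochs: int = 1000
    min_gradient: float = 1e-7
    damping_init: float = 1e-3
    damping_up: float = 10.0
    damping_down: float = 0.1
    damping_max: float = 1e10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("train/val/test fractions must sum to 1")
        if self.max_validation_failures < 1:
            raise ValueError("max_validation_failures must be >= 1")


@dataclass(frozen=True)
class TrainingReport:
    epochs: int
    mse: float
    test_mse: float | None
    gradient: float
    seconds: float
    stop_reason: str


@dataclass
class Network:
    """Fully connected tanh-hidden, linear-output feedforward net."""

    arch: NetArchitecture
    n_inputs: int
    weights: list[np.ndarray]   # one (fan_in, fan_out) matrix per layer
    biases: list[np.ndarray]

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def predict(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ W + b)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()

    # --- flat parameter vector <-> layer arrays ------------------------------
    def get_theta(self) -> np.ndarray:
        return np.concatenate([np.concatenate([W.ravel(), b.ravel()])
                               for W, b in zip(self.weights, self.biases)])

    def set_theta(self, theta: np.ndarray) -> None:
        pos = 0
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[i] = theta[pos:pos + W.size].reshape(W.shape)
            pos += W.size
            self.biases[i] = theta[pos:pos + b.size].reshape(b.shape)
            pos += b.size
        assert pos == theta.size

    def jacobian(self, X: np.ndarray) -> np.ndarray:
        """d(output)/d(theta), one row per sample, via batched backprop."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        acts = [X]
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ W + b)
            acts.append(a)
        # g[l] = d(output)/d(pre-activation of layer l), built backwards
        gs: list[np.ndarray] = [None] * len(self.weights)  # type: ignore[list-item]
        gs[-1] = np.ones((n, 1))
        for l in range(len(self.weights) - 2, -1, -1):
            upstream = gs[l + 1] @ self.weights[l + 1].T
            gs[l] = upstream * (1.0 - acts[l + 1] ** 2)
        blocks = []
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            jw = acts[l][:, :, None] * gs[l][:, None, :]   # n x fan_in x fan_out
            blocks.append(jw.reshape(n, W.size))
            blocks.append(gs[l])
        return np.concatenate(blocks, axis=1)


def build_network(arch: NetArchitecture, n_inputs: int, seed: int = 0) -> Network:
    """Seeded network with uniform [-0.5, 0.5] initial weights and biases."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = [n_inputs] + [arch.neurons_per_layer] * arch.hidden_layers + [1]
    weights = [rng.uniform(-0.5, 0.5, (a, b)) for a, b in zip(sizes[:-1], sizes[1:])]
    biases = [rng.uniform(-0.5, 0.5, b) for b in sizes[1:]]
    net = Network(arch=arch, n_inputs=n_inputs, weights=weights, biases=biases)
    assert net.n_parameters == arch.n_parameters(n_inputs)
    return net


def lm_step(J: np.ndarray, e: np.ndarray, mu: float) -> np.ndarray:
    """One damped Gauss–Newton step: solve (J^T J + mu I) delta = J^T e.

    Uses the dual (J J^T + mu I) system when parameters outnumber samples;
    the two forms are algebraically identical.
    """
    n, p = J.shape
    if p <= n:
        A = J.T @ J + mu * np.eye(p)
        return np.linalg.solve(A, J.T @ e)
    A = J @ J.T + mu * np.eye(n)
    return J.T @ np.linalg.solve(A, e)


@dataclass
class _MinMaxScaler:
    """Per-feature affine map onto [-1, 1] fitted on the training partition."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_MinMaxScaler":
        return cls(lo=X.min(axis=0), hi=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        span = np.where(span > 0, span, 1.0)
        return 2.0 * (X - self.lo) / span - 1.0


def split_indices(n: int, config: TrainingConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic shuffled 60/20/20 (by default) train/val/test partition."""
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    n_train = int(round(config.train_frac * n))
    n_val = int(round(config.val_frac * n))
    return order[:n_train], order[n_train:n_train + n_val], order[n_train + n_val:]


def lm_train(net: Network, inputs: np.ndarray, response: np.ndarray,
             config: TrainingConfig = TrainingConfig(),
             partitions: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
             trace: list | None = None) -> TrainingReport:
    """Train in place; returns the report at the best-validation weights.

    ``partitions`` overrides the seeded train/val/test split (index triples).
    ``trace`` (if a list) collects per-epoch (theta, train_sse, val_mse).
    """
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("inputs and response are not aligned")
    if partitions is None:
        partitions = split_indices(len(y), config)
    idx_train, idx_val, idx_test = partitions
    scaler = _MinMaxScaler.fit(X[idx_train])
    Xtr, ytr = scaler.transform(X[idx_train]), y[idx_train]
    Xval, yval = scaler.transform(X[idx_val]), y[idx_val]
    Xtest, ytest = scaler.transform(X[idx_test]), y[idx_test]

    def val_mse(theta=None):
        if len(yval) == 0:
            return np.inf
        return float(np.mean((yval - net.predict(Xval)) ** 2))

    t0 = time.perf_counter()
    mu = config.damping_init
    theta = net.get_theta()
    e = ytr - net.predict(Xtr)
    sse = float(e @ e)
    best_theta = theta.copy()
    best_val = val_mse()
    failures = 0
    epochs = 0
    stop_reason = STOP_EPOCHS
    gradient = np.nan

    while epochs < config.max_epochs:
        J = net.jacobian(Xtr)
        g = J.T @ e
        gradient = float(np.linalg.norm(g))
        if gradient < config.min_gradient:
            stop_reason = STOP_GRADIENT
            break
        # inner damping loop: retry with larger mu until the step helps
        JJ = J @ J.T if J.shape[1] > J.shape[0] else J.T @ J
        accepted = False
        while mu <= config.damping_max:
            n_, p_ = J.shape
            if p_ <= n_:
                delta = np.linalg.solve(JJ + mu * np.eye(p_), g)
            else:
                delta = J.T @ np.linalg.solve(JJ + mu * np.eye(n_), e)
            cand = theta + delta
            net.set_theta(cand)
            e_new = ytr - net.predict(Xtr)
            sse_new = float(e_new @ e_new)
            if np.isfinite(sse_new) and sse_new < sse:
                theta, e, sse = cand, e_new, sse_new
                mu = max(mu * config.damping_down, 1e-300)
                accepted = True
                break
            mu *= config.damping_up
        if not accepted:
            net.set_theta(theta)
            stop_reason = STOP_DAMPING
            break
        epochs += 1
        vm = val_mse()
        if trace is not None:
            trace.append((theta.copy(), sse, vm))
        if vm < best_val:
            best_val = vm
            best_theta = theta.copy()
            failures = 0
        else:
            failures += 1
            if failures >= config.max_validation_failures:
                stop_reason = STOP_VALIDATION
                break

    # report at the best-validation weights
    if np.isfinite(best_val):
        net.set_theta(best_theta)
    e_best = ytr - net.predict(Xtr)
    J_best = net.jacobian(Xtr)
    gradient = float(np.linalg.norm(J_best.T @ e_best))
    test_mse = (float(np.mean((ytest - net.predict(Xtest)) ** 2))
                if len(ytest) else None)
    mse = best_val if np.isfinite(best_val) else float(np.mean(e_best ** 2))
    return TrainingReport(
        epochs=max(epochs, 1), mse=mse, test_mse=test_mse,
        gradient=gradient, seconds=time.perf_counter() - t0,
        stop_reason=stop_reason)


def continuous_features(table: CohortTable) -> np.ndarray:
    """Regression inputs: raw numeric values + 0/1-encoded qualitative labels."""
    labels = label_cohort(table)
    cols = []
    for j, spec in enumerate(table.schema):
        if spec.is_numeric:
            cols.append(table.records[spec.name].to_numpy(dtype=float))
        else:
            cols.append(labels.values[:, j].astype(float))
    return np.column_stack(cols)


def architecture_sweep(inputs: np.ndarray, response: np.ndarray,
                       config: TrainingConfig = TrainingConfig(),
                       architectures=SWEEP_ARCHITECTURES) -> pd.DataFrame:
    """Train every sweep architecture on the identical seeded split.

    Returns one row per architecture (epochs, best-validation MSE, test MSE,
    gradient, seconds, stop reason) with the minimum-MSE architecture flagged.
    """
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    partitions = split_indices(len(y), config)
    rows = []
    for layers, neurons in architectures:
        arch = NetArchitecture(hidden_layers=layers, neurons_per_layer=neurons)
        net = build_network(arch, X.shape[1], seed=config.seed)
        report = lm_train(net, X, y, config, partitions=partitions)
        rows.append({
            "hidden_layers": layers,
            "neurons_per_layer": neurons,
            "n_parameters": arch.n_parameters(X.shape[1]),
            "epochs": report.epochs,
            "mse": report.mse,
            "test_mse": report.test_mse,
            "gradient": report.gradient,
            "seconds": report.seconds,
            "stop_reason": report.stop_reason,
        })
    frame = pd.DataFrame(rows)
    frame["best"] = frame["mse"] == frame["mse"].min()
    return frame


def regression_accuracy(predictions, truth, tolerance: float = 5.0) -> float:
    """Share (%) of predictions within ``tolerance`` points of the truth on
    the 0–100 response scale."""
    pred = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(truth, dtype=float).ravel()
    if pred.size == 0 or pred.shape != y.shape:
        raise ValueError("prediction/truth vectors must be aligned and non-empty")
    return 100.0 * float(np.mean(np.abs(pred - y) <= tolerance))
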