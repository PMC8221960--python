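"""Training, inference and ablation for the quantized lifetime network.

`QCNNLifetimeRegressor` is a scikit-learn-style estimator: ``fit`` trains the
quantized network on histograms (rows of counts) against lifetimes in ns with
Adam on an MSE loss, using the straight-through estimator for all quantizers;
``predict`` maps histograms to lifetimes.  Histograms are normalised by their
maximum bin before entering the network, which makes inference invariant to
overall intensity.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ..core import DatasetSpec
from .network import QCNN, NetworkSpec, QuantScheme
from .quantize import FULL_PRECISION

__all__ = ["QCNNLifetimeRegressor", "TrainConfig", "train_on_spec", "ablate_quantization"]


class TrainConfig:
    """Training hyperparameters: Adam, lr 1e-4, batch 128, 100 epochs, MSE loss."""

    def __init__(self, epochs: int = 100, batch_size: int = 128, lr: float = 1e-4, seed: int = 0):
        if epochs < 1 or batch_size < 1 or lr <= 0:
            raise ValueError("epochs, batch_size and lr must be positive")
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed


def _normalize(x: np.ndarray, rule: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if rule == "max":
        scale = x.max(axis=1, keepdims=True)
    elif rule == "sum":
        scale = x.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown normalization rule {rule!r}")
    return x / np.maximum(scale, 1e-12)


class _Adam:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            p.value -= self.lr * (p.m / bias1) / (np.sqrt(p.v / bias2) + self.eps)


class QCNNLifetimeRegressor(BaseEstimator, RegressorMixin):
    """Quantized-CNN lifetime regressor (scikit-learn interface).

    Parameters
    ----------
    w_bits, a_bits : int or "full"
        Quantization bit widths for the three middle convolution blocks
        (defaults 1 and 4, the configuration found optimal for this network).
    epochs, batch_size, learning_rate : training hyperparameters
        Defaults: 100 epochs, batch 128, Adam at 1e-4.
    val_fraction : float
        Trailing fraction of ``fit`` data held out for the validation curve.
    normalization : "sum" or "max"
        Per-histogram intensity normalisation applied before the network.
        Dividing by the total count ("sum", the default) is robust at low
        photon counts, where the maximum bin is dominated by noise spikes.
    gamma_init : float
        Initial batch-norm scale.  Values below 1 start the activations
        mostly inside the quantizer's [0, 1] clamp range, which speeds up
        convergence of low-bit activation schemes.
    ood_min_counts : float
        Background-subtracted total count below which a prediction is flagged
        out-of-domain (see ``predict_with_flags``).
    seed : int
        Seeds weight initialisation and mini-batch shuffling.

    Attributes
    ----------
    model_ : the trained network
    loss_curve_, validation_loss_curve_ : per-epoch MSE (ns^2)
    best_validation_loss_ : float
    n_parameters_ : int
    """

    def __init__(
        self,
        w_bits: int | str = 1,
        a_bits: int | str = 4,
        epochs: int = 100,
        batch_size: int = 128,
        learning_rate: float = 1e-4,
        val_fraction: float = 0.2,
        normalization: str = "sum",
        gamma_init: float = 0.5,
        ood_min_counts: float = 50.0,
        tau_floor_ns: float = 0.0,
        seed: int = 0,
    ):
        self.w_bits = w_bits
        self.a_bits = a_bits
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.val_fraction = val_fraction
        self.normalization = normalization
        self.gamma_init = gamma_init
        self.ood_min_counts = ood_min_counts
        self.tau_floor_ns = tau_floor_ns
        self.seed = seed

    # -- training --------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        split_labels: np.ndarray | None = None,
    ) -> "QCNNLifetimeRegressor":
        """Train on ``(n_samples, n_bins)`` histograms and lifetimes in ns.

        ``split_labels`` ("train"/"val" per sample) overrides the default
        trailing-fraction validation split.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_samples, n_bins) matching y")
        if split_labels is not None:
            val_mask = np.asarray(split_labels) == "val"
        else:
            n_val = int(round(self.val_fraction * X.shape[0]))
            val_mask = np.zeros(X.shape[0], dtype=bool)
            if n_val:
                val_mask[-n_val:] = True

        xn = _normalize(X, self.normalization)
        x_tr, y_tr = xn[~val_mask], y[~val_mask]
        x_va, y_va = xn[val_mask], y[val_mask]

        quant = QuantScheme(w_bits=self.w_bits, a_bits=self.a_bits)
        spec = NetworkSpec(input_bins=X.shape[1])
        model = QCNN(spec=spec, quant=quant, seed=self.seed, gamma_init=self.gamma_init)
        opt = _Adam(model.params, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)

        n = x_tr.shape[0]
        bs = min(self.batch_size, n)
        train_curve, val_curve = [], []
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n - bs + 1, bs):
                idx = order[start : start + bs]
                xb, yb = x_tr[idx], y_tr[idx]
                pred = model.forward(xb, train=True)
                err = pred - yb
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (loss={loss}) at epoch {_epoch}"
                    )
                model.zero_grad()
                model.backward((2.0 / bs) * err.astype(np.float32))
                opt.step()
                losses.append(loss)
            train_curve.append(float(np.mean(losses)))
            if x_va.shape[0]:
                val_pred = self._batched_forward(model, x_va)
                val_curve.append(float(np.mean((val_pred - y_va) ** 2)))

        self.model_ = model
        self.loss_curve_ = np.asarray(train_curve)
        self.validation_loss_curve_ = np.asarray(val_curve)
        self.best_validation_loss_ = float(np.min(val_curve)) if val_curve else float("nan")
        self.n_parameters_ = model.n_parameters()
        return self

    @staticmethod
    def _batched_forward(model: QCNN, x: np.ndarray, chunk: int = 2048) -> np.ndarray:
        out = np.empty(x.shape[0], dtype=np.float32)
        for s in range(0, x.shape[0], chunk):
            out[s : s + chunk] = model.forward(x[s : s + chunk], train=False)
        return out

    # -- inference -------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Lifetimes in ns for ``(n_samples, n_bins)`` histograms."""
        if not hasattr(self, "model_"):
            raise RuntimeError("regressor is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=np.float32))
        pred = self._batched_forward(self.model_, _normalize(X, self.normalization))
        return np.maximum(pred, self.tau_floor_ns)

    def predict_with_flags(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictions plus an out-of-domain flag per histogram.

        A histogram whose background-subtracted total count (background from
        the leading 50 bins, or a tenth of the histogram if shorter) falls
        below ``ood_min_counts`` is outside the training manifold; its
        prediction is returned but flagged.
        """
        X = np.atleast_2d(np.asarray(X, dtype=np.float32))
        lead = min(50, max(1, X.shape[1] // 10))
        bg = X[:, :lead].mean(axis=1, keepdims=True)
        net = np.clip(X - bg, 0.0, None).sum(axis=1)
        return self.predict(X), net < self.ood_min_counts

    # -- persistence -----------------------------------------------------
    def save(self, path: str) -> None:
        """Write a single-file checkpoint (.npz: weights + config JSON)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("regressor is not fitted")
        config = json.dumps(
            dict(
                params=self.get_params(),
                input_bins=self.model_.spec.input_bins,
                n_parameters=self.n_parameters_,
            )
        )
        np.savez(
            path,
            __config__=np.frombuffer(config.encode(), dtype=np.uint8),
            loss_curve=self.loss_curve_,
            validation_loss_curve=self.validation_loss_curve_,
            **self.model_.state_dict(),
        )

    @classmethod
    def load(cls, path: str) -> "QCNNLifetimeRegressor":
        with np.load(path) as data:
            config = json.loads(bytes(data["__config__"]).decode())
            est = cls(**config["params"])
            spec = NetworkSpec(input_bins=config["input_bins"])
            model = QCNN(spec=spec, quant=QuantScheme(est.w_bits, est.a_bits), seed=est.seed)
            model.load_state_dict({k: data[k] for k in data.files
                                   if k.startswith(("block", "head"))})
            est.model_ = model
            est.loss_curve_ = data["loss_curve"]
            est.validation_loss_curve_ = data["validation_loss_curve"]
        est.best_validation_loss_ = float(np.min(est.validation_loss_curve_)) \
            if est.validation_loss_curve_.size else float("nan")
        est.n_parameters_ = model.n_parameters()
        return est


def train_on_spec(
    dataset_spec: DatasetSpec,
    regressor: QCNNLifetimeRegressor | None = None,
    **regressor_kwargs,
) -> QCNNLifetimeRegressor:
    """Generate the synthetic dataset for ``dataset_spec`` and train on it."""
    from ..simulate import sample_dataset

    est = regressor or QCNNLifetimeRegressor(**regressor_kwargs)
    hists, taus, labels = sample_dataset(dataset_spec)
    return est.fit(hists, taus, split_labels=labels)


def ablate_quantization(
    X: np.ndarray,
    y: np.ndarray,
    split_labels: np.ndarray | None,
    bit_grid: list[tuple[int | str, int | str]],
    seed: int = 0,
    **train_kwargs,
) -> dict[tuple[int | str, int | str], float]:
    """Best validation MSE for each (w_bits, a_bits) cell, same data and seed.

    Every cell is trained from the identical initial seed on the identical
    split, so differences isolate the effect of the quantization widths.
    """
    results: dict[tuple[int | str, int | str], float] = {}
    for w_bits, a_bits in bit_grid:
        est = QCNNLifetimeRegressor(w_bits=w_bits, a_bits=a_bits, seed=seed, **train_kwargs)
        est.fit(X, y, split_labels=split_labels)
        results[(w_bits, a_bits)] = est.best_validation_loss_
    return results
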