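"""Sex classifiers over normalized gray-matter images.

Two models are provided in a statsmodels-like shape (a model object built
from data whose ``fit()`` returns a results object):

* :class:`VoxelLogit` — voxelwise logistic regression.  The femaleness
  score is the affine form ``z = w0 + w1 x~1 + ... + wm x~m`` over the
  whole input cuboid (one weight per voxel plus a bias, m + 1 parameters),
  trained by minimizing mean cross-entropy plus an L2 penalty
  ``lambda * ||w||^2`` on the voxel weights (bias excluded, default
  ``lambda = 0.1``).

* :class:`BraiNN` — a small 3D CNN: max-pool (6x6x6 at full resolution) →
  valid 7x7x7 convolution with 32 filters → per-element PReLU → 2x2x2
  max-pool → flatten → dense 128 → per-element PReLU → dropout 0.5 →
  dense 1.  Its final layer is a logistic regression on the 128
  penultimate features.  At the full 113x137x113 grid this architecture
  has exactly 1,264,769 trainable parameters (voxelwise logistic
  regression has 1,749,354).

A brain is classified female iff the femaleness probability
``p = sigmoid(z)`` exceeds 0.5, i.e. iff ``z > 0`` strictly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod

import numpy as np

from . import nn
from .nn import bce_with_logits, sigmoid
from .training import FitRecord, fit_loop

__all__ = [
    "FemalenessResult", "BraiNNSpec", "shape_trace", "count_parameters",
    "build_brainn", "VoxelLogit", "VoxelLogitResults", "BraiNN",
    "BraiNNResults", "logreg_score", "FULL_INPUT_DIMS",
]

FULL_INPUT_DIMS = (113, 137, 113)


@dataclass(frozen=True)
class FemalenessResult:
    """Femaleness score, probability and the resulting hard label."""

    score: float
    probability: float

    @property
    def label(self) -> str:
        # strict p > 0.5 rule: a boundary score of exactly 0 is male
        return "female" if self.score > 0 else "male"


# ---------------------------------------------------------------------------
# architecture arithmetic


@dataclass(frozen=True)
class BraiNNSpec:
    """Architecture hyperparameters of the 3D CNN."""

    input_dims: tuple[int, int, int] = FULL_INPUT_DIMS
    pool1: int = 6
    conv_kernel: int = 7
    n_filters: int = 32
    pool2: int = 2
    dense_units: int = 128
    dropout_rate: float = 0.5

    @classmethod
    def full(cls) -> "BraiNNSpec":
        return cls()

    @classmethod
    def desk(cls, input_dims: tuple[int, int, int] = (32, 38, 32),
             ) -> "BraiNNSpec":
        """Down-scaled variant with pool/kernel sizes shrunk with the grid."""
        return cls(input_dims=input_dims, pool1=2, conv_kernel=3,
                   n_filters=8, pool2=2, dense_units=32)


def shape_trace(spec: BraiNNSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Per-stage output shapes (channels-first), validating every stage.

    Pooling uses floor division (no padding); convolution is valid, so an
    extent of ``d`` becomes ``d - kernel + 1`` and must stay positive.
    """
    def pool(dims, s, stage):
        out = tuple(d // s for d in dims)
        if min(out) == 0:
            raise ValueError(f"stage '{stage}' collapses to zero extent "
                             f"(input {dims}, pool {s})")
        return out

    d0 = tuple(spec.input_dims)
    trace = [("input", (1,) + d0)]
    d1 = pool(d0, spec.pool1, "pool1")
    trace.append(("pool1", (1,) + d1))
    d2 = tuple(d - spec.conv_kernel + 1 for d in d1)
    if min(d2) <= 0:
        raise ValueError(f"stage 'conv' collapses to zero extent "
                         f"(input {d1}, kernel {spec.conv_kernel})")
    trace.append(("conv", (spec.n_filters,) + d2))
    trace.append(("prelu1", (spec.n_filters,) + d2))
    d3 = pool(d2, spec.pool2, "pool2")
    trace.append(("pool2", (spec.n_filters,) + d3))
    trace.append(("flatten", (spec.n_filters * prod(d3),)))
    trace.append(("dense1", (spec.dense_units,)))
    trace.append(("prelu2", (spec.dense_units,)))
    trace.append(("output", (1,)))
    return trace


def count_parameters(obj) -> int:
    """Exact trainable-parameter count of a spec, model or results object.

    For the CNN this counts convolution kernels and biases, one PReLU slope
    per activation element (both activations), and the dense layers; for
    voxelwise logistic regression it is the voxel count plus one bias.
    """
    if isinstance(obj, BraiNNSpec):
        trace = dict(shape_trace(obj))
        k, f = obj.conv_kernel, obj.n_filters
        n_conv = f * k ** 3 + f
        n_prelu1 = prod(trace["conv"])
        flat = trace["flatten"][0]
        n_dense1 = flat * obj.dense_units + obj.dense_units
        n_prelu2 = obj.dense_units
        n_out = obj.dense_units + 1
        return n_conv + n_prelu1 + n_dense1 + n_prelu2 + n_out
    if isinstance(obj, VoxelLogit):
        return obj.n_voxels + 1
    if isinstance(obj, VoxelLogitResults):
        return obj.params.size + 1
    if isinstance(obj, (BraiNN, BraiNNResults)):
        return count_parameters(obj.spec)
    raise TypeError(f"cannot count parameters of {type(obj).__name__}")


def build_brainn(input_dims: tuple[int, int, int],
                 spec: BraiNNSpec | None = None) -> BraiNNSpec:
    """Validate the architecture at ``input_dims``, returning the spec."""
    if spec is None:
        spec = BraiNNSpec(input_dims=tuple(input_dims))
    else:
        spec = BraiNNSpec(**{**spec.__dict__, "input_dims": tuple(input_dims)})
    shape_trace(spec)  # raises on stage collapse
    return spec


# ---------------------------------------------------------------------------
# voxelwise logistic regression


class VoxelLogit:
    """Voxelwise logistic regression model for sex classification.

    Parameters
    ----------
    images : ndarray
        Normalized images, shape ``(n, nx, ny, nz)`` or pre-flattened
        ``(n, m)``.  The whole cuboid is used as input.
    labels : ndarray
        Femaleness labels (1 = female, 0 = male).
    penalty : float
        L2 regularization strength ``lambda`` on the voxel weights.
    """

    def __init__(self, images: np.ndarray, labels: np.ndarray,
                 penalty: float = 0.1):
        X = np.asarray(images)
        self.image_shape = X.shape[1:] if X.ndim > 2 else None
        self.exog = X.reshape(X.shape[0], -1)
        self.endog = np.asarray(labels, dtype=np.float64)
        if len(self.exog) != len(self.endog):
            raise ValueError("images and labels length mismatch")
        self.penalty = float(penalty)
        self.n_voxels = self.exog.shape[1]
        self._w = nn.Param("logit.w", np.zeros(self.n_voxels))
        self._w0 = nn.Param("logit.w0", np.zeros(1))

    # trainable protocol -----------------------------------------------------
    def params(self):
        return [self._w, self._w0]

    def zero_grad(self):
        self._w.grad[...] = 0.0
        self._w0.grad[...] = 0.0

    def _scores(self, X):
        return X.astype(np.float64) @ self._w.value + self._w0.value[0]

    def loss_and_grad(self, Xb, yb):
        Xb = Xb.reshape(len(Xb), -1)
        z = self._scores(Xb)
        loss, dz = bce_with_logits(z, yb)
        self._w.grad += Xb.T.astype(np.float64) @ dz
        self._w0.grad += dz.sum()
        if self.penalty:
            loss += self.penalty * float(self._w.value @ self._w.value)
            self._w.grad += 2.0 * self.penalty * self._w.value
        return loss

    def eval_loss(self, Xv, yv):
        Xv = Xv.reshape(len(Xv), -1)
        loss, _ = bce_with_logits(self._scores(Xv), yv)
        if self.penalty:
            loss += self.penalty * float(self._w.value @ self._w.value)
        return loss

    def get_state(self):
        return [self._w.value.copy(), self._w0.value.copy()]

    def set_state(self, state):
        self._w.value[...] = state[0]
        self._w0.value[...] = state[1]

    # ------------------------------------------------------------------------
    def fit(self, *, epochs: int = 30, lr: float = 1e-4, batch_size: int = 16,
            validation: tuple[np.ndarray, np.ndarray] | None = None,
            seed: int = 0) -> "VoxelLogitResults":
        rng = np.random.default_rng(seed)
        record = fit_loop(self, self.exog, self.endog, epochs=epochs, lr=lr,
                          batch_size=batch_size, validation=validation,
                          rng=rng)
        self.set_state(record.checkpoint)
        return VoxelLogitResults(model=self, params=self._w.value.copy(),
                                 bias=float(self._w0.value[0]), record=record)


@dataclass
class VoxelLogitResults:
    """Fitted voxelwise logistic regression."""

    model: VoxelLogit
    params: np.ndarray  # voxel weights
    bias: float
    record: FitRecord

    @property
    def weight_grid(self) -> np.ndarray:
        if self.model.image_shape is None:
            return self.params
        return self.params.reshape(self.model.image_shape)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Femaleness scores z for a stack of images."""
        X = np.asarray(images).reshape(len(images), -1)
        if X.shape[1] != self.params.size:
            raise ValueError("input dimension mismatch")
        return X.astype(np.float64) @ self.params + self.bias

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return sigmoid(self.predict(images))

    def summary(self) -> str:
        r = self.record
        lines = [
            "Voxelwise logistic regression",
            f"  parameters:        {self.params.size + 1:,}",
            f"  L2 penalty lambda: {self.model.penalty}",
            f"  epochs run:        {len(r.train_loss)}",
            f"  final train loss:  {r.train_loss[-1]:.4f}",
        ]
        if r.val_loss:
            lines.append(f"  best val loss:     {r.checkpoint_val_loss:.4f} "
                         f"(epoch {r.checkpoint_epoch + 1})")
        return "\n".join(lines)


def logreg_score(results, image: np.ndarray) -> FemalenessResult:
    """Score one image with a fitted linear model."""
    z = float(results.predict(image[None])[0])
    return FemalenessResult(score=z, probability=float(sigmoid(np.array(z))))


# ---------------------------------------------------------------------------
# the 3D CNN


class BraiNN:
    """Small 3D convolutional sex classifier.

    ``images`` is a stack ``(n, nx, ny, nz)``; ``spec`` defaults to the
    full-resolution architecture when the grid matches 113x137x113 and to
    the proportionally scaled desk variant otherwise.
    """

    def __init__(self, images: np.ndarray, labels: np.ndarray,
                 spec: BraiNNSpec | None = None, seed: int = 0):
        X = np.asarray(images)
        dims = tuple(X.shape[1:])
        if spec is None:
            spec = (BraiNNSpec.full() if dims == FULL_INPUT_DIMS
                    else BraiNNSpec.desk(dims))
        if tuple(spec.input_dims) != dims:
            raise ValueError(f"spec input dims {spec.input_dims} != data {dims}")
        shape_trace(spec)
        self.spec = spec
        self.exog = X
        self.endog = np.asarray(labels, dtype=np.float64)
        rng = np.random.default_rng(seed)
        trace = dict(shape_trace(spec))
        self.net = nn.Sequential([
            nn.MaxPool3D(spec.pool1),
            nn.Conv3D(1, spec.n_filters, spec.conv_kernel, rng),
            nn.PReLU(trace["conv"]),
            nn.MaxPool3D(spec.pool2),
            nn.Flatten(),
            nn.Dense(trace["flatten"][0], spec.dense_units, rng),
            nn.PReLU((spec.dense_units,)),
            nn.Dropout(spec.dropout_rate, rng),
            nn.Dense(spec.dense_units, 1, rng),
        ])

    # trainable protocol -----------------------------------------------------
    def params(self):
        return self.net.params()

    def zero_grad(self):
        self.net.zero_grad()

    def _forward(self, X, training):
        return self.net.forward(X[:, None].astype(np.float64),
                                training=training)[:, 0]

    def loss_and_grad(self, Xb, yb):
        z = self._forward(Xb, training=True)
        loss, dz = bce_with_logits(z, yb)
        self.net.backward(dz[:, None])
        return loss

    def eval_loss(self, Xv, yv, batch_size: int = 64):
        losses, weights = [], []
        for s in range(0, len(Xv), batch_size):
            z = self._forward(Xv[s:s + batch_size], training=False)
            loss, _ = bce_with_logits(z, yv[s:s + batch_size])
            losses.append(loss)
            weights.append(len(z))
        return float(np.average(losses, weights=weights))

    def get_state(self):
        return self.net.get_state()

    def set_state(self, state):
        self.net.set_state(state)

    # ------------------------------------------------------------------------
    def fit(self, *, epochs: int = 100, lr: float = 1e-4, batch_size: int = 16,
            validation: tuple[np.ndarray, np.ndarray] | None = None,
            seed: int = 0) -> "BraiNNResults":
        rng = np.random.default_rng(seed)
        record = fit_loop(self, self.exog, self.endog, epochs=epochs, lr=lr,
                          batch_size=batch_size, validation=validation,
                          rng=rng)
        self.set_state(record.checkpoint)
        return BraiNNResults(model=self, spec=self.spec, record=record)


@dataclass
class BraiNNResults:
    """Fitted 3D CNN classifier."""

    model: BraiNN
    spec: BraiNNSpec
    record: FitRecord

    def predict(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Femaleness scores z (dropout inactive; deterministic)."""
        X = np.asarray(images)
        if tuple(X.shape[1:]) != tuple(self.spec.input_dims):
            raise ValueError("input dimension mismatch")
        out = [self.model._forward(X[s:s + batch_size], training=False)
               for s in range(0, len(X), batch_size)]
        return np.concatenate(out)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return sigmoid(self.predict(images))

    def features(self, images: np.ndarray) -> np.ndarray:
        """Penultimate-layer features (the inputs of the final dense layer)."""
        X = np.asarray(images)[:, None].astype(np.float64)
        for layer in self.model.net.layers[:-2]:  # up to and incl. prelu2
            X = layer.forward(X, training=False)
        return X

    @property
    def final_layer(self) -> tuple[np.ndarray, float]:
        """Weights and bias of the output layer: a logistic regression on
        the penultimate features."""
        dense = self.model.net.layers[-1]
        return dense.w.value[:, 0].copy(), float(dense.b.value[0])

    def summary(self) -> str:
        r = self.record
        lines = [
            "BraiNN 3D convolutional classifier",
            f"  input dims:       {self.spec.input_dims}",
            f"  parameters:       {count_parameters(self.spec):,}",
            f"  epochs run:       {len(r.train_loss)}",
            f"  final train loss: {r.train_loss[-1]:.4f}",
        ]
        if r.val_loss:
            lines.append(f"  best val loss:    {r.checkpoint_val_loss:.4f} "
                         f"(epoch {r.checkpoint_epoch + 1})")
        return "\n".join(lines)
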