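"""Cost-sensitive reconstruction loss, norm penalty, and Adam training.

Known associations (positives) are vastly outnumbered by unknown pairs, so
the squared reconstruction error is split by a positive/negative mask pair
and weighted by the balance parameter alpha = P/(P+N).  Test-fold pairs are
excluded from both masks and therefore contribute nothing to the loss.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .datasets import Config
from .model import ModelParams, forward_scores, init_params
from .networks import ViewGraphs

__all__ = [
    "MaskPair",
    "TrainResult",
    "balance_alpha",
    "reconstruction_loss",
    "regularization_loss",
    "total_loss",
    "train_model",
]


@dataclasses.dataclass(frozen=True)
class MaskPair:
    """Disjoint binary masks of training positives and training negatives
    over the nl x nd pair grid; pairs in neither mask are held out."""

    omega_P: np.ndarray
    omega_N: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.omega_P)
        N = np.asarray(self.omega_N)
        if P.shape != N.shape:
            raise ValueError("mask shapes differ")
        if ((P != 0) & (N != 0)).any():
            raise ValueError("positive and negative masks overlap")


def balance_alpha(masks: MaskPair) -> float:
    """alpha = sum(omega_P) / (sum(omega_P) + sum(omega_N)), in (0, 1)."""
    p = float(np.sum(masks.omega_P))
    n = float(np.sum(masks.omega_N))
    if p == 0 or n == 0:
        raise ValueError("both masks must be nonempty")
    return p / (p + n)


def _rec_loss_t(scores: Tensor, LD: np.ndarray, masks: MaskPair,
                alpha: float) -> Tensor:
    diff = scores + ad.constant(-LD)
    pos = ad.masked_sum_squares(diff, np.asarray(masks.omega_P, dtype=float))
    neg = ad.masked_sum_squares(diff, np.asarray(masks.omega_N, dtype=float))
    return alpha * pos + (1.0 - alpha) * neg


def reconstruction_loss(LD_prime: np.ndarray, LD: np.ndarray,
                        masks: MaskPair, alpha: float) -> float:
    """alpha*||omega_P (LD' - LD)||_F^2 + (1-alpha)*||omega_N (LD' - LD)||_F^2."""
    return float(_rec_loss_t(ad.constant(LD_prime), np.asarray(LD, dtype=float),
                             masks, alpha).value)


def _reg_loss_t(params: ModelParams) -> Tensor:
    terms = [ad.sum_squares(p) for p in params.regularized()]
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out


def regularization_loss(params: ModelParams) -> float:
    """Sum of squared Frobenius norms of the convolution weights, attention
    weights, offsets and the decoder map Wd."""
    return float(_reg_loss_t(params).value)


def total_loss(rec: float, reg: float, gamma_reg: float) -> float:
    return rec + gamma_reg * reg


@dataclasses.dataclass
class TrainResult:
    params: ModelParams
    scores: np.ndarray      # nl x nd association scores, unsquashed
    loss_trace: np.ndarray  # total loss per epoch (before that epoch's step)
    alpha: float


class _Adam:
    def __init__(self, params: list[Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def build_loss(views: ViewGraphs, LD: np.ndarray, masks: MaskPair,
               params: ModelParams, alpha: float, gamma_reg: float):
    """One forward pass; returns (total-loss tensor, score tensor)."""
    scores = forward_scores(views, params)
    loss = _rec_loss_t(scores, LD, masks, alpha)
    if gamma_reg > 0:
        loss = loss + gamma_reg * _reg_loss_t(params)
    return loss, scores


def train_model(views: ViewGraphs, LD: np.ndarray, masks: MaskPair,
                config: Config, rng: np.random.Generator | None = None,
                params: ModelParams | None = None) -> TrainResult:
    """Full-batch Adam minimization of the cost-sensitive total loss.

    The whole graph is one training sample, so every epoch is one gradient
    step.  Deterministic given the seed: the only randomness is the Glorot
    initialization.
    """
    LD = np.asarray(LD, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if params is None:
        in1 = views.X1.shape[1] if config.view in ("both", "net1") else None
        in2 = views.F1.shape[1] if config.view in ("both", "net2") else None
        params = init_params(config, in1, in2, rng)
    alpha = balance_alpha(masks)
    if config.alpha_mode == "complement":
        alpha = 1.0 - alpha
    opt = _Adam(params.trainable(), lr=config.learning_rate)
    trace = np.empty(config.epochs)
    for epoch in range(config.epochs):
        opt.zero_grad()
        loss, _ = build_loss(views, LD, masks, params, alpha, config.gamma_reg)
        value = float(loss.value)
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        trace[epoch] = value
        loss.backward()
        opt.step()
    final_scores = forward_scores(views, params).value
    return TrainResult(params=params, scores=final_scores, loss_trace=trace,
                       alpha=alpha)
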