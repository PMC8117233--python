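"""Batch sampling and RMSprop training of the two-stream recurrent model."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ..errors import ConfigError
from ..observer import TrackingRecord
from ..trajectory import Contrast, Pursuit
from .layers import DTYPE
from .model import SHAPE_CLASSES, RnnConfig, TwoStreamRnn

log = logging.getLogger(__name__)

_CLASS_INDEX = {kind: i for i, kind in enumerate(SHAPE_CLASSES)}


@dataclass
class TrainingBatch:
    """Downsampled training windows with labels and condition flags."""

    X: np.ndarray    # (Bs, T, 4): p_x, p_y, s_x, s_y
    C: np.ndarray    # (Bs, 2): contrast (low=0/high=1), pursuit (smooth=0/saccadic=1)
    y_s: np.ndarray  # (Bs, T) per-step obstruction labels
    y_d: np.ndarray  # (Bs,) shape-class indices


def categorical_flags(record: TrackingRecord) -> Tuple[float, float]:
    contrast = 1.0 if record.config.contrast is Contrast.HIGH else 0.0
    pursuit = 1.0 if record.config.pursuit is Pursuit.SACCADIC else 0.0
    return contrast, pursuit


def extract_window(
    record: TrackingRecord, start: int, cfg: RnnConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """One subsequence: (T, 4) features and (T,) labels, decimated to the
    training rate (every cfg.decimation-th sample of a len_in window)."""
    idx = start + cfg.decimation * np.arange(cfg.subsequence_len_train)
    x = np.stack([record.p_x[idx], record.p_y[idx],
                  record.s_x[idx], record.s_y[idx]], axis=-1).astype(DTYPE)
    y = np.asarray(record.occluded)[idx].astype(int)
    return x, y


def sample_batch(
    records: Sequence[TrackingRecord],
    cfg: RnnConfig,
    rng: np.random.Generator,
) -> TrainingBatch:
    """Bs trials with replacement, one uniformly-placed window from each."""
    usable = [r for r in records if len(r) >= cfg.subsequence_len_in]
    n_short = len(records) - len(usable)
    if n_short:
        log.debug("skipped %d trials shorter than %d samples", n_short,
                  cfg.subsequence_len_in)
    if not usable:
        raise ConfigError(
            f"no trial has >= {cfg.subsequence_len_in} samples")
    Bs, T = cfg.batch_size, cfg.subsequence_len_train
    X = np.empty((Bs, T, 4), dtype=DTYPE)
    C = np.empty((Bs, 2), dtype=DTYPE)
    y_s = np.empty((Bs, T), dtype=int)
    y_d = np.empty(Bs, dtype=int)
    choice = rng.integers(len(usable), size=Bs)
    for i, j in enumerate(choice):
        r = usable[j]
        start = int(rng.integers(len(r) - cfg.subsequence_len_in + 1))
        X[i], y_s[i] = extract_window(r, start, cfg)
        C[i] = categorical_flags(r)
        y_d[i] = _CLASS_INDEX[r.scotoma.kind]
    return TrainingBatch(X=X, C=C, y_s=y_s, y_d=y_d)


class RMSprop:
    """Adaptive-gradient update: cache = rho*cache + (1-rho)*g^2."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float, rho: float = 0.9,
                 eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        for k, p in params.items():
            g = grads[k]
            c = self.cache[k]
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= (self.lr * g / (np.sqrt(c) + self.eps)).astype(p.dtype)


def clip_gradients(grads: Dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most max_norm."""
    total = float(np.sqrt(sum(float((g * g).sum()) for g in grads.values())))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total


@dataclass
class TrainingResult:
    model: TwoStreamRnn
    loss_history: List[float] = field(default_factory=list)


def train(
    records: Sequence[TrackingRecord],
    cfg: RnnConfig = RnnConfig(),
    log_every: int = 200,
) -> TrainingResult:
    """Mini-batch RMSprop on the weighted dual-head cross-entropy.

    Requires the cohort to contain all four shape classes; aborts with a
    diagnostic if the loss becomes non-finite.
    """
    present = {r.scotoma.kind for r in records}
    missing = set(SHAPE_CLASSES) - present
    if missing:
        raise ConfigError(
            f"training cohort lacks conditions: {sorted(m.value for m in missing)}")
    rng = np.random.default_rng(cfg.rng_seed)
    model = TwoStreamRnn(cfg)
    opt = RMSprop(model.params, lr=cfg.learning_rate, rho=cfg.rmsprop_rho)
    history: List[float] = []
    for it in range(cfg.iterations):
        batch = sample_batch(records, cfg, rng)
        model.zero_grads()
        J = model.loss_and_grads(batch.X, batch.C, batch.y_s, batch.y_d)
        if not np.isfinite(J):
            raise RuntimeError(
                f"training diverged at iteration {it}: loss={J!r}; "
                f"last finite losses: {history[-5:]}")
        clip_gradients(model.grads, cfg.grad_clip)
        opt.step(model.params, model.grads)
        history.append(J)
        if log_every and (it + 1) % log_every == 0:
            log.info("iteration %d/%d loss %.4f", it + 1, cfg.iterations, J)
    return TrainingResult(model=model, loss_history=history)
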