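"""Two-stream recurrent model: sequential gaze/stimulus stream (3 stacked
bidirectional GRU layers) plus a categorical stream (dense over the two
binary condition flags), feeding a per-step scotoma softmax and a pooled
4-class defect-shape softmax.

Loss: J = alpha * CE(point-wise head) + beta * CE(shape head), with the
point-wise cross-entropy averaged over steps and batch and the shape
cross-entropy averaged over batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from ..errors import ConfigError
from ..scotoma import ScotomaKind
from .layers import (
    DTYPE,
    BiGRU,
    Dense,
    collect_grads,
    collect_params,
    softmax,
    zero_grads,
)

#: shape-class ordering used for labels, predictions and ties
SHAPE_CLASSES: Tuple[ScotomaKind, ...] = (
    ScotomaKind.NONE,
    ScotomaKind.CENTRAL,
    ScotomaKind.PERIPHERAL,
    ScotomaKind.HEMIFIELD,
)

N_SHAPE_CLASSES = len(SHAPE_CLASSES)
N_POINT_CLASSES = 2  # unobstructed / obstructed
N_SEQ_FEATURES = 4   # p_x, p_y, s_x, s_y
N_CAT_FEATURES = 2   # contrast, pursuit

LOG_EPS = 1e-12


@dataclass(frozen=True)
class RnnConfig:
    """Architecture and training hyperparameters."""

    gru_layers: int = 3
    hidden_units: int = 32            # per direction
    categorical_dense_units: int = 16
    alpha: float = 0.75               # point-wise loss weight
    beta: float = 0.25                # shape loss weight
    batch_size: int = 128
    iterations: int = 2000            # desk-scale default; full-scale profile 15000
    subsequence_len_in: int = 1000    # samples at the native 240 Hz
    subsequence_len_train: int = 250  # steps after downsampling to 60 Hz
    learning_rate: float = 1e-3
    rmsprop_rho: float = 0.9
    grad_clip: float = 5.0
    input_scale: float = 10.0         # degrees; positions divided by this
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ConfigError(f"alpha + beta must equal 1, got {self.alpha + self.beta}")
        if self.subsequence_len_in % self.subsequence_len_train != 0:
            raise ConfigError("subsequence_len_in must be a multiple of subsequence_len_train")
        if self.gru_layers < 1 or self.hidden_units < 1 or self.batch_size < 1:
            raise ConfigError("gru_layers, hidden_units, batch_size must be >= 1")

    @property
    def decimation(self) -> int:
        return self.subsequence_len_in // self.subsequence_len_train


class TwoStreamRnn:
    """Dual-head recurrent classifier over downsampled tracking windows."""

    def __init__(self, cfg: RnnConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        H, Dc = cfg.hidden_units, cfg.categorical_dense_units
        self.grus = []
        n_in = N_SEQ_FEATURES
        for _ in range(cfg.gru_layers):
            self.grus.append(BiGRU(n_in, H, rng))
            n_in = 2 * H
        self.cat_dense = Dense(N_CAT_FEATURES, Dc, rng)
        self.pw_head = Dense(2 * H + Dc, N_POINT_CLASSES, rng)
        self.shape_head = Dense(2 * H + Dc, N_SHAPE_CLASSES, rng)
        self._cache: Dict[str, np.ndarray] = {}

    def _named_modules(self):
        mods = [(f"gru{i}", g) for i, g in enumerate(self.grus)]
        return mods + [("cat_dense", self.cat_dense),
                       ("pw_head", self.pw_head),
                       ("shape_head", self.shape_head)]

    @property
    def params(self) -> Dict[str, np.ndarray]:
        return collect_params(self._named_modules())

    @property
    def grads(self) -> Dict[str, np.ndarray]:
        return collect_grads(self._named_modules())

    def zero_grads(self) -> None:
        zero_grads(self._named_modules())

    # forward -------------------------------------------------------------

    def forward(self, X: np.ndarray, C: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Logits of both heads for X (B, T, 4) and C (B, 2)."""
        X = np.asarray(X, dtype=DTYPE)
        C = np.asarray(C, dtype=DTYPE)
        if X.ndim != 3 or X.shape[-1] != N_SEQ_FEATURES:
            raise ConfigError(f"X must be (B, T, {N_SEQ_FEATURES}), got {X.shape}")
        if C.ndim != 2 or C.shape[-1] != N_CAT_FEATURES:
            raise ConfigError(f"C must be (B, {N_CAT_FEATURES}), got {C.shape}")
        B, T, _ = X.shape
        seq = X / DTYPE(self.cfg.input_scale)
        for gru in self.grus:
            seq = gru.forward(seq)                     # (B, T, 2H)
        cat_pre = self.cat_dense.forward(C)
        catf = np.maximum(cat_pre, 0.0)                # (B, Dc)
        pw_in = np.concatenate(
            [seq, np.broadcast_to(catf[:, None, :], (B, T, catf.shape[-1]))], axis=-1)
        pw_logits = self.pw_head.forward(pw_in)        # (B, T, 2)
        pooled = seq.mean(axis=1)                      # (B, 2H)
        shape_in = np.concatenate([pooled, catf], axis=-1)
        shape_logits = self.shape_head.forward(shape_in)  # (B, 4)
        self._cache = {"B": B, "T": T, "cat_pre": cat_pre, "nh": seq.shape[-1]}
        return pw_logits, shape_logits

    def predict_proba(self, X: np.ndarray, C: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        pw_logits, shape_logits = self.forward(X, C)
        return softmax(pw_logits), softmax(shape_logits)

    # loss / backward -----------------------------------------------------

    def loss(self, pw_probs: np.ndarray, shape_probs: np.ndarray,
             y_s: np.ndarray, y_d: np.ndarray) -> float:
        """Weighted cross-entropy of both heads (probabilities in, scalar out)."""
        B, T, _ = pw_probs.shape
        p_true_s = np.take_along_axis(pw_probs, y_s[..., None], axis=-1)[..., 0]
        p_true_d = shape_probs[np.arange(B), y_d]
        ce_s = -np.log(np.maximum(p_true_s, LOG_EPS)).mean()
        ce_d = -np.log(np.maximum(p_true_d, LOG_EPS)).mean()
        return float(self.cfg.alpha * ce_s + self.cfg.beta * ce_d)

    def loss_and_grads(self, X, C, y_s, y_d) -> float:
        """One forward/backward pass; accumulates parameter gradients."""
        y_s = np.asarray(y_s, dtype=int)
        y_d = np.asarray(y_d, dtype=int)
        pw_logits, shape_logits = self.forward(X, C)
        pw_p = softmax(pw_logits)
        sh_p = softmax(shape_logits)
        J = self.loss(pw_p, sh_p, y_s, y_d)

        B, T = self._cache["B"], self._cache["T"]
        nh = self._cache["nh"]
        dpw = pw_p.copy()
        np.put_along_axis(dpw, y_s[..., None],
                          np.take_along_axis(dpw, y_s[..., None], axis=-1) - 1.0,
                          axis=-1)
        dpw *= DTYPE(self.cfg.alpha / (B * T))
        dsh = sh_p.copy()
        dsh[np.arange(B), y_d] -= 1.0
        dsh *= DTYPE(self.cfg.beta / B)

        dpw_in = self.pw_head.backward(dpw)            # (B, T, 2H + Dc)
        dshape_in = self.shape_head.backward(dsh)      # (B, 2H + Dc)
        dseq = dpw_in[..., :nh].copy()
        dseq += dshape_in[:, None, :nh] / DTYPE(T)     # mean-pool gradient
        dcatf = dpw_in[..., nh:].sum(axis=1) + dshape_in[:, nh:]
        dcat_pre = dcatf * (self._cache["cat_pre"] > 0)
        self.cat_dense.backward(dcat_pre.astype(DTYPE))
        for gru in reversed(self.grus):
            dseq = gru.backward(dseq.astype(DTYPE))
        return J
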