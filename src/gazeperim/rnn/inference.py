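"""Inference: ensemble shape prediction, point-wise map reconstruction and
the miscalibration-robustness harness."""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from ..errors import ConfigError
from ..mapping import GridSpec, VisualFieldMap, backproject_coords
from ..observer import TrackingRecord
from ..scotoma import ScotomaKind
from .layers import DTYPE, softmax
from .model import SHAPE_CLASSES, RnnConfig, TwoStreamRnn
from .train import categorical_flags, extract_window


def ensemble_windows(
    records: Sequence[TrackingRecord],
    cfg: RnnConfig,
    rng: np.random.Generator | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """One downsampled subsequence per trial (the K windows of the ensemble
    average).  Window placement is random when an rng is given, else each
    window starts at sample 0."""
    if not records:
        raise ConfigError("no records to predict from")
    X, C = [], []
    for r in records:
        if len(r) < cfg.subsequence_len_in:
            raise ConfigError(f"trial {r.trial_id} shorter than one window")
        start = (int(rng.integers(len(r) - cfg.subsequence_len_in + 1))
                 if rng is not None else 0)
        x, _ = extract_window(r, start, cfg)
        X.append(x)
        C.append(categorical_flags(r))
    return np.stack(X), np.asarray(C, dtype=DTYPE)


def predict_shape(
    model: TwoStreamRnn,
    records: Sequence[TrackingRecord],
    rng: np.random.Generator | None = None,
) -> Tuple[ScotomaKind, np.ndarray]:
    """Average the K per-window shape distributions, argmax the mean.

    Ties resolve to the lowest class index.  Returns (kind, mean probs).
    """
    X, C = ensemble_windows(records, model.cfg, rng)
    _, shape_probs = model.predict_proba(X, C)
    mean_probs = shape_probs.mean(axis=0)
    return SHAPE_CLASSES[int(np.argmax(mean_probs))], mean_probs


def predict_pointwise_map(
    model: TwoStreamRnn,
    records: Sequence[TrackingRecord],
    grid: GridSpec = GridSpec(),
) -> VisualFieldMap:
    """Tile each trial into non-overlapping windows, classify each retained
    (60 Hz) step, and back-project the predicted flags."""
    cfg = model.cfg
    flags_all: List[np.ndarray] = []
    rx_all: List[np.ndarray] = []
    ry_all: List[np.ndarray] = []
    for r in records:
        starts = range(0, len(r) - cfg.subsequence_len_in + 1, cfg.subsequence_len_in)
        for start in starts:
            x, _ = extract_window(r, start, cfg)
            pw_probs, _ = model.predict_proba(x[None],
                                              np.asarray([categorical_flags(r)], dtype=DTYPE))
            flags = np.argmax(pw_probs[0], axis=-1).astype(np.uint8)
            idx = start + cfg.decimation * np.arange(cfg.subsequence_len_train)
            rx = np.asarray(r.s_x)[idx] - np.asarray(r.p_x)[idx]
            ry = np.asarray(r.s_y)[idx] - np.asarray(r.p_y)[idx]
            if grid.flip_sign:
                rx, ry = -rx, -ry
            flags_all.append(flags)
            rx_all.append(rx)
            ry_all.append(ry)
    if not flags_all:
        raise ConfigError("no full windows available for map reconstruction")
    return backproject_coords(np.concatenate(flags_all), np.concatenate(rx_all),
                              np.concatenate(ry_all), grid)


def _with_gaze_offset(record: TrackingRecord, dx: float, dy: float) -> TrackingRecord:
    """Copy of a record with a constant offset added to the gaze trace
    (ground-truth flags untouched: the distortion is a measurement error)."""
    return TrackingRecord(
        config=record.config, scotoma=record.scotoma,
        s_x=record.s_x, s_y=record.s_y,
        p_x=np.asarray(record.p_x) + dx, p_y=np.asarray(record.p_y) + dy,
        occluded=record.occluded,
        participant_id=record.participant_id, trial_id=record.trial_id,
    )


def miscalibration_robustness(
    model: TwoStreamRnn,
    test_sets: Sequence[Tuple[ScotomaKind, Sequence[TrackingRecord]]],
    magnitudes: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
    rng: np.random.Generator | None = None,
) -> Dict[float, float]:
    """Shape-classification accuracy under constant gaze offsets.

    ``test_sets`` pairs the true defect kind with that participant's records.
    Each (magnitude, test set) draws a random offset direction.  Returns
    {magnitude: accuracy}; chance level is 1/4.
    """
    rng = rng or np.random.default_rng(0)
    out: Dict[float, float] = {}
    for mag in magnitudes:
        hits = 0
        for true_kind, records in test_sets:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            dx, dy = mag * np.cos(theta), mag * np.sin(theta)
            distorted = [_with_gaze_offset(r, dx, dy) for r in records]
            pred, _ = predict_shape(model, distorted, rng)
            hits += int(pred is ScotomaKind(true_kind))
        out[float(mag)] = hits / len(test_sets)
    return out
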