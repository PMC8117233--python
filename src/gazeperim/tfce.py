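"""Threshold-free cluster enhancement of positional deviation time series.

Pipeline: deviation series D(t) (Euclidean eye-stimulus distance) ->
TFCE transform (discrete height integration of extent^E * height^H) ->
pooled normative distribution from no-loss trials -> percentile threshold ->
binarized loss/healthy flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .errors import ConfigError, ContaminationError, MalformedRecordError
from .observer import TrackingRecord
from .scotoma import ScotomaKind


@dataclass(frozen=True)
class TfceParams:
    """Exponents and discretization of the TFCE height integral."""

    E: float = 2.0
    H: float = 0.5
    n_steps: int = 2500            # dh = (max - min) / n_steps
    extent_unit: str = "seconds"   # or "samples"

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ConfigError("E and H must be >= 0")
        if self.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        if self.extent_unit not in ("seconds", "samples"):
            raise ConfigError(f"unknown extent_unit {self.extent_unit!r}")


@dataclass
class DeviationSeries:
    """Nonnegative eye-stimulus distances, one value per sample."""

    values: np.ndarray
    dt: float
    provenance: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TfceSeries:
    """TFCE-transformed deviations plus the parameters that produced them."""

    values: np.ndarray
    params: TfceParams
    h0: float
    h_max: float
    dt: float
    provenance: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class NormativeDistribution:
    """Pooled TFCE values from defect-free trials (empirical distribution)."""

    values: np.ndarray
    source_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ConfigError("normative distribution must be nonempty")
        if np.any(self.values < 0):
            raise ConfigError("TFCE values must be nonnegative")

    def percentile(self, lambda_n: float) -> float:
        return float(np.percentile(self.values, lambda_n))


@dataclass
class BinarySeries:
    """Loss/healthy flags from thresholding a TFCE series at F(lambda_n)."""

    flags: np.ndarray
    lambda_n: float
    threshold_value: float

    def __len__(self) -> int:
        return len(self.flags)


def deviation_series(record: TrackingRecord) -> DeviationSeries:
    """D(t) = sqrt((p_x - s_x)^2 + (p_y - s_y)^2), per sample."""
    if not (len(record.p_x) == len(record.s_x) == len(record.p_y) == len(record.s_y)):
        raise MalformedRecordError("gaze/stimulus length mismatch")
    d = np.hypot(np.asarray(record.p_x) - np.asarray(record.s_x),
                 np.asarray(record.p_y) - np.asarray(record.s_y))
    return DeviationSeries(
        values=d,
        dt=record.config.dt,
        provenance={
            "participant_id": record.participant_id,
            "trial_id": record.trial_id,
            "condition": record.scotoma.kind.value,
        },
    )


def tfce_transform(D: DeviationSeries, params: TfceParams = TfceParams()) -> TfceSeries:
    """Discrete TFCE: for each sample t, sum e_t(h)^E * h^H * dh over heights
    h in (h0, max(D)] with h <= D(t), where e_t(h) is the duration of the
    maximal contiguous run containing t with D >= h.

    A constant series yields all zeros (degenerate, zero-width integral).
    """
    v = np.asarray(D.values, dtype=float)
    if v.size == 0:
        raise MalformedRecordError("empty deviation series")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise MalformedRecordError("deviations must be finite and nonnegative")
    h0 = float(v.min())
    h_max = float(v.max())
    out = np.zeros_like(v)
    if h_max > h0:
        dh = (h_max - h0) / params.n_steps
        unit = D.dt if params.extent_unit == "seconds" else 1.0
        E, H = params.E, params.H
        for k in range(1, params.n_steps + 1):
            h = h0 + k * dh
            mask = v >= h
            # run-length encode the supra-threshold mask
            edges = np.flatnonzero(np.diff(np.concatenate(
                ([0], mask.view(np.int8), [0]))))
            starts, ends = edges[0::2], edges[1::2]
            lengths = ends - starts
            contrib = ((lengths * unit) ** E) * (h ** H) * dh
            out[mask] += np.repeat(contrib, lengths)
    return TfceSeries(values=out, params=params, h0=h0, h_max=h_max,
                      dt=D.dt, provenance=dict(D.provenance))


def build_normative_distribution(
    no_loss_series: Iterable[TfceSeries],
) -> NormativeDistribution:
    """Pool TFCE values of defect-free trials into one empirical distribution.

    Raises ContaminationError if any series' provenance carries a scotoma
    condition other than "none".
    """
    pooled: List[np.ndarray] = []
    sources: List[str] = []
    for s in no_loss_series:
        cond = s.provenance.get("condition", ScotomaKind.NONE.value)
        if cond != ScotomaKind.NONE.value:
            raise ContaminationError(
                f"trial {s.provenance.get('trial_id', '?')} has condition {cond!r}, "
                "normative pool must contain only no-loss trials"
            )
        pooled.append(np.asarray(s.values, dtype=float))
        pid = s.provenance.get("participant_id")
        if pid and pid not in sources:
            sources.append(pid)
    if not pooled:
        raise ConfigError("no trials supplied for the normative distribution")
    return NormativeDistribution(values=np.concatenate(pooled), source_ids=sources)


def binarize(
    series: TfceSeries | np.ndarray,
    F: NormativeDistribution,
    lambda_n: float,
) -> BinarySeries:
    """Flag "visual loss" where the TFCE value strictly exceeds F(lambda_n)."""
    if not (1.0 <= lambda_n <= 100.0):
        raise ConfigError(f"lambda_n must be in [1, 100], got {lambda_n}")
    values = series.values if isinstance(series, TfceSeries) else np.asarray(series)
    threshold = F.percentile(lambda_n)
    flags = (values > threshold).astype(np.uint8)
    return BinarySeries(flags=flags, lambda_n=float(lambda_n),
                        threshold_value=threshold)
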