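"""Gaze-contingent visual field defect geometry.

Occlusion is decided in retinotopic coordinates r = stimulus - gaze: the
defect is centered on the current point of gaze, so only the relative
position matters.  Kinds: central disk, peripheral (everything outside a
central hole), right hemifield, or none.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import MalformedRecordError, SpecificationError


class ScotomaKind(str, Enum):
    NONE = "none"
    CENTRAL = "central"
    PERIPHERAL = "peripheral"
    HEMIFIELD = "hemifield"


@dataclass(frozen=True)
class ScotomaSpec:
    """Defect kind plus its size (diameter of the disk/hole, degrees)."""

    kind: ScotomaKind = ScotomaKind.NONE
    size_deg: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ScotomaKind(self.kind))
        if self.kind in (ScotomaKind.CENTRAL, ScotomaKind.PERIPHERAL) and self.size_deg <= 0:
            raise SpecificationError(f"size_deg must be positive, got {self.size_deg}")


def is_occluded(s_x, s_y, p_x, p_y, spec: ScotomaSpec):
    """Whether the stimulus at (s_x, s_y) is hidden given gaze at (p_x, p_y).

    Accepts scalars or equal-shaped arrays; returns booleans of the same
    shape.  Central occludes the closed disk ||r|| <= size/2; peripheral its
    open complement; hemifield occludes strictly r_x > 0.
    """
    r_x = np.asarray(s_x, dtype=float) - np.asarray(p_x, dtype=float)
    r_y = np.asarray(s_y, dtype=float) - np.asarray(p_y, dtype=float)
    if not (np.all(np.isfinite(r_x)) and np.all(np.isfinite(r_y))):
        raise MalformedRecordError("non-finite coordinates in occlusion test")
    kind = spec.kind
    if kind is ScotomaKind.NONE:
        return np.zeros(np.shape(r_x), dtype=bool) if r_x.ndim else np.bool_(False)
    if kind is ScotomaKind.CENTRAL:
        return np.hypot(r_x, r_y) <= spec.size_deg / 2.0
    if kind is ScotomaKind.PERIPHERAL:
        return np.hypot(r_x, r_y) > spec.size_deg / 2.0
    if kind is ScotomaKind.HEMIFIELD:
        return r_x > 0.0
    raise SpecificationError(f"unknown scotoma kind: {kind!r}")


def ground_truth_labels(record) -> np.ndarray:
    """Per-sample a-priori occlusion flags for a tracking record (uint8)."""
    s_x, s_y = np.asarray(record.s_x), np.asarray(record.s_y)
    p_x, p_y = np.asarray(record.p_x), np.asarray(record.p_y)
    if not (len(s_x) == len(s_y) == len(p_x) == len(p_y)):
        raise MalformedRecordError(
            f"sequence length mismatch: s=({len(s_x)},{len(s_y)}) p=({len(p_x)},{len(p_y)})"
        )
    return np.asarray(is_occluded(s_x, s_y, p_x, p_y, record.scotoma), dtype=np.uint8)
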