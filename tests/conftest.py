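"""Shared fixtures: small synthetic records and cohorts, generated on the fly."""

from __future__ import annotations

import numpy as np
import pytest

from gazeperim.observer import (
    ObserverParams,
    ProtocolConfig,
    TrackingRecord,
    simulate_cohort,
    simulate_gaze,
)
from gazeperim.scotoma import ScotomaKind, ScotomaSpec, ground_truth_labels
from gazeperim.trajectory import TrialConfig, generate_trajectory


def make_record(
    s_x, s_y, p_x, p_y,
    kind: ScotomaKind = ScotomaKind.NONE,
    sample_rate: float = 240.0,
    participant_id: str = "P00",
    trial_id: str = "T00",
) -> TrackingRecord:
    """Build a consistent record from raw traces (flags recomputed)."""
    s_x, s_y = np.asarray(s_x, float), np.asarray(s_y, float)
    p_x, p_y = np.asarray(p_x, float), np.asarray(p_y, float)
    cfg = TrialConfig(duration=len(s_x) / sample_rate, sample_rate=sample_rate)
    spec = ScotomaSpec(kind=kind)
    rec = TrackingRecord(
        config=cfg, scotoma=spec, s_x=s_x, s_y=s_y, p_x=p_x, p_y=p_y,
        occluded=np.zeros(len(s_x), dtype=np.uint8),
        participant_id=participant_id, trial_id=trial_id,
    )
    rec.occluded = ground_truth_labels(rec)
    return rec


@pytest.fixture(scope="session")
def short_trial():
    """One 5-s no-loss trial with default observer parameters."""
    cfg = TrialConfig(duration=5.0, rng_seed=11)
    traj = generate_trajectory(cfg)
    return simulate_gaze(traj, ScotomaSpec(), ObserverParams(rng_seed=12), cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    """5 participants x 4 conditions x 4 short trials: fast CV material."""
    protocol = ProtocolConfig(repetitions=1, duration=8.0)
    return simulate_cohort(5, protocol=protocol, seed=202)
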