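"""Synthetic observer: gaze traces of a simulated tracker under a scotoma.

The observer is a minimal closed-loop controller running at the display rate:

* while the (perception-delayed) stimulus is visible, gaze velocity follows
  the delayed stimulus velocity scaled by a pursuit gain, plus Brownian motor
  noise; a corrective saccade (jump to the delayed target position plus
  landing noise) fires once the perceived positional error has exceeded a
  trigger threshold for at least the saccade latency;
* while the stimulus falls inside the gaze-contingent defect there is no
  visual feedback: gaze extrapolates the last velocity (or freezes), and
  after a sustained loss of the target an exploratory search saccade jumps
  to the extrapolated target position plus isotropic scatter.

This replaces the human participants of the original protocol; its only
required property downstream is that occlusion inflates the magnitude and
duration of positional deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ConfigError, MalformedRecordError
from .scotoma import ScotomaKind, ScotomaSpec, ground_truth_labels
from .trajectory import (
    Contrast,
    Pursuit,
    StimulusTrajectory,
    TrialConfig,
    WalkParams,
    generate_trajectory,
)


@dataclass(frozen=True)
class ObserverParams:
    """Tracking-behavior parameters of one simulated observer."""

    pursuit_gain: float = 0.95
    position_gain: float = 3.0            # 1/s, catch-up correction of position error
    reaction_latency_high: float = 0.12   # s, high-contrast stimulus
    reaction_latency_low: float = 0.18    # s, low-contrast stimulus
    position_noise_sd: float = 0.3        # deg per sqrt(s), Brownian motor noise
    low_contrast_noise_factor: float = 1.5
    saccade_trigger_error: float = 2.0    # deg
    saccade_latency: float = 0.08         # s error must persist before a saccade
    saccade_landing_noise_sd: float = 0.7  # deg
    saccade_undershoot: float = 0.1       # fraction of the error left uncorrected
    occluded_behavior: str = "extrapolate"  # or "freeze"
    search_interval: float = 0.4          # s of continuous occlusion before a search saccade
    search_scatter_sd: float = 2.0        # deg, isotropic scatter of search landings
    compensation_magnitude: float = 3.0   # deg, gaze bias away from a consistent loss zone
    compensation_rate: float = 0.1        # EMA rate of the loss-direction estimate
    sweep_step: float = 5.0               # deg, step size of the systematic search sweep
    lapse_rate: float = 0.15              # 1/s, Poisson rate of blinks/attention lapses
    lapse_duration: Tuple[float, float] = (0.2, 0.6)  # s, uniform lapse length
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pursuit_gain <= 1.5):
            raise ConfigError(f"pursuit_gain must be in (0, 1.5], got {self.pursuit_gain}")
        if min(self.reaction_latency_high, self.reaction_latency_low,
               self.saccade_latency) < 0:
            raise ConfigError("latencies must be >= 0")
        if min(self.position_noise_sd, self.saccade_landing_noise_sd) < 0:
            raise ConfigError("noise SDs must be >= 0")
        if not (0.0 <= self.saccade_undershoot < 1.0):
            raise ConfigError("saccade_undershoot must be in [0, 1)")
        if self.occluded_behavior not in ("extrapolate", "freeze"):
            raise ConfigError(f"unknown occluded_behavior {self.occluded_behavior!r}")

    def latency_for(self, contrast: Contrast) -> float:
        return (self.reaction_latency_high if Contrast(contrast) is Contrast.HIGH
                else self.reaction_latency_low)

    def noise_for(self, contrast: Contrast) -> float:
        f = 1.0 if Contrast(contrast) is Contrast.HIGH else self.low_contrast_noise_factor
        return self.position_noise_sd * f


@dataclass
class TrackingRecord:
    """One simulated trial: stimulus path, gaze trace, metadata, GT flags."""

    config: TrialConfig
    scotoma: ScotomaSpec
    s_x: np.ndarray
    s_y: np.ndarray
    p_x: np.ndarray
    p_y: np.ndarray
    occluded: np.ndarray
    participant_id: str = "P00"
    trial_id: str = "T00"

    def __post_init__(self) -> None:
        n = len(self.s_x)
        for name in ("s_y", "p_x", "p_y", "occluded"):
            if len(getattr(self, name)) != n:
                raise MalformedRecordError(
                    f"{name} has length {len(getattr(self, name))}, expected {n}"
                )
        for name in ("s_x", "s_y", "p_x", "p_y"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise MalformedRecordError(f"non-finite values in {name}")

    def __len__(self) -> int:
        return len(self.s_x)


def simulate_gaze(
    traj: StimulusTrajectory,
    spec: ScotomaSpec,
    obs: ObserverParams,
    cfg: TrialConfig,
    participant_id: str = "P00",
    trial_id: str = "T00",
) -> TrackingRecord:
    """Run the closed-loop observer over one stimulus trajectory."""
    n, dt = cfg.n_samples, cfg.dt
    if len(traj) != n:
        raise MalformedRecordError(f"trajectory length {len(traj)} != config samples {n}")
    rng = np.random.default_rng(obs.rng_seed)

    sx, sy = traj.s_x, traj.s_y
    latency = obs.latency_for(cfg.contrast)
    delay = int(round(latency * cfg.sample_rate))
    motor_sd = obs.noise_for(cfg.contrast) * math.sqrt(dt)
    motor = rng.normal(0.0, motor_sd, size=(n, 2)) if motor_sd > 0 else np.zeros((n, 2))
    land = rng.normal(0.0, obs.saccade_landing_noise_sd, size=(n, 2)) \
        if obs.saccade_landing_noise_sd > 0 else np.zeros((n, 2))
    search = rng.normal(0.0, obs.search_scatter_sd, size=(n, 2)) \
        if obs.search_scatter_sd > 0 else np.zeros((n, 2))
    scan = rng.uniform([-cfg.field_halfwidth_x, -cfg.field_halfwidth_y],
                       [cfg.field_halfwidth_x, cfg.field_halfwidth_y], size=(n, 2))
    # blinks / attention lapses: no visual feedback, gaze extrapolates
    lapse = np.zeros(n, dtype=bool)
    if obs.lapse_rate > 0:
        t_lapse = rng.exponential(1.0 / obs.lapse_rate)
        while t_lapse < cfg.duration:
            a = int(t_lapse * cfg.sample_rate)
            b = a + max(1, int(rng.uniform(*obs.lapse_duration) * cfg.sample_rate))
            lapse[a:min(b, n)] = True
            t_lapse += rng.exponential(1.0 / obs.lapse_rate)

    # scalar loop state (plain floats: ~5x faster than numpy scalars here)
    px = np.empty(n)
    py = np.empty(n)
    occ = np.zeros(n, dtype=np.uint8)
    gx, gy = float(sx[0]), float(sy[0])
    vx = vy = 0.0
    err_timer = 0.0
    extrapolate = obs.occluded_behavior == "extrapolate"
    gain = obs.pursuit_gain
    pos_gain = obs.position_gain
    kind = spec.kind
    radius = spec.size_deg / 2.0
    # gaze cannot wander far off the display
    gx_lim = cfg.field_halfwidth_x + 2.0
    gy_lim = cfg.field_halfwidth_y + 2.0

    def occluded_at(i: int, ex: float, ey: float) -> bool:
        rx = sx[i] - ex
        ry = sy[i] - ey
        if kind is ScotomaKind.CENTRAL:
            return math.hypot(rx, ry) <= radius
        if kind is ScotomaKind.PERIPHERAL:
            return math.hypot(rx, ry) > radius
        if kind is ScotomaKind.HEMIFIELD:
            return rx > 0.0
        return False

    px[0], py[0] = gx, gy
    occ[0] = occluded_at(0, gx, gy)
    rate = cfg.sample_rate

    # last-seen target state for extrapolated search saccades
    lsx, lsy = float(sx[0]), float(sy[0])
    lvx = lvy = 0.0
    occ_timer = 0.0
    n_search = 0
    swx = swy = 0.0  # sweep direction
    # adaptive compensation: EMA of the (unit) retinotopic direction in which
    # the target is repeatedly lost; gaze biases the aim point away from it
    # (the strategy hemianopic observers adopt).  For central/peripheral
    # defects loss directions cancel and the bias stays near zero.
    bx = by = 0.0
    beta = obs.compensation_rate
    c_mag = obs.compensation_magnitude

    for t in range(1, n):
        j = t - delay  # index of the stimulus sample currently perceived
        # bias engages only for a consistent loss direction (|b| -> 1)
        bmag = math.hypot(bx, by)
        if bmag > 0.3 and c_mag > 0:
            scale = c_mag * min(1.0, (bmag - 0.3) / 0.4) / bmag
            ox_c, oy_c = scale * bx, scale * by
        else:
            ox_c = oy_c = 0.0
        if j >= 0 and not occ[j] and not lapse[t]:
            # visual feedback available: velocity matching on the delayed target
            if j >= 1:
                tvx = (sx[j] - sx[j - 1]) * rate
                tvy = (sy[j] - sy[j - 1]) * rate
            else:
                tvx = tvy = 0.0
            # predictive pursuit: extrapolate the delayed percept to "now",
            # canceling the steady-state lag of speed x latency; the aim
            # point carries the compensatory bias away from the loss zone
            tx = sx[j] + tvx * latency + ox_c
            ty = sy[j] + tvy * latency + oy_c
            ex = gx - tx
            ey = gy - ty
            # velocity matching plus catch-up correction of the position error
            vx = gain * tvx - pos_gain * ex
            vy = gain * tvy - pos_gain * ey
            # remember the unbiased target estimate for search/loss tracking
            lsx, lsy, lvx, lvy = tx - ox_c, ty - oy_c, tvx, tvy
            occ_timer = 0.0
            n_search = 0
            reappeared = j >= 1 and occ[j - 1]  # target just re-entered view
            if reappeared:
                # a lost target consistently refound on one side implies the
                # loss zone lies opposite; the EMA of -unit(reappearance
                # direction) estimates it (cancels for symmetric defects)
                rfx = tx - ox_c - gx
                rfy = ty - oy_c - gy
                norm = math.hypot(rfx, rfy)
                if norm > 1.0:
                    bx += beta * (-rfx / norm - bx)
                    by += beta * (-rfy / norm - by)
            if math.hypot(ex, ey) > obs.saccade_trigger_error:
                err_timer += dt
            else:
                err_timer = 0.0
            # orienting saccades to a reappearing target skip the dwell
            if err_timer >= obs.saccade_latency or (
                    reappeared and math.hypot(ex, ey) > obs.saccade_trigger_error):
                # saccades characteristically undershoot: a fraction of the
                # pre-saccadic error is left uncorrected
                u = obs.saccade_undershoot
                gx = tx + u * ex + land[t, 0]
                gy = ty + u * ey + land[t, 1]
                err_timer = 0.0
                px[t], py[t] = gx, gy
                occ[t] = occluded_at(t, gx, gy)
                continue
        else:
            # no feedback: extrapolate last velocity or freeze; trigger timer
            # halts, but sustained loss of the target provokes an exploratory
            # search saccade toward the extrapolated target position
            if not extrapolate:
                vx = vy = 0.0
            occ_timer += dt
            # no search during a lapse: the observer knows the target did not
            # vanish, it will be there when the eyes reopen
            if (not lapse[t] and obs.search_interval > 0
                    and occ_timer >= obs.search_interval):
                # escalate: local probes near the estimate first, then a
                # systematic sweep (toward the estimated loss zone if one is
                # known) that overtakes the target, so detection happens at a
                # small seeing-side offset
                lead = min(occ_timer, 0.5)
                if n_search < 2:
                    widen = 1.0 if n_search == 0 else 2.0
                    gx = lsx + lvx * lead + ox_c + widen * search[t, 0]
                    gy = lsy + lvy * lead + oy_c + widen * search[t, 1]
                else:
                    if n_search == 2:
                        if bmag > 0.3:
                            swx, swy = bx / bmag, by / bmag
                        else:
                            dxe = lsx + lvx * lead - gx
                            dye = lsy + lvy * lead - gy
                            nrm = math.hypot(dxe, dye)
                            if nrm > 2.0:
                                swx, swy = dxe / nrm, dye / nrm
                            else:
                                ang = math.atan2(scan[t, 1], scan[t, 0])
                                swx, swy = math.cos(ang), math.sin(ang)
                    gx += obs.sweep_step * swx + 0.3 * search[t, 0]
                    gy += obs.sweep_step * swy + 0.3 * search[t, 1]
                    if abs(gx) >= gx_lim or abs(gy) >= gy_lim:
                        # blocked at the display edge: pick a fresh direction
                        ang = math.atan2(scan[t, 1], scan[t, 0])
                        swx, swy = math.cos(ang), math.sin(ang)
                n_search += 1
                occ_timer = 0.0
                vx = vy = 0.0
                if gx > gx_lim: gx = gx_lim
                elif gx < -gx_lim: gx = -gx_lim
                if gy > gy_lim: gy = gy_lim
                elif gy < -gy_lim: gy = -gy_lim
                px[t], py[t] = gx, gy
                occ[t] = occluded_at(t, gx, gy)
                continue
        gx += vx * dt + motor[t, 0]
        gy += vy * dt + motor[t, 1]
        if gx > gx_lim: gx = gx_lim
        elif gx < -gx_lim: gx = -gx_lim
        if gy > gy_lim: gy = gy_lim
        elif gy < -gy_lim: gy = -gy_lim
        px[t], py[t] = gx, gy
        occ[t] = occluded_at(t, gx, gy)

    return TrackingRecord(
        config=cfg, scotoma=spec,
        s_x=sx.copy(), s_y=sy.copy(), p_x=px, p_y=py, occluded=occ,
        participant_id=participant_id, trial_id=trial_id,
    )


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition protocol: repetitions x contrasts x pursuit modes."""

    repetitions: int = 6
    contrasts: Tuple[Contrast, ...] = (Contrast.LOW, Contrast.HIGH)
    pursuits: Tuple[Pursuit, ...] = (Pursuit.SMOOTH, Pursuit.SACCADIC)
    duration: float = 20.0
    sample_rate: float = 240.0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        object.__setattr__(self, "contrasts", tuple(Contrast(c) for c in self.contrasts))
        object.__setattr__(self, "pursuits", tuple(Pursuit(p) for p in self.pursuits))

    @property
    def n_trials(self) -> int:
        return self.repetitions * len(self.contrasts) * len(self.pursuits)


@dataclass(frozen=True)
class PopulationConfig:
    """Population spread of observer parameters (truncated-normal sampling)."""

    gain_sd: float = 0.05
    latency_sd: float = 0.02
    noise_sd_sd: float = 0.05
    trigger_sd: float = 0.3
    landing_sd_sd: float = 0.1


def draw_observer_params(
    rng: np.random.Generator,
    base: ObserverParams = ObserverParams(),
    pop: PopulationConfig = PopulationConfig(),
) -> ObserverParams:
    """Sample one participant's parameters from the population distributions."""

    def trunc(mean: float, sd: float, lo: float, hi: float) -> float:
        return float(np.clip(rng.normal(mean, sd), lo, hi))

    return replace(
        base,
        pursuit_gain=trunc(base.pursuit_gain, pop.gain_sd, 0.5, 1.2),
        reaction_latency_high=trunc(base.reaction_latency_high, pop.latency_sd, 0.05, 0.4),
        reaction_latency_low=trunc(base.reaction_latency_low, pop.latency_sd, 0.05, 0.5),
        position_noise_sd=trunc(base.position_noise_sd, pop.noise_sd_sd, 0.05, 1.0),
        saccade_trigger_error=trunc(base.saccade_trigger_error, pop.trigger_sd, 0.5, 4.0),
        saccade_landing_noise_sd=trunc(base.saccade_landing_noise_sd, pop.landing_sd_sd,
                                       0.05, 1.5),
        rng_seed=int(rng.integers(2**31)),
    )


def simulate_participant(
    participant_id: str,
    spec: ScotomaSpec,
    protocol: ProtocolConfig = ProtocolConfig(),
    obs: ObserverParams | None = None,
    walk: WalkParams | None = None,
    rng_seed: int = 0,
) -> List[TrackingRecord]:
    """Simulate one participant's full session for one VFD condition.

    With the default protocol this yields 6 x 2 x 2 = 24 twenty-second
    records.  Trial seeds and per-trial observer seeds are spawned from
    rng_seed, so the session is reproducible from (participant_id, seed).
    """
    rng = np.random.default_rng(rng_seed)
    obs = obs if obs is not None else draw_observer_params(rng)
    records: List[TrackingRecord] = []
    for rep in range(protocol.repetitions):
        for contrast in protocol.contrasts:
            for pursuit in protocol.pursuits:
                cfg = TrialConfig(
                    duration=protocol.duration,
                    sample_rate=protocol.sample_rate,
                    contrast=contrast,
                    pursuit=pursuit,
                    rng_seed=int(rng.integers(2**31)),
                )
                traj = generate_trajectory(cfg, walk)
                trial_obs = replace(obs, rng_seed=int(rng.integers(2**31)))
                trial_id = (f"{participant_id}_{spec.kind.value}_r{rep}"
                            f"_{contrast.value}_{pursuit.value}")
                records.append(simulate_gaze(traj, spec, trial_obs, cfg,
                                             participant_id=participant_id,
                                             trial_id=trial_id))
    return records


#: the four defect conditions of the standard protocol
STANDARD_CONDITIONS: Tuple[ScotomaSpec, ...] = (
    ScotomaSpec(ScotomaKind.NONE),
    ScotomaSpec(ScotomaKind.CENTRAL, 10.0),
    ScotomaSpec(ScotomaKind.PERIPHERAL, 10.0),
    ScotomaSpec(ScotomaKind.HEMIFIELD),
)


def simulate_cohort(
    n_participants: int,
    protocol: ProtocolConfig = ProtocolConfig(),
    conditions: Sequence[ScotomaSpec] = STANDARD_CONDITIONS,
    walk: WalkParams | None = None,
    seed: int = 0,
) -> Dict[str, Dict[ScotomaKind, List[TrackingRecord]]]:
    """Simulate a cohort; every participant runs every VFD condition.

    Returns {participant_id: {scotoma kind: [records]}}.  Observer parameters
    are drawn once per participant, so folds over participants differ
    meaningfully.
    """
    ss = np.random.SeedSequence(seed)
    cohort: Dict[str, Dict[ScotomaKind, List[TrackingRecord]]] = {}
    for i, child in enumerate(ss.spawn(n_participants), start=1):
        pid = f"P{i:02d}"
        prng = np.random.default_rng(child)
        obs = draw_observer_params(prng)
        cohort[pid] = {}
        for spec in conditions:
            cohort[pid][spec.kind] = simulate_participant(
                pid, spec, protocol, obs=obs, walk=walk,
                rng_seed=int(prng.integers(2**31)),
            )
    return cohort


def verify_labels(record: TrackingRecord) -> bool:
    """True iff the stored occlusion flags match a recomputation from (s, p)."""
    return bool(np.array_equal(record.occluded, ground_truth_labels(record)))
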