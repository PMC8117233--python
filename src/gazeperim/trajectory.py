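"""Pseudo-random-walk stimulus trajectories for continuous tracking trials.

The smooth component is a first-order autocorrelated velocity process: the
speed relaxes toward a mean value (an AR(1)/Ornstein-Uhlenbeck process) while
the heading performs rotation diffusion.  In the saccadic-pursuit condition
the walk is interleaved with displacement jumps at random intervals, drawing
the new position uniformly within the field.  The path is confined to the
field rectangle by reflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigError


class Contrast(str, Enum):
    """Stimulus contrast relative to the gray background."""

    LOW = "low"    # 5 %
    HIGH = "high"  # 50 %


class Pursuit(str, Enum):
    SMOOTH = "smooth"
    SACCADIC = "saccadic"


@dataclass(frozen=True)
class TrialConfig:
    """Static parameters of one 20-s tracking trial."""

    duration: float = 20.0
    sample_rate: float = 240.0
    contrast: Contrast = Contrast.HIGH
    pursuit: Pursuit = Pursuit.SMOOTH
    field_halfwidth_x: float = 24.0
    field_halfwidth_y: float = 13.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError(f"duration must be positive, got {self.duration}")
        if self.sample_rate <= 0:
            raise ConfigError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.field_halfwidth_x <= 0 or self.field_halfwidth_y <= 0:
            raise ConfigError("field halfwidths must be positive")
        # Coerce plain strings ("low", "smooth", ...) to enums for convenience.
        object.__setattr__(self, "contrast", Contrast(self.contrast))
        object.__setattr__(self, "pursuit", Pursuit(self.pursuit))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass(frozen=True)
class WalkParams:
    """Statistics of the stimulus random walk (stand-ins, all configurable)."""

    mean_speed: float = 10.0          # deg/s
    speed_relaxation: float = 2.0     # 1/s, pull of speed toward mean_speed
    speed_noise_sd: float = 6.0       # deg/s per sqrt(s)
    turn_rate_sd: float = 2.5         # rad per sqrt(s), heading diffusion
    jump_interval: Tuple[float, float] = (1.0, 3.0)  # s, uniform inter-jump

    def __post_init__(self) -> None:
        if self.mean_speed <= 0:
            raise ConfigError("mean_speed must be positive")
        lo, hi = self.jump_interval
        if not (0 < lo <= hi):
            raise ConfigError(f"invalid jump_interval {self.jump_interval}")


@dataclass
class StimulusTrajectory:
    """Stimulus path in degrees of visual angle, origin at screen center."""

    s_x: np.ndarray
    s_y: np.ndarray
    jump_times: np.ndarray  # sample indices of displacement jumps
    config: TrialConfig

    def __len__(self) -> int:
        return len(self.s_x)


def _fold(x: np.ndarray, half: float) -> np.ndarray:
    """Reflect an unbounded coordinate into [-half, half] (triangle wave)."""
    period = 4.0 * half
    y = np.mod(x + half, period)
    y = np.where(y > 2.0 * half, period - y, y)
    return y - half


def _ou_speed(rng: np.random.Generator, n: int, dt: float, p: WalkParams) -> np.ndarray:
    """Exact AR(1) discretization of the speed process, clipped at zero."""
    a = np.exp(-p.speed_relaxation * dt)
    innov_sd = p.speed_noise_sd * np.sqrt(dt)
    noise = rng.normal(0.0, innov_sd, size=n)
    dev = lfilter([1.0], [1.0, -a], noise)  # AR(1) around zero, dev[0] = noise[0]
    return np.maximum(p.mean_speed + dev, 0.0)


def generate_trajectory(cfg: TrialConfig, walk: WalkParams | None = None) -> StimulusTrajectory:
    """Generate a stimulus path for one trial, reproducible from cfg.rng_seed.

    Smooth pursuit yields no jumps; saccadic pursuit inserts displacement
    jumps at uniform random intervals, resuming the walk from the new
    position.
    """
    walk = walk or WalkParams()
    rng = np.random.default_rng(cfg.rng_seed)
    n, dt = cfg.n_samples, cfg.dt
    hx, hy = cfg.field_halfwidth_x, cfg.field_halfwidth_y

    speed = _ou_speed(rng, n, dt, walk)
    heading = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(
        rng.normal(0.0, walk.turn_rate_sd * np.sqrt(dt), size=n)
    )
    dx = speed * np.cos(heading) * dt
    dy = speed * np.sin(heading) * dt

    if cfg.pursuit is Pursuit.SACCADIC:
        jump_idx = []
        t = rng.uniform(*walk.jump_interval)
        while t < cfg.duration:
            k = int(round(t * cfg.sample_rate))
            if 0 < k < n:
                jump_idx.append(k)
            t += rng.uniform(*walk.jump_interval)
        jump_idx = sorted(set(jump_idx))
        targets = rng.uniform([-hx, -hy], [hx, hy], size=(len(jump_idx), 2))
    else:
        jump_idx, targets = [], np.empty((0, 2))

    s_x = np.empty(n)
    s_y = np.empty(n)
    bounds = [0] + list(jump_idx) + [n]
    start = np.zeros(2)
    for seg, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        # segment starts at `start`, first sample of the segment sits there
        cx = start[0] + np.concatenate(([0.0], np.cumsum(dx[a + 1:b])))
        cy = start[1] + np.concatenate(([0.0], np.cumsum(dy[a + 1:b])))
        s_x[a:b] = _fold(cx, hx)
        s_y[a:b] = _fold(cy, hy)
        if seg < len(jump_idx):
            start = targets[seg]

    return StimulusTrajectory(
        s_x=s_x, s_y=s_y, jump_times=np.asarray(jump_idx, dtype=int), config=cfg
    )
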