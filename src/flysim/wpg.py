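"""Open-loop wing-beat pattern generator (WPG).

Produces a fixed, mirror-symmetric, cyclic baseline trajectory of the six
wing angles (stroke/yaw, deviation/roll and pitch per wing) and replays it
at a commandable frequency.  A single scalar command in [-1, 1] modulates
the wing-beat frequency within a 10% band centred on the 218 Hz fly
average (command 0 -> 218 Hz, command +-1 -> +-5%).  Frequency changes are
phase-continuous: only the phase velocity is ramped (linearly, completing
within about one wing-beat cycle), so the output angles never jump.

Angle channels, in order: ``yaw_L, roll_L, pitch_L, yaw_R, roll_R,
pitch_R`` (radians).  Mirror convention: reflecting through the body's
sagittal plane maps left to right with signs ``(-1, -1, +1)`` — stroke and
deviation negate, pitch about the span axis is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASE_FREQUENCY_HZ = 218.0
FREQUENCY_HALF_RANGE = 0.05  # "10% range centred at 218 Hz" -> +-5%

CHANNELS = ("yaw_L", "roll_L", "pitch_L", "yaw_R", "roll_R", "pitch_R")
#: left-to-right mirror signs for (yaw, roll, pitch)
MIRROR_SIGNS = np.array([-1.0, -1.0, 1.0])


class ContractError(ValueError):
    pass


@dataclass
class WingBeatPattern:
    """One period of the baseline pattern on a phase grid in [0, 1).

    ``angles`` has shape (N, 6) radians; the pattern is treated as
    periodic, so the sample at phase 1 wraps to phase 0.
    """

    phase: np.ndarray
    angles: np.ndarray
    base_frequency: float = BASE_FREQUENCY_HZ
    source: str = "synthetic"

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.phase.ndim != 1 or self.angles.shape != (self.phase.size, 6):
            raise ContractError("pattern needs a (N,) phase grid and (N, 6) angles")
        if self.phase.size == 0:
            raise ContractError("empty pattern")
        if np.any(np.diff(self.phase) <= 0) or self.phase[0] < 0 or self.phase[-1] >= 1:
            raise ContractError("phase grid must be strictly increasing in [0, 1)")

    def sample(self, phase: float) -> np.ndarray:
        """Periodic linear interpolation of the six angles at a phase."""
        p = float(phase) % 1.0
        grid = np.concatenate([self.phase, [self.phase[0] + 1.0]])
        wrapped = np.vstack([self.angles, self.angles[:1]])
        if p < grid[0]:
            p += 1.0
        idx = np.searchsorted(grid, p, side="right") - 1
        idx = min(idx, grid.size - 2)
        t = (p - grid[idx]) / (grid[idx + 1] - grid[idx])
        return (1 - t) * wrapped[idx] + t * wrapped[idx + 1]

    def amplitude(self) -> np.ndarray:
        """Per-channel half peak-to-peak amplitude, radians."""
        return 0.5 * (self.angles.max(axis=0) - self.angles.min(axis=0))

    # -- construction ---------------------------------------------------

    @classmethod
    def synthetic_hover(
        cls,
        n: int = 256,
        stroke_amp_deg: float = 70.0,
        deviation_amp_deg: float = 15.0,
        pitch_amp_deg: float = 45.0,
        base_frequency: float = BASE_FREQUENCY_HZ,
    ) -> "WingBeatPattern":
        """Hovering-like baseline: sinusoidal stroke, figure-of-eight
        deviation, pitch flipping at each stroke reversal."""
        phase = np.arange(n) / n
        two_pi = 2 * np.pi * phase
        stroke = np.deg2rad(stroke_amp_deg) * np.cos(two_pi)
        deviation = np.deg2rad(deviation_amp_deg) * np.sin(2 * two_pi)
        pitch = np.deg2rad(pitch_amp_deg) * np.sin(two_pi)
        left = np.stack([stroke, deviation, pitch], axis=1)
        right = left * MIRROR_SIGNS
        return cls(phase, np.hstack([left, right]), base_frequency, "synthetic")

    @classmethod
    def from_csv(cls, path, base_frequency: float = BASE_FREQUENCY_HZ,
                 channel_map: dict | None = None) -> "WingBeatPattern":
        """Load a pattern CSV with columns ``phase, yaw_L_deg, ...``.

        ``channel_map`` optionally renames file columns to the canonical
        channel names before loading (sign conventions differ between
        recording set-ups).
        """
        df = pd.read_csv(path)
        if channel_map:
            df = df.rename(columns=channel_map)
        cols = [f"{c}_deg" for c in CHANNELS]
        missing = [c for c in ["phase"] + cols if c not in df.columns]
        if missing:
            raise ContractError(f"pattern CSV missing columns: {missing}")
        return cls(
            df["phase"].to_numpy(),
            np.deg2rad(df[cols].to_numpy()),
            base_frequency,
            str(path),
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"phase": self.phase})
        for i, c in enumerate(CHANNELS):
            df[f"{c}_deg"] = np.rad2deg(self.angles[:, i])
        df.to_csv(path, index=False)


def check_mirror_symmetry(pattern: WingBeatPattern, tol: float = 1e-9):
    """True iff right channels mirror the left ones; also the max asymmetry.

    The asymmetry is the largest absolute difference (radians) between a
    right-wing channel and the sign-mapped left-wing channel.
    """
    left = pattern.angles[:, :3]
    right = pattern.angles[:, 3:]
    asym = float(np.max(np.abs(right - left * MIRROR_SIGNS)))
    return asym <= tol, asym


@dataclass
class WPGState:
    """Mutable replay state: phase (mod 1) and the frequency ramp."""

    phase: float = 0.0
    frequency: float = BASE_FREQUENCY_HZ
    pending_frequency: float = BASE_FREQUENCY_HZ
    total_phase: float = 0.0  # unwrapped, for drift-free bookkeeping
    _comp: float = 0.0  # Kahan compensation of the phase accumulator

    def wrapped(self) -> float:
        return self.phase % 1.0


class WingPatternGenerator:
    """Replays a :class:`WingBeatPattern` with commandable frequency."""

    def __init__(
        self,
        pattern: WingBeatPattern,
        base_frequency: float | None = None,
        half_range: float = FREQUENCY_HALF_RANGE,
    ):
        self.pattern = pattern
        self.base_frequency = (
            pattern.base_frequency if base_frequency is None else base_frequency
        )
        self.half_range = half_range
        # a full-band frequency swing completes within one wing-beat cycle
        self._ramp_rate = (
            2 * self.half_range * self.base_frequency * self.base_frequency
        )

    def command_frequency(self, command: float) -> float:
        """Map a [-1, 1] command to Hz; out-of-range commands are clamped."""
        if command < -1.0 or command > 1.0:
            logger.warning("frequency command %.3f outside [-1, 1]; clamped", command)
            command = float(np.clip(command, -1.0, 1.0))
        return self.base_frequency * (1.0 + self.half_range * command)

    def init_state(self, phase: float = 0.0) -> WPGState:
        f = self.base_frequency
        return WPGState(phase=phase, frequency=f, pending_frequency=f,
                        total_phase=phase)

    def step(self, state: WPGState, dt: float, freq_command: float = 0.0):
        """Advance one control step; returns ``(new_state, six angles)``.

        The frequency ramps linearly towards the commanded value at a rate
        that completes a full-band swing in one wing-beat cycle, so the
        phase (and hence the output angles) stays continuous across
        frequency switches.
        """
        if dt <= 0:
            raise ContractError("dt must be > 0")
        target = self.command_frequency(freq_command)
        df = np.clip(target - state.frequency,
                     -self._ramp_rate * dt, self._ramp_rate * dt)
        freq = state.frequency + float(df)
        # Kahan-compensated accumulation keeps the phase drift-free
        # (~1 ulp of the total rather than O(k) rounding) over long runs
        incr = freq * dt - state._comp
        total = state.total_phase + incr
        comp = (total - state.total_phase) - incr
        new = WPGState(
            phase=total % 1.0,
            frequency=freq,
            pending_frequency=target,
            total_phase=total,
            _comp=comp,
        )
        return new, self.pattern.sample(new.phase)
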