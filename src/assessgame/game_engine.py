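"""Target-path generation and the ROM-to-screen calibration of the game.

The avatar's vertical screen position is an affine function of the target
joint's angle.  The game is calibrated to the participant's maximum active
range of motion (ROM) and the playable band covers 90% of that ROM,
centered on the ROM midpoint; angles outside the usable band clamp to the
screen edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session_model import Calibration, JointId, TargetPath, ValidationError

# screen band the target path is confined to, so stars never sit on the edge
_PATH_LO, _PATH_HI = 0.05, 0.95


@dataclass(frozen=True)
class ScreenMapping:
    """Affine, strictly monotone map from joint angle (deg) to screen [0, 1].

    ``angle_low`` and ``angle_high`` are the usable-range endpoints: they map
    to screen 0 and 1 exactly.  Increasing flexion angle maps upward on the
    screen by default; pass ``invert=True`` for joints cued the other way.
    """

    calibration: Calibration
    angle_low: float
    angle_high: float
    invert: bool = False

    def __post_init__(self) -> None:
        if not self.angle_high > self.angle_low:
            raise ValidationError("usable range must have positive span")

    @property
    def slope(self) -> float:
        s = 1.0 / (self.angle_high - self.angle_low)
        return -s if self.invert else s

    @property
    def offset(self) -> float:
        # screen = slope * angle + offset (before clamping)
        if self.invert:
            return 1.0 + self.angle_low / (self.angle_high - self.angle_low)
        return -self.angle_low / (self.angle_high - self.angle_low)

    def to_screen(self, angle):
        """Map angle(s) to clamped screen position(s)."""
        pos = (np.asarray(angle, dtype=float) - self.angle_low) / (
            self.angle_high - self.angle_low
        )
        if self.invert:
            pos = 1.0 - pos
        return np.clip(pos, 0.0, 1.0)

    def to_angle(self, position):
        """Inverse map: screen position(s) in [0, 1] to angle(s) in degrees."""
        pos = np.asarray(position, dtype=float)
        if self.invert:
            pos = 1.0 - pos
        return self.angle_low + pos * (self.angle_high - self.angle_low)


def calibrate_rom(
    angle_min: float,
    angle_max: float,
    usable_fraction: float = 0.9,
    joint: JointId | None = None,
    invert: bool = False,
) -> ScreenMapping:
    """Build the angle-to-screen mapping from a measured active ROM.

    The usable span is ``usable_fraction`` x ROM, centered on the ROM
    midpoint (a symmetric 5% margin at each end by default).  A ROM below
    10 degrees is rejected: such joints cannot be tested with the game.
    """
    joint = joint if joint is not None else JointId("left", "knee")
    cal = Calibration(joint, angle_min, angle_max, usable_fraction)  # enforces ROM >= 10
    mid = 0.5 * (angle_min + angle_max)
    half = 0.5 * usable_fraction * cal.rom
    return ScreenMapping(cal, mid - half, mid + half, invert=invert)


def map_angle_to_screen(angle, mapping: ScreenMapping):
    """Screen position of ``angle`` under ``mapping`` (affine, clamped)."""
    return mapping.to_screen(angle)


def generate_target_path(
    duration: float = 30.0,
    n_curves: int = 4,
    seed: int = 0,
    sampling_rate: float = 50.0,
    star_interval: float = 2.0,
) -> TargetPath:
    """Generate a smooth target path of upward and downward curves.

    The path is a random-phase sum of ``n_curves`` sinusoids with periods of
    3–10 s, affinely rescaled into [0.05, 0.95].  It is deterministic for a
    fixed seed and always contains at least one interior local maximum and
    minimum.  Stars are spaced evenly at ``star_interval`` seconds.
    """
    if n_curves < 2:
        raise ValidationError(
            "n_curves must be >= 2: the path must contain both an upward and a downward curve"
        )
    if not duration > 0:
        raise ValidationError("duration must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    for attempt in range(8):  # resample in the (rare) degenerate monotone case
        periods = rng.uniform(3.0, 10.0, size=n_curves)
        phases = rng.uniform(0.0, 2 * np.pi, size=n_curves)
        amps = rng.uniform(0.5, 1.0, size=n_curves) / n_curves
        y = np.sum(
            amps[:, None] * np.sin(2 * np.pi * t[None, :] / periods[:, None] + phases[:, None]),
            axis=0,
        )
        span = y.max() - y.min()
        if span < 1e-9:
            continue
        y = _PATH_LO + (y - y.min()) * (_PATH_HI - _PATH_LO) / span
        d = np.diff(y)
        sc = np.diff(np.sign(d[d != 0]))
        if np.any(sc < 0) and np.any(sc > 0):
            break
    star_times = np.arange(star_interval, duration, star_interval)
    return TargetPath(
        duration=duration, positions=y, sampling_rate=sampling_rate, star_times=star_times
    )


__all__ = ["ScreenMapping", "calibrate_rom", "generate_target_path", "map_angle_to_screen"]
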