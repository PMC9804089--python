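"""Domain types for game sessions, clinical ratings, and their file round-trip.

This module is the single home of the coordinate and unit conventions used
throughout the package:

* joint angles in **degrees**, angular speeds in **degrees/second**,
* time in **seconds**, acceleration in **g**,
* screen positions normalized to **[0, 1]** with 0 = bottom of the screen,
* sensor axes: ``x`` points anteriorly in the sagittal plane, ``y`` laterally
  and ``z`` along the segment's long axis, so a segment at rest in the neutral
  posture reads approximately ``(0, 0, -1)`` g.

A *session* is one trial of the "catch the stars" game: one target joint is
calibrated to the participant's active range of motion, an owl avatar is
steered along a star-studded target path by isolated flexion/extension of
that joint, and six proximal/distal 3-axis accelerometer pairs (bilateral
hip, knee, ankle) record what every joint actually did.

On disk a session is a directory with a JSON metadata document and
long-format CSV files (``sensors.csv``, ``path.csv``, ``avatar.csv``) so that
recordings stay diff-able and language neutral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

SIDES = ("left", "right")
JOINTS = ("hip", "knee", "ankle")
OCCASIONS = ("test", "retest")
#: involuntary-movement types a therapist can tick during a trial
MOVEMENT_TYPES = ("mirror", "trunk", "other_joint")

MIN_ROM_DEG = 10.0


class SessionFormatError(ValueError):
    """A session file violates the on-disk schema."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


@dataclass(frozen=True, order=True)
class JointId:
    """One of the six lower-limb joints: a (side, joint) pair."""

    side: str
    joint: str

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}; expected one of {SIDES}")
        if self.joint not in JOINTS:
            raise ValidationError(f"unknown joint {self.joint!r}; expected one of {JOINTS}")

    @property
    def label(self) -> str:
        return f"{self.side}_{self.joint}"

    @classmethod
    def parse(cls, label: str) -> "JointId":
        try:
            side, joint = label.split("_", 1)
        except ValueError as exc:
            raise ValidationError(f"cannot parse joint label {label!r}") from exc
        return cls(side, joint)

    def mirrored(self) -> "JointId":
        """The contralateral homologue (same joint, other side)."""
        other = "right" if self.side == "left" else "left"
        return JointId(other, self.joint)


def all_joints() -> tuple[JointId, ...]:
    """The six joints of one participant, in a fixed canonical order."""
    return tuple(JointId(s, j) for s in SIDES for j in JOINTS)


@dataclass(frozen=True)
class AffectedSideMap:
    """Which body side is clinically more affected.

    The label comes from the diagnosis (input metadata), never from scores;
    for bilateral involvement one side is still designated the more affected
    one, as is usual clinical practice.
    """

    more_affected: str

    def __post_init__(self) -> None:
        if self.more_affected not in SIDES:
            raise ValidationError(f"more_affected must be one of {SIDES}")

    @property
    def less_affected(self) -> str:
        return "right" if self.more_affected == "left" else "left"

    def label(self, side: str) -> str:
        return "more_affected" if side == self.more_affected else "less_affected"


@dataclass
class SensorPairTrace:
    """Proximal (reference) and distal 3-axis accelerometer traces of one joint.

    ``missing_mask`` has shape ``(n, 2)``; column 0 flags samples where the
    proximal sensor dropped out, column 1 the distal one.  Missing samples
    keep a placeholder value and are never silently filled at read time.
    """

    joint: JointId
    proximal: np.ndarray
    distal: np.ndarray
    sampling_rate: float
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        if self.proximal.ndim != 2 or self.proximal.shape[1] != 3:
            raise ValidationError(f"{self.joint.label}: proximal trace must be (n, 3)")
        if self.proximal.shape != self.distal.shape:
            raise ValidationError(
                f"{self.joint.label}: proximal and distal traces differ in shape "
                f"({self.proximal.shape} vs {self.distal.shape})"
            )
        if not self.sampling_rate > 0:
            raise ValidationError(f"{self.joint.label}: sampling_rate must be > 0")
        n = len(self.proximal)
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, 2), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, 2):
            raise ValidationError(f"{self.joint.label}: missing_mask must be (n, 2)")
        if n and self.missing_mask.all(axis=0).any():
            raise ValidationError(f"{self.joint.label}: a sensor is missing for 100% of samples")

    @property
    def n_samples(self) -> int:
        return len(self.proximal)

    @property
    def missing_fraction(self) -> float:
        """Fraction of (sample, sensor) slots flagged missing."""
        if self.missing_mask.size == 0:
            return 0.0
        return float(self.missing_mask.mean())


@dataclass(frozen=True)
class Calibration:
    """Active range of motion of the target joint, in degrees.

    The game is calibrated so the participant steers within
    ``usable_fraction`` (default 90%) of this range; joints with an active
    ROM below 10 degrees cannot be tested.
    """

    joint: JointId
    angle_min: float
    angle_max: float
    usable_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.angle_max - self.angle_min < MIN_ROM_DEG:
            raise ValidationError(
                f"{self.joint.label}: active ROM "
                f"{self.angle_max - self.angle_min:.1f} deg is below the "
                f"{MIN_ROM_DEG:.0f} deg minimum required to play"
            )
        if not 0 < self.usable_fraction <= 1:
            raise ValidationError("usable_fraction must be in (0, 1]")

    @property
    def rom(self) -> float:
        return self.angle_max - self.angle_min


@dataclass
class TargetPath:
    """The star-studded target trajectory of the 30 s test phase.

    Positions are normalized screen heights sampled at ``sampling_rate``;
    the path must contain both upward and downward curves (at least one
    interior local maximum and minimum).
    """

    duration: float
    positions: np.ndarray
    sampling_rate: float
    star_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.star_times = np.asarray(self.star_times, dtype=float)
        if not self.duration > 0:
            raise ValidationError("path duration must be > 0")
        if self.positions.min(initial=0.0) < 0 or self.positions.max(initial=0.0) > 1:
            raise ValidationError("path positions must lie in [0, 1]")
        expected = int(round(self.duration * self.sampling_rate))
        if abs(len(self.positions) - expected) > 1:
            raise ValidationError(
                f"path has {len(self.positions)} samples; expected ~{expected} "
                f"for {self.duration} s at {self.sampling_rate} Hz"
            )
        d = np.diff(self.positions)
        sign_changes = np.diff(np.sign(d[d != 0]))
        if not (np.any(sign_changes < 0) and np.any(sign_changes > 0)):
            raise ValidationError("path must contain both an upward and a downward curve")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) / self.sampling_rate


@dataclass
class GameSession:
    """One trial: one target joint, full six-pair recording, avatar trace.

    The recording covers the 25 s accommodation phase followed by the
    ``path.duration`` (30 s) test phase; the avatar trace covers the test
    phase only, which is the part that is scored.
    """

    participant_id: str
    occasion: str
    target_joint: JointId
    calibration: Calibration
    path: TargetPath
    traces: Mapping[JointId, SensorPairTrace]
    avatar_trace: np.ndarray
    accommodation_duration: float = 25.0

    def __post_init__(self) -> None:
        if self.occasion not in OCCASIONS:
            raise ValidationError(f"occasion must be one of {OCCASIONS}")
        missing = set(all_joints()) - set(self.traces)
        if missing:
            raise ValidationError(
                "session must contain all 6 sensor pairs; missing: "
                + ", ".join(sorted(j.label for j in missing))
            )
        if self.target_joint not in self.traces:
            raise ValidationError(f"target joint {self.target_joint.label} has no trace")
        if self.calibration.joint != self.target_joint:
            raise ValidationError("calibration joint must equal the target joint")
        fs = self.sampling_rate
        n_expected = int(round((self.accommodation_duration + self.path.duration) * fs))
        for jid, tr in self.traces.items():
            if tr.sampling_rate != fs:
                raise ValidationError(f"{jid.label}: sampling rate differs across traces")
            if abs(tr.n_samples - n_expected) > 1:
                raise ValidationError(
                    f"{jid.label}: trace has {tr.n_samples} samples, expected "
                    f"~{n_expected} covering accommodation + test phases"
                )
        self.avatar_trace = np.asarray(self.avatar_trace, dtype=float)
        if len(self.avatar_trace) != len(self.path.positions):
            raise ValidationError(
                f"avatar trace has {len(self.avatar_trace)} samples; "
                f"path has {len(self.path.positions)}"
            )
        if self.avatar_trace.size and (
            self.avatar_trace.min() < 0 or self.avatar_trace.max() > 1
        ):
            raise ValidationError("avatar positions must lie in [0, 1]")

    @property
    def sampling_rate(self) -> float:
        return next(iter(self.traces.values())).sampling_rate

    @property
    def test_slice(self) -> slice:
        """Index range of the test phase within the full sensor traces."""
        n_acc = int(round(self.accommodation_duration * self.sampling_rate))
        return slice(n_acc, n_acc + len(self.path.positions))

    @property
    def session_key(self) -> str:
        return f"{self.participant_id}_{self.occasion}_{self.target_joint.label}"


@dataclass
class ClinicalRatings:
    """Comparator measures for one participant and occasion.

    * ``scale`` — clinical selective-control rating per joint: 0 = unable,
      1 = impaired, 2 = normal; ``None`` marks a joint excluded from testing.
    * ``gmfcs`` — gross motor function classification, level 1–5.
    * ``therapist_counts`` — per target-joint trial, how many involuntary
      movement *types* (mirror / trunk / other joint) the therapist saw at
      least once: 0–3.
    """

    participant_id: str
    occasion: str
    gmfcs: int
    scale: Mapping[JointId, Optional[int]]
    therapist_counts: Mapping[JointId, int]

    def __post_init__(self) -> None:
        if self.occasion not in OCCASIONS:
            raise ValidationError(f"occasion must be one of {OCCASIONS}")
        if self.gmfcs not in range(1, 6):
            raise ValidationError("GMFCS level must be 1..5")
        for jid, v in self.scale.items():
            if v is not None and v not in (0, 1, 2):
                raise ValidationError(f"{jid.label}: SCALE value must be 0, 1 or 2")
        for jid, v in self.therapist_counts.items():
            if v not in (0, 1, 2, 3):
                raise ValidationError(f"{jid.label}: therapist count must be 0..3")


def encode_therapist_rating(observed_types: Iterable[str]) -> int:
    """Encode the therapist's involuntary-movement observation as 0–3 points.

    One point is given for each movement type (mirror, trunk, other joint)
    observed at least once during the trial; a selectively performed
    movement gets 0.
    """
    observed = set(observed_types)
    unknown = observed - set(MOVEMENT_TYPES)
    if unknown:
        raise ValidationError(
            f"unknown involuntary movement type(s) {sorted(unknown)}; "
            f"expected a subset of {MOVEMENT_TYPES}"
        )
    return len(observed)


# ---------------------------------------------------------------------------
# File round-trip
# ---------------------------------------------------------------------------

_AXES = ("x", "y", "z")


def write_session(session: GameSession, path: str | Path) -> Path:
    """Write a session to ``path`` (a directory) as JSON metadata + CSVs."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    fs = session.sampling_rate
    meta = {
        "participant_id": session.participant_id,
        "occasion": session.occasion,
        "target_joint": session.target_joint.label,
        "accommodation_duration_s": session.accommodation_duration,
        "sampling_rate_hz": fs,
        "calibration": {
            "angle_min_deg": session.calibration.angle_min,
            "angle_max_deg": session.calibration.angle_max,
            "usable_fraction": session.calibration.usable_fraction,
        },
        "path": {
            "duration_s": session.path.duration,
            "star_times_s": session.path.star_times.tolist(),
        },
    }
    (d / "session.json").write_text(json.dumps(meta, indent=1))

    frames = []
    for jid in all_joints():
        tr = session.traces[jid]
        t = np.arange(tr.n_samples) / fs
        for si, (sensor, data) in enumerate((("proximal", tr.proximal), ("distal", tr.distal))):
            for ai, axis in enumerate(_AXES):
                frames.append(
                    pd.DataFrame(
                        {
                            "time_s": t,
                            "side": jid.side,
                            "joint": jid.joint,
                            "sensor": sensor,
                            "axis": axis,
                            "value_g": data[:, ai],
                            "missing": tr.missing_mask[:, si].astype(int),
                        }
                    )
                )
    pd.concat(frames, ignore_index=True).to_csv(d / "sensors.csv", index=False)

    t_test = session.path.times
    pd.DataFrame({"time_s": t_test, "position": session.path.positions}).to_csv(
        d / "path.csv", index=False
    )
    pd.DataFrame({"time_s": t_test, "position": session.avatar_trace}).to_csv(
        d / "avatar.csv", index=False
    )
    return d


def read_session(path: str | Path) -> GameSession:
    """Read a session directory written by :func:`write_session`.

    Schema violations raise :class:`SessionFormatError` naming the offending
    field or joint; missing samples stay masked, nothing is imputed here.
    """
    d = Path(path)
    meta_file = d / "session.json"
    if not meta_file.exists():
        raise SessionFormatError(f"{d}: no session.json")
    meta = json.loads(meta_file.read_text())
    for key in ("participant_id", "occasion", "target_joint", "sampling_rate_hz"):
        if key not in meta:
            raise SessionFormatError(f"{d}: session.json misses field {key!r}")
    fs = float(meta["sampling_rate_hz"])
    target = JointId.parse(meta["target_joint"])

    sensors = pd.read_csv(d / "sensors.csv")
    traces: dict[JointId, SensorPairTrace] = {}
    for (side, joint), grp in sensors.groupby(["side", "joint"], sort=False):
        jid = JointId(str(side), str(joint))
        arrays = {}
        masks = {}
        for sensor, sgrp in grp.groupby("sensor"):
            cols = []
            mask = None
            for axis in _AXES:
                ax = sgrp[sgrp["axis"] == axis].sort_values("time_s")
                if ax.empty:
                    raise SessionFormatError(f"{d}: {jid.label} {sensor} misses axis {axis}")
                cols.append(ax["value_g"].to_numpy())
                mask = ax["missing"].to_numpy().astype(bool)
            arrays[sensor] = np.column_stack(cols)
            masks[sensor] = mask
        for sensor in ("proximal", "distal"):
            if sensor not in arrays:
                raise SessionFormatError(f"{d}: {jid.label} misses {sensor} sensor data")
        mm = np.column_stack([masks["proximal"], masks["distal"]])
        traces[jid] = SensorPairTrace(jid, arrays["proximal"], arrays["distal"], fs, mm)
    missing_joints = set(all_joints()) - set(traces)
    if missing_joints:
        raise SessionFormatError(
            f"{d}: sensors.csv misses sensor pair(s) "
            + ", ".join(sorted(j.label for j in missing_joints))
        )

    path_df = pd.read_csv(d / "path.csv")
    avatar_df = pd.read_csv(d / "avatar.csv")
    cal = meta["calibration"]
    try:
        session = GameSession(
            participant_id=str(meta["participant_id"]),
            occasion=str(meta["occasion"]),
            target_joint=target,
            calibration=Calibration(
                target, cal["angle_min_deg"], cal["angle_max_deg"], cal["usable_fraction"]
            ),
            path=TargetPath(
                duration=float(meta["path"]["duration_s"]),
                positions=path_df["position"].to_numpy(),
                sampling_rate=fs,
                star_times=np.asarray(meta["path"]["star_times_s"], dtype=float),
            ),
            traces=traces,
            avatar_trace=avatar_df["position"].to_numpy(),
            accommodation_duration=float(meta["accommodation_duration_s"]),
        )
    except ValidationError as exc:
        raise SessionFormatError(f"{d}: {exc}") from exc
    return session


def write_ratings(ratings: Iterable[ClinicalRatings], path: str | Path) -> Path:
    """Write clinical ratings as a long-format CSV (one row per joint)."""
    rows = []
    for r in ratings:
        for jid in all_joints():
            scale = r.scale.get(jid)
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "occasion": r.occasion,
                    "side": jid.side,
                    "joint": jid.joint,
                    "scale": "" if scale is None else scale,
                    "gmfcs": r.gmfcs,
                    "therapist_count": r.therapist_counts.get(jid, 0),
                }
            )
    out = Path(path)
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def read_ratings(path: str | Path) -> list[ClinicalRatings]:
    df = pd.read_csv(path)
    out = []
    for (pid, occ), grp in df.groupby(["participant_id", "occasion"], sort=False):
        scale: dict[JointId, Optional[int]] = {}
        counts: dict[JointId, int] = {}
        for _, row in grp.iterrows():
            jid = JointId(str(row["side"]), str(row["joint"]))
            scale[jid] = None if pd.isna(row["scale"]) else int(row["scale"])
            counts[jid] = int(row["therapist_count"])
        out.append(
            ClinicalRatings(
                participant_id=str(pid),
                occasion=str(occ),
                gmfcs=int(grp["gmfcs"].iloc[0]),
                scale=scale,
                therapist_counts=counts,
            )
        )
    return out


__all__ = [
    "AffectedSideMap",
    "Calibration",
    "ClinicalRatings",
    "GameSession",
    "JointId",
    "SensorPairTrace",
    "SessionFormatError",
    "TargetPath",
    "ValidationError",
    "all_joints",
    "encode_therapist_rating",
    "read_ratings",
    "read_session",
    "write_ratings",
    "write_session",
]
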