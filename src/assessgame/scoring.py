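"""Measurement core: sensor traces -> joint angles -> standardized scores.

The pipeline for one trial is

1. fill occasional sensor dropouts by chained-equation multiple imputation
   (mean of 50 draws; a joint with >= 20% missing samples in any channel is
   flagged untestable and excluded),
2. transform each accelerometer pair to a joint angle: the sagittal
   inclination of each sensor is the ``atan2`` of its gravity components and
   the joint angle is distal minus proximal inclination, so whole-segment
   (compensatory) motion cancels,
3. differentiate to angular joint speed (deg/s),
4. score the test phase: the *accuracy score* is the RMS error between the
   avatar and the target path standardized to the SD of a neurologically
   intact adult reference cohort; the *involuntary movement score* (IMS) is
   the mean, over the five nontarget joints, of the joint's mean absolute
   angular speed expressed as a z-score against the same adult reference.

Larger values mean worse selective control for both scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .session_model import (
    AffectedSideMap,
    GameSession,
    JointId,
    SensorPairTrace,
    ValidationError,
    all_joints,
)

#: missing fraction at or above which a joint cannot be scored
UNTESTABLE_MISSING_FRACTION = 0.20
#: default cutoff (Hz) of the zero-phase low-pass applied before inclination
DEFAULT_LOWPASS_HZ = 3.0
#: sustained sub-0.3 g acceleration marks unreliable gravity sensing
LOW_G_THRESHOLD = 0.3


class UntestableJointError(ValueError):
    """A joint cannot be scored (e.g. too many missing samples)."""


class DegenerateReferenceError(ValueError):
    """An adult reference SD is zero; standardization is undefined."""


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute_missing(
    values: np.ndarray,
    mask: np.ndarray,
    predictors: Optional[np.ndarray] = None,
    predictor_valid: Optional[np.ndarray] = None,
    sampling_rate: float = 50.0,
    n_imputations: int = 50,
    seed: int = 0,
    window_s: float = 0.5,
) -> np.ndarray:
    """Impute masked samples of one channel by chained-equation regression.

    For each contiguous gap, a linear model of the channel on time and on
    the synchronous predictor channels (the other sensor of the same joint)
    is fitted over the observed samples within ``window_s`` seconds of the
    gap; ``n_imputations`` posterior-predictive draws are averaged into the
    imputed value.  Observed samples are never touched, and the result is
    deterministic for a fixed seed.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValidationError("mask and values must have equal shape")
    if mask.mean() >= UNTESTABLE_MISSING_FRACTION:
        raise UntestableJointError(
            f"{mask.mean():.0%} of samples missing (>= "
            f"{UNTESTABLE_MISSING_FRACTION:.0%}); joint is untestable"
        )
    if not mask.any():
        return values.copy()

    rng = np.random.default_rng(seed)
    out = values.copy()
    n = len(values)
    w = max(int(round(window_s * sampling_rate)), 4)
    if predictors is not None:
        predictors = np.asarray(predictors, dtype=float)
        if predictor_valid is None:
            predictor_valid = np.ones(n, dtype=bool)

    # contiguous gaps
    idx = np.flatnonzero(mask)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for gap in np.split(idx, splits):
        lo, hi = gap[0], gap[-1]
        window = np.arange(max(lo - w, 0), min(hi + w + 1, n))
        train = window[~mask[window]]
        use_pred = (
            predictors is not None
            and predictor_valid[gap].all()
            and len(train) > 0
            and predictor_valid[train].mean() > 0.5
        )
        if use_pred:
            train = train[predictor_valid[train]]

        def design(rows: np.ndarray) -> np.ndarray:
            cols = [np.ones(len(rows)), (rows - lo) / sampling_rate]
            if use_pred:
                cols.extend(predictors[rows].T)
            return np.column_stack(cols)

        X = design(train)
        if len(train) < X.shape[1] + 2:
            # too little local context for a regression: linear interpolation
            obs = np.flatnonzero(~mask)
            out[gap] = np.interp(gap, obs, values[obs])
            continue
        y = values[train]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(train) - X.shape[1], 1)
        sigma = float(np.sqrt(resid @ resid / dof))
        cov = sigma**2 * np.linalg.pinv(X.T @ X)
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta)))
        X0 = design(gap)
        betas = beta[None, :] + rng.standard_normal((n_imputations, len(beta))) @ L.T
        draws = betas @ X0.T + rng.normal(0.0, sigma, size=(n_imputations, len(gap)))
        out[gap] = draws.mean(axis=0)
    return out


def impute_trace(
    trace: SensorPairTrace, n_imputations: int = 50, seed: int = 0
) -> SensorPairTrace:
    """Impute all missing samples of a sensor pair, channel by channel.

    Each channel is regressed on time and on the three synchronous channels
    of the *other* sensor of the pair.  Raises :class:`UntestableJointError`
    if any sensor is missing for >= 20% of samples.
    """
    mm = trace.missing_mask
    if not mm.any():
        return trace
    for si, name in enumerate(("proximal", "distal")):
        if mm[:, si].mean() >= UNTESTABLE_MISSING_FRACTION:
            raise UntestableJointError(
                f"{trace.joint.label}: {name} sensor missing for "
                f"{mm[:, si].mean():.0%} of samples"
            )
    data = {"proximal": trace.proximal.copy(), "distal": trace.distal.copy()}
    other = {"proximal": "distal", "distal": "proximal"}
    source = {"proximal": trace.proximal, "distal": trace.distal}
    for si, name in enumerate(("proximal", "distal")):
        osi = 1 - si
        for ai in range(3):
            data[name][:, ai] = impute_missing(
                source[name][:, ai],
                mm[:, si],
                predictors=source[other[name]],
                predictor_valid=~mm[:, osi],
                sampling_rate=trace.sampling_rate,
                n_imputations=n_imputations,
                seed=seed + 7 * si + ai,
            )
    return SensorPairTrace(
        trace.joint, data["proximal"], data["distal"], trace.sampling_rate, mm.copy()
    )


# ---------------------------------------------------------------------------
# Angles and speeds
# ---------------------------------------------------------------------------


@dataclass
class AngleTrace:
    """Joint angle (deg) and angular speed (deg/s) over one recording."""

    joint: JointId
    angles: np.ndarray
    sampling_rate: float
    low_g_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if not np.isfinite(self.angles).all():
            raise ValidationError(f"{self.joint.label}: non-finite angles after imputation")

    @property
    def speeds(self) -> np.ndarray:
        return angular_speed(self.angles, self.sampling_rate)


def _lowpass(data: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    if cutoff is None or cutoff <= 0 or cutoff >= fs / 2:
        return data
    b, a = signal.butter(4, cutoff / (fs / 2))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(data) <= padlen + 1:
        return data
    return signal.filtfilt(b, a, data, axis=0)


def estimate_joint_angle(
    trace: SensorPairTrace, lowpass_hz: float | None = DEFAULT_LOWPASS_HZ
) -> AngleTrace:
    """Joint angle = distal minus proximal sagittal inclination.

    Each sensor's sagittal inclination is ``atan2(a_x, -a_z)`` of its
    (low-pass filtered) gravity components; subtracting the proximal
    (reference) sensor rejects whole-segment compensatory motion.  Assumes
    quasi-static gravity sensing: the traces are low-pass filtered at
    ``lowpass_hz`` (4th-order Butterworth, zero-phase) before the
    inclination is taken.  Imputation must already have been applied.
    """
    if trace.missing_mask.any() and not (
        np.isfinite(trace.proximal).all() and np.isfinite(trace.distal).all()
    ):
        raise ValidationError(f"{trace.joint.label}: impute before estimating angles")
    fs = trace.sampling_rate
    prox = _lowpass(trace.proximal, fs, lowpass_hz)
    dist = _lowpass(trace.distal, fs, lowpass_hz)

    low_g = None
    norms = np.minimum(np.linalg.norm(prox, axis=1), np.linalg.norm(dist, axis=1))
    win = max(int(round(0.5 * fs)), 1)
    if len(norms) >= win:
        below = norms < LOW_G_THRESHOLD
        sustained = np.convolve(below.astype(int), np.ones(win, dtype=int), "same") >= win
        if sustained.any():
            low_g = sustained
            warnings.warn(
                f"{trace.joint.label}: sustained acceleration below "
                f"{LOW_G_THRESHOLD} g; inclination unreliable on flagged samples",
                stacklevel=2,
            )

    incl_p = np.degrees(np.arctan2(prox[:, 0], -prox[:, 2]))
    incl_d = np.degrees(np.arctan2(dist[:, 0], -dist[:, 2]))
    return AngleTrace(trace.joint, incl_d - incl_p, fs, low_g)


def angular_speed(angles: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Angular speed as forward differences x sampling rate (deg/s).

    The last value is repeated so speeds and angles have equal length.
    """
    angles = np.asarray(angles, dtype=float)
    if len(angles) < 2:
        return np.zeros_like(angles)
    d = np.diff(angles) * sampling_rate
    return np.append(d, d[-1])


# ---------------------------------------------------------------------------
# Raw per-trial measurements
# ---------------------------------------------------------------------------


def tracking_error(avatar_trace: np.ndarray, path_positions: np.ndarray) -> float:
    """RMS error between avatar and target path, normalized screen units."""
    avatar = np.asarray(avatar_trace, dtype=float)
    target = np.asarray(path_positions, dtype=float)
    if avatar.shape != target.shape:
        raise ValidationError(
            f"avatar ({avatar.shape}) and path ({target.shape}) are not time-aligned"
        )
    return float(np.sqrt(np.mean((avatar - target) ** 2)))


def movement_metric(speeds: np.ndarray) -> float:
    """Mean absolute angular speed (deg/s) of one nontarget joint."""
    return float(np.mean(np.abs(np.asarray(speeds, dtype=float))))


@dataclass
class SessionMeasurement:
    """Raw (unstandardized) measurements of one trial, test phase only."""

    participant_id: str
    occasion: str
    target_joint: JointId
    error: Optional[float]
    movement: dict[JointId, float]
    excluded: bool = False
    reason: Optional[str] = None


def measure_session(
    session: GameSession,
    lowpass_hz: float | None = DEFAULT_LOWPASS_HZ,
    n_imputations: int = 50,
    seed: int = 0,
) -> SessionMeasurement:
    """Impute, derive angles/speeds, and measure one trial.

    The tracking error and movement metrics are evaluated over the 30 s
    test phase only.  If the *target* joint is untestable the whole trial is
    excluded; an untestable nontarget joint is dropped from the movement
    metrics (the IMS is then averaged over the remaining joints).
    """
    test = session.test_slice
    movement: dict[JointId, float] = {}
    error: Optional[float] = None
    for ji, jid in enumerate(all_joints()):
        try:
            tr = impute_trace(
                session.traces[jid], n_imputations=n_imputations, seed=seed + 101 * ji
            )
        except UntestableJointError as exc:
            if jid == session.target_joint:
                return SessionMeasurement(
                    session.participant_id,
                    session.occasion,
                    session.target_joint,
                    None,
                    {},
                    excluded=True,
                    reason=str(exc),
                )
            continue
        if jid != session.target_joint:
            at = estimate_joint_angle(tr, lowpass_hz=lowpass_hz)
            movement[jid] = movement_metric(at.speeds[test])
    error = tracking_error(session.avatar_trace, session.path.positions)
    return SessionMeasurement(
        session.participant_id, session.occasion, session.target_joint, error, movement
    )


# ---------------------------------------------------------------------------
# Adult reference and standardized scores
# ---------------------------------------------------------------------------


def _context_key(target: JointId, pooled: bool) -> str:
    return target.joint if pooled else target.label


def _nontarget_key(target: JointId, nontarget: JointId, pooled: bool) -> str:
    if not pooled:
        return nontarget.label
    rel = "ipsi" if nontarget.side == target.side else "contra"
    return f"{rel}_{nontarget.joint}"


@dataclass
class ReferenceStats:
    """Adult-cohort means and SDs used to standardize the two scores.

    With ``pooled=True`` (default) the left/right target trials of each
    joint are pooled via mirroring, so every context is backed by the full
    adult cohort; nontarget joints are then keyed by their relation to the
    target (ipsi-/contralateral x joint).
    """

    err: dict[str, tuple[float, float]]
    move: dict[str, dict[str, tuple[float, float]]]
    n_adults: int
    pooled: bool = True

    def error_stats(self, target: JointId) -> tuple[float, float]:
        return self.err[_context_key(target, self.pooled)]

    def movement_stats(self, target: JointId, nontarget: JointId) -> tuple[float, float]:
        ctx = _context_key(target, self.pooled)
        return self.move[ctx][_nontarget_key(target, nontarget, self.pooled)]

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "n_adults": self.n_adults,
            "pooled": self.pooled,
            "error": {k: {"mean": m, "sd": s} for k, (m, s) in self.err.items()},
            "movement": {
                k: {kk: {"mean": m, "sd": s} for kk, (m, s) in v.items()}
                for k, v in self.move.items()
            },
        }
        p = Path(path)
        p.write_text(json.dumps(doc, indent=1))
        return p

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceStats":
        doc = json.loads(Path(path).read_text())
        return cls(
            err={k: (v["mean"], v["sd"]) for k, v in doc["error"].items()},
            move={
                k: {kk: (vv["mean"], vv["sd"]) for kk, vv in v.items()}
                for k, v in doc["movement"].items()
            },
            n_adults=int(doc["n_adults"]),
            pooled=bool(doc["pooled"]),
        )


def build_reference(
    measurements: Iterable[SessionMeasurement],
    n_adults: Optional[int] = None,
    pooled: bool = True,
) -> ReferenceStats:
    """Sample means and SDs (ddof=1) of the adult cohort, per context.

    Requires at least 3 adult trials per target-joint context; a zero SD
    anywhere raises :class:`DegenerateReferenceError`.
    """
    errs: dict[str, list[float]] = {}
    moves: dict[str, dict[str, list[float]]] = {}
    participants = set()
    ctx_participants: dict[str, set] = {}
    for m in measurements:
        if m.excluded or m.error is None:
            continue
        participants.add(m.participant_id)
        ctx = _context_key(m.target_joint, pooled)
        ctx_participants.setdefault(ctx, set()).add(m.participant_id)
        errs.setdefault(ctx, []).append(m.error)
        for jid, val in m.movement.items():
            key = _nontarget_key(m.target_joint, jid, pooled)
            moves.setdefault(ctx, {}).setdefault(key, []).append(val)

    for ctx, pids in ctx_participants.items():
        if len(pids) < 3:
            raise ValidationError(f"reference context {ctx}: need >= 3 adults")

    def stats(vals: Sequence[float], what: str) -> tuple[float, float]:
        if len(vals) < 3:
            raise ValidationError(f"reference context {what}: need >= 3 adult trials")
        mu = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if sd <= 0:
            raise DegenerateReferenceError(f"reference context {what}: SD is zero")
        return mu, sd

    err = {k: stats(v, k) for k, v in errs.items()}
    move = {k: {kk: stats(vv, f"{k}/{kk}") for kk, vv in v.items()} for k, v in moves.items()}
    return ReferenceStats(err, move, n_adults or len(participants), pooled)


def accuracy_score(
    error: float, ref: ReferenceStats, target: JointId, centered: bool = False
) -> float:
    """Tracking error standardized to the adult SD (optionally centered)."""
    mu, sd = ref.error_stats(target)
    return (error - (mu if centered else 0.0)) / sd


def involuntary_movement_score(
    metrics: Mapping[JointId, float], ref: ReferenceStats, target: JointId
) -> float:
    """Mean z-score of the nontarget joints' movement vs the adult reference.

    Not clipped: adult-typical fidgeting below the reference mean yields a
    (slightly) negative score.
    """
    if not metrics:
        raise ValidationError("IMS needs at least one nontarget joint metric")
    z = [
        (m - mu) / sd
        for jid, m in metrics.items()
        for mu, sd in [ref.movement_stats(target, jid)]
    ]
    return float(np.mean(z))


# ---------------------------------------------------------------------------
# Score sets and summaries
# ---------------------------------------------------------------------------

SUMMARY_KEYS = ("more_affected", "less_affected", "total")


def summarize_scores(
    per_joint: Mapping[JointId, float],
    affected: AffectedSideMap,
    excluded: Iterable[JointId] = (),
) -> dict[str, Optional[float]]:
    """Leg means (more/less affected) and the overall mean of available joints.

    A leg whose joints are all excluded gets ``None`` (summary missing).
    """
    excluded = set(excluded)
    available = {j: v for j, v in per_joint.items() if j not in excluded}
    out: dict[str, Optional[float]] = {}
    for key, side in (
        ("more_affected", affected.more_affected),
        ("less_affected", affected.less_affected),
    ):
        vals = [v for j, v in available.items() if j.side == side]
        out[key] = float(np.mean(vals)) if vals else None
    out["total"] = float(np.mean(list(available.values()))) if available else None
    return out


@dataclass
class ScoreSet:
    """Per-joint accuracy and IMS plus leg/total summaries for one occasion."""

    participant_id: str
    occasion: str
    affected: AffectedSideMap
    accuracy: dict[JointId, float] = field(default_factory=dict)
    ims: dict[JointId, float] = field(default_factory=dict)
    joints_excluded: dict[JointId, str] = field(default_factory=dict)

    def summary(self, score: str) -> dict[str, Optional[float]]:
        per_joint = {"accuracy": self.accuracy, "ims": self.ims}[score]
        return summarize_scores(per_joint, self.affected, self.joints_excluded)


def build_scoreset(
    measurements: Iterable[SessionMeasurement],
    ref: ReferenceStats,
    affected: AffectedSideMap,
    centered_accuracy: bool = False,
) -> ScoreSet:
    """Standardize one participant-occasion's trial measurements."""
    ms = list(measurements)
    if not ms:
        raise ValidationError("no measurements to score")
    pid = ms[0].participant_id
    occ = ms[0].occasion
    ss = ScoreSet(pid, occ, affected)
    for m in ms:
        if m.participant_id != pid or m.occasion != occ:
            raise ValidationError("measurements mix participants or occasions")
        if m.excluded or m.error is None:
            ss.joints_excluded[m.target_joint] = m.reason or "untestable"
            continue
        ss.accuracy[m.target_joint] = accuracy_score(
            m.error, ref, m.target_joint, centered=centered_accuracy
        )
        ss.ims[m.target_joint] = involuntary_movement_score(m.movement, ref, m.target_joint)
    return ss


def scores_to_frame(scoresets: Iterable[ScoreSet]) -> pd.DataFrame:
    """Long-format score table with per-joint rows and summary rows."""
    rows = []
    for ss in scoresets:
        for jid in all_joints():
            if jid in ss.joints_excluded:
                rows.append(
                    {
                        "participant_id": ss.participant_id,
                        "occasion": ss.occasion,
                        "side": jid.side,
                        "joint": jid.joint,
                        "accuracy": np.nan,
                        "ims": np.nan,
                        "excluded": 1,
                        "reason": ss.joints_excluded[jid],
                    }
                )
            elif jid in ss.accuracy:
                rows.append(
                    {
                        "participant_id": ss.participant_id,
                        "occasion": ss.occasion,
                        "side": jid.side,
                        "joint": jid.joint,
                        "accuracy": ss.accuracy[jid],
                        "ims": ss.ims.get(jid, np.nan),
                        "excluded": 0,
                        "reason": "",
                    }
                )
        acc = ss.summary("accuracy")
        ims = ss.summary("ims")
        for key in SUMMARY_KEYS:
            rows.append(
                {
                    "participant_id": ss.participant_id,
                    "occasion": ss.occasion,
                    "side": key,
                    "joint": "summary",
                    "accuracy": np.nan if acc[key] is None else acc[key],
                    "ims": np.nan if ims[key] is None else ims[key],
                    "excluded": 0,
                    "reason": "",
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "AngleTrace",
    "DegenerateReferenceError",
    "ReferenceStats",
    "ScoreSet",
    "SessionMeasurement",
    "UntestableJointError",
    "accuracy_score",
    "angular_speed",
    "build_reference",
    "build_scoreset",
    "estimate_joint_angle",
    "impute_missing",
    "impute_trace",
    "involuntary_movement_score",
    "measure_session",
    "movement_metric",
    "scores_to_frame",
    "summarize_scores",
    "tracking_error",
]
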