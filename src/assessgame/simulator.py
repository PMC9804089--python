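"""Synthetic cohorts for the selective-motor-control game.

Generates the three groups of the study design — a neurologically intact
adult reference cohort, neurologically intact children (controls), and
children with impaired selective control (patients) — with a test-retest
repetition for the patients, plus synthetic clinical comparator ratings.

Each participant carries latent impairment parameters:

* ``sigma_track`` — SD of the avatar tracking error (normalized screen
  units) injected on top of the target path,
* ``lag`` — reaction delay in seconds,
* coupling gains ``c_mirror`` / ``c_adjacent`` / ``c_other`` — how strongly
  a nontarget joint co-moves with the target joint (contralateral
  homologue, ipsilateral neighbour, and any remaining joint respectively),
* ``fidget_sd`` — baseline band-limited angular-speed noise (deg/s) present
  in every joint, so the adult reference has nonzero SDs,
* ``trunk`` — a latent trunk-involvement variable visible to the therapist
  rating but not to the six joint sensors.

The latent truth is retained for every generated session, which makes
parameter-recovery checks possible (injected coupling should come back as
a high involuntary-movement score, injected tracking noise as a high
accuracy score).

The sensor model is pure gravity sensing (no linear-acceleration artifact)
plus white noise, so the scoring module's inclination inversion is exact up
to noise, and short MCAR sensor dropouts emulate the occasional recording
breakdowns seen in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .game_engine import calibrate_rom, generate_target_path
from .session_model import (
    AffectedSideMap,
    ClinicalRatings,
    GameSession,
    JointId,
    SensorPairTrace,
    TargetPath,
    all_joints,
)

_ADJACENT = {("hip", "knee"), ("knee", "hip"), ("knee", "ankle"), ("ankle", "knee")}


@dataclass
class SimulationConfig:
    """Study-design parameters and latent-impairment distributions.

    Cohort sizes and phase timings follow the study design this package
    emulates (31 adults, 31 control children, 20 patients; 25 s
    accommodation + 30 s test at 50 Hz).  The lognormal location/scale
    pairs below define the per-participant latent parameter draws.
    """

    n_adults: int = 31
    n_controls: int = 31
    n_patients: int = 20
    seed: int = 0

    sampling_rate: float = 50.0
    accommodation_duration: float = 25.0
    test_duration: float = 30.0
    n_curves: int = 3
    star_interval: float = 2.0
    usable_fraction: float = 0.9

    sensor_noise_sd: float = 0.02  # g
    proximal_wobble_sd: float = 0.3  # deg
    missing_rate: float = 0.008  # MCAR dropout fraction per sensor
    fidget_sd_median: float = 1.0  # deg/s
    fidget_sd_sigma: float = 0.3

    # age ranges (years)
    adult_age_range: tuple[float, float] = (18.0, 50.0)
    control_age_range: tuple[float, float] = (6.0, 18.0)
    patient_age_range: tuple[float, float] = (7.9, 17.4)

    # tracking noise sigma_track (normalized screen units), lognormal(median, sigma)
    adult_sigma_track: tuple[float, float] = (0.035, 0.70)
    control_sigma_track: tuple[float, float] = (0.035, 0.40)
    patient_sigma_track: tuple[float, float] = (0.055, 0.40)
    #: cutoff (Hz) of the tracking-error noise: tracking errors are slow
    #: drifts away from the path, not sample-to-sample jitter
    tracking_noise_cutoff: float = 0.3
    # reaction lag (s), uniform ranges
    adult_lag: tuple[float, float] = (0.03, 0.10)
    child_lag: tuple[float, float] = (0.04, 0.12)

    # coupling gains, lognormal(median, sigma)
    adult_coupling: tuple[float, float] = (0.004, 0.5)
    control_coupling: tuple[float, float] = (0.025, 0.5)
    patient_mirror: float = 0.26
    patient_adjacent: float = 0.16
    patient_other: float = 0.06
    #: one latent severity factor scales all three coupling gains of a
    #: patient (lognormal sigma), with a small independent per-type jitter
    patient_severity_sigma: float = 0.60
    patient_coupling_jitter: float = 0.12
    #: log-linear decrease of control children's coupling/tracking noise with
    #: age (per year, centered at 12 y): the maturation trend
    coupling_maturation_rate: float = 0.15
    tracking_maturation_rate: float = 0.05

    #: multiplier applied to impairment when the target joint is on the more
    #: affected side (patients), lognormal(median, sigma)
    patient_asymmetry: tuple[float, float] = (1.3, 0.10)
    trunk_latent: tuple[float, float] = (0.10, 0.8)

    #: SD of the multiplicative lognormal perturbation of latent parameters
    #: between the test and retest occasions
    occasion_noise: float = 0.15
    retest_groups: tuple[str, ...] = ("patient",)

    # ROM draw (deg): span uniform range and midpoint uniform range per joint
    rom_span_range: tuple[float, float] = (35.0, 65.0)
    rom_mid_range: tuple[float, float] = (15.0, 35.0)

    # comparator-rating thresholds on the latent impairment index
    scale_thresholds: tuple[float, float] = (0.85, 1.35)
    gmfcs_thresholds: tuple[float, float, float] = (0.80, 1.10, 1.45)
    therapist_mirror_threshold: float = 0.22
    therapist_adjacent_threshold: float = 0.13
    therapist_trunk_threshold: float = 0.12
    therapist_trial_noise: float = 0.35

    def to_yaml(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        from pathlib import Path

        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in doc.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown simulation config key {k!r}")
            default = getattr(cfg, k)
            if isinstance(default, tuple):
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg


@dataclass
class ParticipantLatent:
    """Latent impairment parameters of one participant at one occasion."""

    participant_id: str
    group: str  # adult | control | patient
    occasion: str
    age: float
    sigma_track: float
    lag: float
    c_mirror: float
    c_adjacent: float
    c_other: float
    fidget_sd: float
    trunk: float
    asymmetry: float
    affected: AffectedSideMap
    rom: dict[JointId, tuple[float, float]] = field(default_factory=dict)

    @property
    def mean_coupling(self) -> float:
        return (self.c_mirror + self.c_adjacent + self.c_other) / 3.0


@dataclass
class StudyData:
    """One simulated study: sessions, latent truth, and comparator ratings."""

    config: SimulationConfig
    sessions: list[GameSession]
    latents: pd.DataFrame
    ratings: list[ClinicalRatings]
    affected: dict[str, AffectedSideMap]

    def sessions_of(self, participant_id: str, occasion: str) -> list[GameSession]:
        return [
            s
            for s in self.sessions
            if s.participant_id == participant_id and s.occasion == occasion
        ]


# ---------------------------------------------------------------------------
# Signal helpers
# ---------------------------------------------------------------------------


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, sd: float, cutoff: float = 2.0
) -> np.ndarray:
    """Low-pass filtered white noise rescaled to an exact sample SD."""
    if sd <= 0 or n < 32:
        return np.zeros(n)
    b, a = signal.butter(2, min(cutoff / (fs / 2), 0.99))
    x = signal.filtfilt(b, a, rng.standard_normal(n))
    s = x.std()
    return x * (sd / s) if s > 0 else np.zeros(n)


def _inclination_to_accel(
    rng: np.random.Generator, incl_deg: np.ndarray, noise_sd: float
) -> np.ndarray:
    """Pure-gravity 3-axis accelerometer reading of a segment inclination."""
    rad = np.radians(incl_deg)
    a = np.column_stack([np.sin(rad), np.zeros_like(rad), -np.cos(rad)])
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    return a


def _dropout_mask(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Short MCAR dropout runs totalling about ``rate`` of the samples."""
    mask = np.zeros(n, dtype=bool)
    if rate <= 0:
        return mask
    target = rate * n
    while mask.sum() < target:
        start = int(rng.integers(0, n))
        length = 1 + int(rng.geometric(0.4))
        mask[start : min(start + length, n)] = True
    return mask


def _coupling_gain(latent: ParticipantLatent, target: JointId, other: JointId) -> float:
    if other == target.mirrored():
        return latent.c_mirror
    if other.side == target.side and (target.joint, other.joint) in _ADJACENT:
        return latent.c_adjacent
    return latent.c_other


# ---------------------------------------------------------------------------
# Session-level simulation
# ---------------------------------------------------------------------------


def simulate_session(
    latent: ParticipantLatent,
    target_joint: JointId,
    path: TargetPath,
    seed: int,
    config: Optional[SimulationConfig] = None,
    sensor_seed: Optional[int] = None,
) -> GameSession:
    """Simulate one trial of one participant.

    The target joint's angle is the inverse screen map of the target path,
    delayed by the participant's lag and perturbed by band-limited tracking
    noise of SD ``sigma_track``; every nontarget joint co-moves with gain
    given by the coupling latent (mirror / adjacent / other) on top of its
    fidget noise.  Deterministic for a fixed seed.

    ``seed`` drives the behavioural draws (tracking noise, fidget, wander);
    ``sensor_seed`` (defaults to ``seed + 1``) drives the measurement layer
    (sensor noise, wobble, dropouts).  Repeating a trial with the same
    ``seed`` but a fresh ``sensor_seed`` replays the same performance under
    new measurement noise, so test-retest disagreement is controlled
    entirely by the latent occasion perturbation plus sensor noise.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    rng_noise = np.random.default_rng(seed + 1 if sensor_seed is None else sensor_seed)
    fs = cfg.sampling_rate
    n_test = len(path.positions)
    n_acc = int(round(cfg.accommodation_duration * fs))
    n = n_acc + n_test

    side_mult = (
        latent.asymmetry if target_joint.side == latent.affected.more_affected else 1.0
    )

    amin, amax = latent.rom[target_joint]
    mapping = calibrate_rom(amin, amax, cfg.usable_fraction, joint=target_joint)

    # avatar over the test phase: delayed path + band-limited tracking noise
    lag_samples = int(round(latent.lag * fs))
    delayed = np.concatenate([np.full(lag_samples, path.positions[0]), path.positions])[
        :n_test
    ]
    noise = _bandlimited_noise(
        rng, n_test, fs, latent.sigma_track * side_mult, cutoff=cfg.tracking_noise_cutoff
    )
    avatar = np.clip(delayed + noise, 0.0, 1.0)
    angle_test = mapping.to_angle(avatar)

    # accommodation: slow wander around the ROM midpoint, blended into the
    # first test-phase angle over the final second
    mid = 0.5 * (amin + amax)
    wander = mid + _bandlimited_noise(rng, n_acc, fs, 0.1 * (amax - amin), cutoff=0.5)
    blend = min(int(round(1.0 * fs)), n_acc)
    if blend > 0:
        wts = np.linspace(0.0, 1.0, blend)
        wander[-blend:] = (1 - wts) * wander[-blend:] + wts * angle_test[0]
    angle_target = np.concatenate([wander, angle_test])

    traces: dict[JointId, SensorPairTrace] = {}
    excursion = angle_target - angle_target[0]
    for jid in all_joints():
        if jid == target_joint:
            angle = angle_target
        else:
            gain = _coupling_gain(latent, target_joint, jid) * side_mult
            fidget_speed = _bandlimited_noise(rng, n, fs, latent.fidget_sd)
            fidget = np.cumsum(fidget_speed) / fs
            angle = gain * excursion + fidget
        prox_incl = _bandlimited_noise(rng_noise, n, fs, cfg.proximal_wobble_sd, cutoff=1.0)
        dist_incl = prox_incl + angle
        prox = _inclination_to_accel(rng_noise, prox_incl, cfg.sensor_noise_sd)
        dist = _inclination_to_accel(rng_noise, dist_incl, cfg.sensor_noise_sd)
        mm = np.column_stack(
            [
                _dropout_mask(rng_noise, n, cfg.missing_rate),
                _dropout_mask(rng_noise, n, cfg.missing_rate),
            ]
        )
        prox[mm[:, 0]] = 0.0  # a dropped-out sensor reports nothing useful
        dist[mm[:, 1]] = 0.0
        traces[jid] = SensorPairTrace(jid, prox, dist, fs, mm)

    return GameSession(
        participant_id=latent.participant_id,
        occasion=latent.occasion,
        target_joint=target_joint,
        calibration=mapping.calibration,
        path=path,
        traces=traces,
        avatar_trace=avatar,
        accommodation_duration=cfg.accommodation_duration,
    )


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def _draw_latent(
    rng: np.random.Generator, pid: str, group: str, cfg: SimulationConfig
) -> ParticipantLatent:
    if group == "adult":
        age = float(rng.uniform(*cfg.adult_age_range))
        sigma_track = _lognormal(rng, *cfg.adult_sigma_track)
        lag = float(rng.uniform(*cfg.adult_lag))
        c = [_lognormal(rng, *cfg.adult_coupling) for _ in range(3)]
        asym = 1.0
        trunk = 0.0
    elif group == "control":
        age = float(rng.uniform(*cfg.control_age_range))
        mat = float(np.exp(-cfg.coupling_maturation_rate * (age - 12.0)))
        tmat = float(np.exp(-cfg.tracking_maturation_rate * (age - 12.0)))
        sigma_track = _lognormal(rng, *cfg.control_sigma_track) * tmat
        lag = float(rng.uniform(*cfg.child_lag))
        base = cfg.control_coupling
        c = [
            _lognormal(rng, base[0], base[1]) * mat,
            _lognormal(rng, base[0] * 0.7, base[1]) * mat,
            _lognormal(rng, base[0] * 0.3, base[1]) * mat,
        ]
        asym = 1.0
        trunk = _lognormal(rng, cfg.trunk_latent[0] * 0.3, cfg.trunk_latent[1])
    elif group == "patient":
        age = float(rng.uniform(*cfg.patient_age_range))
        sigma_track = _lognormal(rng, *cfg.patient_sigma_track)
        lag = float(rng.uniform(*cfg.child_lag))
        severity = _lognormal(rng, 1.0, cfg.patient_severity_sigma)
        c = [
            severity * _lognormal(rng, m, cfg.patient_coupling_jitter)
            for m in (cfg.patient_mirror, cfg.patient_adjacent, cfg.patient_other)
        ]
        asym = _lognormal(rng, *cfg.patient_asymmetry)
        trunk = _lognormal(rng, *cfg.trunk_latent)
    else:
        raise ValueError(f"unknown group {group!r}")

    fidget = _lognormal(rng, cfg.fidget_sd_median, cfg.fidget_sd_sigma)
    affected = AffectedSideMap("left" if rng.random() < 0.5 else "right")
    rom = {}
    for jid in all_joints():
        span = float(rng.uniform(*cfg.rom_span_range))
        mid = float(rng.uniform(*cfg.rom_mid_range))
        rom[jid] = (mid - span / 2.0, mid + span / 2.0)
    return ParticipantLatent(
        participant_id=pid,
        group=group,
        occasion="test",
        age=age,
        sigma_track=sigma_track,
        lag=lag,
        c_mirror=c[0],
        c_adjacent=c[1],
        c_other=c[2],
        fidget_sd=fidget,
        trunk=trunk,
        asymmetry=asym,
        affected=affected,
        rom=rom,
    )


def _perturb_for_retest(
    rng: np.random.Generator, latent: ParticipantLatent, occasion_noise: float
) -> ParticipantLatent:
    def jitter(x: float) -> float:
        if occasion_noise <= 0:
            return x
        return float(x * np.exp(occasion_noise * rng.standard_normal()))

    return replace(
        latent,
        occasion="retest",
        sigma_track=jitter(latent.sigma_track),
        c_mirror=jitter(latent.c_mirror),
        c_adjacent=jitter(latent.c_adjacent),
        c_other=jitter(latent.c_other),
        fidget_sd=jitter(latent.fidget_sd),
        trunk=jitter(latent.trunk),
    )


def _latent_row(lat: ParticipantLatent) -> dict:
    return {
        "participant_id": lat.participant_id,
        "group": lat.group,
        "occasion": lat.occasion,
        "age": lat.age,
        "sigma_track": lat.sigma_track,
        "lag": lat.lag,
        "c_mirror": lat.c_mirror,
        "c_adjacent": lat.c_adjacent,
        "c_other": lat.c_other,
        "mean_coupling": lat.mean_coupling,
        "fidget_sd": lat.fidget_sd,
        "trunk": lat.trunk,
        "asymmetry": lat.asymmetry,
        "more_affected": lat.affected.more_affected,
    }


def _rate_patient(
    rng: np.random.Generator, lat: ParticipantLatent, cfg: SimulationConfig
) -> ClinicalRatings:
    """Threshold the latent impairment into SCALE / GMFCS / therapist counts."""
    scale: dict[JointId, Optional[int]] = {}
    impair_values = []
    for jid in all_joints():
        mult = lat.asymmetry if jid.side == lat.affected.more_affected else 1.0
        impair = (
            0.5 * (lat.sigma_track / 0.055) + 0.5 * ((lat.c_mirror + lat.c_adjacent) / 0.48)
        ) * mult + float(rng.normal(0.0, 0.15))
        impair_values.append(impair)
        t1, t2 = cfg.scale_thresholds
        scale[jid] = 2 if impair < t1 else (1 if impair < t2 else 0)
    g = float(np.mean(impair_values))
    g1, g2, g3 = cfg.gmfcs_thresholds
    gmfcs = 1 + (g >= g1) + (g >= g2) + (g >= g3)

    counts: dict[JointId, int] = {}
    for jid in all_joints():
        mult = lat.asymmetry if jid.side == lat.affected.more_affected else 1.0
        tn = cfg.therapist_trial_noise

        def seen(value: float, threshold: float) -> bool:
            return value * float(np.exp(tn * rng.standard_normal())) > threshold

        types = set()
        if seen(lat.c_mirror * mult, cfg.therapist_mirror_threshold):
            types.add("mirror")
        if seen(lat.c_adjacent * mult, cfg.therapist_adjacent_threshold):
            types.add("other_joint")
        if seen(lat.trunk, cfg.therapist_trunk_threshold):
            types.add("trunk")
        counts[jid] = len(types)
    return ClinicalRatings(
        participant_id=lat.participant_id,
        occasion=lat.occasion,
        gmfcs=int(gmfcs),
        scale=scale,
        therapist_counts=counts,
    )


def simulate_cohorts(config: Optional[SimulationConfig] = None) -> StudyData:
    """Simulate the full study: all groups, 6 target joints, retest occasions.

    Control children's latent coupling (and, more weakly, tracking noise)
    decreases log-linearly with age — the maturation trend; patients are
    drawn with larger tracking noise and coupling gains.  Synthetic SCALE,
    GMFCS and therapist ratings are produced for the patients by
    thresholding the latent impairment.
    """
    cfg = config or SimulationConfig()
    root = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    groups = (
        [("adult", i) for i in range(cfg.n_adults)]
        + [("control", i) for i in range(cfg.n_controls)]
        + [("patient", i) for i in range(cfg.n_patients)]
    )
    sessions: list[GameSession] = []
    latent_rows: list[dict] = []
    ratings: list[ClinicalRatings] = []
    affected: dict[str, AffectedSideMap] = {}

    for group, i in groups:
        pid = f"{group[:3]}{i + 1:03d}"
        prng = np.random.default_rng(root.integers(2**31))
        lat = _draw_latent(prng, pid, group, cfg)
        affected[pid] = lat.affected
        occasions = [lat]
        if group in cfg.retest_groups:
            occasions.append(_perturb_for_retest(prng, lat, cfg.occasion_noise))
        # one behavioural seed and path per trial, shared across occasions:
        # the retest differs through the latent perturbation and fresh
        # measurement noise, not through a resampled performance
        paths = {}
        trial_seeds = {}
        for jid in all_joints():
            paths[jid] = generate_target_path(
                duration=cfg.test_duration,
                n_curves=cfg.n_curves,
                seed=int(prng.integers(2**31)),
                sampling_rate=cfg.sampling_rate,
                star_interval=cfg.star_interval,
            )
            trial_seeds[jid] = int(prng.integers(2**31))
        for occ_lat in occasions:
            latent_rows.append(_latent_row(occ_lat))
            if group == "patient":
                ratings.append(_rate_patient(prng, occ_lat, cfg))
            for jid in all_joints():
                sessions.append(
                    simulate_session(
                        occ_lat,
                        jid,
                        paths[jid],
                        seed=trial_seeds[jid],
                        config=cfg,
                        sensor_seed=int(prng.integers(2**31)),
                    )
                )

    return StudyData(
        config=cfg,
        sessions=sessions,
        latents=pd.DataFrame(latent_rows),
        ratings=ratings,
        affected=affected,
    )


__all__ = [
    "ParticipantLatent",
    "SimulationConfig",
    "StudyData",
    "simulate_cohorts",
    "simulate_session",
]
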