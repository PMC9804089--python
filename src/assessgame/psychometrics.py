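"""Validity and reliability statistics for the game scores.

Covers the full battery used to evaluate the assessment:

* relative test-retest reliability: ICC(2,1) — two-way random effects,
  absolute agreement, single measure — with BCa bootstrap CIs,
* absolute reliability: SEM = sqrt(trial variance + residual error
  variance), MDC95 = 1.96 * sqrt(2) * SEM, MDC as a percentage of the
  test/retest grand mean, and the fraction of participants who could
  improve by the MDC without passing the best possible score of 0,
* concurrent validity: tie-corrected rank correlations (Spearman for
  summary scores, Kendall tau-b for individual joints) with magnitude
  bands,
* discriminative validity: a robust bootstrapped ANCOVA comparing two
  groups at fixed age design points via a running-interval smoother,
* the a-priori power computation for the smallest detectable correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_DESIGN_POINTS = (9.5, 12.5, 15.5)

#: magnitude bands for rank correlation coefficients
CORRELATION_BANDS = (
    (0.00, 0.29, "negligible"),
    (0.30, 0.49, "low"),
    (0.50, 0.69, "moderate"),
    (0.70, 0.89, "high"),
    (0.90, 1.00, "very high"),
)


class DegenerateStatisticError(ValueError):
    """The requested statistic is undefined on the given data."""


# ---------------------------------------------------------------------------
# ICC(2,1) and absolute reliability
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityResult:
    """Relative and absolute test-retest reliability of one score."""

    icc: float
    icc_ci: tuple[float, float]
    var_subject: float
    var_trial: float
    var_error: float
    sem: float
    mdc95: float
    mdc_pct_grand_mean: Optional[int]
    wilcoxon_p: float
    mean_test: float
    mean_retest: float
    n_subjects: int
    n_boot: int
    ci_outside_point: bool = False  # BCa CI can exclude the point estimate

    @property
    def band(self) -> str:
        return classify_icc(self.icc)


def icc_2_1(scores: np.ndarray) -> tuple[float, dict[str, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``scores`` is an ``n_subjects x k`` matrix (k=2 for test/retest) with no
    missing cells.  Returns the ICC and the ANOVA variance components
    (subject, trial, residual error); negative component estimates are
    reported as computed — truncation to zero is the caller's decision.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise DegenerateStatisticError("need an n x k matrix with k >= 2")
    if np.isnan(x).any():
        raise DegenerateStatisticError("missing cells; drop incomplete subjects first")
    n, k = x.shape
    if n < 3:
        raise DegenerateStatisticError("need at least 3 subjects")
    grand = x.mean()
    if np.allclose(x, grand):
        raise DegenerateStatisticError("zero total variance; ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))
    components = {
        "var_subject": (ms_r - ms_e) / k,
        "var_trial": (ms_c - ms_e) / n,
        "var_error": ms_e,
    }
    return float(icc), components


def sem_mdc(var_trial: float, var_error: float) -> tuple[float, float]:
    """SEM = sqrt(trial + residual error variance); MDC95 = 1.96*sqrt(2)*SEM.

    Components must be nonnegative: ANOVA estimates below zero must be
    truncated to 0 by the caller, explicitly.
    """
    if var_trial < 0 or var_error < 0:
        raise DegenerateStatisticError(
            "variance components must be >= 0 (truncate negative ANOVA estimates first)"
        )
    sem = math.sqrt(var_trial + var_error)
    return sem, 1.96 * math.sqrt(2.0) * sem


def mdc_percent_grand_mean(mean_test: float, mean_retest: float, mdc95: float) -> int:
    """MDC95 as an integer percentage of the test/retest grand mean."""
    grand = 0.5 * (mean_test + mean_retest)
    if grand <= 0:
        raise DegenerateStatisticError("grand mean must be positive")
    return int(round(100.0 * mdc95 / grand))


def improvable_fraction(scores: Sequence[float], mdc95: float) -> tuple[float, int]:
    """Fraction (and count) of participants who could improve by the MDC.

    A participant can improve if reducing their score by the MDC does not
    pass 0, the best possible score: ``score - mdc95 >= 0``.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise DegenerateStatisticError("no scores given")
    if (s < 0).any():
        raise DegenerateStatisticError("scores must be >= 0")
    n_ok = int(np.sum(s - mdc95 >= 0))
    return n_ok / s.size, n_ok


def wilcoxon_signed_rank(test: Sequence[float], retest: Sequence[float]) -> float:
    """Two-tailed p of the signed-rank test for a systematic test-retest shift.

    Zero differences are dropped; the exact distribution is used for n <= 25
    without ties in the absolute differences, the normal approximation with
    tie correction otherwise.  All-zero differences give p = 1 with a warning.
    """
    d = np.asarray(test, dtype=float) - np.asarray(retest, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all test-retest differences are zero", stacklevel=2)
        return 1.0
    if d.size < 5:
        raise DegenerateStatisticError("need >= 5 nonzero paired differences")
    has_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    return float(stats.wilcoxon(d, method=method).pvalue)


def reliability_analysis(
    test: Sequence[float],
    retest: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> ReliabilityResult:
    """Full test-retest reliability of one score.

    Subjects with a missing value on either occasion are excluded listwise.
    Negative trial/error variance components are truncated to 0 (with a
    warning) before the SEM.
    """
    x = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    x = x[~np.isnan(x).any(axis=1)]
    icc, comp = icc_2_1(x)
    lo, hi = bca_ci(lambda m: icc_2_1(m)[0], x, n_boot=n_boot, level=level, seed=seed)
    var_t, var_e = comp["var_trial"], comp["var_error"]
    if var_t < 0 or var_e < 0:
        warnings.warn("negative variance component estimate truncated to 0", stacklevel=2)
        var_t, var_e = max(var_t, 0.0), max(var_e, 0.0)
    sem, mdc95 = sem_mdc(var_t, var_e)
    try:
        wilcoxon_p = wilcoxon_signed_rank(x[:, 0], x[:, 1])
    except DegenerateStatisticError:
        warnings.warn("too few nonzero differences for the signed-rank test", stacklevel=2)
        wilcoxon_p = float("nan")
    mean_test, mean_retest = float(x[:, 0].mean()), float(x[:, 1].mean())
    grand = 0.5 * (mean_test + mean_retest)
    mdc_pct = mdc_percent_grand_mean(mean_test, mean_retest, mdc95) if grand > 0 else None
    return ReliabilityResult(
        icc=icc,
        icc_ci=(lo, hi),
        var_subject=comp["var_subject"],
        var_trial=var_t,
        var_error=var_e,
        sem=sem,
        mdc95=mdc95,
        mdc_pct_grand_mean=mdc_pct,
        wilcoxon_p=wilcoxon_p,
        mean_test=mean_test,
        mean_retest=mean_retest,
        n_subjects=len(x),
        n_boot=n_boot,
        ci_outside_point=not (lo <= icc <= hi),
    )


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------


def bca_ci(
    statistic_fn: Callable[[np.ndarray], float],
    data: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    force_zero_bias_accel: bool = False,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI of a subject-level statistic.

    ``data`` holds one row per subject; replicates resample whole rows.  The
    bias correction comes from the fraction of replicates below the point
    estimate and the acceleration from jackknife skewness.  With
    ``force_zero_bias_accel`` the interval reduces to the plain percentile
    interval.  Deterministic for a fixed seed.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = len(x)
    if n < 3:
        raise DegenerateStatisticError("need at least 3 subjects for a bootstrap CI")
    theta = float(statistic_fn(x))
    rng = np.random.default_rng(seed)

    reps = np.empty(n_boot)
    failed = 0
    for i in range(n_boot):
        sample = x[rng.integers(0, n, size=n)]
        try:
            reps[i] = float(statistic_fn(sample))
        except Exception:
            reps[i] = np.nan
            failed += 1
    if failed > 0.10 * n_boot:
        raise DegenerateStatisticError(
            f"statistic undefined on {failed / n_boot:.0%} of bootstrap replicates"
        )
    reps = reps[~np.isnan(reps)]
    if np.allclose(reps, reps[0]) and np.isclose(theta, reps[0]):
        return theta, theta

    alpha = 1.0 - level
    if force_zero_bias_accel:
        z0 = 0.0
        a = 0.0
    else:
        prop = np.mean(reps < theta) + 0.5 * np.mean(reps == theta)
        prop = min(max(prop, 1.0 / (len(reps) + 1)), 1.0 - 1.0 / (len(reps) + 1))
        z0 = stats.norm.ppf(prop)
        try:
            jack = np.array([float(statistic_fn(np.delete(x, i, axis=0))) for i in range(n)])
            jm = jack.mean()
            num = np.sum((jm - jack) ** 3)
            den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
            a = num / den if den > 0 else 0.0
        except Exception:
            warnings.warn(
                "jackknife undefined on leave-one-out samples; acceleration set to 0",
                stacklevel=2,
            )
            a = 0.0

    def adj(q: float) -> float:
        z = stats.norm.ppf(q)
        return float(stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z))))

    lo = float(np.quantile(reps, adj(alpha / 2)))
    hi = float(np.quantile(reps, adj(1.0 - alpha / 2)))
    return lo, hi


# ---------------------------------------------------------------------------
# Rank correlations and bands
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    """A rank correlation with its two-tailed p-value and magnitude band."""

    coefficient: float
    p: float
    n: int
    kind: str  # "spearman" | "kendall_tau_b"

    @property
    def band(self) -> str:
        return classify_correlation(self.coefficient)


def _paired_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DegenerateStatisticError("need >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateStatisticError("zero variance; coefficient undefined")
    return x, y


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation (Pearson on midranks), two-tailed p."""
    x, y = _paired_complete(x, y)
    res = stats.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x), "spearman")


def kendall_tau_b(x, y) -> CorrelationResult:
    """Kendall tau-b (tie-corrected in both margins), two-tailed p."""
    x, y = _paired_complete(x, y)
    res = stats.kendalltau(x, y, variant="b")
    return CorrelationResult(
        float(res.statistic), float(res.pvalue), len(x), "kendall_tau_b"
    )


def classify_correlation(r: float) -> str:
    """Magnitude band of a correlation coefficient.

    negligible |r| <= 0.29, low 0.30-0.49, moderate 0.50-0.69,
    high 0.70-0.89, very high >= 0.90.
    """
    a = abs(r)
    if a > 1 + 1e-12:
        raise DegenerateStatisticError("|r| must be <= 1")
    for lo, hi, name in CORRELATION_BANDS:
        if a <= hi + 0.005:  # printed thresholds are 2-decimal closed bounds
            return name
    return "very high"


def classify_icc(icc: float, ci: Optional[tuple[float, float]] = None):
    """Reliability band of an ICC (optionally also of its CI bounds).

    poor < 0.50, moderate 0.50-0.75, good 0.75-0.90, excellent > 0.90.
    With a CI the bands of the bounds are returned too, since reliability is
    interpreted from the ICC together with its CI.
    """

    def band(v: float) -> str:
        if v < 0.50:
            return "poor"
        if v < 0.75:
            return "moderate"
        if v < 0.90:
            return "good"
        return "excellent"

    if ci is None:
        return band(icc)
    return band(icc), (band(ci[0]), band(ci[1]))


# ---------------------------------------------------------------------------
# Robust ANCOVA (running-interval smoother)
# ---------------------------------------------------------------------------


@dataclass
class AncovaPoint:
    """Group comparison at one covariate design point."""

    x0: float
    est1: float
    est2: float
    difference: float
    ci: tuple[float, float]
    n1: int
    n2: int
    skipped: bool = False


@dataclass
class AncovaResult:
    points: list[AncovaPoint]
    span: float
    n_boot: int
    trim: float
    alpha_adjusted: float

    def excludes_zero(self) -> list[bool]:
        return [not (p.ci[0] <= 0.0 <= p.ci[1]) for p in self.points if not p.skipped]


def _madn(x: np.ndarray) -> float:
    """Normalized median absolute deviation (consistent with the SD)."""
    return float(np.median(np.abs(x - np.median(x))) / 0.6745)


def robust_ancova(
    x1,
    y1,
    x2,
    y2,
    design_points: Sequence[float] = DEFAULT_DESIGN_POINTS,
    span: float = 0.7,
    n_boot: int = 2000,
    trim: float = 0.0,
    level: float = 0.95,
    seed: int = 0,
    min_window: int = 5,
) -> AncovaResult:
    """Compare two groups at fixed covariate values via a running-interval
    smoother with a percentile bootstrap.

    At each design point ``x0`` the members of each group whose covariate
    lies within ``span * MADN`` (MADN computed per group) of ``x0`` form the
    local sample; the trimmed means of the two local samples (``trim=0``
    gives ordinary means) are compared with a percentile bootstrap of the
    difference.  CIs are Bonferroni-adjusted across the design points.  A
    design point with fewer than ``min_window`` members in either group is
    skipped with a warning.
    """
    x1, y1 = np.asarray(x1, float), np.asarray(y1, float)
    x2, y2 = np.asarray(x2, float), np.asarray(y2, float)
    rng = np.random.default_rng(seed)
    points = list(design_points)
    alpha_adj = (1.0 - level) / len(points)

    def tmean(v: np.ndarray, axis=None) -> np.ndarray:
        if trim <= 0:
            return np.mean(v, axis=axis)
        v = np.sort(v, axis=axis)
        g = int(np.floor(trim * v.shape[-1]))
        sl = slice(g, v.shape[-1] - g)
        return np.mean(v[..., sl], axis=axis)

    h1 = span * _madn(x1)
    h2 = span * _madn(x2)
    out = []
    for x0 in points:
        s1 = y1[np.abs(x1 - x0) <= h1]
        s2 = y2[np.abs(x2 - x0) <= h2]
        if len(s1) < min_window or len(s2) < min_window:
            warnings.warn(
                f"design point {x0}: local window too small "
                f"(n1={len(s1)}, n2={len(s2)}); skipped",
                stacklevel=2,
            )
            out.append(
                AncovaPoint(x0, np.nan, np.nan, np.nan, (np.nan, np.nan), len(s1), len(s2), True)
            )
            continue
        e1, e2 = float(tmean(s1)), float(tmean(s2))
        b1 = s1[rng.integers(0, len(s1), size=(n_boot, len(s1)))]
        b2 = s2[rng.integers(0, len(s2), size=(n_boot, len(s2)))]
        diffs = tmean(b1, axis=1) - tmean(b2, axis=1)
        lo = float(np.quantile(diffs, alpha_adj / 2))
        hi = float(np.quantile(diffs, 1.0 - alpha_adj / 2))
        out.append(AncovaPoint(x0, e1, e2, e1 - e2, (lo, hi), len(s1), len(s2)))
    return AncovaResult(out, span, n_boot, trim, alpha_adj)


# ---------------------------------------------------------------------------
# Power: smallest detectable correlation
# ---------------------------------------------------------------------------


def min_detectable_r(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest |r| detectable by the two-sided test of zero correlation.

    Uses the Fisher z approximation with a small-sample bias term: the
    noncentrality is ``sqrt(n-3) * (atanh(r) + r / (2(n-1)))``.  Returned
    rounded to 2 decimals.
    """
    if n < 4:
        raise DegenerateStatisticError("need n >= 4")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise DegenerateStatisticError("alpha and power must be in (0, 1)")
    za = stats.norm.ppf(1.0 - alpha / 2)

    def attained_power(r: float) -> float:
        ncp = math.sqrt(n - 3) * (math.atanh(r) + r / (2 * (n - 1)))
        return float(stats.norm.cdf(ncp - za) + stats.norm.cdf(-ncp - za))

    from scipy.optimize import brentq

    r_hi = 1.0 - 1e-9
    if attained_power(r_hi) < power:
        raise DegenerateStatisticError(f"power {power} unreachable at n={n}")
    r = brentq(lambda r: attained_power(r) - power, 1e-9, r_hi, xtol=1e-10)
    return round(float(r), 2)


# ---------------------------------------------------------------------------
# Concurrent validity table
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ("more_affected", "less_affected", "total")


def concurrent_validity_table(
    scores: pd.DataFrame, ratings: pd.DataFrame, affected: dict[str, str]
) -> pd.DataFrame:
    """Correlate the game scores with the clinical comparator measures.

    ``scores`` is the long-format score table (per-joint and summary rows,
    one occasion); ``ratings`` the long-format ratings table; ``affected``
    maps participant id to the more-affected side.  Returns one row per
    (comparator, game score) pair with Spearman rho and p per summary
    column — the layout of a concurrent-validity table: SCALE and GMFCS
    against both scores, the therapist's involuntary-movement rating
    against the IMS.  Excluded joints are removed from both sides of each
    pairing before summarizing.  Cells with fewer than 4 complete pairs are
    NA.
    """
    scores = scores[scores["occasion"] == scores["occasion"].iloc[0]]
    ratings = ratings[ratings["occasion"].isin(scores["occasion"].unique())]
    joints = scores[scores["joint"] != "summary"].copy()
    excluded = {
        (r["participant_id"], r["side"], r["joint"])
        for _, r in joints.iterrows()
        if r["excluded"] == 1
    }

    def side_key(pid: str, side: str) -> str:
        return "more_affected" if side == affected[pid] else "less_affected"

    # comparator summaries honoring the joint-exclusion rule
    comp_rows = []
    for pid, grp in ratings.groupby("participant_id"):
        if pid not in set(scores["participant_id"]):
            continue
        vals: dict[str, dict[str, list[float]]] = {
            "scale": {k: [] for k in SUMMARY_COLUMNS},
            "therapist": {k: [] for k in SUMMARY_COLUMNS},
        }
        for _, r in grp.iterrows():
            if (pid, r["side"], r["joint"]) in excluded:
                continue
            sk = side_key(pid, r["side"])
            if not pd.isna(r["scale"]):
                vals["scale"][sk].append(float(r["scale"]))
                vals["scale"]["total"].append(float(r["scale"]))
            vals["therapist"][sk].append(float(r["therapist_count"]))
            vals["therapist"]["total"].append(float(r["therapist_count"]))
        row = {"participant_id": pid, "gmfcs": float(grp["gmfcs"].iloc[0])}
        for meas in ("scale", "therapist"):
            for k in SUMMARY_COLUMNS:
                row[f"{meas}_{k}"] = np.mean(vals[meas][k]) if vals[meas][k] else np.nan
        comp_rows.append(row)
    comp = pd.DataFrame(comp_rows)

    summ = scores[scores["joint"] == "summary"].pivot_table(
        index="participant_id", columns="side", values=["accuracy", "ims"]
    )

    def corr_cell(game_col: tuple, comp_col: str) -> tuple[float, float]:
        merged = pd.merge(
            summ[game_col].rename("g").reset_index(),
            comp[["participant_id", comp_col]].rename(columns={comp_col: "c"}),
            on="participant_id",
        ).dropna()
        if len(merged) < 4:
            return np.nan, np.nan
        try:
            res = spearman_rho(merged["g"], merged["c"])
        except DegenerateStatisticError:
            return np.nan, np.nan
        return res.coefficient, res.p

    rows = []
    layout = [
        ("SCALE", "accuracy", lambda k: f"scale_{k}"),
        ("SCALE", "ims", lambda k: f"scale_{k}"),
        ("GMFCS", "accuracy", lambda k: "gmfcs"),
        ("GMFCS", "ims", lambda k: "gmfcs"),
        ("therapist", "ims", lambda k: f"therapist_{k}"),
    ]
    for comparator, score_name, comp_col_of in layout:
        row: dict = {"comparator": comparator, "score": score_name}
        for k in SUMMARY_COLUMNS:
            rho, p = corr_cell((score_name, k), comp_col_of(k))
            row[f"{k}_rho"] = rho
            row[f"{k}_p"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def per_joint_validity_table(scores: pd.DataFrame, ratings: pd.DataFrame) -> pd.DataFrame:
    """Kendall tau-b between per-joint game scores and per-joint comparators."""
    joints = scores[(scores["joint"] != "summary") & (scores["excluded"] == 0)]
    merged = pd.merge(
        joints,
        ratings,
        on=["participant_id", "occasion", "side", "joint"],
        how="inner",
    )
    rows = []
    for side, joint in merged.groupby(["side", "joint"]).groups:
        sub = merged[(merged["side"] == side) & (merged["joint"] == joint)]
        for comp_col, game_col in (
            ("scale", "accuracy"),
            ("scale", "ims"),
            ("therapist_count", "ims"),
        ):
            pairs = sub[[game_col, comp_col]].dropna()
            try:
                res = kendall_tau_b(pairs[game_col], pairs[comp_col])
                tau, p, n = res.coefficient, res.p, res.n
            except DegenerateStatisticError:
                tau, p, n = np.nan, np.nan, len(pairs)
            rows.append(
                {
                    "side": side,
                    "joint": joint,
                    "comparator": comp_col,
                    "score": game_col,
                    "tau_b": tau,
                    "p": p,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "AncovaPoint",
    "AncovaResult",
    "CorrelationResult",
    "DegenerateStatisticError",
    "ReliabilityResult",
    "bca_ci",
    "classify_correlation",
    "classify_icc",
    "concurrent_validity_table",
    "icc_2_1",
    "improvable_fraction",
    "kendall_tau_b",
    "mdc_percent_grand_mean",
    "min_detectable_r",
    "per_joint_validity_table",
    "reliability_analysis",
    "robust_ancova",
    "sem_mdc",
    "spearman_rho",
    "wilcoxon_signed_rank",
]
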