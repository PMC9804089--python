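"""Statistical battery vs independent brute-force oracles and closed forms."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from assessgame.psychometrics import (
    DegenerateStatisticError,
    bca_ci,
    classify_correlation,
    classify_icc,
    icc_2_1,
    improvable_fraction,
    kendall_tau_b,
    mdc_percent_grand_mean,
    min_detectable_r,
    reliability_analysis,
    robust_ancova,
    sem_mdc,
    spearman_rho,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def icc21_oracle(x: np.ndarray) -> float:
    """ICC(2,1) from explicitly accumulated two-way ANOVA sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_between_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_between_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum((v - grand) ** 2 for v in x.ravel())
    ms_r = ss_between_rows / (n - 1)
    ms_c = ss_between_cols / (k - 1)
    ms_e = (ss_total - ss_between_rows - ss_between_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


def tau_b_oracle(x, y) -> float:
    """Kendall tau-b by explicit pair counting with tie terms."""
    x = list(x)
    y = list(y)
    n = len(x)
    conc = disc = tie_x = tie_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx = x[i] - x[j]
        dy = y[i] - y[j]
        if dx == 0 and dy == 0:
            tie_x += 1
            tie_y += 1
        elif dx == 0:
            tie_x += 1
        elif dy == 0:
            tie_y += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tie_x) * (n0 - tie_y))
    return (conc - disc) / denom if denom > 0 else float("nan")


def spearman_oracle(x, y) -> float:
    """Pearson correlation of midranks."""

    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def wilcoxon_exact_oracle(d) -> float:
    """Exact signed-rank p by enumeration of all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
    )
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(2 * min(p_le, p_ge), 1.0)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [3.0, 3.0]])
        icc, comp = icc_2_1(x)
        assert icc == pytest.approx(1.0)
        assert comp["var_error"] == pytest.approx(0.0)

    def test_worked_matrix_matches_anova_oracle(self):
        x = np.array([[1, 2], [2, 3], [4, 4], [6, 5]], dtype=float)
        icc, _ = icc_2_1(x)
        assert icc == pytest.approx(icc21_oracle(x), abs=1e-12)

    def test_location_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 2))
        assert icc_2_1(x)[0] == pytest.approx(icc_2_1(x + 17.3)[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matrices_match_oracle_and_pingouin(self, seed):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        x = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1)) * 2
        icc, _ = icc_2_1(x)
        assert icc == pytest.approx(icc21_oracle(x), abs=1e-10)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile(["a", "b"], n),
                "score": x.ravel(),
            }
        )
        ping = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        )
        # two-way random, absolute agreement, single measure
        row = ping["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ping.loc[row, "ICC"].iloc[0])
        assert icc == pytest.approx(icc2, abs=1e-8)

    def test_zero_variance_undefined(self):
        with pytest.raises(DegenerateStatisticError):
            icc_2_1(np.full((5, 2), 3.0))

    def test_known_variance_component_recovery(self):
        # 200 subjects x 2 trials with known variance components
        rng = np.random.default_rng(42)
        var_s, var_t, var_e = 1.0, 0.05, 0.15
        n = 200
        subj = rng.normal(0, math.sqrt(var_s), size=(n, 1))
        trial = rng.normal(0, math.sqrt(var_t), size=(1, 2))
        x = subj + trial + rng.normal(0, math.sqrt(var_e), size=(n, 2))
        icc, _ = icc_2_1(x)
        truth = var_s / (var_s + var_t + var_e)
        assert icc == pytest.approx(truth, abs=0.03)


# ---------------------------------------------------------------------------
# SEM / MDC / improvable fraction
# ---------------------------------------------------------------------------


class TestAbsoluteReliability:
    def test_zero_components(self):
        assert sem_mdc(0.0, 0.0) == (0.0, 0.0)

    def test_arithmetic(self):
        sem, mdc = sem_mdc(0.02, 0.02)
        assert sem == pytest.approx(0.2)
        assert mdc == pytest.approx(0.5544, abs=1e-4)

    def test_negative_component_rejected(self):
        with pytest.raises(DegenerateStatisticError, match="truncate"):
            sem_mdc(-0.01, 0.02)

    def test_consistency_with_sd_route(self):
        # SD*sqrt(1-ICC) approximates MDC95/(1.96*sqrt(2)) on published-style
        # numbers: pooled SD 1.35, ICC 0.97, MDC95 0.63
        lhs = 0.63 / (1.96 * math.sqrt(2))
        rhs = 1.35 * math.sqrt(1 - 0.97)
        assert lhs == pytest.approx(rhs, rel=0.10)

    @pytest.mark.parametrize(
        "means_mdc, expected",
        [
            ((2.55, 2.47, 0.63), 25),
            ((1.88, 2.09, 1.97), 99),
            ((2.0, 2.0, 1.0), 50),
        ],
    )
    def test_mdc_percent(self, means_mdc, expected):
        assert mdc_percent_grand_mean(*means_mdc) == expected

    def test_mdc_percent_nonpositive_mean(self):
        with pytest.raises(DegenerateStatisticError):
            mdc_percent_grand_mean(0.0, 0.0, 1.0)

    def test_improvable_fraction(self):
        frac, n = improvable_fraction([0.5, 1.0, 2.0], 0.8)
        assert (frac, n) == (pytest.approx(2 / 3), 2)
        frac, n = improvable_fraction([2.0, 3.0], 0.5)
        assert (frac, n) == (1.0, 2)
        # 16 of 17 participants reported as 94%
        frac, n = improvable_fraction([1.0] * 16 + [0.2], 0.5)
        assert n == 16
        assert round(100 * frac) == 94


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------


class TestBca:
    def test_constant_statistic_degenerates(self):
        lo, hi = bca_ci(lambda m: 3.0, np.arange(10.0), n_boot=50, seed=0)
        assert (lo, hi) == (3.0, 3.0)

    def test_forced_zero_equals_percentile_interval(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal(40)
        stat = lambda m: float(np.mean(m))
        lo, hi = bca_ci(stat, data, n_boot=400, seed=9, force_zero_bias_accel=True)
        # reproduce the replicate stream and take plain percentiles
        x = data[:, None]
        rng2 = np.random.default_rng(9)
        reps = np.array(
            [stat(x[rng2.integers(0, len(x), size=len(x))]) for _ in range(400)]
        )
        assert lo == pytest.approx(float(np.quantile(reps, 0.025)), abs=1e-12)
        assert hi == pytest.approx(float(np.quantile(reps, 0.975)), abs=1e-12)

    def test_symmetric_data_bca_close_to_percentile(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal(200)
        stat = lambda m: float(np.mean(m))
        bca = bca_ci(stat, data, n_boot=600, seed=3)
        pct = bca_ci(stat, data, n_boot=600, seed=3, force_zero_bias_accel=True)
        se = np.std(data, ddof=1) / math.sqrt(len(data))
        assert abs(bca[0] - pct[0]) < se
        assert abs(bca[1] - pct[1]) < se

    def test_coverage_of_normal_mean(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            data = rng.standard_normal(200)
            lo, hi = bca_ci(
                lambda m: float(np.mean(m)), data, n_boot=1000, seed=1000 + i
            )
            hits += lo <= 0.0 <= hi
        assert hits / n_rep == pytest.approx(0.95, abs=0.03)

    def test_deterministic_per_seed(self):
        data = np.arange(20.0)
        a = bca_ci(lambda m: float(np.median(m)), data, n_boot=200, seed=5)
        b = bca_ci(lambda m: float(np.median(m)), data, n_boot=200, seed=5)
        assert a == b


# ---------------------------------------------------------------------------
# Rank correlations
# ---------------------------------------------------------------------------


class TestRankCorrelations:
    def test_strictly_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0, 12.0]
        y = [v**3 + 1 for v in x]
        assert spearman_rho(x, y).coefficient == pytest.approx(1.0)
        assert kendall_tau_b(x, y).coefficient == pytest.approx(1.0)

    def test_tau_b_worked_example(self):
        res = kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4])
        # C=5, D=1, no ties
        assert res.coefficient == pytest.approx(2 / 3)

    def test_tau_b_tie_corrected_example(self):
        # C=1, D=0, one tie in each margin
        res = kendall_tau_b([1, 1, 2], [1, 2, 2])
        assert res.coefficient == pytest.approx(0.5)

    def test_exhaustive_small_instances_match_oracles(self):
        # all value assignments over a small alphabet, n = 3 and 4
        for n, alphabet in ((3, (0, 1, 2)), (4, (0, 1, 2))):
            for x in itertools.product(alphabet, repeat=n):
                if len(set(x)) == 1:
                    continue
                for y in itertools.product(alphabet, repeat=n):
                    if len(set(y)) == 1:
                        continue
                    tau = kendall_tau_b(x, y).coefficient
                    assert tau == pytest.approx(tau_b_oracle(x, y), abs=1e-12)
                    rho = spearman_rho(x, y).coefficient
                    assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_binary_vectors_n6_match_oracles(self):
        for x in itertools.product((0, 1), repeat=6):
            if len(set(x)) == 1:
                continue
            for y in itertools.product((0, 1), repeat=6):
                if len(set(y)) == 1:
                    continue
                assert kendall_tau_b(x, y).coefficient == pytest.approx(
                    tau_b_oracle(x, y), abs=1e-12
                )

    def test_random_vectors_match_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 4, size=n)
            y = rng.integers(0, 4, size=n)
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            assert kendall_tau_b(x, y).coefficient == pytest.approx(
                tau_b_oracle(x, y), abs=1e-12
            )
            assert spearman_rho(x, y).coefficient == pytest.approx(
                spearman_oracle(x, y), abs=1e-12
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_missing_dropped_pairwise(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 1.0, 8.0, 10.0]
        assert spearman_rho(x, y).n == 4


class TestBands:
    @pytest.mark.parametrize(
        "r, band",
        [
            (0.0, "negligible"),
            (0.29, "negligible"),
            (-0.35, "low"),
            (0.56, "moderate"),
            (0.70, "high"),
            (0.95, "very high"),
        ],
    )
    def test_correlation_bands(self, r, band):
        assert classify_correlation(r) == band

    def test_icc_bands(self):
        assert classify_icc(0.49) == "poor"
        assert classify_icc(0.52) == "moderate"
        assert classify_icc(0.86) == "good"
        assert classify_icc(0.94) == "excellent"
        band, (lo_band, hi_band) = classify_icc(0.86, (0.76, 0.93))
        assert (band, lo_band, hi_band) == ("good", "good", "excellent")


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_all_positive_n6(self):
        # six positive differences of distinct magnitude: exact p = 2/2^6
        p = wilcoxon_signed_rank([2, 4, 6, 8, 10, 12.5], [1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(2 / 64)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(15):
            n = int(rng.integers(5, 9))
            d = np.round(rng.standard_normal(n) * 10, 3)
            if len(np.unique(np.abs(d))) < n or (d == 0).any():
                continue
            p = wilcoxon_signed_rank(d, np.zeros(n))
            assert p == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-12)

    def test_sign_flip_symmetry(self):
        d = np.array([1.2, -0.4, 2.2, -3.1, 0.6, 1.9])
        p1 = wilcoxon_signed_rank(d, np.zeros(6))
        p2 = wilcoxon_signed_rank(-d, np.zeros(6))
        assert p1 == pytest.approx(p2)

    def test_no_systematic_shift_gives_large_p(self):
        test = np.linspace(1, 3, 12)
        noise = np.tile([0.01, -0.01], 6)
        p = wilcoxon_signed_rank(test + noise, test)
        assert p > 0.8

    def test_all_zero_differences_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            p = wilcoxon_signed_rank([1.0] * 6, [1.0] * 6)
        assert p == 1.0


# ---------------------------------------------------------------------------
# Robust ANCOVA
# ---------------------------------------------------------------------------


class TestRobustAncova:
    def test_constant_shift_recovery(self):
        rng = np.random.default_rng(0)
        x1 = rng.uniform(6, 18, 100)
        x2 = rng.uniform(6, 18, 100)
        y1 = 0.1 * x1 + 1.0 + rng.normal(0, 0.1, 100)
        y2 = 0.1 * x2 + rng.normal(0, 0.1, 100)
        res = robust_ancova(x1, y1, x2, y2, n_boot=600, seed=1)
        for p in res.points:
            assert not p.skipped
            assert 0.8 <= p.difference <= 1.2

    def test_null_split_cis_contain_zero(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(6, 18, 120)
        y = 0.05 * x + rng.normal(0, 0.3, 120)
        hits = 0
        for seed in range(6):
            perm = np.random.default_rng(seed).permutation(120)
            a, b = perm[:60], perm[60:]
            res = robust_ancova(x[a], y[a], x[b], y[b], n_boot=500, seed=seed)
            hits += all(p.ci[0] <= 0 <= p.ci[1] for p in res.points if not p.skipped)
        assert hits >= 5

    def test_infinite_span_degenerates_to_plain_mean_bootstrap(self):
        rng = np.random.default_rng(2)
        x1, x2 = rng.uniform(6, 18, 40), rng.uniform(6, 18, 45)
        y1, y2 = rng.normal(1, 0.5, 40), rng.normal(0, 0.5, 45)
        res = robust_ancova(x1, y1, x2, y2, design_points=[12.0], span=1e9,
                            n_boot=300, seed=4)
        p = res.points[0]
        assert p.n1 == 40 and p.n2 == 45
        assert p.difference == pytest.approx(np.mean(y1) - np.mean(y2))
        # reproduce the bootstrap stream: plain group-mean comparison
        rng2 = np.random.default_rng(4)
        b1 = y1[rng2.integers(0, 40, size=(300, 40))]
        b2 = y2[rng2.integers(0, 45, size=(300, 45))]
        diffs = b1.mean(axis=1) - b2.mean(axis=1)
        assert p.ci[0] == pytest.approx(float(np.quantile(diffs, 0.025)), abs=1e-12)
        assert p.ci[1] == pytest.approx(float(np.quantile(diffs, 0.975)), abs=1e-12)

    def test_empty_window_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(6, 18, 30)
        y = rng.normal(size=30)
        with pytest.warns(UserWarning, match="skipped"):
            res = robust_ancova(x, y, x, y, design_points=[99.0], n_boot=100, seed=0)
        assert res.points[0].skipped

    def test_trimmed_means_used_when_requested(self):
        y1 = np.array([0.0] * 10 + [100.0])  # one gross outlier
        y2 = np.zeros(11)
        x = np.linspace(6, 18, 11)
        res = robust_ancova(x, y1, x, y2, design_points=[12.0], span=1e9,
                            trim=0.2, n_boot=100, seed=0)
        assert abs(res.points[0].difference) < 1.0


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------


class TestPower:
    def test_reference_value_n20(self):
        assert min_detectable_r(20, 0.05, 0.80) == 0.58

    def test_larger_samples_detect_smaller_correlations(self):
        assert min_detectable_r(50) < min_detectable_r(20)

    def test_n50_value(self):
        assert min_detectable_r(50, 0.05, 0.80) == pytest.approx(0.38, abs=0.01)

    def test_solution_attains_target_power(self):
        # verify the root against the power function it solves
        n, alpha, power = 24, 0.05, 0.80
        r = min_detectable_r(n, alpha, power)
        za = stats.norm.ppf(1 - alpha / 2)
        ncp = math.sqrt(n - 3) * (math.atanh(r) + r / (2 * (n - 1)))
        attained = stats.norm.cdf(ncp - za) + stats.norm.cdf(-ncp - za)
        assert attained == pytest.approx(power, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(DegenerateStatisticError):
            min_detectable_r(3)
        with pytest.raises(DegenerateStatisticError):
            min_detectable_r(20, alpha=0.0)


# ---------------------------------------------------------------------------
# Reliability wrapper
# ---------------------------------------------------------------------------


class TestReliabilityAnalysis:
    def test_full_result_fields(self):
        rng = np.random.default_rng(6)
        subj = rng.normal(2.5, 1.0, size=(17, 1))
        x = subj + rng.normal(0, 0.3, size=(17, 2))
        res = reliability_analysis(x[:, 0], x[:, 1], n_boot=200, seed=1)
        assert -1 < res.icc <= 1
        assert res.sem >= 0
        assert res.mdc95 == pytest.approx(1.96 * math.sqrt(2) * res.sem)
        assert res.n_subjects == 17
        assert res.icc_ci[0] <= res.icc_ci[1]

    def test_listwise_exclusion_of_missing_retest(self):
        test = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        retest = [1.1, np.nan, 2.9, 4.2, 5.1, 5.8]
        res = reliability_analysis(test, retest, n_boot=100, seed=0)
        assert res.n_subjects == 5
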