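"""Statistical layer vs brute-force oracles: ranks, agreement, U test, ROC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from noisekit import (abs_error_summary, agreement_report, bland_altman,
                      excluded_fraction_correlation, group_compare, roc,
                      snr_from_thresholds, spearman)
from noisekit.roimetrics import StudyRecord
from noisekit.statseval import records_to_frame


def brute_rank(v):
    """Average ranks with ties, by definition."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j - 1) / 2.0 + 1.0
        i = j
    return ranks


class TestSpearman:
    def test_monotone_limits(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [10, 20, 30, 40, 50])[0] == pytest.approx(1.0)
        assert spearman(x, [50, 40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        y[3] = y[4]  # introduce a tie
        r, _ = spearman(x, y)
        rx, ry = brute_rank(x), brute_rank(y)
        manual = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(manual, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            spearman([1.0, 2.0, np.nan], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_methods(self):
        bias, lo, hi = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_hand_computed_fixture(self):
        # d = {1,1,1,3}: bias 1.5, SD 1.0 -> LoA 1.5 ± 1.96
        a = np.array([2.0, 3.0, 4.0, 8.0])
        b = a - np.array([1.0, 1.0, 1.0, 3.0])
        bias, lo, hi = bland_altman(a, b)
        assert bias == pytest.approx(1.5)
        assert lo == pytest.approx(-0.46)
        assert hi == pytest.approx(3.46)

    def test_constant_offset_zero_width(self):
        a = np.array([5.0, 6.0, 7.0])
        bias, lo, hi = bland_altman(a, a - 2.0)
        assert bias == pytest.approx(2.0)
        assert hi - lo == pytest.approx(0.0)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])

    def test_loa_cover_95pct_of_gaussian_differences(self, rng):
        a = rng.normal(10, 1, 200)
        b = a + rng.normal(0.5, 0.3, 200)
        bias, lo, hi = bland_altman(a, b)
        inside = np.mean((a - b >= lo) & (a - b <= hi))
        # binomial sampling tolerance at n=200 (~3 SE)
        assert inside == pytest.approx(0.95, abs=0.05)


class TestAbsErrorSummary:
    def test_identical_pairs(self):
        mad, _, mare, _, _ = abs_error_summary([1.0, 2.0], [1.0, 2.0])
        assert mad == 0.0 and mare == 0.0

    def test_hand_oracle(self):
        mad, _, mare, _, _ = abs_error_summary([11.0, 33.0], [10.0, 30.0])
        assert mad == pytest.approx(2.0)
        assert mare == pytest.approx(10.0)

    def test_single_pair_ci_undefined(self):
        mad, mad_ci, mare, mare_ci, _ = abs_error_summary([2.0], [1.0])
        assert mad_ci is None and mare_ci is None

    def test_zero_reference_excluded(self):
        _, _, mare, _, n_exc = abs_error_summary([1.0, 2.0], [0.0, 1.0])
        assert n_exc == 1
        assert mare == pytest.approx(100.0)


def _records(groups):
    recs = []
    i = 0
    for label, values in groups.items():
        for v in values:
            recs.append(StudyRecord(study_id=f"s{i}", noise=float(v),
                                    snr=500.0 / float(v), attenuation=500.0,
                                    quality_label=label))
            i += 1
    return recs


def brute_u(x, y):
    """U statistic by exhaustive pair counting (ties count half)."""
    return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0
               for xi in x for yi in y)


class TestGroupCompare:
    def test_identical_groups_p_near_one(self):
        res = group_compare(_records({"fully_diagnostic": [1, 2, 3, 4],
                                      "non_diagnostic": [1, 2, 3, 4]}), "noise")
        (_, p), = [tuple(v.values()) for v in res["pairwise"].values()]
        assert p > 0.5

    def test_separated_groups_u_and_exact_p(self):
        res = group_compare(_records({"fully_diagnostic": [1, 2, 3],
                                      "non_diagnostic": [11, 12, 13]}), "noise")
        stats = list(res["pairwise"].values())[0]
        # exhaustive enumeration: all 20 assignments, U=0 is one-of-20 extreme
        x, y = [1, 2, 3], [11, 12, 13]
        assert brute_u(x, y) == 0.0
        assert stats["U"] == 0.0
        count_le = sum(1 for combo in itertools.combinations(range(6), 3)
                       if brute_u([(x + y)[i] for i in combo],
                                  [(x + y)[i] for i in range(6)
                                   if i not in combo]) <= 0.0)
        exact_p = 2 * count_le / 20
        assert stats["p"] == pytest.approx(exact_p)

    def test_median_and_iqr_reported(self):
        res = group_compare(_records({"fully_diagnostic": [1, 2, 9],
                                      "non_diagnostic": [4, 5, 6]}), "noise")
        assert res["groups"]["fully_diagnostic"]["median"] == 2.0
        assert res["groups"]["non_diagnostic"]["n"] == 3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare(_records({"fully_diagnostic": [1, 2, 3]}), "noise")


class TestRoc:
    def test_perfect_separation(self):
        recs = _records({"fully_diagnostic": [20, 21, 22, 23],
                         "non_diagnostic": [40, 41, 42, 43]})
        res = roc(recs, "noise", direction="higher")
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 23 < res.cutoff <= 40

    def test_constant_scores_auc_half(self):
        recs = _records({"fully_diagnostic": [30] * 5, "non_diagnostic": [30] * 5})
        res = roc(recs, "noise", direction="higher")
        assert res.auc == pytest.approx(0.5)

    def test_auc_matches_concordant_pair_counting(self, rng):
        pos = rng.normal(40, 5, 6)
        neg = rng.normal(33, 5, 6)
        recs = _records({"non_diagnostic": pos, "fully_diagnostic": neg})
        res = roc(recs, "noise", direction="higher")
        oracle = brute_u(pos, neg) / (len(pos) * len(neg))
        assert res.auc == pytest.approx(oracle, abs=1e-9)

    def test_direction_lower_for_snr(self):
        recs = _records({"fully_diagnostic": [25, 26, 27, 28],
                         "non_diagnostic": [45, 46, 47, 48]})
        res = roc(recs, "snr", direction="lower")   # snr = 500/noise
        assert res.auc == 1.0

    def test_auc_antisymmetry(self, rng):
        scores = rng.normal(size=12)
        labels = ["non_diagnostic"] * 6 + ["fully_diagnostic"] * 6
        recs = [StudyRecord(study_id=f"s{i}", noise=float(s), snr=1.0,
                            attenuation=1.0, quality_label=l)
                for i, (s, l) in enumerate(zip(scores, labels))]
        hi = roc(recs, "noise", direction="higher").auc
        lo = roc(recs, "noise", direction="lower").auc
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc(_records({"non_diagnostic": [1, 2, 3]}), "noise")

    def test_delong_ci_contains_auc_and_shrinks(self, rng):
        def make(n):
            return _records({"non_diagnostic": rng.normal(40, 5, n),
                             "fully_diagnostic": rng.normal(33, 5, 3 * n)})
        small = roc(make(10), "noise")
        big = roc(make(100), "noise")
        assert small.auc_ci[0] <= small.auc <= small.auc_ci[1]
        assert (big.auc_ci[1] - big.auc_ci[0]) < (small.auc_ci[1] - small.auc_ci[0])


class TestSnrFromThresholds:
    @pytest.mark.parametrize("att,noise,expected", [
        (400.0, 30.0, 13.3),
        (35.0, 35.0, 1.0),
        (450.0, 30.0, 15.0),
    ])
    def test_values(self, att, noise, expected):
        assert snr_from_thresholds(att, noise) == expected

    def test_zero_noise_threshold_rejected(self):
        with pytest.raises(ValueError):
            snr_from_thresholds(400.0, 0.0)


class TestExcludedFractionCorrelation:
    def _cohort_records(self, link, rng, n=120):
        recs = []
        for i in range(n):
            noise = float(rng.normal(36, 6))
            frac = (0.02 + 0.3 * (noise - 25) / 25 if link
                    else float(rng.uniform(0.02, 0.4)))
            frac += float(rng.normal(0, 0.05))
            frac = float(np.clip(frac, 0.001, 0.5))
            total = float(rng.normal(350, 40))
            recs.append(StudyRecord(
                study_id=f"s{i}", noise=noise, snr=500.0 / noise,
                attenuation=500.0, quality_label="excluded_parts",
                excluded_length=frac * total, total_length=total))
        return recs

    def test_sign_recovery_with_monotone_link(self, rng):
        out = excluded_fraction_correlation(self._cohort_records(True, rng))
        assert out["r_noise_vs_excluded_fraction"][0] > 0
        assert out["r_snr_vs_excluded_fraction"][0] < 0
        assert out["r_snr_vs_excluded_fraction"][1] < 0.01

    def test_independent_null_small_r(self, rng):
        out = excluded_fraction_correlation(self._cohort_records(False, rng))
        assert abs(out["r_noise_vs_excluded_fraction"][0]) < 0.25

    def test_low_n_flagged_and_missing_skipped(self, rng):
        recs = self._cohort_records(True, rng, n=5)
        recs[0].excluded_length = None
        out = excluded_fraction_correlation(recs)
        assert out["low_n"] is True
        assert out["n_skipped"] == 1 and out["n"] == 4


class TestNullCalibration:
    def test_mann_whitney_p_uniform_under_null(self):
        """Exact-method p-values are uniform when both groups share one law."""
        from scipy import stats
        from noisekit.statseval import _mann_whitney
        rng = np.random.default_rng(2024)
        ps = [_mann_whitney(rng.normal(size=15), rng.normal(size=15))[1]
              for _ in range(500)]
        ks_p = stats.kstest(ps, "uniform").pvalue
        assert ks_p > 0.01


class TestAgreementReport:
    def test_full_battery_consistency(self, rng):
        manual = rng.normal(35, 5, 60)
        auto = manual + rng.normal(1.4, 2.0, 60)
        rep = agreement_report(auto, manual, "noise")
        assert rep.loa_low <= rep.bias <= rep.loa_high
        assert rep.spearman_r > 0.8
        assert rep.mean_abs_diff > 0
        assert rep.mean_abs_diff_ci[0] < rep.mean_abs_diff < rep.mean_abs_diff_ci[1]

    def test_records_to_frame_types(self):
        recs = _records({"fully_diagnostic": [30.0], "non_diagnostic": [40.0]})
        df = records_to_frame(recs)
        assert isinstance(df, pd.DataFrame)
        assert set(df["quality_label"]) == {"fully_diagnostic", "non_diagnostic"}
        with pytest.raises(TypeError):
            records_to_frame([object()])
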