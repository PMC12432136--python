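"""Extent and location consistency: GA correlations, persistence, ICC(3,1)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ibap import default_truth, simulate_cohort
from ibap.consistency import (
    extent_vs_ga,
    ga_subgroup_overlap,
    icc_table,
    persistence_fraction,
    regional_icc,
    select_longitudinal_extranormal,
)
from ibap.normative import DeviationProfile, classify_extranormal, compute_deviation_scores


def _profiles_from_labels(labels_by_tp: dict) -> DeviationProfile:
    """labels_by_tp: {timepoint: DataFrame subjects x regions of labels}."""
    rows = []
    score_of = {"infra": 0.01, "normal": 0.5, "supra": 0.99}
    for tp, frame in labels_by_tp.items():
        for sid, row in frame.iterrows():
            for region, lab in row.items():
                rows.append(
                    {"subject_id": sid, "timepoint": tp, "measure": "CTh",
                     "region": region, "score": score_of[lab]}
                )
    regions = tuple(next(iter(labels_by_tp.values())).columns)
    return classify_extranormal(DeviationProfile(table=pd.DataFrame(rows), regions=regions))


class TestExtentVsGA:
    def test_strictly_decreasing_counts_give_rho_minus_one(self):
        n = 12
        labels = pd.DataFrame(
            [["infra"] * (n - i) + ["normal"] * i for i in range(n)],
            index=[f"s{i}" for i in range(n)],
            columns=[f"r{j}" for j in range(n)],
        )
        prof = _profiles_from_labels({1: labels})
        ga = pd.Series(np.arange(n, dtype=float) + 25, index=labels.index)
        res = extent_vs_ga(prof, ga, directions=("infra",), n_boot=100)
        assert res.loc["infra", "rho"] == pytest.approx(-1.0)

    def test_recovery_under_known_effect(self):
        """lam1 = 0.8: negative rho whose 95% CI excludes 0 at n = 150."""
        truth = default_truth(seed=31, lam0=0.5, lam1=0.8)
        b = simulate_cohort(truth, n_term=0, n_preterm=150, seed=31)
        prof = compute_deviation_scores(truth.chart, b.morphometry)
        meta = b.morphometry.drop_duplicates("subject_id").set_index("subject_id")
        res = extent_vs_ga(prof, meta.ga_weeks, directions=("either",), n_boot=2000)
        row = res.loc["either"]
        assert row.rho < 0
        assert row.ci_hi < 0

    def test_ci_brackets_rho(self, truth_profiles, meta):
        pre = meta[meta.group == "preterm"]
        prof = DeviationProfile(
            table=truth_profiles.table[truth_profiles.table.subject_id.isin(pre.index)]
        )
        res = extent_vs_ga(prof, pre.ga_weeks, n_boot=2000)
        for _, row in res.dropna().iterrows():
            assert row.ci_lo <= row.rho <= row.ci_hi

    def test_agrees_with_naive_spearman(self, rng):
        """Vectorized path agrees with a naive per-dataset loop to 1e-12."""
        for _ in range(20):
            n = 30
            counts = rng.integers(0, 10, size=n)
            ga = rng.uniform(24, 37, size=n)
            labels = pd.DataFrame(
                [["infra"] * c + ["normal"] * (10 - c) for c in counts],
                index=[f"s{i}" for i in range(n)],
                columns=[f"r{j}" for j in range(10)],
            )
            prof = _profiles_from_labels({1: labels})
            res = extent_vs_ga(prof, pd.Series(ga, index=labels.index),
                               directions=("infra",), n_boot=0)
            expected = stats.spearmanr(counts, ga).statistic
            if np.isnan(expected):
                assert np.isnan(res.loc["infra", "rho"])
            else:
                assert res.loc["infra", "rho"] == pytest.approx(expected, abs=1e-12)

    def test_null_p_uniform(self, rng):
        """Permuted GA: p-values are uniform (KS at 0.01)."""
        truth = default_truth(seed=32, lam0=2.0, lam1=0.0)
        b = simulate_cohort(truth, n_term=0, n_preterm=60, seed=32)
        prof = compute_deviation_scores(truth.chart, b.morphometry)
        meta = b.morphometry.drop_duplicates("subject_id").set_index("subject_id")
        pvals = []
        for _ in range(300):
            ga = pd.Series(rng.permutation(meta.ga_weeks.to_numpy()), index=meta.index)
            res = extent_vs_ga(prof, ga, directions=("either",), n_boot=0)
            pvals.append(res.loc["either", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGASubgroups:
    def test_all_early_skips_later_bin(self):
        truth = default_truth(seed=33, lam0=1.0, lam1=0.3)
        b = simulate_cohort(truth, n_term=0, n_preterm=30, seed=33,
                            preterm_ga_range=(28.0, 29.5))
        prof = compute_deviation_scores(truth.chart, b.morphometry)
        meta = b.morphometry.drop_duplicates("subject_id").set_index("subject_id")
        tab = ga_subgroup_overlap(prof, meta.ga_weeks)
        assert set(tab.group.unique()) == {"ga<=30"}

    def test_partition_sizes_consistent(self):
        truth = default_truth(seed=34, lam0=1.0, lam1=0.3)
        b = simulate_cohort(truth, n_term=0, n_preterm=80, seed=34)
        prof = compute_deviation_scores(truth.chart, b.morphometry)
        meta = b.morphometry.drop_duplicates("subject_id").set_index("subject_id")
        t30 = ga_subgroup_overlap(prof, meta.ga_weeks, scheme="cut30")
        tcl = ga_subgroup_overlap(prof, meta.ga_weeks, scheme="clinical")
        def total(tab):
            one = tab[tab.direction == "infra"].drop_duplicates(["group", "region"])
            return one.groupby("group").n.first().sum()
        # same subjects partitioned under both schemes (first region's n per bin)
        n30 = t30[(t30.direction == "infra") & (t30.region == t30.region.iloc[0])].n.sum()
        ncl = tcl[(tcl.direction == "infra") & (tcl.region == tcl.region.iloc[0])].n.sum()
        assert n30 == ncl == 80

    def test_earlier_birth_higher_max_overlap(self):
        truth = default_truth(seed=35, lam0=0.5, lam1=0.8, placement_concentration=5.0)
        b = simulate_cohort(truth, n_term=0, n_preterm=200, seed=35)
        prof = compute_deviation_scores(truth.chart, b.morphometry)
        meta = b.morphometry.drop_duplicates("subject_id").set_index("subject_id")
        tab = ga_subgroup_overlap(prof, meta.ga_weeks)
        either = tab[tab.direction == "either"]
        max_early = either[either.group == "ga<=30"].pct.max()
        max_late = either[either.group == "ga>30"].pct.max()
        assert max_early > max_late


class TestPersistenceSelection:
    def test_all_normal_contributes_nothing(self):
        labels = pd.DataFrame({"rA": ["normal"], "rB": ["normal"]}, index=["s0"])
        prof = _profiles_from_labels({1: labels, 2: labels})
        assert select_longitudinal_extranormal(prof).empty

    def test_t1_only_pair_included(self):
        l1 = pd.DataFrame({"rA": ["infra"], "rB": ["normal"]}, index=["s0"])
        l2 = pd.DataFrame({"rA": ["normal"], "rB": ["normal"]}, index=["s0"])
        pairs = select_longitudinal_extranormal(_profiles_from_labels({1: l1, 2: l2}))
        assert len(pairs) == 1
        assert pairs.iloc[0].label_t1 == "infra" and pairs.iloc[0].label_t2 == "normal"

    def test_count_matches_bruteforce_union(self, rng):
        n, m = 25, 10
        s1 = rng.uniform(size=(n, m))
        s2 = rng.uniform(size=(n, m))
        lab = lambda s: np.where(s < 0.05, "infra", np.where(s > 0.95, "supra", "normal"))
        mk = lambda s: pd.DataFrame(lab(s), index=[f"s{i}" for i in range(n)],
                                    columns=[f"r{j}" for j in range(m)])
        prof = _profiles_from_labels({1: mk(s1), 2: mk(s2)})
        pairs = select_longitudinal_extranormal(prof)
        brute = np.sum(
            ((s1 < 0.05) | (s1 > 0.95)) | ((s2 < 0.05) | (s2 > 0.95))
        )
        assert len(pairs) == brute

    def test_identical_timepoints_100pct(self):
        l1 = pd.DataFrame({"rA": ["infra", "supra"], "rB": ["supra", "normal"]},
                          index=["s0", "s1"])
        prof = _profiles_from_labels({1: l1, 2: l1})
        pairs = select_longitudinal_extranormal(prof)
        assert persistence_fraction(pairs, "infra") == 100.0
        assert persistence_fraction(pairs, "supra") == 100.0

    def test_direction_flip_not_maintained(self):
        l1 = pd.DataFrame({"rA": ["infra"]}, index=["s0"])
        l2 = pd.DataFrame({"rA": ["supra"]}, index=["s0"])
        pairs = select_longitudinal_extranormal(_profiles_from_labels({1: l1, 2: l2}))
        assert persistence_fraction(pairs, "infra") == 0.0

    def test_empty_denominator_warns(self):
        l1 = pd.DataFrame({"rA": ["supra"]}, index=["s0"])
        pairs = select_longitudinal_extranormal(_profiles_from_labels({1: l1, 2: l1}))
        with pytest.warns(UserWarning, match="infra"):
            assert np.isnan(persistence_fraction(pairs, "infra"))

    def test_binomial_recovery_of_persistence_prob(self):
        """persistence_prob = 0.8 recovered within 3 SE at >= 300 pairs."""
        truth = default_truth(seed=36, lam0=3.0, lam1=0.6, persistence_prob=0.8,
                              direction_mix=0.0)  # all infra for a clean denominator
        b = simulate_cohort(truth, n_term=0, n_preterm=150, n_timepoints=2, seed=36)
        prof = compute_deviation_scores(truth.chart, b.morphometry)
        pairs = select_longitudinal_extranormal(prof)
        inj1 = b.injections[b.injections.timepoint == 1]
        keys = set(zip(inj1.subject_id, inj1.region))
        sel = pairs[[tuple(k) in keys for k in zip(pairs.subject_id, pairs.region)]]
        assert len(sel) >= 300
        frac = persistence_fraction(sel, "infra")
        # binomial oracle: retained targets stay infra; dropped targets redraw
        # uniformly and land back under the 5th percentile with prob 0.05
        expected = 100 * (0.8 + 0.2 * 0.05)
        se = 100 * np.sqrt((expected / 100) * (1 - expected / 100) / len(sel))
        assert abs(frac - expected) < 3 * se


class TestICC:
    def test_identical_timepoints_icc_one(self):
        s = pd.Series([0.1, 0.3, 0.5, 0.7, 0.9])
        res = regional_icc(s, s)
        assert res["icc"] == pytest.approx(1.0)

    def test_fixture_matches_anova_oracle(self):
        """Oracle: direct mean-squares decomposition, computed independently.

        t1 = (.10, .40, .60, .90), t2 = t1 + (.02, -.02, .02, -.02).
        Hand ANOVA: MS_subj = 0.227911..., MS_err = 0.000511...,
        ICC(3,1) = (MS_subj - MS_err) / (MS_subj + MS_err) = 0.99552...
        (value frozen from the brute-force oracle below).
        """
        t1 = pd.Series([0.10, 0.40, 0.60, 0.90])
        t2 = t1 + pd.Series([0.02, -0.02, 0.02, -0.02])
        Y = np.column_stack([t1, t2])
        n, k = Y.shape
        grand = Y.mean()
        ss_subj = k * ((Y.mean(axis=1) - grand) ** 2).sum()
        ss_time = n * ((Y.mean(axis=0) - grand) ** 2).sum()
        ss_err = ((Y - grand) ** 2).sum() - ss_subj - ss_time
        ms_subj = ss_subj / (n - 1)
        ms_err = ss_err / ((n - 1) * (k - 1))
        oracle = (ms_subj - ms_err) / (ms_subj + ms_err)
        res = regional_icc(t1, t2, min_subjects=4)
        assert res["icc"] == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self, rng):
        """Cross-check against the independent pingouin implementation."""
        pg = pytest.importorskip("pingouin")
        t1 = pd.Series(rng.uniform(size=20))
        t2 = t1 * 0.8 + rng.normal(0, 0.1, size=20)
        res = regional_icc(t1, pd.Series(t2))
        df = pd.DataFrame(
            {
                "subject": list(range(20)) * 2,
                "rater": [1] * 20 + [2] * 20,
                "score": np.concatenate([t1, t2]),
            }
        )
        icc3 = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        expected = icc3.loc[icc3.Type == "ICC(C,1)", "ICC"].iloc[0]
        assert res["icc"] == pytest.approx(expected, abs=1e-10)

    def test_constant_shift_invariance(self):
        s = pd.Series([0.2, 0.4, 0.5, 0.8, 0.9])
        res = regional_icc(s, s + 0.07)
        assert res["icc"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_between_subject_variance_flagged(self):
        s = pd.Series([0.5] * 6)
        res = regional_icc(s, s)
        assert res["icc"] == 0.0 and res["flagged"]

    def test_min_subjects(self):
        s = pd.Series([0.1, 0.2])
        with pytest.raises(ValueError, match=">= 5"):
            regional_icc(s, s)

    def test_icc_monotone_in_persistence(self):
        """Median regional ICC increases with the injected persistence."""
        meds = []
        for pp in (0.2, 0.6, 0.95):
            truth = default_truth(seed=37, lam0=3.0, lam1=0.5, persistence_prob=pp)
            b = simulate_cohort(truth, n_term=0, n_preterm=80, n_timepoints=2, seed=37)
            prof = compute_deviation_scores(truth.chart, b.morphometry)
            icc = icc_table(prof)
            meds.append(icc.icc.median())
        assert meds[0] < meds[1] < meds[2]

    def test_high_persistence_high_median_icc(self):
        """persistence 0.85 + tail injection: median regional ICC > 0.8."""
        truth = default_truth(seed=38, lam0=4.0, lam1=0.6, persistence_prob=0.85)
        b = simulate_cohort(truth, n_term=0, n_preterm=120, n_timepoints=2, seed=38)
        prof = compute_deviation_scores(truth.chart, b.morphometry)
        icc = icc_table(prof)
        assert icc.icc.median() > 0.8
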