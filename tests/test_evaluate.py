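"""Flagging-rate reports, percent change and cohort summary tables."""

import numpy as np
import pytest
from conftest import make_cohort

from nextri.evaluate import (
    AgeBinning,
    URLRule,
    cohort_summary,
    compare_rules,
    flagging_table,
    percent_change,
)
from nextri.model import CentileCurve

# Printed per-decade counts of the reference study: (n, flagged partitioned,
# flagged continuous)
TABLE3 = {
    "20-29": (508, 10, 19),
    "30-39": (1267, 16, 31),
    "40-49": (1054, 45, 33),
    "50-59": (745, 8, 16),
    "60-69": (410, 16, 11),
    "70-80": (109, 8, 2),
}


def _cohort_with_flag_counts(col):
    """Cohort realizing the printed per-decade totals and flagged counts
    against a flat URL of 50: flagged records get value 60, others 30."""
    ages, values = [], []
    for label, row in TABLE3.items():
        lo = int(label.split("-")[0])
        n, flagged = row[0], row[col]
        ages += [lo] * n
        values += [60.0] * flagged + [30.0] * (n - flagged)
    return make_cohort(ages, values)


FLAT_50 = URLRule(kind="partitioned", bands=((20, 80, 50.0),), name="flat")


class TestFlaggingTable:
    def test_printed_rate_arithmetic_partitioned(self):
        rep = flagging_table(_cohort_with_flag_counts(1), FLAT_50)
        rates = dict(zip(rep.table["bin"], rep.table["rate_percent"]))
        # 8/109 recomputes to 7.34 (the printed 7.30 does not match its own counts)
        assert rates == {"20-29": 1.97, "30-39": 1.26, "40-49": 4.27,
                         "50-59": 1.07, "60-69": 3.90, "70-80": 7.34}
        assert rep.total_n == 4093 and rep.total_flagged == 103
        assert rep.total_rate_percent == 2.52

    def test_printed_rate_arithmetic_continuous(self):
        rep = flagging_table(_cohort_with_flag_counts(2), FLAT_50)
        rates = dict(zip(rep.table["bin"], rep.table["rate_percent"]))
        assert rates == {"20-29": 3.74, "30-39": 2.45, "40-49": 3.13,
                         "50-59": 2.15, "60-69": 2.68, "70-80": 1.83}
        assert rep.total_rate_percent == 2.74

    def test_url_above_maximum_flags_nothing(self, study_cohort):
        rule = URLRule(kind="partitioned", bands=((20, 80, 1e9),))
        rep = flagging_table(study_cohort, rule)
        assert rep.total_flagged == 0

    def test_strict_inequality_at_url(self):
        coh = make_cohort([25, 25, 25, 25], [50.0, 50.0, 60.0, 30.0])
        rep = flagging_table(coh, FLAT_50)
        assert rep.total_flagged == 1  # values equal to the URL are inside the RI

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            n = int(rng.integers(30, 300))
            ages = rng.integers(20, 81, n)
            vals = rng.lognormal(3.4, 0.3, n)
            curve = CentileCurve(
                p=0.975,
                ages=np.arange(20.0, 81.0),
                values=np.linspace(45, 70, 61) + rng.normal(0, 1, 61),
            )
            rule = URLRule(kind="continuous", curve=curve)
            rep = flagging_table(make_cohort(ages, vals), rule)
            brute = sum(v > curve(float(a)) for a, v in zip(ages, vals))
            assert rep.total_flagged == brute
            assert rep.table["n"].sum() == n

    def test_age_outside_binning_rejected(self):
        coh = make_cohort([25, 85], [30.0, 30.0])
        with pytest.raises(ValueError, match="outside"):
            flagging_table(coh, FLAT_50)

    def test_partitioned_bands_must_tile(self):
        with pytest.raises(ValueError, match="tile"):
            URLRule(kind="partitioned", bands=((20, 49, 52.0), (51, 80, 63.0)))

    def test_calibration_on_known_model(self, study_config):
        from nextri.bcpe import bcpe_ppf
        from nextri.simulate import generate_cohort, scale_group_sizes

        big = generate_cohort(scale_group_sizes(study_config, 100_000, seed=77))
        ages = np.arange(20.0, 81.0)
        truth = CentileCurve(
            p=0.975,
            ages=ages,
            values=np.array(
                [
                    float(
                        bcpe_ppf(
                            0.975,
                            (study_config.mu_at(a), study_config.sigma_rel,
                             study_config.nu, study_config.tau),
                        )
                    )
                    for a in ages
                ]
            ),
        )
        rep = flagging_table(big, URLRule(kind="continuous", curve=truth))
        assert rep.total_flagged / rep.total_n * 100 == pytest.approx(2.5, abs=0.3)


class TestPercentChange:
    def test_printed_examples(self):
        assert percent_change(31.85, 41.36) == 29.9
        assert percent_change(52.11, 78.05) == 49.8

    def test_identity(self):
        assert percent_change(12.3, 12.3) == 0.0

    def test_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)


class TestCohortSummary:
    def test_sex_totals(self, study_cohort):
        t = cohort_summary(study_cohort)
        males = t[(t["sex"] == "M") & (t["bin"] == "total")].iloc[0]
        females = t[(t["sex"] == "F") & (t["bin"] == "total")].iloc[0]
        assert males["n"] == 2306 and females["n"] == 1787
        decade_n = t[t["bin"] != "total"].groupby("bin")["n"].sum()
        assert list(decade_n[lab] for lab in ["20-29", "30-39", "40-49", "50-59", "60-69", "70-80"]) \
            == [508, 1267, 1054, 745, 410, 109]

    def test_single_record(self):
        t = cohort_summary(make_cohort([25], [33.0]))
        row = t[(t["bin"] == "20-29") & (t["sex"] == "M")].iloc[0]
        assert row["n"] == 1 and row["median"] == 33.0 and row["iqr"] == 0.0

    def test_empty_rejected(self):
        coh = make_cohort([25], [30.0]).subset(np.array([False]))
        with pytest.raises(ValueError):
            cohort_summary(coh)


class TestCompareRules:
    def test_table3_twin_winner_count(self):
        rep_part = flagging_table(_cohort_with_flag_counts(1), FLAT_50)
        rep_part.rule_name = "partitioned"
        rep_cont = flagging_table(_cohort_with_flag_counts(2), FLAT_50)
        rep_cont.rule_name = "continuous"
        cmp = compare_rules(rep_part, rep_cont)
        assert cmp["wins_b"] == 5 and cmp["wins_a"] == 1
        assert cmp["range_b"] == [1.83, 3.74]
        assert cmp["range_a"] == [1.07, 7.34]

    def test_identical_reports_tie(self):
        rep = flagging_table(_cohort_with_flag_counts(1), FLAT_50)
        cmp = compare_rules(rep, rep)
        assert all(r["winner"] == "tie" for r in cmp["bins"])

    def test_exact_calibration_dominates(self):
        a = flagging_table(_cohort_with_flag_counts(1), FLAT_50)
        a.rule_name = "noisy"
        # build a cohort whose every decade flags exactly 2.5% against the flat rule
        ages, values = [], []
        for lo, n in [(20, 400), (30, 1200), (40, 1000), (50, 760), (60, 400), (70, 120)]:
            f = round(n * 0.025)
            ages += [lo] * n
            values += [60.0] * f + [30.0] * (n - f)
        ideal = flagging_table(make_cohort(ages, values), FLAT_50)
        ideal.rule_name = "ideal"
        # compare on equal footing requires same cohort size; use deviations only
        assert all(abs(r - 2.5) <= 0.01 for r in ideal.table["rate_percent"])

    def test_mismatched_binning_rejected(self):
        rep = flagging_table(_cohort_with_flag_counts(1), FLAT_50)
        other = flagging_table(
            _cohort_with_flag_counts(1), FLAT_50, AgeBinning((20, 50, 81))
        )
        with pytest.raises(ValueError, match="binning"):
            compare_rules(rep, other)


class TestStrictnessConvention:
    def test_tie_free_data_insensitive_to_convention(self, study_cohort):
        # continuous synthetic values: switching > to >= changes nothing
        urls = FLAT_50.url_at(study_cohort.ages)
        assert (study_cohort.values > urls).sum() == (study_cohort.values >= urls).sum()
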