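"""Synthetic cohort generator: determinism, fidelity, contamination."""

import numpy as np
import pytest
from scipy import stats

from nextri.bcpe import bcpe_pdf
from nextri.cohort import Cohort
from nextri.simulate import (
    GeneratorConfig,
    config_from_file,
    default_config,
    generate_cohort,
    inject_nse_creatinine,
    scale_group_sizes,
)

# Decade totals and sex totals of the reference population table
DECADE_TOTALS = {"20-29": 508, "30-39": 1267, "40-49": 1054, "50-59": 745, "60-69": 410, "70-80": 109}
DECADE_MEDIANS = {  # pooled-by-sex printed medians, pg/mL
    "20-29": (30.87, 31.25),
    "30-39": (30.59, 31.59),
    "40-49": (33.51, 31.9),
    "50-59": (35.14, 34.69),
    "60-69": (36.88, 36.4),
    "70-80": (39.61, 43.25),
}


class TestConfig:
    def test_table1_structure(self, study_config):
        assert study_config.n_total == 4093
        males = sum(v["M"] for v in study_config.group_sizes.values())
        females = sum(v["F"] for v in study_config.group_sizes.values())
        assert (males, females) == (2306, 1787)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(sigma_rel=-0.1),
            dict(tau=0.0),
            dict(contamination_rate=0.5),
            dict(mu_curve={20: -3.0}),
            dict(group_sizes={"20-29": {"M": -5}}),
            dict(group_sizes={"29-20": {"M": 5}}),
        ],
    )
    def test_invalid_config_names_field(self, bad):
        with pytest.raises(ValueError, match="config field"):
            default_config(seed=1, **bad)

    def test_config_from_yaml_requires_seed(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("sigma_rel: 0.3\n")
        with pytest.raises(ValueError, match="seed"):
            config_from_file(p)
        p.write_text("seed: 3\nmu_curve: {20: 31, 80: 41}\n")
        cfg = config_from_file(p)
        assert cfg.seed == 3 and cfg.mu_curve == {20: 31.0, 80: 41.0}


class TestGenerate:
    def test_count_and_validity(self, study_cohort):
        assert len(study_cohort) == 4093
        df = study_cohort.data
        assert df["subject_id"].is_unique
        assert df["age"].between(20, 80).all()
        assert (df["progrp"] > 0).all()

    def test_decade_medians_near_targets(self, study_cohort):
        # pooled per-decade medians within +/-2 pg/mL of the printed medians
        df = study_cohort.data
        for label, (med_m, med_f) in DECADE_MEDIANS.items():
            lo, hi = (int(x) for x in label.split("-"))
            pooled = df.loc[df["age"].between(lo, hi), "progrp"].median()
            target = np.mean([med_m, med_f])
            assert abs(pooled - target) < 2.0, (label, pooled, target)

    def test_determinism_byte_identical(self, study_config):
        a = generate_cohort(study_config).to_csv()
        b = generate_cohort(study_config).to_csv()
        assert a == b

    def test_different_seed_differs(self, study_config, study_cohort):
        other = generate_cohort(default_config(seed=8))
        assert not np.array_equal(other.values, study_cohort.values)

    def test_empty_config_gives_empty_cohort(self):
        cfg = default_config(seed=1, group_sizes={"20-29": {"M": 0, "F": 0}})
        assert len(generate_cohort(cfg)) == 0

    def test_degenerate_scale_collapses_to_median(self):
        cfg = default_config(
            seed=5, sigma_rel=1e-7, nu=1.0, tau=2.0, mu_curve={20: 30.0, 80: 30.0}
        )
        coh = generate_cohort(cfg)
        assert np.all(np.abs(coh.values - 30.0) < 0.01)

    def test_median_fidelity_constant_mu(self):
        # flat mu: pooled decade median within 3x the order-statistic SE
        cfg = default_config(seed=21, mu_curve={20: 31.0, 80: 31.0})
        coh = generate_cohort(cfg)
        dens = float(bcpe_pdf(31.0, (31.0, cfg.sigma_rel, cfg.nu, cfg.tau)))
        df = coh.data
        for label, n in DECADE_TOTALS.items():
            if n < 200:
                continue
            lo, hi = (int(x) for x in label.split("-"))
            med = df.loc[df["age"].between(lo, hi), "progrp"].median()
            se = 1.0 / (2.0 * dens * np.sqrt(n))
            assert abs(med - 31.0) < 3 * se, label

    def test_contamination_accounting(self):
        cfg = default_config(seed=9, contamination_rate=0.05, contamination_scale=4.0)
        coh = generate_cohort(cfg)
        clean = generate_cohort(default_config(seed=9))
        n_contaminated = int((coh.values != clean.values).sum())
        expected = sum(
            int(np.floor(0.05 * n)) for g in cfg.group_sizes.values() for n in g.values()
        )
        assert n_contaminated == expected
        assert np.allclose(
            np.sort(coh.values[coh.values != clean.values]),
            np.sort(clean.values[coh.values != clean.values] * 4.0),
        )

    def test_sex_offset(self):
        cfg = default_config(seed=3, sex_offset=8.0, mu_curve={20: 31.0, 80: 31.0})
        df = generate_cohort(cfg).data
        gap = df.loc[df.sex == "M", "progrp"].median() - df.loc[df.sex == "F", "progrp"].median()
        assert gap == pytest.approx(8.0, abs=1.5)


class TestInjectScreeningAnalytes:
    def test_fraction_zero_all_pass(self, study_cohort, study_config):
        coh = inject_nse_creatinine(study_cohort, study_config)
        df = coh.data
        thr = np.where(df.sex == "M", 16.4, np.where(df.age < 50, 14.47, 17.25))
        assert (df["nse"].to_numpy() < thr).all()
        assert (df["creatinine"] <= 133.0).all()

    def test_fraction_one_all_violate(self, study_cohort):
        cfg = default_config(seed=7, screen_violation_rate=1.0)
        df = inject_nse_creatinine(study_cohort, cfg).data
        thr = np.where(df.sex == "M", 16.4, np.where(df.age < 50, 14.47, 17.25))
        assert ((df["nse"].to_numpy() >= thr) | (df["creatinine"] > 133.0)).all()

    def test_reproducible_violator_count(self):
        cfg = default_config(
            seed=3, screen_violation_rate=0.1, group_sizes={"20-29": {"M": 50, "F": 50}}
        )
        coh = generate_cohort(cfg)
        a = inject_nse_creatinine(coh, cfg).data
        b = inject_nse_creatinine(coh, cfg).data
        assert a.equals(b)
        assert (a["creatinine"] > 133.0).sum() > 0

    def test_empty_cohort_rejected(self):
        cfg = default_config(seed=1, group_sizes={"20-29": {"M": 0}})
        with pytest.raises(ValueError):
            inject_nse_creatinine(generate_cohort(cfg), cfg)


class TestScaling:
    def test_scale_preserves_total_and_mix(self, study_config):
        scaled = scale_group_sizes(study_config, 100_000)
        assert scaled.n_total == 100_000
        frac = scaled.group_sizes["30-39"]["M"] / 100_000
        assert frac == pytest.approx(698 / 4093, abs=1e-4)


class TestCohortIO:
    def test_csv_roundtrip(self, tmp_path, study_cohort):
        path = tmp_path / "c.csv"
        study_cohort.to_csv(path)
        back = Cohort.from_csv(path)
        assert len(back) == len(study_cohort)
        assert np.allclose(back.values, study_cohort.values)
        assert (back.data["sex"] == study_cohort.data["sex"]).all()

    def test_duplicate_ids_rejected(self):
        from conftest import make_cohort

        with pytest.raises(ValueError, match="duplicate"):
            make_cohort([25, 30], [30.0, 31.0], subject_id=["A", "A"], provenance="x")
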