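"""Synthetic-cohort generator: determinism, carrier model, recovery."""

import numpy as np
import pytest
from scipy import stats as sps

from varburden.clinical import pooled_t_from_summary
from varburden.filtering import FilterConfig, select_qualifying
from varburden.simulate import (
    AFSpectrum,
    ClassModel,
    ScoreModel,
    SimConfig,
    recovery_experiment,
    simulate_carriers,
    simulate_clinical,
    simulate_cohort,
    simulate_sites,
    simulate_tables,
)


def _small_config(**kwargs):
    defaults = dict(
        n_cases=100,
        n_controls=300,
        classes={
            "truncating": ClassModel(p0=0.01, odds_ratio=2.0, n_sites=3),
            "missense": ClassModel(p0=0.05, odds_ratio=1.5, n_sites=10),
            "synonymous": ClassModel(p0=0.02, odds_ratio=1.0, n_sites=4),
        },
        seed=123,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestSimulateSites:
    def test_same_seed_identical_sites(self):
        config = _small_config()
        assert simulate_sites(config) == simulate_sites(config)

    def test_different_seed_differs(self):
        a = simulate_sites(_small_config(seed=1))
        b = simulate_sites(_small_config(seed=2))
        assert a != b

    def test_zero_deleterious_fraction(self):
        config = _small_config(score_model=ScoreModel(deleterious_fraction=0.0))
        sites = simulate_sites(config)
        qs = select_qualifying(sites, config.gene, "deleterious_missense",
                               FilterConfig())
        assert qs.variants == []

    def test_common_fraction_fails_rarity_filter(self):
        """~10% of sites planted above the threshold get filtered out."""
        config = _small_config(
            classes={"missense": ClassModel(p0=0.01, odds_ratio=1.0,
                                            n_sites=1000)},
            af_spectrum=AFSpectrum(frac_common=0.1),
        )
        sites = simulate_sites(config)
        qs = select_qualifying(sites, config.gene, "missense", FilterConfig())
        n_filtered = 1000 - len(qs.variants)
        # binomial(1000, 0.1): 5 sigma band around the expectation
        assert 100 - 5 * 9.5 <= n_filtered <= 100 + 5 * 9.5

    def test_rare_sites_all_pass_filter(self):
        config = _small_config()
        sites = simulate_sites(config)
        for label in ("truncating", "missense", "synonymous"):
            qs = select_qualifying(sites, config.gene, label, FilterConfig())
            expected = config.classes[label].n_sites
            assert len(qs.variants) == expected


class TestSimulateCarriers:
    def test_null_odds_ratio_means_equal_probabilities(self):
        model = ClassModel(p0=0.3, odds_ratio=1.0, n_sites=1)
        assert model.p1 == pytest.approx(0.3)

    def test_odds_transformation(self):
        model = ClassModel(p0=0.001, odds_ratio=5.0, n_sites=1)
        odds0 = 0.001 / 0.999
        assert model.p1 == pytest.approx(5 * odds0 / (1 + 5 * odds0))

    def test_zero_baseline_gives_zero_carriers(self):
        config = _small_config(
            classes={"missense": ClassModel(p0=0.0, odds_ratio=5.0, n_sites=5)}
        )
        cohort = simulate_cohort(config)
        assert all(not v.carrier_ids for v in cohort.variants)

    def test_carriers_are_on_the_roster(self):
        cohort = simulate_cohort(_small_config())
        roster = set(cohort.roster)
        for v in cohort.variants:
            assert v.carrier_ids <= roster

    def test_seeded_run_reproducible(self):
        config = _small_config()
        sites = simulate_sites(config)
        a = simulate_carriers(sites, config)
        b = simulate_carriers(sites, config)
        assert [v.carrier_ids for v in a.variants] == [
            v.carrier_ids for v in b.variants
        ]

    def test_large_sample_odds_ratio_recovers_truth(self):
        """Law of large numbers: realized OR within 20% of the target."""
        config = SimConfig(
            n_cases=100_000,
            n_controls=100_000,
            classes={"missense": ClassModel(p0=0.001, odds_ratio=5.0,
                                            n_sites=5)},
            seed=7,
        )
        cohort = simulate_cohort(config)
        a, b = cohort.carrier_counts("missense")
        realized = (a / (config.n_cases - a)) / (b / (config.n_controls - b))
        assert realized == pytest.approx(5.0, rel=0.2)

    def test_table_shortcut_matches_carrier_model_marginals(self):
        rng = np.random.default_rng(11)
        tables = simulate_tables(0.01, 2.0, 5000, 5000, 400, rng)
        model = ClassModel(p0=0.01, odds_ratio=2.0, n_sites=1)
        assert tables[:, 0].mean() / 5000 == pytest.approx(model.p1, rel=0.05)
        assert tables[:, 1].mean() / 5000 == pytest.approx(0.01, rel=0.05)


class TestSimulateClinical:
    ROWS = [
        ("wall", "continuous", {"g1": (19.0, 5.0, 50), "g2": (17.0, 4.0, 200)}),
        ("events", "categorical", {"g1": (0.2, 50), "g2": (0.1, 200)}),
    ]

    def test_seeded_fixture_reproducible(self):
        a = simulate_clinical(self.ROWS, seed=5)
        b = simulate_clinical(self.ROWS, seed=5)
        for key in a.raw:
            assert np.array_equal(a.raw[key], b.raw[key])

    def test_summary_equals_raw_moments(self):
        fix = simulate_clinical(self.ROWS, seed=5)
        s = fix.rows[0].groups["g1"]
        raw = fix.raw[("wall", "g1")]
        assert s.mean == pytest.approx(raw.mean())
        assert s.sd == pytest.approx(raw.std(ddof=1))

    def test_summary_and_raw_paths_agree(self):
        fix = simulate_clinical(self.ROWS, seed=9)
        res = pooled_t_from_summary(fix.rows[0].groups["g1"],
                                    fix.rows[0].groups["g2"])
        t, p = sps.ttest_ind(fix.raw[("wall", "g1")], fix.raw[("wall", "g2")],
                             equal_var=True)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_two_sided == pytest.approx(p, abs=1e-10)

    def test_null_p_values_are_uniform(self):
        """Identical groups: pooled-t P over replicates is Uniform(0,1)."""
        rows = [("x", "continuous", {"g1": (10.0, 2.0, 40),
                                     "g2": (10.0, 2.0, 40)})]
        seeds = np.random.SeedSequence(0).generate_state(2000) >> 1
        ps = []
        for seed in seeds:
            fix = simulate_clinical(rows, seed=int(seed))
            ps.append(
                pooled_t_from_summary(fix.rows[0].groups["g1"],
                                      fix.rows[0].groups["g2"]).p_two_sided
            )
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.05

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate_clinical([("x", "continuous", {"g1": (1.0, 0.0, 10)})])


class TestRecovery:
    def test_single_replicate_report(self):
        report = recovery_experiment(_small_config(), n_replicates=1)
        assert len(report.replicates) == 3  # one row per class
        assert set(report.summary.columns) >= {
            "true_or", "mean_log_or", "ci_coverage", "rejection_rate",
        }

    def test_replicates_are_seed_stable(self):
        a = recovery_experiment(_small_config(), n_replicates=5)
        b = recovery_experiment(_small_config(), n_replicates=5)
        assert a.replicates.equals(b.replicates)

    def test_enriched_class_recovers_odds_ratio(self):
        """Median estimate within a factor of 2 of the generating value."""
        config = SimConfig(
            n_cases=793,
            n_controls=4523,
            classes={"truncating": ClassModel(p0=0.0009, odds_ratio=8.0,
                                              n_sites=3)},
            seed=31,
        )
        report = recovery_experiment(config, n_replicates=100)
        finite = report.replicates["or_sample"].replace(
            [np.inf, -np.inf], np.nan
        ).dropna()
        median = float(finite[finite > 0].median())
        assert 4.0 <= median <= 16.0

    def test_invalid_replicate_count(self):
        with pytest.raises(ValueError):
            recovery_experiment(_small_config(), n_replicates=0)


def test_sim_config_validation():
    with pytest.raises(ValueError):
        ClassModel(p0=1.5, odds_ratio=1.0, n_sites=1)
    with pytest.raises(ValueError):
        ClassModel(p0=0.1, odds_ratio=-1.0, n_sites=1)
    with pytest.raises(ValueError):
        SimConfig(n_cases=0)
    with pytest.raises(ValueError):
        SimConfig(classes={})
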