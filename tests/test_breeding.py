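"""Mating design, offspring allocation, genotyping strategies and selection."""

import collections

import numpy as np
import pytest

from troutsim import (
    ScenarioConfig,
    allocate_offspring,
    expected_cross_year_relationship,
    expected_repeat_dams,
    partly_factorial_matings,
    run_replicate,
    select_for_genotyping,
)
from troutsim.population import ENV_C


class TestPartlyFactorialMating:
    def test_full_scale_counts(self, rng):
        pairs = partly_factorial_matings(np.arange(50), 100 + np.arange(50), rng)
        assert len(pairs) == 100
        cfg = ScenarioConfig.full_scale()
        assert cfg.n_matings == 100
        assert cfg.n_offspring == 20000

    def test_two_by_two_gives_all_four_pairs(self, rng):
        pairs = partly_factorial_matings(np.array([0, 1]), np.array([10, 11]), rng)
        assert sorted(pairs) == [(0, 10), (0, 11), (1, 10), (1, 11)]

    @pytest.mark.parametrize("n", [2, 3, 7, 50])
    def test_degree_two_with_distinct_partners(self, n, rng):
        sires = np.arange(n)
        dams = 1000 + np.arange(n)
        pairs = partly_factorial_matings(sires, dams, rng)
        sire_partners = collections.defaultdict(set)
        dam_partners = collections.defaultdict(set)
        for s, d in pairs:
            sire_partners[s].add(d)
            dam_partners[d].add(s)
        assert all(len(v) == 2 for v in sire_partners.values())
        assert all(len(v) == 2 for v in dam_partners.values())
        counts = collections.Counter(x for p in pairs for x in p)
        assert set(counts.values()) == {2}

    def test_too_few_parents_rejected(self, rng):
        with pytest.raises(ValueError):
            partly_factorial_matings(np.array([1]), np.array([2]), rng)


class TestAllocation:
    def test_exact_split(self, rng):
        env = allocate_offspring(20000, 0.20, rng)
        assert (env == ENV_C).sum() == 4000
        assert (env != ENV_C).sum() == 16000

    def test_all_to_B_when_zero(self, rng):
        env = allocate_offspring(500, 0.0, rng)
        assert (env == ENV_C).sum() == 0

    def test_family_wise_fractions_average_to_prop(self):
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(50):
            env = allocate_offspring(2000, 0.2, rng)
            fam = np.repeat(np.arange(20), 100)
            fracs.append([np.mean(env[fam == f] == ENV_C) for f in range(20)])
        assert np.mean(fracs) == pytest.approx(0.2, abs=0.01)


class TestSelectForGenotyping:
    def _phen(self, n, seed=0):
        return np.random.default_rng(seed).standard_normal(n)

    @pytest.mark.parametrize(
        "strategy,n,budget",
        [
            ("Random", 400, 20),
            ("Top1_1", 400, 20),
            ("T1_1B1_1", 400, 20),
            ("T1_2B1_2", 400, 20),
            ("T3_4B1_4", 1600, 80),
        ],
    )
    def test_budget_and_one_chance(self, strategy, n, budget, rng):
        phen = self._phen(n)
        chosen = select_for_genotyping(phen, strategy, budget, 20, rng)
        assert chosen.size == budget
        assert np.unique(chosen).size == budget  # no fish genotyped twice

    def test_top_strategy_small_bruteforce(self, rng):
        """With 40 fish and 2 groups of 20 the selected fish are exactly the
        maxima of a disjoint partition: the global best is always selected,
        and the two picks beat everyone else in their own group."""
        phen = self._phen(40, seed=4)
        for _ in range(20):
            chosen = select_for_genotyping(phen, "Top1_1", 2, 20, rng)
            assert chosen.size == 2
            assert np.argmax(phen) in chosen
            others = np.setdiff1d(np.arange(40), chosen)
            # the two winners cover 40 fish: their min beats at least 19 others
            assert (phen[others] < phen[chosen].min()).sum() >= 19

    def test_top_and_bottom_strategy_contains_extremes(self, rng):
        phen = self._phen(400, seed=5)
        chosen = select_for_genotyping(phen, "T1_1B1_1", 20, 20, rng)
        assert np.argmax(phen) in chosen
        assert np.argmin(phen) in chosen
        ranks = np.argsort(np.argsort(phen))[chosen]
        assert (ranks >= 200).sum() == 10 and (ranks < 200).sum() == 10

    def test_t3_4b1_4_top_bottom_ratio(self, rng):
        phen = self._phen(1600, seed=6)
        chosen = select_for_genotyping(phen, "T3_4B1_4", 80, 20, rng)
        ranks = np.argsort(np.argsort(phen))[chosen]
        assert (ranks >= 800).sum() == 60  # three quarters from the top pool
        assert (ranks < 800).sum() == 20

    def test_top_selection_intensity(self):
        """The genotyped sample under best-of-20 screening averages the
        expected maximum of 20 standard normals (~1.87 SD), checked against
        a direct Monte Carlo oracle."""
        rng = np.random.default_rng(8)
        oracle = np.random.default_rng(9).standard_normal((200000, 20)).max(axis=1).mean()
        means = []
        for _ in range(30):
            phen = rng.standard_normal(2000)
            chosen = select_for_genotyping(phen, "Top1_1", 100, 20, rng)
            means.append(phen[chosen].mean())
        assert np.mean(means) == pytest.approx(oracle, abs=0.03)

    @pytest.mark.parametrize(
        "strategy,n,budget,err",
        [
            ("Top1_1", 100, 20, "groups"),  # needs 400 fish
            ("T1_1B1_1", 400, 21, "even"),
            ("T3_4B1_4", 1600, 82, "divisible"),
            ("Random", 10, 20, "exceeds"),
        ],
    )
    def test_infeasible_configurations_rejected(self, strategy, n, budget, err, rng):
        with pytest.raises(ValueError, match=err):
            select_for_genotyping(self._phen(n), strategy, budget, 20, rng)


class TestRepeatDams:
    def test_analytic_value_matches_monte_carlo(self):
        """50 dams drawn from 400 females with the 200 three-year-olds all
        retained: analytic expectation vs direct simulation of the scheme."""
        rng = np.random.default_rng(0)
        analytic = expected_repeat_dams(50, 400, 200, 200)
        reps = 20000
        count = 0
        for _ in range(reps):
            # pool: ids 0..199 new (retained next year), 200..399 old
            dams_t = rng.choice(400, 50, replace=False)
            dams_t1 = rng.choice(400, 50, replace=False)  # next year: 0..199 keep ids
            count += np.intersect1d(dams_t[dams_t < 200], dams_t1[dams_t1 < 200]).size
        mc = count / reps
        assert analytic == pytest.approx(3.125)
        assert mc == pytest.approx(analytic, abs=0.05)

    def test_low_retention_value(self):
        assert expected_repeat_dams(50, 400, 360, 40) == pytest.approx(0.625)

    def test_cross_year_relationship(self):
        assert expected_cross_year_relationship(50, 400, 200, 200) == pytest.approx(0.015625)


class TestScenarioConfig:
    def test_profiles_validate(self):
        for cfg in (ScenarioConfig.full_scale(), ScenarioConfig.desk(), ScenarioConfig.micro()):
            cfg.validate()

    def test_desk_preserves_structural_ratios(self):
        full, desk = ScenarioConfig.full_scale(), ScenarioConfig.desk()
        assert desk.group_size == full.group_size == 20
        assert desk.genotyping_budget / desk.n_offspring == pytest.approx(
            full.genotyping_budget / full.n_offspring
        )
        assert desk.n_years == full.n_years == 21
        assert desk.n_dams / desk.female_pool_size == pytest.approx(
            full.n_dams / full.female_pool_size
        )

    def test_budget_split_and_female_counts(self):
        cfg = ScenarioConfig.full_scale()
        assert (cfg.budget_B, cfg.budget_C) == (800, 200)
        assert (cfg.n_offspring_B, cfg.n_offspring_C) == (16000, 4000)
        assert (cfg.n_new_females, cfg.n_retained_females) == (200, 200)
        low = ScenarioConfig.full_scale(prop_females_kept=0.11)
        assert (low.n_new_females, low.n_retained_females) == (360, 40)

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig.micro(c_genotyping_strategy="Fancy").validate()
        with pytest.raises(ValueError):
            ScenarioConfig.micro(b_genotyping_strategy="T1_1B1_1").validate()
        with pytest.raises(ValueError):
            ScenarioConfig.micro(c_genotyping_strategy="T3_4B1_4").validate()
        with pytest.raises(ValueError):
            ScenarioConfig.micro(prop_genotyping_C=1.5).validate()
        with pytest.raises(ValueError):
            ScenarioConfig.micro(n_sires=1, n_dams=1).validate()

    def test_auto_male_fraction(self):
        assert ScenarioConfig.full_scale().resolved_male_fraction_B() == pytest.approx(0.75)
        assert ScenarioConfig.desk().resolved_male_fraction_B() == pytest.approx(0.5)


@pytest.fixture(scope="module")
def micro_run(micro_config):
    return run_replicate(micro_config, seed=1, keep_pedigree=True)


class TestBreedingLoop:
    def test_budget_conservation_every_year(self, micro_run, micro_config):
        for year, n in micro_run.n_genotyped_by_year.items():
            assert n == micro_config.genotyping_budget

    def test_early_years_have_no_evaluation(self, micro_run):
        assert all(t >= 4 for t in micro_run.eval_snapshots)
        assert set(micro_run.G_by_year) == set(range(1, 13))

    def test_inbreeding_series_valid(self, micro_run):
        F = np.array(list(micro_run.F_by_year.values()))
        assert np.all((F >= 0) & (F < 1))
        assert all(micro_run.F_by_year[t] == 0 for t in (1, 2, 3))

    def test_pedigree_complete_and_consistent(self, micro_run, micro_config):
        df = micro_run.pedigree.to_dataframe()
        offspring = df[df.birth_year >= 1]
        assert len(offspring) == micro_config.n_offspring * micro_config.n_years
        # every parent exists and was born at least 3 years earlier
        # (founders carry birth year -1 and seed the first three cohorts)
        by_id = df.set_index("id").birth_year
        sire_born = by_id[offspring.sire].values
        ok = (sire_born == -1) | (sire_born <= offspring.birth_year.values - 3)
        assert np.all(ok)
        genotyped_per_cohort = offspring.groupby("birth_year").genotyped.sum()
        for year, n in genotyped_per_cohort.items():
            if year <= micro_config.n_years - 3:
                assert n == micro_config.genotyping_budget

    def test_sires_are_genotyped_B_males(self, micro_run):
        """C testers are never selection candidates: every sire of a
        selected cohort (year >= 4) is a genotyped male kept in B."""
        df = micro_run.pedigree.to_dataframe()
        selected = df[df.birth_year >= 4]
        sires = df.set_index("id").loc[np.unique(selected.sire)]
        assert (sires.env == 0).all()
        assert sires.male.all()
        assert sires.genotyped.all()

    def test_cohort_inbreeding_matches_pedigree_algorithm(self, micro_run):
        """The tracker-based per-cohort F equals Wright's F computed from the
        complete pedigree."""
        from troutsim import pedigree_inbreeding

        df = micro_run.pedigree.to_dataframe()
        idx = {int(i): k for k, i in enumerate(df.id)}
        sire = np.array([idx.get(int(s), -1) for s in df.sire])
        dam = np.array([idx.get(int(d), -1) for d in df.dam])
        F = pedigree_inbreeding(sire, dam)
        for year, f_tracked in micro_run.F_by_year.items():
            mask = (df.birth_year == year).values
            assert F[mask].mean() == pytest.approx(f_tracked, abs=1e-12)

    def test_too_few_genotyped_males_raises(self):
        # one male in the whole B cohort can never supply two sires
        cfg = ScenarioConfig.micro(male_fraction_B=0.006)
        with pytest.raises(ValueError, match="genotyped males"):
            run_replicate(cfg, seed=0, n_years=5)
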