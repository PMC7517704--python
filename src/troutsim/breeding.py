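"""The yearly sib-testing breeding cycle.

Each year, 50 three-year-old sires and 50 dams (drawn from a pool of 400
three- and four-year-old females) are mated in a partly factorial design --
every sire to two dams and every dam to two sires -- producing 100 full-sib
families of 200 fish.  Offspring are split between the breeding environment
B (where the selection candidates stay) and the commercial environment C
(where their sibs are performance-tested and serve as the reference
population).  Three years later the cohort is phenotyped, a fixed genotyping
budget is spent according to one of five phenotype-based strategies, GEBV
are computed by GBLUP over all genotyped fish to date, and the next round of
parents is selected.  All counts scale down proportionally in the reduced
"desk" profile.

Genotyping strategies (budget fish genotyped in every case):

* ``Random``      -- a uniform sample.
* ``Top1_1``      -- the best fish of each random group of 20.
* ``T1_1B1_1``    -- best and worst of each group (half as many groups).
* ``T1_2B1_2``    -- best and worst of each group, then the best of each
                     random pair of top fish and the worst of each pair of
                     bottom fish.
* ``T3_4B1_4``    -- best and worst of each group, then the best three of
                     each random four top fish and the worst one of each
                     four bottom fish.

Every fish enters at most one screening group ("one chance" rule).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import genome as gn
from .evaluation import (
    EvaluationData,
    REMLResult,
    VarianceComponents,
    estimate_varcomp_reml,
    solve_gblup,
)
from .population import ENV_B, ENV_C, KinshipTracker, Pedigree

__all__ = [
    "ScenarioConfig",
    "PopulationState",
    "ReplicateResult",
    "partly_factorial_matings",
    "allocate_offspring",
    "select_for_genotyping",
    "run_breeding_cycle",
    "run_replicate",
    "expected_repeat_dams",
    "expected_cross_year_relationship",
    "optimize_sex_ratio",
    "GENOTYPING_STRATEGIES",
]

GENOTYPING_STRATEGIES = ("Random", "Top1_1", "T1_1B1_1", "T1_2B1_2", "T3_4B1_4")


@dataclass
class ScenarioConfig:
    """One cell of the factor grid plus scale parameters.

    The factor levels mirror the study design: genotyping strategy per
    environment, genetic correlation ``r_g`` between the B- and C-measured
    trait, heritability ``h2``, the share of the genotyping budget (and of
    offspring) allocated to C, and the proportion of selected females kept
    for a second spawning year.
    """

    # investigated factors
    c_genotyping_strategy: str = "Random"
    b_genotyping_strategy: str = "Top1_1"
    r_g: float = 0.5
    h2: float = 0.3
    prop_genotyping_C: float = 0.20
    prop_females_kept: float = 1.00

    # scale of the scheme
    n_sires: int = 50
    n_dams: int = 50
    family_size: int = 200
    genotyping_budget: int = 1000
    female_pool_size: int = 400
    n_years: int = 21
    group_size: int = 20

    # synthetic founder genome
    n_founders: int = 958
    n_chromosomes: int = 29
    total_length_cM: float = 2927.1
    n_markers: int = 32709
    n_qtl: int = 3742
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_mixing_generations: int = 10

    # sex handling: fraction of B offspring that are male ("auto" leaves
    # exactly group_size females per newly selected female, the rest male)
    male_fraction_B: float | str = "auto"
    genotype_females: bool = False

    # metric windows
    eval_years: tuple[int, int, int] = (10, 11, 12)
    gain_early_years: tuple[int, ...] = (5, 6, 7)
    gain_late_years: tuple[int, ...] = (19, 20, 21)

    # -- derived quantities ------------------------------------------------
    @property
    def n_matings(self) -> int:
        return 2 * self.n_sires

    @property
    def n_offspring(self) -> int:
        return self.n_matings * self.family_size

    @property
    def n_offspring_C(self) -> int:
        return round(self.prop_genotyping_C * self.n_offspring)

    @property
    def n_offspring_B(self) -> int:
        return self.n_offspring - self.n_offspring_C

    @property
    def budget_C(self) -> int:
        return round(self.prop_genotyping_C * self.genotyping_budget)

    @property
    def budget_B(self) -> int:
        return self.genotyping_budget - self.budget_C

    @property
    def n_new_females(self) -> int:
        """Three-year-old females selected each year."""
        return round(self.female_pool_size / (1.0 + self.prop_females_kept))

    @property
    def n_retained_females(self) -> int:
        """Four-year-old females kept from the previous year's selection."""
        return self.female_pool_size - self.n_new_females

    @property
    def n_loci(self) -> int:
        return self.n_markers + self.n_qtl

    def resolved_male_fraction_B(self) -> float:
        if self.male_fraction_B != "auto":
            f = float(self.male_fraction_B)
            if not (0.0 < f < 1.0):
                raise ValueError("male_fraction_B must lie in (0, 1)")
            return f
        if self.n_offspring_B == 0:
            return 0.5
        needed_females = self.group_size * self.n_new_females
        if not self.genotype_females and needed_females >= self.n_offspring_B:
            raise ValueError(
                "scheme infeasible: phenotypic female selection needs "
                f"{needed_females} B females but only {self.n_offspring_B} B fish exist; "
                "raise the offspring count or lower the female pool"
            )
        if self.genotype_females:
            return 0.5
        return 1.0 - needed_females / self.n_offspring_B

    def true_varcomp(self) -> VarianceComponents:
        return VarianceComponents.from_true(self.r_g, self.h2)

    def validate(self) -> None:
        if self.c_genotyping_strategy not in GENOTYPING_STRATEGIES:
            raise ValueError(f"unknown C genotyping strategy {self.c_genotyping_strategy!r}")
        if self.b_genotyping_strategy not in GENOTYPING_STRATEGIES:
            raise ValueError(f"unknown B genotyping strategy {self.b_genotyping_strategy!r}")
        if self.b_genotyping_strategy == "T1_1B1_1":
            raise ValueError("T1_1B1_1 is only applied to fish in C in this design")
        if self.c_genotyping_strategy == "T3_4B1_4":
            raise ValueError("T3_4B1_4 is only applied to fish in B in this design")
        if not 0.0 <= self.prop_genotyping_C < 1.0:
            raise ValueError("prop_genotyping_C must lie in [0, 1)")
        if not 0.0 < self.prop_females_kept <= 1.0:
            raise ValueError("prop_females_kept must lie in (0, 1]")
        if abs(self.prop_genotyping_C * self.genotyping_budget - self.budget_C) > 1e-9:
            raise ValueError("budget times prop_genotyping_C must be an integer")
        if min(self.n_sires, self.n_dams) < 2:
            raise ValueError("partly factorial mating needs at least 2 sires and 2 dams")
        if self.n_sires != self.n_dams:
            raise ValueError("the degree-2 factorial design needs equal sire and dam counts")
        if self.n_qtl >= self.n_loci:
            raise ValueError("QTL count must be smaller than the locus count")
        if self.n_years < max(self.gain_late_years, default=0):
            pass  # shortened runs are allowed; gain windows are checked at use
        _check_strategy_feasible(
            self.c_genotyping_strategy, self.n_offspring_C, self.budget_C, self.group_size
        )
        _check_strategy_feasible(
            self.b_genotyping_strategy, self.n_offspring_B, self.budget_B, self.group_size
        )
        self.resolved_male_fraction_B()

    # -- profiles ----------------------------------------------------------
    @classmethod
    def full_scale(cls, **overrides) -> "ScenarioConfig":
        """The published scheme: 20,000 offspring and 1,000 genotyped per year."""
        return cls(**overrides)

    @classmethod
    def desk(cls, **overrides) -> "ScenarioConfig":
        """Reduced-scale profile preserving every structural ratio.

        2,000 offspring and 100 genotyped per year keep the 1-in-20
        screening groups, the degree-2 factorial mating, the 3-year lag and
        the 21-year horizon; the genome shrinks to ~3,000 markers + 400 QTL
        on the same 29-chromosome, 2927.1 cM map.
        """
        base = dict(
            n_sires=10,
            n_dams=10,
            family_size=100,
            genotyping_budget=100,
            female_pool_size=80,
            n_founders=200,
            n_markers=3000,
            n_qtl=400,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def micro(cls, **overrides) -> "ScenarioConfig":
        """Tiny profile for tests: 200 offspring/year, 40 genotyped, groups of 5."""
        base = dict(
            n_sires=2,
            n_dams=2,
            family_size=50,
            genotyping_budget=40,
            female_pool_size=16,
            group_size=5,
            n_founders=60,
            n_chromosomes=5,
            total_length_cM=500.0,
            n_markers=300,
            n_qtl=60,
            n_years=12,
            eval_years=(8, 9, 10),
            gain_early_years=(4, 5),
            gain_late_years=(11, 12),
        )
        base.update(overrides)
        return cls(**base)


def _check_strategy_feasible(strategy: str, n_fish: int, budget: int, group_size: int) -> None:
    if budget == 0:
        return
    if budget > n_fish:
        raise ValueError(f"budget {budget} exceeds the {n_fish} fish available")
    if strategy == "Random":
        return
    groups_needed = {"Top1_1": budget, "T1_1B1_1": -(-budget // 2), "T1_2B1_2": budget, "T3_4B1_4": budget}[strategy]
    if strategy == "T1_1B1_1" and budget % 2:
        raise ValueError("T1_1B1_1 needs an even budget (best and worst per group)")
    if strategy == "T1_2B1_2" and budget % 2:
        raise ValueError("T1_2B1_2 needs an even budget (pairs of top and bottom fish)")
    if strategy == "T3_4B1_4" and budget % 4:
        raise ValueError("T3_4B1_4 needs a budget divisible by 4 (fours of top and bottom fish)")
    if groups_needed * group_size > n_fish:
        raise ValueError(
            f"{strategy} needs {groups_needed} disjoint groups of {group_size} "
            f"({groups_needed * group_size} fish) but only {n_fish} are available"
        )


# ---------------------------------------------------------------------------
# elementary operations


def partly_factorial_matings(
    sires: np.ndarray, dams: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Random degree-2 partly factorial design.

    Every sire is mated to two distinct dams and every dam to two distinct
    sires.  Built from two random parent orderings joined by a random cyclic
    offset, which guarantees the degree constraints for any count >= 2.
    """
    sires = np.asarray(sires)
    dams = np.asarray(dams)
    n = sires.size
    if n != dams.size:
        raise ValueError("need equal numbers of sires and dams")
    if n < 2:
        raise ValueError("partly factorial mating is infeasible with fewer than 2 pairs")
    ps = rng.permutation(sires)
    pd_ = rng.permutation(dams)
    shift = int(rng.integers(1, n))
    pairs = [(int(ps[i]), int(pd_[i])) for i in range(n)]
    pairs += [(int(ps[i]), int(pd_[(i + shift) % n])) for i in range(n)]
    return pairs


def allocate_offspring(
    n_offspring: int, prop_C: float, rng: np.random.Generator
) -> np.ndarray:
    """Environment assignment: exactly ``round(prop_C * n)`` fish to C, at random."""
    if not 0.0 <= prop_C < 1.0:
        raise ValueError("prop_C must lie in [0, 1)")
    n_C = round(prop_C * n_offspring)
    env = np.full(n_offspring, ENV_B, dtype=np.int8)
    env[rng.choice(n_offspring, size=n_C, replace=False)] = ENV_C
    return env


def _disjoint_groups(n_fish: int, n_groups: int, group_size: int, rng: np.random.Generator):
    """Random partition into disjoint groups; leftover fish are not screened."""
    if n_groups * group_size > n_fish:
        raise ValueError("not enough fish for the required screening groups")
    perm = rng.permutation(n_fish)[: n_groups * group_size]
    return perm.reshape(n_groups, group_size)


def _best_of_each(groups: np.ndarray, phen: np.ndarray) -> np.ndarray:
    return groups[np.arange(groups.shape[0]), np.argmax(phen[groups], axis=1)]


def _worst_of_each(groups: np.ndarray, phen: np.ndarray) -> np.ndarray:
    return groups[np.arange(groups.shape[0]), np.argmin(phen[groups], axis=1)]


def select_for_genotyping(
    phenotypes: np.ndarray,
    strategy: str,
    budget: int,
    group_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of the fish to genotype under one of the five strategies.

    "Best"/"worst" is by the phenotype measured in the fish's own
    environment; ties (measure-zero for continuous phenotypes) break toward
    the lower index for determinism.  Each fish is screened at most once.
    """
    phen = np.asarray(phenotypes, dtype=np.float64)
    n = phen.size
    _check_strategy_feasible(strategy, n, budget, group_size)
    if budget == 0:
        return np.empty(0, dtype=np.int64)
    if strategy == "Random":
        return np.sort(rng.choice(n, size=budget, replace=False))
    if strategy == "Top1_1":
        groups = _disjoint_groups(n, budget, group_size, rng)
        return np.sort(_best_of_each(groups, phen))
    if strategy == "T1_1B1_1":
        groups = _disjoint_groups(n, budget // 2, group_size, rng)
        return np.sort(np.r_[_best_of_each(groups, phen), _worst_of_each(groups, phen)])
    if strategy == "T1_2B1_2":
        groups = _disjoint_groups(n, budget, group_size, rng)
        tops = rng.permutation(_best_of_each(groups, phen)).reshape(-1, 2)
        bots = rng.permutation(_worst_of_each(groups, phen)).reshape(-1, 2)
        keep_top = _best_of_each(np.arange(tops.size).reshape(-1, 2), phen[tops.ravel()])
        keep_bot = _worst_of_each(np.arange(bots.size).reshape(-1, 2), phen[bots.ravel()])
        return np.sort(np.r_[tops.ravel()[keep_top], bots.ravel()[keep_bot]])
    if strategy == "T3_4B1_4":
        groups = _disjoint_groups(n, budget, group_size, rng)
        tops = rng.permutation(_best_of_each(groups, phen)).reshape(-1, 4)
        bots = rng.permutation(_worst_of_each(groups, phen)).reshape(-1, 4)
        # keep the best 3 of each random four top fish
        order = np.argsort(phen[tops], axis=1)
        keep_top = np.take_along_axis(tops, order[:, 1:], axis=1).ravel()
        keep_bot = _worst_of_each(np.arange(bots.size).reshape(-1, 4), phen[bots.ravel()])
        return np.sort(np.r_[keep_top, bots.ravel()[keep_bot]])
    raise ValueError(f"unknown strategy {strategy!r}")


def expected_repeat_dams(
    n_dams: int = 50, pool_size: int = 400, n_new: int = 200, n_retained: int = 200
) -> float:
    """Expected number of females serving as dams in two consecutive years.

    A year-t dam is a uniform draw from the pool; she can repeat only if she
    is a current-year (three-year-old) selection that gets retained, and is
    then drawn again among next year's dams:
    ``n_dams * (n_retained / pool) * (n_dams / pool)``.
    """
    return n_dams * (n_retained / pool_size) * (n_dams / pool_size)


def expected_cross_year_relationship(
    n_dams: int = 50, pool_size: int = 400, n_new: int = 200, n_retained: int = 200
) -> float:
    """Additive relationship between current-year offspring and the
    previous-year offspring of a repeated dam, for non-inbred unrelated
    parents: P(dam repeated) times the maternal half-sib relationship 1/4."""
    repeat_prob = expected_repeat_dams(n_dams, pool_size, n_new, n_retained) / n_dams
    return repeat_prob * 0.25


# ---------------------------------------------------------------------------
# population state and the yearly cycle


@dataclass
class _Cohort:
    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    male: np.ndarray
    env: np.ndarray
    tbv: np.ndarray  # (n, 2)
    haplos: Optional[np.ndarray]  # dropped once the cohort ages out
    phen: Optional[np.ndarray] = None
    genotyped_ids: Optional[np.ndarray] = None


@dataclass
class _GenoRegistry:
    """Marker genotypes and single phenotypic records of all genotyped fish."""

    marker_freqs: np.ndarray
    dosage_blocks: list = field(default_factory=list)
    ids: list = field(default_factory=list)
    y: list = field(default_factory=list)
    env: list = field(default_factory=list)
    year: list = field(default_factory=list)
    tbv: list = field(default_factory=list)
    male: list = field(default_factory=list)
    birth_year: list = field(default_factory=list)
    G: Optional[np.ndarray] = None
    _W: Optional[np.ndarray] = None
    _scale: Optional[float] = None

    @property
    def n(self) -> int:
        return sum(len(b) for b in self.ids)

    def add(self, dosages, ids, y, env, year, tbv, male, birth_year) -> None:
        W_new = dosages.astype(np.float64) - 2.0 * self.marker_freqs
        if self._scale is None:
            p = self.marker_freqs
            self._scale = 2.0 * float(np.sum(p * (1.0 - p)))
        if self._W is None:
            self._W = W_new
            self.G = (W_new @ W_new.T) / self._scale
        else:
            cross = (W_new @ self._W.T) / self._scale
            own = (W_new @ W_new.T) / self._scale
            n_old = self._W.shape[0]
            m = W_new.shape[0]
            G = np.empty((n_old + m, n_old + m))
            G[:n_old, :n_old] = self.G
            G[n_old:, :n_old] = cross
            G[:n_old, n_old:] = cross.T
            G[n_old:, n_old:] = own
            self.G = G
            self._W = np.vstack([self._W, W_new])
        self.ids.append(np.asarray(ids, dtype=np.int64))
        self.y.append(np.asarray(y, dtype=np.float64))
        self.env.append(np.asarray(env, dtype=np.int64))
        self.year.append(np.full(len(ids), year, dtype=np.int64))
        self.tbv.append(np.asarray(tbv, dtype=np.float64))
        self.male.append(np.asarray(male, dtype=bool))
        self.birth_year.append(np.full(len(ids), birth_year, dtype=np.int64))

    def evaluation_data(self) -> EvaluationData:
        return EvaluationData(
            y=np.concatenate(self.y),
            animal=np.arange(self.n),
            env=np.concatenate(self.env),
            year=np.concatenate(self.year),
            n_animals=self.n,
        )

    def all_ids(self) -> np.ndarray:
        return np.concatenate(self.ids)


@dataclass
class PopulationState:
    """Everything the yearly cycle reads and writes."""

    config: ScenarioConfig
    gmap: gn.GenomeMap
    arch: gn.TraitArchitecture
    founder_haplos: np.ndarray
    founder_ids: np.ndarray
    founder_male: np.ndarray
    registry: _GenoRegistry
    pedigree: Pedigree
    kinship: KinshipTracker
    rng_streams: dict
    year: int = 0
    next_id: int = 0
    cohorts: dict = field(default_factory=dict)
    prev_new_females: Optional[np.ndarray] = None  # ids of last year's 3yo selection
    haplo_lookup: dict = field(default_factory=dict)  # id -> (cohort year or "founder")
    G_by_year: dict = field(default_factory=dict)
    F_by_year: dict = field(default_factory=dict)
    eval_snapshots: dict = field(default_factory=dict)
    gebv_by_id: dict = field(default_factory=dict)
    n_genotyped_by_year: dict = field(default_factory=dict)
    applied_ridge_years: list = field(default_factory=list)
    reml_result: Optional[REMLResult] = None

    def haplos_of(self, ids: np.ndarray) -> np.ndarray:
        out = np.empty((len(ids), 2, self.gmap.n_loci), dtype=np.uint8)
        for k, id_ in enumerate(ids):
            src = self.haplo_lookup[int(id_)]
            if src == "founder":
                out[k] = self.founder_haplos[int(np.searchsorted(self.founder_ids, id_))]
            else:
                coh = self.cohorts[src]
                out[k] = coh.haplos[int(np.searchsorted(coh.ids, id_))]
        return out


def initialize_state(config: ScenarioConfig, seed) -> PopulationState:
    """Build founders, map and trait architecture; year counter at 0.

    All randomness flows from named substreams of one seed so that the
    founder genome is shared by scenarios that share a replicate index.
    """
    config.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    keys = ("map", "founders", "architecture", "phenotypes", "genotyping", "mating", "selection")
    children = ss.spawn(len(keys))
    streams = {k: np.random.default_rng(c) for k, c in zip(keys, children)}
    gmap = gn.build_genetic_map(
        config.n_chromosomes, config.total_length_cM, config.n_loci, streams["map"]
    )
    founders = gn.generate_founder_population(
        config.n_founders,
        gmap,
        config.maf_low,
        config.maf_high,
        config.n_mixing_generations,
        streams["founders"],
    )
    arch = gn.assign_trait_architecture(
        gmap, founders, config.n_qtl, config.r_g, config.h2, streams["architecture"]
    )
    founder_ids = np.arange(config.n_founders, dtype=np.int64)
    founder_male = np.zeros(config.n_founders, dtype=bool)
    founder_male[: config.n_founders // 2] = True
    marker_freqs = founders[:, :, arch.marker_indices].sum(axis=(0, 1)) / (2.0 * config.n_founders)
    pedigree = Pedigree()
    pedigree.append(
        founder_ids,
        np.full(config.n_founders, -1),
        np.full(config.n_founders, -1),
        birth_year=-1,
        sex_male=founder_male,
        env=np.full(config.n_founders, -1),
    )
    state = PopulationState(
        config=config,
        gmap=gmap,
        arch=arch,
        founder_haplos=founders,
        founder_ids=founder_ids,
        founder_male=founder_male,
        registry=_GenoRegistry(marker_freqs=marker_freqs),
        pedigree=pedigree,
        kinship=KinshipTracker(founder_ids),
        rng_streams=streams,
        next_id=config.n_founders,
    )
    for id_ in founder_ids:
        state.haplo_lookup[int(id_)] = "founder"
    return state


def _phenotype_cohort(state: PopulationState, cohort: _Cohort) -> None:
    rng = state.rng_streams["phenotypes"]
    own_tbv = cohort.tbv[np.arange(len(cohort.ids)), cohort.env]
    cohort.phen = gn.simulate_phenotypes(own_tbv, state.arch.sigma_e2, rng)


def _genotype_and_evaluate(state: PopulationState, cohort: _Cohort, year: int) -> None:
    cfg = state.config
    rng = state.rng_streams["genotyping"]
    chosen_parts = []
    for env, strategy, budget in (
        (ENV_B, cfg.b_genotyping_strategy, cfg.budget_B),
        (ENV_C, cfg.c_genotyping_strategy, cfg.budget_C),
    ):
        pool = np.flatnonzero(cohort.env == env)
        if budget == 0 or pool.size == 0:
            continue
        local = select_for_genotyping(cohort.phen[pool], strategy, budget, cfg.group_size, rng)
        chosen_parts.append(pool[local])
    chosen = np.sort(np.concatenate(chosen_parts))
    dosages = cohort.haplos[chosen][:, :, state.arch.marker_indices].sum(axis=1)
    state.registry.add(
        dosages,
        ids=cohort.ids[chosen],
        y=cohort.phen[chosen],
        env=cohort.env[chosen],
        year=year,
        tbv=cohort.tbv[chosen],
        male=cohort.male[chosen],
        birth_year=year - 3,
    )
    cohort.genotyped_ids = cohort.ids[chosen]
    state.pedigree.mark_genotyped(cohort.genotyped_ids)
    state.n_genotyped_by_year[year] = int(chosen.size)

    data = state.registry.evaluation_data()
    result = solve_gblup(data, state.registry.G, cfg.true_varcomp())
    if result.applied_ridge:
        state.applied_ridge_years.append((year, result.applied_ridge))
    all_ids = state.registry.all_ids()
    state.gebv_by_id = {
        int(i): (result.gebv[k, 0], result.gebv[k, 1]) for k, i in enumerate(all_ids)
    }
    # record the 3-year-old genotyped B candidates of this year
    is_current = np.isin(all_ids, cohort.genotyped_ids)
    envs = np.concatenate(state.registry.env)
    sel = is_current & (envs == ENV_B)
    tbv_all = np.vstack(state.registry.tbv)
    crit = 1 if cfg.prop_genotyping_C > 0 else 0  # GEBV of C trait, else B trait
    state.eval_snapshots[year] = {
        "ids": all_ids[sel],
        "gebv": result.gebv[sel, crit],
        "tbv_C": tbv_all[sel, 1],
    }


def _selection_criterion(state: PopulationState, ids: np.ndarray) -> np.ndarray:
    """GEBV used for ranking: C trait when C records exist, else B trait."""
    crit = 1 if state.config.prop_genotyping_C > 0 else 0
    return np.array([state.gebv_by_id[int(i)][crit] for i in ids])


def _select_parents(state: PopulationState, cohort: _Cohort, year: int):
    cfg = state.config
    rng = state.rng_streams["selection"]

    geno = cohort.genotyped_ids
    geno_local = np.searchsorted(cohort.ids, geno)
    # sires come from genotyped B males only: C testers are never candidates
    geno_male = geno[cohort.male[geno_local] & (cohort.env[geno_local] == ENV_B)]
    if geno_male.size < cfg.n_sires:
        raise ValueError(
            f"only {geno_male.size} genotyped males at year {year}: cannot select "
            f"{cfg.n_sires} sires; adjust male_fraction_B"
        )
    crit = _selection_criterion(state, geno_male)
    sires = geno_male[np.argsort(-crit, kind="stable")[: cfg.n_sires]]

    if cfg.genotype_females:
        geno_fem = geno[(~cohort.male[geno_local]) & (cohort.env[geno_local] == ENV_B)]
        if geno_fem.size < cfg.n_new_females:
            raise ValueError(
                f"only {geno_fem.size} genotyped females at year {year}: cannot select "
                f"{cfg.n_new_females}"
            )
        critf = _selection_criterion(state, geno_fem)
        new_females = geno_fem[np.argsort(-critf, kind="stable")[: cfg.n_new_females]]
    else:
        fem = np.flatnonzero((~cohort.male) & (cohort.env == ENV_B))
        groups = _disjoint_groups(fem.size, cfg.n_new_females, cfg.group_size, rng)
        best = _best_of_each(groups, cohort.phen[fem])
        new_females = cohort.ids[fem[best]]

    prev = state.prev_new_females
    n_keep = cfg.n_retained_females
    if prev is None or len(prev) < n_keep:
        raise RuntimeError("female retention pool missing; state not bootstrapped")
    if cfg.genotype_females and all(int(i) in state.gebv_by_id for i in prev):
        critp = _selection_criterion(state, prev)
        retained = prev[np.argsort(-critp, kind="stable")[:n_keep]]
    else:
        retained = rng.choice(prev, size=n_keep, replace=False)

    pool = np.concatenate([new_females, retained])
    dams = rng.choice(pool, size=cfg.n_dams, replace=False)
    return sires, dams, new_females


def _make_cohort(state: PopulationState, sires: np.ndarray, dams: np.ndarray, year: int) -> None:
    cfg = state.config
    rng = state.rng_streams["mating"]
    pairs = partly_factorial_matings(sires, dams, rng)
    sire_ids = np.repeat([p[0] for p in pairs], cfg.family_size)
    dam_ids = np.repeat([p[1] for p in pairs], cfg.family_size)
    n = sire_ids.size

    sire_h = state.haplos_of(np.array([p[0] for p in pairs]))
    dam_h = state.haplos_of(np.array([p[1] for p in pairs]))
    rep = np.repeat(np.arange(len(pairs)), cfg.family_size)
    g_s = gn.sample_gametes(sire_h[rep], state.gmap, rng)
    g_d = gn.sample_gametes(dam_h[rep], state.gmap, rng)
    haplos = np.stack([g_s, g_d], axis=1)

    env = allocate_offspring(n, cfg.prop_genotyping_C, rng)
    male = np.zeros(n, dtype=bool)
    b_idx = np.flatnonzero(env == ENV_B)
    c_idx = np.flatnonzero(env == ENV_C)
    mf = cfg.resolved_male_fraction_B()
    n_male_B = round(mf * b_idx.size)
    male[rng.permutation(b_idx)[:n_male_B]] = True
    male[rng.permutation(c_idx)[: c_idx.size // 2]] = True

    tbv = gn.true_breeding_values(haplos, state.arch)
    ids = np.arange(state.next_id, state.next_id + n, dtype=np.int64)
    state.next_id += n

    cohort = _Cohort(
        ids=ids, sire=sire_ids, dam=dam_ids, male=male, env=env, tbv=tbv, haplos=haplos
    )
    state.cohorts[year] = cohort
    for id_ in ids:
        state.haplo_lookup[int(id_)] = year
    state.pedigree.append(ids, sire_ids, dam_ids, year, male, env)

    state.G_by_year[year] = float(tbv[:, 1].mean())
    pair_F = state.kinship.inbreeding_of_offspring(
        np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])
    )
    state.F_by_year[year] = float(pair_F.mean())

    # age out cohorts no longer needed as parents (kept: 3yo and 4yo)
    stale = year - 5
    if stale in state.cohorts and state.cohorts[stale].haplos is not None:
        old = state.cohorts[stale]
        for id_ in old.ids:
            state.haplo_lookup.pop(int(id_), None)
        old.haplos = None


def _track_selected(state: PopulationState, cohort: _Cohort, selected_ids: np.ndarray) -> None:
    """Register newly selected parents with the kinship tracker."""
    new = np.array([i for i in selected_ids if int(i) not in state.kinship], dtype=np.int64)
    if new.size == 0:
        return
    local = np.searchsorted(cohort.ids, new)
    state.kinship.add(new, cohort.sire[local], cohort.dam[local])


def run_breeding_cycle(state: PopulationState, year: int) -> None:
    """Advance the scheme by one year.

    Years 1-3 draw parents at random from the founder base; from year 4 the
    cohort born three years earlier is phenotyped, genotyped under the
    configured strategies, evaluated by GBLUP with the true variance
    components, and the new sires, females and dams are selected.
    """
    cfg = state.config
    rng = state.rng_streams["selection"]
    state.year = year
    if year <= 3:
        males = state.founder_ids[state.founder_male]
        fems = state.founder_ids[~state.founder_male]
        sires = rng.choice(males, size=cfg.n_sires, replace=False)
        dams = rng.choice(fems, size=cfg.n_dams, replace=False)
        if year == 3:
            # bootstrap the retention pool with base-population females
            state.prev_new_females = rng.choice(fems, size=cfg.n_new_females, replace=False)
    else:
        cohort = state.cohorts[year - 3]
        _phenotype_cohort(state, cohort)
        _genotype_and_evaluate(state, cohort, year)
        sires, dams, new_females = _select_parents(state, cohort, year)
        _track_selected(state, cohort, np.concatenate([sires, new_females]))
        state.prev_new_females = new_females
    _make_cohort(state, sires, dams, year)


@dataclass
class ReplicateResult:
    """Per-replicate simulation outputs feeding the metrics module."""

    G_by_year: dict
    F_by_year: dict
    eval_snapshots: dict
    n_genotyped_by_year: dict
    config: ScenarioConfig
    reml_result: Optional[REMLResult] = None
    pedigree: Optional[Pedigree] = None


def run_replicate(
    config: ScenarioConfig,
    seed,
    reml_year: int | None = None,
    n_years: int | None = None,
    keep_pedigree: bool = False,
    reml_max_iter: int = 200,
) -> ReplicateResult:
    """One full replicate of the breeding scheme."""
    state = initialize_state(config, seed)
    last = n_years if n_years is not None else config.n_years
    for year in range(1, last + 1):
        run_breeding_cycle(state, year)
        if reml_year is not None and year == reml_year:
            data = state.registry.evaluation_data()
            state.reml_result = estimate_varcomp_reml(
                data, state.registry.G, max_iter=reml_max_iter
            )
    return ReplicateResult(
        G_by_year=state.G_by_year,
        F_by_year=state.F_by_year,
        eval_snapshots=state.eval_snapshots,
        n_genotyped_by_year=state.n_genotyped_by_year,
        config=config,
        reml_result=state.reml_result,
        pedigree=state.pedigree if keep_pedigree else None,
    )


def optimize_sex_ratio(
    config: ScenarioConfig,
    grid: tuple[float, ...],
    pilot_replicates: int = 2,
    pilot_years: int | None = None,
    seed: int = 0,
) -> float:
    """Pick the B male fraction maximizing mean gain over short pilot runs.

    Purely optional: scenarios normally fix the fraction in the config (the
    "auto" rule).  The returned value is always a grid member.
    """
    from .metrics import rate_of_genetic_gain

    if len(grid) == 1:
        return float(grid[0])
    best, best_gain = None, -np.inf
    for frac in grid:
        cfg = dataclasses.replace(config, male_fraction_B=float(frac))
        last = pilot_years or cfg.n_years
        early = cfg.gain_early_years
        late = cfg.gain_late_years
        if max(late) > last:  # shortened pilot: measure gain over what exists
            early = tuple(t for t in early if t <= last - 2) or (4,)
            late = (last - 1, last)
        gains = []
        for rep in range(pilot_replicates):
            res = run_replicate(cfg, np.random.SeedSequence([seed, rep]), n_years=last)
            gains.append(rate_of_genetic_gain(res.G_by_year, early, late))
        g = float(np.mean(gains))
        if g > best_gain:
            best, best_gain = float(frac), g
    return best
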