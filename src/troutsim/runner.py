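"""Scenario grids, replicate orchestration and table-shaped reporting.

A scenario grid reproduces the base-plus-alternatives structure of the
study: a base scheme (random genotyping in C, top-of-group genotyping in B,
20% of genotyping to C, all selected females kept a second year) crossed
with the genetic correlation and heritability levels, plus one-factor
sweeps.  Each scenario runs independent replicates with seeds derived from a
master seed and a scenario hash, so adding scenarios never perturbs the
seeds of existing ones.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd

from .breeding import ReplicateResult, ScenarioConfig, run_replicate
from .metrics import MetricsReport, accuracy_and_bias, rate_of_genetic_gain, rate_of_inbreeding, summarize_replicates

__all__ = [
    "ScenarioGrid",
    "build_scenario_grid",
    "scenario_seed",
    "replicate_metrics",
    "run_scenario",
    "run_reml_snapshot",
    "report",
]

R_G_LEVELS = (0.2, 0.5, 0.8)
H2_LEVELS = (0.1, 0.3)
C_STRATEGIES = ("Random", "T1_1B1_1", "T1_2B1_2", "Top1_1")
B_STRATEGIES = ("Random", "T3_4B1_4", "T1_2B1_2", "Top1_1")
ALLOCATION_LEVELS = (0.0, 0.20, 0.40, 0.60)
RETENTION_LEVELS = (1.00, 0.11)


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a scenario run bit for bit."""

    scenario: str
    master_seed: int
    n_replicates: int
    profile: str
    software_version: str
    output_dir: str

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def cohort_summary(result: ReplicateResult) -> pd.DataFrame:
    """Per-year cohort table: mean C-trait TBV, mean inbreeding, genotyped count."""
    years = sorted(result.G_by_year)
    return pd.DataFrame(
        {
            "year": years,
            "mean_tbv_C": [result.G_by_year[t] for t in years],
            "mean_inbreeding": [result.F_by_year.get(t, np.nan) for t in years],
            "n_genotyped": [result.n_genotyped_by_year.get(t, 0) for t in years],
        }
    )


@dataclasses.dataclass
class ScenarioGrid:
    """Named scenario configurations; not the full factor cross."""

    scenarios: dict[str, ScenarioConfig]

    def __iter__(self):
        return iter(self.scenarios.items())

    def __len__(self):
        return len(self.scenarios)


def build_scenario_grid(
    base_overrides: dict | None = None,
    profile: str = "full",
    sweeps: tuple[str, ...] = ("c_strategy", "b_strategy", "allocation"),
) -> ScenarioGrid:
    """Base scenario plus one-factor-at-a-time sweeps.

    ``c_strategy``: four C genotyping strategies x r_g x h2 (B fixed at
    Top1_1).  ``b_strategy``: four B strategies x r_g x h2 (C random).
    ``allocation``: genotyping share to C in {0, 20, 40, 60}% crossed with
    female retention {100%, 11%} x r_g, at h2 = 0.3 only.
    """
    maker = {"full": ScenarioConfig.full_scale, "desk": ScenarioConfig.desk, "micro": ScenarioConfig.micro}
    if profile not in maker:
        raise ValueError(f"unknown profile {profile!r}")
    overrides = dict(base_overrides or {})
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown factors in overrides: {sorted(unknown)}")

    def make(**kw) -> ScenarioConfig:
        merged = {**overrides, **kw}
        return maker[profile](**merged)

    grid: dict[str, ScenarioConfig] = {}
    for rg in R_G_LEVELS:
        for h2 in H2_LEVELS:
            grid[f"base_rg{rg}_h{h2}"] = make(r_g=rg, h2=h2)
    if "c_strategy" in sweeps:
        for strat in C_STRATEGIES:
            for rg in R_G_LEVELS:
                for h2 in H2_LEVELS:
                    grid[f"C_{strat}_rg{rg}_h{h2}"] = make(
                        c_genotyping_strategy=strat, r_g=rg, h2=h2
                    )
    if "b_strategy" in sweeps:
        for strat in B_STRATEGIES:
            for rg in R_G_LEVELS:
                for h2 in H2_LEVELS:
                    grid[f"B_{strat}_rg{rg}_h{h2}"] = make(
                        b_genotyping_strategy=strat,
                        c_genotyping_strategy="Random",
                        r_g=rg,
                        h2=h2,
                    )
    if "allocation" in sweeps:
        for kept in RETENTION_LEVELS:
            for prop in ALLOCATION_LEVELS:
                for rg in R_G_LEVELS:
                    name = f"alloc_pC{int(prop * 100)}_pF{int(kept * 100)}_rg{rg}"
                    try:
                        grid[name] = make(
                            prop_genotyping_C=prop,
                            prop_females_kept=kept,
                            h2=0.3,
                            c_genotyping_strategy="Random",
                        )
                        grid[name].validate()
                    except ValueError:
                        # a cell can be infeasible at reduced scale (e.g. the
                        # 11% retention pool outgrows the female cohort)
                        grid.pop(name, None)
    return ScenarioGrid(grid)


def scenario_seed(config: ScenarioConfig, master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Stable per-replicate seed from the master seed and a config hash."""
    key = repr(sorted(dataclasses.asdict(config).items())).encode()
    h = zlib.crc32(key)
    return np.random.SeedSequence([int(master_seed), int(h), int(replicate)])


def replicate_metrics(result: ReplicateResult) -> dict[str, float]:
    """Gain, inbreeding, accuracy and bias of one replicate."""
    cfg = result.config
    out: dict[str, float] = {}
    try:
        out["delta_G"] = rate_of_genetic_gain(
            result.G_by_year, cfg.gain_early_years, cfg.gain_late_years
        )
    except ValueError:
        out["delta_G"] = np.nan
    years = [t for t in range(5, cfg.n_years + 1) if t in result.F_by_year]
    out["delta_F_percent"] = (
        rate_of_inbreeding(result.F_by_year, years) if len(years) >= 3 else np.nan
    )
    pairs = [
        (result.eval_snapshots[t]["gebv"], result.eval_snapshots[t]["tbv_C"])
        for t in cfg.eval_years
        if t in result.eval_snapshots
    ]
    if pairs:
        out["accuracy"], out["bias_slope"] = accuracy_and_bias(pairs)
    else:
        out["accuracy"] = out["bias_slope"] = np.nan
    return out


def run_scenario(
    config: ScenarioConfig,
    n_replicates: int,
    master_seed: int,
    reml_year: int | None = None,
    n_years: int | None = None,
    reml_max_iter: int = 50,
    progress: bool = False,
) -> pd.DataFrame:
    """Independent replicates of one scenario; one metrics row per replicate.

    When ``reml_year`` is set, a bivariate REML snapshot is fitted to the
    records accumulated at that year and the estimates are reported as extra
    columns (the snapshot is a side channel: selection keeps using the true
    variance components).  A failed replicate is recorded as a NaN row so
    the scenario continues.
    """
    rows = []
    for rep in range(n_replicates):
        seed = scenario_seed(config, master_seed, rep)
        try:
            res = run_replicate(
                config, seed, reml_year=reml_year, n_years=n_years, reml_max_iter=reml_max_iter
            )
            row = {"replicate": rep, **replicate_metrics(res)}
            if res.reml_result is not None:
                vc = res.reml_result.varcomp
                row.update(
                    sigma2_gB_hat=vc.sigma2_gB,
                    sigma2_gC_hat=vc.sigma2_gC,
                    sigma_gBgC_hat=vc.sigma_gBgC,
                    sigma2_eB_hat=vc.sigma2_eB,
                    sigma2_eC_hat=vc.sigma2_eC,
                    h2_B_hat=vc.h2_B,
                    h2_C_hat=vc.h2_C,
                    reml_converged=float(res.reml_result.converged),
                )
            row["failed"] = 0.0
        except Exception as exc:  # noqa: BLE001 - a replicate failure must not kill the scenario
            row = {"replicate": rep, "failed": 1.0, "error": str(exc)}
        rows.append(row)
        if progress:
            import sys

            print(f"  replicate {rep + 1}/{n_replicates} done", file=sys.stderr)
    return pd.DataFrame(rows)


def run_reml_snapshot(
    config: ScenarioConfig, n_replicates: int, master_seed: int, year: int = 10
) -> pd.DataFrame:
    """Variance-component snapshot: run each replicate to ``year`` only."""
    return run_scenario(config, n_replicates, master_seed, reml_year=year, n_years=year)


def report(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Scenario summary table: replicate mean and SE of every metric."""
    rows = []
    for name, df in results.items():
        ok = df[df.get("failed", 0.0) == 0.0]
        if len(ok) < 2:
            continue
        rep: MetricsReport = summarize_replicates(ok.drop(columns=["replicate"], errors="ignore"))
        row = {"scenario": name, "n_replicates": rep.n_replicates}
        for metric in rep.mean.index:
            if metric == "failed":
                continue
            row[metric] = rep.mean[metric]
            row[f"{metric}_se"] = rep.se[metric]
        if np.isfinite(row.get("delta_F_percent", np.nan)) and row.get("delta_F_percent"):
            row["gain_per_percent_inbreeding"] = row["delta_G"] / row["delta_F_percent"]
        rows.append(row)
    return pd.DataFrame(rows)
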