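"""Estimate variance components mid-scheme and see the genotyping distortion.

Runs the micro profile to year 10 under two B-genotyping strategies and fits
the bivariate REML to all accumulated genotyped records.  With random
genotyping the estimates sit near the simulated values (genetic variance 1,
residual 2.333 at h2 = 0.3); top-of-group genotyping truncates the sample
and collapses the apparent genetic variance in B.
Run:  python examples/reml_snapshot.py
"""

from troutsim import ScenarioConfig
from troutsim.runner import run_reml_snapshot

for strategy in ("Random", "Top1_1"):
    cfg = ScenarioConfig.micro(
        b_genotyping_strategy=strategy, c_genotyping_strategy="Random",
        r_g=0.5, h2=0.3,
    )
    df = run_reml_snapshot(cfg, n_replicates=4, master_seed=11, year=10)
    ok = df[df.failed == 0.0]
    print(f"B genotyping {strategy:<8}: "
          f"sigma2_gB {ok.sigma2_gB_hat.mean():.2f} (simulated 1), "
          f"sigma2_eB {ok.sigma2_eB_hat.mean():.2f} (simulated 2.33), "
          f"h2_B {ok.h2_B_hat.mean():.2f} (simulated 0.3)")
print()
print("Screening only phenotypic winners removes most of the genetic spread")
print("from the genotyped sample, so REML attributes too little variance to")
print("genetics: random genotyping is needed for variance estimation.")
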