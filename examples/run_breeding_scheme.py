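"""Run a few replicates of the sib-testing breeding scheme end to end.

Uses the tiny "micro" profile (200 offspring/year) so the script finishes in
seconds; swap in ``ScenarioConfig.desk()`` for the reduced-scale study
profile (2,000 offspring/year, minutes per replicate set).
Run:  python examples/run_breeding_scheme.py
"""

from troutsim import ScenarioConfig
from troutsim.runner import report, run_scenario

cfg = ScenarioConfig.micro(r_g=0.5, h2=0.3)
df = run_scenario(cfg, n_replicates=5, master_seed=42)
summary = report({"micro_base": df}).iloc[0]

print(f"scenario: C-{cfg.c_genotyping_strategy}, B-{cfg.b_genotyping_strategy}, "
      f"r_g={cfg.r_g}, h2={cfg.h2}, {cfg.n_offspring} offspring/yr")
print(f"replicates            : {int(summary.n_replicates)}")
print(f"rate of gain dG       : {summary.delta_G:.3f} +- {summary.delta_G_se:.3f} "
      "(C-trait genetic SD per year)")
print(f"rate of inbreeding dF : {summary.delta_F_percent:.2f} +- {summary.delta_F_percent_se:.2f} % per generation")
print(f"GEBV accuracy         : {summary.accuracy:.3f} +- {summary.accuracy_se:.3f}")
print(f"dispersion bias       : {summary.bias_slope:.3f} +- {summary.bias_slope_se:.3f} "
      "(TBV-on-GEBV slope; 1 = unbiased)")
print()
print("dG is measured on the commercial-environment trait (the breeding goal);")
print("accuracy and bias are for the C-trait GEBV of the genotyped candidates")
print("that stayed in the breeding environment.")
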