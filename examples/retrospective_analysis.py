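"""Full retrospective analysis on a simulated healthy/cancer cohort.

Generates a cohort with the calibrated label mixtures and a hazard
increment of 0.15 per detected SIG1 taxon, runs the whole pipeline
(scoring, contrast, survival correlation, median split, volcano,
subtypes), and prints the headline statistics.
"""

from sigscore import SimulationConfig, run_retrospective_analysis, simulate_cohort

sim = simulate_cohort(SimulationConfig(seed=7, n_healthy=400, n_cancer=400))
report = run_retrospective_analysis(sim.table, sim.clinical)

summary = report.summary()
c = summary["contrast"]
print("label counts (healthy/cancer x SIG1+/GRAY/SIG2+):")
print(report.contrast.table_2x3.to_string())
print(f"Fisher exact p = {c['fisher_p']:.3g}, odds ratio = {c['odds_ratio']:.2f}")
r1 = summary["survival_correlation_sig1"]
print(f"SIG1 count vs overall survival: Spearman rho = {r1['rho']:.3f} "
      f"(p = {r1['p_value']:.3g}, n = {r1['n']})")
ms = summary["median_split_os"]
print(f"median split at n_sig1 > {ms['threshold']:.0f}: log-rank p = "
      f"{ms['logrank_p']:.3g}; median OS {ms['median_high']:.1f} vs "
      f"{ms['median_low']:.1f} months")
sub = report.subtypes["subtype"].value_counts().to_dict()
print("dysbiosis subtypes:", sub)
print()
print("cancer samples skew dysbiotic/gray, the SIG1 burden correlates")
print("negatively with survival, and the high-SIG1 arm dies faster —")
print("the three signals the generator plants and the pipeline recovers.")
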