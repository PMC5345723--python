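"""Replicated genotyping-effort study on a scaled synthetic trial.

Runs the full pipeline at 0/50/100% family genotyping effort (0% is the
pedigree-only baseline): per replicate, the genotyped set is subsampled
per family, G is rebuilt and blended into H, the bivariate model is
refitted, and breeding-value accuracies are computed at variance
components fixed to the full-genotyping estimates.
"""

from singlestep import (
    EffortScenario, SimConfig, StudyConfig, run_effort_study,
    simulate_population,
)
from singlestep.io import write_report

cfg = SimConfig(n_families=40, n_provenances=8, n_markers=500, seed=3)
ped, truth, genotypes, phenotypes = simulate_population(cfg)

scenarios = [EffortScenario(0), EffortScenario(50, n_reps=3), EffortScenario(100)]
results = run_effort_study(phenotypes, ped, genotypes, scenarios,
                           StudyConfig(seed=3))

print(f"{'effort':>6} {'h2 HT':>7} {'h2 WD':>7} {'AIC':>9} "
      f"{'acc geno':>9} {'acc non':>8} {'rho prog':>9}")
for r in results:
    m = r.aggregate()["mean"]
    acc_g = m.get("acc_genotyped_HT", float("nan"))
    acc_n = m.get("acc_nongenotyped_HT", float("nan"))
    print(f"{r.effort:>5}% {m['h2_HT']:7.3f} {m['h2_WD']:7.3f} "
          f"{m['aic']:9.1f} {acc_g:9.3f} {acc_n:8.3f} "
          f"{m['spearman_progeny_HT']:9.3f}")

paths = write_report(results, "scratch/effort_demo")
print(f"\nwrote tables and JSON to {paths['json'].parent}/")
print("Reading the table: AIC falls as genotyping rises (better fit); the "
      "genotyped progeny gain accuracy while the nongenotyped stay at the "
      "pedigree baseline; the Spearman rho against the 0% ranking drops "
      "below 1, i.e. marker information reorders the candidates.")
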