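"""Run the entire analysis chain on a small synthetic cohort.

simulate -> fit both models per subject -> convergence checks -> LOO ->
learning metrics -> subgrouping -> age classification -> bias screen,
all from one seeded configuration.  Writes every stage artifact under
./scratch/pipeline_demo and prints the consolidated summary.  Rerunning
with the same config and seed reproduces the outputs byte for byte.
"""

from navlearn import RunConfig, SamplerConfig, run_pipeline

config = RunConfig(
    preset="behavioral",
    sampler=SamplerConfig(chains=2, iterations=600, warmup=300, seed=7),
    k_range=(3, 6),
    cv_folds=5,
    n_young=8,
    n_old=8,
)

report = run_pipeline(config, "scratch/pipeline_demo")
print(f"subjects analysed:        {len(report.metrics)}")
print(f"selected learner groups:  k = {report.selected_k} "
      f"(silhouettes {dict((k, round(v, 3)) for k, v in report.silhouette_by_k.items())})")
print(f"mean LOO difference:      "
      f"{report.metrics['loo_difference'].mean():+.1f} (block - trial; "
      "positive favors block-wise learning states)")
print(f"age-group mean AUC:       {report.mean_auc:.3f}")
print(f"bias cells significant after correction: "
      f"{int(report.bias_table['significant_bonferroni'].sum())} of "
      f"{len(report.bias_table)}")
print(f"subjects flagged by convergence check:   "
      f"{report.flagged_subjects or 'none'}")
print("\nArtifacts (trials, metrics, subgroups, classifier, bias tables) "
      "are under scratch/pipeline_demo/.")
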