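"""End-to-end framework run: CV, distance-based transferability regression,
screening, and daily flux simulation at meteorological stations.

Runs a compact configuration (small forests, 3-fold x 3-split CV) and prints
the run report: model counts, the share of skilful models, the regression's
classification accuracy, and how many met stations received a model.
"""

from fluxbridge import HyperSearchConfig, NetworkConfig, PipelineConfig, run_full_pipeline

cfg = PipelineConfig(
    network=NetworkConfig(
        n_flux_stations=24, n_met_stations=6, years=(2010, 2011),
        missing_rate=0.03, seed=3,
    ),
    k=3, p=3,
    hyper=HyperSearchConfig(
        n_iter=1, n_estimators=(30, 30), allow_unlimited_depth=False,
        max_depth=(14, 14), min_samples_leaf=(2, 2), max_features=(0.7, 0.7),
        max_train_rows=4000,
    ),
    seed=3,
)
result = run_full_pipeline(cfg, out_dir="scratch/example_run")
r = result.report

print(f"models trained: {r.model_count} "
      f"(categories x k x p x scenarios x targets)")
print(f"evaluations per category: {r.evaluation_counts}")
print("\nshare of (model, test station) evaluations with R2 >= 0.5:")
for key, frac in sorted(r.frac_evals_r2_ge_05.items()):
    print(f"  {key}: {100 * frac:.1f}%")
print("\nquality-class accuracy of the R2-simulation regression:")
for key, acc in sorted(r.rsm_accuracy.items()):
    print(f"  {key}: {100 * acc:.1f}%")
print("\npercentage of met stations that received a model:")
for key, pct in sorted(r.transfer_pct.items()):
    print(f"  {key}: {pct:.1f}%")
print("\nPer-station daily NEE/WF CSVs and station_info.csv written under "
      "scratch/example_run/fluxes/")
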