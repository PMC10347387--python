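"""A reduced factorial benchmark: imputers x selectors x algorithms.

Runs a 2 x 2 x 3 slice of the full grid on a shared stratified 8:2 split,
ranks the models by Model Benefit, and regresses the metrics on the
pipeline factors.  (The full 4 x 4 x 6 x 2-flag grid -- 192 models -- runs
the same way via the default ExperimentConfig; it takes a few minutes.)
"""

import glycobench as gb

catalog = gb.load_variable_catalog()
config = gb.CohortConfig(n=980, seed=4)
cohort = gb.inject_missingness(gb.sample_cohort(catalog, config), config)
screened, _ = gb.apply_prescreen(cohort)

experiment = gb.ExperimentConfig(
    seed=4,
    imputers=("SI", "OD"),
    selectors=("LA", "RD"),
    algorithms=("LGBM", "LR", "CB"),
    include_fbg_flags=(True, False),
    folds=3,
    grids=gb.fast_grids(),
)
records, man = gb.run_factorial(screened, experiment)
print(f"trained {len(records)} models over {len(man)} dataset variants")

frame = gb.records_frame(records)
best_with = frame[frame.include_fbg].AUC.max()
best_without = frame[~frame.include_fbg].AUC.max()
print(f"best AUC with FBG {best_with:.3f} vs without {best_without:.3f}")

print("\ntop 5 by Model Benefit:")
for r in gb.rank_models(records, "MB", top=5):
    flag = "FBG+" if r.include_fbg else "FBG-"
    print(f"  {r.algorithm:>4} dataset {r.dataset_number:>2} {flag} "
          f"MB {r.metrics['MB']:>9.2f}  AUC {r.metrics['AUC']:.3f}  "
          f"acc {r.metrics['accuracy']:.3f}")

meta = gb.meta_regression(records, metrics=("MB", "AUC"))
print("\nmeta-regression of performance on pipeline factors:")
print(meta.table.to_string(index=False))
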