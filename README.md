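# bioind

Machine-learning identification of **bioindicator taxa** in anaerobic
chain-elongation bioreactors, and quantitative prediction of process
performance from them.

## The problem

Two semi-continuous bioreactors ferment xylan and lactate to medium-chain
carboxylates (n-butyrate C4, n-caproate C6, n-caprylate C8) while the
hydraulic retention time (HRT) is shortened from 8 d to 2 d over a 211-day
run — gradually in reactor A, in one fast step in reactor B. The microbial
community is tracked as a rarefied table of 16S rRNA amplicon sequence
variants (ASVs). Two questions follow:

1. Which ASVs discriminate the HRT 8 d regime from the HRT 2 d regime
   (**HRT bioindicators**), and do they transfer between independently
   operated reactors?
2. Can the abundances of a handful of ASVs predict the numeric values of
   process parameters — above all C6/C8 productivity
   (mmol C L⁻¹ d⁻¹) — on a reactor the model never saw?

`bioind` implements the full two-step random-forest workflow:

- **Step 1 (classification).** A random forest (2000 trees, mtry 40)
  separates HRT8 from HRT2 samples; features are ranked by mean decrease in
  Gini impurity, recursively eliminated, filtered at 1 % of total Gini and
  cut to the top 15 per reactor. The intersection of the A- and B-trained
  sets is the shared HRT bioindicator set; accuracy is measured
  cross-reactor (train A → test B and vice versa).
- **Step 2 (regression).** Regression forests predict concentrations,
  productivities, yields and richness from bioindicator abundances, gated
  at >80 % out-of-bag explained variance in both training orientations.
  Per-parameter **non-HRT bioindicators** (top-15 by node-purity
  importance over all ASVs) capture time-driven community assembly; HRT
  bioindicators absent from them are **time-independent** indicators.
  Prediction error is RRMSE = 100·RMSE/mean, averaged over 100
  random-subsample forest replicates (4 of the HRT set, 5 of a non-HRT
  set), with a 10 % predictability cutoff.

Around the core: SMOTE class balancing, a linear/SVM/RF benchmark under
5-fold CV, rarefaction, alpha diversity (observed ASVs, Shannon),
Bray–Curtis + NMDS + PERMANOVA with BH-FDR, a Spearman co-occurrence
network (|rho| > 0.7, FDR-adjusted p < 0.05, Gephi export), and a
synthetic two-reactor generator with planted ground truth for end-to-end
validation.

## Worked example

```python
from bioind import SimulationConfig, simulate_experiment
from bioind.workflow import WorkflowConfig, run_two_step_workflow

table, metadata, truth = simulate_experiment(SimulationConfig(seed=3))
result = run_two_step_workflow(
    table, metadata,
    WorkflowConfig(n_trees=300, n_trees_regression=1000,
                   n_replicates=25, parameters=("prod_C6", "prod_C8"),
                   seed=3),
)
print("cross-reactor accuracy:", result.cross_accuracy)
print("shared HRT bioindicators:", result.shared.asv_ids)
print("time-independent:", result.time_independent.asv_ids)
for rep in result.replicate_reports:
    if rep.parameter == "prod_C6":
        print(rep.set_name, "mean RRMSE %.1f%%" % rep.mean_rrmse)
```

Output on this seed (the simulation plants 11 HRT responders, 4 of them
time-independent, among 71 ASVs):

```
cross-reactor accuracy: {'A->B': 0.9629629629629629, 'B->A': 0.9629629629629629}
shared HRT bioindicators: ['ASV008', 'ASV005', 'ASV007', 'ASV011', 'ASV010',
                           'ASV003', 'ASV004', 'ASV001', 'ASV006', 'ASV009',
                           'ASV002', 'ASV063']
time-independent: ['ASV003', 'ASV004', 'ASV001', 'ASV006', 'ASV009', 'ASV002', 'ASV063']
HRT/A&B mean RRMSE 24.1%
prod_C6/A mean RRMSE 16.0%
HRT/A&B mean RRMSE 21.8%
prod_C6/B mean RRMSE 14.0%
```

The classifier transfers at 96 % accuracy between reactors, the shared set
contains all 11 planted responders (ASV001–ASV011), and the
time-independent set contains all four planted HRT markers that do not
track productivity numerically (ASV001–ASV004). Replicate RRMSE for C6
productivity reflects this simulation's deliberately large within-phase
productivity wobble — around 9–24 % depending on the seed's realization;
the methods note discusses why the wobble level trades off against
time-independence detection.

The same workflow runs on real tables from the command line:

```bash
bioind simulate --out-dir data/ --seed 1
bioind validate --abundance data/abundance.tsv --metadata data/metadata.tsv
bioind workflow --simulate --out-dir out/ --seed 1
bioind diversity --abundance ... --metadata ... --out-dir out/
bioind network   --abundance ... --metadata ... --out-dir out/
```

Input formats: a samples × ASVs TSV/CSV (counts or relative abundances), a
metadata TSV with columns `sample_id, reactor, day, hrt, conc_lactate,
conc_C4, conc_C6, conc_C8, prod_C4, prod_C6, prod_C8, yield_C4, yield_C6,
yield_C8`, and an optional taxonomy TSV (`asv_id, phylum … genus`).

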