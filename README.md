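# qsarwb

A 2D-QSAR workbench for small-molecule activity modeling: molecular
descriptors, MLR model building with SFS/GA feature selection, a full
internal/external validation battery, leverage applicability domain,
intelligent consensus prediction, and MM-GBSA component bookkeeping — with
a synthetic-data generator so every stage is testable offline.

## Who it is for

Medicinal and computational chemists building interpretable linear
structure–activity models — for example, regressing the potency (pIC50) of
enzyme inhibitors such as soluble epoxide hydrolase (sEH) ligands on
topological and pharmacophoric descriptors — who need reproducible model
selection, the standard validation metric roster, and an explicit
applicability domain.

## The model and its statistics

The core object is the multiple linear regression

```
pIC50 = b0 + Σ_j b_j · x_j ,     pIC50 = −log10(IC50 / 10⁶)  (IC50 in µM)
```

where the `x_j` are molecular descriptors chosen by sequential forward
selection (four scorers — R², −MAE, −mean-Poisson-deviance,
−mean-gamma-deviance — each with and without 5-fold CV) or by a genetic
algorithm (population 100, 100 generations, crossover p = 1.0, mutation
p = 0.3, 30 survivors, repeated seeded runs). Nine descriptor sets × (8 SFS
+ 1 GA) configurations give the conventional 81-model screen.

Models are judged by: R², R²_adj, F, MAE, leave-one-out Q² (1 − PRESS/TSS),
Roy's rm²/Δrm², the Todeschini K_xx/ΔK multivariate correlation indices and
per-descriptor VIF on the training set; Q²_F1 (= R²_Pred), Q²_F2, Q²_F3,
RMSEP and rm²_test externally; plus a Y-randomization test reporting
cR_p² = R·√(R² − R̄_r²). The applicability domain is the classic Williams
plot: leverage h_i against standardized residuals, h* = 3(p+1)/n,
residual cutoff ±3.

The descriptor engine implements, with open documented conventions, the
eight families of the final published-style model: Broto–Moreau
autocorrelation (`ATS6m`), the Barysz-matrix Balaban index (`J_Dz(p)`),
three CATS2D pharmacophore-pair counts, a dipole-weighted edge-adjacency
spectral moment (`SM14_AEA(dm)`), the N–O atom-pair frequency at distance 9
(`F09[N-O]`) and the vdW-volume-weighted radial distribution function at
14 Å (`RDF140v`).

## Worked example

```python
from qsarwb.synthetic import SimSpec, gen_descriptor_dataset
from qsarwb.dataset_io import pretreat, split_dataset
from qsarwb.feature_selection import SelectionConfig, sfs_mlr
from qsarwb.validation import validate_model

table, truth = gen_descriptor_dataset(SimSpec(n_compounds=184, seed=18))
train, test = split_dataset(table, test_fraction=0.2, seed=3).apply(table)
cand = sfs_mlr(pretreat(train), SelectionConfig(method="SFS", max_features=4))
report = validate_model(cand.model, train, test, y_randomization_runs=1000, seed=1)
print("selected:", cand.descriptor_names)
print(report.summary_line(len(train), len(test)))
print("cR_p2 =", round(report.y_randomization["crp2"], 3))
```

prints

```
selected: ['x2', 'x1', 'x16', 'x22']
N_training = 147, R2 = 0.999, R2_adj = 0.999, Q2_LOO = 0.999, MAE = 0.085, rm2_LOO = 0.999, delta_rm2_LOO = 0.001, K_xx = 0.073, delta_K = 0.220. N_test = 37, Q2_F1 = 0.999, Q2_F2 = 0.999, Q2_F3 = 0.999, RMSEP = 0.106, rm2_test = 0.996, delta_rm2_test = 0.001
cR_p2 = 0.985
```

The selector recovers the two planted descriptors (`x1`, `x2`) first; the
near-unity internal and external Q² values reflect the low simulated noise
(σ = 0.1 pIC50 units), and a cR_p² far above 0.5 confirms the model is not
a chance correlation. The same flow is available from the shell:

```bash
qsarwb simulate --seed 18 --out synth.csv
qsarwb split --input synth.csv --test-fraction 0.2 --seed 3 --out-prefix run
qsarwb select --method sfs --train run_train.csv --max-features 4 --out model.json
qsarwb validate --model model.json --train run_train.csv --test run_test.csv --out report.json
qsarwb ad --model model.json --train run_train.csv --test run_test.csv --out williams.csv
```

Descriptors for real molecules come from SMILES or (3D) SDF input:

```bash
qsarwb descriptors --in mols.smi --set table1 --out desc.csv
```

## Layout

| module | role |
| --- | --- |
| `qsarwb.dataset_io` | tables, pIC50 conversion, splitting, pretreatment |
| `qsarwb.descriptors` | molecular graphs, PPP typing, the eight descriptor families |
| `qsarwb.feature_selection` | SFS grid and GA subset search |
| `qsarwb.models` | MLR, PLS with Q²_LOO stop rule, tuned MLP/RF/SVM |
| `qsarwb.validation` | the full metric battery and Y-randomization |
| `qsarwb.applicability_domain` | leverages, Williams plot |
| `qsarwb.consensus` | CM0–CM3 intelligent consensus prediction |
| `qsarwb.reporting` | model reports, MM-GBSA totals |
| `qsarwb.synthetic` | planted-signal datasets, fixture molecules |

See `docs/methods.md` for conventions, assumptions and limitations.
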