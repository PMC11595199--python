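# plperm

Placental permeability modeling toolkit. Predicts **log FM** — the base-10
logarithm of the fetal-to-maternal blood concentration ratio at equilibrium —
from molecular descriptor tables, and screens compound libraries for
drug-likeness and likely placental transfer.

The package bundles:

* a **model bank** of nine fixed-coefficient published predictors
  (`eq1`–`eq9`): plain MLR QSAR models, two ARKA aggregate models, and two
  PLS q-RASAR models, plus FM-cutoff permeability classification
  (C/NC, PL1/PL0; cutoff FM = 0.3, boundary inclusive);
* the **model-building machinery** that produces such models: OLS, forward
  stepwise selection on partial-F p-values, NIPALS PLS with auto-scaling,
  iterative VIP-based variable reduction, and exhaustive best-subset search
  ranked by leave-one-out Q²;
* **ARKA** supervised dimensionality reduction (min-max scaling, median
  response split, group-mean aggregates, confidence-quadrant labeling);
* **Read-Across / q-RASAR**: Euclidean-, Gaussian- and Laplacian-kernel
  similarity prediction, grid-search hyperparameter optimization,
  similarity/concordance descriptor computation (RA function, Avg_Sim,
  SD_Sim, MaxPos, MaxNeg, gm), descriptor-pool fusion and final PLS;
* **validation metrics** (R², R²_adj, F, Q²_LOO, 8-fold RMSECV, Q²_F1,
  Q²_F2, RMSEP, R²_ext);
* **drug-likeness filters** (Lipinski ×2, Veber, Ghose ×2, Palm, Egan,
  Muegge) and hierarchical clustering of binary filter profiles against the
  PL permeability score;
* a seeded **synthetic data generator** with realistic property envelopes
  (M_w ≤ ~700 Da, TPSA 0–271 Å², log P −1 to 6) and a linear log FM truth,
  so the whole pipeline is testable without external data.

## Library quick start

```python
import numpy as np
from plperm import get_model, predict_log_fm, classify_permeability
from plperm.data_io import DescriptorTable

table = DescriptorTable(["BP3"], ["M_w", "TPSA"], np.array([[228.2, 46.5]]))
log_fm = predict_log_fm(get_model("eq1"), table)["BP3"]
call = classify_permeability(log_fm)          # -> C/NC, PL1/PL0
```

Building a q-RASAR model on synthetic data:

```python
from plperm.synthetic_data import generate_reference_like
from plperm.read_across_rasar import optimize_hyperparameters, build_qrasar

ds = generate_reference_like(seed=1)          # 54 compounds, 40 train / 14 test
config, grid_report = optimize_hyperparameters(
    ds.ids("train"), ds.X("train"), ds.y("train"), seed=1
)
result = build_qrasar(ds, ["M_w", "TPSA", "iLOGP"], config)
print(result.selected, result.report.rounded())
```

## Command line

The console script `plperm` exposes every stage:

```bash
plperm predict  --model eq6 --in table.csv --out pred.csv [--fm-cutoff 0.3]
plperm validate --model eq3 --train train.csv --test test.csv --seed 1
plperm fit      --method {ols,stepwise,pls,vip,best-subset} --train train.csv
plperm arka     --train train.csv --test test.csv --descriptors M_w,TPSA --center
plperm rasar    --mode {optimize,features,build} --train train.csv --grid grid.yaml
plperm filters  --in table.csv --tolerance strict --cluster --linkage complete
plperm simulate --n 54 --seed 7 --out synth.csv
plperm screen   --config run.yaml
```

Input tables are delimited text (default comma, UTF-8): header row, first
column compound id, remaining columns numeric descriptors. Missing values
are hard errors; nothing is imputed. Filter evaluation expects the columns
`M_w, MLOGP, cLogP, WLOGP, XLOGP, HA, HD, FRB, TPSA, MR, Atoms, Rings,
Carbons, Heteroatoms` (filters whose inputs are absent are reported as
not-evaluable, never as failed).

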