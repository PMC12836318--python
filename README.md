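# dabarrier

Structure–reactivity analysis for uncatalyzed hydrocarbon Diels–Alder
cycloadditions: combinatorial reaction-space enumeration, steric/electronic
descriptor assembly, activation-barrier regression and Shapley-value
feature attribution — with a synthetic, DFT-emulating data generator so
the whole analysis runs and is testable offline.

## The problem

A [4+2] cycloaddition joins a conjugated diene (carbons C1–C4) and a
dienophile (C5–C6) through up to four stereochemical channels (endo/exo ×
two regiochemical bond pairings).  Which substituents sit at the six
backbone carbons controls the activation free energy ΔG‡ over tens of
kcal/mol.  `dabarrier` is for computational/physical organic chemists who
want to

* enumerate and sample the substituted reaction space (nine substituent
  choices at C1/C4/C5/C6, five at C2/C3) with molecular symmetry handled
  correctly;
* assemble the standard descriptor set — frontier orbital energies, the
  two charge-transfer gaps and their minimum
  `min_LUMO–HOMO = min(LUMO_dienophile − HOMO_diene, LUMO_diene − HOMO_dienophile)`,
  Hammett σp, substituent volumes, sterimol, NPA charges, pz populations;
* compose solution-phase free energies
  `G = E(BS2) + G(BS1) − E(BS1) + ΔG(1 atm→1 M)` and select the
  minimum-barrier pathway ΔG‡_min;
* fit random-forest / gradient-boosting barrier models with the repeated
  train/test-split + out-of-bag protocol and 10-fold CV tuning; and
* attribute predictions with *exact* interventional Shapley values
  φᵢ (in kcal/mol, summing to the deviation of each prediction from the
  background mean — the efficiency axiom), including a first-party
  polynomial-time algorithm for tree ensembles verified against
  brute-force coalition enumeration.

The synthetic generator encodes the mechanistic ground truth the analysis
should recover: barriers rise linearly with `min_LUMO–HOMO`, carry
additive per-position volume terms (internal C2/C3 positions spanning
about −6…+17 kcal/mol, dienophile −3…+7, terminal −6…+4), a
conformational-strain bonus of 12 kcal/mol when both internal carbons are
bulky (the reactive s-cis conformation forces them onto one face), a
trans-orientation congestion penalty at bulky terminals, and Gaussian
noise.

## Worked example

```python
from dabarrier import BarrierModel, generate_dataset, rank_features

df, meta = generate_dataset(1000, seed=0)
model = BarrierModel(df)          # reduced 13-descriptor feature set
results = model.fit(seed=0)
print(results.summary())

report = model.evaluate_repeated_splits(n_iter=5, seed=0)
print(f"validation R2 (5 splits): {report.r2_validation:.3f}")
print(f"test MAE:                 {report.mae_test:.2f} kcal/mol")

attr = results.shapley_values(n_explain=64, background_size=50, seed=0)
print("top features by mean |phi| (kcal/mol):")
for name in rank_features(attr)[:5]:
    print(f"  {name:14s} {attr.global_importance[name]:.2f}")
```

prints

```
Barrier regression results
============================================
model:             rf (600 trees)
n observations:    1000
n features:        13
target:            dg_act_min [kcal/mol]
R2 (train):        0.990
MAE (train):       1.305 kcal/mol
R2 (out-of-bag):   0.922
validation R2 (5 splits): 0.929
test MAE:                 3.53 kcal/mol
top features by mean |phi| (kcal/mol):
  vol_C3         6.92
  vol_C2         5.95
  min_lumo_homo  3.54
  vol_C1         2.37
  vol_C4         2.26
```

The forest explains ~93 % of the held-out barrier variance; attribution
recovers the generator's ground truth — internal-position steric bulk
(vol_C2/vol_C3, which carry the conformational-strain mechanism) dominates,
the minimum frontier gap is the leading electronic descriptor, and the
terminal/dienophile volumes follow with smaller effects.

The same stages are available from the shell:

```bash
dabarrier enumerate --count-only          # 46575 symmetry-distinct reactions
dabarrier simulate --n 1000 --seed 0 --out data.csv
dabarrier train --data data.csv --model rf --report-out report.json
dabarrier explain --model model.joblib --data data.csv --out shap.csv
dabarrier run --seed 0 --outdir pipeline_run   # end to end, one manifest
```

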