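# mmpcliff

Interpretable activity-cliff prediction for matched molecular pairs.

An **activity cliff (AC)** is a pair of structurally similar compounds with a
large potency difference — here, a matched molecular pair (MMP) whose pKi
values differ by more than 2 log units (pairs differing by less than 1 log
unit are non-cliffs; anything in between is discarded as ambiguous).  Cliffs
carry concentrated structure–activity information, so medicinal chemists both
want to predict them and to understand *why* a model predicts them.

`mmpcliff` is for cheminformaticians working on lead optimization who need
cliff predictions they can argue about at the whiteboard: every prediction
comes with an exact, per-feature additive explanation that can be painted
back onto the two molecules.

## The method

An MMP is a compound pair sharing a single-cut **core** and differing in one
**substituent** exchange.  Each MMP is encoded by three sparse binary
segments of ECFP-style circular substructure features (bond diameters 2 and
4, unfolded identifiers, sorted bit assignment, no collisions):

- core features,
- substituent XOR features (present in exactly one substituent — the
  transformation),
- substituent AND features (common to both).

Similarity between MMPs `u, v` is the **MMP kernel**, a product of
segment-wise Tanimoto kernels

```
K_MMP(u, v) = K_Tan(u_c, v_c) · K_Tan(u_s, v_s),
K_Tan(u, v) = ⟨u,v⟩ / (⟨u,u⟩ + ⟨v,v⟩ − ⟨u,v⟩),
```

and classification uses an SVM with decision function
`f(x) = sign(Σᵢ αᵢyᵢ K_MMP(x⁽ⁱ⁾, x) − b)`.

Because the Tanimoto denominator is constant within one kernel evaluation,
each kernel value expands into one term per shared feature.  For the product
kernel this expansion yields **cross-terms**, one per shared
(core feature d_c, substituent feature d_s) pair:

```
frag_fc(x, d_c, d_s, i) = αᵢyᵢ / (denom_c · denom_s)
```

Splitting every cross-term 50/50 between d_c and d_s makes the decision value
an **exact** sum of per-feature contributions — no sampling, no
approximation; the sum of contributions minus the bias reproduces `f(x)` to
machine precision.  Contributions are then distributed evenly over the
atoms and bonds of the substructure occurrences behind each feature, giving
a warm/cool heat map on the two structures.  A from-scratch **Kernel SHAP**
explainer is included as the model-independent control; unlike the exact
decomposition it routinely assigns weight to features *absent* from the
explained pair.

Evaluation is by matched-molecular-series (MMS) leave-one-out: each series
(all MMPs sharing a core) is held out in turn, test MMPs sharing a compound
with the training set are eliminated, and recall / ROC AUC / MCC are computed
on the pooled predictions — so no core and no compound ever crosses the
train/test boundary.

## Worked example

The package ships a deterministic generator of analog series with a planted
cliff-driving substituent (tert-butyl, +2.5 pKi):

```bash
mmpcliff fixtures --out compounds.csv --seed 7
mmpcliff fragment --input compounds.csv --out mmps.csv
mmpcliff train    --mmps mmps.csv --out model.json --c-grid 1,10 --seed 7
mmpcliff evaluate --mmps mmps.csv --out-prefix eval --c-grid 1,10 --seed 7
```

which prints

```
48 compounds -> compounds.csv
48 compounds -> 358 labeled MMPs -> mmps.csv
trained on 358 MMPs: C=10.0, 298 support vectors
recall=0.556 auc_roc=1.000 mcc=0.699
```

The positive pooled MCC means the model generalizes the planted
transformation to series it has never seen.  Explaining one held-out cliff
(methoxy → tert-butyl on a naphthalene core):

```bash
mmpcliff explain --model model.json --mmps mmps.csv --mmp "S00C01|S00C00" --out-prefix expl
# decision=0.9999 (kernel_sum=1.7659, b=0.7660)
head -5 expl.tsv
# segment  feature              bit  contribution
# sub      ('X', 1307554649)    46   0.2848052360222995
# sub      ('X', 3537123720)    126  0.2848052360222995
# sub      ('X', 4103162553)    150  0.2848052360222995
# core     951226070            21   0.1293057142774114
```

The largest contributions sit on the XOR substituent features — exactly the
exchanged groups that cause the cliff — and `expl_low.svg` /
`expl_high.svg` show them colored on the structures.  The SHAP control on
the same pair:

```bash
mmpcliff compare --model model.json --mmps mmps.csv --mmp "S00C01|S00C00" --samples 512 --seed 7
# absent-mass fraction: exact=0.000 shap=0.300
```

The exact method puts zero attribution mass on absent features by
construction; Kernel SHAP puts 30% of its mass there.

## Library use

```python
from mmpcliff import (read_compound_table, generate_mmps, group_into_mms,
                      build_universe, fingerprint_mmp, MMPKernelSVC,
                      decompose_mmp, map_to_structure)

compounds = read_compound_table("compounds.csv")
mmps = generate_mmps(compounds)
universe = build_universe(mmps)
X = [fingerprint_mmp(m, universe) for m in mmps]
y = [int(m.label.value == "AC") for m in mmps]
model = MMPKernelSVC(C_grid=(1.0, 10.0), random_state=0).fit(X, y)
explanation = decompose_mmp(model, X[0])        # exact additive contributions
weights = map_to_structure(explanation, X[0])   # atom/bond heat map
```

Estimators follow the scikit-learn protocol (`fit` / `predict` /
`decision_function` / `get_params`), with fitted attributes
(`support_fingerprints_`, `dual_coefs_`, `bias_`, `C_`) exposed for
inspection.

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
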