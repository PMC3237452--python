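# ischemix

Statistical process monitoring of liver-perfusion metabolomics: a metabolic
index of ischemic injury and an online fresh-vs-ischemic classifier for
machine-perfused livers.

## The problem

Donor livers recovered after cardiac death carry warm-ischemic injury whose
severity is hard to judge. During normothermic machine perfusion the organ
is metabolically active, and hourly perfusate samples (amino acids, urea,
ammonia, glucose, lactate, ketone bodies, albumin — a 25-metabolite panel)
trace its functional state. Because hepatic metabolism is a tightly coupled
network, the metabolites are strongly auto- and cross-correlated in time;
univariate tests miss pathway-level changes. `ischemix` implements the
multivariate batch-monitoring treatment of this problem:

* **Multiway PCA (MPCA).** The hourly trajectories of I perfusions form an
  I×J×K array (batches × metabolites × hours). Unfolded batchwise to I×JK
  and scaled per (metabolite, hour) column, fresh-liver perfusions define a
  normal-operation model **X** = **T P**′ + **E** with R = 3 orthonormal
  loading vectors.
* **SPE ischemia index.** A new perfusion **x** is scaled with the training
  scaler and projected; its squared prediction error
  SPE = ‖**x**(I − **PP**′)‖² measures correlation structure the fresh
  model cannot explain. Control limits come from the scaled-χ²
  approximation g·χ²_h with g = v/2m, h = 2m²/v matched to the training SPE
  sample (computed leave-one-out so the limits hold for new batches).
  Online, SPE_k is computed each hour from the data seen so far, and
  log₁₀(SPE_k) > 1.35 is the heuristic ischemia alarm.
* **Contribution diagnostics.** SPE decomposes into per-(metabolite, hour)
  terms e²_jk; the signed normalized errors e_jk/ŝ_jk say whether a
  metabolite ran above or below the fresh expectation, and metabolites
  outside the ±3σ band of normal contributions are flagged per hour.
* **MPLS-DA classification.** NIPALS partial least squares regresses the
  unfolded trajectories on a dummy class matrix (fresh → [1, 0], ischemic →
  [0, 1]); the normalized predicted response is a *quality estimate*, with
  quality > 0.5 called fresh. Variable importance in projection (VIP > 1)
  names the discriminating metabolites. Per-hour models give online
  quality estimates during perfusion.
* **Case-resampling cross-validation.** Repeated 5 + 5 training draws with
  replacement (≤ 2 copies of a batch per draw); every batch never drawn is
  a test case. Pooled confusion counts give sensitivity and specificity,
  offline and per hour.

The original study's perfusion data are not public, so the package ships a
first-class synthetic generator (`ischemix.simulate`) reproducing the
statistical structure the analysis assumes: linear fresh mean trajectories,
a 3-factor low-rank covariance across metabolite-time columns, and a
warm-ischemia signature (albumin depressed throughout, ornithine switching
sign at 2 h, arginine minimum at 4 h, late tyrosine rise, early lactate
surge, glutamate/glutamine changes) on top of a small network-wide drift.

## Worked example

```python
import ischemix as ix

config = ix.GeneratorConfig(seed=0)              # 10 fresh + 6 WI livers
model  = ix.fit_mpca(ix.generate_fresh(config), R=3)
wi     = ix.generate_wi(config.with_(seed=1_000_003))
trace  = model.online_trace(wi.batches[0])       # hour-by-hour SPE_k
```

prints, via `examples/02_ischemia_index.py`:

```
MPCA model: R=3 components explain 74.4% of fresh variance

online monitoring of WI01:
hour   SPE_k   99% limit   log10(SPE_k)   ischemia?
  1     100.0       42.6        2.00        YES
  2     131.3       34.7        2.12        YES
  ...
  6     132.4       65.0        2.12        YES

a held-out fresh liver for comparison: log10(SPE_k) = [0.86 1.04 1.15 0.84 0.82 0.93]
```

The warm-ischemic liver sits above the 99% fresh limit — and above the
1.35 log-index threshold — from the first hour of perfusion to the last,
while a held-out fresh liver never approaches it. Offline cross-validated
classification on the same study design
(`examples/05_cross_validation.py`) reports

```
offline CV (100 runs, 823 test predictions): accuracy=1.000 sensitivity=1.000 specificity=1.000
```

The other examples show contribution tables naming the deviating
metabolites per liver and hour (`03`), quality estimates and the VIP
ranking that recovers the injury panel — albumin, arginine, glutamate,
ornithine, tyrosine (`04`).

A thin CLI wraps the same workflow:

```sh
ischemix simulate --out study.csv --seed 0
ischemix fit study.csv --model-out mpca.json
ischemix monitor study.csv --model mpca.json --out-dir monitor/
ischemix cv study.csv --out-dir cv/ --runs 100
ischemix report cv/
```

## Layout

```
src/ischemix/      panel, dataset, simulate, preprocess, mpca, plsda,
                   crossval, io, cli
examples/          one narrative script per capability
tests/             unit, property and end-to-end statistical tests
docs/methods.md    model assumptions, defaults, numerical choices, limits
```
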