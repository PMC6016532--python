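# scanmorph

Measurement-error analysis for 3D landmark geometric morphometrics.

When the same specimens are digitized repeatedly from two 3D capture
devices (say, a structured-light surface scanner and a µCT scanner),
how much of the resulting shape variation is biology, and how much is
asymmetry, device signature, or plain digitization error?  `scanmorph`
implements the full analysis chain used to answer that question in
repeated-measure morphometric studies of small specimens such as rodent
crania:

* **Superimposition** — generalized Procrustes analysis (GPA) with
  projection to tangent space, including **sliding semilandmarks**: curve
  points slide along the chord through their neighbours and surface patch
  points within their local tangent plane, minimizing Procrustes distance
  to the consensus.
* **Object-symmetry decomposition** — each configuration is jointly
  superimposed with its mirrored, relabeled copy; the average is the
  symmetric shape component, the remainder the asymmetric one
  (directional asymmetry = its mean, fluctuating asymmetry = its
  individual variation).
* **Procrustes ANOVA** — sequential (Type I) sums of squares of shape
  over design factors (individual, side, individual × side, device, …),
  with residual-randomization permutation tests and %Var / R² summaries:
  a factor's share is SS_factor / SS_total.
* **Error metrics** — repeatability, the intraclass-correlation analogue
  from ANOVA mean squares,

      s²_A = (MS_among − MS_within) / r,   R = s²_A / (s²_A + MS_within),

  over configurable landmark subsets; and per-individual/device
  Procrustes variance (trace of the replicate covariance over *n*) with a
  permutation test for device differences.
* **Classification** — PCA, between-group PCA (principal axes of the
  group mean shapes), and leave-one-out cross-validated nearest-mean
  classification summarized by confusion matrices, accuracy, and Cohen's
  κ.
* **Synthetic data** — a generator that emulates the full replicate study
  design (19 individuals × 2 devices × 3 replicates, 289 points: 58
  fixed, 145 curve semilandmarks, 86 patch points) with known variance
  components and recorded ground truth, so every stage is testable
  without any data download.

Landmark data are read and written as long/wide CSV or TPS (LM3) files,
with slider, bilateral-pair, and factor tables as small CSVs.

## Worked example

Simulate the default two-device replicate design and run the asymmetry
ANOVA and per-device repeatability:

```python
import scanmorph as sm

params = sm.SyntheticParams(n_individuals=19, replicates=3, seed=7)
dataset, truth = sm.simulate_dataset(params)

fit = sm.slide_gpa(dataset, truth.sliders)          # GPA + sliding
dec = sm.decompose(fit.aligned, truth.bilateral)    # symmetry split
table = sm.symmetry_anova(dec, dataset.factors, n_perm=199, seed=7)
print(table[["Df", "SS", "MS", "%Var", "F", "Pr(>F)"]].round(6).to_string())

rep1 = sm.repeatability(dataset, device="dev1", sliders=truth.sliders)
rep2 = sm.repeatability(dataset, device="dev2", sliders=truth.sliders)
print(f"repeatability dev1 (noisier): {rep1.r_value:.3f}")
print(f"repeatability dev2          : {rep2.r_value:.3f}")
```

Output:

```
             Df        SS        MS        %Var            F  Pr(>F)
Individual   18  0.199871  0.011104   57.876916   431.045724   0.005
Side          1  0.107555  0.107555   31.144724  4175.177632   0.005
Ind * Side   18  0.008666  0.000481    2.509326    18.688524   0.005
Device       19  0.024842  0.001307    7.193460    50.754518   0.005
Residuals   171  0.004405  0.000026    1.275574          NaN     NaN
Total       227  0.345339       NaN  100.000000          NaN     NaN
repeatability dev1 (noisier): 0.959
repeatability dev2          : 0.989
```

Variation among individuals dominates (57.9 %Var), directional asymmetry
(`Side`) is next, the systematic device field explains 7.2%, and replicate
digitization error the residual 1.3% — the variance structure the
generator was configured with.  The noisier device's repeatability
(0.959) is lower than the cleaner device's (0.989): its digitization
error is a larger fraction of the among-individual variation.

The same sequence is available from a shell:

```sh
scanmorph run-all --seed 7 --synthetic --out results/
scanmorph simulate --seed 7 --out synthetic/     # write data + truth files
scanmorph repeatability --landmarks synthetic/landmarks.csv \
    --factors synthetic/factors.csv --device dev1
```

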