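# tscm-kinetics

Kinetic modelling of human CD8+ T stem-cell-like memory (T_SCM) subpopulations
from deuterated-water (²H₂O) labelling studies.

The package implements the full analysis chain for a heavy-water labelling
study of three T-cell pools — naive (T_N) and the CD95int / CD95hi T_SCM
subpopulations:

1. **Calibration** — fit the three-phase body-water label availability S(t)
   from saliva enrichment, and the DNA amplification factor `b_w` from blood
   monocytes (a fast-turnover reference population) via a delayed
   marrow/blood compartment model.
2. **Lineage models** — five candidate models (A: independent homogeneous
   pools, B: independent kinetically heterogeneous pools, C: forked
   differentiation with a clonal burst 2^k, D: linear differentiation
   T_N → CD95int → CD95hi, E: the mirror path T_N → CD95hi → CD95int).
   Constant pool sizes eliminate the disappearance rates analytically;
   label enrichment follows exactly solvable piecewise-linear ODE systems.
3. **Observables** — naive-vs-T_SCM telomere-length difference θ, the
   post-vaccination decay of antigen-specific (yellow-fever tetramer+)
   frequencies, clonal half-lives ln2/(net clonal loss) and pool residency
   times.
4. **Inference** — a joint objective over labelling, telomere and vaccine
   cohort data, seeded multi-start optimisation (simplex burn-in + bounded
   trust-region least squares), nonparametric bootstrap, model comparison,
   and out-of-sample prediction of subset-resolved decay.
5. **Cohort statistics** — multipotency index, self-renewal percentage,
   2^(−ΔCT) expression, log-linear decline regression with a slope-contrast
   interaction test, and nonparametric group comparisons.
6. **Synthetic data** — a first-class generator that simulates the whole
   study design (labelling protocol, analytic replicates, cross-sectional
   cohorts) from known ground truth, used throughout the test suite.

## Quick start

```python
import tscm_kinetics as tk

# simulate a study with known ground truth (linear model D)
design = tk.StudyDesign(master_seed=0)
truth = tk.default_truth("D")
bundle = tk.generate_study("D", truth, tk.default_saliva_truth(),
                           tk.default_monocyte_truth(), design, seed=0)
aux = tk.generate_aux_data(truth, design, seed=0)

# calibrate S(t) and b_w, then fit the lineage model jointly
bundle = tk.calibrate_bundle(bundle)
fit = tk.fit_model("D", bundle, aux, n_starts=8, master_seed=0)
print(fit.params.p_1, fit.params.p_2)   # ~8e-4 and ~2e-3 per day
print(tk.clonal_half_lives(fit.params))  # clone half-lives in days
print(tk.telomere_theta(fit.params, method="algebraic"))  # ~520 bp

# bootstrap uncertainty
boot = tk.bootstrap_fit("D", bundle, aux, n_boot=25, master_seed=0,
                        n_starts=2, point_fit=fit)
print(boot.median["p_2"], boot.iqr_low["p_2"], boot.iqr_high["p_2"])
```

On the default synthetic study this recovers the proliferation rates used to
generate the data (p_2 ≈ 0.002/day, i.e. one division every ~1.4 years for
CD95hi cells; p_1 ≈ 0.0008/day, one per ~3.4 years for CD95int) and prefers
model D over A/B/C/E in the comparison table.

## Command line

```bash
tscmkin simulate --out-dir simulated --model D --seed 0
tscmkin fit config.yaml --model D
tscmkin bootstrap config.yaml --model D --n-boot 100
tscmkin compare config.yaml
tscmkin predict config.yaml --init-cd95int 0.05 --init-cd95hi 0.02
tscmkin stats cohort.csv
tscmkin run-all config.yaml
```

`config.yaml` holds paths, per-donor pool-ratio constants (R_1 = CD95int/T_N,
R_2 = CD95hi/T_N), optimizer and bootstrap settings; every output is stamped
with the config hash and master seed.

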