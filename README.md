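# cdmtau

Classification accuracy for cognitive diagnosis models (CDMs), with a
nonparametric-bootstrap multiple-imputation (MI) correction for
model-parameter uncertainty.

CDMs are constrained latent class models that classify respondents —
students, patients, job candidates — on K binary attributes (mastered /
not mastered) from J binary item responses, guided by a Q-matrix that
declares which attributes each item requires. `cdmtau` implements:

- the **DINA** model (two parameters per item: guessing *g<sub>j</sub>* and
  slip *s<sub>j</sub>*) and the saturated **G-DINA** model (one success
  probability per reduced attribute profile of each item), estimated by
  marginal maximum likelihood via EM;
- **EAP classification**: each attribute's marginal posterior mastery
  probability P(α<sub>ik</sub> = 1 | **x**<sub>i</sub>, **δ**, **π**),
  thresholded at 0.5;
- the **τ / τ<sub>k</sub> accuracy indices**, which estimate the proportion
  of correctly classified attribute profiles (PCV) and attributes (PCA)
  from the posteriors:

  τ = (1/N) Σᵢ P(**α̂**ᵢ | **x**ᵢ, **δ**, **π**),  
  τₖ = (1/N) Σᵢ [ α̂ᵢₖ Pᵢₖ + (1 − α̂ᵢₖ)(1 − Pᵢₖ) ];

- the **MI correction**: posteriors computed at EM point estimates treat
  **δ** and **π** as known and are therefore too peaked in finite samples,
  so τ is biased upward — sometimes drastically (a practitioner can read
  τ ≈ 0.9 when barely 20% of profiles are actually correct). The correction
  approximates P(**α**ₗ | **x**ᵢ) = ∫ P(**α**ₗ | **x**ᵢ, **ϑ**) P(**ϑ** | **X**) d**ϑ**
  by refitting the model on R bootstrap resamples of the respondents and
  averaging the R posteriors, holding the original classifications fixed;
- a **simulation harness** (built-in K = 5 Q-matrices for J = 15/30,
  uniform and higher-order 2PL attribute structures, item-quality levels
  IQ ∈ {0.4, 0.6, 0.8}) that benchmarks both estimators against the true
  accuracy of the classifications, plus a subsampling study for real data.

## Worked example

```python
import cdmtau as ct

# one simulated dataset: DINA, 15 items, 5 attributes, low item quality
cond = ct.SimCondition(model="dina", J=15, N=100, iq=0.4)
x, alpha_true, gen_params, q = ct.simulate_dataset(cond, seed=1)

fit = ct.fit_em(x, q, "dina")
cls = ct.eap_classify(ct.marginal_mastery(fit.posteriors, q.profiles))
em = ct.reliability_report(fit.posteriors, cls, method="EM")

ens = ct.build_ensemble(x, q, "dina", R=100, seed=2)
mi = ct.tau_mi(x, q, cls, ens)
truth = ct.true_accuracy(alpha_true, cls.alpha_hat)

print(f"tau_EM = {em.tau:.3f}  tau_MI = {mi.tau:.3f}  PCV = {truth.pcv:.3f}")
```

Output:

```
tau_EM = 0.756  tau_MI = 0.353  PCV = 0.200
```

With 100 respondents and noisy items, the point-estimate index claims 76%
of profiles are correctly classified; the true figure is 20%, and the
MI-corrected index (35%) is far closer to it. Averaged over replications
(`ct.run_condition`), this condition gives mean τ^EM ≈ 0.69, mean
τ^MI ≈ 0.29 and mean PCV ≈ 0.15.

The same pipeline is available from the shell:

```
cdmtau fixtures --out-dir data --seed 3
cdmtau fit --responses data/responses.csv --qmatrix data/qmatrix.csv --out fit.json
cdmtau mi  --responses data/responses.csv --qmatrix data/qmatrix.csv -R 500 --seed 1 --out mi.json
cdmtau simulate --model gdina -J 30 -N 100 --iq 0.4 --reps 100 -R 500 --seed 1 --out-dir results/
```

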