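# pathcommit

Transition path sampling, committor analysis and machine-learned
reaction coordinates for rare-event kinetics, exercised end to end on
stochastic toy systems.

## The problem

Ion-binding events such as a Mg²⁺ ion trading a first-shell water for an
RNA phosphate oxygen are rare (milliseconds to seconds) and strongly
solvent-coupled: no single geometric distance predicts whether a
configuration will commit to the bound or unbound state. The principled
answer is the **committor** p_A(X) — the probability that a trajectory
started from configuration X with Maxwell–Boltzmann velocities reaches
state A before state B — which is the ideal reaction coordinate but is
expensive to estimate and opaque to interpret.

`pathcommit` packages the full analysis chain used to attack this class
of problem, for researchers who want to study, test, or teach the
methodology on systems where ground truth is computable:

1. **Two-way-shooting TPS** harvests an ensemble of fixed-length reactive
   paths between metastable states A and B (accept iff the trial path
   connects the states).
2. **Committor analysis** labels shooting points with (n_A, n_B) counts
   from ~100 trial trajectories each; transition states are
   0.45 < p_A < 0.55, and candidate coordinates are judged by comparing
   p(p_A) on their level sets with the binomial reference of an ideal
   coordinate.
3. **Committor regression** fits a multilayer perceptron q̃(X) with the
   logistic link p = 1/(1+e^(−q̃)) by minimizing the binomial negative
   log likelihood
   l = −Σᵢ [n_Aⁱ ln pᵢ + n_Bⁱ ln(1−pᵢ)],
   with random-search architecture optimization, early stopping and
   plateau learning-rate reduction.
4. **Permutation relevance** ranks features singly
   (r_s = (lᵢ−l_opt)/(l_max−l_opt)) and in combination (greedy removal,
   N(N+1)/2 permuted-dataset evaluations).
5. **Umbrella sampling + WHAM** reconstructs 1D/2D free-energy profiles,
   with block-convergence analysis and the transition-state-theory rate
   upper bound k_TST = √(k_BT/2πm) e^(−F(x*)) / ∫_reactant e^(−F) dx.

A molecular feature battery (the effective hydration distance s₆,
the atan2-based coordinate λ, Steinhardt q₃/q₄/q₆, tetrahedral order,
hydrogen-bond counts — 83 columns in the default schema) is included for
coordination-shell geometries, along with a synthetic-data module that
generates binomially labelled shooting datasets with known committor
laws. See `docs/methods.md` for the model details and design choices.

## Worked example

Tune a committor network on synthetic shooting data with a known
committor law (sigmoid in the first feature, ten pure-noise features,
100 trial trajectories per point), then rank the features:

```python
import numpy as np
import pathcommit as pc

data = pc.fixture_shooting_data(n_points=2000, n_features=11,
                                n_trials=100, seed=42)
model, search = pc.tune(data, n_trials=6, rng_seed=7)
print(f"best architecture: {model.spec.n_hidden_layers} hidden layers x "
      f"{model.spec.neurons_per_layer} neurons ({model.spec.activation})")
print(f"validation loss: {model.validation_loss:.1f}")
rms = pc.rms_committor_error(model, data, reference="true")
print(f"test RMS committor error: {100 * rms:.1f}%")

report = pc.relevance_report(model, data, rng_seed=0)
top = np.argsort(report.r_single)[::-1][:3]
print("most relevant features:",
      [(data.feature_names[i], round(report.r_single[i], 2)) for i in top])
print(f"permuted-dataset evaluations: {report.n_evaluations}")
```

Output:

```
best architecture: 4 hidden layers x 184 neurons (relu)
validation loss: 5263.6
test RMS committor error: 2.4%
most relevant features: [('f1', np.float64(1.0)), ('f9', np.float64(0.0)), ('f8', np.float64(0.0))]
permuted-dataset evaluations: 66
```

The network recovers the generating committor to 2.4% RMS — well below
the 5% binomial noise floor of the labels — and the relevance analysis
pins all the information on `f1`, the only feature the generating law
uses; the ten noise features score ≈ 0. The 66 evaluations are
N(N+1)/2 for N = 11 features.

The same workflow runs from the shell: `pathcommit pipeline --config
run.yaml --seed 3 --out results/` chains toy dynamics → TPS → committor
labelling → architecture search → relevance → umbrella sampling/WHAM →
TST, writing CSV/JSON artifacts and a manifest. Subcommands
(`simulate`, `tps`, `committor`, `features`, `train`, `tune`,
`relevance`, `fes`, `tst`) expose the stages individually.

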