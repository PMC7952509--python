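# gmmresid

Residual-based class enumeration for growth mixture models.

Longitudinal studies in the behavioral and health sciences often contain
unknown subpopulations that follow distinct developmental trajectories
(e.g., groups of individuals whose drinking, symptom, or performance levels
change differently over time). `gmmresid` implements an algorithmic
alternative to traditional growth-mixture class enumeration: instead of
fitting K-class mixtures and comparing information criteria, it clusters
individuals directly on their *individual case residuals* (ICRs) from fitted
latent growth curve models, and determines the number of classes from how
much each additional class genuinely tightens those residuals. It also ships
the Monte Carlo machinery to measure how often the procedure recovers the
true number of classes under controlled low-separation designs.

## The model and the algorithm

A latent growth curve model for T repeated measures y with a latent level
η₀ and shape η₁ has implied moments

    μ = Λη,   Σ = ΛΨΛ′ + Θ

with Λ the T×2 loading matrix (linear loadings 0,1,…,T−1 or latent-basis
loadings 0, b₂, …, 1), Ψ the 2×2 factor covariance matrix and Θ a diagonal
matrix of occasion residual variances. Models are fitted by normal-theory
maximum likelihood on the sample mean and covariance with analytic
gradients.

Given a fitted (local) model, each individual's growth factors are estimated
with Bartlett factor scores η̂ᵢ = η̄ + (Λ′Θ⁻¹Λ)⁻¹Λ′Θ⁻¹(yᵢ − μ), and the ICR
ε_itj is the residual of y_t regressed on the factor-j score. The closeness
of individual i to class k is

    CM_ik = A_ik / ( Σᵢ A_ik / (N − 2) ),
    A_ik  = Σⱼ Σₜ ε²_itjk / com(η_jk, y_tj)

where the communality com is the mean squared correlation between the
measures and the factor score. Individuals move to the class with the
smallest CM_ik; local models are refitted; the loop stops when fewer than 5%
of individuals change class. Candidate class counts K = 1, 2, … are accepted
while the mean within-class closeness drops by more than a calibrated
relative threshold (default 0.39, set so that splitting an already
homogeneous class is accepted only a few percent of the time — the guard
against over-extraction).

## Worked example

Simulate two well-separated trajectory classes (Mahalanobis distance 5
between class means) and enumerate:

```bash
gmmresid simulate --model 1 --k 2 --n 540 --md 5 --seed 11 \
    --out example.csv --labels truth.csv
gmmresid enumerate --input example.csv --kmax 5 --seed 1 \
    --out enum.json --labels-out assigned.csv
```

`enum.json` then contains

```
k_hat = 2, converged = true, class_sizes = [271, 269]
candidates: K=1 mean closeness 127.75  (baseline)
            K=2 mean closeness  10.98  relative drop 0.914 -> accepted
            K=3 mean closeness   8.14  relative drop 0.259 -> rejected (<= 0.39)
```

Splitting into the two real classes slashes the mean closeness by 91%, far
above the acceptance threshold, while a third class only buys the mechanical
26% that any further split of homogeneous data yields, so enumeration stops
at K̂ = 2. The assigned labels agree with the generating labels for 99% of
individuals.

The same machinery runs from Python:

```python
from gmmresid import GrowthModelSpec, SimulationDesign, simulate, select_num_classes

sim = simulate(SimulationDesign(k=2, n=540, model=1, md=5.0), seed=11)
res = select_num_classes(sim.data, GrowthModelSpec(4), k_max=5)
print(res.k_hat, res.partition.class_sizes)   # 2 [271 269]
```

## The Monte Carlo performance study

`gmmresid study` measures, for each cell of a {trajectory shape} × {true K}
× {N} grid, the percentage of replications in which the selected number of
classes equals the generating one. The study design fixes T = 4 occasions,
Ψ = diag(0.25, 0.04), residual variances (0.15, 0.20, 0.20, 0.35), equal
class sizes, and adjacent-class Mahalanobis separation MD = 1 (a severely
overlapping condition), and varies true K ∈ {2,3,4}, N ∈ {180, 540, 1080},
and whether classes differ in intercept only (model 1) or in intercept and
slope (model 2):

```bash
gmmresid study --models 1,2 --k 2,3,4 --n 180,540,1080 \
    --reps 100 --seed 42 --out table.csv --json table.json
```

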