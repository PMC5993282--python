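# odestep

Efficient parameter estimation for ordinary differential equation
models from noisy time-course data, using the one-step (Le Cam)
method.

## The problem

Dynamic processes in systems biology, chemical kinetics and
epidemiology are routinely modelled as ODE systems

```
x'(t) = F(x(t); θ),    x(t₁) = ξ,
```

observed at n time points with additive noise,
`Y_ij = x_i(η₀, t_j) + ε_ij`, `η = (ξ, θ)`.  Nonlinear least squares
(NLS) — minimizing `R_n(η) = Σ_ij (Y_ij − x_i(η, t_j))²` — is
statistically efficient but needs an iterative optimizer with repeated
numerical integration and a good starting point.  Smoothing-based
("gradient matching") estimators are fast and need no starting point,
but waste information.

`odestep` combines the two: a nonparametric smooth of the data feeds a
√n-consistent preliminary estimator (the direct integral estimator, or
smooth-and-match), and a single damped Newton-type correction

```
η̄ = η̂ + (SᵀS + λI)⁻¹ Sᵀ(Y − x(η̂)),    S = ∂x/∂η from the sensitivity ODEs,
```

— one Levenberg–Marquardt iteration — makes it asymptotically
equivalent to NLS.  The smoothing bandwidth is chosen in a data-driven
way by scanning a candidate grid proportional to n^(−1/3) and keeping
the estimate whose integrated trajectory best fits the raw data.
Confidence intervals come from the plug-in Fisher information
`I(η) = Σ_i σ_i⁻² ∫ (∂x_i/∂η)ᵀ(∂x_i/∂η) dF_T`.

The package ships the estimator, an NLS baseline, six benchmark models
(scalar exponential, Lotka–Volterra, Robertson stiff kinetics, Goodwin
oscillator, nitrogen-oxide reaction, α-pinene isomerization), a
scenario registry with the standard simulation setups, and a
Monte-Carlo driver.  It is for statisticians and modellers who want
NLS-quality point and interval estimates without hand-tuned starting
values, and for methodologists reproducing the benchmark studies.

## Worked example

Simulate one noisy Lotka–Volterra dataset (51 equidistant times on
[0, 10], σ = 0.05) and estimate all six unknowns:

```
$ odestep simulate --scenario table2_n51 --replicate 0 --out lv.csv
$ odestep fit --model lotka_volterra --data lv.csv
parameter         estimate            SE        CI low       CI high
xi1                1.00831     0.0159216      0.977109       1.03952
xi2               0.499512     0.0131284      0.473781      0.525243
theta1            0.496658      0.017288      0.462774      0.530541
theta2            0.499559      0.014353      0.471428      0.527691
theta3             0.50431     0.0141548      0.476567      0.532053
theta4            0.498413     0.0125975      0.473722      0.523103
selected bandwidth: 0.00539312   rss: 0.262949   sigma2: [0.00262949]
```

The truth is ξ₀ = (1, 0.5), θ₀ = (0.5, 0.5, 0.5, 0.5): every 95%
interval covers its target, the residual sum of squares matches the
noise floor (n·d·σ² ≈ 0.255), and σ̂² ≈ 0.0026 recovers σ = 0.05.  The
same pipeline is available as a library:

```python
import numpy as np
from odestep import get_model, select_estimate, bandwidth_grid
from odestep.experiments import dataset_from_csv
from odestep.inference import summarize

model = get_model("lotka_volterra")
data = dataset_from_csv("lv.csv")
bw = bandwidth_grid(data.times.size, span=data.times[-1] - data.times[0])
result = select_estimate(model, data, bw)        # data-driven one-step fit
inference = summarize(model, result.eta_bar, data,
                      free_mask=result.free_mask)
```

`odestep mc --scenario table1_A_n21` replicates a whole simulation
study and prints per-parameter means, empirical standard errors
("STE"), average estimated asymptotic standard deviations ("ASYM") and
95% interval coverage.

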