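# npmix

Scalable nonparametric maximum likelihood estimation (NPMLE) of a mixing
distribution in (multivariate, heteroscedastic) Gaussian mixture models,
plus empirical-Bayes and optimal-transport denoising.

Given observations `Y_i = theta_i + Z_i` with `theta_i ~ G*` unknown and
`Z_i ~ N(0, Sigma_i)` with known covariances, the package fixes a support
grid `mu_1..mu_m` and maximizes the marginal log-likelihood over the
mixture weights on the simplex:

```
maximize (1/n) sum_i log( sum_j L_ij x_j ),   L_ij = phi_{Sigma_i}(Y_i - mu_j).
```

The solver is an augmented Lagrangian method applied to the Lagrangian
dual, with a semismooth Newton inner solver. The generalized Hessian is
`sigma [ (1/n^2) L S L' + D ]` with `S` a 0/1 diagonal selecting the
active grid columns, so each Newton system reduces (via
Sherman–Morrison–Woodbury) to a system of size `s = |active set|`, which
shrinks toward the number of NPMLE support points. This makes instances
with `n = 10^4, m = 5*10^3` solvable to KKT residual `~1e-8` in seconds.

Two denoisers post-process a fit:

- **eb** — posterior means under the fitted prior (convex combinations of
  grid atoms, may land off the support of `G*`);
- **ot** — barycentric projection of the exact optimal-transport coupling
  between the empirical law of `Y` and the fitted mixing distribution
  (estimates concentrate on the fitted atoms).

## Layout

| module | contents |
| --- | --- |
| `npmix.types` | `MixtureData`, `MixingDistribution`, `SolverConfig` |
| `npmix.grid` | 1-D / box / geometric-scale support grids |
| `npmix.likelihood` | row-scaled likelihood matrix, optional truncated pivoted QR |
| `npmix.ssn` | proximal map of the log-barrier, Moreau envelope, semismooth Newton inner solver |
| `npmix.alm` | outer augmented Lagrangian loop, KKT residual report |
| `npmix.denoise` | posterior means, exact Kantorovich LP, barycentric projection |
| `npmix.simulate` | seeded generators for the built-in simulation designs |
| `npmix.oracles` | EM, projected gradient and brute-force simplex reference solvers |
| `npmix.io`, `npmix.cli` | delimited-text I/O, JSON results, `npmix` command |

## CLI

```sh
# simulate a two-point sparse-means data set
npmix simulate example1 --n 1000 --nu 3 --tau 50 --seed 1 --out obs.csv

# fit the NPMLE on a 500-point grid
npmix fit --input obs.csv --grid-size 500 --tol 1e-7 --out result.json

# denoise by posterior means and transport projection
npmix denoise --input obs.csv --mixing result.json --method both --out denoised.csv
```

Scenarios: `example1` (two-point prior 0/nu with an exact count of
planted signals), `example2` (normal/t4/t6 blocks, fitted as a Gaussian
scale mixture with `--mixture scale`), `circles` (two concentric circles
in 2-D), `generic` (arbitrary discrete prior via `--atoms`/`--weights`).
Heteroscedastic noise is supplied with `--cov FILE --cov-mode
shared|diag|full` (diag: one row of variances per observation; full:
stacked d×d blocks).

## Python API

```python
import numpy as np
from npmix import (gen_example1, build_grid_1d, compute_likelihood_matrix,
                   alm_fit, SolverConfig, denoise)

data, theta = gen_example1(n=1000, nu=3.0, tau=50, seed=1)
support = build_grid_1d(data, m=500)
L = compute_likelihood_matrix(data, support)
result = alm_fit(L, support, SolverConfig(tol=1e-7))
print(result.report.eta_max, result.mixing.m)
```
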