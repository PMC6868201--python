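# fcidim

Intrinsic dimension estimation from the **full correlation integral**
(FCI), with a multiscale local variant and seeded synthetic-manifold
generators.

## The problem

Given N samples in R^D that lie on a manifold of intrinsic dimension
d ≤ D, how many degrees of freedom does the data actually have?
Classical geometric estimators (Grassberger–Procaccia correlation
dimension and its k-NN descendants) read d from the small-radius scaling
of the correlation integral

ρ_X(r) = 2/(N(N−1)) · Σ_{μ<ν} θ(r − ‖x^μ − x^ν‖) ~ r^d,   r → 0,

but sampling the small-r regime takes exponentially many points in d, so
for d ≳ 10 they underestimate badly. Projective methods (PCA) need
N ≳ d·log d and fail on curved manifolds. This package instead fits the
**entire** pair-distance CDF with the closed-form chord-length
distribution of a uniform hypersphere,

ρ̄(r̄) = 1/2 + (Ω_{m−1}/2Ω_m)(r̄² − 2) · ₂F₁(1/2, 1 − m/2; 3/2; ((r̄²−2)/2)²),
r̄ = r/r_s,

whose steepness at its midpoint grows like √m. The bulk of the distance
distribution is well sampled at any N, so the estimator stays accurate
even in the extreme undersampled regime N < d. The protocol: centre the
data, project every sample to the unit sphere, fit (m, r_s), report
d_est = m̂ + 1. A multiscale variant runs the same fit inside
neighbourhoods of growing radius around several centres and summarises
the resulting local-dimension curves by their minimum (curved manifolds)
and their plateau modes (mixed-dimension data). The classical correlation
dimension is included as a baseline, and generators for the validation
manifold families (embedded binary cubes, Gaussians, hypercubes, a
strongly curved polar-map family, the Swiss roll, two-cube unions,
high-contrast blob images) ship as first-class, tested code.

## Worked example

```python
from fcidim import FCIEstimator, CorrelationDimension, MultiscaleFCI
from fcidim.synthetic_data import gen_hypercube, gen_swiss_roll

# 100 samples of a 100-dimensional hypercube in R^500: N == d
X = gen_hypercube(100, d=100, D=500, seed=1)
est = FCIEstimator(random_state=1).fit(X)
print(est.dimension_, est.dimension_rounded_)
print(CorrelationDimension().fit(X).dimension_)

# a curved manifold: global FCI overestimates, the multiscale minimum does not
S = gen_swiss_roll(2000, seed=0)
print(FCIEstimator(random_state=0).fit(S).dimension_)
ms = MultiscaleFCI(n_centers=5, random_state=0).fit(S)
print(ms.dimension_rounded_, ms.plateau_modes_)
```

Output:

```
101.73385965500765 102
34.73313824720258
2.3028071465052236
2 [2.0116470612974267]
```

With only 100 samples of a 100-dimensional manifold the FCI fit reads
101.7 (1.7% high), while the correlation-dimension baseline collapses to
34.7 — the small-radius regime it relies on is unsampled. On the Swiss
roll the global fit reports 2.3 (curvature inflates the apparent
dimension of the rolled-up sheet), whereas the multiscale minimum and
its plateau mode both identify the true dimension 2.

The same functionality is exposed on the command line:

```bash
fcidim generate --family hypercube --d 40 --ambient 60 --n 500 --seed 1 data.csv
fcidim estimate data.csv --seed 1          # JSON report, d_est ≈ 40
fcidim multiscale data.csv --centers 5 --seed 1
fcidim corrdim data.csv
```

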