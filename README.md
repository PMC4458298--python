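# fmtunmix

Temporal unmixing of dynamic fluorescence molecular tomography (FMT) data
by convex nonnegative blind source separation, with PCA and ICA baselines,
eigenvalue-based source counting, a 2-D diffusion finite-element forward
model for simulation, and a Monte Carlo noise-robustness benchmark.

## The problem

In dynamic FMT a fluorescent dye is injected and boundary photon-density
images are recorded at a handful of time points (minutes apart).  Each
organ or tissue region holds the dye with its own pharmacokinetics, so the
recorded K×N stack is a linear mixture

    Ψ = Σₚ cₚ(tₖ) · aₚ  +  B  +  ε ,

where `aₚ` is the fixed spatial pattern of source p, `cₚ` its nonnegative
time course, `B` a static background (removed by subtracting a
pre-injection frame) and `ε` Gaussian noise.  Unmixing the stack recovers
which structures hold the dye and how its concentration evolves — before
any tomographic reconstruction.

PCA and ICA solve this only when the sources are spatially uncorrelated or
independent.  The convex approach (CAMNS: convex analysis of mixtures of
nonnegative sources) instead assumes **local dominance** — every source
has at least one *pure pixel* where the others vanish — and uses the fact
that, after sum-normalizing the frames, the true sources are exactly the
extreme points of the polyhedron

    { s = Hβ + d : s ≥ 0 } ,

where `d` is the mean observation and `H` an orthonormal basis of the
centered observation span.  Each extreme point is found by minimizing and
maximizing a random linear functional `rᵀ(Hβ + d)` over that polyhedron —
two linear programs per draw — with subsequent directions projected
orthogonal to the vertices already found.  The number of sources P is read
off the eigenspectrum of the K×K frame correlation matrix (number of
nonnegligible eigenvalues).

Separation quality is scored as

    δ = Σₚ Σₙ ( ȳ_pn − s̄_pn )² ,

the summed squared difference between max-normalized estimated and true
source images after best-permutation matching.

## Worked example

```python
import numpy as np
from fmtunmix import (NoiseSpec, camns_lp, pca_unmix, delta_rmse,
                      estimate_source_count, simulate_dynamic_measurements,
                      simulation_sources)

# two overlapping organ sources with correlated kinetics (r = 0.82)
patterns, courses = simulation_sources("correlated")
stack = simulate_dynamic_measurements(
    patterns, courses, noise=NoiseSpec(psnr_db=60.0, seed=0))

rep = estimate_source_count(stack, method="log-gap")
print(rep.estimated_P)
# 2          (eigenvalues 9.3e-02, 1.9e-03, then a flat 1e-06 noise floor)

res = camns_lp(stack, rep.estimated_P, rng_seed=0)
print(round(delta_rmse(res.sources, patterns).total_delta, 3))
# 0.031

ref = pca_unmix(stack, 2)
print(round(delta_rmse(ref.sources, patterns,
                       allow_sign_flip=True).total_delta, 3))
# 51.855
```

Two nonnegligible eigenvalues reveal the two sources; the convex method
recovers both overlapping images almost exactly (δ ≈ 0.03) while PCA —
whose orthogonality assumption the overlap violates — fails structurally
(δ ≈ 52) no matter how small the noise.  On spatially disjoint sources
with uncorrelated kinetics all three methods converge to δ below 10⁻² as
the noise vanishes.

## Command line

```sh
fmtunmix simulate  --config scene.yaml --seed 1 --out run/
fmtunmix unmix     --stack run/stack.npz --methods camns,pca,ica \
                   --sources auto --out run/results/
fmtunmix benchmark --config scene.yaml --reps 20 --out run/bench/
```

`simulate` renders a scene (phantom geometry, optics, disk inclusions with
time courses) through the diffusion FEM into a measurement stack
(NPZ + multi-page TIFF) plus ground truth and a provenance file;
`unmix` runs the selected methods (refusing un-subtracted backgrounds
unless `--subtract-background` is given); `benchmark` runs the Monte Carlo
noise study and writes CSV/JSON/plot.  Exit codes: 0 ok, 1 config/I-O,
2 algorithmic failure.

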