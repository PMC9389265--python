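# tpsreg

Membrane-computing swarm optimization for intensity-based 2D medical
image registration.

`tpsreg` registers a moving (*float*) image onto a fixed (*reference*)
image by searching the space of rigid+scale transforms
`(x, y, θ, Z)` — translation in pixels (x positive up, y positive left),
rotation in degrees (CCW), isotropic scale about the image center — for
the parameters maximizing the mutual information

    MI(A, B) = Σ_{a,b} p(a,b) · log2[ p(a,b) / (p(a) p(b)) ]

between the binned intensities of the reference and the resampled float.
MI is the standard similarity metric for multimodal alignment (e.g. a
T1-weighted against a T2-weighted MRI slice) because it rewards
statistical dependence rather than intensity agreement.

The optimizer is a **tissue P system**: a fixed 13-membrane, three-level
tree whose nine leaf membranes each evolve a small particle swarm under a
PSO-style velocity rule with three attractors (membrane-local best, a
randomly chosen sibling best, the parent's best). Communication rules
copy — never move — local bests between siblings, up to the three
mid-level membranes and finally to the output membrane, whose object
after a fixed number of steps is the answer. Every selection is a
max-substitution, so the global best is monotone, and a run is a pure
function of its seed. GA, flat PSO, and PSO+Powell baselines share the
same objective, bounds and seeding contracts, and a benchmark harness
runs repeated seeded trials and reports Max/Min/Mean/Δ summaries
(Δ = half-range) of parameter-recovery errors and MI.

Everything runs on synthetic brain-slice phantoms generated in-process
(nested-ellipse anatomy with a CSF class that is dark in the T1-like and
bright in the T2-like contrast), so no external data is needed; PNG/TIFF
and single NIfTI slices are supported as inputs too.

## Worked example

```python
import numpy as np
from tpsreg import (
    PhantomSpec, TransformParams, TPSysIRRegistration,
    make_phantom, make_float,
)

# a 128x128 synthetic brain slice, and a float image built from it by a
# known transform: 8 px up, 6 px left, 5 degrees CCW
ref, labels = make_phantom(PhantomSpec(size=128, noise_sd=0.01, seed=0))
truth = TransformParams(x=8, y=6, theta=5, z=1.0)
flt = make_float(ref, truth)

est = TPSysIRRegistration(
    bounds=((-15, 15), (-15, 15), (-15, 15), (1, 1)),  # scale known = 1
    random_state=1,
)
est.fit(ref, flt)
inv = truth.inverse()
print(f"recovered: x={est.params_.x:+.3f} y={est.params_.y:+.3f} "
      f"theta={est.params_.theta:+.3f}")
print(f"truth:     x={inv.x:+.3f} y={inv.y:+.3f} theta={inv.theta:+.3f}")
print(f"MI at optimum: {est.score_:.3f} bits")
```

Output:

```
recovered: x=-8.482 y=-5.292 theta=-5.022
truth:     x=-8.492 y=-5.280 theta=-5.000
MI at optimum: 1.969 bits
```

The recovered parameters are the *inverse* of the construction transform
(the float must be moved back), matched here to about 0.01 px and 0.02°;
the MI of ~1.97 bits is close to the reference's own marginal entropy at
64 bins, i.e. near-perfect alignment. The estimators follow scikit-learn
conventions (`get_params`/`set_params`/`clone`, fitted attributes with a
trailing underscore, `transform` to resample the float under the
recovered parameters); `run_tps`, `run_pso`, `run_ga` and
`run_pso_powell` are thin functional wrappers.

## Command line

```sh
tpsreg phantom --size 128 --modality-pair --float-params 8 6 5 0.8 --out-dir data
tpsreg register data/phantom.png data/phantom_float.png -a tpsysir --seed 1
tpsreg benchmark bench.yaml --out-dir results
```

`benchmark` takes a YAML config (phantom size, ground-truth transform,
algorithms, repetitions, bounds, per-algorithm options) and writes
per-run JSON records, a Max/Min/Mean/Δ summary CSV, and a boxplot-ready
long-format CSV of MI values.

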