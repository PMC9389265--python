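"""Scikit-learn-style registration estimators.

Each estimator wraps one optimizer behind the familiar
``fit``/``transform`` surface: ``fit(reference, floating)`` searches the
transform box for the parameters maximizing mutual information between
the reference and the resampled floating image; ``transform`` applies the
recovered transform. Hyperparameters are constructor arguments (so
``get_params``/``set_params``/``clone`` work for grid searches), and all
fitted state carries the trailing-underscore convention:

``params_``
    the recovered :class:`~tpsreg.imaging.TransformParams`;
``score_``
    the mutual information (bits) at ``params_``;
``trace_``
    the per-step global-best score trace;
``result_``
    the full :class:`~tpsreg.tps_core.RegistrationResult`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .baselines import (
    GAConfig,
    PowellConfig,
    PSOConfig,
    optimize_ga,
    optimize_pso,
    optimize_pso_powell,
)
from .imaging import Image2D, TransformParams, apply_transform, similarity
from .tps_core import DEFAULT_BOUNDS, EvolutionConfig, optimize_tps

__all__ = [
    "TPSysIRRegistration",
    "PSORegistration",
    "GARegistration",
    "PSOPowellRegistration",
]


def _as_image(obj) -> Image2D:
    if isinstance(obj, Image2D):
        return obj
    return Image2D.from_array(np.asarray(obj, dtype=float))


class BaseRegistration(BaseEstimator):
    """Shared fit/transform machinery; subclasses supply the optimizer."""

    def __init__(self, bounds=DEFAULT_BOUNDS, bins: int = 64, random_state: int = 0):
        self.bounds = bounds
        self.bins = bins
        self.random_state = random_state

    def _optimize(self, objective):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, reference, floating):
        """Estimate the transform registering ``floating`` onto ``reference``.

        Both operands may be :class:`Image2D` or raw 2D arrays (min-max
        normalized on entry).
        """
        ref = _as_image(reference)
        flt = _as_image(floating)
        if ref.shape != flt.shape:
            raise ValueError(
                f"reference and floating shapes differ: {ref.shape} vs {flt.shape}"
            )

        def objective(p: np.ndarray) -> float:
            return similarity(
                ref, flt, TransformParams.from_array(p), bins=self.bins
            )

        result = self._optimize(objective)
        self.reference_ = ref
        self.floating_ = flt
        self.result_ = result
        self.params_ = result.best_params
        self.score_ = result.best_score
        self.trace_ = result.trace
        self.n_evaluations_ = self._budget()
        return self

    def transform(self, X=None) -> Image2D:
        """Resample an image (default: the fitted floating image) under
        the recovered transform."""
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted; call fit first")
        img = self.floating_ if X is None else _as_image(X)
        return apply_transform(img, self.params_)

    def fit_transform(self, reference, floating) -> Image2D:
        return self.fit(reference, floating).transform()

    def score(self, reference=None, floating=None) -> float:
        """MI (bits) of the fitted registration; recomputable on new data."""
        if reference is None:
            return self.score_
        ref = _as_image(reference)
        flt = self.floating_ if floating is None else _as_image(floating)
        return similarity(ref, flt, self.params_, bins=self.bins)

    def _budget(self) -> int:  # objective evaluations consumed by fit
        raise NotImplementedError


class TPSysIRRegistration(BaseRegistration):
    """Tissue-P-system registration (the method this package exists for).

    Nine leaf membranes of ``particles_per_membrane`` particles each evolve
    under the three-attractor PSO rule; sibling/parent communication and
    max-substitution promote the best object to the output membrane over
    ``steps`` system steps.
    """

    def __init__(
        self,
        bounds=DEFAULT_BOUNDS,
        bins: int = 64,
        random_state: int = 0,
        omega_start: float = 0.9,
        omega_end: float = 0.4,
        l0: float = 1.4,
        l1: float = 1.4,
        l2: float = 1.4,
        particles_per_membrane: int = 10,
        steps: int = 40,
        velocity_clamp=None,
    ):
        super().__init__(bounds=bounds, bins=bins, random_state=random_state)
        self.omega_start = omega_start
        self.omega_end = omega_end
        self.l0 = l0
        self.l1 = l1
        self.l2 = l2
        self.particles_per_membrane = particles_per_membrane
        self.steps = steps
        self.velocity_clamp = velocity_clamp

    def _config(self) -> EvolutionConfig:
        return EvolutionConfig(
            bounds=tuple(tuple(b) for b in self.bounds),
            omega_start=self.omega_start,
            omega_end=self.omega_end,
            l0=self.l0,
            l1=self.l1,
            l2=self.l2,
            particles_per_membrane=self.particles_per_membrane,
            steps=self.steps,
            bins=self.bins,
            seed=self.random_state,
            velocity_clamp=self.velocity_clamp,
        )

    def _optimize(self, objective):
        return optimize_tps(objective, self._config())

    def _budget(self) -> int:
        return 9 * self.particles_per_membrane * (self.steps + 1)


class PSORegistration(BaseRegistration):
    """Plain flat-swarm global-best PSO baseline."""

    def __init__(
        self,
        bounds=DEFAULT_BOUNDS,
        bins: int = 64,
        random_state: int = 0,
        swarm: int = 30,
        iters: int = 60,
        omega_start: float = 0.9,
        omega_end: float = 0.4,
        c1: float = 2.0,
        c2: float = 2.0,
    ):
        super().__init__(bounds=bounds, bins=bins, random_state=random_state)
        self.swarm = swarm
        self.iters = iters
        self.omega_start = omega_start
        self.omega_end = omega_end
        self.c1 = c1
        self.c2 = c2

    def _optimize(self, objective):
        cfg = PSOConfig(
            swarm=self.swarm,
            iters=self.iters,
            omega_start=self.omega_start,
            omega_end=self.omega_end,
            c1=self.c1,
            c2=self.c2,
            bins=self.bins,
        )
        return optimize_pso(objective, self.bounds, cfg, self.random_state)

    def _budget(self) -> int:
        return self.swarm * (self.iters + 1)


class GARegistration(BaseRegistration):
    """Real-coded genetic-algorithm baseline."""

    def __init__(
        self,
        bounds=DEFAULT_BOUNDS,
        bins: int = 64,
        random_state: int = 0,
        population: int = 40,
        generations: int = 80,
        crossover_rate: float = 0.9,
        mutation_rate: float = 0.1,
    ):
        super().__init__(bounds=bounds, bins=bins, random_state=random_state)
        self.population = population
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate

    def _optimize(self, objective):
        cfg = GAConfig(
            population=self.population,
            generations=self.generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            bins=self.bins,
        )
        return optimize_ga(objective, self.bounds, cfg, self.random_state)

    def _budget(self) -> int:
        return self.population * (self.generations + 1)


class PSOPowellRegistration(BaseRegistration):
    """PSO hybridized with Powell coordinate-direction refinement."""

    def __init__(
        self,
        bounds=DEFAULT_BOUNDS,
        bins: int = 64,
        random_state: int = 0,
        swarm: int = 30,
        iters: int = 60,
        tol: float = 1e-4,
        max_sweeps: int = 20,
    ):
        super().__init__(bounds=bounds, bins=bins, random_state=random_state)
        self.swarm = swarm
        self.iters = iters
        self.tol = tol
        self.max_sweeps = max_sweeps

    def _optimize(self, objective):
        cfg = PowellConfig(
            pso=PSOConfig(swarm=self.swarm, iters=self.iters, bins=self.bins),
            tol=self.tol,
            max_sweeps=self.max_sweeps,
            bins=self.bins,
        )
        return optimize_pso_powell(objective, self.bounds, cfg, self.random_state)

    def _budget(self) -> int:
        return self.swarm * (self.iters + 1)  # plus the refinement line searches
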