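"""Desirability-based multi-response optimization of cytokine concentrations.

Each fitted dose-response surface is mapped through a one-sided (maximize)
desirability function d(y) in [0, 1]; individual desirabilities combine via
the geometric mean into an overall desirability D(x).  D is maximized by a
basin-hopping global search restarted from random points inside the
hypersphere ||x||_2 <= radius (the design's axial distance, so optima are
never extrapolations beyond the tested concentration range), and the top-k
restart solutions are averaged into the reported optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import basinhopping

from .doe import CCDesign, coded_to_conc
from .rsm import ResponseModel, predict

__all__ = [
    "DesirabilitySpec",
    "OptimizationConfig",
    "OptimizationResult",
    "desirability",
    "overall_desirability",
    "default_anchors",
    "optimize",
]

_CLIP_LO = 1e-12


@dataclass(frozen=True)
class DesirabilitySpec:
    """One-sided desirability ramp for a response to be maximized.

    d = 0 below ``lower``, 1 above ``upper``, ((y - L)/(U - L))^weight
    between; ``weight`` shapes the ramp (1 = linear).
    """

    response_name: str
    lower: float
    upper: float
    weight: float = 1.0
    goal: str = "maximize"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"{self.response_name}: lower must be < upper "
                f"({self.lower} >= {self.upper})"
            )
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.goal != "maximize":
            raise ValueError("only goal='maximize' is supported")


@dataclass
class OptimizationConfig:
    radius: float = 2.366
    n_restarts: int = 25
    top_k: int = 5
    seed: int = 0
    n_hops: int = 10  # basin-hopping iterations per restart
    step_size: float = 0.5  # hop displacement scale

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.top_k > self.n_restarts:
            raise ValueError("top_k cannot exceed n_restarts")


@dataclass
class OptimizationResult:
    solutions: list[tuple[np.ndarray, float]]  # (coded point, D), D descending
    averaged_optimum_coded: np.ndarray
    averaged_optimum_conc: dict[str, float]
    predicted_counts: dict[str, float]
    overall_desirability: float
    seed: int
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)


def desirability(value: float, spec: DesirabilitySpec) -> float:
    """Scale a predicted count into [0, 1]; monotone nondecreasing."""
    if value <= spec.lower:
        return 0.0
    if value >= spec.upper:
        return 1.0
    return ((value - spec.lower) / (spec.upper - spec.lower)) ** spec.weight


def overall_desirability(
    per_response_values: dict[str, float], specs: list[DesirabilitySpec]
) -> float:
    """Geometric mean of the individual desirabilities.

    Any single zero desirability annihilates the overall score.
    """
    if not specs:
        raise ValueError("at least one desirability spec is required")
    ds = []
    for spec in specs:
        if spec.response_name not in per_response_values:
            raise KeyError(f"no value for response {spec.response_name!r}")
        ds.append(desirability(per_response_values[spec.response_name], spec))
    if any(d == 0.0 for d in ds):
        return 0.0
    return float(math.exp(np.mean(np.log(ds))))


def default_anchors(
    model: ResponseModel, design: CCDesign, weight: float = 1.0
) -> DesirabilitySpec:
    """Anchor the ramp at the min/max predicted counts over the design points.

    The design-point prediction range is the least arbitrary [0,1] scaling
    when no explicit anchors are supplied; both ends remain overridable.
    """
    preds = [predict(model, x)[1] for x in design.coded_matrix]
    lo, hi = float(min(preds)), float(max(preds))
    if not lo < hi:
        hi = lo + 1.0  # flat surface: degenerate ramp, desirability stays 0
    return DesirabilitySpec(model.response_name, lower=lo, upper=hi, weight=weight)


def _project(x: np.ndarray, radius: float) -> np.ndarray:
    """Radial projection onto the closed ball of the given radius."""
    nrm = float(np.linalg.norm(x))
    if nrm > radius:
        return x * (radius / nrm)
    return x


def _sample_in_ball(rng: np.random.Generator, k: int, radius: float) -> np.ndarray:
    """Uniform draw in the k-ball: normalized Gaussian direction x radius*u^(1/k)."""
    d = rng.standard_normal(k)
    d /= np.linalg.norm(d)
    return d * radius * rng.uniform() ** (1.0 / k)


def optimize(
    models: list[ResponseModel],
    specs: list[DesirabilitySpec],
    config: OptimizationConfig,
    factors=None,
) -> OptimizationResult:
    """Maximize the overall desirability inside the feasibility hypersphere.

    Runs ``n_restarts`` independent basin-hopping searches of -D from points
    drawn uniformly in the ball; candidates outside the sphere are radially
    projected before evaluation, so every reported solution is feasible.
    The averaged optimum is the arithmetic mean of the ``top_k`` best restart
    solutions, mapped to concentration units when ``factors`` (list of
    FactorSpec, order matching the models' factors) is given.
    """
    by_name = {m.response_name: m for m in models}
    for spec in specs:
        if spec.response_name not in by_name:
            raise KeyError(f"no model for response {spec.response_name!r}")
    if not specs:
        raise ValueError("at least one desirability spec is required")
    used = [by_name[s.response_name] for s in specs]
    k = used[0].n_factors
    if any(m.n_factors != k for m in used):
        raise ValueError("models disagree on number of factors")
    # Deterministic spec order: results must not depend on list permutation.
    order = sorted(range(len(specs)), key=lambda i: specs[i].response_name)
    specs_sorted = [specs[i] for i in order]
    models_sorted = [used[i] for i in order]

    def d_overall(x: np.ndarray, clip: bool) -> float:
        ds = []
        for m, s in zip(models_sorted, specs_sorted):
            _, cnt = predict(m, x)
            d = desirability(cnt, s)
            ds.append(max(d, _CLIP_LO) if clip else d)
        if not clip and any(d == 0.0 for d in ds):
            return 0.0
        return float(math.exp(np.mean(np.log(ds))))

    def objective(x: np.ndarray) -> float:
        # clipped inside the search so log stays finite and gradients informative
        return -d_overall(_project(np.asarray(x, float), config.radius), clip=True)

    rng = np.random.default_rng(config.seed)
    solutions: list[tuple[np.ndarray, float]] = []
    for _ in range(config.n_restarts):
        x0 = _sample_in_ball(rng, k, config.radius)
        res = basinhopping(
            objective,
            x0,
            niter=config.n_hops,
            stepsize=config.step_size,
            minimizer_kwargs={"method": "Nelder-Mead", "options": {"xatol": 1e-6, "fatol": 1e-10}},
            rng=np.random.default_rng(int(rng.integers(2**31 - 1))),
        )
        x_best = _project(np.asarray(res.x, float), config.radius)
        solutions.append((x_best, d_overall(x_best, clip=False)))

    solutions.sort(key=lambda s: -s[1])
    degenerate = all(d == 0.0 for _, d in solutions)
    top = solutions[: config.top_k]
    avg = np.mean([x for x, _ in top], axis=0)

    conc: dict[str, float] = {}
    if factors is not None:
        conc = {
            f.name: coded_to_conc(f, avg[j]) for j, f in enumerate(factors)
        }
    preds = {m.response_name: predict(m, avg)[1] for m in models}
    notes = ["degenerate: objective flat at zero"] if degenerate else []
    return OptimizationResult(
        solutions=solutions,
        averaged_optimum_coded=avg,
        averaged_optimum_conc=conc,
        predicted_counts=preds,
        overall_desirability=d_overall(avg, clip=False),
        seed=config.seed,
        degenerate=degenerate,
        notes=notes,
    )
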