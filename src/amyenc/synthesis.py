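"""Activation maximization by evolutionary search over generator codes.

A synthesis target is a feature-space direction: the mean of an encoding
model's coefficient columns over a chosen voxel set, so that its dot
product with a feature vector equals the mean predicted (centered)
activation of those voxels.  The optimizer evolves generator latent codes
to maximize ``dot(extract(generate(z)), target)`` with a (mu/mu_w, lambda)
evolution strategy using log-rank recombination weights and cumulative
step-size adaptation.  Runs whose objective never improves, or whose final
image stays within tolerance of the initialization image, are flagged as
non-converged and excluded from downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import EncodingModel
from .synthetic import ToyNetworks

logger = logging.getLogger(__name__)


@dataclass
class SynthesisTarget:
    """A feature-space direction to maximize, tied to one encoding model."""

    beta: np.ndarray
    subject_id: str
    region: str

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("target coefficients must be finite")
        if np.linalg.norm(self.beta) == 0:
            raise ValueError("target has zero norm")


@dataclass
class SynthesisResult:
    """Outcome of one seeded activation-maximization run."""

    final_code: np.ndarray
    objective_trace: np.ndarray  # best-so-far per generation
    initial_objective: float
    seed: int
    converged: bool = False
    final_image: np.ndarray | None = None
    initial_image: np.ndarray | None = None
    target_subject: str | None = None
    target_region: str | None = None

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    @property
    def gain(self) -> float:
        return self.final_objective - self.initial_objective


def make_target(
    model: EncodingModel, voxel_subset: np.ndarray | None = None
) -> SynthesisTarget:
    """Build a synthesis target from an encoding model's coefficients.

    ``voxel_subset`` indexes columns within the model's region; ``None``
    uses all of them.  The target is the mean coefficient column, so
    ``dot(target, f - x_mean)`` equals the mean centered predicted
    activation over the chosen voxels for any feature vector ``f``.
    """
    B = model.pls.coefficients
    if voxel_subset is None:
        cols = B
    else:
        voxel_subset = np.asarray(voxel_subset, dtype=int)
        if voxel_subset.size == 0:
            raise ValueError("voxel subset is empty")
        if voxel_subset.min() < 0 or voxel_subset.max() >= B.shape[1]:
            raise ValueError("voxel subset out of range for this model")
        cols = B[:, voxel_subset]
    return SynthesisTarget(
        beta=cols.mean(axis=1), subject_id=model.subject_id, region=model.region
    )


def synthesis_objective(
    code: np.ndarray, networks: ToyNetworks, target: SynthesisTarget
) -> "float | np.ndarray":
    """Objective value(s): feature response of the rendered code(s) to the target.

    Accepts a single code (1-D) or a batch (2-D, one code per row).
    """
    code = np.asarray(code, dtype=float)
    feats = networks.features_from_code(code)
    out = feats @ target.beta
    if code.ndim == 1:
        return float(out)
    return out


def _rank_weights(mu: int) -> tuple[np.ndarray, float]:
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    return w, 1.0 / float((w**2).sum())


def evolve_maximize(
    objective,
    d_z: int,
    population: int = 28,
    generations: int = 100,
    init_sigma: float = 1.0,
    seed: int = 0,
    render=None,
) -> SynthesisResult:
    """Maximize ``objective`` over latent codes with a (mu/mu_w, lambda)-ES.

    Each generation samples ``population`` offspring around the current
    mean, recombines the best half with log-rank weights, and adapts the
    global step size by cumulative path length.  The best-so-far code and
    objective are tracked, so the trace is non-decreasing by construction.

    Parameters
    ----------
    objective
        Callable mapping a batch of codes (lambda x d_z) — or a single 1-D
        code — to objective value(s); larger is better.
    render
        Optional callable mapping a code to an image, used to store the
        initialization and final images for the convergence filter.
    """
    if population < 4:
        raise ValueError("population must be >= 4")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    lam = int(population)
    mu = lam // 2
    weights, mueff = _rank_weights(mu)
    cs = (mueff + 2.0) / (d_z + mueff + 5.0)
    ds = 1.0 + cs + 2.0 * max(0.0, np.sqrt((mueff - 1.0) / (d_z + 1.0)) - 1.0)
    chi_n = np.sqrt(d_z) * (1.0 - 1.0 / (4.0 * d_z) + 1.0 / (21.0 * d_z**2))

    init_code = rng.standard_normal(d_z)  # random starting point
    mean = init_code.copy()
    sigma = float(init_sigma)
    ps = np.zeros(d_z)

    def _eval(codes: np.ndarray) -> np.ndarray:
        vals = objective(codes)
        vals = np.atleast_1d(np.asarray(vals, dtype=float))
        if vals.shape != (codes.shape[0],):
            # objective only handles single codes; fall back to a loop
            vals = np.array([float(objective(c)) for c in codes])
        if not np.all(np.isfinite(vals)):
            raise RuntimeError(
                f"non-finite objective value encountered (sigma={sigma:.3g})"
            )
        return vals

    f0 = _eval(mean[None, :])[0]
    best_code = mean.copy()
    best_f = f0
    trace = np.empty(generations)
    for g in range(generations):
        Z = rng.standard_normal((lam, d_z))
        codes = mean + sigma * Z
        f = _eval(codes)
        order = np.argsort(-f)
        if f[order[0]] > best_f:
            best_f = float(f[order[0]])
            best_code = codes[order[0]].copy()
        zw = weights @ Z[order[:mu]]
        mean = mean + sigma * zw
        ps = (1.0 - cs) * ps + np.sqrt(cs * (2.0 - cs) * mueff) * zw
        sigma *= np.exp((cs / ds) * (np.linalg.norm(ps) / chi_n - 1.0))
        trace[g] = best_f

    result = SynthesisResult(
        final_code=best_code,
        objective_trace=trace,
        initial_objective=float(f0),
        seed=seed,
    )
    if render is not None:
        result.initial_image = np.asarray(render(init_code))
        result.final_image = np.asarray(render(best_code))
    return result


def synthesize_one(
    networks: ToyNetworks,
    target: SynthesisTarget,
    seed: int,
    population: int = 28,
    generations: int = 100,
    init_sigma: float = 1.0,
) -> SynthesisResult:
    """Run one activation-maximization for a target, rendering its images."""

    def objective(codes):
        return synthesis_objective(codes, networks, target)

    result = evolve_maximize(
        objective,
        d_z=networks.d_z,
        population=population,
        generations=generations,
        init_sigma=init_sigma,
        seed=seed,
        render=networks.generate,
    )
    result.target_subject = target.subject_id
    result.target_region = target.region
    return result


def convergence_filter(
    results: list[SynthesisResult],
    image_tol: float = 0.005,
    min_gain: float = 1e-6,
) -> list[SynthesisResult]:
    """Mark converged runs and return the retained subset.

    A run is excluded if its best-so-far objective gained less than
    ``min_gain`` over the initialization, or if its final image differs
    from the initialization image by less than ``image_tol`` mean absolute
    pixel difference (an optimization that stalled on an identical image).
    Runs without stored images are judged on gain alone.
    """
    if len(results) == 0:
        raise ValueError("no synthesis results to filter")
    retained = []
    for res in results:
        ok = res.gain >= min_gain
        if ok and res.final_image is not None and res.initial_image is not None:
            ok = float(np.abs(res.final_image - res.initial_image).mean()) >= image_tol
        res.converged = bool(ok)
        if ok:
            retained.append(res)
    n_drop = len(results) - len(retained)
    if n_drop:
        logger.info("convergence filter excluded %d of %d runs", n_drop, len(results))
    return retained


@dataclass
class SynthesisBattery:
    """All retained stimuli of a synthesis campaign plus their manifest."""

    results: list[SynthesisResult]
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)


def synthesize_battery(
    models: "dict[tuple[str, str], EncodingModel] | list[EncodingModel]",
    networks: ToyNetworks,
    n_seeds_per_target: int = 3,
    population: int = 28,
    generations: int = 100,
    init_sigma: float = 1.0,
    image_tol: float = 0.005,
    min_gain: float = 1e-6,
    base_seed: int = 0,
) -> SynthesisBattery:
    """Synthesize stimuli for every (subject, region) encoding model.

    Each target gets ``n_seeds_per_target`` independently seeded runs; the
    convergence filter is applied and a manifest of retained stimuli is
    assembled.  Per-run failures are logged and skipped without aborting
    the battery.
    """
    if isinstance(models, dict):
        model_list = list(models.values())
    else:
        model_list = list(models)
    if len(model_list) == 0:
        raise ValueError("no encoding models supplied")
    seed_rng = np.random.default_rng(base_seed)
    all_results: list[SynthesisResult] = []
    for model in model_list:
        target = make_target(model)
        for _ in range(n_seeds_per_target):
            run_seed = int(seed_rng.integers(0, 2**31 - 1))
            try:
                res = synthesize_one(
                    networks,
                    target,
                    seed=run_seed,
                    population=population,
                    generations=generations,
                    init_sigma=init_sigma,
                )
            except Exception:
                logger.exception(
                    "synthesis failed for %s/%s seed %d",
                    model.subject_id,
                    model.region,
                    run_seed,
                )
                continue
            all_results.append(res)
    retained = convergence_filter(all_results, image_tol=image_tol, min_gain=min_gain)
    manifest = pd.DataFrame(
        {
            "stimulus_id": np.arange(len(retained)),
            "target_region": [r.target_region for r in retained],
            "target_subject": [r.target_subject for r in retained],
            "seed": [r.seed for r in retained],
            "converged": [r.converged for r in retained],
            "final_objective": [r.final_objective for r in retained],
        }
    )
    return SynthesisBattery(results=retained, manifest=manifest)
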