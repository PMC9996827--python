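"""Best-fit search and DRAM MCMC over the adsorption-state space.

The posterior is ``exp(-chi^2 / 2)`` under uniform priors inside the
parameter bounds.  The two orientation angles live on a torus: proposals
wrap across +-180 degrees so a chain can step from theta = -179 to +178,
which removes the artificial reflecting barrier at the seam and improves
mixing for modes near it.  Penetration and Gamma proposals are reflected
at their bounds instead.

The sampler is a delayed-rejection adaptive Metropolis (DRAM): a
symmetric Gaussian random walk whose covariance adapts to the sampled
history, with one delayed-rejection stage at a contracted scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import differential_evolution, minimize

from .reflectivity import ContrastDefinition, ReflectivityCurve, chi_squared, simulate_contrast
from .slabs import AdsorptionState, Orientation, PackingError, SliceConfig
from .structure import ProteinModel

__all__ = ["wrap_angle", "FitProblem", "SamplerConfig", "MCMCChain",
           "best_fit", "run_mcmc", "combine_chains"]


def wrap_angle(x):
    """Wrap an angle in degrees to the half-open interval [-180, 180)."""
    return ((np.asarray(x) + 180.0) % 360.0) - 180.0 if np.ndim(x) \
        else float(((x + 180.0) % 360.0) - 180.0)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a proposal back into [lo, hi] by reflection at the bounds."""
    width = hi - lo
    if width <= 0:
        return lo
    y = (x - lo) % (2.0 * width)
    return lo + (y if y <= width else 2.0 * width - y)


@dataclass
class FitProblem:
    """A simultaneous multi-contrast fit of one rigid-body state.

    Free parameters are (theta, phi, z_pen, gamma), optionally extended
    with per-contrast intensity scales and flat backgrounds.  Gamma and
    the orientation are shared across all contrasts of the condition;
    only the nuisance parameters are per-contrast.
    """

    model: ProteinModel
    datasets: list[tuple[ContrastDefinition, ReflectivityCurve]]
    config: SliceConfig = field(default_factory=SliceConfig)
    bounds: dict[str, tuple[float, float]] | None = None
    fit_scale: bool = False
    fit_background: bool = False

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one dataset is required")
        ext = self.model.positions.max(axis=0) - self.model.positions.min(axis=0)
        diameter = float(np.linalg.norm(ext))
        defaults = {
            "theta": (-180.0, 180.0),
            "phi": (-180.0, 180.0),
            "z_pen": (0.0, diameter),
            "gamma": (0.0, 5.0),
            "scale": (0.5, 2.0),
            "background": (0.0, 1e-4),
        }
        if self.bounds:
            defaults.update(self.bounds)
        self._bounds_map = defaults

    @property
    def param_names(self) -> list[str]:
        names = ["theta", "phi", "z_pen", "gamma"]
        if self.fit_scale:
            names += [f"scale_{c.name}" for c, _ in self.datasets]
        if self.fit_background:
            names += [f"background_{c.name}" for c, _ in self.datasets]
        return names

    @property
    def bounds_array(self) -> np.ndarray:
        rows = [self._bounds_map[n if n in self._bounds_map else n.split("_")[0]]
                for n in self.param_names]
        return np.array(rows, dtype=float)

    @property
    def periodic(self) -> np.ndarray:
        return np.array([n in ("theta", "phi") for n in self.param_names])

    def states(self, params: np.ndarray) -> list[AdsorptionState]:
        """Per-dataset adsorption states implied by a parameter vector."""
        theta, phi, z_pen, gamma = params[:4]
        k = 4
        n = len(self.datasets)
        scales = params[k:k + n] if self.fit_scale else np.ones(n)
        k += n if self.fit_scale else 0
        bgs = params[k:k + n] if self.fit_background else np.zeros(n)
        base = AdsorptionState(
            orientation=Orientation(wrap_angle(theta), wrap_angle(phi)),
            z_pen=max(z_pen, 0.0), gamma=max(gamma, 0.0))
        return [replace(base, scale=float(s), background=float(b))
                for s, b in zip(scales, bgs)]

    def simulate(self, params: np.ndarray) -> list[ReflectivityCurve]:
        return [simulate_contrast(self.model, st, contrast, self.config)
                for st, (contrast, _) in zip(self.states(params), self.datasets)]

    def chi2(self, params: np.ndarray) -> float:
        try:
            sims = self.simulate(params)
        except PackingError:
            return np.inf
        return chi_squared(sims, [curve for _, curve in self.datasets])

    def log_posterior(self, params: np.ndarray) -> float:
        params = np.asarray(params, dtype=float).copy()
        params[self.periodic] = wrap_angle(params[self.periodic])
        lo, hi = self.bounds_array.T
        if np.any(params < lo - 1e-12) or np.any(params > hi + 1e-12):
            return -np.inf
        c2 = self.chi2(params)
        return -np.inf if not np.isfinite(c2) else -0.5 * c2


def best_fit(problem: FitProblem, seed: int = 0,
             maxiter: int = 100, popsize: int = 15,
             grid_step: float = 5.0, n_seeds: int = 5):
    """Global chi-squared minimisation.

    The orientation posterior can be orders of magnitude narrower than
    the 360-degree angle domain, so a single stochastic search is
    unreliable.  Three stages are used: (1) differential evolution over
    the full box pins down Gamma and penetration; (2) a coarse
    (theta, phi) grid scan at the stage-1 nuisance values locates
    candidate orientation basins; (3) derivative-free simplex refinement
    from the best candidates (the residue-to-slice binning makes chi^2
    piecewise smooth, so gradients are untrustworthy).  Deterministic
    given ``seed``.  Returns ``(states, params, chi2)`` where ``states``
    holds the per-contrast :class:`AdsorptionState`.
    """
    bounds = [tuple(b) for b in problem.bounds_array]
    result = differential_evolution(
        problem.chi2, bounds, seed=seed, maxiter=maxiter, popsize=popsize,
        init="sobol", polish=False, tol=1e-8)
    if not np.isfinite(result.fun):
        raise RuntimeError("no physically valid state found inside the bounds "
                           "(packing failure everywhere); widen the bounds or "
                           "lower gamma_max")
    base = np.asarray(result.x, dtype=float)
    candidates = [base]
    if problem.periodic[:2].all():
        grid = np.arange(-180.0, 180.0, grid_step)
        scores = np.full((len(grid), len(grid)), np.inf)
        probe = base.copy()
        for i, theta in enumerate(grid):
            for j, phi in enumerate(grid):
                probe[0], probe[1] = theta, phi
                scores[i, j] = problem.chi2(probe)
        order = np.argsort(scores.ravel(), kind="stable")[:n_seeds]
        for flat in order:
            i, j = divmod(int(flat), len(grid))
            cand = base.copy()
            cand[0], cand[1] = grid[i], grid[j]
            candidates.append(cand)
    best_x, best_f = base, result.fun
    for x0 in candidates:
        x = x0
        fval = np.inf
        for _ in range(3):  # simplex restarts until converged
            res = minimize(problem.chi2, x, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-8,
                                    "maxfev": 4000})
            x = res.x
            if abs(fval - res.fun) < 1e-6:
                break
            fval = res.fun
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    params = np.asarray(best_x, dtype=float)
    params[problem.periodic] = wrap_angle(params[problem.periodic])
    lo, hi = problem.bounds_array.T
    params = np.clip(params, lo, hi)
    return problem.states(params), params, float(best_f)


@dataclass
class SamplerConfig:
    """DRAM settings.

    Production-scale defaults follow the regime of millions of steps
    with a 10% burn-in; tests and examples scale ``n_steps`` down.
    """

    n_steps: int = 2_000_000
    n_burn: int = 200_000
    n_repeats: int = 1
    seed: int = 0
    adapt_interval: int = 1_000
    adapt_start: int = 500
    dr_scale: float = 0.2
    initial_step_fraction: float = 0.02  # of each bound width
    wrap_angles: bool = True

    def __post_init__(self) -> None:
        if self.n_steps <= self.n_burn:
            raise ValueError("n_steps must exceed n_burn")


@dataclass
class MCMCChain:
    """An accepted-step record over the parameter space."""

    steps: np.ndarray  # (n_steps, d), angles wrapped
    log_post: np.ndarray
    param_names: list[str]
    n_burn: int
    seed: int
    repeat_id: int = 0
    acceptance_rate: float = np.nan
    segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def posterior(self) -> np.ndarray:
        """Post-burn-in steps."""
        return self.steps[self.n_burn:]

    def save(self, path) -> None:
        """Columnar text chain plus a JSON metadata sidecar."""
        header = "step\t" + "\t".join(self.param_names) + "\tlog_post"
        idx = np.arange(len(self.steps))
        np.savetxt(path, np.column_stack([idx, self.steps, self.log_post]),
                   header=header, delimiter="\t")
        meta = {"n_burn": self.n_burn, "seed": self.seed,
                "repeat_id": self.repeat_id,
                "acceptance_rate": self.acceptance_rate,
                "param_names": self.param_names,
                "segments": self.segments}
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "MCMCChain":
        data = np.loadtxt(path, ndmin=2)
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
        return cls(steps=data[:, 1:-1], log_post=data[:, -1],
                   param_names=meta["param_names"], n_burn=meta["n_burn"],
                   seed=meta["seed"], repeat_id=meta["repeat_id"],
                   acceptance_rate=meta["acceptance_rate"],
                   segments=[tuple(s) for s in meta.get("segments", [])])


def _log1mexp(log_a: float) -> float:
    """log(1 - exp(log_a)) for log_a < 0."""
    if log_a >= 0.0:
        return -np.inf
    return float(np.log1p(-np.exp(log_a)))


def run_mcmc(target, config: SamplerConfig,
             x0: np.ndarray | None = None) -> list[MCMCChain]:
    """Sample a target posterior with DRAM, one chain per repeat.

    ``target`` provides ``log_posterior(x)``, ``bounds_array`` (d, 2) and
    ``periodic`` (boolean mask); :class:`FitProblem` satisfies this, as
    does any analytic test density with the same surface.  Repeats differ
    only by seeds spawned deterministically from ``config.seed``.
    """
    bounds = np.asarray(target.bounds_array, dtype=float)
    periodic = np.asarray(target.periodic, dtype=bool)
    if not config.wrap_angles:
        periodic = np.zeros_like(periodic)
    names = list(getattr(target, "param_names",
                         [f"p{i}" for i in range(len(bounds))]))
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_repeats)
    chains = []
    for repeat, seed_seq in enumerate(seeds):
        rng = np.random.default_rng(seed_seq)
        chains.append(_dram_single(target, config, bounds, periodic, names,
                                   rng, int(seed_seq.generate_state(1)[0] % 2**31),
                                   repeat, x0))
    return chains


def _constrain_eval(x: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    y = x.copy()
    y[periodic] = wrap_angle(y[periodic])
    return y


def _dram_single(target, config, bounds, periodic, names, rng, seed_id,
                 repeat, x0) -> MCMCChain:
    d = len(bounds)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if x0 is None:
        x = lo + rng.uniform(size=d) * (hi - lo)
    else:
        x = np.asarray(x0, dtype=float).copy()
    lpx = target.log_posterior(_constrain_eval(x, periodic))
    if not np.isfinite(lpx):
        raise ValueError("non-finite posterior at the initial state; "
                         "start from a best_fit result instead")

    cov = np.diag(((hi - lo) * config.initial_step_fraction) ** 2)
    chol = cholesky(cov, lower=True)
    sd = 2.4 ** 2 / d
    eps = 1e-10 * np.diag((hi - lo) ** 2)

    def propose(center: np.ndarray, scale: float) -> np.ndarray:
        y = center + scale * (chol @ rng.standard_normal(d))
        for j in range(d):
            if not periodic[j]:
                y[j] = _reflect(y[j], lo[j], hi[j])
        return y

    def log_q(y: np.ndarray, center: np.ndarray) -> float:
        delta = y - center
        delta[periodic] = wrap_angle(delta[periodic])
        v = solve_triangular(chol, delta, lower=True)
        return -0.5 * float(v @ v)

    steps = np.empty((config.n_steps, d))
    logps = np.empty(config.n_steps)
    accepted = 0
    for i in range(config.n_steps):
        y1 = propose(x, 1.0)
        lpy1 = target.log_posterior(_constrain_eval(y1, periodic))
        log_a1 = min(0.0, lpy1 - lpx)
        if np.log(rng.uniform()) < log_a1:
            x, lpx = y1, lpy1
            accepted += 1
        else:
            # delayed-rejection stage at a contracted scale
            y2 = propose(x, config.dr_scale)
            lpy2 = target.log_posterior(_constrain_eval(y2, periodic))
            if np.isfinite(lpy2):
                log_a1_rev = min(0.0, lpy1 - lpy2)
                num = lpy2 + log_q(y1, y2) + _log1mexp(log_a1_rev)
                den = lpx + log_q(y1, x) + _log1mexp(log_a1)
                if np.log(rng.uniform()) < min(0.0, num - den):
                    x, lpx = y2, lpy2
                    accepted += 1
        steps[i] = x
        logps[i] = lpx
        if i + 1 >= config.adapt_start and (i + 1) % config.adapt_interval == 0:
            sample_cov = np.cov(steps[: i + 1].T)
            sample_cov = np.atleast_2d(sample_cov)
            try:
                chol = cholesky(sd * sample_cov + eps, lower=True)
            except np.linalg.LinAlgError:
                pass  # keep previous proposal
    wrapped = steps.copy()
    wrapped[:, periodic] = wrap_angle(wrapped[:, periodic])
    return MCMCChain(steps=wrapped, log_post=logps, param_names=names,
                     n_burn=config.n_burn, seed=seed_id, repeat_id=repeat,
                     acceptance_rate=accepted / config.n_steps,
                     segments=[(repeat, config.n_steps)])


def combine_chains(chains: list[MCMCChain]) -> MCMCChain:
    """Concatenate the post-burn-in parts of several chains.

    Intended for multimodal posteriors whose modes do not mix: separate
    chains started at each local minimum are merged, with provenance of
    every segment recorded.
    """
    if not chains:
        raise ValueError("no chains to combine")
    names = chains[0].param_names
    for c in chains:
        if c.param_names != names:
            raise ValueError("chains have inconsistent parameter spaces")
    steps = np.concatenate([c.posterior for c in chains])
    logps = np.concatenate([c.log_post[c.n_burn:] for c in chains])
    segments = [(c.repeat_id, len(c.posterior)) for c in chains]
    rates = [c.acceptance_rate for c in chains]
    return MCMCChain(steps=steps, log_post=logps, param_names=names,
                     n_burn=0, seed=chains[0].seed, repeat_id=-1,
                     acceptance_rate=float(np.nanmean(rates)),
                     segments=segments)
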