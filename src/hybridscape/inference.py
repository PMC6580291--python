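"""Scenario fitting by Poisson composite likelihood and AIC model selection.

The observed joint SFS is compared with a scenario's expected spectrum per
unit theta; the scaling theta is profiled analytically, so it never counts as
a free parameter.  Optimization is derivative-free (Nelder-Mead on log- or
logit-transformed parameters) with a fixed simulation seed per restart, so
that within a restart the Monte-Carlo objective is a deterministic function
of the parameters (common random numbers).

The model-selection table follows standard information-criterion practice:
AIC = 2k - 2 lnL, models with deltaAIC < 10 retained, a [0, 1] model score
(Delta_max - deltaAIC_i)/Delta_max, and Akaike weights
wAIC_i = exp(-deltaAIC_i/2) / sum_j exp(-deltaAIC_j/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize
from scipy.special import gammaln, expit, logit

from ._coalescent import expected_jafs
from .demography import (
    PARAM_KINDS,
    ScenarioParams,
    compile_scenario,
    free_params,
)
from .sfs import JointSFS

__all__ = [
    "poisson_loglik",
    "FitResult",
    "fit_scenario",
    "aic",
    "model_selection",
    "DemographicModel",
    "DemographicResults",
    "ModelComparison",
]

_MODEL_FLOOR = 1e-12

#: optimization bounds in natural parameter space, per parameter kind
DEFAULT_BOUNDS = {
    "size": (1e-2, 100.0),
    "mig": (1e-2, 50.0),
    "time": (1e-2, 20.0),
    "frac": (1e-3, 1.0 - 1e-3),
    "timefrac": (1e-3, 1.0 - 1e-3),
}
_DEFAULT_INIT = {"size": 1.0, "mig": 1.0, "time": 1.0, "frac": 0.5, "timefrac": 0.5}


def poisson_loglik(obs: JointSFS, model_per_theta: JointSFS, floor: float = _MODEL_FLOOR):
    """Composite Poisson log-likelihood over unmasked cells.

    Returns ``(loglik, theta_hat)`` where ``theta_hat = sum(obs)/sum(model)``
    is the analytically optimal scaling.  Model cells below *floor* are
    clamped so the likelihood stays finite at finite Monte-Carlo resolution.
    """
    if not obs.compatible_with(model_per_theta):
        raise ValueError("observed and model spectra have mismatched shape/folding/mask")
    keep = ~obs.mask
    o = obs.entries[keep]
    m = model_per_theta.entries[keep]
    msum = m.sum()
    if msum <= 0:
        raise ValueError("model spectrum has no unmasked mass")
    theta = o.sum() / msum
    lam = np.clip(theta * m, floor, None)
    ll = float(np.sum(o * np.log(lam) - lam - gammaln(o + 1.0)))
    return ll, float(theta)


@dataclass
class FitResult:
    """Best-of-restarts maximum-likelihood fit of one scenario."""

    model: str
    params: dict[str, float]
    loglik: float
    theta: float
    k: int
    restarts: list[dict] = field(default_factory=list, repr=False)
    seed: int | None = None

    def scenario_params(self) -> ScenarioParams:
        return ScenarioParams(**self.params)


# ---------------------------------------------------------------------------
# Parameter transforms


def _to_z(x: float, kind: str, lo: float, hi: float) -> float:
    if kind in ("frac", "timefrac"):
        return float(logit(np.clip(x, lo, hi)))
    return float(np.log(np.clip(x, lo, hi)))


def _from_z(z: float, kind: str, lo: float, hi: float) -> float:
    x = float(expit(z)) if kind in ("frac", "timefrac") else float(np.exp(z))
    return float(np.clip(x, lo, hi))


def _build_params(model: str, x: dict[str, float]) -> ScenarioParams:
    names = free_params(model)
    vals = {}
    Ts = x.get("Ts")
    for name in names:
        if PARAM_KINDS[name] == "timefrac":
            vals[name] = x[name] * Ts  # sub-times parameterized as fractions of Ts
        else:
            vals[name] = x[name]
    return ScenarioParams(**vals)


def fit_scenario(
    obs: JointSFS,
    model: str,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    n_reps: int = 5000,
    init: dict[str, float] | None = None,
    maxiter: int | None = None,
) -> FitResult:
    """Fit one named scenario to an observed spectrum.

    Each restart is an independent optimization with its own fixed
    simulation seed for the expected-JAFS engine (common random numbers, so
    the objective is deterministic within a restart).  A restart runs a
    small differential-evolution global stage on a coarse (quarter-*n_reps*)
    objective — its initial population spans the full transformed bounds and
    includes the *init* point — followed by chained Nelder-Mead rounds that
    end at full Monte-Carlo resolution.  Sub-times (Tam, Tsc, Th) are
    optimized as fractions of Ts so chronology constraints hold by
    construction; reported values are in absolute units.
    """
    names = free_params(model)
    kinds = [PARAM_KINDS[n] for n in names]
    bnds = []
    for n, kind in zip(names, kinds):
        lo, hi = (bounds or {}).get(n, DEFAULT_BOUNDS[kind])
        if not np.isfinite(lo) or not np.isfinite(hi) or lo <= 0 and kind not in ("frac", "timefrac"):
            raise ValueError(f"bounds for {n} must be finite and positive")
        bnds.append((lo, hi))
    x0 = {n: (init or {}).get(n, _DEFAULT_INIT[k]) for n, k in zip(names, kinds)}
    z0 = np.array([_to_z(x0[n], k, *b) for n, k, b in zip(names, kinds, bnds)])
    z_lo = np.array([_to_z(b[0], k, *b) for k, b in zip(kinds, bnds)])
    z_hi = np.array([_to_z(b[1], k, *b) for k, b in zip(kinds, bnds)])
    root = np.random.SeedSequence(seed)
    restart_seeds = root.generate_state(2 * n_restarts + 2, dtype=np.uint32)
    log = []
    best = None

    def _objective_factory(sim_seed):
        def make_objective(reps):
            def objective(z):
                x = {n: _from_z(zi, k, *b) for n, zi, k, b in zip(names, z, kinds, bnds)}
                try:
                    comp = compile_scenario(model, _build_params(model, x))
                except ValueError:
                    return 1e12
                mdl = expected_jafs(comp, obs.sample_sizes, n_reps=reps, seed=sim_seed)
                if obs.folded:
                    from .sfs import fold_jafs

                    mdl = fold_jafs(mdl)
                ll, _ = poisson_loglik(obs, mdl)
                return -ll

            return objective

        return make_objective

    dim = len(names)
    for r in range(n_restarts):
        rng = np.random.default_rng(restart_seeds[2 * r])
        sim_seed = int(restart_seeds[2 * r + 1] & 0x7FFFFFFF)
        make_objective = _objective_factory(sim_seed)

        mi = maxiter or 150 * dim
        coarse_reps = max(400, n_reps // 4)
        coarse_obj = make_objective(coarse_reps)

        # global stage: small differential evolution on the coarse objective,
        # initial population across the full transformed bounds plus the init
        pop_size = max(16, 5 * dim)
        pop = rng.uniform(z_lo, z_hi, size=(pop_size, dim))
        pop[0] = z0
        pop[1] = z0 + rng.uniform(-np.log(3.0), np.log(3.0), dim)
        de = differential_evolution(
            coarse_obj,
            list(zip(z_lo, z_hi)),
            init=pop,
            maxiter=10 + 3 * dim,  # basin location only; NM does the refining
            tol=1e-8,
            seed=int(restart_seeds[2 * r]),
            polish=False,
            updating="immediate",
        )
        n_eval = int(de.nfev)

        opts = {"xatol": 1e-3, "fatol": 1e-3, "adaptive": True}

        def simplex(center, step):
            # initial simplex steps must exceed the Monte-Carlo jitter of the
            # objective, or Nelder-Mead stalls at its starting point
            verts = [center]
            for d in range(dim):
                v = center.copy()
                v[d] += step * (1 if rng.random() < 0.5 else -1)
                verts.append(v)
            return np.array(verts)

        # chained local rounds, ending at full Monte-Carlo resolution
        res = None
        x_cur = de.x
        for reps, it, step in ((coarse_reps, mi, 0.4), (n_reps, mi // 3, 0.15)):
            res = minimize(
                make_objective(reps),
                x_cur,
                method="Nelder-Mead",
                options={"maxiter": it, "initial_simplex": simplex(x_cur, step), **opts},
            )
            x_cur = res.x
            n_eval += int(res.nfev)
        x_end = {n: _from_z(zi, k, *b) for n, zi, k, b in zip(names, res.x, kinds, bnds)}
        entry = {
            "restart": r,
            "sim_seed": sim_seed,
            "start": {n: _from_z(zi, k, *b) for n, zi, k, b in zip(names, de.x, kinds, bnds)},
            "end": x_end,
            "loglik": -float(res.fun),
            "converged": bool(res.success),
            "n_eval": n_eval,
        }
        log.append(entry)
        if best is None or entry["loglik"] > best["loglik"]:
            best = entry
    if best is None or not np.isfinite(best["loglik"]):
        raise RuntimeError(f"all restarts failed for {model}: {log}")
    # recompute theta and report parameters in natural units
    p_best = _build_params(model, best["end"])
    comp = compile_scenario(model, p_best)
    mdl = expected_jafs(comp, obs.sample_sizes, n_reps=n_reps, seed=best["sim_seed"])
    if obs.folded:
        from .sfs import fold_jafs

        mdl = fold_jafs(mdl)
    ll, theta = poisson_loglik(obs, mdl)
    params = {n: getattr(p_best, n) for n in names}
    return FitResult(
        model=model,
        params=params,
        loglik=float(ll),
        theta=theta,
        k=len(names),
        restarts=log,
        seed=seed,
    )


def fit_model_set(
    obs: JointSFS,
    models: list[str],
    n_restarts: int | dict[str, int] = 10,
    seed: int = 0,
    n_reps: int = 5000,
    maxiter: int | None = None,
    init: dict | None = None,
) -> dict[str, FitResult]:
    """Fit a collection of scenarios with nested warm starts.

    Models are fitted in the given order; each model's default initialization
    is taken from the parameters of the best fit (highest log-likelihood) so
    far, restricted to the parameter names the two models share.  Simpler
    members of a nested hierarchy therefore guide the richer ones, while the
    global search stage still explores the full bounds.  *n_restarts* may be
    a mapping from model name to restart count (richer models often warrant
    more restarts).
    """
    fits: dict[str, FitResult] = {}
    best_so_far: FitResult | None = None
    for i, m in enumerate(models):
        this_init = dict(init or {})
        if best_so_far is not None:
            shared = set(free_params(m)) & set(best_so_far.params)
            for name in shared:
                if PARAM_KINDS[name] == "timefrac":
                    # stored values are absolute; re-expressed via this Ts later
                    continue
                this_init[name] = best_so_far.params[name]
        nr = n_restarts.get(m, 1) if isinstance(n_restarts, dict) else n_restarts
        fr = fit_scenario(
            obs, m, n_restarts=nr, seed=seed + 1000 * i,
            n_reps=n_reps, init=this_init or None, maxiter=maxiter,
        )
        fits[m] = fr
        if best_so_far is None or fr.loglik > best_so_far.loglik:
            best_so_far = fr
    return fits


def aic(fit: FitResult) -> float:
    """Akaike information criterion, 2k - 2 lnL (composite likelihood, no
    small-sample correction)."""
    return 2.0 * fit.k - 2.0 * fit.loglik


def model_selection(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fitted scenarios: AIC, deltaAIC, retention (deltaAIC < 10),
    model score, and Akaike weights."""
    if len(fits) < 2:
        raise ValueError("model selection needs at least 2 fits")
    names = [f.model for f in fits]
    aics = np.array([aic(f) for f in fits])
    delta = aics - aics.min()
    dmax = delta.max()
    if dmax == 0.0:
        warnings.warn("all models have equal AIC; scores defined as 1")
        scores = np.ones_like(delta)
    else:
        scores = (dmax - delta) / dmax
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return pd.DataFrame(
        {
            "MODEL": names,
            "MLE": [f.loglik for f in fits],
            "k": [f.k for f in fits],
            "theta": [f.theta for f in fits],
            "AIC": aics,
            "deltaAIC": delta,
            "retained": delta < 10.0,
            "score": scores,
            "wAIC": w,
        }
    ).set_index("MODEL")


# ---------------------------------------------------------------------------
# Model/Results interface


class DemographicModel:
    """A demographic scenario to be fitted to an observed joint SFS.

    Examples
    --------
    >>> model = DemographicModel(obs_sfs, "IM")           # doctest: +SKIP
    >>> results = model.fit(n_restarts=10, seed=1)        # doctest: +SKIP
    >>> print(results.summary())                          # doctest: +SKIP
    """

    def __init__(
        self,
        obs: JointSFS,
        model: str,
        bounds: dict | None = None,
        n_reps: int = 5000,
    ) -> None:
        free_params(model)  # validates the name
        self.obs = obs
        self.model = model
        self.bounds = bounds
        self.n_reps = n_reps

    def fit(
        self,
        n_restarts: int = 10,
        seed: int = 0,
        init: dict | None = None,
        maxiter: int | None = None,
    ) -> "DemographicResults":
        fr = fit_scenario(
            self.obs,
            self.model,
            bounds=self.bounds,
            n_restarts=n_restarts,
            seed=seed,
            n_reps=self.n_reps,
            init=init,
            maxiter=maxiter,
        )
        return DemographicResults(self, fr)

    def expected(self, params: ScenarioParams, n_reps: int | None = None, seed: int = 0) -> JointSFS:
        comp = compile_scenario(self.model, params)
        return expected_jafs(comp, self.obs.sample_sizes, n_reps or self.n_reps, seed)


class DemographicResults:
    """Fit results: MLE parameters, log-likelihood, theta, AIC, restart log."""

    def __init__(self, model: DemographicModel, fit: FitResult) -> None:
        self.model = model
        self.fit_result = fit
        self.params = pd.Series(fit.params, name=fit.model)
        self.loglik = fit.loglik
        self.theta = fit.theta
        self.k = fit.k

    @property
    def aic(self) -> float:
        return aic(self.fit_result)

    def summary(self) -> str:
        lines = [
            "Demographic scenario fit (Poisson composite likelihood)",
            "=" * 56,
            f"model:            {self.fit_result.model}",
            f"log-likelihood:   {self.loglik:.2f}",
            f"theta:            {self.theta:.4g}",
            f"free parameters:  {self.k}",
            f"AIC:              {self.aic:.2f}",
            f"restarts:         {len(self.fit_result.restarts)}",
            "-" * 56,
        ]
        for name, val in self.params.items():
            lines.append(f"{name:>8s}  {val:12.4g}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DemographicResults {self.fit_result.model} lnL={self.loglik:.2f}>"


class ModelComparison:
    """AIC comparison across fitted scenarios."""

    def __init__(self, results: list) -> None:
        fits = [r.fit_result if isinstance(r, DemographicResults) else r for r in results]
        self.table = model_selection(fits)

    @property
    def best_model(self) -> str:
        return str(self.table["AIC"].idxmin())

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    def summary(self) -> str:
        with pd.option_context("display.width", 120, "display.float_format", "{:.3f}".format):
            return str(self.table.sort_values("AIC"))
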