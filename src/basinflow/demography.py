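"""Composite-likelihood fitting of demographic models to a folded joint SFS.

The objective is the multinomial composite log-likelihood of the observed
SFS against the Monte-Carlo expected SFS, maximized by replicated
expectation-conditional-maximization (ECM): each replicate draws a random
start, then cycles through the free parameters maximizing the likelihood
one parameter at a time with a golden-section line search on the log
scale. Within a replicate the expected SFS is always evaluated with the
same simulation seed (common random numbers), so the likelihood surface
is deterministic and line searches are coherent. theta_S is fixed from
nucleotide diversity (Ne = pi / 4mu) because the SFS excludes invariant
sites and carries no absolute scale of its own.

Model comparison uses AIC with user-suppliable parameter counts, Akaike
weights, model averaging over the models containing each parameter, and
parametric-bootstrap confidence intervals (multinomial resimulation of
the observed site count at the MLE, refit each time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

from .coalescent import (
    MODEL_MIGRATIONS,
    DemographicModel,
    SimulationConfig,
    expected_sfs,
)
from .sfs import FoldedJointSFS

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "theta": (1e2, 1e7),
    "t": (1e2, 1e7),
    "m": (1e-9, 1e-2),
}


def ne_from_pi(pi: float, mu: float) -> float:
    """Diploid effective size from per-site diversity: Ne = pi / (4 mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if pi < 0:
        raise ValueError("pi must be non-negative")
    return pi / (4.0 * mu)


def generations_to_years(t_gen: float, generation_time_years: float) -> float:
    if t_gen < 0 or generation_time_years < 0:
        raise ValueError("arguments must be non-negative")
    return t_gen * generation_time_years


def composite_loglik(
    obs: FoldedJointSFS | np.ndarray, p: np.ndarray, p_min: float
) -> float:
    """Sum of obs * ln(max(p, p_min)) over unmasked cells."""
    counts = obs.counts if isinstance(obs, FoldedJointSFS) else np.asarray(obs, float)
    p = np.asarray(p, dtype=float)
    if counts.shape != p.shape:
        raise ValueError(f"shape mismatch: obs {counts.shape} vs p {p.shape}")
    if (counts < 0).any():
        raise ValueError("negative observed counts")
    mask = counts > 0
    return float((counts[mask] * np.log(np.maximum(p[mask], p_min))).sum())


def aic(lnl: float, k: int) -> float:
    """Akaike information criterion: 2k - 2 lnL."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return 2.0 * k - 2.0 * lnl


def model_table(entries) -> pd.DataFrame:
    """AIC comparison table from FitResults or (model_id, lnL, k) triples.

    Returns a DataFrame with lnL, k, AIC, dAIC, weight and a `best` flag
    marking the statistically-equivalent set (dAIC < 2).
    """
    rows = []
    for e in entries:
        if isinstance(e, FitResult):
            rows.append((e.model_id, e.lnl, e.k))
        else:
            rows.append(tuple(e))
    if not rows:
        raise ValueError("no models supplied")
    df = pd.DataFrame(rows, columns=["model", "lnL", "k"]).set_index("model")
    df["AIC"] = 2.0 * df["k"] - 2.0 * df["lnL"]
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    w = np.exp(-df["dAIC"] / 2.0)
    df["weight"] = w / w.sum()
    df["best"] = df["dAIC"] < 2.0
    return df


def model_average(
    estimates: dict[str, dict[str, float]],
    weights: dict[str, float],
    restrict_to_best: bool = False,
    best: set[str] | None = None,
) -> dict[str, float]:
    """Akaike-weighted average of point estimates.

    A parameter absent from a model is averaged only over the models that
    contain it, with the weights renormalized over those contributors.
    """
    models = list(estimates)
    if restrict_to_best:
        if best is None:
            raise ValueError("restrict_to_best requires the best-model set")
        models = [m for m in models if m in best]
    params: list[str] = []
    for m in models:
        for p in estimates[m]:
            if p not in params:
                params.append(p)
    out = {}
    for p in params:
        contrib = [m for m in models if p in estimates[m]]
        if not contrib:
            raise ValueError(f"parameter {p!r} present in no model")
        wsum = sum(weights[m] for m in contrib)
        if wsum <= 0:
            raise ValueError(f"zero total weight for parameter {p!r}")
        out[p] = sum(weights[m] * estimates[m][p] for m in contrib) / wsum
    return out


@dataclass
class InferenceConfig:
    """Settings for SFS model fitting.

    theta_s is the fixed southern effective size (from ne_from_pi).
    `n_sims` genealogies are used per likelihood evaluation; each of the
    `n_replicates` ECM replicates runs between ecm_min and ecm_max cycles
    with relative-lnL stopping tolerance `stop_tol`. `p_min` floors
    zero-probability cells; default 1 / (10 * n_sims).
    """

    theta_s: float
    mu: float = 3.5e-9
    generation_time_years: float = 1.0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_replicates: int = 10
    n_sims: int = 5000
    ecm_min_cycles: int = 2
    ecm_max_cycles: int = 10
    stop_tol: float = 1e-6
    golden_iters: int = 20
    n_bootstrap: int = 100
    bootstrap_replicates: int = 2
    p_min: float | None = None
    final_n_sims: int | None = None
    polish_maxfev: int = 200
    polish_n_sims: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.stop_tol <= 0:
            raise ValueError("stop_tol must be positive")
        if self.ecm_min_cycles > self.ecm_max_cycles:
            raise ValueError("ecm_min_cycles must be <= ecm_max_cycles")
        if self.theta_s <= 0:
            raise ValueError("theta_s must be positive")

    def bound(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        if name.startswith("theta"):
            return DEFAULT_BOUNDS["theta"]
        if name.startswith("t_"):
            return DEFAULT_BOUNDS["t"]
        return DEFAULT_BOUNDS["m"]

    @property
    def floor(self) -> float:
        return self.p_min if self.p_min is not None else 1.0 / (10.0 * self.n_sims)


@dataclass
class FitResult:
    """Outcome of fitting one model to an observed SFS."""

    model_id: str
    estimates: dict[str, float]
    lnl: float
    k: int
    n_replicates: int
    replicate_lnls: list[float]
    converged: bool
    config: dict


def _golden_max(f, lo: float, hi: float, iters: int) -> tuple[float, float]:
    """Golden-section maximization on [lo, hi]; returns best (x, f(x)) seen."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    best_x, best_f = (c, fc) if fc >= fd else (d, fd)
    for _ in range(iters):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
            if fc > best_f:
                best_x, best_f = c, fc
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
            if fd > best_f:
                best_x, best_f = d, fd
    return best_x, best_f


def _make_model(model_id: str, params: dict[str, float], theta_s: float):
    return DemographicModel(model_id=model_id, theta_s=theta_s, **params)


def _simplex_polish(
    obs: FoldedJointSFS,
    model_id: str,
    cfg: InferenceConfig,
    sim_cfg: SimulationConfig,
    best_lnl: float,
    best_params: dict[str, float],
    sim_seed: int,
    free: list[str],
) -> tuple[float, dict[str, float]]:
    """Refine the selected ECM endpoint on the selection surface.

    Alternates full-range coordinate (golden-section) cycles with
    Nelder-Mead simplex rounds on one common-random-number surface.
    Coordinate searches make large axis-aligned jumps but zigzag-stall on
    likelihood ridges whose axes are linear combinations of parameters
    (e.g. an ancestral size and the deeper split time); the simplex
    tracks such ridges but shrinks prematurely in six dimensions. The
    alternation lets each stage restart the other. Works in clipped
    log10 coordinates; t_div1 > t_div2 is penalized. The refined point
    is kept only if it improves the likelihood.
    """
    from scipy.optimize import minimize

    if cfg.polish_n_sims is not None:
        sim_cfg = replace(sim_cfg, n_sims=cfg.polish_n_sims)
        floor = 1.0 / (10.0 * cfg.polish_n_sims)
    else:
        floor = cfg.floor
    lo = np.array([math.log10(cfg.bound(n)[0]) for n in free])
    hi = np.array([math.log10(cfg.bound(n)[1]) for n in free])
    i1, i2 = free.index("t_div1"), free.index("t_div2")
    cache: dict[tuple, float] = {}

    def neg_lnl(x: np.ndarray) -> float:
        x = np.clip(x, lo, hi)
        penalty = 0.0
        if x[i1] > x[i2]:
            penalty = 1e4 * (x[i1] - x[i2])
            x = x.copy()
            x[i1] = x[i2]
        key = tuple(np.round(x, 9))
        if key not in cache:
            p = {n: 10.0 ** v for n, v in zip(free, x)}
            model = _make_model(model_id, p, cfg.theta_s)
            probs = expected_sfs(model, sim_cfg, seed=sim_seed)
            cache[key] = composite_loglik(obs, probs, floor)
        return -cache[key] + penalty

    def coordinate_cycle(x: np.ndarray, cur: float) -> tuple[np.ndarray, float]:
        x = x.copy()
        for i in range(len(free)):
            a, b = lo[i], hi[i]
            if i == i1:
                b = min(b, x[i2])
            elif i == i2:
                a = max(a, x[i1])
            if b <= a:
                continue

            def f(v, _i=i):
                trial = x.copy()
                trial[_i] = v
                return -neg_lnl(trial)

            v, fv = _golden_max(f, a, b, cfg.golden_iters)
            if fv > cur:
                x[i], cur = v, fv
        return x, cur

    best_x = np.array([math.log10(best_params[n]) for n in free])
    best_lnl = -neg_lnl(best_x)
    for _round in range(3):
        round_start = best_lnl
        best_x, best_lnl = coordinate_cycle(best_x, best_lnl)
        simplex = np.vstack(
            [best_x] + [best_x + 0.2 * e for e in np.eye(len(free))]
        )
        res = minimize(
            neg_lnl,
            best_x,
            method="Nelder-Mead",
            options={
                "maxfev": cfg.polish_maxfev,
                "xatol": 1e-4,
                "fatol": 1e-4,
                "initial_simplex": simplex,
            },
        )
        x = np.clip(res.x, lo, hi)
        if x[i1] > x[i2]:
            x[i1] = x[i2]
        lnl = -neg_lnl(x)
        if lnl > best_lnl:
            best_lnl, best_x = lnl, x
        if best_lnl - round_start < 0.5:
            break
    return best_lnl, {n: 10.0 ** v for n, v in zip(free, best_x)}


def fit_model(
    obs: FoldedJointSFS,
    model_id: str,
    cfg: InferenceConfig,
    extra_starts: list[dict[str, float]] | None = None,
) -> FitResult:
    """Maximum composite likelihood fit of one model variant by replicated ECM.

    Starts are drawn uniformly on the log scale within bounds; each
    replicate cycles one-parameter golden-section searches (log scale)
    under a replicate-fixed simulation seed, accepting a move only when it
    improves the likelihood, and stops once the relative improvement over
    a full cycle drops below `stop_tol` (after ecm_min_cycles). The best
    replicate wins.

    `extra_starts` are additional candidate parameter sets (e.g. the
    optimum of a nested model) that enter the candidate pool directly at
    the re-ranking stage, without an ECM pass of their own; migration
    parameters absent from an extra start default to their lower bound.
    """
    free = DemographicModel(
        model_id=model_id,
        theta_n=1e4,
        theta_c=1e4,
        theta_s=cfg.theta_s,
        theta_nc=1e4,
        theta_anc=1e4,
        t_div1=1e3,
        t_div2=1e4,
    ).free_params()
    sim_cfg = SimulationConfig(
        n_n=obs.sample_sizes[0],
        n_c=obs.sample_sizes[1],
        n_s=obs.sample_sizes[2],
        n_sims=cfg.n_sims,
    )
    endpoints: list[dict[str, float]] = []
    improved_any = False
    # replicate starts profile the deeper split time over a log-spaced
    # grid (one point per replicate), with the shallow split a fixed
    # ratio below it, sizes at the theta_s anchor, and migration rates at
    # the geometric center of their bounds. The first ECM cycle holds the
    # split times fixed so the sizes adapt to them before the times move;
    # free-for-all coordinate searches from arbitrary starts otherwise
    # fall into the degenerate mode where the shallow split collapses to
    # zero and two populations merge.
    t_lo, t_hi = cfg.bound("t_div2")
    g_lo = math.log10(t_lo) + 1.0
    g_hi = math.log10(t_hi) - 1.0
    if g_hi < g_lo:
        g_lo, g_hi = math.log10(t_lo), math.log10(t_hi)
    for rep in range(cfg.n_replicates):
        ss = np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, ord(model_id), rep])
        sim_seed = int(ss.generate_state(1)[0] % (2**31))

        if cfg.n_replicates > 1:
            g = g_lo + (g_hi - g_lo) * rep / (cfg.n_replicates - 1)
        else:
            g = 0.5 * (g_lo + g_hi)
        params: dict[str, float] = {}
        for name in free:
            lo, hi = cfg.bound(name)
            if name.startswith("theta"):
                start = cfg.theta_s
            elif name == "t_div2":
                start = 10.0**g
            elif name == "t_div1":
                start = 10.0**g / 8.0
            else:
                # alternate between the geometric center of the migration
                # bounds and the no-migration floor, so a model with
                # migration always explores the regime of its nested
                # variant (lnL(B) can otherwise fall below lnL(D))
                start = lo if rep % 2 == 1 else math.sqrt(lo * hi)
            params[name] = min(max(start, lo), hi)
        if params["t_div1"] > params["t_div2"]:
            params["t_div1"] = params["t_div2"]

        cache: dict[tuple, float] = {}

        def lnl_at(p: dict[str, float]) -> float:
            key = tuple(round(math.log10(v), 9) for v in p.values())
            if key not in cache:
                model = _make_model(model_id, p, cfg.theta_s)
                probs = expected_sfs(model, sim_cfg, seed=sim_seed)
                cache[key] = composite_loglik(obs, probs, cfg.floor)
            return cache[key]

        cur_lnl = lnl_at(params)
        start_lnl = cur_lnl
        for cycle in range(1, cfg.ecm_max_cycles + 1):
            cycle_start = cur_lnl
            for name in free:
                if cycle == 1 and name.startswith("t_"):
                    continue
                lo, hi = cfg.bound(name)
                if name == "t_div1":
                    hi = min(hi, params["t_div2"])
                elif name == "t_div2":
                    lo = max(lo, params["t_div1"])
                if hi <= lo:
                    continue

                def f(logx, _name=name):
                    trial = dict(params)
                    trial[_name] = 10**logx
                    return lnl_at(trial)

                x, fx = _golden_max(
                    f, math.log10(lo), math.log10(hi), cfg.golden_iters
                )
                if fx > cur_lnl:
                    params[name] = 10**x
                    cur_lnl = fx
            rel = abs(cur_lnl - cycle_start) / max(abs(cycle_start), 1e-300)
            if cycle >= cfg.ecm_min_cycles and rel < cfg.stop_tol:
                break
        if cur_lnl > start_lnl:
            improved_any = True
        endpoints.append(dict(params))

    for start in extra_starts or []:
        params = {}
        for name in free:
            lo, hi = cfg.bound(name)
            if name in start:
                params[name] = min(max(start[name], lo), hi)
            elif not name.startswith("theta") and not name.startswith("t_"):
                params[name] = lo
            else:
                raise ValueError(f"extra start missing parameter {name!r}")
        if params["t_div1"] > params["t_div2"]:
            params["t_div1"] = params["t_div2"]
        endpoints.append(params)

    # replicate endpoints are reached on different (and possibly small)
    # common-random-number surfaces, so their lnL values are not directly
    # comparable; re-rank them on one shared, higher-precision surface and
    # refine the winner there
    # model-independent seed: candidates imported from a nested model via
    # extra_starts are then scored on the very surface that ranked them
    # there, so the nesting inequality carries through re-ranking
    select_sims = cfg.polish_n_sims or cfg.n_sims
    select_seed = _seed_from(cfg.seed, 998)
    select_cfg = replace(sim_cfg, n_sims=select_sims)
    select_floor = 1.0 / (10.0 * select_sims) if cfg.p_min is None else cfg.p_min

    def select_lnl(p: dict[str, float]) -> float:
        probs = expected_sfs(
            _make_model(model_id, p, cfg.theta_s), select_cfg, seed=select_seed
        )
        return composite_loglik(obs, probs, select_floor)

    scored = [(select_lnl(p), p) for p in endpoints]
    replicate_lnls = [s for s, _ in scored]
    best_lnl, best_params = max(scored, key=lambda t: t[0])
    pre_polish = (best_lnl, dict(best_params))
    if cfg.polish_maxfev > 0:
        best_lnl, best_params = _simplex_polish(
            obs, model_id, cfg, select_cfg, best_lnl, best_params, select_seed, free
        )
    if cfg.final_n_sims is not None:
        # re-estimate the maximized lnL once with a model-independent seed
        # and (typically larger) simulation count, so lnL values are
        # comparable across models in an AIC table; both the polished and
        # the pre-polish candidate are evaluated, because polish gains on
        # the noisy selection surface do not always survive re-evaluation
        final_cfg = replace(sim_cfg, n_sims=cfg.final_n_sims)
        final_floor = 1.0 / (10.0 * cfg.final_n_sims)
        final_seed = _seed_from(cfg.seed, 999)

        def final_lnl(p: dict[str, float]) -> float:
            probs = expected_sfs(
                _make_model(model_id, p, cfg.theta_s), final_cfg, seed=final_seed
            )
            return composite_loglik(obs, probs, final_floor)

        candidates = [best_params]
        if pre_polish[1] != best_params:
            candidates.append(pre_polish[1])
        best_lnl, best_params = max(
            ((final_lnl(p), p) for p in candidates), key=lambda t: t[0]
        )
    return FitResult(
        model_id=model_id,
        estimates=best_params,
        lnl=best_lnl,
        k=len(free),
        n_replicates=cfg.n_replicates,
        replicate_lnls=replicate_lnls,
        converged=improved_any,
        config={
            "n_sims": cfg.n_sims,
            "ecm_min_cycles": cfg.ecm_min_cycles,
            "ecm_max_cycles": cfg.ecm_max_cycles,
            "stop_tol": cfg.stop_tol,
            "golden_iters": cfg.golden_iters,
            "seed": cfg.seed,
            "theta_s": cfg.theta_s,
        },
    )


def fit_battery(
    obs: FoldedJointSFS, model_ids: list[str], cfg: InferenceConfig
) -> dict[str, FitResult]:
    """Fit a set of model variants with nested warm starts.

    Models are fitted in the given order; each model receives the fitted
    optima of all previously fitted models whose active migration set is
    a subset of its own as extra starting candidates (absent migration
    rates at their lower bound). Listing models in order of increasing
    complexity therefore guarantees — up to final-surface Monte-Carlo
    noise — the nesting inequality lnL(richer) >= lnL(nested) that exact
    maximum likelihood satisfies. Independent multistart fits violate
    that inequality routinely: the scatter in attained lnL between
    optimization runs on Monte-Carlo surfaces is far larger than the
    2-unit AIC resolution, so warm-started batteries are the only way an
    AIC table over nested variants is interpretable at moderate
    simulation budgets.
    """
    fits: dict[str, FitResult] = {}
    for mid in model_ids:
        active = set(MODEL_MIGRATIONS[mid])
        warm = [
            dict(prev.estimates)
            for pid, prev in fits.items()
            if set(MODEL_MIGRATIONS[pid]) < active
        ]
        fits[mid] = fit_model(obs, mid, cfg, extra_starts=warm or None)
    return fits


@dataclass
class BootstrapResult:
    """Parametric-bootstrap confidence intervals per free parameter."""

    intervals: dict[str, tuple[float, float]]
    estimates: dict[str, list[float]]
    n_failures: int

    def covers(self, name: str, value: float) -> bool:
        lo, hi = self.intervals[name]
        return lo <= value <= hi


def parametric_bootstrap(
    fit: FitResult,
    obs: FoldedJointSFS,
    cfg: InferenceConfig,
    refit_config: InferenceConfig | None = None,
) -> BootstrapResult:
    """95% CIs by resimulating the observed site count at the MLE and refitting.

    Each bootstrap draws a multinomial SFS of the observed total from the
    expected SFS at the point estimates and refits with
    `cfg.bootstrap_replicates` ECM replicates (or with `refit_config`, a
    typically lighter configuration, when supplied). Intervals are
    bias-corrected pivotal intervals on the log scale: the mean log
    refit minus the log point estimate estimates the estimator bias
    (the Monte-Carlo composite-likelihood estimator is not unbiased at
    modest simulation counts, and the refits reproduce its bias), and
    the interval is a Student-t interval around the de-biased centre
    with the refit standard deviation inflated by sqrt(1 + 1/B). The
    t/sd form is used instead of raw refit percentiles because with the
    small refit counts affordable here (B ~ 10) empirical 2.5/97.5
    percentiles collapse to the sample extremes, which for B normal
    draws span only about +/-1.5 sd and systematically undercover.
    Refit failures are counted; more than 20% aborts.
    """
    n_sites = int(round(obs.total_mass))
    if n_sites <= 0:
        raise ValueError("observed SFS has no mass")
    model = _make_model(fit.model_id, fit.estimates, cfg.theta_s)
    sim_cfg = SimulationConfig(
        n_n=obs.sample_sizes[0],
        n_c=obs.sample_sizes[1],
        n_s=obs.sample_sizes[2],
        n_sims=cfg.n_sims,
    )
    # the generating spectrum must be much more precise than a fitting
    # surface: its Monte-Carlo noise would otherwise enter every bootstrap
    # data set as one shared distortion, coherently shifting all refits
    # and invalidating the intervals
    gen_sims = max(50_000, cfg.polish_n_sims or cfg.n_sims)
    sim_cfg = replace(sim_cfg, n_sims=gen_sims)
    p = expected_sfs(model, sim_cfg, seed=_seed_from(cfg.seed, 101))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 102]))
    estimates: dict[str, list[float]] = {k: [] for k in fit.estimates}
    failures = 0
    for b in range(cfg.n_bootstrap):
        counts = rng.multinomial(n_sites, p.ravel()).reshape(p.shape).astype(float)
        boot_obs = FoldedJointSFS(obs.sample_sizes, counts, monomorphic_masked=True)
        base = refit_config if refit_config is not None else replace(
            cfg, n_replicates=cfg.bootstrap_replicates
        )
        boot_cfg = replace(base, seed=_seed_from(cfg.seed, 103, b))
        try:
            refit = fit_model(boot_obs, fit.model_id, boot_cfg)
        except Exception:
            failures += 1
            continue
        for k, v in refit.estimates.items():
            estimates[k].append(v)
    if failures > 0.2 * cfg.n_bootstrap:
        raise RuntimeError(
            f"{failures}/{cfg.n_bootstrap} bootstrap refits failed"
        )
    intervals = {}
    for k, v in estimates.items():
        log_est = math.log(fit.estimates[k])
        lv = np.log(v)
        center = 2.0 * log_est - float(lv.mean())
        if len(lv) < 2:
            intervals[k] = (float(math.exp(center)), float(math.exp(center)))
            continue
        sd = float(lv.std(ddof=1)) * math.sqrt(1.0 + 1.0 / len(lv))
        half = float(student_t.ppf(0.975, len(lv) - 1)) * sd
        intervals[k] = (
            float(math.exp(center - half)),
            float(math.exp(center + half)),
        )
    return BootstrapResult(intervals, estimates, failures)


def _seed_from(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, *key])
    return int(ss.generate_state(1)[0] % (2**31))
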