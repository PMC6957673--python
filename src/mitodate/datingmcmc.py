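"""Bayesian divergence dating on a fixed rooted topology.

A relaxed lognormal clock (iid per-branch rate multipliers with mean 1), a
Yule prior on node ages, normal calibration priors whose 2.5%/97.5%
quantiles match the fossil age windows, and a single-chain
Metropolis-Hastings sampler.  The substitution model's exchangeabilities
and base frequencies are held fixed (typically at their ML estimates);
the gamma shape and invariant proportion are sampled.

Summaries are the shortest (highest-posterior-density) interval and an
initial-positive-sequence effective sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .datingpl import Calibration, resolve_calibration_node
from .mlphylo import SubstitutionModel, TreeLikelihood
from .seqio import Alignment

__all__ = [
    "McmcConfig",
    "McmcState",
    "McmcTrace",
    "HpdInterval",
    "log_posterior",
    "run_mcmc",
    "hpd_interval",
    "effective_sample_size",
]


@dataclass
class McmcConfig:
    """Chain settings.

    The default is a desk-scale chain (2e5 generations, sampling every
    100, 10% burn-in); the study-scale settings (1e7 generations, sample
    every 1e3, burn-in 1e6) can be requested explicitly.
    """

    n_generations: int = 200_000
    sample_every: int = 100
    burn_in: int | None = None          # default: 10% of generations
    seed: int | None = None
    likelihood: bool = True             # False = prior-only sampling
    step_sizes: dict[str, float] = field(default_factory=lambda: {
        "root_scale": 0.2, "rate_scale": 0.6, "clock_scale": 0.3,
        "sigma_scale": 0.4, "yule_scale": 0.5, "alpha_scale": 0.3,
        "p_inv_slide": 0.1,
    })

    def resolved_burn_in(self) -> int:
        b = (self.n_generations // 10) if self.burn_in is None else self.burn_in
        if b >= self.n_generations:
            raise ValueError("burn-in must be smaller than n_generations")
        return b


#: exponential hyperprior rates: sigma ~ Exp(3), Yule birth ~ Exp(10) (mean
#: 0.1 per Ma); clock mean and gamma shape get bounded log-uniform priors
SIGMA_PRIOR_RATE = 3.0
YULE_PRIOR_RATE = 10.0
CLOCK_BOUNDS = (1e-8, 10.0)
ALPHA_BOUNDS = (0.02, 100.0)


@dataclass
class McmcState:
    """One point in the parameter space of the dating model."""

    ages: np.ndarray            # per postorder node; tips 0
    multipliers: np.ndarray     # per non-root node (branch to parent)
    clock_mean: float           # substitutions/site/Ma
    sigma: float                # lognormal sd of the multipliers
    yule_rate: float            # birth rate (1/Ma)
    alpha: float
    p_inv: float

    def copy(self) -> "McmcState":
        return McmcState(self.ages.copy(), self.multipliers.copy(),
                         self.clock_mean, self.sigma, self.yule_rate,
                         self.alpha, self.p_inv)


class _Problem:
    """Indexing and posterior evaluation for a fixed rooted topology."""

    def __init__(self, alignment: Alignment | None, topology: dendropy.Tree,
                 calibrations: Sequence[Calibration],
                 model: SubstitutionModel, use_likelihood: bool = True):
        if len(topology.seed_node.child_nodes()) != 2:
            raise ValueError("dating needs a rooted (binary root) topology")
        self.tree = topology
        nodes = list(topology.postorder_node_iter())
        self.n = len(nodes)
        self.root = self.n - 1
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n, -1, int)
        self.is_tip = np.zeros(self.n, bool)
        for i, nd in enumerate(nodes):
            self.is_tip[i] = nd.is_leaf()
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
        self.internal = np.flatnonzero(~self.is_tip)
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        for i in range(self.n - 1):
            self.children[self.parent[i]].append(i)
        self.clades = {
            i: frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for i, nd in enumerate(nodes)
        }
        # internal descendants (inclusive) per internal node, for the
        # subtree-scale proposal
        self.internal_desc: dict[int, list[int]] = {}
        for i in self.internal:
            desc = [i]
            stack = list(self.children[i])
            while stack:
                j = stack.pop()
                if not self.is_tip[j]:
                    desc.append(j)
                    stack.extend(self.children[j])
            self.internal_desc[int(i)] = desc
        self.cal_nodes = [
            (index[id(resolve_calibration_node(topology, c))], c)
            for c in calibrations
        ]
        self.use_likelihood = use_likelihood and alignment is not None
        self.engine = (TreeLikelihood(alignment, topology, model)
                       if self.use_likelihood else None)
        self.model = model

    # -- priors -----------------------------------------------------------
    def log_prior(self, s: McmcState) -> float:
        ages = s.ages
        durations = ages[self.parent[: self.root]] - ages[: self.root]
        if np.any(durations <= 0) or ages[self.root] <= 0:
            return -np.inf
        if not (CLOCK_BOUNDS[0] <= s.clock_mean <= CLOCK_BOUNDS[1]):
            return -np.inf
        if not (ALPHA_BOUNDS[0] <= s.alpha <= ALPHA_BOUNDS[1]):
            return -np.inf
        if not (0.0 <= s.p_inv <= 0.99) or s.sigma <= 0 or s.yule_rate <= 0:
            return -np.inf
        if np.any(s.multipliers <= 0):
            return -np.inf
        lp = 0.0
        # Yule (pure birth) on internal node ages
        internal_ages = ages[self.internal]
        lp += (len(internal_ages) * np.log(s.yule_rate)
               - s.yule_rate * internal_ages.sum())
        # iid lognormal multipliers with mean 1: log m ~ N(-sigma^2/2, sigma^2)
        logm = np.log(s.multipliers)
        lp += float(np.sum(
            -np.log(s.multipliers) - np.log(s.sigma)
            - 0.5 * np.log(2 * np.pi)
            - (logm + s.sigma**2 / 2.0) ** 2 / (2.0 * s.sigma**2)))
        # normal calibration priors: window = central 95% interval
        for node, cal in self.cal_nodes:
            mu = 0.5 * (cal.min_age + cal.max_age)
            sd = (cal.max_age - cal.min_age) / 3.92
            lp += -0.5 * np.log(2 * np.pi) - np.log(sd) \
                - (ages[node] - mu) ** 2 / (2 * sd**2)
        # hyperpriors
        lp += -SIGMA_PRIOR_RATE * s.sigma
        lp += -YULE_PRIOR_RATE * s.yule_rate
        lp += -np.log(s.clock_mean)   # log-uniform within bounds
        lp += -np.log(s.alpha)
        return float(lp)

    def branch_lengths(self, s: McmcState) -> np.ndarray:
        durations = s.ages[self.parent[: self.root]] - s.ages[: self.root]
        return durations * s.clock_mean * s.multipliers

    def log_likelihood(self, s: McmcState) -> float:
        if not self.use_likelihood:
            return 0.0
        model = self.engine.model
        if model.alpha != s.alpha or model.p_inv != s.p_inv:
            self.engine.set_model(replace(model, alpha=s.alpha,
                                          p_inv=s.p_inv))
        return self.engine.log_likelihood(self.branch_lengths(s))

    def log_posterior(self, s: McmcState) -> float:
        lp = self.log_prior(s)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(s)


def log_posterior(state: McmcState, alignment: Alignment | None,
                  topology: dendropy.Tree,
                  calibrations: Sequence[Calibration],
                  model: SubstitutionModel,
                  use_likelihood: bool = True) -> float:
    """Log posterior density of a state (likelihood + priors)."""
    return _Problem(alignment, topology, calibrations, model,
                    use_likelihood).log_posterior(state)


@dataclass
class McmcTrace:
    """Retained samples of a dating chain."""

    ages: np.ndarray                       # (n_samples, n_nodes)
    params: pd.DataFrame                   # clock, sigma, yule, alpha, ...
    clades: dict[int, frozenset]
    acceptance: dict[str, float]
    config: McmcConfig

    def age_samples(self, tips: Sequence[str]) -> np.ndarray:
        """Posterior sample of the age of the MRCA of the given tips."""
        want = frozenset(tips)
        candidates = [i for i, c in self.clades.items() if want <= c]
        node = min(candidates, key=lambda i: len(self.clades[i]))
        return self.ages[:, node]

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for name in self.params.columns:
            x = self.params[name].to_numpy()
            h = hpd_interval(x, mass)
            rows.append(dict(parameter=name, median=float(np.median(x)),
                             mean=float(np.mean(x)), hpd_low=h.lower,
                             hpd_high=h.upper,
                             ess=effective_sample_size(x)))
        return pd.DataFrame(rows)


def _initial_state(problem: _Problem, rng: np.random.Generator) -> McmcState:
    n = problem.n
    ages = np.zeros(n)
    # topology height in edges, for proportional starting ages
    height = np.zeros(n, int)
    for i in range(n):
        for c in problem.children[i]:
            height[i] = max(height[i], height[c] + 1)
    cal_by_node = dict(problem.cal_nodes)
    root_cal = cal_by_node.get(problem.root)
    if root_cal is not None:
        root_age = 0.5 * (root_cal.min_age + root_cal.max_age)
    else:
        root_age = 1.3 * max(0.5 * (c.min_age + c.max_age)
                             for _, c in problem.cal_nodes)
    for i in problem.internal:
        ages[i] = root_age * height[i] / height[problem.root]
    # nudge calibrated nodes toward their windows where ordering allows
    for node, cal in sorted(cal_by_node.items(), key=lambda kv: -kv[0]):
        target = 0.5 * (cal.min_age + cal.max_age)
        lo = max((ages[c] for c in problem.children[node]), default=0.0)
        hi = ages[problem.parent[node]] if node != problem.root else np.inf
        ages[node] = float(np.clip(target, lo + 1e-6, hi - 1e-6))
    return McmcState(
        ages=ages,
        multipliers=np.ones(n - 1),
        clock_mean=0.001,
        sigma=0.3,
        yule_rate=0.1,
        alpha=problem.model.alpha,
        p_inv=problem.model.p_inv,
    )


def run_mcmc(alignment: Alignment | None, topology: dendropy.Tree,
             calibrations: Sequence[Calibration],
             config: McmcConfig | None = None,
             model: SubstitutionModel | None = None) -> McmcTrace:
    """Metropolis-Hastings sampling of the dating posterior.

    Proposals: a uniform slide of one internal node's age inside the
    interval allowed by its parent and children, a multiplicative scale of
    the root height above its older child, and multiplicative scales of a
    branch multiplier, the clock mean, the lognormal sd, the Yule rate and
    the gamma shape, plus a reflected slide of the invariant proportion.
    Reproducible given ``config.seed``.
    """
    config = config or McmcConfig()
    if model is None:
        model = SubstitutionModel(alpha=0.5, p_inv=0.2)
    if not calibrations:
        raise ValueError("at least one calibration is required")
    burn = config.resolved_burn_in()
    problem = _Problem(alignment, topology, calibrations, model,
                       config.likelihood)
    rng = np.random.default_rng(config.seed)
    state = _initial_state(problem, rng)
    lp = problem.log_posterior(state)
    if not np.isfinite(lp):
        raise RuntimeError("could not construct a feasible initial state")

    steps = config.step_sizes
    moves = ["age", "subtree", "root", "mult", "clock", "sigma", "yule",
             "alpha", "pinv"]
    weights = np.array([3.0, 2.0, 1.0, 3.0, 1.0, 0.5, 0.5, 0.5, 0.5])
    prior_only_moves = {"sigma", "yule"}
    weights = weights / weights.sum()
    n_prop = {m: 0 for m in moves}
    n_acc = {m: 0 for m in moves}
    non_root_internal = [int(i) for i in problem.internal
                         if i != problem.root]
    lp_prior = problem.log_prior(state)
    lp_like = problem.log_likelihood(state)
    lp = lp_prior + lp_like

    retained_ages = []
    retained_params = []

    for gen in range(1, config.n_generations + 1):
        move = moves[rng.choice(len(moves), p=weights)]
        n_prop[move] += 1
        new = state.copy()
        log_h = 0.0
        if move == "age" and non_root_internal:
            i = non_root_internal[rng.integers(len(non_root_internal))]
            lo = max(state.ages[c] for c in problem.children[i])
            hi = state.ages[problem.parent[i]]
            new.ages[i] = rng.uniform(lo, hi)
        elif move == "subtree" and non_root_internal:
            # scale all internal ages of a subtree jointly; essential for
            # shallow clades whose ages are strongly correlated
            i = non_root_internal[rng.integers(len(non_root_internal))]
            desc = problem.internal_desc[i]
            u = rng.uniform(-steps["root_scale"], steps["root_scale"])
            factor = np.exp(u)
            for j in desc:
                new.ages[j] = state.ages[j] * factor
            log_h = len(desc) * u
        elif move == "root":
            r = problem.root
            lo = max(state.ages[c] for c in problem.children[r])
            u = rng.uniform(-steps["root_scale"], steps["root_scale"])
            new.ages[r] = lo + (state.ages[r] - lo) * np.exp(u)
            log_h = u
        elif move == "mult":
            j = rng.integers(len(state.multipliers))
            u = rng.uniform(-steps["rate_scale"], steps["rate_scale"])
            new.multipliers[j] = state.multipliers[j] * np.exp(u)
            log_h = u
        elif move == "clock":
            u = rng.uniform(-steps["clock_scale"], steps["clock_scale"])
            new.clock_mean = state.clock_mean * np.exp(u)
            log_h = u
        elif move == "sigma":
            u = rng.uniform(-steps["sigma_scale"], steps["sigma_scale"])
            new.sigma = state.sigma * np.exp(u)
            log_h = u
        elif move == "yule":
            u = rng.uniform(-steps["yule_scale"], steps["yule_scale"])
            new.yule_rate = state.yule_rate * np.exp(u)
            log_h = u
        elif move == "alpha":
            u = rng.uniform(-steps["alpha_scale"], steps["alpha_scale"])
            new.alpha = state.alpha * np.exp(u)
            log_h = u
        else:  # pinv: reflected slide
            x = state.p_inv + rng.uniform(-steps["p_inv_slide"],
                                          steps["p_inv_slide"])
            lo, hi = 0.0, 0.99
            while x < lo or x > hi:
                x = 2 * lo - x if x < lo else 2 * hi - x
            new.p_inv = x
        new_prior = problem.log_prior(new)
        if np.isfinite(new_prior):
            new_like = (lp_like if move in prior_only_moves
                        else problem.log_likelihood(new))
            new_lp = new_prior + new_like
        else:
            new_like, new_lp = -np.inf, -np.inf
        if np.log(rng.random()) < (new_lp - lp) + log_h:
            state, lp = new, new_lp
            lp_prior, lp_like = new_prior, new_like
            n_acc[move] += 1
        if gen > burn and gen % config.sample_every == 0:
            retained_ages.append(state.ages.copy())
            retained_params.append(dict(
                log_posterior=lp, clock_mean=state.clock_mean,
                sigma=state.sigma, yule_rate=state.yule_rate,
                alpha=state.alpha, p_inv=state.p_inv,
                mean_multiplier=float(state.multipliers.mean()),
                root_age=float(state.ages[problem.root]),
            ))

    acceptance = {m: (n_acc[m] / n_prop[m] if n_prop[m] else np.nan)
                  for m in moves}
    return McmcTrace(
        ages=np.asarray(retained_ages),
        params=pd.DataFrame(retained_params),
        clades=problem.clades,
        acceptance=acceptance,
        config=config,
    )


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class HpdInterval:
    lower: float
    upper: float
    mass: float = 0.95


def hpd_interval(samples: Sequence[float] | np.ndarray,
                 mass: float = 0.95) -> HpdInterval:
    """Shortest interval containing at least ``mass`` of the samples."""
    x = np.sort(np.asarray(samples, float))
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise ValueError("need at least two finite samples")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    k = int(np.ceil(mass * n)) - 1
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return HpdInterval(float(x[i]), float(x[i + k]), mass)


def effective_sample_size(trace: Sequence[float] | np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS.

    ``n / (1 + 2 sum rho_k)`` with the autocorrelation sum truncated at the
    first lag pair whose sum is non-positive.  A constant trace is
    degenerate; it is reported as n with a warning.
    """
    x = np.asarray(trace, float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    var = x.var()
    if var == 0:
        warnings.warn("constant trace: ESS is degenerate, reporting n",
                      RuntimeWarning)
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (var * n)
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = acf[k] + acf[k + 1] if k + 1 < n else acf[k]
        if pair <= 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))
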