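"""Bayesian MCMC over the chromosome-number model.

Protocol: each tree in a posterior tree set gets its own chain, initialized
from Uniform(0, 1) draws, run for a fixed number of generations (one
generation = one sweep updating every free rate once) under independent
Exp(0.5) priors; a fixed burnin is discarded and the post-burnin portions
of all chains are pooled into the posterior estimate.  Taxa with several
chromosome records contribute one record per tree, drawn uniformly at
random, so record uncertainty is integrated over the tree set.

The default sampler is univariate slice sampling with stepping-out (width
1), which mixes well enough that short chains are informative; a
random-walk Metropolis variant (reflected at zero) exists mainly so that
detailed balance can be unit-tested against an analytic target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .statespace import (
    PARAM_NAMES,
    RateMatrixBuilder,
    RateParameters,
    StateSpace,
    build_state_space,
    infer_default_bounds,
)
from .likelihood import (
    MissingTipDataError,
    TipObservation,
    log_prior,
    pruning_loglik,
    rescale_to_unit_height,
)
from . import _pruning
from .trees import Phylogeny

logger = logging.getLogger(__name__)

SINGLE_REGIME_NAMES_FULL = ("gamma", "delta", "rho")
SINGLE_REGIME_NAMES_CONSTRAINED = ("gamma", "delta")


class SmallCladeError(ValueError):
    """Raised when a single-regime clade has too few tips to fit reliably."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampling protocol configuration (defaults follow the study protocol:
    50 generations per tree, first 25 discarded, Exp(0.5) prior)."""

    n_generations: int = 50
    burnin: int = 25
    prior_rate: float = 0.5
    init: str = "uniform01"
    sampler: str = "slice"
    model: str = "full"  # or "no_polyploidy"
    regimes: str = "two_regime"  # or "single_regime"
    root_mode: str = "fitzjohn"
    slice_width: float = 1.0
    metropolis_step: float = 0.3
    max_stepout: int = 200

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be positive")
        if not (0 <= self.burnin < self.n_generations):
            raise ValueError("need 0 <= burnin < n_generations")
        if self.prior_rate <= 0:
            raise ValueError("prior_rate must be positive")
        if self.sampler not in ("slice", "metropolis"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        if self.model not in ("full", "no_polyploidy"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.regimes not in ("two_regime", "single_regime"):
            raise ValueError(f"unknown regimes mode {self.regimes!r}")
        if self.init != "uniform01":
            raise ValueError(f"unknown init mode {self.init!r}")


def free_parameter_names(model: str, regimes: str) -> Tuple[str, ...]:
    """Names of the free rates for a model/regime combination."""
    if regimes == "two_regime":
        names = PARAM_NAMES
        if model == "no_polyploidy":
            names = tuple(n for n in names if not n.startswith("rho"))
        return names
    if model == "no_polyploidy":
        return SINGLE_REGIME_NAMES_CONSTRAINED
    return SINGLE_REGIME_NAMES_FULL


@dataclass
class MCMCChain:
    """One tree's chain: per-generation samples of the free rates (in
    per-unit-tree units) plus bookkeeping for back-transformation."""

    param_names: Tuple[str, ...]
    samples: np.ndarray  # (n_generations, n_free), per unit tree height
    log_posterior: np.ndarray
    tree_id: str
    scale: float  # original tree height in Myr
    seed: Optional[int]
    burnin: int
    stats: Dict[str, float] = field(default_factory=dict)

    @property
    def n_generations(self) -> int:
        return self.samples.shape[0]

    @property
    def samples_per_myr(self) -> np.ndarray:
        return self.samples / self.scale

    def post_burnin(self, units: str = "per_unit_tree") -> np.ndarray:
        block = self.samples if units == "per_unit_tree" else self.samples_per_myr
        return block[self.burnin :]

    def to_dataframe(self) -> pd.DataFrame:
        """Retained (post-burnin) generations with per-unit and per-Myr
        blocks, log-posterior, tree id and seed."""
        gens = np.arange(self.burnin, self.n_generations)
        data = {"generation": gens, "tree_id": self.tree_id}
        for j, name in enumerate(self.param_names):
            data[name] = self.samples[self.burnin :, j]
        for j, name in enumerate(self.param_names):
            data[f"{name}_per_Myr"] = self.samples_per_myr[self.burnin :, j]
        data["log_posterior"] = self.log_posterior[self.burnin :]
        data["scale_Myr"] = self.scale
        data["seed"] = -1 if self.seed is None else self.seed
        return pd.DataFrame(data)


def init_params(config: MCMCConfig, rng: np.random.Generator) -> RateParameters:
    """Draw initial rates i.i.d. Uniform(0, 1); fixed rates (rho under the
    constrained model) are set to zero."""
    names = free_parameter_names(config.model, "two_regime")
    draw = rng.uniform(0.0, 1.0, size=len(names))
    kwargs = dict(zip(names, draw))
    return RateParameters(**kwargs)


def _init_vector(n_free: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.0, 1.0, size=n_free)


def _slice_sweep(
    vec: np.ndarray,
    lp: float,
    logpost: Callable[[np.ndarray], float],
    rng: np.random.Generator,
    width: float,
    max_stepout: int,
) -> Tuple[np.ndarray, float, int]:
    """One slice-sampling sweep (stepping-out then shrinkage per parameter).

    Exploits that the posterior is -inf below zero: the left edge is clipped
    at 0, which preserves the slice within the support.
    """
    n_eval = 0
    for i in range(vec.size):
        x0 = vec[i]
        logy = lp + math.log(rng.uniform())
        u = rng.uniform(0.0, width)
        left = x0 - u
        right = left + width
        steps = max_stepout
        while left > 0.0 and steps > 0:
            vec[i] = left
            n_eval += 1
            if logpost(vec) <= logy:
                break
            left -= width
            steps -= 1
        if left < 0.0:
            left = 0.0
        steps = max_stepout
        while steps > 0:
            vec[i] = right
            n_eval += 1
            if logpost(vec) <= logy:
                break
            right += width
            steps -= 1
        while True:
            x1 = rng.uniform(left, right)
            vec[i] = x1
            n_eval += 1
            lp1 = logpost(vec)
            if lp1 >= logy:
                lp = lp1
                break
            if x1 < x0:
                left = x1
            else:
                right = x1
    return vec, lp, n_eval


def _metropolis_sweep(
    vec: np.ndarray,
    lp: float,
    logpost: Callable[[np.ndarray], float],
    rng: np.random.Generator,
    step: float,
) -> Tuple[np.ndarray, float, int]:
    """Random-walk Metropolis, one parameter at a time, reflected at zero
    (symmetric proposal, so plain Metropolis acceptance)."""
    accepted = 0
    for i in range(vec.size):
        old = vec[i]
        prop = old + rng.normal(0.0, step)
        if prop < 0.0:
            prop = -prop
        vec[i] = prop
        lp1 = logpost(vec)
        if math.log(rng.uniform()) < lp1 - lp:
            lp = lp1
            accepted += 1
        else:
            vec[i] = old
    return vec, lp, accepted


def sample_posterior(
    logpost: Callable[[np.ndarray], float],
    n_free: int,
    config: MCMCConfig,
    rng: np.random.Generator,
    init: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, Dict[str, float]]:
    """Run one chain against an arbitrary log-posterior over [0, inf)^k.

    Returns (samples, log-posterior trace, sampler statistics).
    """
    vec = _init_vector(n_free, rng) if init is None else np.asarray(init, float).copy()
    lp = logpost(vec)
    if not np.isfinite(lp):
        raise ValueError("initial state has non-finite log-posterior")
    samples = np.empty((config.n_generations, n_free))
    lps = np.empty(config.n_generations)
    total_stat = 0.0
    for g in range(config.n_generations):
        if config.sampler == "slice":
            vec, lp, stat = _slice_sweep(
                vec, lp, logpost, rng, config.slice_width, config.max_stepout
            )
        else:
            vec, lp, stat = _metropolis_sweep(
                vec, lp, logpost, rng, config.metropolis_step
            )
        total_stat += stat
        samples[g] = vec
        lps[g] = lp
    per_gen = total_stat / config.n_generations
    key = "evals_per_generation" if config.sampler == "slice" else "accepts_per_generation"
    return samples, lps, {key: per_gen}


def make_log_posterior(
    tree_unit: Phylogeny,
    tip_data: Mapping[str, TipObservation],
    space: StateSpace,
    config: MCMCConfig,
    loglik_fn: Optional[Callable[[np.ndarray], float]] = None,
) -> Tuple[Callable[[np.ndarray], float], Tuple[str, ...]]:
    """Build the vectorized log-posterior over the free rates."""
    names = free_parameter_names(config.model, config.regimes)
    if config.regimes == "single_regime" and len(space.types) != 1:
        raise ValueError("single-regime fits need a single-type state space")
    builder = RateMatrixBuilder(space, names)

    def logpost(vec: np.ndarray) -> float:
        if np.any(vec < 0):
            return -np.inf
        lp = log_prior(vec, config.prior_rate)
        if not np.isfinite(lp):
            return -np.inf
        if loglik_fn is not None:
            ll = loglik_fn(vec)
        else:
            Q = builder.fill(vec)
            flat, start, count = tree_unit.flat_children()
            ll = float(
                _pruning.prune_loglik_kernel(
                    tree_unit.postorder,
                    flat,
                    start,
                    count,
                    tree_unit.brlen,
                    logpost._tip_state,
                    tree_unit.n_tips,
                    Q,
                    _pruning.ROOT_FLAT
                    if config.root_mode == "flat"
                    else _pruning.ROOT_FITZJOHN,
                )
            )
            if ll == -np.inf:
                # truncated-series zero vs genuinely impossible data: let
                # the dense matrix-exponential path decide (rare)
                from .likelihood import _pruning_loglik_dense

                ll = _pruning_loglik_dense(
                    tree_unit, logpost._tip_state, Q, config.root_mode
                )
        if math.isnan(ll):
            raise FloatingPointError("likelihood evaluated to NaN")
        return lp + ll

    if loglik_fn is None:
        from .likelihood import _tip_state_indices

        logpost._tip_state = _tip_state_indices(tree_unit, tip_data, space)
        tree_unit.brlen = np.ascontiguousarray(tree_unit.brlen, dtype=float)
    return logpost, names


def run_mcmc(
    tree: Phylogeny,
    data: Mapping[str, TipObservation],
    space: StateSpace,
    config: MCMCConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    tree_id: Optional[str] = None,
    loglik_fn: Optional[Callable[[np.ndarray], float]] = None,
) -> MCMCChain:
    """One chain on one tree: rescale to unit height, sample, attach the
    back-transformation scale."""
    if rng is None:
        rng = np.random.default_rng(seed)
    tree_unit, scale = rescale_to_unit_height(tree)
    logpost, names = make_log_posterior(tree_unit, data, space, config, loglik_fn)
    samples, lps, stats = sample_posterior(logpost, len(names), config, rng)
    chain = MCMCChain(
        param_names=names,
        samples=samples,
        log_posterior=lps,
        tree_id=tree_id if tree_id is not None else (tree.label or "tree"),
        scale=scale,
        seed=seed,
        burnin=config.burnin,
        stats=stats,
    )
    logger.info(
        "chain %s: %d generations, scale %.4g Myr, %s",
        chain.tree_id,
        chain.n_generations,
        scale,
        stats,
    )
    return chain


def run_over_trees(
    trees: Sequence[Phylogeny],
    dataset,
    config: MCMCConfig,
    seed: int,
    space: Optional[StateSpace] = None,
) -> List[MCMCChain]:
    """The study protocol across a posterior tree set.

    For each tree, one chromosome record per taxon is drawn uniformly at
    random from that taxon's records, then one chain is run.  The master
    seed spawns an independent, tree-index-keyed substream per tree, so
    results for tree *i* do not depend on how many trees follow it.
    """
    missing = set()
    for tree in trees:
        missing.update(lab for lab in tree.tip_labels if lab not in dataset.records)
    if missing:
        raise MissingTipDataError(
            "taxa missing from the chromosome dataset: "
            + ", ".join(sorted(missing)[:20])
        )
    if space is None:
        bounds = infer_default_bounds(dataset)
        space = build_state_space(*bounds)
    chains = []
    for i, tree in enumerate(trees):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        tip_data = dataset.sample_tips(rng)
        chain = run_mcmc(
            tree,
            tip_data,
            space,
            config,
            rng=rng,
            seed=seed,
            tree_id=tree.label or f"tree_{i}",
        )
        chains.append(chain)
    return chains


def fit_single_regime(
    tree: Phylogeny,
    data: Mapping[str, TipObservation],
    config: MCMCConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    space: Optional[StateSpace] = None,
    min_tips: int = 20,
    allow_small: bool = False,
    tree_id: Optional[str] = None,
) -> MCMCChain:
    """Rate estimation for a clade fixed for one centromere regime.

    Only gamma, delta (and rho under the full model) are estimated; regime
    transitions are absent.  Clades at or below ``min_tips`` matched tips
    are refused unless ``allow_small`` overrides (small samples give
    unreliable rate estimates).
    """
    ctypes = {data[lab].centromere for lab in tree.tip_labels if lab in data}
    if len(ctypes) != 1:
        raise ValueError(
            "single-regime fit requires all tips to share one centromere type; "
            f"found {sorted(c.value for c in ctypes)}"
        )
    if tree.n_tips <= min_tips:
        if not allow_small:
            raise SmallCladeError(
                f"clade has {tree.n_tips} matched tips; fits with <= {min_tips} "
                "tips are refused because rate estimates become unreliable "
                "(pass allow_small=True to override)"
            )
        logger.warning(
            "fitting a clade with only %d tips (threshold %d): rate estimates "
            "may be unreliable",
            tree.n_tips,
            min_tips,
        )
    (ctype,) = ctypes
    if space is None:
        ns = [data[lab].haploid_n for lab in tree.tip_labels]
        bounds = infer_default_bounds(ns)
        space = build_state_space(*bounds, types=(ctype,))
    config = replace(config, regimes="single_regime")
    return run_mcmc(tree, data, space, config, seed=seed, rng=rng, tree_id=tree_id)


def pool_chains(
    chains: Sequence[MCMCChain], units: str = "per_Myr"
) -> pd.DataFrame:
    """Concatenate post-burnin samples across chains (the pooled posterior).

    Columns are the free-rate names in the requested units, plus
    ``log_posterior`` and ``tree_id``.
    """
    if not chains:
        raise ValueError("no chains to pool")
    names = chains[0].param_names
    frames = []
    for chain in chains:
        if chain.param_names != names:
            raise ValueError("chains have inconsistent parameter sets")
        block = chain.post_burnin(
            "per_Myr" if units == "per_Myr" else "per_unit_tree"
        )
        df = pd.DataFrame(block, columns=list(names))
        df["log_posterior"] = chain.log_posterior[chain.burnin :]
        df["tree_id"] = chain.tree_id
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_chains(chains: Sequence[MCMCChain], path) -> None:
    """Write all retained generations as one tab-delimited table."""
    pd.concat([c.to_dataframe() for c in chains], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
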