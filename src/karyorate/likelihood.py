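"""Pruning likelihood for chromosome-number evolution on a time tree.

Fitting happens on trees rescaled to unit root-to-tip height, so sampled
rates are in events per unit tree; reported rates are back-transformed to
events per million years by dividing by the original height.  The
log-likelihood itself is the standard post-order pruning recursion with
per-node rescaling; at the root the state frequencies are either uniform
("flat") or proportional to each state's share of the root conditional
likelihood ("fitzjohn").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Tuple

import numpy as np

from . import _pruning
from .statespace import (
    PARAM_NAMES,
    CentromereType,
    RateMatrix,
    RateParameters,
    StateSpace,
    build_rate_matrix,
    transition_probability_matrix,
)
from .trees import Phylogeny

logger = logging.getLogger(__name__)

ROOT_MODES = {"flat": _pruning.ROOT_FLAT, "fitzjohn": _pruning.ROOT_FITZJOHN}


class MissingTipDataError(KeyError):
    pass


@dataclass(frozen=True)
class TipObservation:
    """One chromosome record attached to a tree tip."""

    taxon: str
    haploid_n: int
    centromere: CentromereType

    def __post_init__(self) -> None:
        if int(self.haploid_n) < 1:
            raise ValueError(
                f"haploid number must be a positive integer, got {self.haploid_n} "
                f"for {self.taxon}"
            )
        object.__setattr__(self, "haploid_n", int(self.haploid_n))
        object.__setattr__(self, "centromere", CentromereType(self.centromere))


def rescale_to_unit_height(
    tree: Phylogeny, allow_non_ultrametric: bool = False
) -> Tuple[Phylogeny, float]:
    """Divide every branch by the root-to-tip height; return (tree, height).

    The height (in Myr) is the scale by which per-unit-tree rates are later
    divided to report events per Myr.
    """
    if not tree.is_ultrametric():
        if not allow_non_ultrametric:
            raise ValueError(
                "tree is not ultrametric; pass allow_non_ultrametric=True to "
                "rescale by maximum root-to-tip depth"
            )
        logger.warning(
            "tree %s is not ultrametric; rescaling by maximum root-to-tip depth",
            tree.label or "<unnamed>",
        )
    height = tree.height
    if height <= 0:
        raise ValueError("tree height must be positive")
    return tree.with_branch_lengths(tree.brlen / height), float(height)


def back_transform_rates(params: RateParameters, scale: float) -> RateParameters:
    """Convert per-unit-tree rates to per-Myr by dividing by the height."""
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if params.units != "per_unit_tree":
        raise ValueError("params are not in per-unit-tree units")
    return params.scaled(1.0 / scale, units="per_Myr")


def forward_transform_rates(params: RateParameters, scale: float) -> RateParameters:
    """Inverse of :func:`back_transform_rates`."""
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if params.units != "per_Myr":
        raise ValueError("params are not in per-Myr units")
    return params.scaled(scale, units="per_unit_tree")


def tip_vector(obs: TipObservation, space: StateSpace) -> np.ndarray:
    """Indicator vector over the state space for a fully observed tip."""
    if not space.contains(obs.haploid_n, obs.centromere):
        raise ValueError(
            f"taxon {obs.taxon}: observation (n={obs.haploid_n}, "
            f"{obs.centromere.value}) outside state space "
            f"[{space.n_min}, {space.n_max}]"
        )
    v = np.zeros(space.size)
    v[space.index_of(obs.haploid_n, obs.centromere)] = 1.0
    return v


def _tip_state_indices(
    tree: Phylogeny, data: Mapping[str, TipObservation], space: StateSpace
) -> np.ndarray:
    missing = [lab for lab in tree.tip_labels if lab not in data]
    if missing:
        raise MissingTipDataError(
            f"no chromosome record for tree tips: {', '.join(sorted(missing))}"
        )
    idx = np.empty(tree.n_tips, dtype=np.int64)
    for i, lab in enumerate(tree.tip_labels):
        obs = data[lab]
        if not space.contains(obs.haploid_n, obs.centromere):
            raise ValueError(
                f"taxon {obs.taxon}: n={obs.haploid_n} outside state-space "
                f"bounds [{space.n_min}, {space.n_max}]"
            )
        idx[i] = space.index_of(obs.haploid_n, obs.centromere)
    return idx


def _pruning_loglik_dense(
    tree: Phylogeny, tip_state: np.ndarray, Q: np.ndarray, root_mode: str
) -> float:
    """Reference pruning path using dense matrix exponentials (memoized per
    branch length within the call)."""
    n_states = Q.shape[0]
    clv = np.zeros((tree.n_nodes, n_states))
    cache: Dict[float, np.ndarray] = {}
    logscale = 0.0
    for node in tree.postorder:
        node = int(node)
        if node < tree.n_tips:
            clv[node, tip_state[node]] = 1.0
            continue
        v = np.ones(n_states)
        for child in tree.children[node]:
            t = float(tree.brlen[child])
            P = cache.get(t)
            if P is None:
                P = transition_probability_matrix(Q, t)
                cache[t] = P
            v = v * (P @ clv[child])
        m = v.max()
        if m <= 0:
            return -np.inf
        clv[node] = v / m
        logscale += math.log(m)
    r = clv[tree.root]
    total = r.sum()
    if total <= 0:
        return -np.inf
    if root_mode == "flat":
        like = total / n_states
    else:
        like = float(r @ r) / total
    return math.log(like) + logscale if like > 0 else -np.inf


def pruning_loglik(
    tree: Phylogeny,
    data: Mapping[str, TipObservation],
    Q: RateMatrix,
    root_mode: str = "fitzjohn",
    method: str = "uniformization",
) -> float:
    """Log-likelihood of the tip observations under the CTMC.

    ``method='uniformization'`` (default) runs the compiled
    action-of-exponential kernel; ``method='expm'`` is the dense
    scaling-and-squaring reference path.  The two agree to <1e-8.
    """
    if root_mode not in ROOT_MODES:
        raise ValueError(f"unknown root mode {root_mode!r}")
    space = Q.statespace
    tip_state = _tip_state_indices(tree, data, space)
    Qe = np.ascontiguousarray(Q.entries, dtype=float)
    if method == "expm":
        value = _pruning_loglik_dense(tree, tip_state, Qe, root_mode)
    elif method == "uniformization":
        flat, start, count = tree.flat_children()
        value = float(
            _pruning.prune_loglik_kernel(
                tree.postorder,
                flat,
                start,
                count,
                np.ascontiguousarray(tree.brlen, dtype=float),
                tip_state,
                tree.n_tips,
                Qe,
                ROOT_MODES[root_mode],
            )
        )
        if value == -math.inf:
            # the truncated series can report exactly zero for transitions
            # needing more events than the truncation order; the dense path
            # distinguishes genuinely impossible data from tiny likelihoods
            value = _pruning_loglik_dense(tree, tip_state, Qe, root_mode)
    else:
        raise ValueError(f"unknown method {method!r}")
    if math.isnan(value):
        raise FloatingPointError(
            f"likelihood evaluated to NaN on tree {tree.label or '<unnamed>'}"
        )
    return value


def log_prior(values: np.ndarray, prior_rate: float) -> float:
    """Sum of independent Exp(prior_rate) log-densities; -inf outside [0, inf)."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        return -np.inf
    return float(values.size * math.log(prior_rate) - prior_rate * values.sum())


def log_posterior(
    params: RateParameters,
    tree: Phylogeny,
    data: Mapping[str, TipObservation],
    space: StateSpace,
    prior_rate: float = 0.5,
    model: str = "full",
    root_mode: str = "fitzjohn",
    loglik_fn: Optional[Callable[[RateParameters], float]] = None,
) -> float:
    """Unnormalized log-posterior: pruning log-likelihood plus independent
    exponential log-priors over the free rates.

    Under the constrained model ("no_polyploidy") the rho rates are fixed at
    zero and excluded from both the generator's free parameters and the
    prior.  ``loglik_fn`` substitutes the likelihood (used for prior-recovery
    checks).
    """
    if model == "full":
        free = PARAM_NAMES
    elif model == "no_polyploidy":
        if params.rho_M != 0.0 or params.rho_H != 0.0:
            raise ValueError("constrained model requires rho_M = rho_H = 0")
        free = tuple(n for n in PARAM_NAMES if not n.startswith("rho"))
    else:
        raise ValueError(f"unknown model {model!r}")
    values = params.as_array(free)
    lp = log_prior(values, prior_rate)
    if not np.isfinite(lp):
        return -np.inf
    if loglik_fn is not None:
        ll = loglik_fn(params)
    else:
        Q = build_rate_matrix(params, space)
        ll = pruning_loglik(tree, data, Q, root_mode=root_mode)
    return lp + ll
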