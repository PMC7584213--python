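"""Synthetic data emulating the structure of the study inputs.

The generator produces: an ultrametric Yule tree scaled to a target height
in Myr; a joint chromosome-number/centromere-regime history simulated
forward along the tree (Gillespie, sharing the generator definition with
the likelihood); a record table in which taxa may carry several chromosome
counts; a "posterior" tree set obtained by jittering branch lengths; and
bootstrap resampling of (tree, record) pairs.

Defaults emulate the empirical setting: a few hundred tips, tree height
of order 100 Myr, haploid numbers centred around 12 inside the observed
range [2, 141], two centromere regimes distributed in clades (regime
switches are rare, so regimes cluster), and multiple records per taxon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .data import ChromosomeDataset
from .likelihood import TipObservation
from .statespace import (
    HOLOCENTRIC,
    MONOCENTRIC,
    CentromereType,
    RateParameters,
    StateSpace,
    build_state_space,
)
from .trees import Phylogeny

State = Tuple[int, CentromereType]


@dataclass(frozen=True)
class Event:
    """One simulated transition on a branch (time measured from the branch's
    rootward end)."""

    node: int  # id of the node below the branch
    time: float
    kind: str  # fission | fusion | polyploidy | switch
    n_from: int
    n_to: int
    ctype_from: CentromereType
    ctype_to: CentromereType


@dataclass(frozen=True)
class SimulationConfig:
    n_tips: int = 200
    tree_model: str = "yule"
    birth_rate: float = 1.0
    tree_height_target: float = 100.0  # Myr
    true_params: RateParameters = field(
        default_factory=lambda: RateParameters(
            gamma_M=0.01,
            gamma_H=0.03,
            delta_M=0.01,
            delta_H=0.01,
            rho_M=0.0,
            rho_H=0.0,
            q_MH=0.005,
            q_HM=0.005,
            units="per_Myr",
        )
    )
    root_state: State = (12, MONOCENTRIC)
    n_min: int = 1
    n_max: int = 150
    records_per_taxon: Union[int, Mapping[str, Sequence[int]]] = 3
    record_jitter: int = 2
    n_posterior_trees: int = 100
    branch_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("need at least 2 tips")
        if self.tree_model != "yule":
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if self.record_jitter < 0 or self.branch_jitter_sd < 0:
            raise ValueError("jitter parameters must be >= 0")
        n0, c0 = self.root_state
        if not (self.n_min <= n0 <= self.n_max):
            raise ValueError("root chromosome number outside the simulation bounds")

    def state_space(self) -> StateSpace:
        return build_state_space(self.n_min, self.n_max)


@dataclass
class SimulatedDataset:
    """Truth-carrying bundle: trees, full node histories, and records."""

    tree: Phylogeny
    trees: List[Phylogeny]
    node_states: Dict[int, State]
    events: List[Event]
    dataset: ChromosomeDataset
    config: SimulationConfig

    def tip_states(self) -> Dict[str, State]:
        return {
            self.tree.tip_labels[i]: self.node_states[i]
            for i in range(self.tree.n_tips)
        }

    def event_counts(self) -> Dict[str, int]:
        counts = {"fission": 0, "fusion": 0, "polyploidy": 0, "switch": 0}
        for ev in self.events:
            counts[ev.kind] += 1
        return counts

    def truth_dict(self) -> Dict[str, object]:
        n0, c0 = self.config.root_state
        return {
            "true_params_per_Myr": {
                name: getattr(self.config.true_params, name)
                for name in (
                    "gamma_M",
                    "gamma_H",
                    "delta_M",
                    "delta_H",
                    "rho_M",
                    "rho_H",
                    "q_MH",
                    "q_HM",
                )
            },
            "root_state": {"haploid_n": n0, "centromere": c0.value},
            "tree_height_Myr": self.tree.height,
            "n_tips": self.tree.n_tips,
            "event_counts": self.event_counts(),
            "seed": self.config.seed,
        }

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float,
    rng: np.random.Generator,
    height_target: Optional[float] = None,
) -> Phylogeny:
    """Pure-birth ultrametric tree with tips labelled t1..tn, linearly
    rescaled so the root-to-tip height equals ``height_target``.

    The root is the first split; with k lineages the next split arrives
    after Exp(k * birth_rate), hitting a uniformly chosen lineage.  After
    the n-th lineage appears the tree grows one final Exp(n * birth_rate)
    stretch, so terminal branches are never zero-length.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips for a tree")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    # each alive lineage: (children-or-None placeholder id, birth time)
    nodes: List[Dict[str, object]] = [{"birth": 0.0, "children": None}]  # root
    alive = [1, 2]
    nodes.append({"birth": 0.0, "children": None, "parent": 0})
    nodes.append({"birth": 0.0, "children": None, "parent": 0})
    nodes[0]["children"] = [1, 2]
    nodes[0]["parent"] = -1
    t = 0.0
    while len(alive) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(alive)))
        idx = int(rng.integers(len(alive)))
        node = alive[idx]
        left = len(nodes)
        nodes.append({"birth": t, "children": None, "parent": node})
        right = len(nodes)
        nodes.append({"birth": t, "children": None, "parent": node})
        nodes[node]["children"] = [left, right]
        nodes[node]["end"] = t
        alive[idx] = left
        alive.append(right)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(alive)))
    for node in alive:
        nodes[node]["end"] = t_end
    nodes[0]["end"] = 0.0

    def render(i: int) -> str:
        brlen = nodes[i]["end"] - nodes[i]["birth"]
        if nodes[i]["children"] is None:
            return f"LEAF:{brlen:.12g}"
        a, b = nodes[i]["children"]
        inner = f"({render(a)},{render(b)})"
        return inner if i == 0 else f"{inner}:{brlen:.12g}"

    newick = render(0) + ";"
    # label leaves t1..tn in newick order
    parts = newick.split("LEAF")
    newick = "".join(
        part + (f"t{k + 1}" if k + 1 < len(parts) else "")
        for k, part in enumerate(parts)
    )
    tree = Phylogeny.from_newick(newick, label="true_tree")
    if height_target is not None:
        height = tree.height
        if height <= 0:
            raise ValueError("degenerate zero-height tree")
        tree = tree.with_branch_lengths(tree.brlen * (height_target / height))
    return tree


def _gillespie_branch(
    state: State,
    length: float,
    params: RateParameters,
    space: StateSpace,
    rng: np.random.Generator,
    node: int,
) -> Tuple[State, List[Event]]:
    """Evolve one branch; events beyond the state-space bounds have rate
    zero in the generator and therefore never fire."""
    n, c = state
    t = 0.0
    events: List[Event] = []
    while True:
        moves: List[Tuple[State, float, str]] = []
        if space.contains(n + 1, c):
            moves.append(((n + 1, c), params.rate("gamma", c), "fission"))
        if space.contains(n - 1, c):
            moves.append(((n - 1, c), params.rate("delta", c), "fusion"))
        if space.contains(2 * n, c):
            moves.append(((2 * n, c), params.rate("rho", c), "polyploidy"))
        other = HOLOCENTRIC if c is MONOCENTRIC else MONOCENTRIC
        q = params.q_MH if c is MONOCENTRIC else params.q_HM
        if space.contains(n, other):
            moves.append(((n, other), q, "switch"))
        total = sum(r for _, r, _ in moves)
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= length:
            break
        u = rng.uniform(0.0, total)
        acc = 0.0
        for target, rate, kind in moves:
            acc += rate
            if u < acc:
                events.append(
                    Event(node, t, kind, n, target[0], c, target[1])
                )
                n, c = target
                break
    return (n, c), events


def simulate_history(
    tree: Phylogeny,
    true_params: RateParameters,
    space: StateSpace,
    root_state: State,
    rng: np.random.Generator,
) -> Tuple[Dict[int, State], List[Event]]:
    """Forward Gillespie simulation of the joint state along every branch.

    ``true_params`` are per-Myr and the tree is in Myr, so rates apply to
    branch lengths directly.  Returns the state at every node and the full
    event log.
    """
    n0, c0 = root_state
    if not space.contains(n0, c0):
        raise ValueError("root state outside the state space")
    states: Dict[int, State] = {}
    events: List[Event] = []
    for node in tree.postorder[::-1]:  # preorder: parents before children
        node = int(node)
        parent = int(tree.parent[node])
        if parent < 0:
            states[node] = (n0, c0)
            continue
        end_state, branch_events = _gillespie_branch(
            states[parent], float(tree.brlen[node]), true_params, space, rng, node
        )
        states[node] = end_state
        events.extend(branch_events)
    return states, events


def make_records(
    tip_states: Mapping[str, State],
    records_per_taxon: Union[int, Mapping[str, Sequence[int]]],
    record_jitter: int,
    rng: np.random.Generator,
    space: StateSpace,
) -> ChromosomeDataset:
    """Record table from true tip states.

    The first record per taxon is the true terminal state; additional
    records perturb the chromosome number by a uniform integer in
    [-jitter, +jitter] (clipped to the space bounds).  The centromere type
    is never perturbed: in the real data it is assigned at clade level.
    """
    if record_jitter < 0:
        raise ValueError("record_jitter must be >= 0")

    def n_records() -> int:
        if isinstance(records_per_taxon, int):
            if records_per_taxon < 1:
                raise ValueError("records_per_taxon must be >= 1")
            return records_per_taxon
        spec = dict(records_per_taxon)
        if "uniform_int" in spec:
            lo, hi = spec["uniform_int"]
            return int(rng.integers(int(lo), int(hi) + 1))
        raise ValueError(f"unknown records_per_taxon spec: {records_per_taxon!r}")

    observations = []
    for taxon, (n, c) in tip_states.items():
        k = n_records()
        observations.append(TipObservation(taxon, n, c))
        for _ in range(k - 1):
            jitter = int(rng.integers(-record_jitter, record_jitter + 1))
            n_extra = int(np.clip(n + jitter, space.n_min, space.n_max))
            observations.append(TipObservation(taxon, n_extra, c))
    return ChromosomeDataset.from_observations(observations)


def emulate_posterior_trees(
    tree: Phylogeny,
    n_posterior_trees: int,
    branch_jitter_sd: float,
    rng: np.random.Generator,
) -> List[Phylogeny]:
    """Branch-length-jittered copies of one topology, emulating a posterior
    tree sample.

    Every branch is multiplied by an i.i.d. lognormal factor (median 1, log
    sd = ``branch_jitter_sd``); terminal branches are then re-extended so
    all trees are ultrametric with the original height.  An internal node
    that jitter would push below the present is clamped just above it (its
    own branch shortened), so only offending branches are corrected and the
    rest of the tree keeps its jittered depths.
    """
    if n_posterior_trees < 1:
        raise ValueError("need at least one tree")
    height = tree.height
    is_tip = np.zeros(tree.n_nodes, dtype=bool)
    is_tip[: tree.n_tips] = True
    max_internal_depth = height * (1.0 - 1e-8)
    out = []
    for k in range(n_posterior_trees):
        if branch_jitter_sd == 0:
            out.append(tree.with_branch_lengths(tree.brlen.copy(), label=f"ptree_{k}"))
            continue
        factors = np.exp(rng.normal(0.0, branch_jitter_sd, size=tree.n_nodes))
        brlen = tree.brlen * factors
        depths = np.zeros(tree.n_nodes)
        for node in tree.postorder[::-1]:  # preorder: parents first
            node = int(node)
            p = int(tree.parent[node])
            if p < 0 or is_tip[node]:
                continue
            d = depths[p] + brlen[node]
            if d > max_internal_depth:
                d = max_internal_depth
                brlen[node] = d - depths[p]
            depths[node] = d
        parent_depth = depths[tree.parent[: tree.n_tips]]
        brlen[: tree.n_tips] = height - parent_depth
        out.append(tree.with_branch_lengths(brlen, label=f"ptree_{k}"))
    return out


def bootstrap_datasets(
    dataset: ChromosomeDataset,
    trees: Sequence[Phylogeny],
    n_boot: int,
    rng: np.random.Generator,
) -> List[Tuple[ChromosomeDataset, Phylogeny]]:
    """Bootstrap over both sources of uncertainty: each replicate draws one
    tree uniformly from the set and one record per taxon."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    out = []
    for _ in range(n_boot):
        tree = trees[int(rng.integers(len(trees)))]
        tip_data = dataset.sample_tips(rng)
        boot = ChromosomeDataset({t: [obs] for t, obs in tip_data.items()})
        out.append((boot, tree))
    return out


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """End-to-end synthetic dataset under the configured true rates."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    space = config.state_space()
    params = config.true_params
    if params.units != "per_Myr":
        raise ValueError("true_params must be in per-Myr units")
    tree = simulate_yule_tree(
        config.n_tips, config.birth_rate, rng, height_target=config.tree_height_target
    )
    node_states, events = simulate_history(
        tree, params, space, config.root_state, rng
    )
    tip_states = {
        tree.tip_labels[i]: node_states[i] for i in range(tree.n_tips)
    }
    dataset = make_records(
        tip_states, config.records_per_taxon, config.record_jitter, rng, space
    )
    trees = emulate_posterior_trees(
        tree, config.n_posterior_trees, config.branch_jitter_sd, rng
    )
    return SimulatedDataset(
        tree=tree,
        trees=trees,
        node_states=node_states,
        events=events,
        dataset=dataset,
        config=config,
    )
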