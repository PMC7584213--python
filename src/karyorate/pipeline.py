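"""End-to-end orchestration: data in -> chains -> DeltaR summary -> reports.

A run reads a tree set and a chromosome record table, executes the MCMC
protocol over all trees, pools the post-burnin samples, summarizes the
DeltaR statistics, and writes chains, summaries and a manifest under one
output directory.  Outputs are deterministic given the configuration and
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .data import ChromosomeDataset, read_chromosome_table
from .inference import (
    MCMCChain,
    MCMCConfig,
    SmallCladeError,
    fit_single_regime,
    pool_chains,
    run_over_trees,
    write_chains,
)
from .likelihood import MissingTipDataError
from .posterior import (
    PosteriorSummary,
    delta_r,
    hpd_interval,
    per_tree_table,
    summarize,
)
from .simulate import bootstrap_datasets
from .statespace import build_state_space, infer_default_bounds
from .trees import Phylogeny, read_tree_set

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    trees_path: str
    data_path: str
    output_dir: str
    seed: int
    model: str = "full"  # or "no_polyploidy"
    regimes: str = "two_regime"
    n_min: Optional[int] = None
    n_max: Optional[int] = None
    prior_rate: float = 0.5
    n_generations: int = 50
    burnin: int = 25
    sampler: str = "slice"
    root_mode: str = "fitzjohn"
    mechanisms: Optional[Tuple[str, ...]] = None
    hpd_prob: float = 0.95
    order_taxa: Optional[Tuple[str, ...]] = None
    order_name: str = "order"
    min_order_taxa: int = 20
    inclusive_threshold: bool = False  # ">= threshold" instead of "> threshold"
    allow_small: bool = False
    check_monophyly: bool = True
    n_boot: int = 100

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("mechanisms", "order_taxa"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> Dict[str, object]:
        d = dataclasses.asdict(self)
        for key in ("mechanisms", "order_taxa"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def mcmc_config(self, regimes: Optional[str] = None) -> MCMCConfig:
        return MCMCConfig(
            n_generations=self.n_generations,
            burnin=self.burnin,
            prior_rate=self.prior_rate,
            sampler=self.sampler,
            model=self.model,
            regimes=regimes or self.regimes,
            root_mode=self.root_mode,
        )

    def active_mechanisms(self) -> Tuple[str, ...]:
        if self.mechanisms is not None:
            return self.mechanisms
        if self.model == "no_polyploidy":
            return ("fission", "fusion")
        return ("fission", "fusion", "polyploidy")


@dataclass
class RunReport:
    output_dir: str
    manifest: List[str]
    config_echo: Dict[str, object]
    summary: Optional[PosteriorSummary] = None
    chains: Optional[List[MCMCChain]] = None
    pooled: Optional[pd.DataFrame] = None
    extra: Dict[str, object] = field(default_factory=dict)

    def validate_manifest(self) -> None:
        for rel in self.manifest:
            p = Path(self.output_dir) / rel
            if not p.exists() or p.stat().st_size == 0:
                raise FileNotFoundError(f"manifest entry missing or empty: {p}")


def _setup_run_log(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("karyorate")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def _teardown_run_log(handler: logging.Handler) -> None:
    logging.getLogger("karyorate").removeHandler(handler)
    handler.close()


def _load_inputs(config: RunConfig) -> Tuple[List[Phylogeny], ChromosomeDataset]:
    trees = read_tree_set(config.trees_path)
    dataset = read_chromosome_table(config.data_path)
    missing = set()
    for tree in trees:
        missing.update(lab for lab in tree.tip_labels if lab not in dataset.records)
    if missing:
        raise MissingTipDataError(
            "pre-flight check failed; tree tips missing from the dataset: "
            + ", ".join(sorted(missing)[:20])
        )
    return trees, dataset


def _state_space(config: RunConfig, dataset: ChromosomeDataset, types=None):
    if config.n_min is not None and config.n_max is not None:
        bounds = (config.n_min, config.n_max)
    else:
        bounds = infer_default_bounds(dataset)
    if types is None:
        return build_state_space(*bounds)
    return build_state_space(*bounds, types=types)


def _write_report_json(outdir: Path, config: RunConfig, manifest: List[str]) -> None:
    report = {
        "software": f"karyorate {__version__}",
        "config": config.to_dict(),
        "seed": config.seed,
        "manifest": sorted(manifest),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_two_regime(config: RunConfig) -> RunReport:
    """The headline analysis: two-regime model over a posterior tree set.

    Writes ``chains.tsv`` (retained generations, per-unit and per-Myr),
    ``summary.json`` (DeltaR per mechanism), ``per_tree.tsv`` (audit table)
    and ``report.json`` (manifest + config echo) under the output
    directory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(outdir)
    t0 = time.time()
    try:
        logger.info("two-regime run starting; config: %s", config.to_dict())
        trees, dataset = _load_inputs(config)
        space = _state_space(config, dataset)
        chains = run_over_trees(
            trees, dataset, config.mcmc_config(), seed=config.seed, space=space
        )
        pooled = pool_chains(chains, units="per_Myr")
        mechanisms = config.active_mechanisms()
        summary = summarize(chains, mechanisms, prob=config.hpd_prob, pooled=pooled)
        write_chains(chains, outdir / "chains.tsv")
        summary.to_json(outdir / "summary.json")
        per_tree_table(chains, mechanisms, config.hpd_prob).to_csv(
            outdir / "per_tree.tsv", sep="\t", index=False
        )
        manifest = ["chains.tsv", "summary.json", "per_tree.tsv", "report.json"]
        _write_report_json(outdir, config, manifest)
        logger.info("two-regime run finished in %.1f s", time.time() - t0)
        report = RunReport(
            output_dir=str(outdir),
            manifest=manifest,
            config_echo=config.to_dict(),
            summary=summary,
            chains=chains,
            pooled=pooled,
        )
        report.validate_manifest()
        return report
    finally:
        _teardown_run_log(handler)


def run_order_level(config: RunConfig) -> RunReport:
    """Single-regime rate estimation for one named clade (e.g. an order).

    The clade is given as a tip subset; by default it must be monophyletic
    in every tree and exceed the minimum-size threshold (rate estimates
    from small clades are unreliable).  Writes per-parameter credible
    intervals pooled over trees.
    """
    if not config.order_taxa:
        raise ValueError("order-level runs need order_taxa in the config")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(outdir)
    try:
        trees, dataset = _load_inputs(config)
        subset = [t for t in config.order_taxa if t in dataset.records]
        n_matched = len(subset)
        threshold_ok = (
            n_matched >= config.min_order_taxa
            if config.inclusive_threshold
            else n_matched > config.min_order_taxa
        )
        if not threshold_ok and not config.allow_small:
            raise SmallCladeError(
                f"order {config.order_name!r} has {n_matched} matched taxa; "
                f"the threshold is {'>=' if config.inclusive_threshold else '>'} "
                f"{config.min_order_taxa}"
            )
        chains = []
        sub_dataset = dataset.subset(subset)
        for i, tree in enumerate(trees):
            if config.check_monophyly and not tree_is_monophyletic(tree, subset):
                raise ValueError(
                    f"taxa of order {config.order_name!r} are not monophyletic "
                    f"in tree {i}"
                )
            pruned = extract_subtree(tree, subset)
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
            rng = np.random.default_rng(ss)
            tip_data = sub_dataset.sample_tips(rng)
            chain = fit_single_regime(
                pruned,
                tip_data,
                config.mcmc_config("single_regime"),
                rng=rng,
                min_tips=config.min_order_taxa,
                allow_small=True,  # the pipeline-level threshold already ran
                tree_id=f"{config.order_name}_tree_{i}",
            )
            chains.append(chain)
        pooled = pool_chains(chains, units="per_Myr")
        rows = []
        for name in chains[0].param_names:
            vals = pooled[name].to_numpy(float)
            low, high = hpd_interval(vals, config.hpd_prob)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(vals.mean()),
                    "median": float(np.median(vals)),
                    "hpd_low": low,
                    "hpd_high": high,
                }
            )
        table = pd.DataFrame(rows)
        write_chains(chains, outdir / "chains.tsv")
        table.to_csv(outdir / "order_rates.tsv", sep="\t", index=False)
        with open(outdir / "order_summary.json", "w") as fh:
            json.dump(
                {
                    "order": config.order_name,
                    "n_matched_taxa": n_matched,
                    "centromere": sub_dataset.centromere_of(subset[0]).value,
                    "rates_per_Myr": {r["parameter"]: r for r in rows},
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        manifest = ["chains.tsv", "order_rates.tsv", "order_summary.json", "report.json"]
        _write_report_json(outdir, config, manifest)
        report = RunReport(
            output_dir=str(outdir),
            manifest=manifest,
            config_echo=config.to_dict(),
            chains=chains,
            pooled=pooled,
            extra={"order_rates": table},
        )
        report.validate_manifest()
        return report
    finally:
        _teardown_run_log(handler)


def run_bootstrap(config: RunConfig, n_boot: Optional[int] = None) -> RunReport:
    """Bootstrap over phylogeny and tip-record uncertainty.

    Each replicate draws one tree and one record per taxon, runs a reduced
    fit, and records each mechanism's DeltaR credible interval.  Reports
    the fraction of intervals spanning zero and the envelope of interval
    endpoints across replicates.
    """
    n_boot = config.n_boot if n_boot is None else n_boot
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(outdir)
    try:
        trees, dataset = _load_inputs(config)
        space = _state_space(config, dataset)
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        replicates = bootstrap_datasets(dataset, trees, n_boot, rng)
        mechanisms = config.active_mechanisms()
        rows = []
        from .inference import run_mcmc

        for b, (boot_data, tree) in enumerate(replicates):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(1000, b))
            chain = run_mcmc(
                tree,
                boot_data.sample_tips(rng),  # single-record: deterministic
                space,
                config.mcmc_config(),
                rng=np.random.default_rng(ss),
                tree_id=f"boot_{b}",
            )
            pooled = pool_chains([chain], units="per_Myr")
            for mech in mechanisms:
                d = delta_r(pooled, mech)
                low, high = hpd_interval(d, config.hpd_prob)
                rows.append(
                    {
                        "replicate": b,
                        "mechanism": mech,
                        "hpd_low": low,
                        "hpd_high": high,
                        "spans_zero": bool(low <= 0 <= high),
                    }
                )
        table = pd.DataFrame(rows)
        summary = {}
        for mech in mechanisms:
            sub = table[table.mechanism == mech]
            summary[mech] = {
                "n_replicates": int(len(sub)),
                "fraction_spanning_zero": float(sub.spans_zero.mean()),
                "envelope_low": float(sub.hpd_low.min()),
                "envelope_high": float(sub.hpd_high.max()),
            }
        table.to_csv(outdir / "bootstrap.tsv", sep="\t", index=False)
        with open(outdir / "bootstrap.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest = ["bootstrap.tsv", "bootstrap.json", "report.json"]
        _write_report_json(outdir, config, manifest)
        report = RunReport(
            output_dir=str(outdir),
            manifest=manifest,
            config_echo=config.to_dict(),
            extra={"bootstrap": summary, "table": table},
        )
        report.validate_manifest()
        return report
    finally:
        _teardown_run_log(handler)


def compare_tree_sets(report_a: RunReport, report_b: RunReport) -> Dict[str, object]:
    """Compare DeltaR posteriors from two runs (e.g. alternative backbone
    tree sets over the same dataset).

    Reports, per mechanism, the difference in posterior means and the
    overlap of the 95% HPD intervals (intersection over union; 1.0 for
    identical intervals, 0.0 for disjoint)."""
    sa, sb = report_a.summary, report_b.summary
    if sa is None or sb is None:
        raise ValueError("both runs must carry a DeltaR summary")
    if set(sa.mechanisms) != set(sb.mechanisms):
        raise ValueError(
            f"mechanism sets differ: {sorted(sa.mechanisms)} vs {sorted(sb.mechanisms)}"
        )
    out = {}
    for mech in sa.mechanisms:
        ma, mb = sa.mechanisms[mech], sb.mechanisms[mech]
        lo = max(ma.hpd_low, mb.hpd_low)
        hi = min(ma.hpd_high, mb.hpd_high)
        inter = max(0.0, hi - lo)
        union = max(ma.hpd_high, mb.hpd_high) - min(ma.hpd_low, mb.hpd_low)
        overlap = 1.0 if union == 0 else inter / union
        out[mech] = {
            "mean_difference": ma.mean - mb.mean,
            "hpd_overlap": overlap,
            "classification_a": ma.classification.value,
            "classification_b": mb.classification.value,
        }
    return out


# --------------------------------------------------------------- tree utils


def tree_is_monophyletic(tree: Phylogeny, labels: Sequence[str]) -> bool:
    """True when the given tips form a clade in the tree."""
    want = set(labels)
    if not want.issubset(set(tree.tip_labels)):
        return False
    in_set = np.zeros(tree.n_nodes, dtype=np.int64)
    total = np.zeros(tree.n_nodes, dtype=np.int64)
    for node in tree.postorder:
        node = int(node)
        if not tree.children[node]:
            total[node] = 1
            in_set[node] = 1 if tree.tip_labels[node] in want else 0
        else:
            for ch in tree.children[node]:
                total[node] += total[ch]
                in_set[node] += in_set[ch]
    k = len(want)
    for node in tree.postorder:
        node = int(node)
        if in_set[node] == k:
            return total[node] == k
    return False


def extract_subtree(tree: Phylogeny, labels: Sequence[str]) -> Phylogeny:
    """Subtree spanned by the given tips (pruning other lineages)."""
    import dendropy

    dtree = dendropy.Tree.get(
        data=tree.to_newick(),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    dtree.retain_taxa_with_labels(list(set(labels)))
    return Phylogeny.from_dendropy(dtree, label=f"{tree.label}_pruned")
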