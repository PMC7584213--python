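"""Posterior summaries: the DeltaR rate-difference statistic, 95% HPD
intervals, and the sign-based decision rule.

For each post-burnin sample the statistic for mechanism x is

    DeltaR_x = rate_x(holocentric) - rate_x(monocentric)

computed on per-Myr (back-transformed) rates so samples pooled across trees
of different heights are comparable.  If the whole 95% highest-posterior-
density interval of DeltaR_x is positive the data support faster
chromosome-number evolution in holocentric clades; entirely negative
supports monocentric clades; otherwise there is no supported difference.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .inference import MCMCChain, pool_chains

#: mechanism name -> rate-parameter stem
MECHANISMS: Dict[str, str] = {
    "fission": "gamma",
    "fusion": "delta",
    "polyploidy": "rho",
}


class Classification(str, enum.Enum):
    HOLOCENTRIC_FASTER = "holocentric_faster"
    MONOCENTRIC_FASTER = "monocentric_faster"
    NO_DIFFERENCE = "no_difference"


def delta_r(pooled: pd.DataFrame, mechanism: str) -> np.ndarray:
    """Per-sample holocentric-minus-monocentric rate difference."""
    stem = MECHANISMS.get(mechanism)
    if stem is None:
        raise KeyError(f"unknown mechanism {mechanism!r}; expected one of "
                       f"{sorted(MECHANISMS)}")
    holo, mono = f"{stem}_H", f"{stem}_M"
    for col in (holo, mono):
        if col not in pooled.columns:
            raise KeyError(
                f"column {col!r} missing from pooled samples; DeltaR is "
                "undefined for single-regime chains"
            )
    return pooled[holo].to_numpy(float) - pooled[mono].to_numpy(float)


def hpd_interval(samples: Sequence[float], prob: float = 0.95) -> Tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding ceil(prob*n)
    samples (leftmost window on ties); endpoints are actual sample values."""
    a = np.sort(np.asarray(samples, dtype=float))
    n = a.size
    if n < 20:
        raise ValueError(f"need at least 20 samples for an HPD interval, got {n}")
    if not (0.0 < prob < 1.0):
        raise ValueError(f"prob must be in (0, 1), got {prob}")
    m = int(math.ceil(prob * n))
    widths = a[m - 1 :] - a[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first (leftmost) minimum
    return float(a[i]), float(a[i + m - 1])


def classify_signal(interval: Tuple[float, float]) -> Classification:
    """Sign rule on the credible interval of DeltaR."""
    low, high = interval
    if low > high:
        raise ValueError(f"invalid interval ({low}, {high})")
    if low > 0:
        return Classification.HOLOCENTRIC_FASTER
    if high < 0:
        return Classification.MONOCENTRIC_FASTER
    return Classification.NO_DIFFERENCE


def fraction_positive(samples: Sequence[float]) -> float:
    """Proportion of samples strictly greater than zero."""
    a = np.asarray(samples, dtype=float)
    if a.size == 0:
        raise ValueError("fraction_positive of an empty sample")
    return float(np.mean(a > 0))


@dataclass(frozen=True)
class MechanismSummary:
    mechanism: str
    mean: float
    median: float
    hpd_low: float
    hpd_high: float
    fraction_positive: float
    fraction_zero: float
    classification: Classification
    n_samples: int

    def to_dict(self) -> Dict[str, object]:
        return {
            "mechanism": self.mechanism,
            "mean": self.mean,
            "median": self.median,
            "hpd_low": self.hpd_low,
            "hpd_high": self.hpd_high,
            "fraction_positive": self.fraction_positive,
            "fraction_zero": self.fraction_zero,
            "classification": self.classification.value,
            "n_samples": self.n_samples,
        }


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-mechanism DeltaR summaries over the pooled posterior."""

    mechanisms: Dict[str, MechanismSummary]
    prob: float

    def classification(self, mechanism: str) -> Classification:
        return self.mechanisms[mechanism].classification

    def to_dict(self) -> Dict[str, object]:
        return {
            "hpd_prob": self.prob,
            "mechanisms": {k: v.to_dict() for k, v in self.mechanisms.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def summarize_samples(
    delta_samples: Mapping[str, np.ndarray], prob: float = 0.95
) -> PosteriorSummary:
    out = {}
    for mech, samples in delta_samples.items():
        samples = np.asarray(samples, dtype=float)
        low, high = hpd_interval(samples, prob)
        out[mech] = MechanismSummary(
            mechanism=mech,
            mean=float(samples.mean()),
            median=float(np.median(samples)),
            hpd_low=low,
            hpd_high=high,
            fraction_positive=fraction_positive(samples),
            fraction_zero=float(np.mean(samples == 0.0)),
            classification=classify_signal((low, high)),
            n_samples=int(samples.size),
        )
    return PosteriorSummary(mechanisms=out, prob=prob)


def summarize(
    chains: Sequence[MCMCChain],
    mechanisms: Iterable[str] = ("fission", "fusion", "polyploidy"),
    prob: float = 0.95,
    pooled: Optional[pd.DataFrame] = None,
) -> PosteriorSummary:
    """Pool post-burnin per-Myr samples across chains and summarize DeltaR
    for each requested mechanism."""
    if pooled is None:
        pooled = pool_chains(chains, units="per_Myr")
    deltas = {mech: delta_r(pooled, mech) for mech in mechanisms}
    return summarize_samples(deltas, prob=prob)


def per_tree_table(
    chains: Sequence[MCMCChain],
    mechanisms: Iterable[str] = ("fission", "fusion"),
    prob: float = 0.95,
) -> pd.DataFrame:
    """Audit table: per-tree DeltaR mean and HPD for each mechanism."""
    rows = []
    for chain in chains:
        pooled = pool_chains([chain], units="per_Myr")
        for mech in mechanisms:
            d = delta_r(pooled, mech)
            low, high = hpd_interval(d, prob) if d.size >= 20 else (np.nan, np.nan)
            rows.append(
                {
                    "tree_id": chain.tree_id,
                    "mechanism": mech,
                    "mean": d.mean(),
                    "hpd_low": low,
                    "hpd_high": high,
                }
            )
    return pd.DataFrame(rows)
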