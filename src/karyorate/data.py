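"""Chromosome record tables.

A dataset maps each taxon (typically a genus) to one or more records of
haploid chromosome number; the centromere regime is assigned at clade level
and must therefore be consistent across a taxon's records.  Taxa with
several records are resolved during fitting by sampling one record per
tree, which propagates record uncertainty into the posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence

import numpy as np
import pandas as pd

from .likelihood import TipObservation
from .statespace import CentromereType


class DataFormatError(ValueError):
    pass


@dataclass
class ChromosomeDataset:
    """taxon -> list of chromosome records (at least one each)."""

    records: Dict[str, List[TipObservation]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, obs_list in self.records.items():
            if not obs_list:
                raise DataFormatError(f"taxon {taxon} has no records")
            ctypes = {o.centromere for o in obs_list}
            if len(ctypes) != 1:
                raise DataFormatError(
                    f"taxon {taxon} has conflicting centromere types "
                    f"{sorted(c.value for c in ctypes)}; the regime is assigned "
                    "at clade level and must be consistent"
                )

    @classmethod
    def from_observations(cls, observations: Iterable[TipObservation]) -> "ChromosomeDataset":
        records: Dict[str, List[TipObservation]] = {}
        for obs in observations:
            records.setdefault(obs.taxon, []).append(obs)
        return cls(records)

    @property
    def taxa(self) -> List[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def haploid_numbers(self) -> Iterator[int]:
        for obs_list in self.records.values():
            for obs in obs_list:
                yield obs.haploid_n

    def centromere_of(self, taxon: str) -> CentromereType:
        return self.records[taxon][0].centromere

    def sample_tips(self, rng: np.random.Generator) -> Dict[str, TipObservation]:
        """One record per taxon, drawn uniformly at random (taxa with a
        single record always contribute that record)."""
        out = {}
        for taxon, obs_list in self.records.items():
            if len(obs_list) == 1:
                out[taxon] = obs_list[0]
            else:
                out[taxon] = obs_list[int(rng.integers(len(obs_list)))]
        return out

    def subset(self, taxa: Sequence[str]) -> "ChromosomeDataset":
        missing = [t for t in taxa if t not in self.records]
        if missing:
            raise KeyError(f"taxa not in dataset: {', '.join(sorted(missing)[:20])}")
        return ChromosomeDataset({t: list(self.records[t]) for t in taxa})

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"taxon": o.taxon, "haploid_n": o.haploid_n, "centromere": o.centromere.value}
            for obs_list in self.records.values()
            for o in obs_list
        ]
        return pd.DataFrame(rows, columns=["taxon", "haploid_n", "centromere"])

    def to_table(self, path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)


def read_chromosome_table(path) -> ChromosomeDataset:
    """Read a delimited record table with header columns
    ``taxon, haploid_n, centromere`` (extra columns ignored).

    The delimiter is sniffed (tab or comma); centromere labels are parsed
    case-insensitively with M/H aliases.  Unparseable rows raise with their
    line number.
    """
    with open(path) as fh:
        header_line = fh.readline()
    sep = "\t" if "\t" in header_line else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ("taxon", "haploid_n", "centromere")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    observations = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # 1-based, after the header
        taxon = " ".join(str(getattr(row, "taxon")).split())
        raw_n = getattr(row, "haploid_n")
        try:
            n = int(str(raw_n).strip())
            if n < 1:
                raise ValueError
        except (TypeError, ValueError):
            raise DataFormatError(
                f"{path}:{line_no}: haploid_n must be a positive integer, "
                f"got {raw_n!r}"
            ) from None
        try:
            ctype = CentromereType.parse(getattr(row, "centromere"))
        except ValueError as exc:
            raise DataFormatError(f"{path}:{line_no}: {exc}") from None
        if not taxon or taxon.lower() == "nan":
            raise DataFormatError(f"{path}:{line_no}: empty taxon label")
        observations.append(TipObservation(taxon, n, ctype))
    if not observations:
        raise DataFormatError(f"{path}: no records found")
    return ChromosomeDataset.from_observations(observations)
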