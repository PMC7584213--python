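"""Joint state space of haploid chromosome number and centromere type.

The model is a continuous-time Markov chain on states ``(i, c)`` where ``i``
is the haploid chromosome number and ``c`` the centromere regime
(monocentric or holocentric).  A lineage can make four kinds of transition:

* fission, ``i -> i + 1``, at rate ``gamma_c``;
* fusion, ``i -> i - 1``, at rate ``delta_c``;
* whole-genome duplication (polyploidy), ``i -> 2i``, at rate ``rho_c``;
* a centromere-regime switch at equal ``i``, at rate ``q_MH`` or ``q_HM``.

Fission, fusion and polyploidy rates are regime-specific, so the full model
has eight rates.  The constrained ("no polyploidy") variant pins both rho
rates to zero.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import scipy.linalg


class CentromereType(str, enum.Enum):
    """Binary centromere regime of a lineage."""

    MONOCENTRIC = "monocentric"
    HOLOCENTRIC = "holocentric"

    @classmethod
    def parse(cls, text: str) -> "CentromereType":
        """Parse a centromere label; accepts full names and M/H aliases,
        case-insensitively."""
        key = str(text).strip().lower()
        if key in ("monocentric", "m", "mono"):
            return cls.MONOCENTRIC
        if key in ("holocentric", "h", "holo"):
            return cls.HOLOCENTRIC
        raise ValueError(f"unrecognized centromere type: {text!r}")

    @property
    def short(self) -> str:
        return "M" if self is CentromereType.MONOCENTRIC else "H"


MONOCENTRIC = CentromereType.MONOCENTRIC
HOLOCENTRIC = CentromereType.HOLOCENTRIC

#: canonical ordering of the eight model rates
PARAM_NAMES: Tuple[str, ...] = (
    "gamma_M",
    "gamma_H",
    "delta_M",
    "delta_H",
    "rho_M",
    "rho_H",
    "q_MH",
    "q_HM",
)


class InvalidBoundsError(ValueError):
    """Raised when chromosome-number bounds are not 1 <= n_min <= n_max."""


@dataclass(frozen=True)
class RateParameters:
    """The model's instantaneous rates.

    Rates are non-negative; units are either events per unit tree height
    (the scale on which fitting happens) or events per million years
    (the scale on which results are reported).
    """

    gamma_M: float = 0.0
    gamma_H: float = 0.0
    delta_M: float = 0.0
    delta_H: float = 0.0
    rho_M: float = 0.0
    rho_H: float = 0.0
    q_MH: float = 0.0
    q_HM: float = 0.0
    units: str = "per_unit_tree"  # or "per_Myr"

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {value}")
        if self.units not in ("per_unit_tree", "per_Myr"):
            raise ValueError(f"unknown units flag: {self.units!r}")

    def as_array(self, names: Sequence[str] = PARAM_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    @classmethod
    def from_array(
        cls,
        values: Sequence[float],
        names: Sequence[str] = PARAM_NAMES,
        units: str = "per_unit_tree",
    ) -> "RateParameters":
        kwargs = dict(zip(names, (float(v) for v in values)))
        return cls(units=units, **kwargs)

    def scaled(self, factor: float, units: str) -> "RateParameters":
        """Return a copy with every rate multiplied by ``factor``."""
        kwargs = {n: getattr(self, n) * factor for n in PARAM_NAMES}
        return RateParameters(units=units, **kwargs)

    def rate(self, mechanism: str, ctype: CentromereType) -> float:
        return getattr(self, f"{mechanism}_{ctype.short}")

    @property
    def is_constrained(self) -> bool:
        """True when polyploidy is switched off exactly."""
        return self.rho_M == 0.0 and self.rho_H == 0.0


@dataclass(frozen=True)
class StateSpace:
    """Ordered enumeration of (haploid number, centromere type) states.

    The ordering is fixed: the monocentric block by ascending ``n``, then the
    holocentric block by ascending ``n``, so indices are reproducible across
    runs.  A single-regime space (one centromere type) is supported for
    order-level fits where the whole clade shares one regime.
    """

    n_min: int
    n_max: int
    types: Tuple[CentromereType, ...] = (MONOCENTRIC, HOLOCENTRIC)
    states: Tuple[Tuple[int, CentromereType], ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_min < 1 or self.n_max < self.n_min:
            raise InvalidBoundsError(
                f"need 1 <= n_min <= n_max, got ({self.n_min}, {self.n_max})"
            )
        states = tuple(
            (n, c) for c in self.types for n in range(self.n_min, self.n_max + 1)
        )
        object.__setattr__(self, "states", states)

    @property
    def size(self) -> int:
        return len(self.states)

    def __len__(self) -> int:
        return self.size

    def index_of(self, n: int, ctype: CentromereType) -> int:
        if ctype not in self.types:
            raise KeyError(f"centromere type {ctype.value} not in this space")
        if not (self.n_min <= n <= self.n_max):
            raise KeyError(f"chromosome number {n} outside [{self.n_min}, {self.n_max}]")
        block = self.types.index(ctype)
        return block * (self.n_max - self.n_min + 1) + (n - self.n_min)

    def state_of(self, index: int) -> Tuple[int, CentromereType]:
        return self.states[index]

    def contains(self, n: int, ctype: CentromereType) -> bool:
        return ctype in self.types and self.n_min <= n <= self.n_max


def build_state_space(
    n_min: int,
    n_max: int,
    types: Tuple[CentromereType, ...] = (MONOCENTRIC, HOLOCENTRIC),
) -> StateSpace:
    """Enumerate the joint states for haploid numbers in [n_min, n_max]."""
    return StateSpace(int(n_min), int(n_max), tuple(types))


def infer_default_bounds(dataset, padding_fraction: float = 0.2) -> Tuple[int, int]:
    """Default chromosome-number bounds from observed data.

    ``n_min`` is one below the observed minimum (floored at 1) and ``n_max``
    is the observed maximum plus ``max(5, ceil(padding_fraction * max))`` so
    that fission and polyploidy have headroom above the data.
    """
    if hasattr(dataset, "haploid_numbers"):
        values = list(dataset.haploid_numbers())
    else:
        values = [int(v) for v in dataset]
    if not values:
        raise ValueError("cannot infer bounds from an empty dataset")
    obs_min, obs_max = min(values), max(values)
    if obs_min < 1:
        raise ValueError(f"haploid numbers must be >= 1, got {obs_min}")
    n_min = max(1, obs_min - 1)
    n_max = obs_max + max(5, math.ceil(padding_fraction * obs_max))
    return n_min, n_max


@dataclass(frozen=True)
class RateMatrix:
    """Generator (instantaneous rate) matrix over a :class:`StateSpace`."""

    entries: np.ndarray
    statespace: StateSpace

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.shape != (self.statespace.size, self.statespace.size):
            raise ValueError("rate matrix shape does not match the state space")
        object.__setattr__(self, "entries", entries)


class RateMatrixBuilder:
    """Precomputed sparsity template for fast repeated generator assembly.

    For a fixed state space the positions of all permitted transitions, and
    which of the eight rates each carries, never change; only the rate values
    do.  MCMC rebuilds the generator at every likelihood evaluation, so the
    (row, column, parameter) triples are computed once and reused.
    """

    def __init__(self, space: StateSpace, param_names: Sequence[str] = PARAM_NAMES):
        self.space = space
        self.param_names = tuple(param_names)
        lookup = {n: k for k, n in enumerate(self.param_names)}
        rows, cols, pidx = [], [], []

        def add(i: int, j: int, pname: str) -> None:
            if pname in lookup:
                rows.append(i)
                cols.append(j)
                pidx.append(lookup[pname])

        single = len(space.types) == 1
        for i, (n, c) in enumerate(space.states):
            suffix = c.short

            # single-regime spaces may use plain names (gamma, delta, rho)
            def pick(base: str) -> str:
                if f"{base}_{suffix}" in lookup:
                    return f"{base}_{suffix}"
                return base

            if space.contains(n + 1, c):
                add(i, space.index_of(n + 1, c), pick("gamma"))
            if space.contains(n - 1, c):
                add(i, space.index_of(n - 1, c), pick("delta"))
            if space.contains(2 * n, c) and 2 * n != n:
                add(i, space.index_of(2 * n, c), pick("rho"))
            if not single:
                other = HOLOCENTRIC if c is MONOCENTRIC else MONOCENTRIC
                qname = "q_MH" if c is MONOCENTRIC else "q_HM"
                if space.contains(n, other):
                    add(i, space.index_of(n, other), qname)

        self._rows = np.asarray(rows, dtype=np.intp)
        self._cols = np.asarray(cols, dtype=np.intp)
        self._pidx = np.asarray(pidx, dtype=np.intp)

    def fill(self, values: Sequence[float]) -> np.ndarray:
        """Dense generator for the given rate vector (order = param_names)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.param_names),):
            raise ValueError("rate vector length does not match the template")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("rates must be finite and >= 0")
        size = self.space.size
        Q = np.zeros((size, size))
        # i -> 2i can coincide with i -> i+1 when i == 1: rates add
        np.add.at(Q, (self._rows, self._cols), values[self._pidx])
        Q[np.diag_indices(size)] = -Q.sum(axis=1)
        return Q


def build_rate_matrix(params: RateParameters, space: StateSpace) -> RateMatrix:
    """Assemble the generator matrix for the eight-rate model.

    Off-diagonal entries connect only states one permitted event apart;
    polyploidy transitions whose target ``2i`` exceeds ``n_max`` are simply
    absent (no truncation to the top state).  Each diagonal entry is minus
    its row's off-diagonal sum, so rows sum to zero.
    """
    builder = RateMatrixBuilder(space)
    Q = builder.fill(params.as_array())
    return RateMatrix(entries=Q, statespace=space)


def transition_probability_matrix(Q, t: float) -> np.ndarray:
    """P(t) = expm(Q t): probability of ending in column state after time t.

    Dense scaling-and-squaring matrix exponential; rows are probability
    vectors for any generator Q and t >= 0.
    """
    if t < 0:
        raise ValueError(f"elapsed time must be >= 0, got {t}")
    entries = Q.entries if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    return scipy.linalg.expm(entries * float(t))
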