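"""Domain types shared across the package: thresholds, modules, partitions."""

from __future__ import annotations

from dataclasses import dataclass, field


COHESIVE = "cohesive"
BISPARSE = "bi-sparse"


@dataclass(frozen=True)
class Thresholds:
    """The three BTS thresholds.

    a1 : lower limit of link density for cohesive-module growth,
    a2 : upper limit of link density for bi-sparse-module growth,
    a3 : lower limit of edge density required to record a bridge matrix.

    They must satisfy ``a1 > a3 > a2`` with ``a1 < 1`` and ``a2 > 0``:
    a1 and a3 bound dense blocks from below, a2 bounds sparse blocks from
    above, and the cohesive > bridge > bi-sparse priority forces a1 > a3.
    """

    a1: float
    a2: float
    a3: float

    def __post_init__(self) -> None:
        if not (self.a1 > self.a3 > self.a2):
            raise ValueError(
                f"thresholds must satisfy a1 > a3 > a2, got "
                f"a1={self.a1}, a3={self.a3}, a2={self.a2}"
            )
        if not (self.a1 < 1):
            raise ValueError(f"a1 must be < 1, got a1={self.a1}")
        if not (self.a2 > 0):
            raise ValueError(f"a2 must be > 0, got a2={self.a2}")


@dataclass
class Module:
    """A detected module: a node set tagged cohesive or bi-sparse."""

    id: int
    members: frozenset[str]
    mtype: str  # COHESIVE or BISPARSE
    edm: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("module members must be nonempty")
        if self.mtype not in (COHESIVE, BISPARSE):
            raise ValueError(f"unknown module type {self.mtype!r}")


@dataclass(frozen=True)
class BridgeMatrix:
    """A recorded dense bridge between two modules (EDBM above a3)."""

    module_a: int
    module_b: int
    edbm: float


@dataclass
class Partition:
    """A complete assignment of network nodes to modules plus bridges.

    ``error`` is the block-model error E of the partition under its fitted
    image graph; ``modularity`` is Newman's Q (NaN for an edgeless network,
    where Q is undefined).
    """

    modules: list[Module]
    bridges: list[BridgeMatrix] = field(default_factory=list)
    error: float = float("nan")
    modularity: float = float("nan")

    def assignment(self) -> dict[str, int]:
        """Node label -> module id map."""
        out: dict[str, int] = {}
        for mod in self.modules:
            for lab in mod.members:
                if lab in out:
                    raise ValueError(f"node {lab!r} assigned to two modules")
                out[lab] = mod.id
        return out

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module_by_id(self, module_id: int) -> Module:
        for mod in self.modules:
            if mod.id == module_id:
                return mod
        raise KeyError(f"no module with id {module_id}")
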