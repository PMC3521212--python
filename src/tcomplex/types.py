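"""Core domain types shared across the pipeline.

The cell cycle provides the discrete "time of reference" for the whole
analysis: the four ordered phases G1 -> S -> G2 -> M (wrapping back to G1).
Every protein is either *dynamic* (peaks in exactly one phase, or on the
boundary between two adjacent phases), *static* (constitutively expressed,
no single peak phase) or *uncertain* (the data do not resolve a unique
peak).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Tuple

import networkx as nx
import pandas as pd

__all__ = [
    "Phase",
    "PHASE_ORDER",
    "BOUNDARY_PAIRS",
    "adjacent_pair",
    "LabelKind",
    "PhaseLabel",
    "STATIC_LABEL",
    "UNCERTAIN_LABEL",
    "PhaseLabelTable",
    "WeightedNetwork",
    "ComplexSet",
    "ExpressionDataset",
]


class Phase(str, enum.Enum):
    """One of the four cell-cycle phases, in progression order."""

    G1 = "G1"
    S = "S"
    G2 = "G2"
    M = "M"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


PHASE_ORDER: Tuple[Phase, ...] = (Phase.G1, Phase.S, Phase.G2, Phase.M)

#: Ordered adjacent pairs in cell-cycle progression order, including the
#: M -> G1 wrap-around.
BOUNDARY_PAIRS: Tuple[Tuple[Phase, Phase], ...] = (
    (Phase.G1, Phase.S),
    (Phase.S, Phase.G2),
    (Phase.G2, Phase.M),
    (Phase.M, Phase.G1),
)


def adjacent_pair(a: Phase, b: Phase) -> Optional[Tuple[Phase, Phase]]:
    """Return the progression-ordered boundary pair for two adjacent phases.

    Returns ``None`` when the phases are not adjacent in the cycle (e.g.
    G1 and G2).  The wrap-around M/G1 is adjacent and ordered (M, G1).
    """
    if (a, b) in BOUNDARY_PAIRS:
        return (a, b)
    if (b, a) in BOUNDARY_PAIRS:
        return (b, a)
    return None


class LabelKind(str, enum.Enum):
    DYNAMIC = "DYNAMIC"
    STATIC = "STATIC"
    UNCERTAIN = "UNCERTAIN"


@dataclass(frozen=True)
class PhaseLabel:
    """A protein's discretized temporal status.

    ``phase`` is set for a pure dynamic label; ``boundary`` for a dynamic
    label on a phase border (ordered in progression order, e.g. (G1, S)).
    Exactly one of the two is set iff ``kind`` is DYNAMIC; neither is set
    for STATIC or UNCERTAIN.
    """

    kind: LabelKind
    phase: Optional[Phase] = None
    boundary: Optional[Tuple[Phase, Phase]] = None

    def __post_init__(self) -> None:
        if self.kind is LabelKind.DYNAMIC:
            if (self.phase is None) == (self.boundary is None):
                raise ValueError(
                    "a DYNAMIC label needs exactly one of phase or boundary"
                )
            if self.boundary is not None and self.boundary not in BOUNDARY_PAIRS:
                raise ValueError(
                    f"boundary {self.boundary} is not an adjacent phase pair "
                    "in cycle order"
                )
        elif self.phase is not None or self.boundary is not None:
            raise ValueError(f"{self.kind.value} labels carry no phase")

    @property
    def is_dynamic(self) -> bool:
        return self.kind is LabelKind.DYNAMIC

    @property
    def covered_phases(self) -> frozenset[Phase]:
        """Phases this label covers: one for a pure dynamic label, the two
        flanking phases for a boundary label, none otherwise."""
        if self.phase is not None:
            return frozenset({self.phase})
        if self.boundary is not None:
            return frozenset(self.boundary)
        return frozenset()

    def __str__(self) -> str:
        if self.kind is LabelKind.STATIC:
            return "Static"
        if self.kind is LabelKind.UNCERTAIN:
            return "Uncertain"
        if self.phase is not None:
            return self.phase.value
        assert self.boundary is not None
        return f"{self.boundary[0].value}/{self.boundary[1].value}"

    @classmethod
    def parse(cls, text: str) -> "PhaseLabel":
        """Parse a label string (case-insensitive): one of G1, S, G2, M,
        the boundary forms G1/S, S/G2, G2/M, M/G1, or Static / Uncertain."""
        t = text.strip().upper()
        if t == "STATIC":
            return STATIC_LABEL
        if t == "UNCERTAIN":
            return UNCERTAIN_LABEL
        if "/" in t:
            parts = t.split("/")
            if len(parts) == 2:
                try:
                    a, b = Phase(parts[0]), Phase(parts[1])
                except ValueError:
                    raise ValueError(f"unknown phase label: {text!r}") from None
                pair = adjacent_pair(a, b)
                if pair is None:
                    raise ValueError(
                        f"{text!r} is not a boundary between adjacent phases"
                    )
                return cls(LabelKind.DYNAMIC, boundary=pair)
            raise ValueError(f"unknown phase label: {text!r}")
        try:
            return cls(LabelKind.DYNAMIC, phase=Phase(t))
        except ValueError:
            raise ValueError(f"unknown phase label: {text!r}") from None


STATIC_LABEL = PhaseLabel(LabelKind.STATIC)
UNCERTAIN_LABEL = PhaseLabel(LabelKind.UNCERTAIN)


@dataclass
class PhaseLabelTable:
    """Map from protein ID to :class:`PhaseLabel` with per-kind totals."""

    labels: dict[str, PhaseLabel] = field(default_factory=dict)

    @property
    def counts(self) -> dict[LabelKind, int]:
        c = Counter(lab.kind for lab in self.labels.values())
        return {kind: c.get(kind, 0) for kind in LabelKind}

    def get(self, protein: str) -> Optional[PhaseLabel]:
        return self.labels.get(protein)

    def __getitem__(self, protein: str) -> PhaseLabel:
        return self.labels[protein]

    def __contains__(self, protein: str) -> bool:
        return protein in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)


class WeightedNetwork:
    """Undirected protein interaction graph with confidence scores in [0, 1].

    A thin wrapper around :class:`networkx.Graph` enforcing the network
    invariants: no self-loops, each unordered pair at most once (guaranteed
    by the graph model), scores within [0, 1].
    """

    def __init__(self, graph: Optional[nx.Graph] = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u!r} not allowed")
            s = data.get("score", 1.0)
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} for edge {u!r}-{v!r} outside [0, 1]")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "WeightedNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, score in edges:
            g.add_edge(u, v, score=float(score))
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> Iterator[Tuple[str, str, float]]:
        for u, v, data in self.graph.edges(data=True):
            yield u, v, data.get("score", 1.0)

    def score(self, u: str, v: str) -> float:
        return self.graph.edges[u, v].get("score", 1.0)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def neighbors(self, node: str) -> Iterator[str]:
        return self.graph.neighbors(node)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        mine = {frozenset((u, v)): s for u, v, s in self.edges()}
        theirs = {frozenset((u, v)): s for u, v, s in other.edges()}
        return mine == theirs


@dataclass
class ComplexSet:
    """Ordered collection of named, non-empty protein sets.

    Carries either predicted clusters or a reference catalogue; duplicate
    member sets are permitted, names must be unique.
    """

    complexes: list[Tuple[str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.complexes]
        if len(names) != len(set(names)):
            dupes = [n for n, k in Counter(names).items() if k > 1]
            raise ValueError(f"duplicate complex names: {dupes}")
        for name, members in self.complexes:
            if not members:
                raise ValueError(f"complex {name!r} has no members")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.complexes]

    def members(self, name: str) -> frozenset[str]:
        for n, m in self.complexes:
            if n == name:
                return m
        raise KeyError(name)

    @property
    def all_proteins(self) -> set[str]:
        out: set[str] = set()
        for _, m in self.complexes:
            out |= m
        return out

    def __iter__(self) -> Iterator[Tuple[str, frozenset[str]]]:
        return iter(self.complexes)

    def __len__(self) -> int:
        return len(self.complexes)


class ExpressionDataset:
    """Proteins x timepoints expression matrix with a timepoint -> phase map.

    ``values`` is a DataFrame indexed by protein ID with one column per
    timepoint; ``timepoint_phase`` assigns every timepoint to a phase, and
    each of the four phases must annotate at least one timepoint.
    """

    def __init__(self, values: pd.DataFrame, timepoint_phase: Mapping[str, Phase]):
        if list(values.columns) != list(timepoint_phase.keys()):
            raise ValueError(
                "timepoint annotation does not match matrix columns"
            )
        missing = set(PHASE_ORDER) - set(timepoint_phase.values())
        if missing:
            raise ValueError(
                f"phases with no annotated timepoint: {sorted(p.value for p in missing)}"
            )
        self.values = values.astype(float)
        self.timepoint_phase = dict(timepoint_phase)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.values.columns)

    @property
    def phases(self) -> list[Phase]:
        """Phase of each timepoint, in column order."""
        return [self.timepoint_phase[t] for t in self.timepoints]

    def same_design(self, other: "ExpressionDataset") -> bool:
        return (
            self.proteins == other.proteins
            and self.timepoints == other.timepoints
            and self.timepoint_phase == other.timepoint_phase
        )
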