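"""Dynamism analysis of a phase-labelled PPI network.

Classifies interactions by the temporal status of their endpoints
(static-static, static-dynamic, dynamic-dynamic) and finds *multiphase
static hubs*: constitutively expressed proteins whose dynamic interaction
partners peak in several different cell-cycle phases — candidates for
temporally "reused", multipurpose proteins.

An edge is *annotated* only when both endpoints carry a STATIC or DYNAMIC
label; UNCERTAIN or unlabelled endpoints leave the edge unannotated, so
the three classes partition the annotated edges exactly.  Boundary labels
(e.g. G1/S) count as dynamic and contribute both flanking phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .types import LabelKind, Phase, PhaseLabelTable, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = ["EdgeClassSummary", "MultiphaseHub", "classify_edges", "find_multiphase_hubs"]


def _pct(count: int, annotated: int) -> float:
    return round(100.0 * count / annotated, 2) if annotated else 0.0


@dataclass(frozen=True)
class EdgeClassSummary:
    """Counts and percentages of S-S / S-D / D-D interactions.

    Percentages are relative to the annotated edges, rounded to 2 decimals
    (exact fractions are available via :meth:`fraction`).
    """

    total_edges: int
    annotated_edges: int
    ss: int
    sd: int
    dd: int

    def __post_init__(self) -> None:
        if self.ss + self.sd + self.dd != self.annotated_edges:
            raise ValueError("S-S + S-D + D-D must equal annotated edges")

    def fraction(self, cls: str) -> float:
        """Exact fraction of annotated edges in class 'ss', 'sd' or 'dd'."""
        if self.annotated_edges == 0:
            return 0.0
        return {"ss": self.ss, "sd": self.sd, "dd": self.dd}[cls] / self.annotated_edges

    @property
    def ss_pct(self) -> float:
        return _pct(self.ss, self.annotated_edges)

    @property
    def sd_pct(self) -> float:
        return _pct(self.sd, self.annotated_edges)

    @property
    def dd_pct(self) -> float:
        return _pct(self.dd, self.annotated_edges)


@dataclass(frozen=True)
class MultiphaseHub:
    """A static protein whose dynamic partners peak in >= 2 distinct phases."""

    protein: str
    degree: int
    dynamic_partner_phases: frozenset[Phase]

    @property
    def n_phases(self) -> int:
        return len(self.dynamic_partner_phases)


def classify_edges(network: WeightedNetwork, labels: PhaseLabelTable) -> EdgeClassSummary:
    """Partition annotated edges into S-S, S-D and D-D classes."""
    ss = sd = dd = annotated = 0
    for u, v, _ in network.edges():
        ku = labels.get(u)
        kv = labels.get(v)
        if ku is None or kv is None:
            continue
        if ku.kind is LabelKind.UNCERTAIN or kv.kind is LabelKind.UNCERTAIN:
            continue
        annotated += 1
        n_dynamic = ku.is_dynamic + kv.is_dynamic
        if n_dynamic == 0:
            ss += 1
        elif n_dynamic == 1:
            sd += 1
        else:
            dd += 1
    if annotated == 0:
        logger.warning("no annotated edges; all percentages reported as 0")
    return EdgeClassSummary(
        total_edges=network.n_edges,
        annotated_edges=annotated,
        ss=ss,
        sd=sd,
        dd=dd,
    )


def find_multiphase_hubs(
    network: WeightedNetwork,
    labels: PhaseLabelTable,
    min_phases: int = 2,
    min_degree: int = 4,
) -> list[MultiphaseHub]:
    """Static proteins whose dynamic neighbours cover >= ``min_phases`` phases.

    Boundary-labelled neighbours contribute both flanking phases.  Results
    are sorted by number of phases covered, then degree (both descending),
    ties broken by protein ID ascending.
    """
    if min_phases < 2:
        raise ValueError("min_phases must be >= 2")
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    hubs: list[MultiphaseHub] = []
    for protein in network.nodes:
        label = labels.get(protein)
        if label is None or label.kind is not LabelKind.STATIC:
            continue
        degree = network.degree(protein)
        if degree < min_degree:
            continue
        phases: set[Phase] = set()
        for nb in network.neighbors(protein):
            nb_label = labels.get(nb)
            if nb_label is not None and nb_label.is_dynamic:
                phases |= nb_label.covered_phases
        if len(phases) >= min_phases:
            hubs.append(MultiphaseHub(protein, degree, frozenset(phases)))
    hubs.sort(key=lambda h: (-h.n_phases, -h.degree, h.protein))
    return hubs
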