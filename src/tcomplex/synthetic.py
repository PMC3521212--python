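"""Synthetic inputs with known ground truth for every pipeline stage.

Two generators:

* :func:`generate_expression` emulates what averaging several microarray
  cell-cycle studies provides: dynamic proteins follow a single-peaked
  cosine over the cycle with the peak centred in their assigned phase,
  static proteins are flat at a baseline, and every measurement carries
  additive Gaussian noise.  Several datasets share the truth but draw
  independent noise.

* :func:`generate_scenario` plants the network structure the complex
  analysis assumes: each static *anchor* protein is shared by several
  phase-specific complexes whose other members are fresh dynamic proteins.
  Within-complex edges are dense and high-scoring (uniform [0.5, 1]);
  background edges are sparse and low-scoring (uniform [0, 0.5]), so a
  0.20 reliability cut-off exercises both retention and rejection.  The
  per-anchor unions act as the *fused clusters* a purely topological
  clustering would report.

All randomness flows from a single integer seed; identical seeds give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    ComplexSet,
    ExpressionDataset,
    LabelKind,
    Phase,
    PHASE_ORDER,
    PhaseLabel,
    PhaseLabelTable,
    STATIC_LABEL,
    WeightedNetwork,
)

__all__ = [
    "ScenarioTruth",
    "generate_expression",
    "expression_for_labels",
    "generate_scenario",
]


@dataclass
class ScenarioTruth:
    """Ground truth of a planted-complex scenario.

    ``complex_phases`` annotates each planted complex with its active
    phase; ``fused_clusters`` are the per-anchor unions a topology-only
    clustering would fuse.
    """

    true_labels: PhaseLabelTable
    planted_complexes: ComplexSet
    complex_phases: dict[str, Phase]
    anchor_proteins: frozenset[str]
    fused_clusters: ComplexSet


def _default_phase_map(timepoints_per_phase: int) -> dict[str, Phase]:
    out: dict[str, Phase] = {}
    t = 0
    for phase in PHASE_ORDER:
        for _ in range(timepoints_per_phase):
            out[f"t{t:02d}"] = phase
            t += 1
    return out


def expression_for_labels(
    labels: PhaseLabelTable,
    timepoints_per_phase: int = 4,
    amplitude: float = 1.0,
    noise_sd: float = 0.1,
    n_datasets: int = 3,
    seed: int = 0,
) -> list[ExpressionDataset]:
    """Expression datasets consistent with a given truth label table.

    Static (and uncertain) proteins get baseline 1.0 plus noise at every
    timepoint; a dynamic protein gets baseline plus
    ``amplitude * cos(2*pi*(t - t_peak)/T)`` with ``t_peak`` at the centre
    of its phase's timepoint block (for a boundary label, at the shared
    border), plus noise.
    """
    if timepoints_per_phase < 2:
        raise ValueError("timepoints_per_phase must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    rng = np.random.default_rng(seed)
    phase_map = _default_phase_map(timepoints_per_phase)
    n_time = 4 * timepoints_per_phase
    t = np.arange(n_time, dtype=float)
    phase_start = {p: i * timepoints_per_phase for i, p in enumerate(PHASE_ORDER)}

    def peak_position(label: PhaseLabel) -> float:
        if label.phase is not None:
            return phase_start[label.phase] + (timepoints_per_phase - 1) / 2.0
        assert label.boundary is not None
        # border between the two blocks: midway between the flanking timepoints
        later = label.boundary[1]
        start = phase_start[later]
        return (start - 0.5) % n_time

    proteins = list(labels.labels)
    signal = np.ones((len(proteins), n_time))
    for i, protein in enumerate(proteins):
        label = labels[protein]
        if label.is_dynamic:
            t_peak = peak_position(label)
            signal[i] += amplitude * np.cos(2 * np.pi * (t - t_peak) / n_time)
    datasets = []
    for _ in range(n_datasets):
        noisy = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        values = pd.DataFrame(noisy, index=proteins, columns=list(phase_map))
        datasets.append(ExpressionDataset(values, phase_map))
    return datasets


def generate_expression(
    n_proteins: int = 100,
    frac_static: float = 0.6,
    timepoints_per_phase: int = 4,
    amplitude: float = 1.0,
    noise_sd: float = 0.1,
    n_datasets: int = 3,
    seed: int = 0,
) -> tuple[list[ExpressionDataset], PhaseLabelTable]:
    """Generate expression datasets plus their truth label table.

    The first ``round(frac_static * n_proteins)`` proteins are static; the
    rest are dynamic with phases assigned round-robin over G1, S, G2, M so
    small runs deterministically cover all four phases.
    """
    if not 0.0 <= frac_static <= 1.0:
        raise ValueError("frac_static must be in [0, 1]")
    n_static = int(round(frac_static * n_proteins))
    labels: dict[str, PhaseLabel] = {}
    for i in range(n_proteins):
        protein = f"P{i:04d}"
        if i < n_static:
            labels[protein] = STATIC_LABEL
        else:
            phase = PHASE_ORDER[(i - n_static) % 4]
            labels[protein] = PhaseLabel(LabelKind.DYNAMIC, phase=phase)
    truth = PhaseLabelTable(labels)
    datasets = expression_for_labels(
        truth,
        timepoints_per_phase=timepoints_per_phase,
        amplitude=amplitude,
        noise_sd=noise_sd,
        n_datasets=n_datasets,
        seed=seed,
    )
    return datasets, truth


def generate_scenario(
    n_anchors: int = 5,
    complexes_per_anchor: int = 3,
    dynamic_core_size: int = 4,
    p_within: float = 0.9,
    p_background: float = 0.05,
    n_noise_proteins: int = 20,
    seed: int = 0,
) -> tuple[WeightedNetwork, ScenarioTruth]:
    """Plant anchored phase-specific complexes in a noisy weighted network.

    Each anchor joins ``complexes_per_anchor`` planted complexes (distinct
    phases, assigned G1 onward), each completed by a fresh set of
    ``dynamic_core_size`` dynamic proteins labelled with the complex's
    phase.  Noise proteins are static bystanders outside every complex.
    """
    if not 1 <= complexes_per_anchor <= 4:
        raise ValueError(
            "complexes_per_anchor must be between 1 and 4: only four phases available"
        )
    if not (0.0 <= p_background <= 1.0 and 0.0 <= p_within <= 1.0):
        raise ValueError("probabilities must be in [0, 1]")
    if p_within <= p_background:
        raise ValueError("p_within must exceed p_background")
    rng = np.random.default_rng(seed)

    labels: dict[str, PhaseLabel] = {}
    planted: list[tuple[str, frozenset[str]]] = []
    complex_phases: dict[str, Phase] = {}
    fused: list[tuple[str, frozenset[str]]] = []
    anchors: list[str] = []
    dyn_counter = 0
    for i in range(n_anchors):
        anchor = f"A{i:03d}"
        anchors.append(anchor)
        labels[anchor] = STATIC_LABEL
        union: set[str] = {anchor}
        for j in range(complexes_per_anchor):
            phase = PHASE_ORDER[j]
            core = []
            for _ in range(dynamic_core_size):
                protein = f"D{dyn_counter:04d}"
                dyn_counter += 1
                labels[protein] = PhaseLabel(LabelKind.DYNAMIC, phase=phase)
                core.append(protein)
            name = f"{anchor}_{phase.value}"
            members = frozenset([anchor, *core])
            planted.append((name, members))
            complex_phases[name] = phase
            union |= members
        fused.append((f"fused_{anchor}", frozenset(union)))
    for k in range(n_noise_proteins):
        labels[f"N{k:03d}"] = STATIC_LABEL

    proteins = list(labels)
    edges: dict[frozenset, float] = {}
    for _, members in planted:
        mem = sorted(members)
        for a_idx in range(len(mem)):
            for b_idx in range(a_idx + 1, len(mem)):
                pair = frozenset((mem[a_idx], mem[b_idx]))
                if pair in edges:
                    continue
                if rng.random() < p_within:
                    edges[pair] = 0.5 + 0.5 * rng.random()
    for a_idx in range(len(proteins)):
        for b_idx in range(a_idx + 1, len(proteins)):
            pair = frozenset((proteins[a_idx], proteins[b_idx]))
            if pair in edges:
                continue
            if rng.random() < p_background:
                edges[pair] = 0.5 * rng.random()

    network = WeightedNetwork.from_edges(
        ((*sorted(pair), score) for pair, score in edges.items()),
        nodes=proteins,
    )
    truth = ScenarioTruth(
        true_labels=PhaseLabelTable(labels),
        planted_complexes=ComplexSet(planted),
        complex_phases=complex_phases,
        anchor_proteins=frozenset(anchors),
        fused_clusters=ComplexSet(fused),
    )
    return network, truth
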