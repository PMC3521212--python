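"""Peak Expression Discretization (PED).

Maps each protein's cell-cycle expression time course(s) to a unique
:class:`~tcomplex.types.PhaseLabel`.  Multiple expression datasets are
first standardized per protein (z-score) and averaged element-wise, so
that studies on different scales contribute equally; each protein is then
assigned the phase in which its averaged profile peaks.  A protein whose
profile peaks in more than one phase is *static* — with two refinements
over that literal rule:

* an amplitude gate (``min_amplitude``): a profile whose total excursion
  is below this relative threshold is static regardless of where its
  (noise-driven) argmax falls;
* a tie tolerance (``tie_tolerance``): phase means within this relative
  fraction of the maximum count as co-maximal.  Two co-maximal *adjacent*
  phases with the global peak at the shared border yield a boundary label
  (e.g. G1/S); adjacent without a border-proximal peak yield UNCERTAIN;
  non-adjacent co-maximal phases yield STATIC.

Setting ``tie_tolerance = 0`` and ``min_amplitude = 0`` recovers the
literal rule: argmax of per-phase means, static only on exact ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ExpressionDataset,
    LabelKind,
    Phase,
    PhaseLabel,
    PhaseLabelTable,
    STATIC_LABEL,
    UNCERTAIN_LABEL,
    adjacent_pair,
)

__all__ = ["PedConfig", "average_datasets", "peak_phase", "discretize"]


@dataclass(frozen=True)
class PedConfig:
    """Tunable thresholds for the discretization.

    tie_tolerance
        Relative fraction of the maximal phase mean within which another
        phase mean counts as co-maximal.
    min_amplitude
        Required relative excursion (max - min over timepoints, divided by
        |profile mean|, or by 1 when the mean is ~0 as it is after
        standardization) for a protein to be eligible for a dynamic label.
    boundary_window
        A peak within this many timepoints of the border between two
        co-maximal adjacent phases produces a boundary label; 1 means the
        two timepoints flanking the border.
    """

    tie_tolerance: float = 0.05
    min_amplitude: float = 0.1
    boundary_window: int = 1

    def __post_init__(self) -> None:
        if self.tie_tolerance < 0 or self.min_amplitude < 0 or self.boundary_window < 0:
            raise ValueError("PedConfig fields must be >= 0")


def _standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Per-protein z-score; zero-variance rows pass through as all-zero."""
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (arr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def average_datasets(datasets: Sequence[ExpressionDataset]) -> ExpressionDataset:
    """Standardize each dataset per protein, then average element-wise.

    All datasets must share protein lists, timepoint lists and the
    timepoint -> phase annotation.
    """
    if not datasets:
        raise ValueError("no datasets to average")
    first = datasets[0]
    for d in datasets[1:]:
        if not first.same_design(d):
            raise ValueError(
                "datasets differ in proteins, timepoints or phase annotation"
            )
    stacked = np.stack([_standardize(d.values).to_numpy() for d in datasets])
    avg = pd.DataFrame(
        stacked.mean(axis=0), index=first.values.index, columns=first.values.columns
    )
    return ExpressionDataset(avg, first.timepoint_phase)


def _border_flanks(phases: Sequence[Phase], pair: tuple[Phase, Phase]) -> list[int]:
    """Timepoint indices flanking every circular transition a -> b."""
    a, b = pair
    n = len(phases)
    flanks: list[int] = []
    for i in range(n):
        j = (i + 1) % n
        if phases[i] is a and phases[j] is b:
            flanks.extend((i, j))
    return flanks


def _circ_dist(i: int, j: int, n: int) -> int:
    d = abs(i - j)
    return min(d, n - d)


def peak_phase(
    profile: Sequence[float],
    phases: Sequence[Phase],
    config: PedConfig = PedConfig(),
) -> PhaseLabel:
    """Discretize one (averaged) profile into a phase label.

    ``phases`` gives the phase of each timepoint, in time order; every one
    of the four phases must annotate at least one timepoint.
    """
    x = np.asarray(profile, dtype=float)
    if len(x) != len(phases):
        raise ValueError("profile length does not match phase annotation")
    phase_means: dict[Phase, float] = {}
    for p in (Phase.G1, Phase.S, Phase.G2, Phase.M):
        idx = [i for i, q in enumerate(phases) if q is p]
        if not idx:
            raise ValueError(f"phase {p.value} has no timepoints")
        phase_means[p] = float(x[idx].mean())

    mean = float(x.mean())
    denom = abs(mean) if abs(mean) > 1e-9 else 1.0
    rel_amplitude = float(x.max() - x.min()) / denom
    if rel_amplitude < config.min_amplitude:
        return STATIC_LABEL

    m_star = max(phase_means.values())
    tol = config.tie_tolerance * abs(m_star)
    co_max = [p for p, m in phase_means.items() if m >= m_star - tol]
    if len(co_max) == 1:
        return PhaseLabel(LabelKind.DYNAMIC, phase=co_max[0])
    if len(co_max) == 2:
        pair = adjacent_pair(co_max[0], co_max[1])
        if pair is not None:
            flanks = _border_flanks(phases, pair)
            peak_idx = int(np.argmax(x))
            n = len(x)
            if flanks and min(
                _circ_dist(peak_idx, f, n) for f in flanks
            ) <= config.boundary_window - 1:
                return PhaseLabel(LabelKind.DYNAMIC, boundary=pair)
            return UNCERTAIN_LABEL
    return STATIC_LABEL


def discretize(
    datasets: Sequence[ExpressionDataset],
    config: PedConfig = PedConfig(),
) -> PhaseLabelTable:
    """Run the full discretization: average datasets, label every protein."""
    avg = average_datasets(datasets)
    phases = avg.phases
    labels = {
        protein: peak_phase(avg.values.loc[protein].to_numpy(), phases, config)
        for protein in avg.proteins
    }
    return PhaseLabelTable(labels)
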