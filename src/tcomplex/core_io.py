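"""Readers and writers for the plain-text formats the pipeline touches.

Formats:

* weighted edge lists — tab- or whitespace-separated ``protein_a protein_b
  [score]`` lines; a missing score means 1.0.  Duplicate unordered pairs are
  merged keeping the maximum score, self-loops are dropped with a warning,
  and edges scoring below the reliability threshold (default 0.20) are
  discarded.
* complex catalogues — one complex per line, optionally prefixed
  ``name:``, members whitespace-separated (the flat shape CYC2008 is
  distributed in).
* phase-label tables — two-column TSV ``protein  label`` with labels
  G1, S, G2, M, G1/S, S/G2, G2/M, M/G1, Static or Uncertain
  (case-insensitive).
* expression matrices — TSV with a ``protein`` index column and one column
  per timepoint, plus a separate two-column ``timepoint  phase`` map.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import pandas as pd

from .types import (
    ComplexSet,
    ExpressionDataset,
    Phase,
    PhaseLabel,
    PhaseLabelTable,
    WeightedNetwork,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Reliability-score cut-off below which interactions are discarded.
DEFAULT_SCORE_THRESHOLD = 0.20

_NETWORK_HEADER = ("protein_a", "protein_b")


class ParseError(ValueError):
    """A line in an input file could not be parsed."""


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_network(
    path: PathLike, score_threshold: float = DEFAULT_SCORE_THRESHOLD
) -> WeightedNetwork:
    """Read a weighted edge list, keeping edges with score >= threshold.

    Duplicate unordered pairs keep the maximum score; self-loops are dropped
    with a logged warning.  Raises :class:`ParseError` on a malformed line
    and ``ValueError`` when no edge survives the filter.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError(f"score threshold {score_threshold} outside [0, 1]")
    best: dict[frozenset, float] = {}
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split()
        if first:
            first = False
            if tuple(f.lower() for f in fields[:2]) == _NETWORK_HEADER:
                continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
        a, b = fields[0], fields[1]
        if len(fields) >= 3:
            try:
                score = float(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: score {fields[2]!r} is not a number"
                ) from None
            if not 0.0 <= score <= 1.0:
                raise ParseError(f"{path}:{lineno}: score {score} outside [0, 1]")
        else:
            score = 1.0
        if a == b:
            logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
            continue
        key = frozenset((a, b))
        if key not in best or score > best[key]:
            best[key] = score
    edges = [
        (*sorted(pair), score)
        for pair, score in best.items()
        if score >= score_threshold
    ]
    if not edges:
        raise ValueError(
            f"empty network: no edge in {path} has score >= {score_threshold}"
        )
    return WeightedNetwork.from_edges(edges)


def write_network(network: WeightedNetwork, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tscore\n")
        for u, v, score in sorted(network.edges()):
            fh.write(f"{u}\t{v}\t{score:.6g}\n")


def read_complexes(path: PathLike) -> ComplexSet:
    """Read a one-complex-per-line file.

    The first token names the complex when it ends with ``:``; otherwise
    names C1, C2, ... are auto-assigned in line order.  Member tokens are
    deduplicated within a line.
    """
    complexes: list[tuple[str, frozenset[str]]] = []
    auto = 0
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if tokens[0].endswith(":"):
            name = tokens[0][:-1]
            members = tokens[1:]
            if not name:
                raise ParseError(f"{path}:{lineno}: empty complex name")
        else:
            auto += 1
            name = f"C{auto}"
            members = tokens
        if not members:
            raise ParseError(f"{path}:{lineno}: complex {name!r} has no members")
        complexes.append((name, frozenset(members)))
    if not complexes:
        raise ValueError(f"no complexes found in {path}")
    return ComplexSet(complexes)


def write_complexes(complexes: ComplexSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in complexes:
            fh.write(f"{name}: " + " ".join(sorted(members)) + "\n")


def read_phase_labels(path: PathLike) -> PhaseLabelTable:
    """Read a two-column ``protein  label`` TSV into a label table.

    A duplicate protein with an identical label is deduplicated silently;
    conflicting labels raise an error.  Unknown label strings raise
    :class:`ParseError` naming the offending value.
    """
    labels: dict[str, PhaseLabel] = {}
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if first:
            first = False
            if fields[0].lower() == "protein":
                continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        protein, text = fields[0], fields[1]
        try:
            label = PhaseLabel.parse(text)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if protein in labels and labels[protein] != label:
            raise ParseError(
                f"{path}:{lineno}: conflicting labels for {protein!r}: "
                f"{labels[protein]} vs {label}"
            )
        labels[protein] = label
    return PhaseLabelTable(labels)


def write_phase_labels(table: PhaseLabelTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tlabel\n")
        for protein in sorted(table.labels):
            fh.write(f"{protein}\t{table.labels[protein]}\n")


def read_phase_map(path: PathLike) -> dict[str, Phase]:
    """Read a two-column ``timepoint  phase`` TSV (order preserved)."""
    out: dict[str, Phase] = {}
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if first:
            first = False
            if fields[0].lower() == "timepoint":
                continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        try:
            out[fields[0]] = Phase(fields[1].strip().upper())
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: unknown phase {fields[1]!r}"
            ) from None
    if not out:
        raise ValueError(f"no timepoints found in {path}")
    return out


def write_phase_map(phase_map: dict[str, Phase], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("timepoint\tphase\n")
        for timepoint, phase in phase_map.items():
            fh.write(f"{timepoint}\t{phase.value}\n")


def read_expression(matrix_path: PathLike, phase_map_path: PathLike) -> ExpressionDataset:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    phase_map = read_phase_map(phase_map_path)
    return ExpressionDataset(values, phase_map)


def write_expression(dataset: ExpressionDataset, matrix_path: PathLike) -> None:
    dataset.values.to_csv(matrix_path, sep="\t", index_label="protein")
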