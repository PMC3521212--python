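"""Core/attachment partition, enrichment statistics and protein classes.

Proteins occurring in exactly one complex of the analysed set are *cores*
("specialized"); proteins shared among two or more complexes are
*attachments* ("reused").  For a complex C with λ_s(C) static and λ_d(C)
dynamic members, the static enrichment of its attachment part is

    E_s(Attach(C)) = λ_s(Attach(C)) / λ_s(C)

and likewise E_d for dynamic members and E_*(Core(C)) for the core part.
The relative enrichment RE = E_s / E_d measures how much more "static"
one part is than "dynamic".  Overall values average the per-complex
enrichments over the complexes where they are defined, and the overall RE
is the ratio of the averaged E values (not the average of per-complex
ratios).

A zero denominator makes an E value *undefined* (not 0); undefined values
are excluded from the overall averages rather than coerced, which is why
the averaged attachment and core enrichments need not sum exactly to 1.
When the averaged dynamic enrichment is 0 while the static one is
positive, the overall RE is reported as infinity.

The same counts feed the protein classification: label kind (static /
dynamic) crossed with reuse status (membership count >= 2) gives
STATIC_REUSED ('date'-hub-like), STATIC_SPECIALIZED ('family'-hub-like),
DYNAMIC_SPECIALIZED ('party'-hub-like) and the unexpected DYNAMIC_REUSED.
"""

from __future__ import annotations

import enum
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .types import ComplexSet, LabelKind, PhaseLabelTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorePartition",
    "ComplexEnrichment",
    "EnrichmentSummary",
    "ProteinCategory",
    "ProteinClassification",
    "partition_core_attachment",
    "complex_enrichment",
    "summarize_enrichment",
    "relative_enrichment",
    "classify_proteins",
]


@dataclass(frozen=True)
class CorePartition:
    """Membership counts over a complex set; role is global per protein."""

    membership_count: dict[str, int]

    def is_attachment(self, protein: str) -> bool:
        return self.membership_count.get(protein, 0) >= 2

    def split(self, members: frozenset[str]) -> tuple[frozenset[str], frozenset[str]]:
        """Partition one complex's members into (core, attachment)."""
        attach = frozenset(p for p in members if self.is_attachment(p))
        return members - attach, attach


def partition_core_attachment(complexes: ComplexSet) -> CorePartition:
    """Count memberships over the supplied set; shared proteins are attachments."""
    if len(complexes) == 0:
        raise ValueError("empty complex set")
    counts: Counter[str] = Counter()
    for _, members in complexes:
        counts.update(members)
    return CorePartition(membership_count=dict(counts))


def relative_enrichment(e_s: float, e_d: float) -> Optional[float]:
    """Static-to-dynamic enrichment ratio E_s / E_d.

    Returns ``inf`` when E_d is 0 but E_s is positive (no dynamic protein
    in that part at all), and ``None`` when both are 0.
    """
    if e_d == 0:
        return math.inf if e_s > 0 else None
    return e_s / e_d


@dataclass(frozen=True)
class ComplexEnrichment:
    """Per-complex λ counts and enrichment values; ``None`` = undefined."""

    name: str
    lambda_s: int
    lambda_d: int
    es_attach: Optional[float]
    ed_attach: Optional[float]
    es_core: Optional[float]
    ed_core: Optional[float]
    re_attach: Optional[float]
    re_core: Optional[float]


def complex_enrichment(
    name: str,
    members: frozenset[str],
    partition: CorePartition,
    labels: PhaseLabelTable,
    uncertain: str = "exclude",
) -> ComplexEnrichment:
    """Enrichment record for one complex.

    ``uncertain`` controls UNCERTAIN (and unlabelled) members: ``exclude``
    drops them from the λ counts, ``static`` folds them into the static
    count.  E values with a zero denominator are undefined (``None``), as
    is RE when the corresponding E_d is undefined or 0.
    """
    if uncertain not in ("exclude", "static"):
        raise ValueError("uncertain must be 'exclude' or 'static'")

    def is_static(protein: str) -> Optional[bool]:
        label = labels.get(protein)
        if label is None or label.kind is LabelKind.UNCERTAIN:
            return True if uncertain == "static" else None
        return label.kind is LabelKind.STATIC

    core, attach = partition.split(members)
    s_total = d_total = s_attach = d_attach = 0
    for protein in members:
        static = is_static(protein)
        if static is None:
            continue
        if static:
            s_total += 1
            s_attach += protein in attach
        else:
            d_total += 1
            d_attach += protein in attach

    es_attach = s_attach / s_total if s_total else None
    ed_attach = d_attach / d_total if d_total else None
    es_core = (s_total - s_attach) / s_total if s_total else None
    ed_core = (d_total - d_attach) / d_total if d_total else None

    def strict_re(e_s: Optional[float], e_d: Optional[float]) -> Optional[float]:
        if e_s is None or e_d is None or e_d == 0:
            return None
        return e_s / e_d

    return ComplexEnrichment(
        name=name,
        lambda_s=s_total,
        lambda_d=d_total,
        es_attach=es_attach,
        ed_attach=ed_attach,
        es_core=es_core,
        ed_core=ed_core,
        re_attach=strict_re(es_attach, ed_attach),
        re_core=strict_re(es_core, ed_core),
    )


def _mean(values: list[float]) -> Optional[float]:
    return sum(values) / len(values) if values else None


@dataclass
class EnrichmentSummary:
    """Overall enrichment averages plus the per-complex table.

    ``n_defined`` records how many complexes entered each average (the
    rest had an undefined value for that quantity).
    """

    per_complex: list[ComplexEnrichment]
    es_attach: Optional[float]
    ed_attach: Optional[float]
    es_core: Optional[float]
    ed_core: Optional[float]
    re_attach: Optional[float]
    re_core: Optional[float]
    n_defined: dict[str, int] = field(default_factory=dict)


def summarize_enrichment(
    complexes: ComplexSet,
    labels: PhaseLabelTable,
    uncertain: str = "exclude",
) -> EnrichmentSummary:
    """Per-complex enrichments plus overall averages and overall RE.

    Overall E values are means over the complexes where they are defined;
    overall RE is the ratio of the averaged static and dynamic enrichments.
    """
    partition = partition_core_attachment(complexes)
    records = [
        complex_enrichment(name, members, partition, labels, uncertain=uncertain)
        for name, members in complexes
    ]
    means: dict[str, Optional[float]] = {}
    n_defined: dict[str, int] = {}
    for key in ("es_attach", "ed_attach", "es_core", "ed_core"):
        defined = [getattr(r, key) for r in records if getattr(r, key) is not None]
        means[key] = _mean(defined)
        n_defined[key] = len(defined)
        if not defined:
            logger.warning("overall %s undefined: no complex defines it", key)

    def overall_re(e_s: Optional[float], e_d: Optional[float]) -> Optional[float]:
        if e_s is None or e_d is None:
            return None
        return relative_enrichment(e_s, e_d)

    return EnrichmentSummary(
        per_complex=records,
        es_attach=means["es_attach"],
        ed_attach=means["ed_attach"],
        es_core=means["es_core"],
        ed_core=means["ed_core"],
        re_attach=overall_re(means["es_attach"], means["ed_attach"]),
        re_core=overall_re(means["es_core"], means["ed_core"]),
        n_defined=n_defined,
    )


class ProteinCategory(str, enum.Enum):
    STATIC_REUSED = "STATIC_REUSED"
    STATIC_SPECIALIZED = "STATIC_SPECIALIZED"
    DYNAMIC_REUSED = "DYNAMIC_REUSED"
    DYNAMIC_SPECIALIZED = "DYNAMIC_SPECIALIZED"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class ProteinClassification:
    """Class per protein; ``unexpected`` flags the DYNAMIC_REUSED cases."""

    classes: dict[str, ProteinCategory]
    unexpected: frozenset[str]


def classify_proteins(
    complexes: ComplexSet,
    labels: PhaseLabelTable,
    uncertain: str = "exclude",
) -> ProteinClassification:
    """Cross label kind with reuse status for every complex member.

    UNCERTAIN and unlabelled proteins are UNCLASSIFIED (or folded into the
    static classes when ``uncertain='static'``).  Dynamic reused proteins
    are flagged: sharing is expected of static anchors, not of
    phase-specific subunits.
    """
    if uncertain not in ("exclude", "static"):
        raise ValueError("uncertain must be 'exclude' or 'static'")
    partition = partition_core_attachment(complexes)
    classes: dict[str, ProteinCategory] = {}
    unexpected: set[str] = set()
    for protein in sorted(complexes.all_proteins):
        label = labels.get(protein)
        if label is None or label.kind is LabelKind.UNCERTAIN:
            if uncertain == "exclude":
                classes[protein] = ProteinCategory.UNCLASSIFIED
                continue
            static = True
        else:
            static = label.kind is LabelKind.STATIC
        reused = partition.is_attachment(protein)
        if static:
            cat = (
                ProteinCategory.STATIC_REUSED
                if reused
                else ProteinCategory.STATIC_SPECIALIZED
            )
        elif reused:
            cat = ProteinCategory.DYNAMIC_REUSED
            unexpected.add(protein)
        else:
            cat = ProteinCategory.DYNAMIC_SPECIALIZED
        classes[protein] = cat
    return ProteinClassification(classes=classes, unexpected=frozenset(unexpected))
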