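"""Core/attachment partition, enrichment E, relative enrichment RE."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from tcomplex import (
    ProteinCategory,
    classify_proteins,
    complex_enrichment,
    decompose_all,
    generate_scenario,
    partition_core_attachment,
    relative_enrichment,
    summarize_enrichment,
)
from tcomplex.types import ComplexSet, PhaseLabel, PhaseLabelTable


def table(**labels: str) -> PhaseLabelTable:
    return PhaseLabelTable({p: PhaseLabel.parse(s) for p, s in labels.items()})


def cset(**complexes) -> ComplexSet:
    return ComplexSet([(n, frozenset(m)) for n, m in complexes.items()])


class TestPartition:
    def test_shared_protein_is_attachment_everywhere(self):
        part = partition_core_attachment(cset(C1="ABX", C2="CDX"))
        assert part.is_attachment("X")
        for p in "ABCD":
            assert not part.is_attachment(p)
        core, attach = part.split(frozenset("ABX"))
        assert (core, attach) == (frozenset("AB"), frozenset("X"))

    def test_single_complex_has_no_attachments(self):
        part = partition_core_attachment(cset(C1="ABC"))
        core, attach = part.split(frozenset("ABC"))
        assert attach == frozenset()
        assert core == frozenset("ABC")

    def test_scenario_attachments_are_exactly_the_anchors(self):
        _, truth = generate_scenario(
            n_anchors=4, complexes_per_anchor=3, dynamic_core_size=3, seed=9
        )
        part = partition_core_attachment(truth.planted_complexes)
        attachments = {
            p for p in truth.planted_complexes.all_proteins
            if part.is_attachment(p)
        }
        assert attachments == set(truth.anchor_proteins)


def brute_force_enrichment(members, attach, labels):
    """Independent oracle: enumerate (member, role, kind) triples."""
    rows = [
        (p, "attach" if p in attach else "core", str(labels[p]))
        for p in members
        if str(labels.get(p)) in ("Static",) or labels.get(p).is_dynamic
    ]
    lam_s = sum(kind == "Static" for _, _, kind in rows)
    lam_d = sum(kind != "Static" for _, _, kind in rows)
    s_att = sum(r == "attach" and k == "Static" for _, r, k in rows)
    d_att = sum(r == "attach" and k != "Static" for _, r, k in rows)
    es_a = s_att / lam_s if lam_s else None
    ed_a = d_att / lam_d if lam_d else None
    es_c = (lam_s - s_att) / lam_s if lam_s else None
    ed_c = (lam_d - d_att) / lam_d if lam_d else None
    return lam_s, lam_d, es_a, ed_a, es_c, ed_c


class TestComplexEnrichment:
    def test_worked_example(self):
        """4 static members (3 shared), 5 dynamic (1 shared):
        E_s(Attach)=0.75, E_d(Attach)=0.20, RE(Attach)=3.75."""
        target = cset(C=["s1", "s2", "s3", "s4", "d1", "d2", "d3", "d4", "d5"])
        other = cset(O=["s1", "s2", "s3", "d1", "z"])
        both = ComplexSet(target.complexes + other.complexes)
        labels = table(
            s1="Static", s2="Static", s3="Static", s4="Static",
            d1="G1", d2="S", d3="G2", d4="M", d5="G1", z="Static",
        )
        part = partition_core_attachment(both)
        r = complex_enrichment("C", both.members("C"), part, labels)
        assert (r.lambda_s, r.lambda_d) == (4, 5)
        assert r.es_attach == pytest.approx(0.75)
        assert r.ed_attach == pytest.approx(0.20)
        assert r.re_attach == pytest.approx(3.75)
        assert r.es_core == pytest.approx(0.25)
        assert r.ed_core == pytest.approx(0.80)
        assert r.re_core == pytest.approx(0.3125)

    def test_zero_denominators_are_undefined_not_zero(self):
        labels = table(a="Static", b="Static", c="Static", d="Static")
        part = partition_core_attachment(cset(C="abcd"))
        r = complex_enrichment("C", frozenset("abcd"), part, labels)
        assert r.es_attach == 0.0  # defined: 0 of 4 statics shared
        assert r.ed_attach is None  # no dynamic member at all
        assert r.re_attach is None

    def test_symmetric_composition_gives_equal_re(self):
        # attach half and core half each hold 1 static + 1 dynamic
        complexes = cset(C=["s1", "d1", "s2", "d2"], O=["s1", "d1", "x"])
        labels = table(s1="Static", s2="Static", d1="G1", d2="M", x="Static")
        part = partition_core_attachment(complexes)
        r = complex_enrichment("C", complexes.members("C"), part, labels)
        assert r.re_attach == pytest.approx(r.re_core)

    @settings(deadline=None, max_examples=40)
    @given(
        membership=st.lists(
            st.tuples(st.booleans(), st.booleans()),  # (shared?, static?)
            min_size=1,
            max_size=10,
        )
    )
    def test_matches_brute_force_oracle(self, membership):
        members = [f"p{i}" for i in range(len(membership))]
        labels = table(
            **{p: "Static" if static else "G1"
               for p, (_, static) in zip(members, membership)}
        )
        shared = [p for p, (s, _) in zip(members, membership) if s]
        complexes = [("C", frozenset(members))]
        if shared:
            complexes.append(("other", frozenset(shared) | {"zzz"}))
        cs = ComplexSet(complexes)
        part = partition_core_attachment(cs)
        r = complex_enrichment("C", cs.members("C"), part, labels)
        exp = brute_force_enrichment(frozenset(members), set(shared), labels)
        got = (r.lambda_s, r.lambda_d, r.es_attach, r.ed_attach,
               r.es_core, r.ed_core)
        assert got == pytest.approx(exp)
        # partition conservation for the defined values
        if r.es_attach is not None:
            assert r.es_attach + r.es_core == pytest.approx(1.0)
        if r.ed_attach is not None:
            assert r.ed_attach + r.ed_core == pytest.approx(1.0)


class TestSummarize:
    def test_overall_re_is_ratio_of_averaged_enrichments(self):
        """The published consolidated-network averages (0.626, 0.184,
        0.445, 0.530) give RE(Attach)=3.402 and RE(Core)~0.840."""
        assert relative_enrichment(0.626, 0.184) == pytest.approx(3.402, abs=5e-4)
        assert relative_enrichment(0.445, 0.530) == pytest.approx(0.840, abs=5e-4)

    def test_single_complex_summary_equals_its_record(self):
        complexes = cset(C=["s1", "d1", "d2"])
        labels = table(s1="Static", d1="G1", d2="M")
        summary = summarize_enrichment(complexes, labels)
        r = summary.per_complex[0]
        assert summary.es_attach == r.es_attach
        assert summary.ed_core == r.ed_core

    def test_undefined_values_excluded_from_averages(self):
        # C1 has no dynamic member: its ed values must not drag the average
        complexes = cset(C1=["s1", "s2"], C2=["s1", "d1", "d2"])
        labels = table(s1="Static", s2="Static", d1="G1", d2="M")
        summary = summarize_enrichment(complexes, labels)
        assert summary.n_defined["ed_attach"] == 1
        assert summary.ed_attach == pytest.approx(0.0)  # from C2 only

    def test_scenario_realizes_the_reuse_hypothesis(self):
        """Decomposing fused clusters of anchored phase complexes yields
        attachments far more static-enriched than cores."""
        _, truth = generate_scenario(
            n_anchors=5, complexes_per_anchor=3, dynamic_core_size=4, seed=4
        )
        outcome = decompose_all(truth.fused_clusters, truth.true_labels)
        summary = summarize_enrichment(outcome.timed_set, truth.true_labels)
        assert summary.re_attach > 1  # anchors (static) are the shared part
        assert summary.re_core < 1
        assert math.isinf(summary.re_attach)  # no dynamic protein is shared


class TestClassifyProteins:
    def test_static_kinase_shared_across_decomposed_complexes_is_reused(
        self, cdc28_labels, cdc28_members
    ):
        outcome = decompose_all(
            ComplexSet([("cdc28", cdc28_members)]), cdc28_labels
        )
        result = classify_proteins(outcome.timed_set, cdc28_labels)
        assert result.classes["Ybr160w"] is ProteinCategory.STATIC_REUSED

    def test_dynamic_in_one_complex_is_specialized(self):
        complexes = cset(C=["d1", "s1"])
        labels = table(d1="G1", s1="Static")
        result = classify_proteins(complexes, labels)
        assert result.classes["d1"] is ProteinCategory.DYNAMIC_SPECIALIZED
        assert result.classes["s1"] is ProteinCategory.STATIC_SPECIALIZED

    def test_scenario_anchors_reused_cores_specialized(self):
        _, truth = generate_scenario(
            n_anchors=3, complexes_per_anchor=3, dynamic_core_size=3, seed=6
        )
        result = classify_proteins(truth.planted_complexes, truth.true_labels)
        for anchor in truth.anchor_proteins:
            assert result.classes[anchor] is ProteinCategory.STATIC_REUSED
        dynamics = truth.planted_complexes.all_proteins - truth.anchor_proteins
        for p in dynamics:
            assert result.classes[p] is ProteinCategory.DYNAMIC_SPECIALIZED
        assert result.unexpected == frozenset()

    def test_dynamic_reused_is_flagged_unexpected(self):
        complexes = cset(C1=["d1", "a"], C2=["d1", "b"])
        labels = table(d1="G1", a="Static", b="Static")
        result = classify_proteins(complexes, labels)
        assert result.classes["d1"] is ProteinCategory.DYNAMIC_REUSED
        assert result.unexpected == frozenset({"d1"})

    def test_uncertain_protein_unclassified(self):
        complexes = cset(C=["u1", "s1"])
        labels = table(u1="Uncertain", s1="Static")
        result = classify_proteins(complexes, labels)
        assert result.classes["u1"] is ProteinCategory.UNCLASSIFIED

    def test_reused_iff_attachment(self):
        complexes = cset(C1="ABX", C2="CDX")
        labels = table(A="Static", B="G1", C="M", D="Static", X="Static")
        part = partition_core_attachment(complexes)
        result = classify_proteins(complexes, labels)
        for p in complexes.all_proteins:
            reused = result.classes[p] in (
                ProteinCategory.STATIC_REUSED, ProteinCategory.DYNAMIC_REUSED
            )
            assert reused == part.is_attachment(p)
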