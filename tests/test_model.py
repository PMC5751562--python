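"""Unit and property tests for the core utility model."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from hugseq.model import (
    ContainmentError,
    GeneImportanceTable,
    Geneset,
    Item,
    NoOccurrenceError,
    Pattern,
    PatientSequence,
    SequentialDataset,
    find_occurrences,
    first_occurrence,
    geneset_utility,
    item_utility,
    pattern_utility,
    pattern_utility_in_patient,
    rest_sequence,
    sequence_total_utility,
    support,
    upper_utility,
    upper_utility_dataset,
)

TOL = 1e-9


class TestPattern:
    def test_parse_roundtrip(self):
        p = Pattern.parse("(G1+ G2-)(G1-)")
        assert str(p) == "(G1+ G2-)(G1-)"
        assert p.length == 2 and p.size == 3

    def test_canonical_order_and_dedup(self):
        assert Pattern.of([["G2-", "G1+", "G1+"]]) == Pattern.of([["G1+", "G2-"]])
        # up sorts before down for the same gene
        assert Pattern.of([["G1-", "G1+"]]).elements[0] == (("G1", "+"), ("G1", "-"))

    @pytest.mark.parametrize("bad", ["", "()", "(G1)"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            Pattern.parse(bad)

    def test_ordering_is_total_and_deterministic(self):
        # element-tuple lexicographic order: a prefix sorts first, and a
        # shorter first element precedes a longer one
        a = Pattern.parse("(G1+)")
        b = Pattern.parse("(G1+ G2-)")
        c = Pattern.parse("(G1+)(G1+)")
        assert sorted([c, b, a]) == [a, c, b]


class TestItemAndGenesetUtility:
    @pytest.mark.parametrize(
        "gene,direction,iu,expected",
        [
            ("G1", "+", 2.2, 1.76),   # importance 0.8
            ("G3", "-", 1.9, 0.19),   # importance 0.1
            ("G2", "+", 0.0, 0.0),    # zero magnitude contributes nothing
            ("G9", "+", 5.0, 0.0),    # unlisted gene defaults to importance 0
        ],
    )
    def test_item_utility(self, toy_imp, gene, direction, iu, expected):
        assert item_utility(Item(gene, direction, iu), toy_imp) == pytest.approx(
            expected, abs=TOL
        )

    def test_pluggable_combiner(self, toy_imp):
        assert item_utility(
            Item("G1", "+", 2.0), toy_imp, combiner=lambda gi, iu: gi + iu
        ) == pytest.approx(2.8, abs=TOL)

    @pytest.mark.parametrize(
        "element,patient_idx,geneset_idx,expected",
        [
            ([("G1", "+"), ("G2", "-")], 0, 0, 3.68),
            ([("G1", "+"), ("G2", "+"), ("G3", "-")], 1, 0, 6.99),
        ],
    )
    def test_geneset_utility_matched_items_only(
        self, toy_dataset, toy_imp, element, patient_idx, geneset_idx, expected
    ):
        gs = toy_dataset.patients[patient_idx].genesets[geneset_idx]
        assert geneset_utility(tuple(element), gs, toy_imp) == pytest.approx(
            expected, abs=TOL
        )

    def test_missing_item_raises(self, toy_dataset, toy_imp):
        gs = toy_dataset.patients[0].genesets[1]  # holds G1- and G3- only
        with pytest.raises(ContainmentError):
            geneset_utility((("G1", "+"),), gs, toy_imp)

    def test_empty_element_sums_to_zero(self, toy_dataset, toy_imp):
        gs = toy_dataset.patients[0].genesets[0]
        assert geneset_utility((), gs, toy_imp) == 0.0


class TestOccurrences:
    def test_two_embeddings_with_known_utilities(self, toy_dataset, toy_imp):
        pat = Pattern.parse("(G1+ G2-)(G1-)")
        occs = find_occurrences(pat, toy_dataset.patients[0], toy_imp)
        assert [(o.time_sample_ids, pytest.approx(o.utility, abs=TOL)) for o in occs] == [
            ((1, 2), 5.6),
            ((1, 3), 7.52),
        ]

    def test_single_item_pattern_scans_every_geneset(self, toy_dataset, toy_imp):
        occs = find_occurrences(
            Pattern.parse("(G1-)"), toy_dataset.patients[2], toy_imp
        )
        assert [o.time_sample_ids for o in occs] == [(1,), (2,), (3,)]
        assert [o.utility for o in occs] == pytest.approx([2.48, 5.28, 12.0], abs=TOL)

    def test_no_embedding_when_item_occurs_once(self, toy_dataset, toy_imp):
        pat = Pattern.parse("(G1+)(G1+)")
        assert find_occurrences(pat, toy_dataset.patients[0], toy_imp) == []

    @pytest.mark.parametrize(
        "pattern,patient_idx,expected",
        [("(G1+ G2-)(G1-)", 0, 7.52), ("(G1-)", 2, 12.0), ("(G1+)(G1+)", 0, 0.0)],
    )
    def test_in_patient_utility_is_max_occurrence(
        self, toy_dataset, toy_imp, pattern, patient_idx, expected
    ):
        got = pattern_utility_in_patient(
            Pattern.parse(pattern), toy_dataset.patients[patient_idx], toy_imp
        )
        assert got == pytest.approx(expected, abs=TOL)

    @pytest.mark.parametrize(
        "pattern,expected",
        [("(G1+)", 6.64), ("(G1-)", 15.84), ("(G2+)", 3.72),
         ("(G2-)", 7.32), ("(G3+)", 0.51), ("(G3-)", 0.35)],
    )
    def test_dataset_utility_of_singletons(self, toy_dataset, pattern, expected):
        assert pattern_utility(Pattern.parse(pattern), toy_dataset) == pytest.approx(
            expected, abs=TOL
        )

    @pytest.mark.parametrize(
        "pattern,expected", [("(G2-)", 3), ("(G1+)", 2), ("(G9+)", 0)]
    )
    def test_support_counts_patients(self, toy_dataset, pattern, expected):
        assert support(Pattern.parse(pattern), toy_dataset) == expected


class TestFirstOccurrenceAndRestSequence:
    def test_first_occurrence_ends_earliest(self, toy_dataset, toy_imp):
        occ = first_occurrence(
            Pattern.parse("(G1+ G2-)(G1-)"), toy_dataset.patients[0], toy_imp
        )
        assert occ.time_sample_ids == (1, 2)

    def test_single_embedding_is_its_own_first(self, toy_dataset, toy_imp):
        occ = first_occurrence(Pattern.parse("(G2+)"), toy_dataset.patients[0], toy_imp)
        assert occ.time_sample_ids == (3,)

    def test_missing_pattern_raises_not_zero(self, toy_dataset, toy_imp):
        with pytest.raises(NoOccurrenceError):
            first_occurrence(Pattern.parse("(G9+)"), toy_dataset.patients[0], toy_imp)

    @pytest.mark.parametrize(
        "pattern,patient_idx,expected_tids",
        [("(G1+ G2-)(G1-)", 0, [2, 3]), ("(G1-)", 2, [1, 2, 3]),
         ("(G2+)", 0, [3])],
    )
    def test_rest_sequence_suffix(
        self, toy_dataset, toy_imp, pattern, patient_idx, expected_tids
    ):
        rest = rest_sequence(
            toy_dataset.patients[patient_idx], Pattern.parse(pattern), toy_imp
        )
        assert [gs.time_sample_id for gs in rest.genesets] == expected_tids


class TestUpperUtility:
    def test_known_value_on_worked_example(self, toy_dataset, toy_imp):
        # GU = 7.52 plus the full suffix utility 7.88 from the first
        # occurrence's last geneset onwards
        psi = upper_utility(
            Pattern.parse("(G1+ G2-)(G1-)"), toy_dataset.patients[0], toy_imp
        )
        assert psi == pytest.approx(15.4, abs=TOL)

    def test_zero_when_absent(self, toy_dataset, toy_imp):
        assert upper_utility(Pattern.parse("(G9+)"), toy_dataset.patients[0], toy_imp) == 0.0

    def test_rest_includes_shared_final_geneset(self, toy_dataset, toy_imp):
        # pattern ending at the final geneset: psi = GU + that geneset's
        # full utility (nothing beyond it)
        pat = Pattern.parse("(G2+)")
        patient = toy_dataset.patients[0]
        psi = upper_utility(pat, patient, toy_imp)
        last = patient.genesets[-1]
        total_last = sum(
            item_utility(Item(g, d, iu), toy_imp) for (g, d), iu in last.items.items()
        )
        assert psi == pytest.approx(1.8 + total_last, abs=TOL)

    def test_dataset_psi_bounds_every_extension(self, toy_dataset):
        from hugseq.oracle import enumerate_patterns
        from conftest import is_tree_ancestor

        stats = enumerate_patterns(toy_dataset, max_size=3)
        by_pattern = {s.pattern: s.utility for s in stats}
        short = [s.pattern for s in stats if s.pattern.size <= 2]
        for alpha in short:
            psi = upper_utility_dataset(alpha, toy_dataset)
            for beta, gu in by_pattern.items():
                if is_tree_ancestor(alpha, beta):
                    assert gu <= psi + TOL


# ---------------------------------------------------------------------------
# property tests on randomly drawn small datasets
# ---------------------------------------------------------------------------

GENES = ["A", "B", "C"]


@st.composite
def datasets(draw):
    imp = GeneImportanceTable(
        {g: draw(st.floats(0.1, 1.0, allow_nan=False)) for g in GENES}
    )
    patients = []
    for pi in range(draw(st.integers(1, 3))):
        genesets = []
        for t in range(1, draw(st.integers(2, 4)) + 1):
            items = {}
            for g in GENES:
                direction = draw(st.sampled_from(["+", "-", None]))
                if direction:
                    items[(g, direction)] = draw(st.floats(1.6, 9.0))
            if items:
                genesets.append(Geneset(t, items))
        patients.append(PatientSequence(f"P{pi}", genesets))
    return SequentialDataset(patients, imp, gamma=1.5)


@st.composite
def patterns(draw):
    elements = []
    for _ in range(draw(st.integers(1, 2))):
        n = draw(st.integers(1, 2))
        ids = draw(
            st.lists(
                st.tuples(st.sampled_from(GENES), st.sampled_from(["+", "-"])),
                min_size=n, max_size=n, unique=True,
            )
        )
        elements.append(ids)
    return Pattern.of(elements)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(datasets(), patterns())
def test_dataset_utility_is_additive_over_patients(dataset, pattern):
    total = pattern_utility(pattern, dataset)
    parts = sum(
        pattern_utility_in_patient(pattern, p, dataset.importance)
        for p in dataset.patients
    )
    assert total == pytest.approx(parts, abs=TOL)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(datasets(), patterns())
def test_in_patient_utility_dominates_every_occurrence(dataset, pattern):
    for patient in dataset.patients:
        occs = find_occurrences(pattern, patient, dataset.importance)
        gu = pattern_utility_in_patient(pattern, patient, dataset.importance)
        assert all(gu >= o.utility - TOL for o in occs)
        if occs:
            assert any(abs(gu - o.utility) <= TOL for o in occs)
        else:
            assert gu == 0.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(datasets(), patterns())
def test_first_occurrence_ends_no_later_than_any(dataset, pattern):
    for patient in dataset.patients:
        occs = find_occurrences(pattern, patient, dataset.importance)
        if not occs:
            continue
        first = first_occurrence(pattern, patient, dataset.importance)
        assert all(
            first.time_sample_ids[-1] <= o.time_sample_ids[-1] for o in occs
        )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(datasets())
def test_support_shrinks_along_tree_extensions(dataset):
    from hugseq.oracle import enumerate_patterns
    from conftest import is_tree_ancestor

    stats = enumerate_patterns(dataset, max_size=2)
    sup = {s.pattern: s.support for s in stats}
    pats = list(sup)
    for alpha in pats:
        for beta in pats:
            if alpha != beta and is_tree_ancestor(alpha, beta):
                assert sup[beta] <= sup[alpha]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(datasets())
def test_whole_sequence_utility_sums_item_utilities(dataset):
    for patient in dataset.patients:
        expected = sum(
            item_utility(Item(g, d, iu), dataset.importance)
            for gs in patient.genesets
            for (g, d), iu in gs.items.items()
        )
        got = sequence_total_utility(patient, dataset.importance)
        assert got == pytest.approx(expected, abs=TOL)
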