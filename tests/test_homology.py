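import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hubseq.homology import (
    BlastBackend,
    HomologyHit,
    HomologyHitList,
    SearchConfig,
    SmithWatermanBackend,
    call_hub_status,
    classify_by_top_hit,
    estimate_interactors,
    parse_blast_tabular,
    search,
    search_many,
)
from hubseq.sequence_io import AMINO_ACIDS, LabelTable, LabeledDataset, ProteinRecord
from hubseq.synthetic_data import mutate_family


def reference_dataset(seqs_with_labels):
    """(id, residues, hub_status, interactor_count) rows -> LabeledDataset."""
    records, rows = [], []
    for ident, seq, status, n in seqs_with_labels:
        records.append(ProteinRecord(ident, seq))
        rows.append({"id": ident, "hub_status": status, "interactor_count": n})
    return LabeledDataset(
        records=records, labels=LabelTable.from_records(rows),
        class_field="hub_status", binary=False,
    )


@pytest.fixture(scope="module")
def family_reference():
    rng = np.random.default_rng(5150)
    seed = ProteinRecord("seed", "".join(rng.choice(list(AMINO_ACIDS), 120)))
    fam = mutate_family(seed, 0.9, 4, 6)
    unrelated = ProteinRecord("far", "".join(rng.choice(list(AMINO_ACIDS), 120)))
    rows = [
        (fam[0].id, fam[0].residues, "hub", 8),
        (fam[1].id, fam[1].residues, "hub", 6),
        (fam[2].id, fam[2].residues, "hub", 10),
        (fam[3].id, fam[3].residues, "non_hub", 1),
        (unrelated.id, unrelated.residues, "non_hub", 2),
    ]
    return seed, reference_dataset(rows)


class TestSearch:
    def test_identical_sequence_is_top_hit(self, family_reference):
        seed, ref = family_reference
        query = ProteinRecord("q_same", ref.records[0].residues)
        hits = search(query, ref)
        assert hits.hits and hits.hits[0].subject_id == ref.records[0].id

    def test_self_hit_excluded(self, family_reference):
        _, ref = family_reference
        hits = search(ref.records[0], ref)
        assert all(h.subject_id != ref.records[0].id for h in hits.hits)

    def test_repeated_search_is_deterministic(self, family_reference):
        seed, ref = family_reference
        h1 = search(seed, ref)
        h2 = search(seed, ref)
        assert h1.hits == h2.hits

    def test_hits_sorted_by_evalue_then_bitscore(self, family_reference):
        seed, ref = family_reference
        hits = search(seed, ref).hits
        keys = [(h.e_value, -h.bit_score, h.subject_id) for h in hits]
        assert keys == sorted(keys)

    def test_random_queries_rarely_hit_unrelated_references(self):
        rng = np.random.default_rng(777)
        ref = reference_dataset(
            [(f"r{i}", "".join(rng.choice(list(AMINO_ACIDS), 100)), "hub", 6) for i in range(30)]
        )
        backend = SmithWatermanBackend()
        queries = [
            ProteinRecord(f"q{i}", "".join(rng.choice(list(AMINO_ACIDS), 100)))
            for i in range(100)
        ]
        lists = search_many(queries, ref, backend=backend)
        empty = sum(1 for q in queries if not lists[q.id].hits)
        assert empty >= 99

    def test_empty_reference_rejected(self):
        ref = reference_dataset([("r0", "ACDEF", "hub", 6)])
        ref.records = []
        with pytest.raises(ValueError):
            search(ProteinRecord("q", "ACDEF"), ref)

    def test_hits_carry_subject_labels_and_interactors(self, family_reference):
        seed, ref = family_reference
        hits = search(seed, ref).hits
        assert all(h.subject_class in ("hub", "non_hub") for h in hits)
        assert all(h.subject_interactors is not None for h in hits)


class TestTopHitRule:
    def test_matching_top_hit_gives_one(self):
        hits = HomologyHitList("q", [HomologyHit("s", 1e-30, 100.0, subject_class="hub")])
        assert classify_by_top_hit(hits, "hub") == 1

    def test_mismatching_top_hit_gives_zero(self):
        hits = HomologyHitList("q", [HomologyHit("s", 1e-30, 100.0, subject_class="non_hub")])
        assert classify_by_top_hit(hits, "hub") == 0

    def test_no_hits_gives_zero(self):
        assert classify_by_top_hit(HomologyHitList("q", []), "hub") == 0


def _hits(classes, counts=None, bits=None):
    counts = counts or [None] * len(classes)
    bits = bits or [100.0 - i for i in range(len(classes))]
    return HomologyHitList(
        "q",
        [
            HomologyHit(f"s{i}", 1e-30 * (i + 1), b, subject_class=c, subject_interactors=n)
            for i, (c, n, b) in enumerate(zip(classes, counts, bits))
        ],
    )


class TestHubCall:
    @pytest.mark.parametrize(
        "classes,expected",
        [
            (["hub"] * 4, "hub"),
            (["non_hub"] * 4, "non_hub"),
            (["hub", "hub", "hub", "non_hub"], "likely_hub"),
            (["non_hub", "non_hub", "non_hub", "hub"], "likely_non_hub"),
            (["hub", "hub", "non_hub", "non_hub"], "unknown"),
            (["hub", "hub", "hub"], "likely_hub"),
            (["non_hub"], "likely_non_hub"),
            (["hub", "non_hub"], "unknown"),
            ([], "unknown"),
        ],
    )
    def test_truth_table(self, classes, expected):
        assert call_hub_status(_hits(classes)).status == expected

    def test_never_definite_below_four_hits(self):
        for n in (1, 2, 3):
            for combo in itertools.product(["hub", "non_hub"], repeat=n):
                status = call_hub_status(_hits(list(combo))).status
                assert status in ("likely_hub", "likely_non_hub", "unknown")

    def test_only_top_four_hits_are_considered(self):
        hits = _hits(["hub", "hub", "hub", "hub", "non_hub"])
        assert call_hub_status(hits).status == "hub"

    def test_non_hub_labels_rejected(self):
        with pytest.raises(ValueError):
            call_hub_status(_hits(["hub", "SIH"]))

    def test_call_carries_interactor_summaries(self):
        call = call_hub_status(_hits(["hub"] * 4, counts=[2, 4, 6, 8], bits=[50.0] * 4))
        assert call.status == "hub"
        assert call.interactor_range == (2, 8)
        assert call.interactor_range[0] <= call.weighted_estimate <= call.interactor_range[1]


class TestInteractorEstimate:
    def test_equal_weights_reduce_to_mean(self):
        _, rng, est = estimate_interactors(_hits(["hub"] * 4, [2, 4, 6, 8], [50.0] * 4))
        assert est == pytest.approx(5.0)
        assert rng == (2, 8)

    def test_single_hit(self):
        top, rng, est = estimate_interactors(_hits(["hub"], [7], [50.0]))
        assert (top, rng, est) == (7, (7, 7), 7.0)

    def test_bit_score_weighted_mean(self):
        _, _, est = estimate_interactors(_hits(["hub", "hub"], [10, 2], [30.0, 10.0]))
        assert est == pytest.approx((300 + 20) / 40)  # = 8.0

    def test_no_interactor_data_leaves_estimate_unset(self):
        assert estimate_interactors(_hits(["hub", "hub"])) == (None, None, None)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=4),
        scale=st.floats(min_value=0.01, max_value=100.0),
        data=st.data(),
    )
    def test_estimate_invariant_to_uniform_weight_scaling(self, counts, scale, data):
        bits = data.draw(
            st.lists(
                st.floats(min_value=1.0, max_value=500.0),
                min_size=len(counts),
                max_size=len(counts),
            )
        )
        base = estimate_interactors(_hits(["hub"] * len(counts), counts, bits))[2]
        scaled = estimate_interactors(
            _hits(["hub"] * len(counts), counts, [b * scale for b in bits])
        )[2]
        assert scaled == pytest.approx(base, rel=1e-9)


class TestBlastBackend:
    OUTFMT6 = (
        "q1\ts1\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-50\t180\n"
        "q1\ts2\t40.0\t90\t54\t2\t5\t94\t3\t92\t2e-06\t45\n"
        "q2\ts1\t38.0\t80\t50\t1\t1\t80\t1\t80\t9e-05\t40\n"
    )

    def test_parse_tabular(self):
        rows = parse_blast_tabular(self.OUTFMT6)
        assert ("q1", "s1", 1e-50, 180.0) in rows
        assert len(rows) == 3

    def test_parse_keeps_best_row_per_pair(self):
        text = self.OUTFMT6 + "q1\ts1\t90.0\t50\t5\t0\t1\t50\t1\t50\t1e-20\t90\n"
        rows = parse_blast_tabular(text)
        assert ("q1", "s1", 1e-50, 180.0) in rows
        assert len(rows) == 3

    def test_malformed_line_rejected(self):
        with pytest.raises(Exception):
            parse_blast_tabular("q1\ts1\tbroken\n")

    def test_live_blast_agrees_with_builtin_on_top_hit(self, family_reference):
        backend = BlastBackend()
        if not backend.available():
            pytest.fail("BLAST+ not on PATH; external backend cannot be exercised")
        seed, ref = family_reference
        query = ProteinRecord("q_fam", ref.records[0].residues)
        blast_hits = search(query, ref, backend=backend)
        builtin_hits = search(query, ref)
        assert blast_hits.hits, "expected significant hits for a family member"
        assert blast_hits.hits[0].subject_id == builtin_hits.hits[0].subject_id
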