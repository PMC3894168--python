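"""Leakage-free dataset construction: purge, dedup, overlap removal."""

from __future__ import annotations

import numpy as np
import pytest

from snpconsensus import (
    AlignedFragmentPair,
    BlastTabularAligner,
    FormatError,
    MutationRecord,
    OverlapSpec,
    PairwiseLocalAligner,
    ValidationError,
    build_independent_dataset,
    deduplicate,
    find_overlapping_positions,
    label_by_activity,
    label_pmd,
    purge_conflicts,
    remove_overlaps,
)
from snpconsensus.records import AMINO_ACIDS


def _mut(pid, pos, label, source="src", wt="A", mut="V"):
    return MutationRecord(pid, pos, wt, mut, label, source)


def _random_protein(rng, length=200):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


class TestPurgeConflicts:
    def test_conflicting_key_removed_entirely(self):
        records = [
            _mut("P1", 10, "neutral", "dbA"),
            _mut("P1", 10, "deleterious", "dbB"),
            _mut("P2", 5, "neutral", "dbA"),
        ]
        kept = purge_conflicts(records)
        assert [r.key for r in kept] == [("P2", 5, "A", "V")]

    def test_no_conflicts_is_identity(self):
        records = [_mut("P1", 10, "neutral"), _mut("P2", 5, "deleterious")]
        assert purge_conflicts(records) == records

    def test_five_records_one_conflicting_pair_leaves_three(self):
        records = [
            _mut("P1", 1, "neutral", "a"),
            _mut("P1", 1, "deleterious", "b"),
            _mut("P1", 2, "neutral", "a"),
            _mut("P2", 1, "deleterious", "a"),
            _mut("P3", 9, "neutral", "c"),
        ]
        assert len(purge_conflicts(records)) == 3

    def test_idempotent(self):
        records = [
            _mut("P1", 1, "neutral", "a"),
            _mut("P1", 1, "deleterious", "b"),
            _mut("P2", 2, "neutral", "a"),
            _mut("P2", 2, "neutral", "b"),
        ]
        once = purge_conflicts(records)
        assert purge_conflicts(once) == once


class TestDeduplicate:
    def test_three_sources_collapse_to_one_record(self):
        records = [
            _mut("P1", 10, "neutral", s) for s in ("dbB", "dbA", "dbC")
        ]
        (survivor,) = deduplicate(records)
        assert survivor.source == "dbA,dbB,dbC"
        assert survivor.label == "neutral"

    def test_unique_keys_are_identity_up_to_order(self):
        records = [_mut("P2", 5, "neutral"), _mut("P1", 10, "deleterious")]
        assert {r.key for r in deduplicate(records)} == {
            r.key for r in records
        }

    def test_ten_records_over_seven_keys(self):
        records = [
            _mut(f"P{i}", 1, "neutral", f"s{j}")
            for i, j in [(1, 1), (1, 2), (2, 1), (3, 1), (3, 2), (3, 3),
                         (4, 1), (5, 1), (6, 1), (7, 1)]
        ]
        assert len(deduplicate(records)) == 7

    def test_conflicting_duplicates_are_a_contract_violation(self):
        records = [
            _mut("P1", 10, "neutral", "a"),
            _mut("P1", 10, "deleterious", "b"),
        ]
        with pytest.raises(Exception, match="purge_conflicts"):
            deduplicate(records)

    def test_idempotent(self):
        records = [
            _mut("P1", 10, "neutral", "b"),
            _mut("P1", 10, "neutral", "a"),
            _mut("P2", 4, "deleterious", "a"),
        ]
        once = deduplicate(records)
        assert deduplicate(once) == once

    def test_random_fixtures_idempotence_and_order_invariance(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            records = [
                _mut(
                    f"P{rng.integers(1, 5)}",
                    int(rng.integers(1, 4)),
                    str(rng.choice(["neutral", "deleterious"])),
                    f"s{rng.integers(1, 4)}",
                )
                for _ in range(n)
            ]
            purged = purge_conflicts(records)
            assert purge_conflicts(purged) == purged
            deduped = deduplicate(purged)
            assert deduplicate(deduped) == deduped
            shuffled = list(purged)
            rng.shuffle(shuffled)
            assert deduplicate(shuffled) == deduped


class TestLabeling:
    @pytest.mark.parametrize(
        "tokens, expected",
        [
            ({"="}, "neutral"),
            ({"++"}, "deleterious"),
            ({"-", "--"}, "deleterious"),
            ({"=", "++"}, "excluded"),
        ],
    )
    def test_pmd_annotation_rules(self, tokens, expected):
        assert label_pmd(tokens) == expected

    def test_empty_token_set_rejected(self):
        with pytest.raises(FormatError):
            label_pmd(set())

    @pytest.mark.parametrize(
        "change, expected",
        [(0.51, "deleterious"), (0.50, "neutral"), (0.0, "neutral")],
    )
    def test_activity_threshold_is_strict(self, change, expected):
        assert label_by_activity(change) == expected

    def test_negative_change_rejected(self):
        with pytest.raises(ValidationError):
            label_by_activity(-0.1)


class FakeAligner:
    """Fragment producer returning a fixed fragment for every pair."""

    def __init__(self, fragments):
        self.fragments = fragments

    def __call__(self, qid, qseq, sid, sseq):
        return [f for f in self.fragments
                if f.query_id == qid and f.subject_id == sid]


def _fragment(identity, evalue=1e-20, n=20):
    return AlignedFragmentPair(
        query_id="Q", subject_id="R",
        query_start=1, query_end=n, subject_start=1, subject_end=n,
        column_map=tuple((i, i) for i in range(1, n + 1)),
        identity=identity, evalue=evalue,
    )


class TestOverlapDetection:
    def test_identical_sequences_overlap_at_mutated_position(self):
        rng = np.random.default_rng(0)
        seq = _random_protein(rng)
        overlaps = find_overlapping_positions(
            {("Q", 10)}, {"Q": seq}, {("Q", 10)}, {"Q": seq},
            PairwiseLocalAligner(),
        )
        assert ("Q", 10) in overlaps

    def test_homologous_sequences_map_positions_through_alignment(self):
        rng = np.random.default_rng(1)
        seq = _random_protein(rng)
        # same sequence under a different identifier: alignment, not the
        # direct-identifier rule, must transmit the overlap
        overlaps = find_overlapping_positions(
            {("Q", 17), ("Q", 60)}, {"Q": seq}, {("R", 17)}, {"R": seq},
            PairwiseLocalAligner(),
        )
        assert overlaps == {("Q", 17)}

    def test_identity_just_below_half_contributes_nothing(self):
        overlaps = find_overlapping_positions(
            {("Q", 5)}, {"Q": "A" * 30}, {("R", 5)}, {"R": "A" * 30},
            FakeAligner([_fragment(identity=0.49)]),
        )
        assert overlaps == set()

    def test_identity_threshold_inclusive_at_half(self):
        overlaps = find_overlapping_positions(
            {("Q", 5)}, {"Q": "A" * 30}, {("R", 5)}, {"R": "A" * 30},
            FakeAligner([_fragment(identity=0.50)]),
        )
        assert overlaps == {("Q", 5)}

    def test_evalue_above_threshold_contributes_nothing(self):
        overlaps = find_overlapping_positions(
            {("Q", 5)}, {"Q": "A" * 30}, {("R", 5)}, {"R": "A" * 30},
            FakeAligner([_fragment(identity=0.9, evalue=1e-5)]),
        )
        assert overlaps == set()

    def test_unrelated_random_sequences_do_not_overlap(self):
        rng = np.random.default_rng(7)
        q, r = _random_protein(rng), _random_protein(rng)
        overlaps = find_overlapping_positions(
            {("Q", p) for p in range(1, 201, 10)}, {"Q": q},
            {("R", p) for p in range(1, 201, 10)}, {"R": r},
            PairwiseLocalAligner(),
        )
        assert overlaps == set()

    def test_missing_sequence_names_the_protein(self):
        with pytest.raises(Exception, match="Q"):
            find_overlapping_positions(
                {("Q", 1)}, {}, {("R", 1)}, {"R": "A" * 30},
                PairwiseLocalAligner(),
            )

    def test_loosening_spec_never_shrinks_the_overlap_set(self):
        frags = [_fragment(identity=0.55, evalue=1e-12),
                 _fragment(identity=0.45, evalue=1e-30)]
        strict = find_overlapping_positions(
            {("Q", 5)}, {"Q": "A" * 30}, {("R", 5)}, {"R": "A" * 30},
            FakeAligner(frags), OverlapSpec(1e-10, 0.5),
        )
        loose = find_overlapping_positions(
            {("Q", 5)}, {"Q": "A" * 30}, {("R", 5)}, {"R": "A" * 30},
            FakeAligner(frags), OverlapSpec(1e-3, 0.4),
        )
        assert strict <= loose


class TestRemoveOverlaps:
    def test_empty_overlap_set_is_identity(self):
        records = [_mut("P1", 1, "neutral")]
        kept, removed = remove_overlaps(records, set())
        assert kept == records and removed == {}

    def test_all_positions_overlapping_empties_the_dataset(self):
        records = [_mut("P1", i, "neutral") for i in range(1, 4)]
        kept, removed = remove_overlaps(
            records, {("P1", i) for i in range(1, 4)}
        )
        assert kept == [] and removed == {"src": 3}

    def test_counting(self):
        records = [_mut("P1", i, "neutral") for i in range(1, 101)]
        overlapping = {("P1", i) for i in range(1, 24)}
        kept, removed = remove_overlaps(records, overlapping)
        assert len(kept) == 77 and removed["src"] == 23


class TestBlastTabularAligner:
    def test_gapless_hsp_maps_linearly(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "Q\tR\t80.0\t50\t10\t0\t11\t60\t101\t150\t1e-30\t120\n"
        )
        aligner = BlastTabularAligner(path)
        (frag,) = aligner("Q", "", "R", "")
        assert frag.identity == pytest.approx(0.8)
        assert frag.evalue == 1e-30
        assert (11, 101) in frag.column_map
        assert (60, 150) in frag.column_map

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("Q\tR\t80.0\n")
        with pytest.raises(FormatError, match="12"):
            BlastTabularAligner(path)

    def test_gapped_hsp_without_sequences_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "Q\tR\t80.0\t50\t5\t1\t11\t60\t101\t148\t1e-30\t120\n"
        )
        aligner = BlastTabularAligner(path)
        with pytest.raises(FormatError, match="gapped"):
            aligner("Q", "", "R", "")


class TestBuildPipeline:
    def _sources(self, rng):
        """Three sources with planted duplicates, conflicts and overlaps."""
        protein = _random_protein(rng, 120)
        other = _random_protein(rng, 120)
        clean = [
            _mut("P1", p, "neutral", "srcA") for p in (5, 15, 25)
        ] + [
            _mut("P1", p, "deleterious", "srcB") for p in (35, 45)
        ]
        duplicates = [_mut("P1", 5, "neutral", "srcB")]  # same key as srcA:5
        conflict = [
            _mut("P2", 7, "neutral", "srcA"),
            _mut("P2", 7, "deleterious", "srcB"),
        ]
        overlapping = [_mut("P1", 60, "neutral", "srcC")]  # in training set
        sources = [
            clean[:3] + conflict[:1],
            clean[3:] + duplicates + conflict[1:],
            overlapping,
        ]
        seqs = {"P1": protein, "P2": other}
        return sources, seqs

    def test_planted_fixture_counts_match_stage_by_stage(self):
        rng = np.random.default_rng(3)
        sources, seqs = self._sources(rng)
        dataset, audit = build_independent_dataset(
            sources,
            training_positions={("P1", 60)},
            training_sequences={"P1": seqs["P1"]},
            holdout_positions=set(),
            holdout_sequences={},
            query_sequences=seqs,
            aligner=PairwiseLocalAligner(),
        )
        stages = audit.as_dict()
        assert stages["concatenated"] == 9
        assert stages["after_conflict_purge"] == 7  # conflict pair removed
        assert stages["after_deduplication"] == 6  # one duplicate merged
        assert stages["after_training_overlap_removal"] == 5
        assert stages["after_holdout_overlap_removal"] == 5
        assert {r.key for r in dataset} == {
            ("P1", 5, "A", "V"), ("P1", 15, "A", "V"), ("P1", 25, "A", "V"),
            ("P1", 35, "A", "V"), ("P1", 45, "A", "V"),
        }
        merged = {r.key: r.source for r in dataset}
        assert merged[("P1", 5, "A", "V")] == "srcA,srcB"

    def test_built_dataset_has_no_residual_overlap(self):
        rng = np.random.default_rng(3)
        sources, seqs = self._sources(rng)
        training_positions = {("P1", 60)}
        dataset, _ = build_independent_dataset(
            sources,
            training_positions=training_positions,
            training_sequences={"P1": seqs["P1"]},
            holdout_positions=set(),
            holdout_sequences={},
            query_sequences=seqs,
            aligner=PairwiseLocalAligner(),
        )
        residual = find_overlapping_positions(
            {(r.protein_id, r.position) for r in dataset},
            seqs,
            training_positions,
            {"P1": seqs["P1"]},
            PairwiseLocalAligner(),
        )
        assert residual == set()

    def test_disjoint_sources_union(self):
        sources = [
            [_mut("P1", 1, "neutral", "a")],
            [_mut("P2", 2, "deleterious", "b")],
        ]
        dataset, audit = build_independent_dataset(
            sources, set(), {}, set(), {},
            {"P1": "A" * 30, "P2": "A" * 30},
            PairwiseLocalAligner(),
        )
        assert len(dataset) == 2
        assert audit.as_dict()["after_holdout_overlap_removal"] == 2

    def test_build_is_order_invariant(self):
        rng = np.random.default_rng(3)
        sources, seqs = self._sources(rng)
        kwargs = dict(
            training_positions={("P1", 60)},
            training_sequences={"P1": seqs["P1"]},
            holdout_positions=set(),
            holdout_sequences={},
            query_sequences=seqs,
            aligner=PairwiseLocalAligner(),
        )
        forward, _ = build_independent_dataset(sources, **kwargs)
        backward, _ = build_independent_dataset(sources[::-1], **kwargs)
        assert forward == backward
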