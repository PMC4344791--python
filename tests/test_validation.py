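import numpy as np
import pandas as pd
import pytest
from Bio import Align

from wheattf.corpus import ESTRecord, StageCategory, TissueCategory
from wheattf.specificity import PresenceMatrix, category_names, classify_specific
from wheattf.validation import (
    AlignmentHit,
    ChangeLogEntry,
    is_matched,
    local_align,
    read_tabular_hits,
    recover_filtered,
    replay_change_log,
    update_from_matches,
)


def _matrix(axis, rows):
    data = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=category_names(axis)).astype(int)
    return PresenceMatrix(axis, data)


class TestLocalAlign:
    def test_identical_sequences(self):
        s = "ACGTACGTACGTACGTACGTACGTACGTAC"
        hit = local_align(("q", s), ("s", s))
        assert hit.identity == 1.0
        assert hit.aln_length == 30

    def test_three_interior_substitutions(self):
        a = "ACGTACGTACGTACGTACGTACGTACGTAC"
        b = list(a)
        for i in (8, 15, 22):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        hit = local_align(("q", a), ("s", "".join(b)))
        assert hit.aln_length == 30
        assert hit.identity == pytest.approx(27 / 30)

    def test_unrelated_sequences_short_chance_alignment(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), size=30))
        b = "".join(rng.choice(list("ACGT"), size=30))
        hit = local_align(("q", a), ("s", b))
        assert hit.aln_length < 30       # only a short chance alignment
        assert hit.aln_length >= 1       # but a hit is still returned

    def test_score_matches_independent_aligner(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -3
        aligner.extend_gap_score = -1
        from wheattf.redundancy import smith_waterman

        rng = np.random.default_rng(13)
        for _ in range(50):
            n, m = rng.integers(10, 50, size=2)
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = "".join(rng.choice(list("ACGT"), size=m))
            assert smith_waterman(a, b).score == pytest.approx(
                aligner.score(a, b)
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            local_align(("q", ""), ("s", "ACGT"))


class TestIsMatched:
    def _hit(self, ratio, identity, qlen, slen):
        return AlignmentHit("q", "s", identity, int(round(ratio * qlen)),
                            qlen, slen, "L1")

    def test_all_criteria_met(self):
        assert is_matched(self._hit(0.96, 0.85, 100, 120)) is True

    def test_coverage_bound_is_strict(self):
        # alignment/query exactly 0.95 fails criterion (i)
        assert is_matched(AlignmentHit("q", "s", 0.99, 95, 100, 120, "L1")) \
            is False

    def test_identity_bound_is_inclusive_but_length_strict(self):
        # identity exactly 0.80 passes (ii); equal lengths fail (iii)
        assert is_matched(AlignmentHit("q", "s", 0.80, 99, 100, 100, "L1")) \
            is False
        assert is_matched(AlignmentHit("q", "s", 0.80, 99, 100, 101, "L1")) \
            is True


class TestUpdateFromMatches:
    def _setup(self):
        matrix = _matrix("stage", {"T1": [0, 0, 0, 0, 1, 0, 0]})  # seedling
        tf_by_query = {"e1": "T1"}
        cats = {"LV": StageCategory.VEGETATIVE, "LS": StageCategory.SEEDLING}
        return matrix, tf_by_query, cats

    def test_new_category_flips_specific_to_unspecific(self):
        matrix, tf_by_query, cats = self._setup()
        hit = AlignmentHit("e1", "s1", 0.99, 99, 100, 120, "LV")
        updated, log = update_from_matches(tf_by_query, matrix, [hit], cats,
                                           "stage")
        assert updated.data.loc["T1", "vegetative"] == 1
        assert classify_specific(updated)["T1"].kind == "unspecific"
        assert len(log) == 1
        assert log[0] == ChangeLogEntry("T1", "stage", "vegetative", "s1",
                                        "blast_update")

    def test_same_category_is_noop(self):
        matrix, tf_by_query, cats = self._setup()
        hit = AlignmentHit("e1", "s1", 0.99, 99, 100, 120, "LS")
        updated, log = update_from_matches(tf_by_query, matrix, [hit], cats,
                                           "stage")
        assert log == []
        assert updated.data.equals(matrix.data)

    def test_unmatched_hit_ignored(self):
        matrix, tf_by_query, cats = self._setup()
        weak = AlignmentHit("e1", "s1", 0.5, 99, 100, 120, "LV")
        updated, log = update_from_matches(tf_by_query, matrix, [weak], cats,
                                           "stage")
        assert log == []

    def test_unknown_tf_rejected(self):
        matrix, tf_by_query, cats = self._setup()
        hit = AlignmentHit("zz", "s1", 0.99, 99, 100, 120, "LV")
        with pytest.raises(KeyError):
            update_from_matches({}, matrix, [hit], cats, "stage")

    def test_monotone_and_idempotent(self):
        matrix, tf_by_query, cats = self._setup()
        hits = [AlignmentHit("e1", "s1", 0.99, 99, 100, 120, "LV")]
        once, log1 = update_from_matches(tf_by_query, matrix, hits, cats,
                                         "stage")
        twice, log2 = update_from_matches(tf_by_query, once, hits, cats,
                                          "stage")
        assert twice.data.equals(once.data)
        assert log2 == []
        assert (once.data.to_numpy() >= matrix.data.to_numpy()).all()


class TestRecoverFiltered:
    def _setup(self):
        matrices = {
            "stage": _matrix("stage", {"T1": [0, 0, 0, 0, 1, 0, 0]}),
            "tissue": _matrix("tissue", {"T1": [0, 0, 0, 1, 0, 0, 0]}),
        }
        cats = {
            "stage": {"LA": StageCategory.SEEDLING,
                      "LB": StageCategory.RIPENING},
            "tissue": {"LA": TissueCategory.ROOT, "LB": TissueCategory.LEAF},
        }
        return matrices, cats

    def test_filtered_tf_donates_categories(self):
        matrices, cats = self._setup()
        dup = ESTRecord("d1", "ACGT" * 20, "LB")
        updated, log = recover_filtered(
            [dup], {"d1": "e1"}, {"e1": "T1"}, lambda est: True,
            matrices, cats,
        )
        assert updated["stage"].data.loc["T1", "ripening"] == 1
        assert updated["tissue"].data.loc["T1", "leaf"] == 1
        assert {(e.axis, e.category) for e in log} == {
            ("stage", "ripening"), ("tissue", "leaf")
        }

    def test_same_category_is_noop(self):
        matrices, cats = self._setup()
        dup = ESTRecord("d1", "ACGT" * 20, "LA")
        updated, log = recover_filtered(
            [dup], {"d1": "e1"}, {"e1": "T1"}, lambda est: True,
            matrices, cats,
        )
        assert log == []

    def test_non_tf_filtered_sequence_ignored(self):
        matrices, cats = self._setup()
        dup = ESTRecord("d1", "ACGT" * 20, "LB")
        updated, log = recover_filtered(
            [dup], {"d1": "e1"}, {"e1": "T1"}, lambda est: False,
            matrices, cats,
        )
        assert log == []

    def test_representative_not_a_tf_ignored(self):
        matrices, cats = self._setup()
        dup = ESTRecord("d1", "ACGT" * 20, "LB")
        updated, log = recover_filtered(
            [dup], {"d1": "e9"}, {"e1": "T1"}, lambda est: True,
            matrices, cats,
        )
        assert log == []

    def test_unmapped_filtered_est_rejected(self):
        matrices, cats = self._setup()
        dup = ESTRecord("d1", "ACGT" * 20, "LB")
        with pytest.raises(KeyError):
            recover_filtered([dup], {}, {}, lambda est: True, matrices, cats)


def test_change_log_replay_reproduces_final(pipeline_result):
    """Replaying the recorded change log from scratch-built initial matrices
    must land exactly on the final matrices."""
    from wheattf.specificity import build_presence
    # rebuild the initial (pre-validation, pre-recovery) matrices
    res = pipeline_result
    for axis in ("stage", "tissue"):
        final = res.matrices[axis]
        initial = final.copy()
        for entry in res.change_log:
            if entry.axis == axis:
                initial.data.loc[entry.tf_id, entry.category] = 0
        # the log only ever sets bits, so clearing them and replaying
        # must reproduce the final matrix
        replayed = replay_change_log(initial, res.change_log)
        assert replayed.data.equals(final.data)


def test_read_tabular_hits_normalises_percent_identity(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "q1\ts1\t98.5\t100\t1\t0\t1\t100\t1\t100\t1e-50\t180\n"
        "q1\ts2\t0.85\t90\t10\t0\t1\t90\t1\t90\t1e-20\t80\n"
    )
    hits = read_tabular_hits(
        path,
        subject_libraries={"s1": "L1", "s2": "L2"},
        query_lengths={"q1": 100},
        subject_lengths={"s1": 120, "s2": 95},
    )
    assert hits[0].identity == pytest.approx(0.985)
    assert hits[1].identity == pytest.approx(0.85)
    assert hits[0].subject_library_id == "L1"
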