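"""Knowledge-base retrieval: blended similarity and candidate pooling."""

import numpy as np
import pytest

from tcmgen.corpus import DataPair
from tcmgen.tkmm import (HerbCandidatePool, KnowledgeBase, blended_similarity,
                         build_kb, select_candidates)


def toy_kb(reps, prescriptions=None):
    reps = np.asarray(reps, dtype=float)
    n = len(reps)
    prescriptions = prescriptions or [[f"H{i}a", f"H{i}b"] for i in range(n)]
    pairs = [DataPair([f"s{i}"], prescriptions[i], source_id=str(i))
             for i in range(n)]
    return build_kb(pairs, lambda toks: reps[int(toks[0][1:])])


class TestBlendedSimilarity:
    def test_self_match_is_minimal_zero(self):
        reps = np.array([[1.0, 2.0], [3.0, -1.0]])
        sims = blended_similarity(reps[0], reps)
        assert sims[0] == pytest.approx(0.0, abs=1e-12)
        assert sims[1] > 0

    def test_pure_cosine_blend(self, rng):
        reps = rng.normal(size=(5, 3))
        cs = rng.normal(size=3)
        sims = blended_similarity(cs, reps, lambda1=1.0, lambda2=0.0)
        cos = reps @ cs / (np.linalg.norm(reps, axis=1) * np.linalg.norm(cs))
        assert np.allclose(sims, 1.0 - cos)

    def test_hand_arithmetic_with_max_ed_normalisation(self):
        cs = np.array([1.0, 0.0])
        reps = np.array([[1.0, 0.0], [0.0, 1.0]])
        sims = blended_similarity(cs, reps, 0.4, 0.6)
        # to (0,1): 0.4*(1-0) + 0.6*(sqrt2/sqrt2) = 1.0 ; to itself: 0
        assert sims[1] == pytest.approx(1.0)
        assert sims[0] == pytest.approx(0.0, abs=1e-12)

    def test_lambda_sum_enforced(self):
        with pytest.raises(ValueError, match="lambda"):
            blended_similarity(np.ones(2), np.ones((1, 2)), 0.4, 0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            blended_similarity(np.zeros(2), np.ones((1, 2)))

    def test_nonnegative(self, rng):
        reps = rng.normal(size=(30, 4))
        sims = blended_similarity(rng.normal(size=4), reps)
        assert np.all(sims >= -1e-12)


class TestSelectCandidates:
    def test_k_equals_d_pools_every_herb(self):
        kb = toy_kb([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        pool = select_candidates(kb, np.array([1.0, 0.2]), k=3)
        assert set(pool.herbs) == {h for r in kb.records for h in r.prescription}

    def test_exact_match_ranks_first(self):
        kb = toy_kb([[2.0, 1.0], [0.0, 3.0], [-1.0, 1.0]])
        pool = select_candidates(kb, np.array([0.0, 3.0]), k=1)
        assert pool.source_record_ids == [1]
        assert pool.scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_first_occurrence_union_order(self):
        kb = toy_kb([[1.0, 0.0], [0.9, 0.1]],
                    prescriptions=[["A", "B"], ["B", "C"]])
        pool = select_candidates(kb, np.array([1.0, 0.0]), k=2)
        assert pool.herbs == ["A", "B", "C"]
        assert pool.scores == sorted(pool.scores)

    def test_k_exceeding_kb_raises(self):
        kb = toy_kb([[1.0, 0.0]])
        with pytest.raises(ValueError, match="k=2"):
            select_candidates(kb, np.array([1.0, 0.0]), k=2)

    def test_self_exclusion(self):
        kb = toy_kb([[1.0, 0.0], [0.8, 0.6]])
        pool = select_candidates(kb, np.array([1.0, 0.0]), k=1,
                                 exclude_source_id="0")
        assert pool.source_record_ids == [1]

    def test_duplicating_unselected_records_is_invariant(self, rng):
        reps = rng.normal(size=(20, 4))
        kb = toy_kb(reps)
        q = reps[3] + 0.01 * rng.normal(size=4)
        base = select_candidates(kb, q, k=5)
        # append copies of records that were not selected
        far = [i for i in range(20) if i not in base.source_record_ids][:3]
        reps2 = np.vstack([reps, reps[far]])
        presc = [kb.records[i].prescription for i in range(20)] + \
                [kb.records[i].prescription for i in far]
        kb2 = toy_kb(reps2, presc)
        again = select_candidates(kb2, q, k=5)
        assert again.source_record_ids == base.source_record_ids

    def test_matches_brute_force_full_sort(self, rng):
        """Exact index agreement with an independent full-sort oracle on a
        200-record KB across 50 queries."""
        reps = rng.normal(size=(200, 8))
        kb = toy_kb(reps)
        for _ in range(50):
            q = rng.normal(size=8)
            got = select_candidates(kb, q, k=20).source_record_ids
            cos = reps @ q / (np.linalg.norm(reps, axis=1) * np.linalg.norm(q))
            ed = np.linalg.norm(reps - q, axis=1)
            sims = 0.4 * (1 - cos) + 0.6 * ed / ed.max()
            want = list(np.argsort(sims, kind="stable")[:20])
            assert got == want


class TestBuildKb:
    def test_one_record_per_pair_in_order(self, tiny_model):
        kb = tiny_model.build_kb()
        assert len(kb) == len(tiny_model.sp_pairs)
        assert kb.records[0].source_id == tiny_model.sp_pairs[0].source_id

    def test_rebuild_is_identical(self, tiny_model):
        k1 = tiny_model.build_kb()
        k2 = tiny_model.build_kb()
        assert np.array_equal(k1.reps, k2.reps)

    def test_same_syndrome_representations_cluster(self, tiny_model):
        """Mean cosine within a syndrome exceeds the cross-syndrome mean,
        even for an untrained encoder (shared tokens drive the states)."""
        kb = tiny_model.build_kb()
        z = np.array([int(r.source_id[1]) for r in kb.records])
        reps = kb.reps / np.linalg.norm(kb.reps, axis=1, keepdims=True)
        cos = reps @ reps.T
        mask_same = (z[:, None] == z[None, :]) & ~np.eye(len(z), dtype=bool)
        mask_cross = z[:, None] != z[None, :]
        assert cos[mask_same].mean() > cos[mask_cross].mean()

    def test_encoder_failure_names_record(self):
        pairs = [DataPair(["ok"], ["H1"]), DataPair(["bad"], ["H2"])]

        def rep(toks):
            if toks == ["bad"]:
                raise RuntimeError("boom")
            return np.ones(3)

        with pytest.raises(RuntimeError, match="record 1"):
            build_kb(pairs, rep)
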