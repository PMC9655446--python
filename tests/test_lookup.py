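"""Similarity ranking, threshold acceptance, and top-R voting."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import herdface as hf
from herdface.exceptions import EmptyGalleryError, InvalidInputError
from herdface.lookup import UNIDENTIFIED, apply_threshold, rank, vote_top_r


def tiny_gallery(vectors, ids=None):
    g = hf.Gallery()
    ids = ids or [f"id{i}" for i in range(len(vectors))]
    for name, vec in zip(ids, vectors):
        hf.enroll(g, name, [np.asarray(vec, float)], merge=True)
    return g


def brute_force_rank(gallery, query, L):
    sims = [
        (hf.cosine_similarity(query, r.embedding), r.identity_id, r.order_index)
        for r in gallery.records
    ]
    sims.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(i, s) for s, i, _ in sims[:L]]


class TestRank:
    def test_enrolled_embedding_is_exact_top(self, embedding_gallery):
        query = embedding_gallery.records[3].embedding
        cands = rank(embedding_gallery, query, 5)
        assert cands[0].record == embedding_gallery.records[3]
        assert cands[0].score == pytest.approx(1.0)

    def test_three_vector_example(self):
        g = tiny_gallery([(1, 0), (0, 1), (-1, 0)], ["r1", "r2", "r3"])
        cands = rank(g, np.array([1.0, 0.1]), 3)
        assert [c.identity_id for c in cands] == ["r1", "r2", "r3"]

    def test_large_L_returns_all_records(self, embedding_gallery):
        assert len(rank(embedding_gallery, embedding_gallery.records[0].embedding, 10**6)) == len(
            embedding_gallery
        )

    def test_empty_gallery_rejected(self):
        with pytest.raises(EmptyGalleryError):
            rank(hf.Gallery(), np.ones(4), 5)

    def test_scores_sorted_non_increasing(self, embedding_gallery, rng):
        cands = rank(embedding_gallery, rng.standard_normal(64), 20)
        scores = [c.score for c in cands]
        assert scores == sorted(scores, reverse=True)

    def test_matches_brute_force_sort_oracle(self):
        """Full-sort oracle equivalence on many random small galleries."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            vecs = rng.standard_normal((n, 6))
            ids = [f"id{int(rng.integers(0, 8))}" for _ in range(n)]
            g = hf.Gallery()
            for name in dict.fromkeys(ids):
                rows = [vecs[i] for i in range(n) if ids[i] == name]
                hf.enroll(g, name, rows, hf.EnrollmentConfig(diversity_threshold=1.0))
            q = rng.standard_normal(6)
            got = [(c.identity_id, c.score) for c in rank(g, q, 10)]
            want = brute_force_rank(g, q, 10)
            assert [i for i, _ in got] == [i for i, _ in want]
            np.testing.assert_allclose(
                [s for _, s in got], [s for _, s in want], atol=1e-12
            )


class TestApplyThreshold:
    def make(self, scores):
        g = tiny_gallery([(1, 0)] * len(scores), [f"id{i}" for i in range(len(scores))])
        return [hf.Candidate(g.records[i], s) for i, s in enumerate(scores)]

    def test_top_score_above_threshold_accepted(self):
        res = apply_threshold(self.make([0.70, 0.5]), 0.68)
        assert res.pip_id == "id0" and res.pip_score == 0.70

    def test_score_equal_to_threshold_rejected(self):
        res = apply_threshold(self.make([0.68]), 0.68)
        assert res.pip_id == UNIDENTIFIED
        assert res.pip_score == 0.68  # pipScore reported regardless

    def test_relaxed_threshold_accepts_weak_match(self):
        assert apply_threshold(self.make([0.01]), 0.0).pip_id == "id0"

    def test_empty_candidates(self):
        res = apply_threshold([], 0.5)
        assert res.pip_id == UNIDENTIFIED and math.isnan(res.pip_score)

    def test_raising_threshold_never_unrejects(self):
        """Monotone acceptance: once UNIDENTIFIED, higher T stays UNIDENTIFIED."""
        cands = self.make([0.42])
        accepted = [apply_threshold(cands, t).accepted for t in np.linspace(-1, 1, 101)]
        assert accepted == sorted(accepted, reverse=True)


class TestVoteTopR:
    def make(self, labeled_scores):
        g = hf.Gallery()
        keep_all = hf.EnrollmentConfig(diversity_threshold=1.0)
        for i, (ident, _) in enumerate(labeled_scores):
            hf.enroll(g, ident, [np.array([1.0, float(i)])], keep_all, merge=True)
        recs = []
        k = {}
        for ident, score in labeled_scores:
            recs.append(hf.Candidate(g.records_for(ident)[k.setdefault(ident, 0)], score))
            k[ident] += 1
        return recs

    def test_r1_is_top_candidate(self):
        cands = self.make([("A", 0.9), ("B", 0.8)])
        assert vote_top_r(cands, 1) == "A"

    def test_majority_wins(self):
        cands = self.make([("A", 0.9), ("B", 0.8), ("B", 0.7), ("C", 0.6), ("B", 0.5)])
        assert vote_top_r(cands, 5) == "B"

    def test_tie_broken_by_best_score(self):
        cands = self.make([("A", 0.9), ("B", 0.8), ("A", 0.7), ("B", 0.6)])
        assert vote_top_r(cands, 4) == "A"

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            vote_top_r([], 3)

    @settings(derandomize=True, max_examples=300)
    @given(
        labels=st.lists(st.sampled_from("ABCD"), min_size=1, max_size=10),
        r=st.integers(1, 10),
    )
    def test_matches_exhaustive_count_oracle(self, labels, r):
        scores = [1.0 - 0.05 * i for i in range(len(labels))]
        cands = self.make(list(zip(labels, scores)))
        winner = vote_top_r(cands, r)
        window = labels[: min(r, len(labels))]
        counts = Counter(window)
        assert counts[winner] == max(counts.values())
        # among max-count labels, winner holds the single best (earliest) score
        tied = [l for l, c in counts.items() if c == counts[winner]]
        assert winner == min(tied, key=lambda l: window.index(l))

    def test_vote_r1_equals_pip_id_when_accepted(self, embedding_gallery, rng):
        for _ in range(50):
            q = rng.standard_normal(64)
            cands = rank(embedding_gallery, q, 10)
            res = apply_threshold(cands, 0.0)
            if res.accepted:
                assert vote_top_r(cands, 1) == res.pip_id


class TestIdentify:
    def test_identify_composes_rank_threshold_vote(self, embedding_gallery, identities, rng):
        mate = identities[0]
        q = hf.sample_embedding(mate, rng)
        res = hf.identify(
            embedding_gallery, q, hf.LookupConfig(threshold=0.68, candidate_list_length=10, top_r=5)
        )
        assert res.pip_id == mate.identity_id
        assert res.pip_score > 0.68

    def test_nonmate_probe_rejected_at_operating_threshold(
        self, embedding_gallery, identities, rng
    ):
        nonmate = [i for i in identities if not i.is_mate][0]
        res = hf.identify(
            embedding_gallery,
            hf.sample_embedding(nonmate, rng),
            hf.LookupConfig(threshold=0.68),
        )
        assert res.pip_id == UNIDENTIFIED

    def test_config_validates_r_le_l(self):
        with pytest.raises(InvalidInputError):
            hf.LookupConfig(candidate_list_length=5, top_r=6)
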