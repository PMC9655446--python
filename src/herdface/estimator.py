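"""scikit-learn estimator facade over the gallery/lookup core.

:class:`OpenSetIdentifier` is an open-set nearest-chip classifier: ``fit``
enrolls labeled embeddings into a gallery (with the same greedy diversity
sampling used by the enrollment pipeline), ``predict`` runs the
rank/threshold/vote lookup per query and returns either an enrolled label
or the reject value ``"UNIDENTIFIED"``. It composes with sklearn model
selection and pipelines; the heavy lifting stays in :mod:`herdface.gallery`
and :mod:`herdface.lookup`, so the estimator and the CLI pipeline can never
disagree.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .gallery import EnrollmentConfig, Gallery, enroll
from .lookup import LookupConfig, apply_threshold, rank, vote_top_r

__all__ = ["OpenSetIdentifier"]


class OpenSetIdentifier(ClassifierMixin, BaseEstimator):
    """Open-set identification by cosine similarity against enrolled chips.

    Parameters
    ----------
    threshold : float, default=0.0
        Acceptance threshold T; the top score must be strictly greater to
        return a label instead of ``"UNIDENTIFIED"``.
    n_candidates : int, default=10
        Candidate list length L kept per query.
    top_r : int, default=1
        Number of top candidates examined by the voting rule (R <= L).
    nim_target : int, default=25
        Maximum records enrolled per identity at fit time.
    diversity_threshold : float, default=0.9
        Greedy enrollment keeps a sample only when its similarity to every
        previously kept sample of the same identity is strictly below this.

    Attributes
    ----------
    gallery_ : Gallery
        The enrolled reference database.
    classes_ : ndarray of str
        Enrolled identity labels (the reject value is not a class).
    n_features_in_ : int
        Embedding dimension seen at fit.
    """

    def __init__(
        self,
        threshold: float = 0.0,
        n_candidates: int = 10,
        top_r: int = 1,
        nim_target: int = 25,
        diversity_threshold: float = 0.9,
    ):
        self.threshold = threshold
        self.n_candidates = n_candidates
        self.top_r = top_r
        self.nim_target = nim_target
        self.diversity_threshold = diversity_threshold

    def _lookup_config(self) -> LookupConfig:
        return LookupConfig(
            threshold=self.threshold,
            candidate_list_length=self.n_candidates,
            top_r=self.top_r,
        )

    def fit(self, X, y):
        """Enroll labeled embeddings: one gallery identity per unique label."""
        self._lookup_config()  # validate hyperparameters early
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D embedding array")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        cfg = EnrollmentConfig(
            nim_target=self.nim_target, diversity_threshold=self.diversity_threshold
        )
        gallery = Gallery()
        labels = [str(v) for v in y]
        for label in dict.fromkeys(labels):  # first-appearance order
            rows = [X[i] for i, l in enumerate(labels) if l == label]
            enroll(gallery, label, rows, cfg)
        self.gallery_ = gallery
        self.classes_ = np.array(sorted(set(labels)))
        self.n_features_in_ = X.shape[1]
        return self

    def _rank_row(self, row):
        return rank(self.gallery_, row, self.n_candidates)

    def predict(self, X):
        """Per query: rank, threshold the top score, vote among the top R."""
        check_is_fitted(self, "gallery_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = []
        for row in X:
            cands = self._rank_row(row)
            result = apply_threshold(cands, self.threshold)
            if result.accepted and self.top_r > 1:
                out.append(vote_top_r(cands, self.top_r))
            else:
                out.append(result.pip_id)
        return np.array(out, dtype=object)

    def decision_function(self, X):
        """Top cosine similarity per query (the pipScore)."""
        check_is_fitted(self, "gallery_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self._rank_row(row)[0].score for row in X])

    def kneighbors_labels(self, X):
        """Ranked candidate (label, score) lists, one per query row."""
        check_is_fitted(self, "gallery_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return [
            [(c.identity_id, c.score) for c in self._rank_row(row)] for row in X
        ]

    def score(self, X, y):
        """Closed-set accuracy counting UNIDENTIFIED as a wrong answer."""
        pred = self.predict(X)
        truth = np.array([str(v) for v in np.asarray(y)], dtype=object)
        return float(np.mean(pred == truth))

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"X_types": ["2darray"], "requires_y": True}
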